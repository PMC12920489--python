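"""Domain scorers, composite MRIx, categories and the close-margin override."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrix import (
    compute_mrix,
    enumerate_score_table,
    score_cohort,
    score_histopathology,
    score_immune,
    score_molecular,
    score_tumor_burden,
)
from mrix.config import ScoringConfig
from mrix.exceptions import ConfigurationError, MRIxError, SchemaError

CAT_RANK = {"low": 0, "intermediate": 1, "high": 2}


@pytest.mark.parametrize(
    "tls, expected",
    [(3.2, 0), (3.0, 0), (10.0, 0), (2.99, 1), (1.0, 1), (0.99, 2), (0.5, 2), (0.0, 2)],
)
def test_histopathology_bands(tls, expected):
    assert score_histopathology(tls) == expected


@pytest.mark.parametrize(
    "panck, ki67, expected",
    [
        (0.0, 3.0, 0),     # no residual tumor cells, quiescent
        (6.0, 25.0, 2),    # heavy burden, highly proliferative
        (0.0, 25.0, 2),    # discordant: Ki-67 dominates (max rule)
        (0.5, 3.0, 1),
        (0.0, 20.0, 1),    # Ki-67 exactly 20 is intermediate
        (5.0, 0.0, 2),
        (4.99, 4.99, 1),
    ],
)
def test_tumor_burden_bands(panck, ki67, expected):
    assert score_tumor_burden(panck, ki67) == expected


@pytest.mark.parametrize(
    "nmut, pdl1, expected",
    [
        (0, 0.6, 0),
        (2, 2.5, 2),
        (1, 0.5, 1),   # a single mutation dominates a favourable PD-L1
        (0, 1.0, 1),   # PD-L1 exactly 1-fold is intermediate
        (0, 2.0, 1),
        (0, 2.01, 2),
        (3, 0.0, 2),
    ],
)
def test_molecular_bands(nmut, pdl1, expected):
    assert score_molecular(nmut, pdl1) == expected


@pytest.mark.parametrize(
    "ratio, gzmb, expected",
    [
        (2.4, 250.0, 0),
        (0.8, 30.0, 2),
        (1.95, 250.0, 1),          # the 1.9-2.0 ratio gap closes downward
        (2.0, 200.0, 1),           # Granzyme B exactly 200 is intermediate
        (2.0, 50.0, 1),
        (5.0, 49.9, 2),
        (math.inf, 250.0, 0),      # CD8 present, no FoxP3: favourable ratio
        (math.nan, 250.0, 2),      # neither cell type: no cytotoxic infiltrate
    ],
)
def test_immune_bands(ratio, gzmb, expected):
    assert score_immune(ratio, gzmb) == expected


@pytest.mark.parametrize(
    "scorer, args",
    [
        (score_histopathology, (-0.1,)),
        (score_tumor_burden, (-1.0, 10.0)),
        (score_tumor_burden, (1.0, 101.0)),
        (score_molecular, (-1, 1.0)),
        (score_molecular, (0.5, 1.0)),
        (score_immune, (-0.5, 10.0)),
        (score_immune, (1.0, -10.0)),
    ],
)
def test_invalid_biomarkers_rejected(scorer, args):
    with pytest.raises(MRIxError):
        scorer(*args)


@pytest.mark.parametrize(
    "scores, margin, exp_score, exp_cat, exp_override",
    [
        ((0, 0, 0, 0), 8.0, 0.0, "low", False),
        ((2, 2, 2, 2), 8.0, 2.0, "high", False),
        ((2, 1, 1, 1), 8.0, 1.3, "intermediate", False),
        ((0, 0, 0, 0), 1.5, 0.0, "high", True),     # close-margin override
        ((0, 0, 0, 0), 2.0, 0.0, "high", True),     # boundary: exactly 2 mm
        ((2, 1, 0, 0), 8.0, 0.85, "intermediate", False),  # 0.85 rounds to 0.9
        ((1, 2, 1, 2), 8.0, 1.45, "high", False),          # 1.45 rounds to 1.5
        ((1, 1, 1, 1), 8.0, 1.0, "intermediate", False),
    ],
)
def test_composite_and_category(scores, margin, exp_score, exp_cat, exp_override):
    res = compute_mrix(scores, margin)
    assert res.score == pytest.approx(exp_score, abs=1e-12)
    assert res.category == exp_cat
    assert res.override_applied is exp_override


def test_bad_weights_rejected():
    with pytest.raises(ConfigurationError):
        ScoringConfig(weights=(0.5, 0.25, 0.25, 0.25))


def test_enumeration_grid_and_monotonicity():
    """All 81 combinations: score grid, range, and category monotone in each domain."""
    tab = enumerate_score_table()
    assert len(tab) == 81
    assert tab.mrix_score.min() == 0.0
    assert tab.mrix_score.max() == 2.0
    steps = np.round(tab.mrix_score / 0.05)
    assert np.allclose(steps * 0.05, tab.mrix_score, atol=1e-12)
    lookup = {
        tuple(r[:4]): CAT_RANK[r[5]]
        for r in tab.itertuples(index=False)
    }
    for combo, rank in lookup.items():
        for i in range(4):
            if combo[i] < 2:
                upper = list(combo)
                upper[i] += 1
                assert lookup[tuple(upper)] >= rank


@given(st.floats(0, 12), st.floats(0, 12))
def test_histopathology_monotone_in_tls(a, b):
    lo, hi = sorted((a, b))
    assert score_histopathology(lo) >= score_histopathology(hi)


@given(st.floats(0, 20), st.floats(0, 20), st.floats(0, 100))
def test_tumor_burden_monotone_in_panck(a, b, ki67):
    lo, hi = sorted((a, b))
    assert score_tumor_burden(hi, ki67) >= score_tumor_burden(lo, ki67)


@given(st.floats(0, 8), st.floats(0, 8), st.integers(0, 4))
def test_molecular_monotone_in_pdl1(a, b, nmut):
    lo, hi = sorted((a, b))
    assert score_molecular(nmut, hi) >= score_molecular(nmut, lo)


@given(st.floats(0, 6), st.floats(0, 6), st.floats(0, 400))
def test_immune_monotone_in_ratio(a, b, gzmb):
    lo, hi = sorted((a, b))
    assert score_immune(lo, gzmb) >= score_immune(hi, gzmb)


def test_score_cohort_appends_without_mutating(training_cohort):
    cols_before = list(training_cohort.columns)
    raw = training_cohort[
        [c for c in training_cohort.columns if "score" not in c and "category" not in c
         and c != "override_applied"]
    ]
    out = score_cohort(raw)
    assert list(raw.columns) == [c for c in cols_before if c in raw.columns]
    assert set(out.columns) >= {"mrix_score", "mrix_category", "override_applied"}
    assert out.mrix_score.between(0, 2).all()
    # the override always lands in the high category
    assert (out.loc[out.override_applied, "mrix_category"] == "high").all()
    # every override has a margin at or under 2 mm and vice versa
    assert (out.override_applied == (out.margin_mm <= 2.0)).all()


def test_score_cohort_missing_column_named():
    df = pd.DataFrame({"tls_density": [1.0]})
    with pytest.raises(SchemaError, match="ki67_pct"):
        score_cohort(df)
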