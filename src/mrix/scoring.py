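"""Margin Risk Index (MRIx) scoring.

Four biological domains of the post-treatment surgical margin are each
graded 0 (low risk), 1 (intermediate) or 2 (high risk):

* histopathology — tertiary lymphoid structure (TLS) density per mm²;
* tumor burden — residual Pan-CK+ foci per mm² and the Ki-67 index (%);
* molecular — driver-mutation count (TP53/NOTCH1 panel) and PD-L1 RNA
  fold-change versus normal mucosa;
* immune contexture — CD8+/FoxP3+ T-cell ratio and Granzyme B+ cell
  density per mm².

Domains with two sub-markers take the worse (maximum) sub-criterion level,
a conservative rule for profiles that straddle bands.  The composite is a
weighted sum (default weights 0.30/0.25/0.25/0.20) on [0, 2]; categories
are read off the composite after half-up rounding to one decimal
(low <= 0.8, intermediate 0.9-1.4, high >= 1.5).  A resection margin of
<= 2 mm is an automatic high-risk indicator that overrides the numeric
category without changing the score itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .config import DOMAINS, ScoringConfig
from .exceptions import MRIxError, SchemaError

CATEGORIES = ("low", "intermediate", "high")

#: Raw biomarker columns required to score a cohort row.
BIOMARKER_COLUMNS = (
    "tls_density",
    "panck_foci",
    "ki67_pct",
    "n_driver_mutations",
    "pdl1_fold",
    "cd8_foxp3_ratio",
    "gzmb_density",
    "margin_mm",
)

SCORE_COLUMNS = tuple(f"{d}_score" for d in DOMAINS)


@dataclass(frozen=True)
class MarginBiomarkers:
    """Raw margin measurements for one patient."""

    tls_density: float
    panck_foci: float
    ki67_pct: float
    n_driver_mutations: int
    pdl1_fold: float
    cd8_foxp3_ratio: float
    gzmb_density: float
    margin_mm: float

    def __post_init__(self) -> None:
        for name in ("tls_density", "panck_foci", "pdl1_fold", "gzmb_density", "margin_mm"):
            v = getattr(self, name)
            if v < 0:
                raise MRIxError(f"{name} must be >= 0, got {v!r}")
        if not 0 <= self.ki67_pct <= 100:
            raise MRIxError(f"ki67_pct must lie in [0, 100], got {self.ki67_pct!r}")
        if self.n_driver_mutations < 0:
            raise MRIxError("n_driver_mutations must be >= 0")
        ratio = self.cd8_foxp3_ratio
        if not math.isnan(ratio) and ratio < 0:
            raise MRIxError("cd8_foxp3_ratio must be >= 0 (NaN = no T cells at all)")


@dataclass(frozen=True)
class DomainScores:
    histopathology: int
    tumor_burden: int
    molecular: int
    immune: int

    def __post_init__(self) -> None:
        for d in DOMAINS:
            if getattr(self, d) not in (0, 1, 2):
                raise MRIxError(f"domain score {d} must be 0, 1 or 2")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return tuple(getattr(self, d) for d in DOMAINS)


@dataclass(frozen=True)
class MRIxResult:
    """Composite score on [0, 2], risk category and the override flag."""

    score: float
    category: str
    override_applied: bool


def _check_nonneg(name: str, value: float) -> None:
    if value < 0 or math.isnan(value):
        raise MRIxError(f"{name} must be a non-negative number, got {value!r}")


def score_histopathology(tls_density: float) -> int:
    """TLS density per mm²: >=3 low, [1, 3) intermediate, <1 high."""
    _check_nonneg("tls_density", tls_density)
    if tls_density >= 3:
        return 0
    if tls_density >= 1:
        return 1
    return 2


def score_tumor_burden(panck_foci: float, ki67_pct: float) -> int:
    """Worse of Pan-CK foci level (0 / (0,5) / >=5) and Ki-67 level (<5 / 5-20 / >20)."""
    _check_nonneg("panck_foci", panck_foci)
    _check_nonneg("ki67_pct", ki67_pct)
    if ki67_pct > 100:
        raise MRIxError(f"ki67_pct must lie in [0, 100], got {ki67_pct!r}")
    panck_level = 0 if panck_foci == 0 else (1 if panck_foci < 5 else 2)
    ki67_level = 0 if ki67_pct < 5 else (1 if ki67_pct <= 20 else 2)
    return max(panck_level, ki67_level)


def score_molecular(n_driver_mutations: int, pdl1_fold: float) -> int:
    """Worse of mutation count (0 / 1 / >=2) and PD-L1 fold (<1 / 1-2 / >2)."""
    if n_driver_mutations < 0 or n_driver_mutations != int(n_driver_mutations):
        raise MRIxError("n_driver_mutations must be a non-negative integer")
    _check_nonneg("pdl1_fold", pdl1_fold)
    mut_level = min(int(n_driver_mutations), 2)
    pdl1_level = 0 if pdl1_fold < 1 else (1 if pdl1_fold <= 2 else 2)
    return max(mut_level, pdl1_level)


def score_immune(cd8_foxp3_ratio: float, gzmb_density: float) -> int:
    """Worse of CD8+/FoxP3+ ratio level (>=2 / [1,2) / <1) and Granzyme B level.

    A ratio of +inf (CD8 present, no FoxP3 cells) is a favourable level 0;
    NaN encodes the degenerate margin with neither cell type and maps to
    level 2 (no cytotoxic infiltrate).
    """
    _check_nonneg("gzmb_density", gzmb_density)
    if math.isnan(cd8_foxp3_ratio):
        ratio_level = 2
    else:
        if cd8_foxp3_ratio < 0:
            raise MRIxError("cd8_foxp3_ratio must be >= 0")
        ratio_level = 0 if cd8_foxp3_ratio >= 2 else (1 if cd8_foxp3_ratio >= 1 else 2)
    gzmb_level = 0 if gzmb_density > 200 else (1 if gzmb_density >= 50 else 2)
    return max(ratio_level, gzmb_level)


def score_domains(biomarkers: MarginBiomarkers) -> DomainScores:
    return DomainScores(
        histopathology=score_histopathology(biomarkers.tls_density),
        tumor_burden=score_tumor_burden(biomarkers.panck_foci, biomarkers.ki67_pct),
        molecular=score_molecular(biomarkers.n_driver_mutations, biomarkers.pdl1_fold),
        immune=score_immune(biomarkers.cd8_foxp3_ratio, biomarkers.gzmb_density),
    )


def _round_half_up_1dp(x: Decimal) -> Decimal:
    return x.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)


def compute_mrix(
    domain_scores: DomainScores | tuple[int, int, int, int],
    margin_mm: float,
    config: ScoringConfig | None = None,
) -> MRIxResult:
    """Weighted composite, risk category and close-margin override.

    The composite is computed exactly in decimal arithmetic (with default
    weights it is a multiple of 0.05); the category lookup uses the score
    rounded half-up to one decimal so the two attainable values falling
    between the printed bins (0.85, 1.45) are assigned upward.
    """
    config = config or ScoringConfig()
    if isinstance(domain_scores, tuple):
        domain_scores = DomainScores(*domain_scores)
    if margin_mm < 0 or math.isnan(margin_mm):
        raise MRIxError("margin_mm must be >= 0")
    score_dec = sum(
        (Decimal(str(w)) * s for w, s in zip(config.weights, domain_scores.as_tuple())),
        Decimal(0),
    )
    rounded = _round_half_up_1dp(score_dec)
    if rounded <= Decimal(str(config.low_max)):
        category = "low"
    elif rounded >= Decimal(str(config.high_min)):
        category = "high"
    else:
        category = "intermediate"
    override = margin_mm <= config.override_margin_mm
    if override:
        category = "high"
    return MRIxResult(score=float(score_dec), category=category, override_applied=override)


def score_cohort(cohort: pd.DataFrame, config: ScoringConfig | None = None) -> pd.DataFrame:
    """Append domain scores, the MRIx composite, category and override flag.

    Pure function: the input frame is not mutated.  Raises
    :class:`SchemaError` naming any missing biomarker column.
    """
    config = config or ScoringConfig()
    missing = [c for c in BIOMARKER_COLUMNS if c not in cohort.columns]
    if missing:
        raise SchemaError(f"missing biomarker column(s): {', '.join(missing)}")
    out = cohort.copy()
    scores = {d: np.empty(len(out), dtype=int) for d in DOMAINS}
    mrix_score = np.empty(len(out))
    mrix_cat = np.empty(len(out), dtype=object)
    override = np.empty(len(out), dtype=bool)
    for i, row in enumerate(out[list(BIOMARKER_COLUMNS)].itertuples(index=False)):
        ds = DomainScores(
            histopathology=score_histopathology(row.tls_density),
            tumor_burden=score_tumor_burden(row.panck_foci, row.ki67_pct),
            molecular=score_molecular(row.n_driver_mutations, row.pdl1_fold),
            immune=score_immune(row.cd8_foxp3_ratio, row.gzmb_density),
        )
        res = compute_mrix(ds, row.margin_mm, config)
        for d in DOMAINS:
            scores[d][i] = getattr(ds, d)
        mrix_score[i] = res.score
        mrix_cat[i] = res.category
        override[i] = res.override_applied
    for d in DOMAINS:
        out[f"{d}_score"] = scores[d]
    out["mrix_score"] = mrix_score
    out["mrix_category"] = mrix_cat
    out["override_applied"] = override
    return out


def enumerate_score_table(config: ScoringConfig | None = None) -> pd.DataFrame:
    """All 81 domain-score combinations with composite and category.

    Useful both as documentation of the rubric and as an exhaustive check
    that the category is monotone non-decreasing in every domain score.
    """
    config = config or ScoringConfig()
    rows = []
    for h in range(3):
        for tb in range(3):
            for m in range(3):
                for im in range(3):
                    res = compute_mrix((h, tb, m, im), margin_mm=10.0, config=config)
                    rows.append(
                        dict(
                            histopathology=h,
                            tumor_burden=tb,
                            molecular=m,
                            immune=im,
                            mrix_score=res.score,
                            mrix_category=res.category,
                        )
                    )
    return pd.DataFrame(rows)
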