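"""Study orchestration: cohort characterisation, domain-level survival
associations, the adjusted multivariable MRIx model, nested model
comparison, and the frozen-score external-validation workflow.

All multivariable models use the same dummy coding with fixed reference
levels (well differentiation, pathologic complete response, low-risk MRIx,
clear margin) and are fitted with the package's own Cox kernel; nested
comparisons are made on the identical complete-case row set so AIC and
likelihood-ratio comparisons are valid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import survival
from .config import DOMAINS, ENDPOINTS, ScoringConfig
from .exceptions import FitError, MRIxError
from .io import CLINICAL_COLUMNS, percent_half_up
from .scoring import CATEGORIES, score_cohort
from .survival import CoxFitResult

logger = logging.getLogger("mrix")

#: Fixed reference level and ordered non-reference levels per model term.
MODEL_TERMS: dict[str, tuple[str, tuple[str, ...]]] = {
    "differentiation": ("well", ("moderate", "poor")),
    "pathologic_response": ("pCR", ("mPR_not_pCR", "no_mPR")),
    "mrix_category": ("low", ("intermediate", "high")),
    "margin_class": ("clear", ("close",)),
}

CLINICAL_MODEL = ("differentiation", "pathologic_response")
TRADITIONAL_MODEL = CLINICAL_MODEL + ("margin_class",)
MRIX_MODEL = CLINICAL_MODEL + ("mrix_category",)
VALIDATION_ADJUSTMENT = CLINICAL_MODEL + ("margin_class", "mrix_category")


def build_design(df: pd.DataFrame, covariates) -> tuple[np.ndarray, tuple[str, ...]]:
    """Dummy-coded design matrix with fixed reference levels.

    Raises :class:`FitError` naming any reference or non-reference level
    with no patients (a degenerate factor cannot be fitted).
    """
    cols, names = [], []
    for cov in covariates:
        ref, levels = MODEL_TERMS[cov]
        present = df[cov].to_numpy()
        if not (present == ref).any():
            raise FitError(f"reference level {ref!r} of {cov!r} has no patients")
        for lvl in levels:
            ind = (present == lvl).astype(float)
            if ind.sum() == 0:
                raise FitError(f"level {lvl!r} of {cov!r} has no patients")
            cols.append(ind)
            names.append(f"{cov}={lvl}")
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, tuple(names)


def _complete_cases(df: pd.DataFrame, columns) -> pd.DataFrame:
    out = df.dropna(subset=[c for c in columns if c in df.columns])
    dropped = len(df) - len(out)
    if dropped:
        logger.info("complete-case filter excluded %d of %d rows", dropped, len(df))
    return out


# ---------------------------------------------------------------------------
# Baseline characteristics
# ---------------------------------------------------------------------------

def baseline_table(cohort_a: pd.DataFrame, cohort_b: pd.DataFrame,
                   covariates=CLINICAL_COLUMNS) -> pd.DataFrame:
    """Per-covariate counts, percentages and a between-cohort test.

    Pearson chi-square on the full contingency table; Fisher's exact test
    for 2x2 tables with any expected cell below 5 (larger sparse tables
    fall back to chi-square with a flag in the ``test`` column).
    """
    if len(cohort_a) == 0 or len(cohort_b) == 0:
        raise MRIxError("baseline table requires non-empty cohorts")
    rows = []
    for cov in covariates:
        levels = [lvl for lvl in pd.unique(pd.concat([cohort_a[cov], cohort_b[cov]]))]
        counts = np.array([
            [(cohort_a[cov] == lvl).sum() for lvl in levels],
            [(cohort_b[cov] == lvl).sum() for lvl in levels],
        ])
        counts = counts[:, counts.sum(axis=0) > 0]
        levels = [lvl for lvl in levels if (cohort_a[cov] == lvl).sum() + (cohort_b[cov] == lvl).sum() > 0]
        if counts.shape[1] < 2 or np.array_equal(counts[0], counts[1]):
            # identical distributions (or a single level): zero statistic
            p, test = (1.0, "chi2") if counts.shape[1] >= 2 else (np.nan, "none")
        else:
            expected = np.outer(counts.sum(1), counts.sum(0)) / counts.sum()
            if counts.shape == (2, 2) and (expected < 5).any():
                _, p = sps.fisher_exact(counts)
                test = "fisher"
            else:
                stat, p, _, _ = sps.chi2_contingency(counts, correction=False)
                test = "chi2" if not (expected < 5).any() else "chi2(small cells)"
        for j, lvl in enumerate(levels):
            rows.append({
                "covariate": cov,
                "level": lvl,
                "n_a": int(counts[0, j]),
                "pct_a": percent_half_up(counts[0, j], len(cohort_a)),
                "n_b": int(counts[1, j]),
                "pct_b": percent_half_up(counts[1, j], len(cohort_b)),
                "p": float(p) if p == p else np.nan,
                "test": test,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Domain-level survival associations
# ---------------------------------------------------------------------------

def domain_outcome_analysis(scored: pd.DataFrame) -> pd.DataFrame:
    """Log-rank test across the three levels of each domain, per endpoint.

    Domain levels with no patients are dropped with a warning; the eight
    p-values (4 domains x 2 endpoints) are Benjamini-Hochberg adjusted.
    """
    rows = []
    for dom in DOMAINS:
        col = f"{dom}_score"
        levels = sorted(scored[col].unique())
        missing = [l for l in (0, 1, 2) if l not in levels]
        if missing:
            warnings.warn(f"domain {dom!r}: level(s) {missing} have no patients and "
                          "were dropped", stacklevel=2)
        for ep in ENDPOINTS:
            if len(levels) < 2:
                rows.append({"domain": dom, "endpoint": ep, "n_levels": len(levels),
                             "chi2": np.nan, "df": 0, "p": np.nan})
                continue
            chi2, df, p = survival.logrank_test(
                scored[f"{ep}_time_months"], scored[f"{ep}_event"], scored[col]
            )
            rows.append({"domain": dom, "endpoint": ep, "n_levels": len(levels),
                         "chi2": chi2, "df": df, "p": p})
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    adj = np.full(len(out), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = survival.bh_adjust(out.loc[ok, "p"].to_numpy())
    out["p_adj"] = adj
    return out


# ---------------------------------------------------------------------------
# Adjusted multivariable MRIx model
# ---------------------------------------------------------------------------

def fit_adjusted_mrix_model(scored: pd.DataFrame, endpoint: str,
                            covariates=MRIX_MODEL) -> CoxFitResult:
    """Multivariable Cox model: differentiation + pathologic response + MRIx
    category (references: well / pCR / low)."""
    if endpoint not in ENDPOINTS:
        raise MRIxError(f"unknown endpoint {endpoint!r}")
    needed = list(covariates) + [f"{endpoint}_time_months", f"{endpoint}_event"]
    df = _complete_cases(scored, needed)
    X, names = build_design(df, covariates)
    return survival.fit_cox(
        df[f"{endpoint}_time_months"], df[f"{endpoint}_event"], X, names=names
    )


# ---------------------------------------------------------------------------
# Nested model comparison
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    """C-index, AIC and likelihood-ratio chain for the three nested models."""

    endpoint: str
    labels: tuple[str, ...]
    fits: dict[str, CoxFitResult]
    c_index: dict[str, float]
    c_ci: dict[str, tuple[float, float]]
    lrt_vs_reference: dict[str, tuple[float, int, float]]
    lrt_vs_previous: dict[str, tuple[float, int, float]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lab in self.labels:
            row = {
                "model": lab,
                "c_index": self.c_index[lab],
                "c_ci_low": self.c_ci[lab][0],
                "c_ci_high": self.c_ci[lab][1],
                "aic": self.fits[lab].aic,
                "k": self.fits[lab].k,
            }
            for key, store in (("vs_reference", self.lrt_vs_reference),
                               ("vs_previous", self.lrt_vs_previous)):
                if lab in store:
                    chi2, df, p = store[lab]
                    row.update({f"lrt_{key}_chi2": chi2, f"lrt_{key}_df": df,
                                f"lrt_{key}_p": p})
            rows.append(row)
        return pd.DataFrame(rows)


def _c_index_with_ci(risk, time, event, rng: np.random.Generator,
                     n_boot: int = 200) -> tuple[float, tuple[float, float]]:
    c = survival.harrell_c(risk, time, event)
    n = len(risk)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            boots.append(survival.harrell_c(risk[idx], time[idx], event[idx]))
        except MRIxError:
            continue
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = np.nan
    return c, (float(lo), float(hi))


def compare_models(scored: pd.DataFrame, endpoint: str, n_boot: int = 200,
                   seed: int = 0) -> ModelComparison:
    """Fit Clinical, Clinical+traditional margin and Clinical+MRIx on the
    identical complete-case rows; report C-index (bootstrap percentile CI),
    AIC, and LRTs against the clinical reference and the previous model."""
    specs = {
        "clinical": CLINICAL_MODEL,
        "clinical+margin": TRADITIONAL_MODEL,
        "clinical+mrix": MRIX_MODEL,
    }
    all_cols = sorted({c for covs in specs.values() for c in covs})
    needed = all_cols + [f"{endpoint}_time_months", f"{endpoint}_event"]
    df = _complete_cases(scored, needed)
    time = df[f"{endpoint}_time_months"].to_numpy()
    event = df[f"{endpoint}_event"].to_numpy()
    rng = np.random.default_rng(seed)
    fits, c_index, c_ci = {}, {}, {}
    for lab, covs in specs.items():
        X, names = build_design(df, covs)
        try:
            fit = survival.fit_cox(time, event, X, names=names)
        except (FitError, MRIxError) as exc:
            raise FitError(f"model {lab!r} could not be fitted: {exc}") from exc
        fits[lab] = fit
        risk = X @ fit.coef
        c_index[lab], c_ci[lab] = _c_index_with_ci(risk, time, event, rng, n_boot)
    labels = tuple(specs)
    vs_ref, vs_prev = {}, {}
    for i, lab in enumerate(labels[1:], start=1):
        vs_ref[lab] = survival.lrt(fits["clinical"], fits[lab])
        # the margin -> MRIx step swaps one term for another; compare by
        # 2*delta-loglik without the strict nesting requirement
        vs_prev[lab] = survival.lrt(fits[labels[i - 1]], fits[lab], check_nested=False)
    return ModelComparison(endpoint=endpoint, labels=labels, fits=fits,
                           c_index=c_index, c_ci=c_ci,
                           lrt_vs_reference=vs_ref, lrt_vs_previous=vs_prev)


# ---------------------------------------------------------------------------
# Frozen-score external validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationBlock:
    """External-validation outputs per endpoint, under frozen scoring."""

    horizon: float
    km_logrank: dict[str, tuple[float, int, float]]
    c_index: dict[str, float]
    adjusted_fit: dict[str, CoxFitResult]
    calibration: dict[str, survival.CalibrationResult]

    def summary_dict(self) -> dict:
        out: dict = {"horizon_months": self.horizon}
        for ep in self.km_logrank:
            chi2, df, p = self.km_logrank[ep]
            fit = self.adjusted_fit[ep]
            cal = self.calibration[ep]
            out[ep] = {
                "logrank": {"chi2": chi2, "df": df, "p": p},
                "c_index": self.c_index[ep],
                "adjusted_hr": {n: float(h) for n, h in zip(fit.names, fit.hr)},
                "hl": {"chi2": cal.hl_chi2, "df": cal.hl_df, "p": cal.hl_p},
            }
        return out


def validate_external(frozen_config: ScoringConfig, cohort: pd.DataFrame,
                      horizon: float = 36.0, n_groups: int = 10) -> ValidationBlock:
    """Apply frozen MRIx thresholds/weights to an independent cohort.

    No re-estimation of weights or cuts occurs; the block reports 3-group
    Kaplan-Meier/log-rank stratification, the C-index of the continuous
    score, the adjusted Cox model (adding traditional margin status to the
    clinical adjustment set) and fixed-horizon calibration with the
    Hosmer-Lemeshow test.
    """
    scored = score_cohort(cohort, frozen_config)
    needed = list(VALIDATION_ADJUSTMENT) + [
        f"{ep}_{suffix}" for ep in ENDPOINTS for suffix in ("time_months", "event")
    ]
    scored = _complete_cases(scored, needed)
    km_logrank, c_index, fits, calib = {}, {}, {}, {}
    for ep in ENDPOINTS:
        time = scored[f"{ep}_time_months"].to_numpy()
        event = scored[f"{ep}_event"].to_numpy()
        present = [c for c in CATEGORIES if (scored["mrix_category"] == c).any()]
        if len(present) < 2:
            raise FitError("MRIx categories are degenerate in the validation cohort")
        km_logrank[ep] = survival.logrank_test(time, event, scored["mrix_category"])
        c_index[ep] = survival.harrell_c(scored["mrix_score"].to_numpy(), time, event)
        X, names = build_design(scored, VALIDATION_ADJUSTMENT)
        fit = survival.fit_cox(time, event, X, names=names)
        fits[ep] = fit
        baseline = survival.breslow_baseline(fit, time, event, X)
        lp = X @ fit.coef
        pred_event = 1.0 - survival.predict_survival(baseline, lp, horizon)
        calib[ep] = survival.hosmer_lemeshow_survival(pred_event, time, event,
                                                      horizon, n_groups=n_groups)
    return ValidationBlock(horizon=horizon, km_logrank=km_logrank,
                           c_index=c_index, adjusted_fit=fits, calibration=calib)


# ---------------------------------------------------------------------------
# Full study report
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    baseline_table: pd.DataFrame | None
    domain_km: pd.DataFrame
    table3_analog: dict[str, CoxFitResult]
    table4_analog: dict[str, ModelComparison]
    validation_block: ValidationBlock | None = None
    notes: list[str] = field(default_factory=list)

    def summary_dict(self) -> dict:
        out: dict = {"notes": self.notes}
        out["adjusted_models"] = {
            ep: {n: float(h) for n, h in zip(fit.names, fit.hr)}
            for ep, fit in self.table3_analog.items()
        }
        out["model_comparison"] = {
            ep: cmpres.to_frame().to_dict(orient="records")
            for ep, cmpres in self.table4_analog.items()
        }
        if self.validation_block is not None:
            out["validation"] = self.validation_block.summary_dict()
        return out


def run_training_analysis(cohort: pd.DataFrame,
                          scoring_config: ScoringConfig | None = None,
                          seed: int = 0, n_boot: int = 200) -> StudyReport:
    """Score the cohort (if needed) and run the training-cohort analyses."""
    scoring_config = scoring_config or ScoringConfig()
    scored = cohort if "mrix_category" in cohort.columns else score_cohort(cohort, scoring_config)
    domain_km = domain_outcome_analysis(scored)
    table3 = {ep: fit_adjusted_mrix_model(scored, ep) for ep in ENDPOINTS}
    table4 = {ep: compare_models(scored, ep, n_boot=n_boot, seed=seed) for ep in ENDPOINTS}
    return StudyReport(baseline_table=None, domain_km=domain_km,
                       table3_analog=table3, table4_analog=table4)
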