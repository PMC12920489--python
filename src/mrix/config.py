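"""Configuration objects for scoring and cohort simulation.

Two configuration families live here:

* :class:`ScoringConfig` — the domain weights, category cut-points and the
  close-margin override threshold of the Margin Risk Index (MRIx).
* :class:`SimulationConfig` — everything needed to generate a synthetic
  cohort: per-domain band marginals, clinical category marginals, true
  log-hazard effects per endpoint, baseline hazard and censoring.

The packaged defaults (:data:`TRAINING_DOMAIN_MARGINALS`,
:data:`TRAINING_CLINICAL_MARGINALS`, :data:`TRAINING_LOG_HR`, and the
validation-cohort analogues) reproduce the published training/validation
cohort marginal frequencies and adjusted hazard ratios, so the default
synthetic cohorts carry the statistical structure that the downstream
analyses assume.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import asdict, dataclass, field, replace

import yaml

from .exceptions import ConfigurationError

ENDPOINTS = ("lrc", "dmfs")

#: Domain order also fixes the weight order (w_H, w_TB, w_M, w_I).
DOMAINS = ("histopathology", "tumor_burden", "molecular", "immune")

#: Observed cohort event fractions used to calibrate the baseline hazard.
TARGET_EVENT_RATES = {"lrc": 0.181, "dmfs": 0.215}

#: Raw margin distance (mm) is drawn uniformly inside these ranges given the
#: sampled margin class; `close` spans 1-5 mm so a quarter of close margins
#: fall at or under the 2 mm override threshold.
CLOSE_MARGIN_RANGE_MM = (1.0, 5.0)
CLEAR_MARGIN_RANGE_MM = (5.0, 15.0)


@dataclass(frozen=True)
class ScoringConfig:
    """Weights, category cut-points and override rule of the MRIx.

    The composite is ``sum(weight[d] * score[d])`` over the four domains;
    the category is read off the composite after half-up rounding to one
    decimal: ``low`` if the rounded score is <= ``low_max``, ``high`` if
    >= ``high_min``, otherwise ``intermediate``.  A resection margin of
    ``override_margin_mm`` or less forces the ``high`` category regardless
    of the numeric score.
    """

    weights: tuple[float, float, float, float] = (0.30, 0.25, 0.25, 0.20)
    low_max: float = 0.8
    high_min: float = 1.5
    override_margin_mm: float = 2.0

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise ConfigurationError(
                f"domain weights must sum to 1, got {sum(self.weights)!r}"
            )
        if any(w < 0 for w in self.weights):
            raise ConfigurationError("domain weights must be non-negative")
        if not 0 < self.low_max < self.high_min:
            raise ConfigurationError("category cuts must satisfy 0 < low_max < high_min")
        if self.override_margin_mm < 0:
            raise ConfigurationError("override_margin_mm must be >= 0")

    @property
    def weight_map(self) -> dict[str, float]:
        return dict(zip(DOMAINS, self.weights))


@dataclass
class BaselineHazard:
    """Baseline hazard of the proportional-hazards data generator.

    ``exponential``: constant hazard ``rate`` per month.
    ``weibull``: hazard of a Weibull with the given ``shape`` and ``scale``
    (months); shape 1 recovers the exponential with rate ``1/scale``.
    """

    family: str = "exponential"
    rate: float = 0.005
    shape: float = 1.0
    scale: float = 200.0

    def validate(self) -> None:
        if self.family not in ("exponential", "weibull"):
            raise ConfigurationError(f"unknown baseline family {self.family!r}")
        if self.family == "exponential" and not self.rate > 0:
            raise ConfigurationError("exponential baseline rate must be > 0")
        if self.family == "weibull" and (self.shape <= 0 or self.scale <= 0):
            raise ConfigurationError("weibull shape and scale must be > 0")


@dataclass
class Censoring:
    """Administrative censoring window (months) plus optional random dropout.

    Administrative censoring time is uniform on [admin_min, admin_max],
    mirroring a follow-up window; ``random_rate`` > 0 adds an independent
    exponential dropout time.
    """

    admin_min: float = 24.0
    admin_max: float = 72.0
    random_rate: float = 0.0

    def validate(self) -> None:
        if not 0 < self.admin_min < self.admin_max:
            raise ConfigurationError("censoring window must satisfy 0 < min < max")
        if self.random_rate < 0:
            raise ConfigurationError("random censoring rate must be >= 0")


def _check_marginal(name: str, probs) -> None:
    probs = list(probs)
    if any(p < 0 for p in probs):
        raise ConfigurationError(f"negative probability in marginal {name!r}")
    if abs(sum(probs) - 1.0) > 1e-9:
        raise ConfigurationError(
            f"marginal {name!r} must sum to 1 (got {sum(probs)!r})"
        )


@dataclass
class SimulationConfig:
    """Full specification of a synthetic cohort.

    Attributes
    ----------
    n_patients
        Number of rows to generate (>= 1).
    domain_marginals
        Per-domain probability triple over the (low, intermediate, high)
        risk bands, keyed by :data:`DOMAINS`.
    clinical_marginals
        Per-covariate category probabilities, keyed by covariate name with
        an ordered ``{level: prob}`` mapping.
    true_log_hr
        ``endpoint -> covariate -> level -> log hazard ratio`` versus the
        covariate's reference level; levels absent from the mapping carry a
        log-HR of 0 only if they are the reference.
    baseline_hazard
        Per-endpoint :class:`BaselineHazard`.
    censoring
        Shared :class:`Censoring` for both endpoints.
    seed
        Seed for the cohort-level random generator.
    """

    n_patients: int = 144
    domain_marginals: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    clinical_marginals: dict[str, dict[str, float]] = field(default_factory=dict)
    true_log_hr: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    baseline_hazard: dict[str, BaselineHazard] = field(default_factory=dict)
    censoring: Censoring = field(default_factory=Censoring)
    seed: int = 0

    def validate(self) -> None:
        if int(self.n_patients) < 1 or self.n_patients != int(self.n_patients):
            raise ConfigurationError("n_patients must be a positive integer")
        for dom in DOMAINS:
            if dom not in self.domain_marginals:
                raise ConfigurationError(f"missing domain marginal for {dom!r}")
            triple = self.domain_marginals[dom]
            if len(triple) != 3:
                raise ConfigurationError(f"domain marginal {dom!r} must have 3 bands")
            _check_marginal(dom, triple)
        for cov, probs in self.clinical_marginals.items():
            _check_marginal(cov, probs.values())
        for ep in self.true_log_hr:
            if ep not in ENDPOINTS:
                raise ConfigurationError(f"unknown endpoint {ep!r}")
        for ep in ENDPOINTS:
            if ep not in self.baseline_hazard:
                raise ConfigurationError(f"missing baseline hazard for endpoint {ep!r}")
            self.baseline_hazard[ep].validate()
        self.censoring.validate()


# --------------------------------------------------------------------------
# Packaged defaults: training cohort (n=144)
# --------------------------------------------------------------------------

TRAINING_DOMAIN_MARGINALS: dict[str, tuple[float, float, float]] = {
    # (low, intermediate, high) band frequencies of the lead sub-marker of
    # each domain: TLS density, Pan-CK foci, driver mutations, CD8/FoxP3.
    "histopathology": (0.354, 0.438, 0.208),
    "tumor_burden": (0.319, 0.403, 0.278),
    "molecular": (0.472, 0.389, 0.139),
    "immune": (0.375, 0.424, 0.201),
}

TRAINING_CLINICAL_MARGINALS: dict[str, dict[str, float]] = {
    "age_group": {"<=55": 0.451, ">55": 0.549},
    "sex": {"male": 0.694, "female": 0.306},
    "primary_site": {"oral_oropharynx": 0.674, "larynx_hypopharynx": 0.326},
    "cps": {"<1": 0.333, ">=1": 0.667},
    "differentiation": {"well": 0.299, "moderate": 0.389, "poor": 0.312},
    "stage": {"III": 0.618, "IV": 0.382},
    "radiologic_response": {"CR": 0.292, "PR": 0.569, "SD": 0.139},
    "pathologic_response": {"pCR": 0.319, "mPR_not_pCR": 0.403, "no_mPR": 0.278},
    "pni": {"no": 0.931, "yes": 0.069},
    "lvi": {"no": 0.937, "yes": 0.063},
    "ene": {"no": 0.972, "yes": 0.028},
    "margin_class": {"close": 0.063, "clear": 0.937},
}

VALIDATION_CLINICAL_MARGINALS: dict[str, dict[str, float]] = {
    "age_group": {"<=55": 0.40, ">55": 0.60},
    "sex": {"male": 0.65, "female": 0.35},
    "primary_site": {"oral_oropharynx": 0.80, "larynx_hypopharynx": 0.20},
    "cps": {"<1": 0.28, ">=1": 0.72},
    "differentiation": {"well": 0.27, "moderate": 0.44, "poor": 0.29},
    "stage": {"III": 0.73, "IV": 0.27},
    "radiologic_response": {"CR": 0.36, "PR": 0.54, "SD": 0.10},
    "pathologic_response": {"pCR": 0.34, "mPR_not_pCR": 0.38, "no_mPR": 0.28},
    "pni": {"no": 0.95, "yes": 0.05},
    "lvi": {"no": 0.95, "yes": 0.05},
    "ene": {"no": 0.97, "yes": 0.03},
    "margin_class": {"close": 0.06, "clear": 0.94},
}

#: Adjusted hazard ratios of the training-cohort multivariable models.
TRAINING_LOG_HR: dict[str, dict[str, dict[str, float]]] = {
    "lrc": {
        "differentiation": {"moderate": math.log(1.56), "poor": math.log(2.19)},
        "pathologic_response": {"mPR_not_pCR": math.log(1.45), "no_mPR": math.log(2.06)},
        "mrix_category": {"intermediate": math.log(1.89), "high": math.log(3.15)},
    },
    "dmfs": {
        "differentiation": {"moderate": math.log(1.62), "poor": math.log(2.00)},
        "pathologic_response": {"mPR_not_pCR": math.log(1.92), "no_mPR": math.log(1.78)},
        "mrix_category": {"intermediate": math.log(2.18), "high": math.log(3.54)},
    },
}

#: Domain-level effects for hazards driven directly by the four 0/1/2 domain
#: scores (used for domain-association analyses).  High-risk hazard ratios
#: follow the published domain-level values where stated (TLS absence
#: 5.92/6.75, tumor burden 7.11 for LRC, molecular MRD 9.40 for DM, immune
#: exhaustion 3.80/4.25); the two unstated high-risk values are set to a
#: neutral 5.0 that preserves the stated ordering, and intermediate levels
#: carry half the high-risk log-hazard.
DOMAIN_LOG_HR: dict[str, dict[str, dict[int, float]]] = {
    "lrc": {
        "histopathology_score": {1: 0.5 * math.log(5.92), 2: math.log(5.92)},
        "tumor_burden_score": {1: 0.5 * math.log(7.11), 2: math.log(7.11)},
        "molecular_score": {1: 0.5 * math.log(5.0), 2: math.log(5.0)},
        "immune_score": {1: 0.5 * math.log(3.80), 2: math.log(3.80)},
    },
    "dmfs": {
        "histopathology_score": {1: 0.5 * math.log(6.75), 2: math.log(6.75)},
        "tumor_burden_score": {1: 0.5 * math.log(5.0), 2: math.log(5.0)},
        "molecular_score": {1: 0.5 * math.log(9.40), 2: math.log(9.40)},
        "immune_score": {1: 0.5 * math.log(4.25), 2: math.log(4.25)},
    },
}

#: Validation-cohort effects: only the high-risk MRIx hazard ratios are
#: cohort-specific; the remaining effects reuse the training values and the
#: traditional margin covariate carries no independent effect.
VALIDATION_LOG_HR: dict[str, dict[str, dict[str, float]]] = {
    "lrc": {
        "differentiation": {"moderate": math.log(1.56), "poor": math.log(2.19)},
        "pathologic_response": {"mPR_not_pCR": math.log(1.45), "no_mPR": math.log(2.06)},
        "margin_class": {"close": 0.0},
        "mrix_category": {"intermediate": math.log(1.89), "high": math.log(2.95)},
    },
    "dmfs": {
        "differentiation": {"moderate": math.log(1.62), "poor": math.log(2.00)},
        "pathologic_response": {"mPR_not_pCR": math.log(1.92), "no_mPR": math.log(1.78)},
        "margin_class": {"close": 0.0},
        "mrix_category": {"intermediate": math.log(2.18), "high": math.log(3.22)},
    },
}


# --------------------------------------------------------------------------
# Serialisation
# --------------------------------------------------------------------------

def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["domain_marginals"] = {k: list(v) for k, v in d["domain_marginals"].items()}
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    d["domain_marginals"] = {
        k: tuple(v) for k, v in d.get("domain_marginals", {}).items()
    }
    d["baseline_hazard"] = {
        ep: BaselineHazard(**bh) for ep, bh in d.get("baseline_hazard", {}).items()
    }
    if "censoring" in d:
        d["censoring"] = Censoring(**d["censoring"])
    cfg = SimulationConfig(**d)
    cfg.validate()
    return cfg


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path) -> SimulationConfig:
    with open(path, encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh))


def config_hash(config: SimulationConfig) -> str:
    """Short stable hash of a configuration, for run logging."""
    blob = yaml.safe_dump(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=int(seed))
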