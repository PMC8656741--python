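"""Synthetic CKD cohort generator.

Emits cohorts with the statistical structure the risk models assume:
a stage 3/4/5 mixture, published marginal means/SDs for labs and
demographics, per-variable missingness rates transcribed from observed
counts in real registry cohorts, horizon-specific KRT event rates, and
loss-to-follow-up thinning -- so every other module is testable without
any clinical data download.

Two presets are bundled:

* ``registry_like_config``  -- a late-stage, real-world dialysis-network
  registry (stage mixture 53/36/11%, mean eGFR 31.9, 24-month event
  rate 19.3%, heavy lab missingness);
* ``study_like_config`` -- an earlier-stage prospective study cohort
  (mostly stage 3, mean eGFR 41.9, low event rates and missingness).

Generation order: stage ~ mixture; eGFR ~ parent normal truncated to
the stage band (parent location recalibrated so the mixture mean equals
the target overall mean); labs ~ truncated normals whose means shift
linearly with standardized eGFR (the only cross-variable dependence);
outcome ~ Bernoulli(logistic(intercept_h + linear predictor)), with the
intercept calibrated by bisection to the target event rate; missingness
is applied last, so the outcome is never missing. One seeded generator
drives the whole run; the same seed reproduces the cohort exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .cohort import STAGE_LOWER_BOUNDS, STAGE_ORDER
from .errors import ConfigError, InvalidInputError

__all__ = [
    "Marginal",
    "CohortConfig",
    "registry_like_config",
    "study_like_config",
    "generate_cohort",
    "calibrate_intercept",
    "generate_expert_ratings",
    "generate_lab_series",
]

_STAGE_BANDS = {"G3": (30.0, 60.0), "G4": (15.0, 30.0), "G5": (1.0, 15.0)}


@dataclass(frozen=True)
class Marginal:
    """Truncated-normal marginal for one continuous variable.

    ``egfr_coupling`` shifts the mean by that many units per SD of
    eGFR above the cohort mean (kidney-function-linked labs).
    """

    mean: float
    sd: float
    floor: float = 0.0
    ceiling: float = float("inf")
    egfr_coupling: float = 0.0


@dataclass(frozen=True)
class CohortConfig:
    n: int
    seed: int
    stage_probs: Mapping[str, float]  # over G3/G4/G5
    egfr_mean: float
    egfr_sd: float
    marginals: Mapping[str, Marginal]
    binary_prevalence: Mapping[str, float]
    smoking_probs: Mapping[str, float]
    male_fraction: float
    missingness: Mapping[str, float]
    missing_mechanism: str = "MCAR"  # MCAR | MAR-stage
    mar_stage_log_odds: float = -0.4  # per stage step past G4 (later = less missing)
    # outcome model: logit(P(event)) = intercept_h + sum w_i * z_i
    outcome_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "egfr": -2.4,
            "egfr_slope": -0.9,
            "log_acr": 0.55,
            "etiology_diabetes": 0.35,
            "age": 0.3,
        }
    )
    target_event_rate: Mapping[int, float] = field(
        default_factory=lambda: {6: 0.0433, 24: 0.1932}
    )
    ltfu_rate: Mapping[int, float] = field(
        default_factory=lambda: {6: 0.179, 24: 0.583}
    )
    slope_mean: float = -2.5  # mL/min/1.73m^2 per year
    slope_sd: float = 3.5
    hospitalization_rate: float = 0.6

    def __post_init__(self) -> None:
        if abs(sum(self.stage_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("stage proportions must sum to 1")
        for h, r in self.target_event_rate.items():
            if not (0.0 < r < 1.0):
                raise ConfigError(f"target event rate for {h} months must lie in (0,1)")
        for name, p in self.missingness.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"missingness[{name}] must lie in [0,1]")


def registry_like_config(n: int = 5000, seed: int = 0, **overrides) -> CohortConfig:
    """Late-stage real-world registry preset (defaults below).

    Missingness probabilities are 1 - observed/total from the source
    registry's descriptive table; prevalences likewise. Comorbidities
    without a published prevalence (dementia, hemiplegia, diabetes with
    organ damage, the liver-disease split) carry invented realistic
    defaults.
    """
    cfg = CohortConfig(
        n=n,
        seed=seed,
        stage_probs={"G3": 0.531, "G4": 0.356, "G5": 0.113},
        egfr_mean=31.93,
        egfr_sd=13.4,
        marginals={
            "age": Marginal(72.15, 11.7, floor=18.0, ceiling=100.0),
            "bmi": Marginal(30.63, 10.92, floor=13.0, ceiling=70.0),
            "albumin": Marginal(4.19, 0.4, floor=1.5),
            "ferritin": Marginal(222.18, 260.98, floor=2.0),
            "hemoglobin": Marginal(12.65, 1.83, floor=5.0, egfr_coupling=0.4),
            "phosphate": Marginal(3.65, 0.74, floor=1.0, egfr_coupling=-0.2),
            "calcium": Marginal(9.36, 0.73, floor=5.0, egfr_coupling=0.1),
            "sodium": Marginal(140.17, 3.16, floor=110.0),
            "pth": Marginal(131.84, 150.12, floor=5.0, egfr_coupling=-50.0),
            # published SD (150.29) for 24-h proteinuria is a printing
            # artifact; a realistic right-skewed spread is used instead
            "urine_protein": Marginal(3.58, 5.0, floor=0.0),
            "acr": Marginal(138.67, 568.28, floor=0.5),
            "systolic_bp": Marginal(137.33, 18.41, floor=70.0, ceiling=260.0),
        },
        binary_prevalence={
            "etiology_diabetes": 0.1604,
            "etiology_polycystic": 0.0212,
            "etiology_hypertension": 0.2343,
            "etiology_glomerulonephritis": 0.0438,
            "peripheral_vascular_disease": 0.0832,
            "coronary_artery_disease": 0.1924,
            "congestive_heart_failure": 0.0837,
            "cerebrovascular_disease": 0.0832,
            "connective_tissue_disorder": 0.0177,
            "hypertension": 0.793,
            "diabetes_no_complications": 0.1337,
            "chronic_pulmonary_disease": 0.0718,
            # invented defaults (no published prevalence):
            "dementia": 0.05,
            "hemiplegia": 0.01,
            "diabetes_organ_damage": 0.20,
            "mild_liver_disease": 0.035,
            "moderate_severe_liver_disease": 0.009,
        },
        smoking_probs={"smoker": 0.144, "ex-smoker": 0.221, "non-smoker": 0.635},
        male_fraction=0.5036,
        missingness={
            "bmi": 0.039,
            "albumin": 0.157,
            "ferritin": 0.676,
            "hemoglobin": 0.027,
            "phosphate": 0.096,
            "calcium": 0.082,
            "sodium": 0.085,
            "pth": 0.580,
            "acr": 0.996,
            "urine_protein": 0.610,
            "systolic_bp": 0.203,
            "smoking": 0.297,
            "egfr_slope": 0.10,
        },
    )
    return replace(cfg, **overrides) if overrides else cfg


def study_like_config(n: int = 4000, seed: int = 0, **overrides) -> CohortConfig:
    """Earlier-stage prospective study preset (mostly stage 3)."""
    base = registry_like_config(n=n, seed=seed)
    cfg = replace(
        base,
        stage_probs={"G3": 0.8854, "G4": 0.1134, "G5": 0.0012},
        egfr_mean=41.92,
        egfr_sd=9.76,
        marginals={
            **base.marginals,
            "age": Marginal(62.12, 10.50, floor=18.0, ceiling=100.0),
            "bmi": Marginal(30.03, 5.91, floor=13.0, ceiling=70.0),
            "albumin": Marginal(3.85, 0.42, floor=1.5),
            "hemoglobin": Marginal(13.49, 1.69, floor=5.0, egfr_coupling=0.4),
            "acr": Marginal(393.63, 888.48, floor=0.5),
            "systolic_bp": Marginal(140.27, 20.53, floor=70.0, ceiling=260.0),
        },
        male_fraction=0.6185,
        target_event_rate={6: 0.0028, 24: 0.0217},
        ltfu_rate={6: 0.042, 24: 0.091},
        missingness={**base.missingness, "acr": 0.0146, "pth": 0.99, "urine_protein": 0.99},
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# eGFR: stage-first sampling with parent-mean recalibration


def _trunc_moments(mu: float, sigma: float, lo: float, hi: float) -> tuple[float, float]:
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    d = sps.norm.cdf(b) - sps.norm.cdf(a)
    mean = mu + sigma * (sps.norm.pdf(a) - sps.norm.pdf(b)) / d
    return mean, d


def _calibrated_egfr_parent_mean(cfg: CohortConfig) -> float:
    """Parent location making the stage-mixture eGFR mean hit the target.

    A single truncated normal cannot reproduce both the published stage
    mixture and the published overall mean; sampling stage first and
    conditioning eGFR on the stage band reconciles the two once the
    parent location is re-solved.
    """

    def mixture_mean(mu: float) -> float:
        total = 0.0
        for stage, w in cfg.stage_probs.items():
            lo, hi = _STAGE_BANDS[stage]
            m, _ = _trunc_moments(mu, cfg.egfr_sd, lo, hi)
            total += w * m
        return total

    try:
        return float(
            optimize.brentq(
                lambda mu: mixture_mean(mu) - cfg.egfr_mean,
                cfg.egfr_mean - 30,
                cfg.egfr_mean + 30,
                xtol=1e-8,
            )
        )
    except ValueError as exc:
        raise ConfigError("cannot reconcile stage mixture with eGFR mean") from exc


def _sample_truncnorm(
    rng: np.random.Generator, mu, sigma: float, lo: float, hi: float, size: int
) -> np.ndarray:
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    u = rng.uniform(size=size)
    cdf_a, cdf_b = sps.norm.cdf(a), sps.norm.cdf(b)
    return mu + sigma * sps.norm.ppf(cdf_a + u * (cdf_b - cdf_a))


def _linear_predictor(cfg: CohortConfig, df: pd.DataFrame) -> np.ndarray:
    """Standardized-feature linear predictor of the latent outcome model.

    Uses the *true* (pre-missingness) values; standardization constants
    come from the config marginals so calibration and generation agree.
    """
    z = np.zeros(len(df))
    w = cfg.outcome_weights
    if "egfr" in w:
        z += w["egfr"] * (df["egfr"] - cfg.egfr_mean) / cfg.egfr_sd
    if "egfr_slope" in w:
        z += w["egfr_slope"] * (df["egfr_slope"] - cfg.slope_mean) / cfg.slope_sd
    if "log_acr" in w:
        m = cfg.marginals["acr"]
        z += w["log_acr"] * (np.log(df["acr"]) - np.log(max(m.mean, 1.0))) / 1.5
    if "etiology_diabetes" in w:
        z += w["etiology_diabetes"] * df["etiology_diabetes"].astype(float)
    if "age" in w:
        m = cfg.marginals["age"]
        z += w["age"] * (df["age"] - m.mean) / m.sd
    return z.to_numpy() if hasattr(z, "to_numpy") else z


def _generate_features(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n
    stages = rng.choice(list(cfg.stage_probs), size=n, p=list(cfg.stage_probs.values()))
    mu = _calibrated_egfr_parent_mean(cfg)
    egfr = np.empty(n)
    for stage, (lo, hi) in _STAGE_BANDS.items():
        mask = stages == stage
        egfr[mask] = _sample_truncnorm(rng, mu, cfg.egfr_sd, lo, hi, int(mask.sum()))
    zegfr = (egfr - cfg.egfr_mean) / cfg.egfr_sd

    df = pd.DataFrame({"stage": stages, "egfr": egfr})
    df["egfr_slope"] = rng.normal(cfg.slope_mean, cfg.slope_sd, size=n)
    df["sex"] = np.where(rng.uniform(size=n) < cfg.male_fraction, "male", "female")
    df["smoking"] = rng.choice(
        list(cfg.smoking_probs), size=n, p=list(cfg.smoking_probs.values())
    )
    for name, m in cfg.marginals.items():
        loc = m.mean + m.egfr_coupling * zegfr
        df[name] = _sample_truncnorm(rng, loc, m.sd, m.floor, m.ceiling, n)
    for name, p in cfg.binary_prevalence.items():
        df[name] = (rng.uniform(size=n) < p).astype(int)
    df["n_hospitalizations"] = rng.poisson(cfg.hospitalization_rate, size=n)
    df.insert(0, "patient_id", [f"SYN{i:06d}" for i in range(n)])
    return df


def calibrate_intercept(
    cfg: CohortConfig,
    target_event_rate: float,
    n_calibration: int = 50_000,
) -> float:
    """Intercept making the expected event rate hit the target.

    Bisects the intercept against the mean of logistic(intercept + lp)
    over a fixed-seed calibration sample of linear predictors; with all
    weights zero this reduces to logit(target) exactly.
    """
    if not (0.0 < target_event_rate < 1.0):
        raise ConfigError("target event rate must lie in (0,1)")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xCA11B]))
    feats = _generate_features(replace(cfg, n=n_calibration), rng)
    lp = _linear_predictor(cfg, feats)

    def rate(c: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(c + lp)))))

    lo, hi = -30.0, 30.0
    if not (rate(lo) < target_event_rate < rate(hi)):
        raise ConfigError("intercept search does not bracket the target rate")
    return float(
        optimize.brentq(lambda c: rate(c) - target_event_rate, lo, hi, xtol=1e-10)
    )


def generate_cohort(cfg: CohortConfig, horizons: tuple[int, ...] = (6, 24)) -> pd.DataFrame:
    """Generate one synthetic cohort with outcomes at the given horizons.

    Adds, per horizon ``h``: ``event_{h}m`` (1/0, NaN when the status is
    not ascertainable) and ``status_{h}m`` (event / event-free /
    lost-to-follow-up). A shared uniform draw makes events nested across
    horizons (a 6-month progressor is also a 24-month progressor).
    Missingness is applied after outcome generation, so outcomes and
    always-recorded fields (age, sex, eGFR, flags) are never masked.
    """
    rng = np.random.default_rng(cfg.seed)
    df = _generate_features(cfg, rng)
    lp = _linear_predictor(cfg, df)

    u_event = rng.uniform(size=cfg.n)
    for h in horizons:
        if h not in cfg.target_event_rate:
            raise ConfigError(f"no target event rate for horizon {h}")
        c = calibrate_intercept(cfg, cfg.target_event_rate[h])
        p = 1.0 / (1.0 + np.exp(-(c + lp)))
        event = (u_event < p).astype(float)
        status = np.where(event == 1.0, "event", "event-free")
        lost = rng.uniform(size=cfg.n) < cfg.ltfu_rate.get(h, 0.0)
        status = np.where(lost, "lost-to-follow-up", status)
        event = np.where(lost, np.nan, event)
        df[f"event_{h}m"] = event
        df[f"status_{h}m"] = status

    # missingness last: outcome columns are never masked
    stage_step = pd.Series(df["stage"]).map({"G3": -1, "G4": 0, "G5": 1}).to_numpy()
    for name, p_miss in cfg.missingness.items():
        if name not in df.columns or p_miss == 0.0:
            continue
        if cfg.missing_mechanism == "MAR-stage" and 0 < p_miss < 1:
            logit = np.log(p_miss / (1 - p_miss)) + cfg.mar_stage_log_odds * stage_step
            p_vec = 1.0 / (1.0 + np.exp(-logit))
        elif cfg.missing_mechanism == "MCAR":
            p_vec = np.full(cfg.n, p_miss)
        elif cfg.missing_mechanism == "MAR-stage":
            p_vec = np.full(cfg.n, p_miss)
        else:
            raise ConfigError(f"unknown missingness mechanism {cfg.missing_mechanism!r}")
        mask = rng.uniform(size=cfg.n) < p_vec
        col = df[name]
        if col.dtype == object:
            df.loc[mask, name] = None
        else:
            df[name] = col.astype(float).mask(mask)
    df.attrs["seed"] = cfg.seed
    df.attrs["generator"] = "nephrisk.synth"
    return df


def generate_lab_series(
    cohort: pd.DataFrame,
    rng: np.random.Generator | int = 0,
    index_date: str = "2020-06-30",
    n_points: int = 3,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Long-format eGFR series consistent with each row's level and slope.

    Places ``n_points`` assessments across the 12 months before the
    index date on the line ``egfr + slope * t`` plus measurement noise;
    enough longitudinal texture for the averaging/slope features, with
    no pretension of full trajectory realism.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    idx = pd.Timestamp(index_date)
    rows = []
    for _, r in cohort.iterrows():
        slope = r.get("egfr_slope")
        if slope is None or (isinstance(slope, float) and np.isnan(slope)):
            slope = 0.0
        offsets = np.sort(rng.uniform(-11.5, 0.0, size=n_points))
        for t_mo in offsets:
            t_yr = t_mo / 12.0
            val = max(r["egfr"] + slope * t_yr + rng.normal(0, noise_sd), 1.0)
            rows.append(
                {
                    "patient_id": r["patient_id"],
                    "variable": "egfr",
                    "date": (idx + pd.Timedelta(days=t_mo * 30.4375)).date().isoformat(),
                    "value": val,
                }
            )
    return pd.DataFrame(rows)


def generate_expert_ratings(
    risks: np.ndarray,
    n_raters: int = 4,
    target_correlation: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Integer 1-10 expert risk ratings correlated with model risks.

    Gaussian-copula construction: the normal scores of the risk ranks
    are mixed with independent rater noise and the latent mapped to ten
    equal-probability rating levels. The mixing weight is adjusted by a
    short fixed-point iteration against the achieved Pearson
    correlation, so the sample correlation lands on the target (checked
    to ~0.02 internally) for n of a few hundred or more.
    """
    risks = np.asarray(risks, dtype=float)
    if np.any((risks < 0) | (risks > 1)):
        raise InvalidInputError("risks must lie in [0,1]")
    if not (-1.0 <= target_correlation <= 1.0):
        raise ConfigError("target correlation must lie in [-1,1]")
    n = len(risks)
    rng = np.random.default_rng(seed)
    ranks = sps.rankdata(risks, method="average")
    z = sps.norm.ppf((ranks - 0.5) / n)
    out = {}
    for r in range(n_raters):
        eps = rng.normal(size=n)
        # |target| == 1 stays exact: no noise, ratings strictly monotone in risk
        rho = (
            target_correlation
            if abs(target_correlation) >= 1.0
            else float(np.clip(target_correlation, -0.999, 0.999))
        )
        for _ in range(8):
            latent = rho * z + np.sqrt(max(1 - rho**2, 0.0)) * eps
            ratings = np.clip(np.floor(10 * sps.norm.cdf(latent)) + 1, 1, 10).astype(int)
            achieved = _safe_pearson(risks, ratings)
            if abs(target_correlation) >= 0.999 or abs(achieved - target_correlation) < 0.02:
                break
            if achieved == 0.0:
                break
            rho = float(np.clip(rho * target_correlation / achieved, -0.999, 0.999))
        out[f"expert_{r + 1}"] = ratings
    return pd.DataFrame(out)


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])
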