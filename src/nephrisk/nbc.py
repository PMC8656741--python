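"""Naive-Bayes risk engine: training, scoring under arbitrary missingness,
value-of-information and normalized-likelihood impact metrics.

The model is a star-topology Bayesian network: a binary outcome Y (KRT
initiation within the horizon) with one conditional probability table
(CPT) per predictor, P(X = level | Y). Scoring marginalizes missing
predictors exactly -- they simply drop out of the likelihood product --
so a risk is computable for every record, including fully empty ones
(the posterior then equals the prior).

Two explanation metrics accompany each prediction:

* **VOI** (value of information), for each *missing* variable: the
  expected reduction in outcome entropy (bits) were that variable
  observed, i.e. the conditional mutual information I(Y; X | evidence)
  under the model. Used to prioritize additional testing.
* **NL** (normalized likelihood), for each *observed* variable: the
  single-variable posterior lift P(ei | Y=1) / P(ei); values > 1 are
  risk-increasing evidence, < 1 risk-decreasing. This is one of several
  impact definitions in the literature; it is isolated behind
  :func:`normalized_likelihood` so alternatives can be swapped in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import EvidenceError, InputFormatError, InvalidInputError, TrainingError
from .variables import VariableSpec

__all__ = [
    "NBCModel",
    "fit_discretization",
    "discretize_value",
    "discretize_frame",
    "fit_nbc",
    "posterior_risk",
    "outcome_entropy",
    "value_of_information",
    "normalized_likelihood",
    "RiskPrediction",
    "predict",
    "predict_frame",
    "score_frame",
    "save_model",
    "load_model",
]

MODEL_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class NBCModel:
    """A trained naive-Bayes risk model for one forecast horizon.

    ``cpts[name]`` is a (2, n_levels) array: row 0 is P(X | Y=0), row 1
    is P(X | Y=1). Laplace smoothing guarantees strictly positive
    entries, so log-space scoring never underflows to -inf.
    """

    horizon_months: int
    prior: float
    specs: tuple[VariableSpec, ...]
    cpts: Mapping[str, np.ndarray]
    smoothing_alpha: float = 1.0
    log_base: float = 2.0  # entropy/VOI unit: bits

    def __post_init__(self) -> None:
        if not (0.0 < self.prior < 1.0):
            raise InvalidInputError(f"prior must lie in (0,1), got {self.prior}")
        for spec in self.specs:
            cpt = self.cpts[spec.name]
            if cpt.shape != (2, spec.n_levels):
                raise InvalidInputError(f"{spec.name}: CPT shape {cpt.shape} mismatch")
            if not np.allclose(cpt.sum(axis=1), 1.0, atol=1e-9):
                raise InvalidInputError(f"{spec.name}: CPT rows must sum to 1")
            if np.any(cpt <= 0):
                raise InvalidInputError(f"{spec.name}: CPT entries must be > 0")

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    def spec(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise EvidenceError(f"unknown variable {name!r}")


def fit_discretization(
    values: Sequence[float] | np.ndarray | pd.Series,
    spec: VariableSpec,
    n_bins: int = 5,
) -> VariableSpec:
    """Equal-frequency bin edges for one continuous variable.

    Edges are interior quantiles of the non-missing training values;
    the outermost bins are unbounded (no +-inf sentinels are stored).
    A variable whose observed values cannot support ``n_bins`` distinct
    quantile edges (constant or all-missing) comes back flagged
    unusable and is dropped from the model.
    """
    if spec.kind != "continuous":
        raise InvalidInputError(f"{spec.name}: only continuous variables are discretized")
    vals = np.asarray(pd.Series(values).dropna(), dtype=float)
    if vals.size == 0 or np.unique(vals).size < 2:
        return _unusable(spec)
    qs = np.arange(1, n_bins) / n_bins
    edges = np.unique(np.quantile(vals, qs))
    if edges.size == 0:
        return _unusable(spec)
    return spec.with_edges(edges)


def _unusable(spec: VariableSpec):
    from dataclasses import replace

    return replace(spec, usable=False)


def discretize_value(spec: VariableSpec, value) -> int | None:
    """Map one raw value to a level index under ``spec``; None if missing."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if spec.kind == "boolean":
        return int(bool(value))
    if spec.kind == "categorical":
        try:
            return spec.categories.index(value)
        except ValueError:
            raise EvidenceError(
                f"{spec.name}: level {value!r} not in {spec.categories}"
            ) from None
    if spec.bin_edges is None:
        raise InvalidInputError(f"{spec.name}: not discretized")
    return int(np.searchsorted(spec.bin_edges, float(value), side="right"))


def discretize_frame(df: pd.DataFrame, specs: Sequence[VariableSpec]) -> pd.DataFrame:
    """Level-index frame (float, NaN = missing) for the spec'd columns."""
    out = {}
    for spec in specs:
        if spec.name not in df.columns:
            out[spec.name] = np.full(len(df), np.nan)
            continue
        col = df[spec.name]
        if spec.kind == "continuous":
            idx = np.searchsorted(np.asarray(spec.bin_edges), col.to_numpy(dtype=float),
                                  side="right").astype(float)
            idx[col.isna().to_numpy()] = np.nan
            out[spec.name] = idx
        elif spec.kind == "boolean":
            idx = col.astype("float")
            bad = ~(idx.isin([0.0, 1.0]) | idx.isna())
            if bad.any():
                raise EvidenceError(f"{spec.name}: non-boolean values present")
            out[spec.name] = idx.to_numpy()
        else:
            cat = pd.Categorical(col, categories=spec.categories)
            unknown = col.notna() & pd.Series(cat.codes == -1, index=col.index)
            if unknown.any():
                bad_vals = sorted(set(col[unknown]))
                raise EvidenceError(f"{spec.name}: unknown levels {bad_vals}")
            codes = cat.codes.astype(float)
            codes[codes == -1] = np.nan
            out[spec.name] = codes
    return pd.DataFrame(out, index=df.index)


def fit_nbc(
    cohort: pd.DataFrame,
    outcome: str | pd.Series,
    specs: Sequence[VariableSpec],
    horizon_months: int,
    smoothing_alpha: float = 1.0,
    n_bins: int = 5,
) -> NBCModel:
    """Fit prior and CPTs from a cohort with a binary outcome column.

    Rows must already be restricted to ascertainable outcomes (events
    and event-free; excluded-death and lost-to-follow-up removed
    upstream). Missing predictor values contribute to neither the
    numerator nor the denominator of that predictor's CPT
    (available-case counting; no imputation). Laplace smoothing with
    ``smoothing_alpha`` pseudo-counts per cell keeps every probability
    strictly positive; ``smoothing_alpha=0`` yields maximum-likelihood
    frequencies (valid only when every cell is populated).
    """
    y = cohort[outcome] if isinstance(outcome, str) else outcome
    y = pd.Series(y).astype(float)
    keep = y.notna()
    y = y[keep].astype(int)
    data = cohort.loc[keep.to_numpy()] if isinstance(outcome, str) else cohort[keep.to_numpy()]
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n0 == 0 or n1 == 0:
        raise TrainingError("cohort must contain both outcome classes")
    prior = n1 / (n0 + n1)

    fitted_specs: list[VariableSpec] = []
    cpts: dict[str, np.ndarray] = {}
    for spec in specs:
        if spec.name not in data.columns:
            continue
        if spec.kind == "continuous" and spec.bin_edges is None:
            spec = fit_discretization(data[spec.name], spec, n_bins=n_bins)
            if not spec.usable:
                continue
        levels = discretize_frame(data[[spec.name]], [spec])[spec.name]
        k = spec.n_levels
        counts = np.zeros((2, k))
        obs = levels.notna().to_numpy()
        lv = levels.to_numpy()[obs].astype(int)
        yy = y.to_numpy()[obs]
        for cls in (0, 1):
            counts[cls] = np.bincount(lv[yy == cls], minlength=k)
        denom = counts.sum(axis=1, keepdims=True) + smoothing_alpha * k
        if smoothing_alpha == 0 and np.any(counts.sum(axis=1) == 0):
            raise TrainingError(f"{spec.name}: no observed values in one class and alpha=0")
        cpt = (counts + smoothing_alpha) / denom
        if np.any(cpt <= 0):
            raise TrainingError(f"{spec.name}: zero cells require smoothing_alpha > 0")
        fitted_specs.append(spec)
        cpts[spec.name] = cpt
    if not fitted_specs:
        raise TrainingError("no usable predictors")
    return NBCModel(
        horizon_months=horizon_months,
        prior=prior,
        specs=tuple(fitted_specs),
        cpts=cpts,
        smoothing_alpha=smoothing_alpha,
    )


def _validate_evidence(model: NBCModel, evidence: Mapping[str, int]) -> None:
    for name, level in evidence.items():
        spec = model.spec(name)  # raises EvidenceError if unknown
        if not (isinstance(level, (int, np.integer)) and 0 <= level < spec.n_levels):
            raise EvidenceError(
                f"{name}: level {level!r} out of range 0..{spec.n_levels - 1}"
            )


def posterior_risk(model: NBCModel, evidence: Mapping[str, int]) -> float:
    """P(Y=1 | evidence) with missing variables marginalized out.

    ``evidence`` maps variable name -> discretized level index; any
    variable not listed is treated as missing and contributes nothing.
    """
    _validate_evidence(model, evidence)
    log1 = math.log(model.prior)
    log0 = math.log1p(-model.prior)
    for name, level in evidence.items():
        cpt = model.cpts[name]
        log1 += math.log(cpt[1, level])
        log0 += math.log(cpt[0, level])
    return 1.0 / (1.0 + math.exp(log0 - log1))


def outcome_entropy(p: float, base: float = 2.0) -> float:
    """Binary entropy H(p) in the given log base (default bits)."""
    if not (0.0 <= p <= 1.0):
        raise InvalidInputError(f"probability must lie in [0,1], got {p}")
    if p in (0.0, 1.0):
        return 0.0
    lb = math.log(base)
    return float(-(p * math.log(p) + (1 - p) * math.log(1 - p)) / lb)


def value_of_information(
    model: NBCModel, evidence: Mapping[str, int], missing_var: str
) -> float:
    """Expected entropy reduction (bits) from observing ``missing_var``.

    VOI = H(Y|e) - sum_x P(X=x|e) H(Y|e, X=x), with
    P(X=x|e) = sum_y P(X=x|y) P(y|e); this equals the conditional
    mutual information I(Y; X | e) under the model, hence is always in
    [0, H(Y|e)].
    """
    if missing_var in evidence:
        raise EvidenceError(f"{missing_var} is already observed")
    spec = model.spec(missing_var)
    p1 = posterior_risk(model, evidence)
    h_before = outcome_entropy(p1, model.log_base)
    cpt = model.cpts[missing_var]
    h_after = 0.0
    for x in range(spec.n_levels):
        p_x = cpt[1, x] * p1 + cpt[0, x] * (1 - p1)
        if p_x == 0:
            continue
        ev = dict(evidence)
        ev[missing_var] = x
        h_after += p_x * outcome_entropy(posterior_risk(model, ev), model.log_base)
    return max(h_before - h_after, 0.0)


def normalized_likelihood(
    model: NBCModel, evidence: Mapping[str, int], observed_var: str
) -> float:
    """Impact of one observed variable: NL = P(ei|Y=1) / P(ei).

    P(ei) is evaluated against the outcome prior, so NL equals the
    single-variable posterior lift P(Y=1|ei)/P(Y=1). NL > 1 marks
    risk-increasing evidence; a variable whose CPT rows coincide for
    both outcome classes has NL = 1 at every level.
    """
    if observed_var not in evidence:
        raise EvidenceError(f"{observed_var} is not observed")
    level = evidence[observed_var]
    _validate_evidence(model, {observed_var: level})
    cpt = model.cpts[observed_var]
    p_e1 = cpt[1, level]
    p_e = model.prior * p_e1 + (1 - model.prior) * cpt[0, level]
    return float(p_e1 / p_e)


@dataclass(frozen=True)
class RiskPrediction:
    """Posterior risk plus ranked per-variable explanation metrics."""

    risk: float
    horizon_months: int
    impacts: tuple[tuple[str, float], ...]  # (observed var, NL), ranked
    voi: tuple[tuple[str, float], ...]  # (missing var, bits), ranked
    entropy_given_evidence: float


def _rank(pairs: dict[str, float], descending_key) -> tuple[tuple[str, float], ...]:
    # sort by metric descending, ties broken lexicographically by name
    return tuple(sorted(pairs.items(), key=lambda kv: (-descending_key(kv[1]), kv[0])))


def predict(model: NBCModel, record: Mapping) -> RiskPrediction:
    """Score one raw (undiscretized) record.

    ``record`` maps variable name -> raw value; anything absent, NaN or
    not in the model is treated as missing. Bundles the posterior risk,
    NL for every observed variable (ranked by distance from 1, i.e.
    strength of influence in either direction) and VOI for every
    missing variable (ranked by bits), ties broken by name.
    """
    evidence: dict[str, int] = {}
    for spec in model.specs:
        if spec.name in record:
            lvl = discretize_value(spec, record[spec.name])
            if lvl is not None:
                evidence[spec.name] = lvl
    risk = posterior_risk(model, evidence)
    impacts = {v: normalized_likelihood(model, evidence, v) for v in evidence}
    voi = {
        v: value_of_information(model, evidence, v)
        for v in model.variable_names
        if v not in evidence
    }
    return RiskPrediction(
        risk=risk,
        horizon_months=model.horizon_months,
        impacts=_rank(impacts, lambda nl: abs(math.log(nl))),
        voi=_rank(voi, lambda b: b),
        entropy_given_evidence=outcome_entropy(risk, model.log_base),
    )


def score_frame(model: NBCModel, df: pd.DataFrame) -> np.ndarray:
    """Vectorized posterior risk for every row of a raw cohort table."""
    levels = discretize_frame(df, model.specs)
    log_odds = np.full(len(df), math.log(model.prior) - math.log1p(-model.prior))
    for spec in model.specs:
        lv = levels[spec.name].to_numpy()
        obs = ~np.isnan(lv)
        cpt = model.cpts[spec.name]
        contrib = np.log(cpt[1, lv[obs].astype(int)]) - np.log(cpt[0, lv[obs].astype(int)])
        log_odds[obs] += contrib
    return 1.0 / (1.0 + np.exp(-log_odds))


def predict_frame(model: NBCModel, df: pd.DataFrame, top_k: int = 3) -> pd.DataFrame:
    """Risk plus top-k impact/VOI summaries for every row."""
    rows = []
    for _, r in df.iterrows():
        pred = predict(model, r.to_dict())
        rows.append(
            {
                "risk": pred.risk,
                "entropy_bits": pred.entropy_given_evidence,
                "top_impacts": ";".join(f"{n}={v:.3f}" for n, v in pred.impacts[:top_k]),
                "top_voi": ";".join(f"{n}={v:.4f}" for n, v in pred.voi[:top_k]),
            }
        )
    return pd.DataFrame(rows, index=df.index)


# ---------------------------------------------------------------------------
# model document serialization (YAML; round-trips exactly)


def _spec_to_doc(spec: VariableSpec) -> dict:
    doc: dict = {"name": spec.name, "kind": spec.kind}
    if spec.categories is not None:
        doc["categories"] = list(spec.categories)
    if spec.bin_edges is not None:
        doc["bin_edges"] = [float(e) for e in spec.bin_edges]
    return doc


def save_model(model: NBCModel, path) -> None:
    """Write the model document (schema, prior, bin edges, CPTs)."""
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "kind": "naive-bayes-risk-model",
        "horizon_months": model.horizon_months,
        "prior": float(model.prior),
        "smoothing_alpha": float(model.smoothing_alpha),
        "log_base": float(model.log_base),
        "variables": [
            {
                **_spec_to_doc(spec),
                "cpt": {
                    "y0": [float(v) for v in model.cpts[spec.name][0]],
                    "y1": [float(v) for v in model.cpts[spec.name][1]],
                },
            }
            for spec in model.specs
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_model(path) -> NBCModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or doc.get("kind") != "naive-bayes-risk-model":
        raise InputFormatError(f"{path}: not a model document")
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise InputFormatError(f"{path}: unsupported schema {doc.get('schema_version')}")
    specs = []
    cpts = {}
    for v in doc["variables"]:
        spec = VariableSpec(
            name=v["name"],
            kind=v["kind"],
            categories=tuple(v["categories"]) if "categories" in v else None,
            bin_edges=tuple(v["bin_edges"]) if "bin_edges" in v else None,
        )
        specs.append(spec)
        cpts[spec.name] = np.array([v["cpt"]["y0"], v["cpt"]["y1"]], dtype=float)
    return NBCModel(
        horizon_months=int(doc["horizon_months"]),
        prior=float(doc["prior"]),
        specs=tuple(specs),
        cpts=cpts,
        smoothing_alpha=float(doc.get("smoothing_alpha", 1.0)),
        log_base=float(doc.get("log_base", 2.0)),
    )
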