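"""Kidney Failure Risk Equation (KFRE) benchmark and computability accounting.

The KFRE is a Cox-model-derived risk equation:

    risk(t) = 1 - S0(t) ^ exp( sum_j beta_j * (x_j - xbar_j) )

with variant-specific predictor sets -- 4VAR: age, sex, eGFR, ACR;
6VAR: 4VAR + diabetes + hypertension. It is a complete-case score: a
record missing any required predictor is *not computable* (a signal
distinct from invalid input), which is exactly the practical gap the
naive-Bayes engine closes. :func:`computability` quantifies that gap on
a cohort.

Coefficients are data, not code: the package ships a clearly labelled
synthetic placeholder set (``data/kfre_synthetic.yaml``) for testing and
plumbing; users supply published coefficient values in the same document
format (variant, units, transforms, centering values, baseline survival).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from math import exp, log
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import InputFormatError, InvalidInputError, NotComputableError

__all__ = [
    "KFRECoefficients",
    "load_coefficients",
    "synthetic_placeholder_coefficients",
    "kfre_risk",
    "kfre_risk_frame",
    "computability",
    "ComputabilityReport",
    "KFRE_PREDICTORS",
]

KFRE_PREDICTORS: Mapping[str, tuple[str, ...]] = {
    "4VAR": ("age", "sex", "egfr", "acr"),
    "6VAR": ("age", "sex", "egfr", "acr", "diabetes", "hypertension"),
}

ACR_MG_PER_MMOL_TO_MG_PER_G = 8.84  # mg/mmol -> mg/g (creatinine MW based)


@dataclass(frozen=True)
class Predictor:
    """One term of the linear predictor."""

    name: str
    coefficient: float
    center: float
    transform: str = "identity"  # identity | log
    unit_factor: float = 1.0  # applied to the raw value before transform

    def contribution(self, value: float) -> float:
        x = value * self.unit_factor
        if self.transform == "log":
            if x <= 0:
                raise InvalidInputError(f"{self.name}: log transform needs value > 0")
            x = log(x)
        elif self.transform != "identity":
            raise InvalidInputError(f"{self.name}: unknown transform {self.transform!r}")
        return self.coefficient * (x - self.center)


@dataclass(frozen=True)
class KFRECoefficients:
    """One KFRE variant: predictor terms plus baseline survival S0."""

    variant: str
    horizon_months: int
    baseline_survival: float
    predictors: tuple[Predictor, ...]
    region: str = "unspecified"
    citation: str = ""

    def __post_init__(self) -> None:
        if self.variant not in KFRE_PREDICTORS:
            raise InvalidInputError(f"variant must be 4VAR or 6VAR, got {self.variant!r}")
        if not (0.0 < self.baseline_survival < 1.0):
            raise InvalidInputError("baseline survival must lie in (0,1)")
        names = tuple(p.name for p in self.predictors)
        if set(names) != set(KFRE_PREDICTORS[self.variant]):
            raise InvalidInputError(
                f"{self.variant} needs predictors {KFRE_PREDICTORS[self.variant]}, got {names}"
            )

    @property
    def required(self) -> tuple[str, ...]:
        return KFRE_PREDICTORS[self.variant]


def _sex_to_male_indicator(value) -> float:
    if isinstance(value, (int, float, np.integer, np.floating)):
        # already an indicator (0/1 or a fractional centering value)
        if 0.0 <= float(value) <= 1.0:
            return float(value)
        raise InvalidInputError(f"sex indicator out of range: {value!r}")
    s = str(value).strip().lower()
    if s in ("m", "male"):
        return 1.0
    if s in ("f", "female"):
        return 0.0
    raise InvalidInputError(f"unrecognized sex {value!r}")


def kfre_risk(coeffs: KFRECoefficients, record: Mapping) -> float:
    """KFRE risk for one record; raises NotComputableError on missing input.

    ``record`` maps predictor name -> value (sex as male/female or a 0/1
    male indicator; diabetes/hypertension as booleans; ACR in the unit
    declared by the coefficient document's ``unit_factor``).
    """
    lp = 0.0
    for p in coeffs.predictors:
        v = record.get(p.name)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise NotComputableError(f"{p.name} missing: {coeffs.variant} not computable")
        if p.name == "sex":
            v = _sex_to_male_indicator(v)
        lp += p.contribution(float(v))
    return 1.0 - coeffs.baseline_survival ** exp(lp)


def kfre_risk_frame(coeffs: KFRECoefficients, df: pd.DataFrame) -> pd.Series:
    """Per-row KFRE risk; NaN where the score is not computable."""
    out = np.full(len(df), np.nan)
    for i, (_, row) in enumerate(df.iterrows()):
        try:
            out[i] = kfre_risk(coeffs, row.to_dict())
        except NotComputableError:
            pass
    return pd.Series(out, index=df.index, name=f"kfre_{coeffs.variant.lower()}")


@dataclass(frozen=True)
class ComputabilityReport:
    """How many cohort records each score can actually be computed for."""

    n_total: int
    n_computable: Mapping[str, int]

    @property
    def share_computable(self) -> dict[str, float]:
        if self.n_total == 0:
            return {k: float("nan") for k in self.n_computable}
        return {k: v / self.n_total for k, v in self.n_computable.items()}


def computability(
    cohort: pd.DataFrame,
    score_requirements: Mapping[str, Sequence[str]],
) -> ComputabilityReport:
    """Count complete-case computable records per score.

    ``score_requirements`` maps score name -> required columns; an empty
    requirement list (the naive-Bayes model, computable under any
    missingness) counts every record.
    """
    n = len(cohort)
    counts: dict[str, int] = {}
    for score, required in score_requirements.items():
        if not required:
            counts[score] = n
            continue
        missing_cols = [c for c in required if c not in cohort.columns]
        if missing_cols:
            counts[score] = 0
            continue
        ok = cohort[list(required)].notna().all(axis=1)
        counts[score] = int(ok.sum())
    return ComputabilityReport(n_total=n, n_computable=counts)


# ---------------------------------------------------------------------------
# coefficient documents


def _doc_to_coeffs(doc: dict, source: str = "<doc>") -> KFRECoefficients:
    try:
        preds = tuple(
            Predictor(
                name=p["name"],
                coefficient=float(p["coefficient"]),
                center=float(p["center"]),
                transform=p.get("transform", "identity"),
                unit_factor=float(p.get("unit_factor", 1.0)),
            )
            for p in doc["predictors"]
        )
        return KFRECoefficients(
            variant=doc["variant"],
            horizon_months=int(doc["horizon_months"]),
            baseline_survival=float(doc["baseline_survival"]),
            predictors=preds,
            region=doc.get("region", "unspecified"),
            citation=doc.get("citation", ""),
        )
    except (KeyError, TypeError) as exc:
        raise InputFormatError(f"{source}: malformed coefficient document: {exc}") from exc


def load_coefficients(path) -> dict[str, KFRECoefficients]:
    """Load a coefficient document holding one or more variants."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    variants = doc["variants"] if isinstance(doc, dict) and "variants" in doc else [doc]
    out = {}
    for v in variants:
        c = _doc_to_coeffs(v, source=str(path))
        out[c.variant] = c
    return out


def synthetic_placeholder_coefficients() -> dict[str, KFRECoefficients]:
    """The bundled SYNTHETIC placeholder coefficient set.

    Plausible in sign and rough magnitude only; not published values.
    Intended for tests, examples and pipeline plumbing.
    """
    ref = resources.files("nephrisk.data").joinpath("kfre_synthetic.yaml")
    with resources.as_file(ref) as path:
        return load_coefficients(path)
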