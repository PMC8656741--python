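"""Registry of model input variables for the two forecast horizons.

The 6-month model uses 28 predictors, the 24-month model 34; the extra
24-month variables are hypertension (etiology and comorbidity),
connective tissue disorder, coronary artery disease, diabetes without
complications and hemiplegia. Kinds drive discretization: continuous
variables get equal-frequency bins at fit time, categorical/boolean
variables use their fixed level sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .errors import InvalidInputError

__all__ = ["VariableSpec", "default_variable_specs", "specs_for_horizon"]


@dataclass(frozen=True)
class VariableSpec:
    """One predictor: its kind, levels and horizon membership."""

    name: str
    kind: str  # continuous | categorical | boolean
    categories: tuple[str, ...] | None = None
    bin_edges: tuple[float, ...] | None = None
    in_model_6: bool = True
    in_model_24: bool = True
    usable: bool = True  # False when discretization failed (e.g. constant)

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical", "boolean"):
            raise InvalidInputError(f"unknown variable kind {self.kind!r}")
        if self.kind == "categorical" and not self.categories:
            raise InvalidInputError(f"{self.name}: categorical needs categories")
        if self.bin_edges is not None and list(self.bin_edges) != sorted(set(self.bin_edges)):
            raise InvalidInputError(f"{self.name}: bin edges must be strictly increasing")

    @property
    def levels(self) -> tuple[str, ...]:
        """Human-readable level labels in storage order."""
        if self.kind == "boolean":
            return ("no", "yes")
        if self.kind == "categorical":
            return tuple(self.categories)
        if self.bin_edges is None:
            raise InvalidInputError(f"{self.name}: continuous variable not discretized")
        edges = self.bin_edges
        labels = [f"<{edges[0]:g}"]
        labels += [f"[{a:g},{b:g})" for a, b in zip(edges[:-1], edges[1:])]
        labels.append(f">={edges[-1]:g}")
        return tuple(labels)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def with_edges(self, edges: Sequence[float]) -> "VariableSpec":
        return replace(self, bin_edges=tuple(float(e) for e in edges))


def _cont(name: str, **kw) -> VariableSpec:
    return VariableSpec(name, "continuous", **kw)


def _boolean(name: str, **kw) -> VariableSpec:
    return VariableSpec(name, "boolean", **kw)


_REGISTRY: tuple[VariableSpec, ...] = (
    # demographics / anthropometrics
    _cont("age"),
    VariableSpec("sex", "categorical", categories=("male", "female")),
    _cont("bmi"),
    VariableSpec("smoking", "categorical", categories=("smoker", "ex-smoker", "non-smoker")),
    # kidney function and blood biomarkers (ascertainment-period averages)
    _cont("albumin"),
    _cont("acr"),
    _cont("calcium"),
    _cont("egfr"),
    _cont("egfr_slope"),
    _cont("hemoglobin"),
    _cont("phosphate"),
    _cont("urine_protein"),
    _cont("pth"),
    _cont("sodium"),
    _cont("ferritin"),
    # etiology of kidney disease
    _boolean("etiology_diabetes"),
    _boolean("etiology_hypertension", in_model_6=False),
    _boolean("etiology_glomerulonephritis"),
    _boolean("etiology_polycystic"),
    # comorbidities (lifetime, boolean flags)
    _boolean("cerebrovascular_disease"),
    _boolean("chronic_pulmonary_disease"),
    _boolean("congestive_heart_failure"),
    _boolean("connective_tissue_disorder", in_model_6=False),
    _boolean("coronary_artery_disease", in_model_6=False),
    _boolean("dementia"),
    _boolean("diabetes_organ_damage"),
    _boolean("diabetes_no_complications", in_model_6=False),
    _boolean("hemiplegia", in_model_6=False),
    _boolean("hypertension", in_model_6=False),
    _boolean("mild_liver_disease"),
    _boolean("moderate_severe_liver_disease"),
    _boolean("peripheral_vascular_disease"),
    # other
    _cont("n_hospitalizations"),
    _cont("systolic_bp"),
)


def default_variable_specs() -> tuple[VariableSpec, ...]:
    """The full 34-variable registry (24-month membership)."""
    return _REGISTRY


def specs_for_horizon(horizon_months: int) -> tuple[VariableSpec, ...]:
    """Predictors belonging to one forecast horizon (28 or 34)."""
    if horizon_months == 6:
        return tuple(s for s in _REGISTRY if s.in_model_6)
    if horizon_months == 24:
        return tuple(s for s in _REGISTRY if s.in_model_24)
    raise InvalidInputError(f"horizon must be 6 or 24 months, got {horizon_months}")
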