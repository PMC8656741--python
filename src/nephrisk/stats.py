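"""Discrimination, calibration, cutoff and incidence statistics.

Implements the validation framework around the risk models: ROC AUC via
the Mann-Whitney estimator with DeLong variance, paired AUC comparison
with a fixed-sequence non-inferiority -> superiority procedure, quintile
calibration charts, Youden-index cutoff selection, confusion-matrix
rates and exact Poisson incidence-density confidence intervals.

The comparison convention throughout: ``delta = AUC(candidate) -
AUC(comparator)``, so positive deltas favour the candidate. Non-
inferiority (margin 0.05) is decided by the one-sided 95% lower
confidence bound of delta staying above -margin; only when that gate
passes is superiority tested (delta >= margin with two-sided DeLong
p < alpha). The fixed-sequence order keeps the type-I error level
without multiplicity adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidInputError, PairingError, TrainingError

__all__ = [
    "AucResult",
    "auc",
    "ComparisonResult",
    "delong_compare",
    "verdict_from_summary",
    "CalibrationChart",
    "calibration_by_quintile",
    "CutoffMetrics",
    "youden_cutoff",
    "confusion_metrics",
    "IncidenceEstimate",
    "incidence_density",
]

AUC_ACCEPTABLE_THRESHOLD = 0.70  # conventional acceptability bar


def _check_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise InvalidInputError("labels must be binary 0/1")
    pos = labels == 1
    if pos.all() or (~pos).all():
        raise TrainingError("AUC undefined: both outcome classes required")
    return pos, ~pos


def _placements(scores: np.ndarray, pos: np.ndarray, neg: np.ndarray):
    """DeLong structural components (placement values) and the AUC.

    v10[i] = fraction of non-events scored below event i (ties half);
    v01[j] = fraction of events scored above non-event j (ties half).
    """
    x, y = scores[pos], scores[neg]
    m, n = len(x), len(y)
    all_ranks = sps.rankdata(np.concatenate([x, y]))
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    v10 = (all_ranks[:m] - rx) / n
    v01 = 1.0 - (all_ranks[m:] - ry) / m
    a = v10.mean()
    return v10, v01, float(a)


@dataclass(frozen=True)
class AucResult:
    auc: float
    se: float
    ci_lower: float
    ci_upper: float
    n_events: int
    n_nonevents: int

    @property
    def acceptable(self) -> bool:
        """Discrimination above the conventional 0.70 bar."""
        return self.auc > AUC_ACCEPTABLE_THRESHOLD


def auc(scores: Sequence[float], labels: Sequence[int], ci_level: float = 0.95) -> AucResult:
    """Mann-Whitney AUC (ties count 1/2) with a DeLong-variance CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise PairingError("scores and labels must have equal length")
    pos, neg = _check_classes(labels)
    v10, v01, a = _placements(scores, pos, neg)
    m, n = int(pos.sum()), int(neg.sum())
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    se = float(np.sqrt(var))
    z = sps.norm.ppf(0.5 + ci_level / 2)
    return AucResult(
        auc=a,
        se=se,
        ci_lower=max(0.0, a - z * se),
        ci_upper=min(1.0, a + z * se),
        n_events=m,
        n_nonevents=n,
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Paired AUC contrast with a fixed-sequence verdict."""

    auc_candidate: float
    auc_comparator: float
    delta: float  # candidate - comparator
    se_delta: float
    delta_lower_one_sided: float  # one-sided 95% lower bound of delta
    p_value: float  # two-sided DeLong p for delta != 0
    verdict: str  # inferior | non-inferior | superior
    margin: float = 0.05


def _fixed_sequence_verdict(
    delta: float, lower_bound: float, p_value: float, margin: float, alpha: float
) -> str:
    if not lower_bound > -margin:
        return "inferior"
    if delta >= margin and p_value < alpha:
        return "superior"
    return "non-inferior"


def delong_compare(
    scores_candidate: Sequence[float],
    scores_comparator: Sequence[float],
    labels: Sequence[int],
    margin: float = 0.05,
    alpha: float = 0.05,
    one_sided_level: float = 0.95,
) -> ComparisonResult:
    """DeLong paired comparison of two scores on the same records.

    Degenerate case: identical score vectors give delta 0 with zero
    variance; the verdict is non-inferior (not superior) and p = 1.
    """
    sa = np.asarray(scores_candidate, dtype=float)
    sb = np.asarray(scores_comparator, dtype=float)
    labels = np.asarray(labels)
    if sa.shape != sb.shape or sa.shape != labels.shape:
        raise PairingError("paired comparison needs equal-length score/label vectors")
    pos, neg = _check_classes(labels)
    v10a, v01a, auc_a = _placements(sa, pos, neg)
    v10b, v01b, auc_b = _placements(sb, pos, neg)
    m, n = int(pos.sum()), int(neg.sum())
    # covariance of (AUC_a, AUC_b) from the placement values
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_delta = max(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1], 0.0)
    se = float(np.sqrt(var_delta))
    delta = auc_a - auc_b
    if se == 0.0:
        p = 1.0 if delta == 0.0 else 0.0
        lower = delta
    else:
        z = delta / se
        p = float(2 * sps.norm.sf(abs(z)))
        lower = delta - sps.norm.ppf(one_sided_level) * se
    verdict = _fixed_sequence_verdict(delta, lower, p, margin, alpha)
    return ComparisonResult(
        auc_candidate=auc_a,
        auc_comparator=auc_b,
        delta=delta,
        se_delta=se,
        delta_lower_one_sided=lower,
        p_value=p,
        verdict=verdict,
        margin=margin,
    )


def verdict_from_summary(
    delta_candidate_minus_comparator: float,
    p_value: float,
    margin: float = 0.05,
    alpha: float = 0.05,
) -> str:
    """Fixed-sequence verdict from a published (delta, p) summary.

    Used when only the point contrast and p-value are available (no
    record-level scores, hence no confidence bound): non-inferiority is
    judged on the point delta against the margin, then superiority at
    delta >= margin with p < alpha.
    """
    d = delta_candidate_minus_comparator
    if not d > -margin:
        return "inferior"
    if d >= margin and p_value < alpha:
        return "superior"
    return "non-inferior"


@dataclass(frozen=True)
class CalibrationChart:
    """Observed incidence and event share per risk quintile."""

    bin_edges: tuple[float, ...]  # score values separating the bins
    n: tuple[int, ...]
    mean_score: tuple[float, ...]
    incidence: tuple[float, ...]
    event_share: tuple[float, ...]  # fraction of all events per bin (NaN if none)


def calibration_by_quintile(
    scores: Sequence[float], labels: Sequence[int], n_bins: int = 5
) -> CalibrationChart:
    """Partition the scored cohort into score quintiles.

    Bin boundaries sit at score order statistics so bin sizes differ by
    at most one; records sharing an identical score always land in the
    same bin (bins then deviate from exact fifths).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    nrec = len(scores)
    if nrec < n_bins:
        raise InvalidInputError(f"need >= {n_bins} records")
    order = np.argsort(scores, kind="stable")
    base_bin = np.floor(np.arange(nrec) * n_bins / nrec).astype(int)
    # force ties into the bin of their first occurrence
    sorted_scores = scores[order]
    for i in range(1, nrec):
        if sorted_scores[i] == sorted_scores[i - 1]:
            base_bin[i] = base_bin[i - 1]
    bins = np.empty(nrec, dtype=int)
    bins[order] = base_bin
    total_events = labels.sum()
    edges, ns, means, inc, share = [], [], [], [], []
    for b in range(n_bins):
        mask = bins == b
        nb = int(mask.sum())
        ns.append(nb)
        if nb == 0:
            means.append(float("nan"))
            inc.append(float("nan"))
            share.append(0.0 if total_events > 0 else float("nan"))
            continue
        means.append(float(scores[mask].mean()))
        ev = labels[mask].sum()
        inc.append(float(ev / nb))
        share.append(float(ev / total_events) if total_events > 0 else float("nan"))
        if b < n_bins - 1:
            edges.append(float(sorted_scores[np.searchsorted(base_bin, b + 1)])
                         if (base_bin == b + 1).any() else float("nan"))
    return CalibrationChart(
        bin_edges=tuple(edges),
        n=tuple(ns),
        mean_score=tuple(means),
        incidence=tuple(inc),
        event_share=tuple(share),
    )


@dataclass(frozen=True)
class CutoffMetrics:
    """Operating-point rates; NaN marks undefined (zero-denominator) rates."""

    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    false_omission_rate: float

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def confusion_metrics(tp: int, fp: int, fn: int, tn: int, cutoff: float = float("nan")) -> CutoffMetrics:
    """Rates from confusion counts; undefined rates come back as NaN."""
    for c in (tp, fp, fn, tn):
        if c < 0:
            raise InvalidInputError("confusion counts must be non-negative")

    def _ratio(num, den):
        return num / den if den > 0 else float("nan")

    return CutoffMetrics(
        cutoff=cutoff,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        false_omission_rate=_ratio(fn, fn + tn),
    )


def youden_cutoff(scores: Sequence[float], labels: Sequence[int]) -> CutoffMetrics:
    """Cutoff maximizing Youden's index over observed score values.

    The classification rule is ``score > cutoff``; ties in the index are
    broken toward the lower cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos, neg = _check_classes(labels)
    best = None
    for c in np.unique(scores):
        tp = int(((scores > c) & pos).sum())
        fp = int(((scores > c) & neg).sum())
        fn = int(pos.sum()) - tp
        tn = int(neg.sum()) - fp
        metrics = confusion_metrics(tp, fp, fn, tn, cutoff=float(c))
        if best is None or metrics.youden > best.youden:
            best = metrics
    return best


@dataclass(frozen=True)
class IncidenceEstimate:
    """Incidence density per 100 person-years with exact Poisson CI."""

    events: int
    person_years: float
    rate_per_100py: float
    ci_lower: float
    ci_upper: float
    level: float = 0.95


def incidence_density(
    events: int, person_years: float, level: float = 0.95
) -> IncidenceEstimate:
    """Event rate per 100 person-years with chi-square exact Poisson CI.

    Lower bound is 0 for zero events; bounds scale inversely with
    person-time (rate equivariance).
    """
    if events < 0:
        raise InvalidInputError("events must be >= 0")
    if person_years <= 0:
        raise InvalidInputError("person_years must be > 0")
    a = (1 - level) / 2
    lo_count = 0.0 if events == 0 else sps.chi2.ppf(a, 2 * events) / 2
    hi_count = sps.chi2.ppf(1 - a, 2 * events + 2) / 2
    scale = 100.0 / person_years
    return IncidenceEstimate(
        events=events,
        person_years=person_years,
        rate_per_100py=events * scale,
        ci_lower=lo_count * scale,
        ci_upper=hi_count * scale,
        level=level,
    )
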