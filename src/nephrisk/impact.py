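"""Referral-impact simulation: events prevented and number needed to treat.

Models a two-arm referral policy on a hypothetical CKD population: the
``n_referred`` patients flagged high-risk enter an intensified
prevention program that divides their ESKD risk by ``effect_size``
(a risk ratio > 1); everyone else receives standard care. The risk
among referred patients is the operating point's PPV, among
non-referred patients the false omission rate (FOR). All arithmetic is
on expectations (no Monte Carlo needed):

    prevented = n_referred * PPV * (1 - 1/effect_size)
    NNT       = n_referred / prevented = 1 / (PPV * (1 - 1/effect_size))

i.e. the NNT is the reciprocal of the absolute risk difference between
standard care and the intervention among the referred. Reported
integers use nearest-integer rounding; raw expectations are retained.

The referral count is an input, not derived from PPV/FOR/baseline:
published operating points are typically rounded and do not solve the
accounting identity exactly, so the simulator checks consistency and
warns rather than re-deriving.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import InvalidInputError

__all__ = [
    "ReferralScenario",
    "ImpactResult",
    "simulate_referral",
    "nnt_from_operating_point",
    "all_in_strategy",
]


@dataclass(frozen=True)
class ReferralScenario:
    """One referral policy on a hypothetical population.

    ``baseline_events`` is the expected ESKD count within the horizon if
    *everyone* received standard care; ``effect_size`` is the risk ratio
    of standard care vs the intensified program (1.5 means the standard
    arm faces 50% higher risk).
    """

    n_population: int
    baseline_events: float
    effect_size: float
    ppv: float
    for_rate: float
    n_referred: int

    def __post_init__(self) -> None:
        if self.n_referred > self.n_population:
            raise InvalidInputError("cannot refer more patients than the population")
        if self.effect_size <= 0:
            raise InvalidInputError("effect size must be > 0")
        for name in ("ppv", "for_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidInputError(f"{name} must lie in [0,1]")


@dataclass(frozen=True)
class ImpactResult:
    """Expected event accounting for one scenario.

    ``nnt`` / ``events_prevented`` are the nearest-integer reported
    values; ``*_raw`` retain the unrounded expectations. ``nnt_raw`` is
    NaN (undefined marker) for a null intervention.
    """

    events_referred_arm: float  # expected events among referred, under intervention
    events_standard_arm: float  # expected events among non-referred
    total_events: float
    events_prevented_raw: float
    events_prevented: int
    overall_effect_size: float  # baseline_events / total_events
    nnt_raw: float
    nnt: int | None


def _finish(
    baseline_events: float, referred_arm: float, standard_arm: float,
    prevented: float, n_treated: float
) -> ImpactResult:
    total = referred_arm + standard_arm
    nnt_raw = n_treated / prevented if prevented > 0 else float("nan")
    return ImpactResult(
        events_referred_arm=referred_arm,
        events_standard_arm=standard_arm,
        total_events=total,
        events_prevented_raw=prevented,
        events_prevented=round(prevented),
        overall_effect_size=baseline_events / total if total > 0 else float("nan"),
        nnt_raw=nnt_raw,
        nnt=round(nnt_raw) if nnt_raw == nnt_raw else None,
    )


def simulate_referral(scenario: ReferralScenario) -> ImpactResult:
    """Expected impact of referring the flagged patients.

    Emits a ``UserWarning`` (not an error) when the operating point and
    baseline disagree by more than 2% -- published operating points are
    often mildly inconsistent after rounding.
    """
    s = scenario
    referred_standard = s.n_referred * s.ppv
    referred_intervention = referred_standard / s.effect_size
    standard_arm = (s.n_population - s.n_referred) * s.for_rate
    implied_baseline = referred_standard + standard_arm
    if s.baseline_events > 0:
        rel = abs(implied_baseline - s.baseline_events) / s.baseline_events
        if rel > 0.02:
            warnings.warn(
                f"operating point implies {implied_baseline:.1f} baseline events "
                f"vs stated {s.baseline_events:.1f} ({rel:.1%} off)",
                UserWarning,
                stacklevel=2,
            )
    prevented = referred_standard - referred_intervention
    return _finish(
        s.baseline_events, referred_intervention, standard_arm, prevented, s.n_referred
    )


def nnt_from_operating_point(ppv: float, effect_size: float) -> tuple[float, int | None]:
    """(raw, reported) NNT from PPV and intervention effect size.

    NNT = 1 / (PPV * (1 - 1/effect_size)); undefined (NaN, None) when
    PPV is 0 or the intervention has no effect.
    """
    if not (0.0 <= ppv <= 1.0):
        raise InvalidInputError("ppv must lie in [0,1]")
    if effect_size <= 0:
        raise InvalidInputError("effect size must be > 0")
    if ppv == 0 or effect_size <= 1:
        return float("nan"), None
    raw = 1.0 / (ppv * (1.0 - 1.0 / effect_size))
    return raw, round(raw)


def all_in_strategy(
    n_population: int, baseline_events: float, effect_size: float
) -> ImpactResult:
    """Refer everyone: the risk-averse comparator policy.

    Equivalent to :func:`simulate_referral` with the whole population
    referred at PPV = baseline_events / n_population.
    """
    if baseline_events > n_population:
        raise InvalidInputError("baseline events cannot exceed the population")
    if effect_size <= 0:
        raise InvalidInputError("effect size must be > 0")
    referred_intervention = baseline_events / effect_size
    prevented = baseline_events - referred_intervention
    return _finish(baseline_events, referred_intervention, 0.0, prevented, n_population)
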