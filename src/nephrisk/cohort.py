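"""Patient/cohort data model and feature engineering.

Covers kidney-function estimation (2009 CKD-EPI creatinine equation),
GFR staging (KDIGO G1-G5 bands), the 12-month ascertainment features
(lab averaging and eGFR slope), urine protein-to-creatinine conversion,
and assembly of the kidney-replacement-therapy (KRT) endpoint at a fixed
horizon.

Cohorts are plain :class:`pandas.DataFrame` objects, one row per
patient-visit, with missing values as NaN/empty cells; longitudinal lab
values travel in a long-format table ``(patient_id, variable, date,
value)``. Units are fixed at the I/O boundary (eGFR in mL/min/1.73 m^2,
ACR in mg/mmol, creatinine in mg/dL); no unit inference is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputFormatError, InvalidInputError

__all__ = [
    "GfrEquationParams",
    "EndpointStatus",
    "STAGE_ORDER",
    "STAGE_LOWER_BOUNDS",
    "estimate_gfr",
    "stage_from_gfr",
    "ascertainment_mean",
    "egfr_slope",
    "pcr_to_acr",
    "assemble_endpoint",
    "assemble_endpoints_frame",
    "read_cohort",
    "write_cohort",
    "read_lab_table",
]

DAYS_PER_MONTH = 30.4375  # mean Gregorian month
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class GfrEquationParams:
    """Coefficients of a CKD-EPI-style creatinine equation.

    Defaults are the published 2009 creatinine equation. Parameters are
    data so recalibrated or alternative equations can be injected. The
    ancestry multiplier defaults to 1 (ancestry is not a model input).
    """

    kappa: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.9, "female": 0.7}
    )
    alpha: Mapping[str, float] = field(
        default_factory=lambda: {"male": -0.411, "female": -0.329}
    )
    max_exponent: float = -1.209
    age_decay: float = 0.993
    scale: float = 141.0
    sex_multiplier: Mapping[str, float] = field(
        default_factory=lambda: {"male": 1.0, "female": 1.018}
    )
    ancestry_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if any(k <= 0 for k in self.kappa.values()):
            raise InvalidInputError("kappa must be positive")


def estimate_gfr(
    scr: float,
    age: float,
    sex: str,
    params: GfrEquationParams | None = None,
) -> float:
    """Estimated GFR (mL/min/1.73 m^2) from serum creatinine (mg/dL).

    Implements ``scale * min(scr/kappa, 1)^alpha * max(scr/kappa, 1)^c
    * age_decay^age * sex_mult * ancestry_mult`` with sex-specific kappa
    and alpha. Strictly decreasing in both creatinine and age.
    """
    if params is None:
        params = GfrEquationParams()
    if not np.isfinite(scr) or scr <= 0:
        raise InvalidInputError(f"serum creatinine must be > 0, got {scr!r}")
    if age < 18:
        raise InvalidInputError("adult equation: age must be >= 18")
    sex = _norm_sex(sex)
    ratio = scr / params.kappa[sex]
    egfr = (
        params.scale
        * min(ratio, 1.0) ** params.alpha[sex]
        * max(ratio, 1.0) ** params.max_exponent
        * params.age_decay**age
        * params.sex_multiplier[sex]
        * params.ancestry_multiplier
    )
    return float(egfr)


def _norm_sex(sex: str) -> str:
    s = str(sex).strip().lower()
    if s in ("m", "male"):
        return "male"
    if s in ("f", "female"):
        return "female"
    raise InvalidInputError(f"unrecognized sex {sex!r}")


# KDIGO bands as half-open real intervals [lower, upper) so every
# non-negative eGFR is classifiable (printed integer ranges "45-59" etc.
# become [45, 60), consistent with G2 60-89 meeting G1 >= 90).
STAGE_ORDER: tuple[str, ...] = ("G5", "G4", "G3b", "G3a", "G2", "G1")
STAGE_LOWER_BOUNDS: tuple[float, ...] = (0.0, 15.0, 30.0, 45.0, 60.0, 90.0)


def stage_from_gfr(egfr: float) -> str:
    """KDIGO GFR category (G1..G5) for one eGFR value."""
    if not np.isfinite(egfr) or egfr < 0:
        raise InvalidInputError(f"eGFR must be >= 0, got {egfr!r}")
    idx = int(np.searchsorted(STAGE_LOWER_BOUNDS, egfr, side="right")) - 1
    return STAGE_ORDER[idx]


def _in_window(
    obs: Sequence[tuple[date, float]], index_date: date, window_months: float
) -> list[tuple[float, float]]:
    """Observations in (index - window, index], as (years-before-index, value).

    The window includes index-day labs; the open lower edge drops
    anything exactly ``window`` months old or older.
    """
    lo = index_date - timedelta(days=window_months * DAYS_PER_MONTH)
    out = []
    for d, v in obs:
        if lo < d <= index_date and np.isfinite(v):
            t_years = (d - index_date).days / DAYS_PER_YEAR
            out.append((t_years, float(v)))
    return out


def ascertainment_mean(
    observations: Sequence[tuple[date, float]],
    index_date: date,
    window_months: float = 12.0,
) -> float | None:
    """Mean of lab observations in the ascertainment window, or None.

    Blood biomarkers enter the risk model averaged over the 12 months
    before the index visit; absence (no in-window observation) is a
    valid outcome, not an error.
    """
    vals = [v for _, v in _in_window(observations, index_date, window_months)]
    if not vals:
        return None
    return float(np.mean(vals))


def egfr_slope(
    observations: Sequence[tuple[date, float]],
    index_date: date,
    window_months: float = 12.0,
) -> float | None:
    """OLS slope of eGFR on time (per year) over the ascertainment window.

    Returns None with fewer than two in-window observations; with
    exactly two the slope is the secant. Order of observations is
    irrelevant.
    """
    pts = _in_window(observations, index_date, window_months)
    if len(pts) < 2:
        return None
    t = np.array([p[0] for p in pts])
    v = np.array([p[1] for p in pts])
    if np.ptp(t) == 0:  # all same day: slope undefined
        return None
    slope = np.polyfit(t, v, 1)[0]
    return float(slope)


def pcr_to_acr(pcr: float, factor: float = 0.6) -> float:
    """Convert urine protein-creatinine ratio to ACR (both mg/mmol).

    The default multiplicative factor 0.6 is the published conversion
    used when ACR itself was not assayed.
    """
    if not np.isfinite(pcr) or pcr < 0:
        raise InvalidInputError(f"PCR must be >= 0, got {pcr!r}")
    return factor * pcr


@dataclass(frozen=True)
class EndpointStatus:
    """Outcome of one patient at one horizon.

    ``status`` is exactly one of ``event`` (chronic KRT started within
    the horizon), ``excluded-death`` (death preceded both KRT and the
    horizon end; such patients are excluded from training/validation),
    ``lost-to-follow-up`` (no creatinine assessment after the horizon
    end and no dialysis-dependence note) or ``event-free``.
    """

    horizon_months: int
    status: str
    time_to_event_months: float | None = None

    def __post_init__(self) -> None:
        if self.status not in ("event", "event-free", "excluded-death", "lost-to-follow-up"):
            raise InvalidInputError(f"unknown status {self.status!r}")
        if self.status == "event":
            if self.time_to_event_months is None:
                raise InvalidInputError("event requires time_to_event_months")
            if self.time_to_event_months > self.horizon_months + 1e-9:
                raise InvalidInputError("time_to_event exceeds horizon")


def assemble_endpoint(
    index_date: date,
    horizon_months: int,
    krt_date: date | None = None,
    krt_acute: bool = False,
    death_date: date | None = None,
    last_creatinine_date: date | None = None,
    dialysis_dependence_note: bool = False,
) -> EndpointStatus:
    """Classify one patient history into an :class:`EndpointStatus`.

    Acute/transient dialysis episodes (``krt_acute=True``) are not
    endpoint events and are ignored entirely.
    """
    if krt_date is not None and krt_date < index_date:
        raise InvalidInputError("KRT before index date: inconsistent history")
    if death_date is not None and death_date < index_date:
        raise InvalidInputError("death before index date: inconsistent history")

    if krt_acute:
        krt_date = None
    horizon_end = index_date + timedelta(days=horizon_months * DAYS_PER_MONTH)

    krt_in_horizon = krt_date is not None and krt_date <= horizon_end
    death_first = death_date is not None and death_date <= horizon_end and (
        krt_date is None or death_date < krt_date
    )
    if krt_in_horizon and not death_first:
        months = (krt_date - index_date).days / DAYS_PER_MONTH
        return EndpointStatus(horizon_months, "event", min(months, float(horizon_months)))
    if death_first:
        return EndpointStatus(horizon_months, "excluded-death")
    followed = (
        dialysis_dependence_note
        or (last_creatinine_date is not None and last_creatinine_date > horizon_end)
    )
    if not followed:
        return EndpointStatus(horizon_months, "lost-to-follow-up")
    return EndpointStatus(horizon_months, "event-free")


def assemble_endpoints_frame(
    histories: pd.DataFrame, horizon_months: int
) -> pd.DataFrame:
    """Vector version of :func:`assemble_endpoint` over a history table.

    Expects columns ``patient_id, index_date`` and optionally
    ``krt_date, krt_acute, death_date, last_creatinine_date,
    dialysis_dependence_note``; returns ``patient_id, status, event,
    time_to_event_months`` where ``event`` is 1/0 and NaN for excluded
    or lost rows.
    """
    rows = []
    for _, r in histories.iterrows():
        st = assemble_endpoint(
            index_date=_as_date(r["index_date"]),
            horizon_months=horizon_months,
            krt_date=_as_date(r.get("krt_date")),
            krt_acute=bool(r.get("krt_acute", False)),
            death_date=_as_date(r.get("death_date")),
            last_creatinine_date=_as_date(r.get("last_creatinine_date")),
            dialysis_dependence_note=bool(r.get("dialysis_dependence_note", False)),
        )
        rows.append(
            {
                "patient_id": r["patient_id"],
                "status": st.status,
                "event": {"event": 1.0, "event-free": 0.0}.get(st.status, np.nan),
                "time_to_event_months": st.time_to_event_months,
            }
        )
    return pd.DataFrame(rows)


def _as_date(x) -> date | None:
    if x is None or (isinstance(x, float) and np.isnan(x)) or (isinstance(x, str) and not x):
        return None
    if isinstance(x, date) and not isinstance(x, pd.Timestamp):
        return x
    ts = pd.Timestamp(x)
    if pd.isna(ts):
        return None
    return ts.date()


def read_cohort(path) -> pd.DataFrame:
    """Read a one-row-per-visit cohort table (CSV, empty cells = missing)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - message passthrough
        raise InputFormatError(f"cannot parse cohort table {path}: {exc}") from exc
    if df.empty or df.shape[1] == 0:
        raise InputFormatError(f"cohort table {path} is empty")
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_lab_table(path) -> pd.DataFrame:
    """Read a long-format lab table (patient_id, variable, date, value)."""
    df = pd.read_csv(path)
    required = {"patient_id", "variable", "date", "value"}
    missing = required - set(df.columns)
    if missing:
        raise InputFormatError(f"lab table missing columns: {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def series_features(
    labs: pd.DataFrame,
    index_dates: Mapping,
    variables: Iterable[str],
    window_months: float = 12.0,
) -> pd.DataFrame:
    """Ascertainment means (and eGFR slope) for every patient.

    ``index_dates`` maps patient_id -> index date. Produces one row per
    patient with a ``<variable>`` column per averaged lab and an
    ``egfr_slope`` column when eGFR series are present.
    """
    out: dict = {}
    for pid, grp in labs.groupby("patient_id"):
        if pid not in index_dates:
            continue
        idx = _as_date(index_dates[pid])
        row: dict = {"patient_id": pid}
        for var in variables:
            obs = [
                (d, v)
                for d, v in zip(grp.loc[grp["variable"] == var, "date"],
                                grp.loc[grp["variable"] == var, "value"])
            ]
            m = ascertainment_mean(obs, idx, window_months)
            if m is not None:
                row[var] = m
            if var == "egfr":
                s = egfr_slope(obs, idx, window_months)
                if s is not None:
                    row["egfr_slope"] = s
        out[pid] = row
    return pd.DataFrame(out.values())
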