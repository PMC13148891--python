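"""Split-luciferase luminescence analysis.

Two assay formats are covered.  The lytic HiBiT assay measures total
HiBiT-tagged glycoprotein in a prep (log10 RLU summaries, dilution
linearity, background subtraction against PBS wells).  The live-cell LgBiT
reporter assay follows transduction in real time: each well's RLU series is
divided by its own pre-treatment baseline to remove well-to-well scale,
replicate wells are averaged per time point, and the mean curve is
summarized by its peak and by the earliest time after which it stays within
a tolerance band of its final level (the plateau).  Treatment effects
(e.g. an endosomal-acidification inhibitor) are reported as control/treated
fold changes, dose response as ratios to the smallest dose, and the link to
genome editing as an OLS of editing % on log10 RLU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WellRecord",
    "TimeCourse",
    "KineticsSummary",
    "CorrelationResult",
    "LyticTiter",
    "read_timecourse",
    "wells_from_frame",
    "normalize_wells",
    "summarize_kinetics",
    "fold_change",
    "dose_linearity",
    "correlate_editing",
    "lytic_titer",
]


@dataclass(frozen=True)
class WellRecord:
    """One well's luminescence time course plus its pre-treatment baseline."""

    well: str
    condition: str
    baseline_rlu: float
    times_h: tuple[float, ...]
    rlu: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times_h) != len(self.rlu):
            raise ValueError("times and RLUs differ in length")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class TimeCourse:
    """Baseline-normalized replicate summary for one condition."""

    condition: str
    times_h: tuple[float, ...]
    mean: tuple[float, ...]
    sd: tuple[float, ...]
    n_wells: int
    excluded_wells: tuple[str, ...] = ()

    def at(self, t: float) -> tuple[float, float]:
        """(mean, sd) at the time point nearest ``t``.

        The match must lie within half the local sampling interval.
        """
        times = np.asarray(self.times_h)
        i = int(np.argmin(np.abs(times - t)))
        gaps = np.diff(times)
        local = gaps[min(i, len(gaps) - 1)] if len(gaps) else np.inf
        if abs(times[i] - t) > local / 2:
            raise ValueError(f"no time point within {local / 2:g} h of t={t:g}")
        return self.mean[i], self.sd[i]


@dataclass(frozen=True)
class KineticsSummary:
    condition: str
    peak: float
    peak_time_h: float
    plateau_time_h: float | None
    plateau_level: float
    censored: bool


@dataclass(frozen=True)
class CorrelationResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class LyticTiter:
    sample: str
    log10_rlu_mean: float
    log10_rlu_sd: float
    rlu_per_ul: float  # background-subtracted, dilution-corrected
    flags: tuple[str, ...] = ()


def read_timecourse(path, baseline_time_h: float = -1.0) -> list[WellRecord]:
    """Read a long-format CSV ``well,condition,time_h,rlu``.

    Rows at ``baseline_time_h`` (pre-treatment) become each well's baseline.
    """
    return wells_from_frame(pd.read_csv(path), baseline_time_h)


def wells_from_frame(df: pd.DataFrame, baseline_time_h: float = -1.0) -> list[WellRecord]:
    out = []
    for (well, condition), sub in df.groupby(["well", "condition"], sort=False):
        sub = sub.sort_values("time_h")
        base = sub[np.isclose(sub["time_h"], baseline_time_h)]
        if base.empty:
            raise ValueError(f"well {well!r} lacks a baseline row at t={baseline_time_h}")
        series = sub[sub["time_h"] > baseline_time_h]
        out.append(
            WellRecord(
                well=str(well),
                condition=str(condition),
                baseline_rlu=float(base["rlu"].mean()),
                times_h=tuple(series["time_h"]),
                rlu=tuple(series["rlu"]),
            )
        )
    return out


def normalize_wells(wells: list[WellRecord]) -> TimeCourse:
    """Per-well baseline normalization, then mean ± SD over replicates.

    Each series is divided by its own pre-treatment RLU, cancelling
    well-to-well scale; wells with a non-positive baseline are excluded
    and flagged.  All wells must share one condition and one time grid.
    """
    if not wells:
        raise ValueError("no wells given")
    conditions = {w.condition for w in wells}
    if len(conditions) > 1:
        raise ValueError(f"wells span multiple conditions: {sorted(conditions)}")
    excluded = tuple(w.well for w in wells if w.baseline_rlu <= 0)
    usable = [w for w in wells if w.baseline_rlu > 0]
    if not usable:
        raise ValueError("no well has a positive baseline")
    grids = {w.times_h for w in usable}
    if len(grids) > 1:
        raise ValueError("replicate wells are on different time grids")
    norm = np.array([np.asarray(w.rlu) / w.baseline_rlu for w in usable])
    return TimeCourse(
        condition=usable[0].condition,
        times_h=usable[0].times_h,
        mean=tuple(norm.mean(axis=0)),
        sd=tuple(norm.std(axis=0, ddof=1) if len(usable) > 1 else np.zeros(norm.shape[1])),
        n_wells=len(usable),
        excluded_wells=excluded,
    )


def summarize_kinetics(
    tc: TimeCourse,
    plateau_tolerance: float = 0.05,
    final_window_h: float = 1.0,
) -> KineticsSummary:
    """Peak and plateau of a mean luminescence curve.

    The plateau level is the mean over the final ``final_window_h`` hours;
    the plateau time is the earliest time after which the curve never
    leaves ``±plateau_tolerance`` (relative) of that level.  A curve that
    is still moving at the last point is flagged censored.
    """
    times = np.asarray(tc.times_h, dtype=float)
    mean = np.asarray(tc.mean, dtype=float)
    if len(times) < 4 or times[-1] - times[0] < 2.0:
        raise ValueError("need >= 4 time points spanning >= 2 h")
    level = float(mean[times >= times[-1] - final_window_h].mean())
    band = plateau_tolerance * abs(level)
    inside = np.abs(mean - level) <= band
    # earliest index from which every later point stays inside the band
    plateau_time: float | None = None
    for i in range(len(times)):
        if inside[i:].all():
            plateau_time = float(times[i])
            break
    peak_i = int(np.argmax(mean))
    return KineticsSummary(
        condition=tc.condition,
        peak=float(mean[peak_i]),
        peak_time_h=float(times[peak_i]),
        plateau_time_h=plateau_time,
        plateau_level=level,
        censored=plateau_time is None,
    )


def fold_change(
    treated: TimeCourse, control: TimeCourse, t: float
) -> tuple[float, float]:
    """Control/treated mean ratio at time ``t`` (values > 1 mean reduction).

    SD is propagated from the two relative errors.  A treated mean of 0
    yields inf rather than an exception.
    """
    c_mean, c_sd = control.at(t)
    t_mean, t_sd = treated.at(t)
    if t_mean == 0:
        return float("inf"), float("nan")
    ratio = c_mean / t_mean
    sd = abs(ratio) * np.sqrt(
        (c_sd / c_mean) ** 2 + (t_sd / t_mean) ** 2
    ) if c_mean else float("nan")
    return float(ratio), float(sd)


def dose_linearity(
    doses: list[tuple[float, TimeCourse]],
    t: float,
    tolerance: float = 0.30,
) -> pd.DataFrame:
    """Dose-response proportionality at time ``t``.

    Each dose's mean signal is ratioed to the smallest dose's; the ratio is
    proportional when it lies within ``±tolerance`` (relative) of the
    volume ratio, otherwise the dose is flagged saturated (below) or
    superlinear (above).
    """
    if len(doses) < 2:
        raise ValueError("need at least two doses")
    doses = sorted(doses, key=lambda d: d[0])
    v0, tc0 = doses[0]
    m0, _ = tc0.at(t)
    rows = []
    for v, tc in doses:
        m, _ = tc.at(t)
        ratio = m / m0
        expected = v / v0
        rel = ratio / expected - 1.0
        if abs(rel) <= tolerance:
            flag = "proportional"
        elif rel < 0:
            flag = "saturated"
        else:
            flag = "superlinear"
        rows.append(
            {"volume_ul": v, "ratio": ratio, "expected_ratio": expected, "flag": flag}
        )
    return pd.DataFrame(rows)


def correlate_editing(points: list[tuple[float, float]]) -> CorrelationResult:
    """OLS of editing efficiency (%) on log10 RLU.

    ``points`` are (log10 RLU, editing %) pairs, replicate-level when
    available.
    """
    if len(points) < 3:
        raise ValueError("need >= 3 points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("predictor has zero variance")
    fit = stats.linregress(x, y)
    return CorrelationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(points),
    )


def lytic_titer(
    rlus: list[float],
    background_rlus: list[float],
    dilution: float = 1.0,
    sample: str = "prep",
) -> LyticTiter:
    """Lytic-assay summary for one prep at one dilution.

    Reports mean ± SD of log10 RLU over replicates (non-positive readings
    are excluded with a flag) and a background-subtracted linear value
    rescaled by the dilution factor to an undiluted per-μL basis; samples
    below background floor at 0 with a flag.
    """
    if not rlus:
        raise ValueError("need >= 1 replicate RLU")
    if dilution < 1:
        raise ValueError("dilution factor must be >= 1")
    flags: list[str] = []
    positive = [r for r in rlus if r > 0]
    if len(positive) < len(rlus):
        flags.append(f"excluded_nonpositive:{len(rlus) - len(positive)}")
    if not positive:
        return LyticTiter(sample, float("nan"), float("nan"), 0.0,
                          tuple(flags) + ("non_quantifiable",))
    logs = np.log10(positive)
    background = float(np.mean(background_rlus)) if background_rlus else 0.0
    net = float(np.mean(positive)) - background
    if net < 0:
        net = 0.0
        flags.append("below_background")
    return LyticTiter(
        sample=sample,
        log10_rlu_mean=float(np.mean(logs)),
        log10_rlu_sd=float(np.std(logs, ddof=1)) if len(logs) > 1 else 0.0,
        rlu_per_ul=net * dilution,
        flags=tuple(flags),
    )
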