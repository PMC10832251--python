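"""CDC bottle bioassay: mortality series, diagnostic parameters, resistance calls.

A bottle bioassay exposes batches of flies (typically 4 bottles x 25 flies
plus one acetone-only control bottle) to an insecticide-coated surface and
scores cumulative mortality every 15 min up to 2 h.  The diagnostic dose/time
pair is calibrated on a susceptible reference strain as the smallest dose that
kills 100% of every bottle within the observation window, together with the
earliest grid time at which it does so.  A field population is then classified
susceptible when its pooled, control-corrected mortality at the diagnostic
time reaches the threshold (default 100%), resistant otherwise.

Control mortality is handled with Abbott's correction, (T - C) / (1 - C); a
run whose control mortality exceeds 10% is invalid, following standard bottle
bioassay practice.  Bottles are pooled (sum dead / sum exposed), matching the
aggregate-mortality reading of the CDC guideline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .popgen import round_half_up

#: the observation grid, minutes
TIME_GRID = (0, 15, 30, 45, 60, 75, 90, 105, 120)

#: control bottles with mortality above this proportion invalidate the run
MAX_CONTROL_MORTALITY = 0.10


class SeriesValidationError(ValueError):
    """A mortality series violates its invariants; names the bottle and time."""


class NoDiagnosticError(ValueError):
    """No dose in the susceptible panel achieved full kill within the window."""


@dataclass(frozen=True)
class MortalitySeries:
    """One bottle's cumulative mortality at fixed time points."""

    bottle_id: str
    location: str
    dose: float                       # ug/ml; 0 for the acetone control
    n_insects: int = 25
    time_points: tuple = TIME_GRID
    cumulative_dead: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "time_points", tuple(int(t) for t in self.time_points))
        object.__setattr__(self, "cumulative_dead", tuple(int(d) for d in self.cumulative_dead))

    def mortality_at(self, time: int) -> float:
        """Proportion dead at a grid time."""
        try:
            idx = self.time_points.index(time)
        except ValueError:
            raise SeriesValidationError(
                f"bottle {self.bottle_id}: time {time} min is not on the observation grid"
            ) from None
        return self.cumulative_dead[idx] / self.n_insects


def validate_series(series: MortalitySeries) -> MortalitySeries:
    """Enforce the series invariants; returns the series unchanged if valid."""
    problems = []
    bid = series.bottle_id
    if series.n_insects <= 0:
        problems.append(f"bottle {bid}: n_insects must be positive")
    if len(series.cumulative_dead) != len(series.time_points):
        problems.append(
            f"bottle {bid}: {len(series.cumulative_dead)} death counts for "
            f"{len(series.time_points)} time points"
        )
    if any(b >= a for a, b in zip(series.time_points[1:], series.time_points)):
        problems.append(f"bottle {bid}: time grid must be strictly increasing")
    prev = None
    for t, d in zip(series.time_points, series.cumulative_dead):
        if d < 0 or d > series.n_insects:
            problems.append(
                f"bottle {bid} at {t} min: dead count {d} outside [0, {series.n_insects}]"
            )
        if prev is not None and d < prev:
            problems.append(
                f"bottle {bid} at {t} min: cumulative deaths decreased ({prev} -> {d})"
            )
        prev = d
    if problems:
        raise SeriesValidationError("; ".join(problems))
    return series


@dataclass(frozen=True)
class AssayRun:
    """All bottles of one location/date: treated replicates plus one control."""

    location: str
    treated: tuple
    control: MortalitySeries
    date: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "treated", tuple(self.treated))
        if not self.treated:
            raise SeriesValidationError(f"{self.location}: no treated bottles")
        doses = {s.dose for s in self.treated}
        if len(doses) != 1:
            raise SeriesValidationError(
                f"{self.location}: treated bottles at mixed doses {sorted(doses)}"
            )
        if self.control.dose != 0:
            raise SeriesValidationError(
                f"{self.location}: control bottle has nonzero dose {self.control.dose}"
            )
        for s in (*self.treated, self.control):
            validate_series(s)

    @property
    def dose(self) -> float:
        return self.treated[0].dose

    def pooled_mortality_at(self, time: int) -> float:
        dead = sum(s.cumulative_dead[s.time_points.index(time)] for s in self.treated)
        n = sum(s.n_insects for s in self.treated)
        return dead / n


@dataclass(frozen=True)
class DiagnosticParams:
    """Diagnostic dose (ug/ml) and time (min) from the susceptible panel."""

    dose: float
    time: int

    def __post_init__(self) -> None:
        if self.dose <= 0 or self.time <= 0:
            raise ValueError("diagnostic dose and time must be positive")


@dataclass(frozen=True)
class ResistanceCall:
    location: str
    status: str                        # susceptible | resistant | invalid
    mortality_at_diagnostic: Optional[float]  # corrected, percent
    time_to_full_mortality: Optional[int]     # minutes, or None if never 100%
    note: str = ""


def abbott_correct(treated_mortality: float, control_mortality: float) -> float:
    """Abbott's control correction, clamped to [0, 1]; identity at zero control."""
    for name, v in (("treated", treated_mortality), ("control", control_mortality)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} mortality must be a proportion in [0, 1], got {v}")
    if control_mortality >= 1.0:
        raise ValueError("control mortality of 100% leaves the correction undefined")
    corrected = (treated_mortality - control_mortality) / (1.0 - control_mortality)
    return min(1.0, max(0.0, corrected))


def time_to_full_mortality(run: AssayRun) -> Optional[int]:
    """Earliest grid time at which pooled raw mortality reaches 100%, or None."""
    for t in run.treated[0].time_points:
        if run.pooled_mortality_at(t) >= 1.0:
            return t
    return None


def diagnostic_from_susceptible(panel: Sequence) -> DiagnosticParams:
    """Diagnostic dose and time from a susceptible-strain dose ladder.

    The diagnostic dose is the smallest dose at which *every* treated bottle
    reaches 100% mortality within the observation window; the diagnostic time
    is the earliest grid time at which all bottles at that dose are at 100%.
    """
    panel = list(panel)
    doses = sorted({run.dose for run in panel})
    if len(doses) < 2:
        raise ValueError("susceptible panel needs at least two doses")
    for dose in doses:
        runs = [r for r in panel if r.dose == dose]
        per_bottle_full = []
        for run in runs:
            for s in run.treated:
                full_times = [
                    t for t, d in zip(s.time_points, s.cumulative_dead) if d >= s.n_insects
                ]
                per_bottle_full.append(min(full_times) if full_times else None)
        if all(t is not None for t in per_bottle_full):
            return DiagnosticParams(dose=dose, time=max(per_bottle_full))
    raise NoDiagnosticError(
        f"no dose in {doses} achieved 100% kill in every bottle within the window; "
        "extend the ladder to higher doses"
    )


def classify_run(
    run: AssayRun,
    params: DiagnosticParams,
    threshold: float = 100.0,
) -> ResistanceCall:
    """Susceptible/resistant call for one field run at the diagnostic parameters.

    Pooled treated mortality at the diagnostic time is Abbott-corrected with
    the control bottle's mortality at the same time; corrected mortality >=
    ``threshold`` (percent) means susceptible.  Control mortality above 10%
    invalidates the run.
    """
    if run.dose != params.dose:
        raise ValueError(
            f"{run.location}: run dose {run.dose} differs from diagnostic dose {params.dose}"
        )
    control_mort = run.control.mortality_at(params.time)
    if control_mort > MAX_CONTROL_MORTALITY:
        return ResistanceCall(
            location=run.location, status="invalid",
            mortality_at_diagnostic=None, time_to_full_mortality=None,
            note=f"control mortality {control_mort:.0%} exceeds "
                 f"{MAX_CONTROL_MORTALITY:.0%} at {params.time} min",
        )
    treated_mort = run.pooled_mortality_at(params.time)
    corrected = abbott_correct(treated_mort, control_mort)
    if control_mort > 0:
        warnings.warn(
            f"{run.location}: control mortality {control_mort:.1%}; "
            "Abbott correction applied", stacklevel=2,
        )
    status = "susceptible" if corrected * 100.0 >= threshold else "resistant"
    return ResistanceCall(
        location=run.location,
        status=status,
        mortality_at_diagnostic=corrected * 100.0,
        time_to_full_mortality=time_to_full_mortality(run),
    )


def prevalence(calls: Sequence) -> float:
    """Resistant share among valid calls, in percent (1 dp, half-up)."""
    valid = [c for c in calls if c.status in ("susceptible", "resistant")]
    invalid = [c for c in calls if c.status == "invalid"]
    if invalid:
        warnings.warn(
            f"{len(invalid)} invalid run(s) excluded from prevalence: "
            f"{[c.location for c in invalid]}", stacklevel=2,
        )
    if not valid:
        raise ValueError("all runs invalid; prevalence undefined")
    resistant = sum(1 for c in valid if c.status == "resistant")
    return round_half_up(100.0 * resistant / len(valid), 1)


# ---------------------------------------------------------------------------
# CSV plumbing
# ---------------------------------------------------------------------------

def _dead_columns(time_points: Sequence) -> list:
    return [f"dead_{t}" for t in time_points]


def read_mortality_csv(path: Union[str, Path], time_points: Sequence = TIME_GRID) -> list:
    """Read bottle series from CSV and group them into per-location AssayRuns.

    Expected columns: location, date, bottle_id, dose_ug_ml, n_insects and one
    ``dead_<t>`` column per grid time.  The dose-0 row of each location is its
    control bottle.
    """
    frame = pd.read_csv(path, comment="#")
    required = ["location", "date", "bottle_id", "dose_ug_ml", "n_insects"]
    required += _dead_columns(time_points)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"mortality CSV: missing column(s) {missing}")
    frame["date"] = frame["date"].fillna("")  # empty dates must not drop groups
    runs = []
    for (location, date), group in frame.groupby(["location", "date"], sort=False):
        treated, control = [], None
        for _, row in group.iterrows():
            series = MortalitySeries(
                bottle_id=str(row["bottle_id"]),
                location=str(location),
                dose=float(row["dose_ug_ml"]),
                n_insects=int(row["n_insects"]),
                time_points=tuple(time_points),
                cumulative_dead=tuple(int(row[c]) for c in _dead_columns(time_points)),
            )
            if series.dose == 0:
                control = series
            else:
                treated.append(series)
        if control is None:
            raise SeriesValidationError(f"{location}: no dose-0 control bottle")
        runs.append(AssayRun(location=str(location), date=str(date),
                             treated=tuple(treated), control=control))
    if not runs:
        raise ValueError(f"mortality CSV has no data rows: {path}")
    return runs


def calls_to_frame(calls: Sequence) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "location": c.location,
            "status": c.status,
            "mortality_at_diagnostic_pct": (
                None if c.mortality_at_diagnostic is None
                else round_half_up(c.mortality_at_diagnostic, 1)
            ),
            "time_to_full_mortality_min": c.time_to_full_mortality,
            "note": c.note,
        } for c in calls],
        columns=["location", "status", "mortality_at_diagnostic_pct",
                 "time_to_full_mortality_min", "note"],
    )
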