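"""Intermittent-hypoxia protocol definition, scheduling and exposure analytics.

A protocol alternates two oxygen levels over two period lengths (here the
reference protocol is 90 s at 5.7% O2 followed by 90 s at 21%), applied for a
daily session of fixed length over a number of days.  Sessions are placed in
the animals' light (sleep) phase, which in the source facility starts at
hour 7 of the day.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Default session start (hours after midnight): beginning of the light phase.
DEFAULT_SESSION_START_HOUR = 7.0


@dataclass
class ProtocolSpec:
    """Two-level, two-period intermittent-hypoxia protocol.

    Levels are O2 percentages (0-21]; a session always starts with
    ``level_1`` (the hypoxic phase) and alternates.
    """

    level_1_pct: float = 5.7
    duration_1_s: float = 90.0
    level_2_pct: float = 21.0
    duration_2_s: float = 90.0
    session_hours: float = 8.0
    n_days: int = 21

    def __post_init__(self) -> None:
        for name, lvl in (("protocol.level_1_pct", self.level_1_pct),
                          ("protocol.level_2_pct", self.level_2_pct)):
            if not 0.0 < lvl <= 21.0:
                raise ValidationError(name, f"O2 level {lvl} outside (0, 21]")
        for name, d in (("protocol.duration_1_s", self.duration_1_s),
                        ("protocol.duration_2_s", self.duration_2_s)):
            if d <= 0:
                raise ValidationError(name, "phase duration must be > 0")
        if not 0.0 < self.session_hours <= 24.0:
            raise ValidationError("protocol.session_hours", "must lie in (0, 24]")
        if self.n_days < 1:
            raise ValidationError("protocol.n_days", "must be >= 1")

    @property
    def cycle_s(self) -> float:
        return self.duration_1_s + self.duration_2_s

    @property
    def cycles_per_session(self) -> int:
        """Number of complete hypoxia/normoxia cycles in one session."""
        return int(self.session_hours * 3600.0 // self.cycle_s)


def build_schedule(
    protocol: ProtocolSpec, session_start_hour: float = DEFAULT_SESSION_START_HOUR
) -> pd.DataFrame:
    """Expand a protocol into a full multi-day phase timeline.

    Returns a DataFrame with columns ``day`` (1-based), ``start_s``, ``end_s``
    (seconds from protocol start, sessions anchored at ``session_start_hour``
    of each day) and ``setpoint_pct``.  The final cycle of a session is
    truncated at the session boundary if the session length is not a whole
    number of cycles.
    """
    if not 0.0 <= session_start_hour < 24.0:
        raise ValidationError("session_start_hour", "must lie in [0, 24)")
    session_len = protocol.session_hours * 3600.0
    phases = []
    for day in range(protocol.n_days):
        t0 = day * 86400.0 + session_start_hour * 3600.0
        t = 0.0
        level, dur = protocol.level_1_pct, protocol.duration_1_s
        while t < session_len:
            end = min(t + dur, session_len)
            phases.append((day + 1, t0 + t, t0 + end, level))
            t = end
            if level == protocol.level_1_pct:
                level, dur = protocol.level_2_pct, protocol.duration_2_s
            else:
                level, dur = protocol.level_1_pct, protocol.duration_1_s
    return pd.DataFrame(phases, columns=["day", "start_s", "end_s", "setpoint_pct"])


@dataclass
class ExposureSummary:
    """Desaturation analytics over a simulated cage-O2 trace.

    An event is a maximal run of samples with cage O2 strictly below the
    threshold; severity-style summaries follow the clinical convention of
    counting excursions and total time below threshold.
    """

    threshold_pct: float
    n_desaturation_events: int
    total_time_below_threshold_s: float
    mean_nadir_pct: float
    n_cycles_per_session: int
    per_day: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        d = {
            "threshold_pct": self.threshold_pct,
            "n_desaturation_events": self.n_desaturation_events,
            "total_time_below_threshold_s": self.total_time_below_threshold_s,
            "mean_nadir_pct": self.mean_nadir_pct,
            "n_cycles_per_session": self.n_cycles_per_session,
        }
        if self.per_day is not None:
            d["per_day"] = self.per_day.to_dict(orient="records")
        return d


def exposure_summary(
    sim, hypoxia_threshold_pct: float, protocol: ProtocolSpec | None = None
) -> ExposureSummary:
    """Summarize hypoxic exposure from a simulation result.

    ``sim`` is a :class:`~ihtwin.simulate.SimResult`; the true cage O2 trace
    is used.  Times are counted on the simulation output grid (one sample
    period per row), so event boundaries are resolved to one sample.
    """
    t = np.asarray(sim.time_s)
    o2_pct = np.asarray(sim.o2_cage) * 100.0
    if t.size == 0:
        raise ValidationError("sim", "empty simulation result")
    dt = float(t[1] - t[0]) if t.size > 1 else 0.0
    below = o2_pct < hypoxia_threshold_pct

    # maximal runs of consecutive below-threshold samples
    edges = np.flatnonzero(np.diff(below.astype(np.int8)))
    starts = list(edges[~below[edges]] + 1)
    ends = list(edges[below[edges]] + 1)
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        ends.append(below.size)

    nadirs = [float(o2_pct[a:b].min()) for a, b in zip(starts, ends)]
    total_below = float(below.sum()) * dt
    n_cycles = protocol.cycles_per_session if protocol is not None else 0
    per_day = _per_day_breakdown(t, below, dt)
    return ExposureSummary(
        threshold_pct=hypoxia_threshold_pct,
        n_desaturation_events=len(starts),
        total_time_below_threshold_s=total_below,
        mean_nadir_pct=float(np.mean(nadirs)) if nadirs else float("nan"),
        n_cycles_per_session=n_cycles,
        per_day=per_day,
    )


def _per_day_breakdown(t: np.ndarray, below: np.ndarray, dt: float) -> pd.DataFrame:
    day = (t // 86400.0).astype(int) + 1
    df = pd.DataFrame({"day": day, "below": below.astype(float) * dt})
    out = df.groupby("day", as_index=False)["below"].sum()
    return out.rename(columns={"below": "time_below_threshold_s"})
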