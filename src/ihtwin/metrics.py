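"""Step-response metrics for chamber transients.

Four quantities characterize a downward (normoxia -> hypoxia) step, matching
how a bench trace of the cage O2 sensor is usually read:

* ``time_to_target_s`` — first time the trace crosses the set level ("reached
  hypoxia");
* ``settle_time_s`` — start of the final interval the trace spends inside the
  tolerance band around the set level without leaving it again ("stabilized");
* ``undershoot_duration_s`` — length of the maximal contiguous excursion
  below set level minus band;
* ``undershoot_nadir_pct`` — minimum O2 within that excursion.

Two distinct operational definitions (first crossing vs. final band entry)
are deliberate: a fast rig reaches the set level within seconds but needs
longer for the trace to flatten inside the band.  Upward steps are handled by
mirroring.  Absent features yield NaN sentinels, never errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

NAN = float("nan")


@dataclass
class TransientMetrics:
    """Step-response summary; NaN marks an absent feature."""

    time_to_target_s: float
    settle_time_s: float
    undershoot_duration_s: float
    undershoot_nadir_pct: float

    def as_dict(self) -> dict:
        return {
            "time_to_target_s": self.time_to_target_s,
            "settle_time_s": self.settle_time_s,
            "undershoot_duration_s": self.undershoot_duration_s,
            "undershoot_nadir_pct": self.undershoot_nadir_pct,
        }

    def as_array(self) -> np.ndarray:
        return np.array([self.time_to_target_s, self.settle_time_s,
                         self.undershoot_duration_s, self.undershoot_nadir_pct])


def compute_metrics(sim, setpoint_pct: float, band_pct: float = 0.5) -> TransientMetrics:
    """Extract transient metrics from a simulated (or constructed) trace.

    ``sim`` needs ``time_s`` and ``o2_cage`` (fractions) attributes; the true
    cage trace is measured, not the noisy sensor channel.  ``setpoint_pct``
    and ``band_pct`` are O2 percentage points.
    """
    t = np.asarray(sim.time_s, dtype=float)
    y = np.asarray(sim.o2_cage, dtype=float) * 100.0
    if t.size < 2:
        raise ValidationError("sim", "need at least two samples")
    return compute_metrics_arrays(t, y, setpoint_pct, band_pct)


def compute_metrics_arrays(
    t: np.ndarray, y_pct: np.ndarray, setpoint_pct: float, band_pct: float
) -> TransientMetrics:
    """Metric extraction on raw (time, O2 %) arrays.

    Crossing times are linearly interpolated between samples, so metrics on
    piecewise-linear traces are exact.
    """
    if band_pct < 0:
        raise ValidationError("band_pct", "must be >= 0")
    sp = setpoint_pct
    downward = y_pct[0] > sp
    # mirror upward steps so "below set level" is always the undershoot side
    z = y_pct - sp if downward else sp - y_pct

    if abs(z[0]) < 1e-12 and np.all(np.abs(z) <= band_pct):
        return TransientMetrics(NAN, NAN, NAN, NAN)

    time_to_target = _first_zero_crossing(t, z)

    lo = np.abs(z) <= band_pct
    settle = _final_entry(t, z, band_pct, lo)

    duration, nadir = _undershoot(t, z, band_pct, y_pct, downward)
    return TransientMetrics(time_to_target, settle, duration, nadir)


def _first_zero_crossing(t: np.ndarray, z: np.ndarray) -> float:
    """First time z (positive at start) reaches zero, interpolated."""
    idx = np.flatnonzero(z <= 0.0)
    if idx.size == 0:
        return NAN
    i = idx[0]
    if i == 0 or z[i] == 0.0 and z[i - 1] == 0.0:
        return float(t[i])
    frac = z[i - 1] / (z[i - 1] - z[i])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def _final_entry(t: np.ndarray, z: np.ndarray, band: float, inside: np.ndarray) -> float:
    """Start of the last interval contained in the band through the end of trace."""
    if not inside[-1]:
        return NAN
    outside = np.flatnonzero(~inside)
    if outside.size == 0:
        return float(t[0])
    i = outside[-1] + 1  # first sample of the final inside run
    # interpolate the band crossing between i-1 (outside) and i (inside)
    edge = band if z[i - 1] > band else -band
    frac = (z[i - 1] - edge) / (z[i - 1] - z[i])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def _undershoot(
    t: np.ndarray, z: np.ndarray, band: float, y_pct: np.ndarray, downward: bool
) -> tuple[float, float]:
    """Maximal contiguous excursion below setpoint - band (mirrored scale)."""
    under = z < -band
    if not under.any():
        return 0.0, NAN
    d = np.diff(under.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if under[0]:
        starts.insert(0, 0)
    if under[-1]:
        ends.append(under.size)
    # pick the longest excursion (ties: the earliest)
    best = max(range(len(starts)), key=lambda j: _span(t, z, band, starts[j], ends[j]))
    a, b = starts[best], ends[best]
    duration = _span(t, z, band, a, b)
    seg = y_pct[a:b]
    nadir = float(seg.min()) if downward else float(seg.max())
    return duration, nadir


def _span(t: np.ndarray, z: np.ndarray, band: float, a: int, b: int) -> float:
    """Length of an excursion [a, b) with interpolated boundary crossings."""
    t0 = float(t[a])
    if a > 0:
        frac = (z[a - 1] + band) / (z[a - 1] - z[a])
        t0 = float(t[a - 1] + frac * (t[a] - t[a - 1]))
    t1 = float(t[b - 1])
    if b < z.size:
        frac = (z[b - 1] + band) / (z[b - 1] - z[b])
        t1 = float(t[b - 1] + frac * (t[b] - t[b - 1]))
    return t1 - t0
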