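"""Dual-sensor control strategy for the hypoxia chamber.

Three cooperating pieces, mirroring the embedded regulator:

* a protocol finite-state machine that alternates the setpoint between two
  oxygen levels over two period lengths;
* a discrete PID loop on the *cage* error that sets the signed flow demand
  (positive opens the nitrogen valve to pull O2 down, negative calls for air
  to push it up, with the on-off air valve opening above a threshold for
  fast elevation);
* the *antechamber* sensor shapes the gas mix rapidly: an integral trim
  opens the small air valve whenever the premixed composition sits below the
  setpoint, steering the delivered mix toward the set level during sustained
  nitrogen pushes;
* a flow-off latch driven by the cage sensor: when the cage reading is
  within a gating band of the setpoint the main valves close, with hysteresis
  on exit.  The small proportional air valve continuously stays open at
  ``min_command``, which softens the undershoot below the hypoxic set level.

All controller-facing O2 quantities are percentages (0-25, the sensor span);
the plant works in fractions and the simulation loop converts at the sensor
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError
from .protocol import ProtocolSpec


@dataclass
class PIDGains:
    """Discrete PID gains, per unit O2-percentage error.

    The output is clamped to [output_min, output_max]; the integral term is
    clamped to +/- integral_limit and frozen while the output is saturated in
    the direction the error would push it further (conditional anti-windup).
    """

    kp: float = 0.4
    ki: float = 0.05
    kd: float = 0.0
    integral_limit: float = 20.0
    output_min: float = -1.0
    output_max: float = 1.0

    def __post_init__(self) -> None:
        if self.output_min > self.output_max:
            raise ValidationError("controller.output_min", "must be <= output_max")
        if self.integral_limit < 0:
            raise ValidationError("controller.integral_limit", "must be >= 0")


@dataclass
class ControllerConfig:
    """Gains plus the gating and valve-sharing parameters."""

    gains: PIDGains = field(default_factory=PIDGains)
    gating_band_pct: float = 0.2       # |cage - setpoint| <= band closes main valves
    gating_hysteresis_pct: float = 0.1  # band + hysteresis must be exceeded to reopen
    min_command: float = 0.05           # floor for the always-open small air valve
    air_onoff_threshold: float = 0.5    # air demand above this opens the on-off valve
    mix_trim_gain: float = 0.0005        # small-valve opening per (% O2 x s) of mix deficit
    sample_period_s: float = 0.1

    def __post_init__(self) -> None:
        if self.gating_band_pct < 0:
            raise ValidationError("controller.gating_band_pct", "must be >= 0")
        if self.gating_hysteresis_pct < 0:
            raise ValidationError("controller.gating_hysteresis_pct", "must be >= 0")
        if not 0.0 <= self.min_command <= 1.0:
            raise ValidationError("controller.min_command", "must lie in [0, 1]")
        if self.sample_period_s <= 0:
            raise ValidationError("controller.sample_period_s", "must be > 0")


@dataclass
class ControllerState:
    """FSM phase tracking plus PID memory, mix trim and the flow-off latch."""

    elapsed_in_phase_s: float = 0.0
    phase: int = 1
    integral: float = 0.0
    previous_error: float | None = None
    gated: bool = False
    mix_trim: float = 0.0


def fsm_step(
    state: ControllerState, protocol: ProtocolSpec, dt_s: float
) -> tuple[float, ControllerState]:
    """Advance the two-level/two-period setpoint machine by one tick.

    Returns the setpoint (O2 %) that applies for the interval just entered.
    The setpoint series is periodic with period duration_1 + duration_2.
    """
    if dt_s <= 0:
        raise ValidationError("dt_s", "must be > 0")
    dur = protocol.duration_1_s if state.phase == 1 else protocol.duration_2_s
    elapsed = state.elapsed_in_phase_s
    phase = state.phase
    # roll over as many phase boundaries as dt crosses (dt >> durations is legal)
    while elapsed >= dur:
        elapsed -= dur
        phase = 2 if phase == 1 else 1
        dur = protocol.duration_1_s if phase == 1 else protocol.duration_2_s
    setpoint = protocol.level_1_pct if phase == 1 else protocol.level_2_pct
    new = ControllerState(elapsed + dt_s, phase, state.integral,
                          state.previous_error, state.gated, state.mix_trim)
    return setpoint, new


def pid_update(
    gains: PIDGains, error: float, state: ControllerState, dt_s: float
) -> tuple[float, ControllerState]:
    """One step of the discrete PID: returns (output, updated state).

    Derivative on the error with a single-step backward difference; on the
    first tick (no history) the derivative term is zero.
    """
    if dt_s <= 0:
        raise ValidationError("dt_s", "must be > 0")
    g = gains
    integral = state.integral + error * dt_s
    integral = min(max(integral, -g.integral_limit), g.integral_limit)
    if state.previous_error is None:
        deriv = 0.0
    else:
        deriv = (error - state.previous_error) / dt_s
    raw = g.kp * error + g.ki * integral + g.kd * deriv
    out = min(max(raw, g.output_min), g.output_max)
    if raw != out and (raw - out) * error > 0:
        # saturated and the error keeps pushing outward: freeze the integral
        integral = state.integral
    new = ControllerState(state.elapsed_in_phase_s, state.phase, integral,
                          error, state.gated, state.mix_trim)
    return out, new


def valve_commands(
    setpoint_pct: float,
    ante_reading_pct: float,
    cage_reading_pct: float,
    state: ControllerState,
    config: ControllerConfig,
    dt_s: float | None = None,
) -> tuple[tuple[float, float, float], ControllerState]:
    """Compute (cmd_n2, cmd_air_onoff, cmd_air_prop) for one controller tick.

    The PID error is the cage reading minus the setpoint: a positive output
    opens the nitrogen valve, a negative output calls for air (the on-off
    valve opens once the demand exceeds ``air_onoff_threshold``, finer air
    control rides on the small valve).  The antechamber reading steers the
    mix: an integral trim opens the small valve while the premixed
    composition sits below the setpoint.  The cage sensor also gates: within
    the gating band of the setpoint the nitrogen and on-off valves close and
    the PID integral and mix trim are held, so stored control effort cannot
    burst out when the latch releases.
    """
    for name, r in (("ante_reading_pct", ante_reading_pct),
                    ("cage_reading_pct", cage_reading_pct)):
        if not 0.0 <= r <= 25.0:
            raise ValidationError(name, f"reading {r} outside the 0-25% sensor span")
    dt = config.sample_period_s if dt_s is None else dt_s

    # flow-off latch with hysteresis, driven by the cage sensor
    dev = abs(cage_reading_pct - setpoint_pct)
    if state.gated:
        gated = dev <= config.gating_band_pct + config.gating_hysteresis_pct
    else:
        gated = dev <= config.gating_band_pct

    if gated:
        new = ControllerState(state.elapsed_in_phase_s, state.phase,
                              state.integral, state.previous_error, True,
                              state.mix_trim)
        cmds = (0.0, 0.0, config.min_command)
        return cmds, new

    error = cage_reading_pct - setpoint_pct
    out, new = pid_update(config.gains, error, state, dt)
    new.gated = False
    trim = state.mix_trim + config.mix_trim_gain * (setpoint_pct - ante_reading_pct) * dt
    new.mix_trim = min(max(trim, 0.0), 1.0)
    cmd_n2 = min(max(out, 0.0), 1.0)
    air_demand = min(max(-out, 0.0), 1.0)
    cmd_air_onoff = 1.0 if air_demand > config.air_onoff_threshold else 0.0
    cmd_air_prop = max(config.min_command, min(air_demand + new.mix_trim, 1.0))
    return (cmd_n2, cmd_air_onoff, cmd_air_prop), new
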