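"""Physical model of the gas path.

The rig mixes compressed air (21% O2) with bottled nitrogen (99.996% pure)
through three valves, feeds the mix through a small mixing antechamber, and
from there into a sealed mouse cage whose outlet stays open, so volumetric
outflow equals inflow and pressure dynamics are ignored.  Both volumes are
treated as well mixed; an optional effective-mixing-volume factor captures
the fact that the cage sensor sits near the inlet and sees a smaller, faster
mixing volume than the full geometric cage.

O2 is carried as a mole fraction in [0, 1] everywhere in this module; flows
are L/min, volumes L, times s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ActuationError, StabilityError, ValidationError

#: O2 fraction of atmospheric air.
AIR_O2_FRACTION = 0.21
#: Residual O2 in 99.996%-pure bottled nitrogen.
NITROGEN_O2_FRACTION = 0.00004

#: Sentinel returned as the mixed O2 fraction when total flow is zero (the
#: composition of a zero flow is undefined).
NO_FLOW_O2 = float("nan")


@dataclass
class GasSource:
    """A supply gas: compressed air or bottled nitrogen."""

    name: str
    o2_fraction: float
    supply_pressure_bar: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.o2_fraction <= 1.0:
            raise ValidationError(f"source.{self.name}.o2_fraction", "must lie in [0, 1]")
        if self.supply_pressure_bar <= 0:
            raise ValidationError(f"source.{self.name}.supply_pressure_bar", "must be > 0")


def air_source(pressure_bar: float = 1.2) -> GasSource:
    return GasSource("air", AIR_O2_FRACTION, pressure_bar)


def nitrogen_source(pressure_bar: float = 2.0) -> GasSource:
    return GasSource("nitrogen", NITROGEN_O2_FRACTION, pressure_bar)


@dataclass
class ValveSpec:
    """A valve on one gas line.

    ``kind`` is ``"on_off"`` (flow is 0 or ``max_flow_lpm``) or
    ``"proportional"`` (flow linear in the command at fixed supply pressure).
    ``min_command`` models the small air valve that continuously stays open
    to soften the undershoot: the effective command never drops below it.
    """

    kind: str
    source: GasSource
    max_flow_lpm: float
    command: float = 0.0
    min_command: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("on_off", "proportional"):
            raise ValidationError("valve.kind", f"unknown kind {self.kind!r}")
        if self.max_flow_lpm < 0:
            raise ValidationError("valve.max_flow_lpm", "must be >= 0")
        if not 0.0 <= self.min_command <= 1.0:
            raise ValidationError("valve.min_command", "must lie in [0, 1]")

    def flow_lpm(self, command: float | None = None) -> float:
        """Delivered flow for a command in [0, 1]."""
        cmd = self.command if command is None else command
        if not 0.0 <= cmd <= 1.0:
            raise ActuationError(f"valve command {cmd} outside [0, 1]")
        cmd = max(cmd, self.min_command)
        if self.kind == "on_off":
            # min_command > 0 would hold an on/off valve open; threshold at 1/2.
            return self.max_flow_lpm if cmd >= 0.5 else 0.0
        return cmd * self.max_flow_lpm


@dataclass
class CompartmentState:
    """A well-mixed gas volume with a single O2 fraction."""

    volume_l: float
    o2_fraction: float
    label: str = "cage"

    def __post_init__(self) -> None:
        if self.volume_l <= 0:
            raise ValidationError(f"{self.label}.volume_l", "must be > 0")
        if not 0.0 <= self.o2_fraction <= 1.0:
            raise ValidationError(f"{self.label}.o2_fraction", "must lie in [0, 1]")


def mix_inflow(valves: list[ValveSpec]) -> tuple[float, float]:
    """Flow-weighted mass balance over the converging gas lines.

    Returns ``(total_flow_lpm, o2_fraction_of_mix)``.  With zero total flow
    the mixed fraction is undefined and the NaN sentinel is returned.
    """
    if not valves:
        raise ActuationError("at least one valve is required")
    total = 0.0
    o2_flux = 0.0
    for v in valves:
        q = v.flow_lpm()
        if q < 0:
            raise ActuationError(f"negative flow {q} from valve on {v.source.name}")
        total += q
        o2_flux += q * v.source.o2_fraction
    if total == 0.0:
        return 0.0, NO_FLOW_O2
    return total, o2_flux / total


def step_compartment(
    state: CompartmentState, total_flow_lpm: float, o2_in: float, dt_s: float
) -> CompartmentState:
    """One explicit-Euler step of the well-mixed dilution ODE.

    dC/dt = (Q/V) (C_in - C), with Q in L/min converted to L/s.  The step is
    rejected when Q*dt/V >= 1, where explicit Euler loses the containment
    property (the new fraction could leave the [C, C_in] interval).
    """
    if dt_s <= 0:
        raise ValidationError("dt_s", "must be > 0")
    if total_flow_lpm == 0.0:
        return CompartmentState(state.volume_l, state.o2_fraction, state.label)
    k = (total_flow_lpm / 60.0) * dt_s / state.volume_l
    if k >= 1.0:
        raise StabilityError(
            f"Q*dt/V = {k:.3f} >= 1 for {state.label}; use dt < "
            f"{60.0 * state.volume_l / total_flow_lpm:.4g} s"
        )
    new = state.o2_fraction + k * (o2_in - state.o2_fraction)
    return CompartmentState(state.volume_l, new, state.label)


def analytic_dilution(c0: float, c_in: float, q_lpm: float, v_l: float, t_s: float) -> float:
    """Closed-form solution of the constant-inflow dilution ODE.

    C(t) = c_in + (c0 - c_in) exp(-(Q/V) t), Q converted from L/min to L/s.
    Used as the independent oracle for the Euler integrator.
    """
    if v_l <= 0:
        raise ValidationError("v_l", "volume must be > 0")
    if q_lpm < 0 or t_s < 0:
        raise ValidationError("q_lpm/t_s", "flow and time must be >= 0")
    return c_in + (c0 - c_in) * math.exp(-(q_lpm / 60.0) * t_s / v_l)


@dataclass
class SensorSpec:
    """Electrochemical O2 sensor: first-order lag, Gaussian noise, ADC quantization.

    ``time_constant_s`` is the cell's response time (a free calibration
    parameter; the transient behaviour of the twin is sensitive to the cage
    sensor's lag).  ``adc_range`` is the O2-fraction span mapped onto the
    converter, so the quantization step is ``adc_range / 2**adc_bits``.
    """

    time_constant_s: float = 1.0
    noise_sd: float = 5e-4
    adc_bits: int = 10
    adc_range: float = 0.25
    sample_period_s: float = 0.1

    def __post_init__(self) -> None:
        if self.time_constant_s < 0:
            raise ValidationError("sensor.time_constant_s", "must be >= 0")
        if self.adc_bits < 1:
            raise ValidationError("sensor.adc_bits", "must be >= 1")
        if self.adc_range <= 0:
            raise ValidationError("sensor.adc_range", "must be > 0")
        if self.sample_period_s <= 0:
            raise ValidationError("sensor.sample_period_s", "must be > 0")

    @property
    def resolution(self) -> float:
        return self.adc_range / (2 ** self.adc_bits)


class Sensor:
    """Stateful sensor wrapper holding the lagged internal reading."""

    def __init__(self, spec: SensorSpec, initial: float):
        self.spec = spec
        self.state = float(initial)

    def advance(self, true_fraction: float, dt_s: float) -> None:
        """Propagate the first-order lag by one plant step (no sampling)."""
        if dt_s <= 0:
            raise ValidationError("dt_s", "must be > 0")
        tau = self.spec.time_constant_s
        if tau == 0.0:
            self.state = true_fraction
        else:
            a = dt_s / tau
            if a > 1.0:
                a = 1.0  # lag faster than the step: snap to the input
            self.state += a * (true_fraction - self.state)

    def sample(self, rng: np.random.Generator | None = None) -> float:
        """Read out: add measurement noise, then quantize and saturate."""
        x = self.state
        if rng is not None and self.spec.noise_sd > 0:
            x += rng.normal(0.0, self.spec.noise_sd)
        res = self.spec.resolution
        x = res * round(x / res)
        return min(max(x, 0.0), self.spec.adc_range)


def sense(
    true_fraction: float,
    sensor: Sensor,
    dt_s: float,
    rng: np.random.Generator | None = None,
) -> float:
    """Advance a sensor one step against the true fraction and sample it."""
    sensor.advance(true_fraction, dt_s)
    return sensor.sample(rng)
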