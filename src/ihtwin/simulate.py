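"""Closed-loop simulation of the chamber.

Topology: air and nitrogen valves converge to a single mixed stream, which
passes through the mixing antechamber (first O2 sensor) and on into the cage
(second O2 sensor).  The cage outlet stays open, so volumetric outflow equals
inflow and both compartments follow the well-mixed dilution ODE.  The
controller runs at the sensor sample period; the plant integrates with
fixed-step explicit Euler at a finer dt between controller ticks.

The hot loop is written flat (scalar locals, no per-step object churn) so a
90-second run at dt = 0.01 s takes tens of milliseconds; calibration relies
on this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .controller import ControllerState, fsm_step, valve_commands
from .errors import StabilityError, ValidationError
from .plant import AIR_O2_FRACTION, NITROGEN_O2_FRACTION

#: CSV column order for exported traces (O2 quantities as fractions).
CSV_COLUMNS = ["time_s", "o2_cage", "o2_ante", "o2_cage_sensed", "o2_ante_sensed",
               "setpoint", "phase", "cmd_n2", "cmd_air_onoff", "cmd_air_prop"]


@dataclass
class SimResult:
    """Time series from one closed-loop run; one row per controller tick.

    O2 series are mole fractions; ``setpoint`` is the commanded fraction.
    """

    dt_s: float
    time_s: np.ndarray
    o2_cage: np.ndarray
    o2_ante: np.ndarray
    o2_cage_sensed: np.ndarray
    o2_ante_sensed: np.ndarray
    setpoint: np.ndarray
    phase: np.ndarray
    cmd_n2: np.ndarray
    cmd_air_onoff: np.ndarray
    cmd_air_prop: np.ndarray
    seed: int = 0
    config_hash: str = ""

    def __post_init__(self) -> None:
        n = self.time_s.size
        for name in ("o2_cage", "o2_ante", "o2_cage_sensed", "o2_ante_sensed",
                     "setpoint", "phase", "cmd_n2", "cmd_air_onoff", "cmd_air_prop"):
            if getattr(self, name).size != n:
                raise ValidationError(f"sim.{name}", "series length mismatch")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in CSV_COLUMNS})

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# seed={self.seed} config_hash={self.config_hash}\n")
            self.to_dataframe().to_csv(fh, index=False)


def simulate(
    config: RunConfig,
    duration_s: float,
    dt_s: float | None = None,
    seed: int = 0,
    initial_o2_pct: float | None = None,
) -> SimResult:
    """Run the closed-loop twin for ``duration_s`` seconds.

    Deterministic for a given (config, seed): the only randomness is sensor
    noise.  Raises :class:`StabilityError` if the Euler step cannot satisfy
    Q*dt/V < 1 for either compartment at the flow cap.
    """
    if duration_s <= 0:
        raise ValidationError("duration_s", "must be > 0")
    p = config.plant
    s = config.sensors
    dt = p.dt_s if dt_s is None else dt_s
    if dt <= 0:
        raise ValidationError("dt_s", "must be > 0")
    ts = s.sample_period_s
    n_sub = max(1, round(ts / dt))
    dt = ts / n_sub  # exact tiling of the controller tick

    v_ante = p.antechamber_volume_l * p.antechamber_mixing_factor
    v_cage = p.cage_volume_l * p.cage_mixing_factor
    q_cap = p.flow_cap_lpm
    for label, v in (("antechamber", v_ante), ("cage", v_cage)):
        k = (q_cap / 60.0) * dt / v
        if k >= 1.0:
            raise StabilityError(
                f"Q*dt/V = {k:.3f} >= 1 for the {label} at the flow cap; "
                f"use dt < {60.0 * v / q_cap:.4g} s")

    ctrl = config.controller.to_controller_config(ts)
    protocol = config.protocol.to_protocol_spec()
    rng = np.random.default_rng(seed)

    c0 = (p.initial_o2_pct if initial_o2_pct is None else initial_o2_pct) / 100.0
    c_a = c_c = s_a = s_c = c0

    tau_a, tau_c = s.antechamber_time_constant_s, s.cage_time_constant_s
    a_lag = min(dt / tau_a, 1.0) if tau_a > 0 else 1.0
    c_lag = min(dt / tau_c, 1.0) if tau_c > 0 else 1.0
    res = s.adc_range / (2 ** s.adc_bits)
    adc_hi = s.adc_range
    noise = s.noise_sd
    qn2, qoo, qsm = p.n2_valve_max_flow_lpm, p.air_onoff_max_flow_lpm, p.air_small_max_flow_lpm
    o2_n2, o2_air = NITROGEN_O2_FRACTION, AIR_O2_FRACTION
    inv60 = dt / 60.0

    n_ticks = max(1, round(duration_s / ts))
    out = np.empty((n_ticks, 8))
    time = np.arange(n_ticks) * ts
    phases = np.empty(n_ticks, dtype=np.int8)

    cstate = ControllerState()
    for i in range(n_ticks):
        # sample both sensors: noise, then quantize, then saturate
        r_a = s_a + (rng.normal(0.0, noise) if noise > 0 else 0.0)
        r_c = s_c + (rng.normal(0.0, noise) if noise > 0 else 0.0)
        r_a = min(max(res * round(r_a / res), 0.0), adc_hi)
        r_c = min(max(res * round(r_c / res), 0.0), adc_hi)

        setpoint, cstate = fsm_step(cstate, protocol, ts)
        (cmd_n2, cmd_oo, cmd_sm), cstate = valve_commands(
            setpoint, r_a * 100.0, r_c * 100.0, cstate, ctrl, ts)

        q_n2 = cmd_n2 * qn2
        q_air = (qoo if cmd_oo >= 0.5 else 0.0) + cmd_sm * qsm
        q = q_n2 + q_air
        if q > q_cap:  # shared supply: scale both lines down to the cap
            scale = q_cap / q
            q_n2 *= scale
            q_air *= scale
            q = q_cap
        c_in = (q_n2 * o2_n2 + q_air * o2_air) / q if q > 0.0 else c_a

        out[i, 0] = c_c
        out[i, 1] = c_a
        out[i, 2] = r_c
        out[i, 3] = r_a
        out[i, 4] = setpoint / 100.0
        out[i, 5] = cmd_n2
        out[i, 6] = cmd_oo
        out[i, 7] = cmd_sm
        phases[i] = cstate.phase

        if q > 0.0:
            k_a = q * inv60 / v_ante
            k_c = q * inv60 / v_cage
            for _ in range(n_sub):
                c_a += k_a * (c_in - c_a)
                c_c += k_c * (c_a - c_c)
                s_a += a_lag * (c_a - s_a)
                s_c += c_lag * (c_c - s_c)
        else:
            for _ in range(n_sub):
                s_a += a_lag * (c_a - s_a)
                s_c += c_lag * (c_c - s_c)

    return SimResult(
        dt_s=ts,
        time_s=time,
        o2_cage=out[:, 0].copy(),
        o2_ante=out[:, 1].copy(),
        o2_cage_sensed=out[:, 2].copy(),
        o2_ante_sensed=out[:, 3].copy(),
        setpoint=out[:, 4].copy(),
        phase=phases,
        cmd_n2=out[:, 5].copy(),
        cmd_air_onoff=out[:, 6].copy(),
        cmd_air_prop=out[:, 7].copy(),
        seed=seed,
        config_hash=config.hash(),
    )


def step_response(
    config: RunConfig,
    duration_s: float = 60.0,
    seed: int = 0,
    from_pct: float = 21.0,
) -> SimResult:
    """The reference transient: plant at ``from_pct``, setpoint at the hypoxic level.

    Uses the protocol's hypoxic level and a session long enough that no phase
    switch occurs within ``duration_s``.
    """
    cfg = config.replace({
        "protocol.duration_1_s": max(duration_s * 2, config.protocol.duration_1_s),
    })
    return simulate(cfg, duration_s, seed=seed, initial_o2_pct=from_pct)
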