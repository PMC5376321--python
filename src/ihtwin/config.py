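"""Run configuration: a flat YAML file with explicit units in the key names.

Sections: ``plant``, ``sensors``, ``controller``, ``protocol``,
``calibration``, ``stats``.  Units are litres, L/min, seconds, bar; O2
quantities carry a ``_pct`` suffix when they are percentages (controller and
protocol side) and are mole fractions otherwise (plant side).  Unknown keys
are rejected on load so that a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path

import yaml

from .controller import ControllerConfig, PIDGains
from .errors import ValidationError
from .protocol import DEFAULT_SESSION_START_HOUR, ProtocolSpec


@dataclass
class PlantConfig:
    """Geometry, supply pressures and valve ratings of the gas path.

    ``*_mixing_factor`` scales the geometric volume to an effective mixing
    volume (the cage sensor sits near the inlet and equilibrates with a
    smaller volume than the whole cage); ``flow_cap_lpm`` is the total
    delivered flow cap shared by all valves.
    """

    antechamber_volume_l: float = 0.05
    antechamber_mixing_factor: float = 1.0
    cage_volume_l: float = 12.4
    cage_mixing_factor: float = 1.0
    flow_cap_lpm: float = 50.0
    n2_pressure_bar: float = 2.0
    air_pressure_bar: float = 1.2
    n2_valve_max_flow_lpm: float = 45.0
    air_onoff_max_flow_lpm: float = 40.0
    air_small_max_flow_lpm: float = 5.0
    initial_o2_pct: float = 21.0
    dt_s: float = 0.01

    def __post_init__(self) -> None:
        positive = ["antechamber_volume_l", "antechamber_mixing_factor", "cage_volume_l",
                    "cage_mixing_factor", "flow_cap_lpm", "n2_pressure_bar",
                    "air_pressure_bar", "dt_s"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValidationError(f"plant.{name}", "must be > 0")
        for name in ["n2_valve_max_flow_lpm", "air_onoff_max_flow_lpm",
                     "air_small_max_flow_lpm"]:
            if getattr(self, name) < 0:
                raise ValidationError(f"plant.{name}", "must be >= 0")
        if not 0.0 <= self.initial_o2_pct <= 25.0:
            raise ValidationError("plant.initial_o2_pct", "must lie in [0, 25] % O2")


@dataclass
class SensorsConfig:
    """Both O2 sensors share the electronics; only the lag differs."""

    antechamber_time_constant_s: float = 0.5
    cage_time_constant_s: float = 1.0
    noise_sd: float = 5e-4
    adc_bits: int = 10
    adc_range: float = 0.25
    sample_period_s: float = 0.1

    def __post_init__(self) -> None:
        for name in ["antechamber_time_constant_s", "cage_time_constant_s", "noise_sd"]:
            if getattr(self, name) < 0:
                raise ValidationError(f"sensors.{name}", "must be >= 0")
        if self.adc_bits < 1:
            raise ValidationError("sensors.adc_bits", "must be >= 1")
        if self.adc_range <= 0:
            raise ValidationError("sensors.adc_range", "must be > 0")
        if self.sample_period_s <= 0:
            raise ValidationError("sensors.sample_period_s", "must be > 0")


@dataclass
class ControllerSection:
    kp: float = 0.4
    ki: float = 0.05
    kd: float = 0.0
    integral_limit: float = 20.0
    gating_band_pct: float = 0.2
    gating_hysteresis_pct: float = 0.1
    min_command: float = 0.05
    air_onoff_threshold: float = 0.5
    mix_trim_gain: float = 0.0005

    def to_controller_config(self, sample_period_s: float) -> ControllerConfig:
        return ControllerConfig(
            gains=PIDGains(self.kp, self.ki, self.kd, self.integral_limit),
            gating_band_pct=self.gating_band_pct,
            gating_hysteresis_pct=self.gating_hysteresis_pct,
            min_command=self.min_command,
            air_onoff_threshold=self.air_onoff_threshold,
            mix_trim_gain=self.mix_trim_gain,
            sample_period_s=sample_period_s,
        )


@dataclass
class ProtocolSection:
    level_1_pct: float = 5.7
    duration_1_s: float = 90.0
    level_2_pct: float = 21.0
    duration_2_s: float = 90.0
    session_hours: float = 8.0
    n_days: int = 21
    session_start_hour: float = DEFAULT_SESSION_START_HOUR

    def __post_init__(self) -> None:
        self.to_protocol_spec()  # ProtocolSpec owns the level/duration bounds
        if not 0.0 <= self.session_start_hour < 24.0:
            raise ValidationError("protocol.session_start_hour", "must lie in [0, 24)")

    def to_protocol_spec(self) -> ProtocolSpec:
        return ProtocolSpec(self.level_1_pct, self.duration_1_s, self.level_2_pct,
                            self.duration_2_s, self.session_hours, self.n_days)


@dataclass
class CalibrationSection:
    """Free parameters (flat config paths + bounds), targets and weights."""

    parameters: dict = field(default_factory=lambda: {
        "plant.cage_mixing_factor": [0.05, 0.6],
        "plant.air_small_max_flow_lpm": [0.5, 10.0],
        "sensors.cage_time_constant_s": [0.2, 8.0],
        "controller.kp": [0.05, 1.0],
        "controller.ki": [0.0, 0.05],
        "controller.min_command": [0.03, 0.3],
    })
    target_time_to_target_s: float = 4.5
    target_settle_time_s: float = 27.0
    target_undershoot_duration_s: float = 12.0
    target_undershoot_nadir_pct: float = 2.0
    weight_time_to_target: float = 1.0
    weight_settle_time: float = 1.0
    weight_undershoot_duration: float = 1.0
    weight_undershoot_nadir: float = 1.0
    metrics_band_pct: float = 0.5
    sim_duration_s: float = 60.0
    n_starts: int = 8
    max_evals_per_start: int = 200


@dataclass
class StatsSection:
    """Synthetic stereology generator + inference defaults.

    Baselines are mean apoptotic counts per animal (pooled over the sampled
    sections of one counting frame per section); the dentate gyrus runs
    higher than the cornu ammonis subfields, and intermittent hypoxia
    multiplies every regional mean by ``ih_effect_multiplier``.
    """

    baseline_ca1: float = 10.0
    baseline_ca3: float = 10.0
    baseline_dg: float = 20.0
    ih_effect_multiplier: float = 1.3
    n_ih: int = 8
    n_ctrl: int = 7
    dispersion: float = 10.0
    frame_um: float = 280.0
    thickness_um: float = 35.0
    n_sections: int = 4
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_ih < 2 or self.n_ctrl < 2:
            raise ValidationError("stats.n_ih/n_ctrl", "group sizes must be >= 2")
        if self.ih_effect_multiplier <= 0:
            raise ValidationError("stats.ih_effect_multiplier", "must be > 0")
        if not 0 < self.alpha < 1:
            raise ValidationError("stats.alpha", "must lie in (0, 1)")


@dataclass
class RunConfig:
    plant: PlantConfig = field(default_factory=PlantConfig)
    sensors: SensorsConfig = field(default_factory=SensorsConfig)
    controller: ControllerSection = field(default_factory=ControllerSection)
    protocol: ProtocolSection = field(default_factory=ProtocolSection)
    calibration: CalibrationSection = field(default_factory=CalibrationSection)
    stats: StatsSection = field(default_factory=StatsSection)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ValidationError("config", "top level must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(sorted(unknown)[0], "unknown config section")
        kwargs = {}
        for f in fields(cls):
            sect = data.get(f.name, {})
            kwargs[f.name] = _section_from_dict(f.name, f.default_factory, sect)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    # -- helpers -----------------------------------------------------------
    def get(self, path: str) -> float:
        """Read a flat ``section.key`` parameter path."""
        section, key = _split_path(path)
        return getattr(getattr(self, section), key)

    def replace(self, updates: dict[str, float]) -> "RunConfig":
        """Return a copy with flat ``section.key`` paths updated (re-validated)."""
        d = self.to_dict()
        for path, value in updates.items():
            section, key = _split_path(path)
            if section not in d or key not in d[section]:
                raise ValidationError(path, "unknown parameter path")
            d[section][key] = value
        return RunConfig.from_dict(d)

    def hash(self) -> str:
        """Stable short hash of the full configuration (for provenance)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _split_path(path: str) -> tuple[str, str]:
    parts = path.split(".")
    if len(parts) != 2:
        raise ValidationError(path, "parameter path must be 'section.key'")
    return parts[0], parts[1]


def _section_from_dict(name: str, factory, data: dict):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError(name, "section must be a mapping")
    cls = type(factory())
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"{name}.{sorted(unknown)[0]}", "unknown config key")
    try:
        return cls(**data)
    except TypeError as exc:
        raise ValidationError(name, str(exc)) from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def default_config_path() -> Path:
    """Path of the calibrated default configuration shipped with the package."""
    return Path(resources.files("ihtwin") / "data" / "default_config.yaml")


def default_config() -> RunConfig:
    """The calibrated default configuration (reproduces the reference transient)."""
    return load_config(default_config_path())
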