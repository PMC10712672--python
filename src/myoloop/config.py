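"""Experiment configuration: nested, schema-validated, round-trippable.

A single YAML/JSON document configures every stage — EMG decoding, muscle,
spindle, plant, task geometry and the synthetic subject.  Every constant of
the protocol (2000 Hz acquisition, 100 Hz loop, 1 Hz 3rd-order Butterworth,
alpha = 1e-4, beta = 1e-18, 128 levels, 40/40 pps gamma, 1 cm gap, 4.4 N
break threshold, 15 s timeout, 1 s dwell) lives here as a default, nowhere
inlined.  Unknown keys are rejected; an empty file yields the full default
configuration; save/load round-trips unchanged.
"""

from __future__ import annotations

import dataclasses
import json
import typing
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .emg import BayesParams
from .muscle import MuscleParams
from .plant import PlantParams
from .spindle import GammaDrive, SpindleParams
from .subject import SubjectParams
from .task import ExperimentModels, default_target_catalog, force_window

__all__ = ["EMGConfig", "TaskConfig", "ExperimentConfig",
           "load_config", "save_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for schema violations in a configuration document."""


@dataclass(frozen=True)
class EMGConfig:
    """EMG decoding settings (Factor 1).

    model : 'linear' or 'bayes'.
    mv_scale : mV per unit drive; None = calibrate from a maximal-effort
        trace at run time.
    """

    model: str = "bayes"
    fs: float = 2000.0
    alpha: float = 1e-4
    beta: float = 1e-18
    n_levels: int = 128
    x_floor: float = 1.0 / 128
    mv_scale: float | None = None
    cutoff_hz: float = 1.0
    order: int = 3

    def __post_init__(self):
        if self.model not in ("linear", "bayes"):
            raise ConfigError(f"emg.model must be 'linear' or 'bayes', "
                              f"got {self.model!r}")

    def bayes_params(self) -> BayesParams:
        return BayesParams(alpha=self.alpha, beta=self.beta,
                           n_levels=self.n_levels, x_floor=self.x_floor)


@dataclass(frozen=True)
class TaskConfig:
    """Press-without-break task geometry and rules."""

    targets: tuple[tuple[float, float], ...] = field(
        default_factory=lambda: tuple(default_target_catalog())
    )
    reps: int = 6
    mapping_gain: float = 1.0
    timeout: float = 15.0
    dwell: float = 1.0
    break_threshold: float = 4.4

    def __post_init__(self):
        if self.reps < 1:
            raise ConfigError("task.reps must be >= 1")
        for d, w in self.targets:
            # raises if any window reaches the break zone
            force_window(d, w, self.mapping_gain, self.break_threshold)


@dataclass(frozen=True)
class ExperimentConfig:
    """Root configuration object."""

    emg: EMGConfig = field(default_factory=EMGConfig)
    feedback_model: str = "spindle"
    muscle: MuscleParams = field(default_factory=MuscleParams)
    spindle: SpindleParams = field(default_factory=SpindleParams)
    gamma: GammaDrive = field(default_factory=GammaDrive)
    plant: PlantParams = field(default_factory=PlantParams)
    subject: SubjectParams = field(default_factory=SubjectParams)
    task: TaskConfig = field(default_factory=TaskConfig)
    control_rate: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.feedback_model not in ("proportional", "spindle"):
            raise ConfigError("feedback_model must be 'proportional' or "
                              "'spindle'")
        if self.control_rate <= 0:
            raise ConfigError("control_rate must be positive")

    def models(self) -> ExperimentModels:
        return ExperimentModels(
            muscle=self.muscle, plant=self.plant, spindle=self.spindle,
            gamma=self.gamma, bayes=self.emg.bayes_params(),
            subject=self.subject, emg_fs=self.emg.fs,
            control_rate=self.control_rate,
            butter_order=self.emg.order,
            butter_cutoff_hz=self.emg.cutoff_hz,
        )


# ---------------------------------------------------------------------------
# Generic dataclass <-> dict machinery
# ---------------------------------------------------------------------------


def _coerce(value, target_type):
    """Convert parsed-YAML values (lists, ints) to annotated field types."""
    origin = typing.get_origin(target_type)
    if origin is typing.Union:  # Optional[...]
        args = [a for a in typing.get_args(target_type) if a is not type(None)]
        if value is None:
            return None
        return _coerce(value, args[0])
    if dataclasses.is_dataclass(target_type):
        if not isinstance(value, dict):
            raise ConfigError(
                f"expected a mapping for {target_type.__name__}, got {value!r}"
            )
        return _build(target_type, value)
    if origin is tuple and isinstance(value, (list, tuple)):
        args = typing.get_args(target_type)
        if len(args) == 2 and args[1] is Ellipsis:
            return tuple(_coerce(v, args[0]) for v in value)
        return tuple(_coerce(v, a) for v, a in zip(value, args))
    if target_type is float and isinstance(value, int):
        return float(value)
    if target_type is float and isinstance(value, str):
        # YAML 1.1 resolves exponent-only scalars like "1e-18" as strings
        try:
            return float(value)
        except ValueError as exc:
            raise ConfigError(f"expected a number, got {value!r}") from exc
    return value


def _build(cls, data: dict):
    hints = typing.get_type_hints(cls)
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in {cls.__name__} "
            f"(valid: {sorted(names)})"
        )
    kwargs = {k: _coerce(v, hints[k]) for k, v in data.items()}
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid {cls.__name__}: {exc}") from exc


def load_config(path: str | Path | None = None) -> ExperimentConfig:
    """Load and validate a YAML/JSON config file; None or an empty file
    yields the full default configuration."""
    if path is None:
        return ExperimentConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config document must be a mapping")
    return _build(ExperimentConfig, data)


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    """Serialize a config so that ``load_config`` round-trips it exactly."""
    data = dataclasses.asdict(config)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
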