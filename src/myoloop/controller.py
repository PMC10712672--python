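"""The 100 Hz closed control loop.

Each control tick consumes one block of raw EMG (20 samples at 2000 Hz),
decodes it to a feedforward drive with the configured filter, superimposes
the proprioceptive correction from the configured feedback pathway, and
advances activation, muscle and plant by one step.

Signal path per tick::

    EMG block -> decoder -> drive          (feedforward)
    l_norm, v_norm -> feedback model -> fb (proprioceptive)
    command = clamp(drive + fb, 0, 1)
    command -> activation -> Hill force -> plant

The feedback is positive when the muscle is stretched beyond its reference
(stretch excites, as in the spinal stretch reflex) and negative while the
muscle shortens during pressing, so it regulates toward the commanded
length.  With feedback gain 0 the loop reduces exactly to open-loop EMG
control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emg import (
    BayesParams,
    BayesianDecoder,
    ButterworthDecoder,
    EMGTrace,
    InvalidParameterError,
)
from .muscle import MuscleParams, MuscleState, activation_dynamics, hill_force
from .plant import (
    PlantParams,
    PlantState,
    muscle_length_from_plant,
    muscle_velocity_from_plant,
    plant_step,
)
from .spindle import (
    GammaDrive,
    PopulationDecoder,
    SpindleParams,
    calibrate_feedback_gain,
    encode_afferents,
    proportional_feedback,
    spindle_rate,
)

__all__ = ["ControllerConfig", "LoopRecord", "ClosedLoopController",
           "run_closed_loop"]

EMG_MODELS = ("linear", "bayes")
FEEDBACK_MODELS = ("proportional", "spindle")


class ConfigurationError(ValueError):
    """Raised at construction for an invalid controller configuration."""


@dataclass(frozen=True)
class ControllerConfig:
    """One of the four experimental conditions.

    emg_model : 'linear' (3rd-order 1 Hz Butterworth envelope) or 'bayes'
        (Bayesian nonlinear filter).
    feedback_model : 'proportional' or 'spindle'.
    control_rate : control-loop rate, Hz.
    feedback_gain : dimensionless; None selects the calibrated default
        (10% stretch -> 1% command change).
    """

    emg_model: str = "bayes"
    feedback_model: str = "spindle"
    control_rate: float = 100.0
    feedback_gain: float | None = None

    def __post_init__(self):
        if self.emg_model not in EMG_MODELS:
            raise ConfigurationError(
                f"emg_model must be one of {EMG_MODELS}, got {self.emg_model!r}"
            )
        if self.feedback_model not in FEEDBACK_MODELS:
            raise ConfigurationError(
                f"feedback_model must be one of {FEEDBACK_MODELS}, "
                f"got {self.feedback_model!r}"
            )
        if self.control_rate <= 0:
            raise ConfigurationError("control_rate must be positive")

    @property
    def label(self) -> str:
        return f"{self.emg_model}+{self.feedback_model}"


@dataclass(frozen=True)
class LoopRecord:
    """One control tick of the closed loop."""

    t: float
    drive: float
    feedback: float
    command: float
    muscle_force: float
    contact_force: float
    l_norm: float


class ClosedLoopController:
    """Stateful 100 Hz controller binding decoder, feedback, muscle, plant.

    Parameters
    ----------
    config : ControllerConfig
        Condition selection (Factor 1 x Factor 2).
    mv_scale : float
        EMG normalization (mV per unit drive), from calibration.
    seed : int or Generator, optional
        Randomness source for the spindle's Poisson afferents; the loop is
        bit-deterministic given the seed.
    """

    def __init__(
        self,
        config: ControllerConfig,
        muscle: MuscleParams | None = None,
        plant: PlantParams | None = None,
        spindle_params: SpindleParams | None = None,
        gamma: GammaDrive | None = None,
        bayes: BayesParams | None = None,
        mv_scale: float = 1.0,
        emg_fs: float = 2000.0,
        butter_order: int = 3,
        butter_cutoff_hz: float = 1.0,
        feedback_window: float = 0.1,
        seed: int | np.random.Generator | None = None,
    ):
        self.config = config
        self.muscle = muscle or MuscleParams()
        self.plant = plant or PlantParams()
        self.spindle_params = spindle_params or SpindleParams()
        self.gamma = gamma or GammaDrive()
        self.dt = 1.0 / config.control_rate
        self.emg_fs = emg_fs
        self.samples_per_tick = int(round(emg_fs / config.control_rate))
        if self.samples_per_tick < 1:
            raise InvalidParameterError("emg_fs must be >= control_rate")

        if config.emg_model == "bayes":
            self.decoder = BayesianDecoder(bayes or BayesParams(), mv_scale)
        else:
            self.decoder = ButterworthDecoder(
                fs=emg_fs, order=butter_order,
                cutoff_hz=butter_cutoff_hz, mv_scale=mv_scale,
            )

        if config.feedback_gain is not None:
            gain = config.feedback_gain
        else:
            gain = calibrate_feedback_gain(
                config.feedback_model,
                gamma=self.gamma,
                spindle_params=self.spindle_params,
                dt=self.dt,
                window=feedback_window,
            )
        self.feedback_gain = gain
        if config.feedback_model == "spindle":
            self._pop_decoder = PopulationDecoder(
                baseline_rate=self.spindle_params.baseline(self.gamma),
                gain=gain,
                window=feedback_window,
                dt=self.dt,
                n_channels=self.spindle_params.n_channels,
            )
        else:
            self._pop_decoder = None
        if not isinstance(seed, np.random.Generator):
            seed = np.random.default_rng(seed)
        self._rng = seed
        self.reset()

    def reset(self, rng: np.random.Generator | None = None) -> None:
        """Return plant, muscle, decoder and feedback path to rest."""
        self.plant_state = PlantState()
        self.activation = 0.0
        self.decoder.reset()
        if self._pop_decoder is not None:
            self._pop_decoder.reset()
        if rng is not None:
            self._rng = rng

    # ------------------------------------------------------------------

    def _feedback(self, l_norm: float, v_norm: float) -> float:
        if self.config.feedback_model == "proportional":
            return proportional_feedback(
                l_norm, self.plant.l_rest, self.feedback_gain
            ).value
        rate = spindle_rate(l_norm, v_norm, self.gamma, self.spindle_params)
        volley = encode_afferents(
            rate, self.spindle_params.n_channels, self.dt, self._rng
        )
        return self._pop_decoder.decode(volley).value

    def control_step(self, drive: float) -> LoopRecord:
        """Advance the loop one tick from a decoded drive value."""
        if not 0.0 <= drive <= 1.0:
            raise InvalidParameterError("drive must lie in [0, 1]")
        l_norm = muscle_length_from_plant(self.plant_state, self.plant)
        v_norm = muscle_velocity_from_plant(self.plant_state, self.plant)
        fb = self._feedback(l_norm, v_norm)
        command = float(np.clip(drive + fb, 0.0, 1.0))
        self.activation = activation_dynamics(
            self.activation, command, self.dt, self.muscle
        )
        force = hill_force(
            MuscleState(l_norm=l_norm, v_norm=v_norm, a=self.activation),
            self.muscle,
        )
        self.plant_state = plant_step(self.plant_state, force, self.dt, self.plant)
        return LoopRecord(
            t=self.plant_state.t,
            drive=drive,
            feedback=fb,
            command=command,
            muscle_force=force,
            contact_force=self.plant_state.contact_force,
            l_norm=l_norm,
        )

    def tick(self, emg_block: np.ndarray) -> LoopRecord:
        """Decode one EMG block (samples_per_tick samples) and step the loop.

        The last sample of the block is the tick's drive — the freshest
        estimate available to a causal controller.
        """
        drive = float(self.decoder.process(np.asarray(emg_block))[-1])
        return self.control_step(drive)


class SourceExhaustedError(RuntimeError):
    """Raised when an EMG source runs out before the requested duration."""


def run_closed_loop(
    emg_source,
    duration: float,
    controller: ClosedLoopController,
) -> list[LoopRecord]:
    """Run the closed loop for ``duration`` seconds.

    ``emg_source`` is either an :class:`~myoloop.emg.EMGTrace` (consumed in
    blocks of ``samples_per_tick``; raises :class:`SourceExhaustedError` if
    it ends early) or a callable ``(tick_index, contact_force) -> block``
    (e.g. the synthetic subject, which closes the visual loop).
    Returns ``duration * control_rate`` records.
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be positive")
    n_ticks = int(round(duration * controller.config.control_rate))
    spt = controller.samples_per_tick
    records: list[LoopRecord] = []
    if isinstance(emg_source, EMGTrace):
        samples = emg_source.samples
        if samples.size < n_ticks * spt:
            raise SourceExhaustedError(
                f"EMG source has {samples.size} samples, "
                f"{n_ticks * spt} required"
            )
        for k in range(n_ticks):
            records.append(controller.tick(samples[k * spt:(k + 1) * spt]))
    else:
        force = 0.0
        for k in range(n_ticks):
            block = emg_source(k, force)
            rec = controller.tick(block)
            force = rec.contact_force
            records.append(rec)
    return records
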