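"""The press-without-break task: trials, blocks, and the 2x2 experiment.

A trial presents a force window [f_min, f_max] below a 4.4 N break
threshold.  The finger starts 1 cm above the transducer; the operator must
press and hold the contact force inside the window for one continuous
second within 15 s, without ever reaching the break threshold.  Target
difficulty follows Fitts' law: ID = log2(2 D / W) bits for a target at
distance D with width W (display units map 1:1 to newtons by default).

Outcomes partition into success / break / timeout.  Movement time MT runs
from trial start to first contact; completion time CT from first contact to
the end of the successful 1 s dwell (the dwell second is included in CT).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .controller import ClosedLoopController, ControllerConfig
from .emg import BayesParams, InvalidInputError, InvalidParameterError
from .muscle import MuscleParams
from .plant import PlantParams
from .spindle import GammaDrive, SpindleParams, calibrate_feedback_gain
from .subject import SubjectParams, SyntheticSubject

__all__ = [
    "TrialSpec",
    "TrialResult",
    "BlockSpec",
    "TrialMonitor",
    "index_of_difficulty",
    "force_window",
    "default_target_catalog",
    "run_trial",
    "run_block",
    "run_experiment",
    "ExperimentModels",
    "ALL_CONDITIONS",
]

#: The four factor combinations: EMG decoding x proprioceptive feedback.
ALL_CONDITIONS = (
    ControllerConfig("linear", "proportional"),
    ControllerConfig("linear", "spindle"),
    ControllerConfig("bayes", "proportional"),
    ControllerConfig("bayes", "spindle"),
)

BREAK_THRESHOLD_N = 4.4


def index_of_difficulty(D: float, W: float) -> float:
    """Fitts index of difficulty, ID = log2(2 D / W) bits."""
    if D <= 0 or W <= 0:
        raise InvalidParameterError("D and W must be positive")
    return math.log2(2.0 * D / W)


def force_window(
    D: float, W: float, mapping_gain: float = 1.0,
    break_threshold: float = BREAK_THRESHOLD_N,
) -> tuple[float, float]:
    """Map target geometry to a force window.

    The bar height mirrors the contact force, so the window is
    (gain*(D - W/2), gain*(D + W/2)).  A window touching the break zone is
    rejected.
    """
    if D <= 0 or W <= 0 or mapping_gain <= 0:
        raise InvalidParameterError("D, W and mapping_gain must be positive")
    f_min = mapping_gain * (D - W / 2.0)
    f_max = mapping_gain * (D + W / 2.0)
    if f_min <= 0:
        raise InvalidParameterError("window must lie above zero force")
    if f_max >= break_threshold:
        raise InvalidParameterError(
            f"window top {f_max:.3f} N reaches the break zone "
            f"({break_threshold} N)"
        )
    return f_min, f_max


def default_target_catalog() -> list[tuple[float, float]]:
    """Six (D, W) pairs spanning IDs 1.5-4.0 bits.

    W = 2 D / 2^ID; distances rise with difficulty and the hardest window's
    top sits at 4.4/1.3 ~ 3.385 N — the break threshold exceeds the highest
    target's upper bound by roughly 30%.
    """
    ids = [1.5, 2.0, 2.5, 3.0, 3.5, 4.0]
    dists = [1.6, 1.9, 2.2, 2.5, 2.85, 3.185]
    return [(d, 2.0 * d / 2.0 ** i) for d, i in zip(dists, ids)]


@dataclass(frozen=True)
class TrialSpec:
    """Target geometry and rules for one trial."""

    D: float
    W: float
    f_min: float
    f_max: float
    timeout: float = 15.0
    dwell: float = 1.0
    break_threshold: float = BREAK_THRESHOLD_N

    def __post_init__(self):
        if not 0 < self.f_min < self.f_max < self.break_threshold:
            raise InvalidParameterError(
                "require 0 < f_min < f_max < break_threshold"
            )
        if self.timeout <= 0 or self.dwell <= 0:
            raise InvalidParameterError("timeout and dwell must be positive")

    @classmethod
    def from_geometry(
        cls, D: float, W: float, mapping_gain: float = 1.0, **kwargs
    ) -> "TrialSpec":
        thr = kwargs.get("break_threshold", BREAK_THRESHOLD_N)
        f_min, f_max = force_window(D, W, mapping_gain, thr)
        return cls(D=D, W=W, f_min=f_min, f_max=f_max, **kwargs)

    @property
    def id_bits(self) -> float:
        return index_of_difficulty(self.D, self.W)

    @property
    def f_center(self) -> float:
        return 0.5 * (self.f_min + self.f_max)


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one trial.

    outcome : 'success' | 'break' | 'timeout'.
    mt : movement time to first contact, s (NaN if contact never occurred).
    ct : completion time, first contact to dwell completion, s; NaN unless
        the trial succeeded.
    """

    outcome: str
    id_bits: float
    mt: float
    ct: float
    peak_force: float
    force_trace: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.outcome not in ("success", "break", "timeout"):
            raise InvalidInputError(f"unknown outcome {self.outcome!r}")

    @property
    def success(self) -> bool:
        return self.outcome == "success"


class TrialMonitor:
    """Discrete-time trial state machine over a 100 Hz force stream.

    Per tick (``update`` returns the outcome once decided, else None):

    1. break check — force >= break_threshold ends the trial immediately
       (threshold inclusive; checked before the dwell so breaking on what
       would be the final dwell tick still fails);
    2. dwell check — a run of ``dwell`` seconds of consecutive in-window
       ticks completes the trial; any excursion resets the run;
    3. timeout at ``timeout`` seconds.

    MT is the timestamp of the first tick with nonzero contact force; CT is
    the time from that tick to the 100th consecutive in-window tick (the
    dwell second is included in CT).  Both are sample timestamps, so a trace
    whose first contact sample is already in-window yields ct = dwell - dt.
    """

    def __init__(self, spec: TrialSpec, control_rate: float = 100.0):
        self.spec = spec
        self.dt = 1.0 / control_rate
        self._dwell_ticks = int(round(spec.dwell * control_rate))
        self._max_ticks = int(round(spec.timeout * control_rate))
        self._tick = 0
        self._in_window_run = 0
        self.mt = math.nan
        self.ct = math.nan
        self.peak_force = 0.0
        self.outcome: str | None = None

    def update(self, force: float) -> str | None:
        if self.outcome is not None:
            return self.outcome
        self._tick += 1
        t = self._tick * self.dt
        self.peak_force = max(self.peak_force, force)
        if force > 0.0 and math.isnan(self.mt):
            self.mt = t
        if force >= self.spec.break_threshold:
            self.outcome = "break"
            return self.outcome
        if self.spec.f_min <= force <= self.spec.f_max:
            self._in_window_run += 1
            if self._in_window_run >= self._dwell_ticks:
                self.outcome = "success"
                self.ct = t - self.mt
                return self.outcome
        else:
            self._in_window_run = 0
        if self._tick >= self._max_ticks:
            self.outcome = "timeout"
            return self.outcome
        return None


@dataclass(frozen=True)
class ExperimentModels:
    """Shared physical/model parameters for an experiment run."""

    muscle: MuscleParams = field(default_factory=MuscleParams)
    plant: PlantParams = field(default_factory=PlantParams)
    spindle: SpindleParams = field(default_factory=SpindleParams)
    gamma: GammaDrive = field(default_factory=GammaDrive)
    bayes: BayesParams = field(default_factory=BayesParams)
    subject: SubjectParams = field(default_factory=SubjectParams)
    emg_fs: float = 2000.0
    control_rate: float = 100.0
    butter_order: int = 3
    butter_cutoff_hz: float = 1.0


def run_trial(
    spec: TrialSpec,
    subject: SyntheticSubject,
    controller: ClosedLoopController,
    rng: np.random.Generator | None = None,
) -> TrialResult:
    """Run one closed-loop trial to its outcome.

    Resets plant, decoder and subject, then advances the loop tick by tick
    feeding the displayed contact force back to the subject, until the
    monitor decides success, break or timeout.
    """
    rng = rng or np.random.default_rng()
    seeds = rng.spawn(2)
    controller.reset(rng=seeds[0])
    subject.reset(spec.f_center, spec.W / 2.0, rng=seeds[1])
    monitor = TrialMonitor(spec, controller.config.control_rate)
    forces: list[float] = []
    force = 0.0
    outcome = None
    k = 0
    while outcome is None:
        block = subject(k, force)
        rec = controller.tick(block)
        force = rec.contact_force
        forces.append(force)
        outcome = monitor.update(force)
        k += 1
    return TrialResult(
        outcome=outcome,
        id_bits=spec.id_bits,
        mt=monitor.mt,
        ct=monitor.ct,
        peak_force=monitor.peak_force,
        force_trace=np.asarray(forces),
    )


@dataclass(frozen=True)
class BlockSpec:
    """One condition block: every ID repeated ``reps`` times, seeded order."""

    condition: ControllerConfig
    targets: tuple[tuple[float, float], ...] = field(
        default_factory=lambda: tuple(default_target_catalog())
    )
    reps: int = 6
    mapping_gain: float = 1.0
    seed: int = 0

    def trial_specs(self) -> list[TrialSpec]:
        return [TrialSpec.from_geometry(d, w, self.mapping_gain)
                for d, w in self.targets]

    def trial_order(self) -> list[int]:
        """Seeded permutation of target indices, each repeated reps times."""
        base = np.repeat(np.arange(len(self.targets)), self.reps)
        rng = np.random.default_rng(self.seed)
        return list(rng.permutation(base))


def _build_controller(
    condition: ControllerConfig,
    models: ExperimentModels,
    mv_scale: float,
    feedback_gain: float | None,
) -> ClosedLoopController:
    cond = replace(condition, feedback_gain=feedback_gain,
                   control_rate=models.control_rate)
    return ClosedLoopController(
        cond,
        muscle=models.muscle,
        plant=models.plant,
        spindle_params=models.spindle,
        gamma=models.gamma,
        bayes=models.bayes,
        mv_scale=mv_scale,
        emg_fs=models.emg_fs,
        butter_order=models.butter_order,
        butter_cutoff_hz=models.butter_cutoff_hz,
    )


def calibrate_subject_mv_scale(
    models: ExperimentModels, seed: int | np.random.SeedSequence
) -> float:
    """mV-to-drive scale from a maximal-effort calibration trace."""
    subj = SyntheticSubject(
        models.subject, models.muscle, models.plant,
        models.emg_fs, models.control_rate,
        seed=np.random.default_rng(seed),
    )
    trace = subj.calibration_trace(duration=2.0)
    return float(np.mean(np.abs(trace.samples)))


def run_block(
    block: BlockSpec,
    models: ExperimentModels | None = None,
    mv_scale: float | None = None,
    feedback_gain: float | None = None,
) -> list[TrialResult]:
    """Run one 36-trial block (6 IDs x 6 reps, seeded order).

    Per-trial randomness derives deterministically from ``block.seed``;
    identical seeds reproduce identical results bit for bit.
    """
    models = models or ExperimentModels()
    ss = np.random.SeedSequence(block.seed)
    ss_calib, ss_gain, ss_trials = ss.spawn(3)
    if mv_scale is None:
        mv_scale = calibrate_subject_mv_scale(models, ss_calib)
    if feedback_gain is None:
        feedback_gain = calibrate_feedback_gain(
            block.condition.feedback_model,
            gamma=models.gamma,
            spindle_params=models.spindle,
            dt=1.0 / models.control_rate,
            seed=int(ss_gain.generate_state(1)[0] % (2 ** 31)),
        )
    controller = _build_controller(block.condition, models, mv_scale,
                                   feedback_gain)
    subject = SyntheticSubject(
        models.subject, models.muscle, models.plant,
        models.emg_fs, models.control_rate,
    )
    specs = block.trial_specs()
    trial_seeds = ss_trials.spawn(len(block.trial_order()))
    results = []
    for seed_seq, idx in zip(trial_seeds, block.trial_order()):
        rng = np.random.default_rng(seed_seq)
        results.append(run_trial(specs[idx], subject, controller, rng))
    return results


def run_experiment(
    models: ExperimentModels | None = None,
    seed: int = 0,
    conditions: tuple[ControllerConfig, ...] = ALL_CONDITIONS,
    reps: int = 6,
    targets: tuple[tuple[float, float], ...] | None = None,
    mapping_gain: float = 1.0,
) -> dict[str, list[TrialResult]]:
    """Run the full randomized-block 2x2 experiment on one synthetic subject.

    Four condition blocks of ``len(targets) * reps`` trials each (144 total
    at the defaults) in a seeded random block order; the mV calibration is
    performed once, as for a single subject visit.  Returns results keyed by
    condition label, insertion-ordered by block presentation.
    """
    models = models or ExperimentModels()
    targets = tuple(targets if targets is not None else default_target_catalog())
    ss = np.random.SeedSequence(seed)
    ss_order, ss_calib, ss_blocks = ss.spawn(3)
    mv_scale = calibrate_subject_mv_scale(models, ss_calib)
    order = np.random.default_rng(ss_order).permutation(len(conditions))
    block_seeds = ss_blocks.generate_state(len(conditions)) % (2 ** 31)
    out: dict[str, list[TrialResult]] = {}
    for pos in order:
        cond = conditions[pos]
        block = BlockSpec(
            condition=cond, targets=targets, reps=reps,
            mapping_gain=mapping_gain, seed=int(block_seeds[pos]),
        )
        out[cond.label] = run_block(block, models, mv_scale=mv_scale)
    return out
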