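"""Synthetic operator: latent motor intent and surface-EMG synthesis.

Closes the loop without human data.  The simulated subject watches the
force display (with a visual reaction delay), forms a piecewise-constant
latent intent — an initial ballistic jump toward the level expected to land
the force near the target-window center, occasional corrective re-aims, and
slow proportional corrections — and expresses that intent as surface EMG:
amplitude-modulated band-limited Gaussian noise,

    emg(t) = x(t) * n(t) * emg_scale_mv,

where x is the latent drive in [0, 1] and n is zero-mean Gaussian noise
band-passed to the carrier band and normalized to unit standard deviation.
The abrupt-transition structure of the intent is exactly the jump-process
prior the Bayesian decoder assumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .emg import EMGTrace, InvalidParameterError
from .muscle import MuscleParams, force_length
from .plant import PlantParams

__all__ = [
    "SubjectParams",
    "IntentTrace",
    "SyntheticSubject",
    "generate_intent",
    "synthesize_emg",
]


@dataclass(frozen=True)
class SubjectParams:
    """Behavioural and signal parameters of the synthetic operator.

    reaction_delay : visual reaction time, s.
    carrier_band : EMG carrier pass-band, Hz (surface-EMG energy band).
    jump_rate : rate (events/s) of corrective intent re-aims while the
        displayed force error exceeds half the target width.
    corrective_gain : slow proportional correction, command units per N of
        displayed force error per second.
    intent_noise_sd : standard deviation of the slow Ornstein-Uhlenbeck
        intent wobble, drive units (motor noise).
    noise_tau : correlation time of the intent wobble, s.
    aim_error_sd : s.d. of the multiplicative error on the ballistic aim
        (imperfect internal model).
    aim_caution : fraction of the half-width by which the ballistic aim
        undershoots the window center (risk aversion toward the break
        zone: 0 aims at the center, 1 at the lower window edge).
    emg_scale_mv : carrier amplitude at full drive, mV.
    """

    reaction_delay: float = 0.2
    carrier_band: tuple[float, float] = (20.0, 450.0)
    jump_rate: float = 2.0
    corrective_gain: float = 0.08
    intent_noise_sd: float = 0.015
    noise_tau: float = 0.3
    aim_error_sd: float = 0.15
    aim_caution: float = 0.5
    emg_scale_mv: float = 1.0

    def __post_init__(self):
        if self.reaction_delay < 0:
            raise InvalidParameterError("reaction_delay must be >= 0")
        lo, hi = self.carrier_band
        if not 0 < lo < hi:
            raise InvalidParameterError("carrier_band must satisfy 0 < lo < hi")
        if self.jump_rate < 0:
            raise InvalidParameterError("jump_rate must be >= 0")
        if self.emg_scale_mv <= 0:
            raise InvalidParameterError("emg_scale_mv must be positive")


@dataclass(frozen=True)
class IntentTrace:
    """Latent drive x(t) in [0, 1] at the EMG sampling rate."""

    x: np.ndarray
    fs: float = 2000.0

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "x", x)
        if x.size and (x.min() < 0 or x.max() > 1):
            raise InvalidParameterError("intent values must lie in [0, 1]")


class _Carrier:
    """Streaming unit-variance band-limited Gaussian noise generator."""

    def __init__(self, fs: float, band: tuple[float, float],
                 rng: np.random.Generator, order: int = 4):
        nyq = fs / 2
        hi = min(band[1], 0.99 * nyq)
        self.sos = _sig.butter(order, [band[0], hi], btype="band", fs=fs,
                               output="sos")
        self.rng = rng
        self.zi = np.zeros((self.sos.shape[0], 2))
        # White noise through H(z) has output variance (1/pi) Int |H|^2 dw;
        # evaluate once so the carrier has exactly unit variance.
        w, h = _sig.sosfreqz(self.sos, worN=8192)
        self.norm = 1.0 / np.sqrt(np.trapezoid(np.abs(h) ** 2, w) / np.pi)

    def block(self, n: int) -> np.ndarray:
        white = self.rng.standard_normal(n)
        y, self.zi = _sig.sosfilt(self.sos, white, zi=self.zi)
        return y * self.norm


class SyntheticSubject:
    """Simulated operator producing EMG blocks inside the closed loop.

    Call :meth:`reset` with a trial's force window, then call the instance
    once per control tick with the current displayed contact force; it
    returns the next block of raw EMG samples.  Matches the
    ``(tick_index, force) -> block`` source signature of
    :func:`myoloop.controller.run_closed_loop`.
    """

    def __init__(
        self,
        params: SubjectParams | None = None,
        muscle: MuscleParams | None = None,
        plant: PlantParams | None = None,
        fs: float = 2000.0,
        control_rate: float = 100.0,
        seed: int | np.random.Generator | None = None,
    ):
        self.params = params or SubjectParams()
        self.muscle = muscle or MuscleParams()
        self.plant = plant or PlantParams()
        self.fs = fs
        self.control_rate = control_rate
        self.dt = 1.0 / control_rate
        self.spt = int(round(fs / control_rate))
        self._delay_ticks = int(round(self.params.reaction_delay * control_rate))
        if not isinstance(seed, np.random.Generator):
            seed = np.random.default_rng(seed)
        self.rng = seed
        self.carrier = _Carrier(fs, self.params.carrier_band, self.rng)
        self.reset(f_target=0.0, half_width=np.inf)

    # ------------------------------------------------------------------

    def _required_drive(self, f_contact: float) -> float:
        """Invert the static command->contact-force chain (internal model).

        At steady state the muscle holds F = f_max * fl(l_contact) * u and
        the plant balance gives contact = k_c (F - k_r * gap)/(k_c + k_r);
        solve for u.
        """
        p, m = self.plant, self.muscle
        f_muscle = (
            f_contact * (p.k_contact + p.k_return) / p.k_contact
            + p.k_return * p.gap
        ) / p.cmd_to_force
        l_contact = p.l_rest - p.length_per_meter * p.gap
        return f_muscle / (m.f_max * force_length(l_contact, m))

    def reset(
        self,
        f_target: float,
        half_width: float,
        rng: np.random.Generator | None = None,
    ) -> None:
        """Prepare for a trial aiming at contact force ``f_target`` (N)."""
        if rng is not None:
            self.rng = rng
            self.carrier = _Carrier(self.fs, self.params.carrier_band, self.rng)
        self.f_target = f_target
        self.half_width = half_width
        aim = 1.0 + self.params.aim_error_sd * self.rng.standard_normal()
        if f_target > 0:
            hw = half_width if np.isfinite(half_width) else 0.0
            f_aim = f_target - self.params.aim_caution * hw
            self.u = float(np.clip(
                self._required_drive(f_aim) * max(aim, 0.1), 0.0, 1.0
            ))
        else:
            self.u = 0.0
        self._noise = 0.0
        self._force_buffer: list[float] = []
        self._last_jump_tick = 0
        self._tick_index = 0

    # ------------------------------------------------------------------

    def __call__(self, tick_index: int, displayed_force: float) -> np.ndarray:
        return self.tick(displayed_force)

    def tick(self, displayed_force: float) -> np.ndarray:
        """One control tick: update intent, emit ``spt`` EMG samples."""
        p = self.params
        self._tick_index += 1
        self._force_buffer.append(displayed_force)
        if len(self._force_buffer) > self._delay_ticks:
            seen = self._force_buffer[-(self._delay_ticks + 1)]
        else:
            seen = 0.0
        if seen > 0.0 and self.f_target > 0:
            err = self.f_target - seen
            # slow proportional correction on the visualized force error
            self.u += p.corrective_gain * err * self.dt
            # occasional ballistic re-aim while clearly outside the window;
            # refractory for one reaction delay after each jump (the subject
            # waits to see the outcome of the previous adjustment)
            refractory = (
                self._tick_index - self._last_jump_tick <= self._delay_ticks
            )
            if (
                abs(err) > self.half_width
                and p.jump_rate > 0
                and not refractory
                and self.rng.random() < p.jump_rate * self.dt
            ):
                factor = float(np.clip(self.f_target / max(seen, 1e-3), 0.5, 2.0))
                self.u *= factor
                self._last_jump_tick = self._tick_index
        self.u = float(np.clip(self.u, 0.0, 1.0))
        # OU motor wobble
        if p.intent_noise_sd > 0:
            self._noise += (
                -self._noise * self.dt / p.noise_tau
                + p.intent_noise_sd
                * np.sqrt(2.0 * self.dt / p.noise_tau)
                * self.rng.standard_normal()
            )
        x = float(np.clip(self.u + self._noise, 0.0, 1.0))
        return x * self.carrier.block(self.spt) * p.emg_scale_mv

    def calibration_trace(self, duration: float = 2.0) -> EMGTrace:
        """Maximal-effort trace (x = 1) for mV-to-drive calibration."""
        n = int(round(duration * self.fs))
        return EMGTrace(self.carrier.block(n) * self.params.emg_scale_mv, self.fs)


# ---------------------------------------------------------------------------
# Offline generation (open loop or against a recorded feedback channel)
# ---------------------------------------------------------------------------


def generate_intent(
    f_target: float,
    half_width: float,
    duration: float,
    params: SubjectParams | None = None,
    feedback_channel=None,
    muscle: MuscleParams | None = None,
    plant: PlantParams | None = None,
    fs: float = 2000.0,
    control_rate: float = 100.0,
    seed: int | np.random.Generator | None = None,
) -> IntentTrace:
    """Generate a latent intent trace for a trial goal.

    ``feedback_channel`` maps a tick index to the displayed force (e.g. a
    recorded trace); ``None`` means no visual feedback (pure ballistic jump
    plus noise).  Deterministic given the seed.
    """
    subj = SyntheticSubject(params, muscle, plant, fs, control_rate, seed)
    subj.reset(f_target, half_width)
    n_ticks = int(round(duration * control_rate))
    xs = np.empty(n_ticks * subj.spt)
    for k in range(n_ticks):
        force = float(feedback_channel(k)) if feedback_channel else 0.0
        subj.tick(force)
        x = float(np.clip(subj.u + subj._noise, 0.0, 1.0))
        xs[k * subj.spt:(k + 1) * subj.spt] = x
    return IntentTrace(xs, fs)


def synthesize_emg(
    intent: IntentTrace,
    params: SubjectParams | None = None,
    seed: int | np.random.Generator | None = None,
) -> EMGTrace:
    """Amplitude-modulate a band-limited unit-variance Gaussian carrier.

    emg = x * carrier * emg_scale_mv; the mean rectified amplitude at
    constant drive c is c * emg_scale_mv * sqrt(2/pi) (folded Gaussian).
    """
    params = params or SubjectParams()
    if not isinstance(seed, np.random.Generator):
        seed = np.random.default_rng(seed)
    carrier = _Carrier(intent.fs, params.carrier_band, seed)
    n = carrier.block(intent.x.size)
    return EMGTrace(intent.x * n * params.emg_scale_mv, intent.fs)
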