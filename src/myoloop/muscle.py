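"""Hill-type muscle: excitation–activation dynamics and force generation.

The virtual flexor converts the (dimensionless) motor command into tendon
force through three stages: a first-order excitation–activation lag, an
active contractile element scaled by force–length and force–velocity
relations, and a passive parallel-elastic element engaged beyond optimal
length.  Force is reported in newtons.

Sign convention: ``v_norm`` is the lengthening velocity in optimal lengths
per second — negative while the muscle shortens (concentric), positive while
it is stretched (eccentric).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emg import InvalidParameterError

__all__ = [
    "MuscleParams",
    "MuscleState",
    "activation_dynamics",
    "force_length",
    "force_velocity",
    "passive_force",
    "hill_force",
]


@dataclass(frozen=True)
class MuscleParams:
    """Hill-model constants (literature-typical defaults, all configurable).

    f_max : maximum isometric force, N.
    l_opt : optimal fiber length, m (lengths are handled normalized; l_opt
        only sets the unit of v_max).
    tau_act / tau_deact : activation and deactivation time constants, s.
    fl_width : width of the Gaussian force–length curve (dimensionless).
    fv_shape : curvature of the Hill force–velocity hyperbola.
    v_max : maximum shortening velocity, l_opt/s.
    k_passive : passive parallel-elastic stiffness (force fraction per
        squared normalized stretch beyond l_opt).
    fv_ecc_max : saturation ceiling of the eccentric force–velocity branch,
        as a multiple of isometric force.
    """

    f_max: float = 10.0
    l_opt: float = 1.0
    tau_act: float = 0.010
    tau_deact: float = 0.040
    fl_width: float = 0.45
    fv_shape: float = 0.25
    v_max: float = 10.0
    k_passive: float = 3.0
    fv_ecc_max: float = 1.5

    def __post_init__(self):
        for name in ("f_max", "l_opt", "tau_act", "tau_deact", "fl_width",
                     "fv_shape", "v_max", "k_passive"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.tau_act > self.tau_deact:
            raise InvalidParameterError("tau_act must be <= tau_deact")
        if self.fv_ecc_max < 1:
            raise InvalidParameterError("fv_ecc_max must be >= 1")


@dataclass(frozen=True)
class MuscleState:
    """Instantaneous muscle state.

    l_norm : length / l_opt (> 0); v_norm : lengthening velocity, l_opt/s;
    a : activation in [0, 1]; force : last computed output force, N.
    """

    l_norm: float = 1.0
    v_norm: float = 0.0
    a: float = 0.0
    force: float = 0.0

    def __post_init__(self):
        if not 0 <= self.a <= 1:
            raise InvalidParameterError("activation must lie in [0, 1]")
        if self.l_norm <= 0:
            raise InvalidParameterError("l_norm must be positive")
        if self.force < 0:
            raise InvalidParameterError("force must be >= 0")


def activation_dynamics(
    a: float, u: float, dt: float, params: MuscleParams
) -> float:
    """One explicit-Euler step of the excitation–activation lag.

    da/dt = (u - a) / tau, with tau = tau_act while excitation exceeds
    activation (calcium release, fast) and tau_deact otherwise (re-uptake,
    slow).  Discrete update: a + dt/tau * (u - a), clamped to [0, 1]; with
    dt >= tau the step lands on u (clamped), which is the documented
    behaviour of the explicit scheme.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    tau = params.tau_act if u > a else params.tau_deact
    a_new = a + (dt / tau) * (u - a)
    return float(np.clip(a_new, 0.0, 1.0))


def force_length(l_norm: float, params: MuscleParams) -> float:
    """Gaussian active force–length relation, maximal (=1) at l_opt."""
    return float(np.exp(-(((l_norm - 1.0) / params.fl_width) ** 2)))


def force_velocity(v_norm: float, params: MuscleParams) -> float:
    """Hill force–velocity relation on the signed lengthening velocity.

    Concentric branch (v_norm <= 0, shortening): the classic hyperbola
    ``(1 + v/v_max) / (1 - v/(fv_shape * v_max))`` with fv(0) = 1 and
    fv(-v_max) = 0 (clamped at 0 beyond v_max).  Eccentric branch
    (v_norm > 0): ``1 + (fv_ecc_max - 1) * v / (v + fv_shape * v_max)``,
    rising from 1 and saturating at fv_ecc_max.
    """
    v = v_norm
    if v <= 0:
        if v <= -params.v_max:
            return 0.0
        return float((1.0 + v / params.v_max)
                     / (1.0 - v / (params.fv_shape * params.v_max)))
    return float(1.0 + (params.fv_ecc_max - 1.0)
                 * v / (v + params.fv_shape * params.v_max))


def passive_force(l_norm: float, params: MuscleParams) -> float:
    """Parallel-elastic force fraction: k_passive * max(0, l_norm - 1)^2."""
    stretch = max(0.0, l_norm - 1.0)
    return params.k_passive * stretch * stretch


def hill_force(state: MuscleState, params: MuscleParams) -> float:
    """Total muscle force in N.

    force = f_max * (a * fl(l) * fv(v) + fp(l)), never negative.
    """
    active = state.a * force_length(state.l_norm, params) * force_velocity(
        state.v_norm, params
    )
    return max(0.0, params.f_max * (active + passive_force(state.l_norm, params)))
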