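"""Virtual tendon-driven finger: 1-DOF plant with compliant contact.

The motor/tendon/finger chain is collapsed to one translational degree of
freedom: the fingertip starts 1 cm above a force transducer, travels freely
across the gap, and presses into a stiff linear contact.  Return springs
(which open the hand in the physical device) act as a linear restoring
term, and an effective damping dominates the free motion so that a brisk
command crosses the gap in a few hundred milliseconds.

A linear kinematic map ties fingertip position to flexor length: the muscle
shortens as the finger flexes, and sub-millimeter transducer deformation
under load still changes muscle length slightly — the task is quasi-
isometric, not strictly isometric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emg import InvalidInputError, InvalidParameterError

__all__ = [
    "PlantParams",
    "PlantState",
    "VirtualObject",
    "plant_step",
    "muscle_length_from_plant",
    "muscle_velocity_from_plant",
    "equilibrium_contact_force",
    "is_broken",
]


@dataclass(frozen=True)
class PlantParams:
    """Virtual plant constants.

    gap : free travel before contact, m (1 cm).
    k_contact : transducer contact stiffness, N/m (2000 N/m keeps task-range
        forces at sub-millimeter penetration).
    damping : effective viscous damping, N*s/m (dominates free motion; the
        reflected motor/tendon friction).
    mass : effective fingertip inertia, kg.
    cmd_to_force : tendon transmission gain from muscle force to fingertip
        force (dimensionless; 1 = direct).
    k_return : return-spring stiffness, N/m (hand-opening springs).
    length_per_meter : flexor shortening per meter of fingertip travel,
        in normalized muscle lengths per m (10 /m: crossing the 1 cm gap
        shortens the muscle by 10%).
    l_rest : normalized muscle length at the start position.
    """

    gap: float = 0.01
    k_contact: float = 2000.0
    damping: float = 80.0
    mass: float = 0.2
    cmd_to_force: float = 1.0
    k_return: float = 20.0
    length_per_meter: float = 10.0
    l_rest: float = 1.0

    def __post_init__(self):
        for name in ("gap", "k_contact", "damping", "mass", "cmd_to_force",
                     "k_return", "length_per_meter", "l_rest"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")


@dataclass(frozen=True)
class PlantState:
    """Fingertip state: position (0 = start, gap = transducer surface),
    velocity, current contact force and time."""

    pos: float = 0.0
    vel: float = 0.0
    contact_force: float = 0.0
    t: float = 0.0

    def __post_init__(self):
        if self.contact_force < 0:
            raise InvalidInputError("contact_force must be >= 0")


@dataclass(frozen=True)
class VirtualObject:
    """Breakable virtual object pressed by the finger."""

    break_threshold: float = 4.4

    def __post_init__(self):
        if self.break_threshold <= 0:
            raise InvalidParameterError("break_threshold must be positive")


def _contact_force(pos: float, params: PlantParams) -> float:
    return max(0.0, params.k_contact * (pos - params.gap))


def plant_step(
    state: PlantState, muscle_force: float, dt: float, params: PlantParams
) -> PlantState:
    """Advance the plant one control tick (semi-implicit Euler).

    mass * acc = cmd_to_force * muscle_force - k_return * pos
                 - damping * vel - contact
    contact = k_contact * (pos - gap) when pos > gap, else 0.

    Velocity is updated first, then position from the new velocity
    (semi-implicit Euler); the damping term is treated implicitly so the
    scheme stays stable at the 100 Hz step for any damping level.  The
    finger cannot be driven below the start stop (pos >= 0).
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    if not np.isfinite(muscle_force):
        raise InvalidInputError("muscle force must be finite")
    if muscle_force < 0:
        raise InvalidInputError("muscle force must be >= 0")
    f_elastic = (
        params.cmd_to_force * muscle_force
        - params.k_return * state.pos
        - _contact_force(state.pos, params)
    )
    vel = (state.vel + dt * f_elastic / params.mass) / (
        1.0 + dt * params.damping / params.mass
    )
    pos = state.pos + dt * vel
    if pos < 0.0:
        pos, vel = 0.0, max(0.0, vel)
    return PlantState(pos, vel, _contact_force(pos, params), state.t + dt)


def muscle_length_from_plant(state: PlantState, params: PlantParams) -> float:
    """Normalized flexor length: l_rest - length_per_meter * pos."""
    return params.l_rest - params.length_per_meter * state.pos


def muscle_velocity_from_plant(state: PlantState, params: PlantParams) -> float:
    """Flexor lengthening velocity in l_opt/s (negative while flexing)."""
    return -params.length_per_meter * state.vel


def equilibrium_contact_force(muscle_force: float, params: PlantParams) -> float:
    """Analytic steady-state contact force for a held muscle force.

    At rest, F = k_return * pos + k_contact * (pos - gap) with
    F = cmd_to_force * muscle_force, giving

        contact = k_contact * (F - k_return * gap) / (k_contact + k_return)

    valid when the finger reaches the transducer (result clamped at 0
    otherwise).
    """
    f = params.cmd_to_force * muscle_force
    contact = (
        params.k_contact
        * (f - params.k_return * params.gap)
        / (params.k_contact + params.k_return)
    )
    return max(0.0, contact)


def is_broken(state: PlantState, obj: VirtualObject) -> bool:
    """True iff the contact force has reached the break threshold
    (threshold-inclusive: exactly 4.4 N breaks the object)."""
    return state.contact_force >= obj.break_threshold
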