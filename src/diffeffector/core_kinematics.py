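"""Skeleton parameterizations, rigid-body dynamics and the Euler integrator.

Two planar skeletons are provided: a point-mass with Cartesian degrees of
freedom, and a two-segment arm with hinge shoulder and elbow moving in a
horizontal plane (no gravity).  All state-propagating functions accept
either plain numpy arrays or :class:`~diffeffector.autodiff.Tensor`
inputs and are differentiable in the latter case.

Generalized coordinates are laid out as ``q = (shoulder, elbow)`` in
radians for the arm (positive flexion increases the angle) and
``q = (x, y)`` in metres for the point-mass.  Batched states use a
leading batch axis: ``q.shape == (batch, 2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, data_of

DT = 0.01  # default integration timestep (s)


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------

@dataclass
class JointState:
    """Generalized coordinates and velocities of a skeleton."""

    q: object     # (..., dof) array or Tensor
    qdot: object  # (..., dof) array or Tensor

    def __post_init__(self):
        if data_of(self.q).shape != data_of(self.qdot).shape:
            raise ValueError("q and qdot must have matching shapes")

    @property
    def dof(self) -> int:
        return data_of(self.q).shape[-1]


@dataclass
class CartesianState:
    """Endpoint position and velocity in world coordinates."""

    pos: object  # (..., 2)
    vel: object  # (..., 2)


# ---------------------------------------------------------------------------
# parameter records
# ---------------------------------------------------------------------------

@dataclass
class PointMassParams:
    mass: float = 1.0
    # workspace bounds, rows are (min, max) per coordinate
    bounds: np.ndarray = field(default_factory=lambda: np.array([[-1.0, 1.0], [-1.0, 1.0]]))

    def __post_init__(self):
        if not self.mass > 0:
            raise ValueError("mass must be strictly positive")
        self.bounds = np.asarray(self.bounds, dtype=float)
        if self.bounds.shape != (2, 2):
            raise ValueError("bounds must be a 2x2 (coordinate, min/max) matrix")


@dataclass
class TwoLinkParams:
    """Planar two-segment arm parameters (upper arm, forearm)."""

    masses: np.ndarray = field(default_factory=lambda: np.array([1.82, 1.43]))
    cog: np.ndarray = field(default_factory=lambda: np.array([0.135, 0.165]))
    inertias: np.ndarray = field(default_factory=lambda: np.array([0.051, 0.057]))
    lengths: np.ndarray = field(default_factory=lambda: np.array([0.309, 0.333]))
    # joint viscosity (N*m*s/rad); damping in the source formalization is
    # opt-in, default off
    viscosity: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    # joint limits in radians, rows are (min, max) for (shoulder, elbow)
    joint_limits: np.ndarray = field(
        default_factory=lambda: np.array(
            [[0.0, np.deg2rad(135.0)], [0.0, np.deg2rad(155.0)]]
        )
    )

    def __post_init__(self):
        for name in ("masses", "cog", "inertias", "lengths", "viscosity", "joint_limits"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("masses", "cog", "inertias", "lengths"):
            if not np.all(getattr(self, name) > 0):
                raise ValueError(f"{name} must be strictly positive")
        B = self.viscosity
        if B.shape != (2, 2) or not np.allclose(B, B.T):
            raise ValueError("viscosity must be a symmetric 2x2 matrix")
        if np.any(np.linalg.eigvalsh(B) < -1e-12):
            raise ValueError("viscosity must be positive semidefinite")


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def point_mass_dynamics(state: JointState, force, params: PointMassParams):
    """Acceleration of the point-mass: ``f / m`` elementwise."""
    if not np.all(np.isfinite(data_of(force))):
        raise ValueError("force must be finite")
    return force * (1.0 / params.mass)


def _split(v):
    """Split the last axis of a (..., 2) array/Tensor into two (..., 1) halves."""
    return v[..., 0:1], v[..., 1:2]


def two_link_inertia(q, params: TwoLinkParams):
    """Entries (m11, m12, m22) of the symmetric 2x2 inertia matrix at ``q``."""
    m1, m2 = params.masses
    lc1, lc2 = params.cog
    i1, i2 = params.inertias
    l1 = params.lengths[0]
    _, q2 = _split(q)
    c2 = ad.cos(q2)
    a = i1 + i2 + m1 * lc1**2 + m2 * (l1**2 + lc2**2)
    b = m2 * l1 * lc2
    m11 = a + 2.0 * b * c2
    m12 = i2 + m2 * lc2**2 + b * c2
    m22_val = i2 + m2 * lc2**2
    m22 = m12 * 0.0 + m22_val  # broadcast to batch shape
    return m11, m12, m22


def two_link_dynamics(state: JointState, torque, params: TwoLinkParams):
    """Joint accelerations solving ``M(q) qdd + c(q, qd) + B qd = tau``.

    Standard planar two-link chain with cos(q2) inertial coupling and
    Coriolis/centripetal vector; horizontal plane, so no gravity term.
    """
    if not np.all(np.isfinite(data_of(torque))):
        raise ValueError("torque must be finite")
    q, qd = state.q, state.qdot
    m2 = params.masses[1]
    lc2 = params.cog[1]
    l1 = params.lengths[0]
    _, q2 = _split(q)
    qd1, qd2 = _split(qd)
    h = m2 * l1 * lc2 * ad.sin(q2)
    c1 = -h * qd2 * (2.0 * qd1 + qd2)
    c2v = h * qd1 * qd1
    B = params.viscosity
    visc1 = B[0, 0] * qd1 + B[0, 1] * qd2
    visc2 = B[1, 0] * qd1 + B[1, 1] * qd2
    t1, t2 = _split(torque)
    rhs1 = t1 - c1 - visc1
    rhs2 = t2 - c2v - visc2
    m11, m12, m22 = two_link_inertia(q, params)
    det = m11 * m22 - m12 * m12
    if np.any(data_of(det) <= 0):
        raise ArithmeticError("singular inertia matrix")  # cannot occur for valid params
    qdd1 = (m22 * rhs1 - m12 * rhs2) / det
    qdd2 = (m11 * rhs2 - m12 * rhs1) / det
    return ad.concatenate([qdd1, qdd2], axis=-1)


def forward_kinematics(state: JointState, params: TwoLinkParams) -> CartesianState:
    """Endpoint position and velocity of the two-link arm.

    Velocity is the analytic Jacobian applied to joint velocities.
    """
    l1, l2 = params.lengths
    q1, q2 = _split(state.q)
    qd1, qd2 = _split(state.qdot)
    s1, c1 = ad.sin(q1), ad.cos(q1)
    s12, c12 = ad.sin(q1 + q2), ad.cos(q1 + q2)
    px = l1 * c1 + l2 * c12
    py = l1 * s1 + l2 * s12
    vx = -(l1 * s1 + l2 * s12) * qd1 - l2 * s12 * qd2
    vy = (l1 * c1 + l2 * c12) * qd1 + l2 * c12 * qd2
    return CartesianState(
        pos=ad.concatenate([px, py], axis=-1),
        vel=ad.concatenate([vx, vy], axis=-1),
    )


def endpoint_jacobian(q, params: TwoLinkParams):
    """Analytic 2x2 endpoint Jacobian entries ``(J11, J12, J21, J22)``."""
    l1, l2 = params.lengths
    q1, q2 = _split(q)
    s1, c1 = ad.sin(q1), ad.cos(q1)
    s12, c12 = ad.sin(q1 + q2), ad.cos(q1 + q2)
    j11 = -(l1 * s1 + l2 * s12)
    j12 = -l2 * s12
    j21 = l1 * c1 + l2 * c12
    j22 = l2 * c12
    return j11, j12, j21, j22


def point_mass_kinematics(state: JointState) -> CartesianState:
    """The point-mass endpoint is its own generalized coordinate."""
    return CartesianState(pos=state.q, vel=state.qdot)


def euler_step(value, derivative, dt: float = DT):
    """One explicit Euler step: ``value + dt * derivative``."""
    if data_of(value).shape != data_of(derivative).shape:
        raise ValueError("value and derivative must have matching shapes")
    return value + dt * derivative
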