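"""Muscle-path geometry: world-frame fixation points, musculotendon
lengths, moment arms and the force-to-torque mapping.

Moment arms are defined as the partial derivative of musculotendon
length with respect to each generalized coordinate; a muscle whose
shortening increases a coordinate therefore has a negative moment arm
for it.  Two routes are provided:

* :func:`geometric_moment_arms` — closed-form chain rule through
  straight-line paths of fixation points expressed in bone-relative
  frames (remains differentiable for end-to-end training);
* :func:`polynomial_length_and_moment_arms` — a quadratic
  length-vs-angle approximation with exact analytic derivatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import data_of
from .core_kinematics import JointState, PointMassParams, TwoLinkParams


@dataclass
class FixationPoint:
    """A muscle fixation point: ``body == 0`` is the world frame (world
    x, y); otherwise coordinates are along-bone / orthogonal offsets from
    the bone's origin."""

    body: int
    coords: np.ndarray  # (2,)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (2,):
            raise ValueError("coords must be a 2-vector")
        if self.body < 0:
            raise ValueError("body index must be nonnegative")


@dataclass
class MusclePath:
    name: str
    points: list[FixationPoint]

    def __post_init__(self):
        if len(self.points) < 2:
            raise ValueError("a muscle path needs at least two fixation points")


@dataclass
class PolynomialPathParams:
    """Coefficients of the quadratic musculotendon-length approximation
    ``l = a0 + a1s*q_s + a1e*q_e + a2e*q_e**2``."""

    a0: float
    a1s: float = 0.0
    a1e: float = 0.0
    a2e: float = 0.0
    name: str = "muscle"

    def __post_init__(self):
        if not self.a0 > 0:
            raise ValueError("a0 must be strictly positive")


# ---------------------------------------------------------------------------
# skeleton frame providers
# ---------------------------------------------------------------------------

class PointMassFrames:
    """Body 1 translates with q = (x, y); no rotation."""

    n_bodies = 1

    def __init__(self, params: PointMassParams | None = None):
        self.params = params or PointMassParams()

    def frames(self, q):
        zero = q[..., 0:1] * 0.0
        return [(q, zero)]

    def frame_jacobian(self, q, j: int):
        d = np.zeros(2)
        d[j] = 1.0
        zeros = data_of(q) * 0.0
        return [(zeros + d, (zeros + 0.0)[..., 0:1])]


class TwoLinkFrames:
    """Body 1 = upper arm rotating about the shoulder at the world
    origin; body 2 = forearm with origin at the elbow, angle q_s + q_e."""

    n_bodies = 2

    def __init__(self, params: TwoLinkParams | None = None):
        self.params = params or TwoLinkParams()

    def frames(self, q):
        l1 = self.params.lengths[0]
        qs, qe = q[..., 0:1], q[..., 1:2]
        zero = qs * 0.0
        elbow = ad.concatenate([l1 * ad.cos(qs), l1 * ad.sin(qs)], axis=-1)
        world_origin = ad.concatenate([zero, zero], axis=-1)
        return [(world_origin, qs), (elbow, qs + qe)]

    def frame_jacobian(self, q, j: int):
        l1 = self.params.lengths[0]
        qs = q[..., 0:1]
        zero = qs * 0.0
        one = zero + 1.0
        zero2 = ad.concatenate([zero, zero], axis=-1)
        if j == 0:
            delbow = ad.concatenate([-l1 * ad.sin(qs), l1 * ad.cos(qs)], axis=-1)
            return [(zero2, one), (delbow, one)]
        return [(zero2, zero), (zero2, one)]


def frames_for(skeleton_params):
    if isinstance(skeleton_params, TwoLinkParams):
        return TwoLinkFrames(skeleton_params)
    if isinstance(skeleton_params, PointMassParams):
        return PointMassFrames(skeleton_params)
    raise TypeError(f"unsupported skeleton parameter type: {type(skeleton_params)!r}")


# ---------------------------------------------------------------------------
# path resolution and lengths
# ---------------------------------------------------------------------------

def _rotate(coords: np.ndarray, angle):
    """R(angle) @ coords for a fixed 2-vector and batched angle (..., 1)."""
    c1, c2 = coords
    ca, sa = ad.cos(angle), ad.sin(angle)
    return ad.concatenate([c1 * ca - c2 * sa, c1 * sa + c2 * ca], axis=-1)


def _rotate_deriv(coords: np.ndarray, angle):
    """d/d(angle) of R(angle) @ coords."""
    c1, c2 = coords
    ca, sa = ad.cos(angle), ad.sin(angle)
    return ad.concatenate([-(c1 * sa + c2 * ca), c1 * ca - c2 * sa], axis=-1)


def resolve_path_points(path: MusclePath, state, skeleton_params):
    """World coordinates of every fixation point at the given state.

    ``state`` may be a :class:`JointState` or a bare ``q`` array/Tensor
    of shape (..., dof).
    """
    q = state.q if isinstance(state, JointState) else state
    frames = frames_for(skeleton_params)
    body_frames = frames.frames(q)
    out = []
    batch_zero = q[..., 0:1] * 0.0
    for pt in path.points:
        if pt.body == 0:
            out.append(ad.concatenate([batch_zero + pt.coords[0],
                                       batch_zero + pt.coords[1]], axis=-1))
        elif pt.body <= frames.n_bodies:
            origin, angle = body_frames[pt.body - 1]
            out.append(origin + _rotate(pt.coords, angle))
        else:
            raise ValueError(f"unknown body index {pt.body}")
    return out


def musculotendon_length(points: Sequence):
    """Total straight-segment path length, shape (..., 1)."""
    if len(points) < 2:
        raise ValueError("need at least two points")
    total = None
    for a, b in zip(points[:-1], points[1:]):
        d = b - a
        seg = ad.sqrt(ad.sum(d * d, axis=-1, keepdims=True))
        total = seg if total is None else total + seg
    return total


def path_length_and_moment_arms(path: MusclePath, q, skeleton_params):
    """Length and analytic moment arms (dl/dq_j) for one muscle path.

    Returns ``(length (..., 1), [ma_j (..., 1) per dof])``.  The chain
    rule runs through the bone frames, so the result itself remains
    differentiable with respect to ``q``.
    """
    frames = frames_for(skeleton_params)
    dof = 2
    body_frames = frames.frames(q)
    jacs = [frames.frame_jacobian(q, j) for j in range(dof)]
    batch_zero = q[..., 0:1] * 0.0
    world_pts, dpts = [], []  # dpts[i][j] = d(world point i)/dq_j
    for pt in path.points:
        if pt.body == 0:
            world_pts.append(ad.concatenate([batch_zero + pt.coords[0],
                                             batch_zero + pt.coords[1]], axis=-1))
            dpts.append([None] * dof)
        else:
            origin, angle = body_frames[pt.body - 1]
            world_pts.append(origin + _rotate(pt.coords, angle))
            rot_d = _rotate_deriv(pt.coords, angle)
            per_dof = []
            for j in range(dof):
                dorigin, dangle = jacs[j][pt.body - 1]
                per_dof.append(dorigin + dangle * rot_d)
            dpts.append(per_dof)
    length = None
    mas = [None] * dof
    for i in range(len(world_pts) - 1):
        d = world_pts[i + 1] - world_pts[i]
        seg = ad.sqrt(ad.sum(d * d, axis=-1, keepdims=True))
        if np.any(data_of(seg) < 1e-12):
            raise ArithmeticError(
                f"degenerate zero-length segment in path '{path.name}'")
        length = seg if length is None else length + seg
        unit = d / seg
        for j in range(dof):
            da = dpts[i][j]
            db = dpts[i + 1][j]
            if da is None and db is None:
                continue
            dd = db - da if (da is not None and db is not None) else (
                db if da is None else -da)
            contrib = ad.sum(unit * dd, axis=-1, keepdims=True)
            mas[j] = contrib if mas[j] is None else mas[j] + contrib
    zero = batch_zero
    mas = [zero if m is None else m for m in mas]
    return length, mas


def geometric_moment_arms(paths: Sequence[MusclePath], state, skeleton_params):
    """Lengths and moment arms for a set of muscles.

    Returns ``(lengths (..., m), [ma_j (..., m) per dof])``.
    """
    q = state.q if isinstance(state, JointState) else state
    lengths, ma_cols = [], None
    for path in paths:
        length, mas = path_length_and_moment_arms(path, q, skeleton_params)
        lengths.append(length)
        if ma_cols is None:
            ma_cols = [[m] for m in mas]
        else:
            for j, m in enumerate(mas):
                ma_cols[j].append(m)
    return (ad.concatenate(lengths, axis=-1),
            [ad.concatenate(cols, axis=-1) for cols in ma_cols])


def polynomial_length_and_moment_arms(coeffs: PolynomialPathParams | Sequence[PolynomialPathParams], q):
    """Quadratic length approximation and its exact partial derivatives.

    For a single coefficient record returns ``(length (..., 1),
    [ma_s, ma_e])``; for a sequence, columns are stacked into (..., m).
    """
    single = isinstance(coeffs, PolynomialPathParams)
    records = [coeffs] if single else list(coeffs)
    qs, qe = q[..., 0:1], q[..., 1:2]
    one = qs * 0.0 + 1.0
    lengths, ma_s, ma_e = [], [], []
    for c in records:
        lengths.append(c.a0 + c.a1s * qs + c.a1e * qe + c.a2e * qe * qe)
        ma_s.append(one * c.a1s)
        ma_e.append(c.a1e + 2.0 * c.a2e * qe)
    if single:
        return lengths[0], [ma_s[0], ma_e[0]]
    return (ad.concatenate(lengths, axis=-1),
            [ad.concatenate(ma_s, axis=-1), ad.concatenate(ma_e, axis=-1)])


def muscle_torque(moment_arms: Sequence, forces):
    """Generalized forces from muscle tensions:
    ``tau_j = -sum_m MA[m, j] * F[m]`` (a pulling force drives each
    coordinate toward shorter musculotendon length)."""
    cols = []
    for ma_j in moment_arms:
        if data_of(ma_j).shape != data_of(forces).shape:
            raise ValueError("moment arm / force shape mismatch")
        cols.append(-ad.sum(ma_j * forces, axis=-1, keepdims=True))
    return ad.concatenate(cols, axis=-1)


def load_muscle_paths(records) -> list[MusclePath]:
    """Build :class:`MusclePath` objects from ``{"name":..., "points":
    [[body, c1, c2], ...]}`` records (the on-disk JSON layout)."""
    paths = []
    for rec in records:
        pts = [FixationPoint(int(b), np.array([x, y])) for b, x, y in rec["points"]]
        paths.append(MusclePath(rec["name"], pts))
    return paths
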