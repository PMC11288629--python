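"""The effector: per-timestep coordination of activation dynamics,
muscle geometry, force production, skeleton dynamics and Euler
integration.

Each :meth:`Effector.step` performs, in order:

1. one Euler step of the excitation-to-activation ODE from the action;
2. geometry refresh (musculotendon lengths, velocities, moment arms) at
   the current configuration;
3. muscle force production;
4. generalized forces = muscle torques + J^T external endpoint force;
5. skeleton dynamics -> accelerations;
6. Euler update of velocities then positions (with joint-limit clamping
   for the arm);
7. cartesian/muscle state refresh.

Everything runs on :mod:`diffeffector.autodiff` tensors when gradients
are requested, making a full rollout differentiable end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from . import autodiff as ad
from . import core_kinematics as ck
from . import muscle_geometry as mg
from . import muscle_models as mm
from ._fastops import (fused_activation_step, fused_arm_kinematics,
                       fused_hill_force, fused_two_link_dynamics)
from .autodiff import data_of
from .core_kinematics import (CartesianState, JointState, PointMassParams,
                              TwoLinkParams)


@dataclass
class EffectorState:
    joint: JointState
    cartesian: CartesianState
    muscle: mm.MuscleState
    moment_arms: list           # per-dof (..., m)
    last_action: object         # (..., m)

    @property
    def batch_size(self) -> int:
        return data_of(self.joint.q).shape[0]


def _load_data(name: str) -> dict:
    return json.loads((resources.files("diffeffector") / "data" / name).read_text())


class Effector:
    """A skeleton plus a set of muscles and their geometry.

    Parameters
    ----------
    skeleton_params:
        :class:`TwoLinkParams` or :class:`PointMassParams`.
    muscles:
        per-muscle :class:`~diffeffector.muscle_models.MuscleParams`.
    geometry:
        either a list of :class:`~diffeffector.muscle_geometry.MusclePath`
        (geometric moment arms) or of
        :class:`~diffeffector.muscle_geometry.PolynomialPathParams`
        (analytic approximation).
    muscle_type:
        ``"hill"`` or ``"relu"``.
    """

    def __init__(self, skeleton_params, muscles, geometry, muscle_type: str = "hill",
                 dt: float = ck.DT, passive_enabled: bool = True,
                 resting_activation: float | None = None, name: str = "effector"):
        if muscle_type not in ("hill", "relu"):
            raise ValueError("muscle_type must be 'hill' or 'relu'")
        self.skeleton_params = skeleton_params
        self.muscles = list(muscles)
        self.geometry = list(geometry)
        if len(self.geometry) != len(self.muscles):
            raise ValueError("one geometry entry per muscle is required")
        self.muscle_type = muscle_type
        self.dt = dt
        self.passive_enabled = passive_enabled
        self.name = name
        self.is_arm = isinstance(skeleton_params, TwoLinkParams)
        self._polynomial = isinstance(self.geometry[0], mg.PolynomialPathParams)
        # resting activation: small epsilon for Hill muscles avoids a dead
        # gradient at exactly zero activation
        if resting_activation is None:
            resting_activation = 1e-3 if muscle_type == "hill" else 0.0
        self.resting_activation = resting_activation
        self._fmax = np.array([m.max_isometric_force for m in self.muscles])
        self._l0 = np.array([m.optimal_muscle_length for m in self.muscles])
        self._tendon = np.array([m.tendon_length for m in self.muscles])
        self._vmax = np.array([m.vmax for m in self.muscles])
        self._tau_act = np.array([m.tau_activation for m in self.muscles])
        self._tau_deact = np.array([m.tau_deactivation for m in self.muscles])
        self._fl_gamma = np.array([m.fl_gamma for m in self.muscles])
        self._fv_af = np.array([m.fv_af for m in self.muscles])
        self._fv_flen = np.array([m.fv_flen for m in self.muscles])
        self._pas_k = np.array([m.passive_shape for m in self.muscles])
        self._pas_eps = np.array([m.passive_strain for m in self.muscles])
        self._pas_slack = np.array([m.normalized_slack_length for m in self.muscles])
        if self._polynomial:
            self._poly_a0 = np.array([c.a0 for c in self.geometry])
            self._poly_a1s = np.array([c.a1s for c in self.geometry])
            self._poly_a1e = np.array([c.a1e for c in self.geometry])
            self._poly_a2e = np.array([c.a2e for c in self.geometry])
        # vectorized fast path for simple point-mass anchor->body paths
        self._pm_anchors = None
        if (not self._polynomial and not self.is_arm
                and all(len(p.points) == 2 and p.points[0].body == 0
                        and p.points[1].body == 1 for p in self.geometry)):
            self._pm_anchors = np.array([p.points[0].coords for p in self.geometry])
            self._pm_offsets = np.array([p.points[1].coords for p in self.geometry])

    # -- public properties --------------------------------------------
    @property
    def n_muscles(self) -> int:
        return len(self.muscles)

    @property
    def dof(self) -> int:
        return 2

    @property
    def max_isometric_force(self) -> np.ndarray:
        return self._fmax

    @property
    def joint_limits(self) -> np.ndarray:
        if self.is_arm:
            return self.skeleton_params.joint_limits
        return self.skeleton_params.bounds

    # -- geometry ------------------------------------------------------
    def _geometry_at(self, q):
        if self._polynomial:
            # vectorized across muscles (equivalent to
            # mg.polynomial_length_and_moment_arms on each record)
            qs, qe = q[..., 0:1], q[..., 1:2]
            lengths = self._poly_a0 + qs * self._poly_a1s + qe * self._poly_a1e \
                + qe * qe * self._poly_a2e
            ma_s = qs * 0.0 + self._poly_a1s
            ma_e = self._poly_a1e + (2.0 * self._poly_a2e) * qe
            return lengths, [ma_s, ma_e]
        if self._pm_anchors is not None:
            # straight anchor-to-point segments: length = ||q + c - a||,
            # moment arms are the unit-vector components
            dx = q[..., 0:1] + (self._pm_offsets[:, 0] - self._pm_anchors[:, 0])
            dy = q[..., 1:2] + (self._pm_offsets[:, 1] - self._pm_anchors[:, 1])
            lengths = ad.sqrt(dx * dx + dy * dy)
            return lengths, [dx / lengths, dy / lengths]
        return mg.geometric_moment_arms(self.geometry, q, self.skeleton_params)

    def _cartesian(self, joint: JointState) -> CartesianState:
        if self.is_arm:
            l1, l2 = self.skeleton_params.lengths
            pv = fused_arm_kinematics(joint.q, joint.qdot, l1, l2)
            return CartesianState(pos=pv[..., 0:2], vel=pv[..., 2:4])
        return ck.point_mass_kinematics(joint)

    def _muscle_state(self, joint: JointState, activation, lengths, mas):
        # chain rule: musculotendon velocity = sum_j MA_j * qdot_j
        vel = None
        for j in range(self.dof):
            contrib = mas[j] * joint.qdot[..., j:j + 1]
            vel = contrib if vel is None else vel + contrib
        fiber_clip_lo = 0.001  # metres; guards degenerate extreme postures
        fiber = ad.clip(lengths - self._tendon, fiber_clip_lo, None)
        lnorm = fiber / self._l0
        vnorm = vel / (self._l0 * self._vmax)
        if self.muscle_type == "relu":
            force = mm.relu_force(activation, self._fmax)
        else:
            force = fused_hill_force(
                lnorm, vnorm, activation, self._fmax, self._fl_gamma,
                self._pas_k, self._pas_eps, self._pas_slack, self._fv_af,
                self._fv_flen, self.passive_enabled)
        return mm.MuscleState(
            activation=activation,
            musculotendon_length=lengths,
            musculotendon_velocity=vel,
            fiber_length_norm=lnorm,
            fiber_velocity_norm=vnorm,
            force=force,
        )

    def _passive(self, lnorm):
        k, eps, slack = self._pas_k, self._pas_eps, self._pas_slack
        raw = (ad.exp(k * ((lnorm - slack) / eps)) - 1.0) / (np.exp(k) - 1.0)
        return ad.maximum(raw, 0.0)

    def _force_velocity(self, vnorm):
        af, flen = self._fv_af, self._fv_flen
        shortening = ad.maximum(
            (1.0 + vnorm) / (1.0 - ad.clip(vnorm, None, 0.0) / af), 0.0)
        c = ad.clip(vnorm, 0.0, None) * (2.0 + 2.0 / af) / (flen - 1.0)
        lengthening = (1.0 + c * flen) / (1.0 + c)
        return ad.where(data_of(vnorm) <= 0.0, shortening, lengthening)

    # -- reset / step --------------------------------------------------
    def reset(self, joint_position=None, batch_size: int = 1,
              rng: np.random.Generator | None = None) -> EffectorState:
        """Fresh state: zero velocities, resting activations.

        Without an explicit ``joint_position``, positions are sampled
        uniformly over the joint-limit box using ``rng``.
        """
        limits = self.joint_limits
        if joint_position is None:
            if rng is None:
                rng = np.random.default_rng()
            q = rng.uniform(limits[:, 0], limits[:, 1], size=(batch_size, 2))
        else:
            q = np.atleast_2d(np.asarray(joint_position, dtype=float))
            if np.any(q < limits[:, 0] - 1e-12) or np.any(q > limits[:, 1] + 1e-12):
                raise ValueError("requested joint position outside joint limits")
            if q.shape[0] == 1 and batch_size > 1:
                q = np.repeat(q, batch_size, axis=0)
        qdot = np.zeros_like(q)
        joint = JointState(q, qdot)
        lengths, mas = self._geometry_at(q)
        activation = np.full((q.shape[0], self.n_muscles), self.resting_activation)
        muscle = self._muscle_state(joint, activation, lengths, mas)
        return EffectorState(
            joint=joint,
            cartesian=self._cartesian(joint),
            muscle=muscle,
            moment_arms=mas,
            last_action=np.zeros((q.shape[0], self.n_muscles)),
        )

    def step(self, state: EffectorState, action, external_endpoint_force=None) -> EffectorState:
        """Advance the effector one timestep (see module docstring for
        the sub-step ordering)."""
        if data_of(action).shape[-1] != self.n_muscles:
            raise ValueError("action length must equal the number of muscles")
        dt = self.dt
        # (1) activation dynamics
        activation = fused_activation_step(action, state.muscle.activation, dt,
                                           self._tau_act, self._tau_deact)
        # (2) geometry at the current configuration: the stored state was
        # refreshed at this q on the previous step (or at reset), so its
        # lengths and moment arms are reused instead of being recomputed
        q, qdot = state.joint.q, state.joint.qdot
        lengths, mas = state.muscle.musculotendon_length, state.moment_arms
        joint = state.joint
        # (3) muscle forces
        muscle = self._muscle_state(joint, activation, lengths, mas)
        # (4) generalized forces
        tau_muscle = mg.muscle_torque(mas, muscle.force)
        if external_endpoint_force is not None:
            fx, fy = external_endpoint_force[..., 0:1], external_endpoint_force[..., 1:2]
            if self.is_arm:
                j11, j12, j21, j22 = ck.endpoint_jacobian(q, self.skeleton_params)
                ext = ad.concatenate([j11 * fx + j21 * fy, j12 * fx + j22 * fy], axis=-1)
            else:
                ext = external_endpoint_force
            tau_total = tau_muscle + ext
        else:
            tau_total = tau_muscle
        # (5) skeleton dynamics
        if self.is_arm:
            qdd = fused_two_link_dynamics(q, qdot, tau_total, self.skeleton_params)
        else:
            qdd = ck.point_mass_dynamics(joint, tau_total, self.skeleton_params)
        # (6) integrate velocities then positions
        qdot_new = ck.euler_step(qdot, qdd, dt)
        q_new = ck.euler_step(q, qdot_new, dt)
        if self.is_arm:
            limits = self.skeleton_params.joint_limits
            inside = (data_of(q_new) >= limits[:, 0]) & (data_of(q_new) <= limits[:, 1])
            q_new = ad.clip(q_new, limits[:, 0], limits[:, 1])
            qdot_new = ad.where(inside, qdot_new, 0.0)
        joint_new = JointState(q_new, qdot_new)
        # (7) refresh dependent states
        lengths_new, mas_new = self._geometry_at(q_new)
        muscle_new = self._muscle_state(joint_new, activation, lengths_new, mas_new)
        new_state = EffectorState(
            joint=joint_new,
            cartesian=self._cartesian(joint_new),
            muscle=muscle_new,
            moment_arms=mas_new,
            last_action=np.clip(data_of(action), 0.0, 1.0),
        )
        self._check_finite(new_state)
        return new_state

    @staticmethod
    def _check_finite(state: EffectorState) -> None:
        for label, value in (("joint position", state.joint.q),
                             ("joint velocity", state.joint.qdot),
                             ("muscle force", state.muscle.force)):
            if not np.all(np.isfinite(data_of(value))):
                raise ArithmeticError(f"integration failure: non-finite {label}")

    # -- bookkeeping ---------------------------------------------------
    def state_dict(self, state: EffectorState) -> dict[str, np.ndarray]:
        """Plain-numpy snapshot of all instantaneous states."""
        return {
            "joint_position": data_of(state.joint.q).copy(),
            "joint_velocity": data_of(state.joint.qdot).copy(),
            "cartesian_position": data_of(state.cartesian.pos).copy(),
            "cartesian_velocity": data_of(state.cartesian.vel).copy(),
            "activation": data_of(state.muscle.activation).copy(),
            "musculotendon_length": data_of(state.muscle.musculotendon_length).copy(),
            "musculotendon_velocity": data_of(state.muscle.musculotendon_velocity).copy(),
            "fiber_length_norm": data_of(state.muscle.fiber_length_norm).copy(),
            "force": data_of(state.muscle.force).copy(),
        }


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def relu_point_mass_24(dt: float = ck.DT) -> Effector:
    """Planar point-mass (m = 1 kg) pulled by four linear muscles
    anchored in an 'X' at (+/-2, +/-2); order: upper-right, lower-right,
    lower-left, upper-left."""
    params = PointMassParams(mass=1.0)
    anchors = [(2.0, 2.0), (2.0, -2.0), (-2.0, -2.0), (-2.0, 2.0)]
    names = ["upper_right", "lower_right", "lower_left", "upper_left"]
    paths = [
        mg.MusclePath(n, [mg.FixationPoint(0, np.array(a)), mg.FixationPoint(1, np.zeros(2))])
        for n, a in zip(names, anchors)
    ]
    # reference length ~ anchor distance from the centre keeps normalized
    # proprioceptive inputs O(1)
    ref = float(np.hypot(2.0, 2.0))
    muscles = [mm.MuscleParams(max_isometric_force=500.0, tendon_length=0.0,
                               optimal_muscle_length=ref, name=n) for n in names]
    return Effector(params, muscles, paths, muscle_type="relu", dt=dt,
                    name="ReluPointMass24")


def _arm26_muscles() -> tuple[list[mm.MuscleParams], float]:
    spec = _load_data("arm26_muscles.json")
    slack = float(spec.get("normalized_slack_length", 1.4))
    muscles = [
        mm.MuscleParams(
            max_isometric_force=rec["max_isometric_force"],
            tendon_length=rec["tendon_length"],
            optimal_muscle_length=rec["optimal_muscle_length"],
            normalized_slack_length=slack,
            name=rec["name"],
        )
        for rec in spec["muscles"]
    ]
    return muscles, slack


def rigid_tendon_arm_26(dt: float = ck.DT, passive_enabled: bool = True) -> Effector:
    """Two-joint, six-muscle arm with polynomial moment-arm approximation."""
    muscles, _ = _arm26_muscles()
    poly = [
        mg.PolynomialPathParams(a0=rec["a0"], a1s=rec["a1s"], a1e=rec["a1e"],
                                a2e=rec["a2e"], name=rec["name"])
        for rec in _load_data("arm26_moment_arm_poly.json")["muscles"]
    ]
    return Effector(TwoLinkParams(), muscles, poly, muscle_type="hill", dt=dt,
                    passive_enabled=passive_enabled, name="RigidTendonArm26")


def geometric_arm_26(dt: float = ck.DT, passive_enabled: bool = True) -> Effector:
    """Two-joint, six-muscle arm with moment arms from the declared
    muscle fixation paths (no approximation)."""
    muscles, _ = _arm26_muscles()
    paths = mg.load_muscle_paths(_load_data("arm26_paths.json")["muscles"])
    return Effector(TwoLinkParams(), muscles, paths, muscle_type="hill", dt=dt,
                    passive_enabled=passive_enabled, name="GeometricArm26")


_PRESETS = {
    "ReluPointMass24": relu_point_mass_24,
    "RigidTendonArm26": rigid_tendon_arm_26,
    "GeometricArm26": geometric_arm_26,
}


def make_effector(name: str, **kwargs) -> Effector:
    """Instantiate a preset effector by name."""
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown effector preset {name!r}; "
                         f"available: {sorted(_PRESETS)}") from None
    return factory(**kwargs)
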