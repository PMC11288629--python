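"""Task environments: delayed noisy observation assembly, trial-condition
sampling (go-cues, catch trials, mechanical perturbations), the curl
field, and the standard agent-environment step contract.

``reset(...) -> (observation, info)`` and ``step(action) ->
(observation, reward, terminated, truncated, info)``.  Reward is always
0 — learning goes through the differentiable loss — and episodes
truncate at the configured horizon.  Observations are tensors so that
gradients flow from actions back through the feedback loop.

Observation layout (fixed): ``[start x, start y, target x, target y,
go-cue] ++ delayed noisy endpoint (2) ++ delayed noisy muscle lengths
and velocities (2m)``.  The go-cue channel steps 1 -> 0 once the cue is
*perceived*, i.e. after the visual delay; the loss-side desired position
switches instantaneously at the cue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import data_of
from .effector import Effector


@dataclass
class FeedbackConfig:
    """Feedback delays (s, multiples of dt) and noise standard deviations."""

    delta_p: float = 0.02   # proprioceptive delay
    delta_v: float = 0.05   # visual delay
    sigma_h: float = 0.0    # GRU hidden noise (consumed by the policy)
    sigma_u: float = 0.0    # action noise
    sigma_p: float = 0.0    # proprioceptive noise
    sigma_v: float = 0.0    # visual noise

    def steps(self, dt: float) -> tuple[int, int]:
        for name, d in (("delta_p", self.delta_p), ("delta_v", self.delta_v)):
            if d < 0:
                raise ValueError(f"{name} must be nonnegative")
            if abs(d / dt - round(d / dt)) > 1e-9:
                raise ValueError(f"{name} must be an integer multiple of dt")
        for name in ("sigma_h", "sigma_u", "sigma_p", "sigma_v"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        return int(round(self.delta_p / dt)), int(round(self.delta_v / dt))


@dataclass
class TrialCondition:
    """A batch of trial conditions (one row per simulation).

    ``gocue_time`` is ``inf`` on catch trials; ``pert_magnitude`` is 0
    when no perturbation applies.
    """

    start_joint: np.ndarray       # (B, 2)
    target_pos: np.ndarray        # (B, 2) cartesian
    gocue_time: np.ndarray        # (B,) seconds, inf = catch
    pert_magnitude: np.ndarray    # (B,) N
    pert_direction: np.ndarray    # (B,) rad
    pert_onset: np.ndarray        # (B,) s
    pert_duration: np.ndarray     # (B,) s

    def __post_init__(self):
        self.start_joint = np.atleast_2d(np.asarray(self.start_joint, float))
        self.target_pos = np.atleast_2d(np.asarray(self.target_pos, float))
        for name in ("gocue_time", "pert_magnitude", "pert_direction",
                     "pert_onset", "pert_duration"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
        if np.any(self.pert_magnitude < 0):
            raise ValueError("perturbation magnitude must be nonnegative")

    @property
    def batch_size(self) -> int:
        return self.start_joint.shape[0]

    @property
    def is_catch(self) -> np.ndarray:
        return ~np.isfinite(self.gocue_time)

    # -- CSV round trip (exact replay) --------------------------------
    _columns = ("start_q1", "start_q2", "target_x", "target_y", "gocue_time",
                "pert_magnitude", "pert_direction", "pert_onset", "pert_duration")

    def to_csv(self, path) -> None:
        table = np.column_stack([
            self.start_joint, self.target_pos, self.gocue_time,
            self.pert_magnitude, self.pert_direction, self.pert_onset,
            self.pert_duration,
        ])
        np.savetxt(path, table, delimiter=",", header=",".join(self._columns),
                   comments="")

    @classmethod
    def from_csv(cls, path) -> "TrialCondition":
        table = np.atleast_2d(np.loadtxt(path, delimiter=",", skiprows=1))
        return cls(start_joint=table[:, 0:2], target_pos=table[:, 2:4],
                   gocue_time=table[:, 4], pert_magnitude=table[:, 5],
                   pert_direction=table[:, 6], pert_onset=table[:, 7],
                   pert_duration=table[:, 8])


def curl_field_force(endpoint_velocity, b: float):
    """Velocity-dependent curl force ``f = b * (-vy, vx)`` — always
    orthogonal to the velocity, counter-clockwise for b > 0."""
    vx = endpoint_velocity[..., 0:1]
    vy = endpoint_velocity[..., 1:2]
    return ad.concatenate([-b * vy, b * vx], axis=-1)


class Environment:
    """Base environment wrapping an :class:`Effector`.

    Subclasses override :meth:`sample_condition` to define the trial
    distribution.  ``curl_b`` switches on the curl field at the endpoint.
    """

    name = "Environment"

    def __init__(self, effector: Effector, feedback: FeedbackConfig | None = None,
                 horizon: float = 1.0, curl_b: float = 0.0):
        self.effector = effector
        self.feedback = feedback or FeedbackConfig()
        self.horizon = horizon
        self.curl_b = curl_b
        self.dt = effector.dt
        self.n_steps = int(round(horizon / self.dt))
        self._prop_steps, self._vis_steps = self.feedback.steps(self.dt)
        self._rng = np.random.default_rng()
        self._state = None

    # -- sizes ---------------------------------------------------------
    @property
    def n_muscles(self) -> int:
        return self.effector.n_muscles

    @property
    def observation_size(self) -> int:
        return 5 + 2 + 2 * self.n_muscles

    # -- condition sampling -------------------------------------------
    def sample_condition(self, batch_size: int,
                         rng: np.random.Generator) -> TrialCondition:
        raise NotImplementedError

    def _sample_uniform_joint(self, batch_size, rng):
        limits = self.effector.joint_limits
        return rng.uniform(limits[:, 0], limits[:, 1], size=(batch_size, 2))

    def _joint_to_endpoint(self, q):
        from .core_kinematics import JointState
        state = JointState(q, np.zeros_like(q))
        if self.effector.is_arm:
            from .core_kinematics import forward_kinematics
            return data_of(forward_kinematics(state, self.effector.skeleton_params).pos)
        return np.asarray(q, float)

    def _sample_perturbation(self, batch_size, rng, prob: float = 0.5,
                             catch_mask=None, duration: float = 0.1):
        """Spec of the training perturbation schedule: 100-ms pulse with
        probability ``prob``, magnitude U(0, 4) N — U(0, 8) N on catch
        trials — uniform orientation and onset."""
        occurs = rng.uniform(size=batch_size) < prob
        hi = np.where(catch_mask, 8.0, 4.0) if catch_mask is not None else 4.0
        mag = rng.uniform(0.0, hi, size=batch_size) * occurs
        direction = rng.uniform(0.0, 2 * np.pi, size=batch_size)
        onset = rng.uniform(0.0, max(self.horizon - duration, 0.0), size=batch_size)
        return mag, direction, onset, np.full(batch_size, duration)

    # -- gym-style API -------------------------------------------------
    def reset(self, conditions: TrialCondition | None = None, seed: int | None = None,
              batch_size: int | None = None):
        if seed is not None:
            self._rng = np.random.default_rng(seed)
        if conditions is None:
            conditions = self.sample_condition(batch_size, self._rng)
        self.conditions = conditions
        B = conditions.batch_size
        self.t = 0
        self._truncated = False
        state = self.effector.reset(joint_position=conditions.start_joint)
        self._state = state
        start_pos = data_of(state.cartesian.pos).copy()
        self._start_pos = start_pos
        self._gocue_step = np.where(
            conditions.is_catch, np.iinfo(np.int32).max,
            np.round(np.nan_to_num(conditions.gocue_time, posinf=0.0) / self.dt),
        ).astype(np.int64)
        self._pert_force = conditions.pert_magnitude[:, None] * np.column_stack(
            [np.cos(conditions.pert_direction), np.sin(conditions.pert_direction)])
        self._vis_buffer = [state.cartesian.pos]
        self._prop_buffer = [self._proprioception(state)]
        obs = self._make_observation()
        return obs, self._info()

    def step(self, action):
        """Apply (noisy) action, advance physics one step, return the
        delayed observation quintuple."""
        if self._state is None:
            raise RuntimeError("call reset() before step()")
        if self._truncated:
            raise RuntimeError("episode is over; call reset()")
        cfg = self.feedback
        if cfg.sigma_u > 0:
            action = action + self._rng.normal(0.0, cfg.sigma_u, data_of(action).shape)
        ext = self._external_force()
        self._state = self.effector.step(self._state, action, ext)
        self.t += 1
        self._vis_buffer.append(self._state.cartesian.pos)
        self._prop_buffer.append(self._proprioception(self._state))
        obs = self._make_observation()
        self._truncated = self.t >= self.n_steps
        return obs, 0.0, False, self._truncated, self._info()

    # -- internals -----------------------------------------------------
    def _external_force(self):
        t_now = self.t * self.dt
        c = self.conditions
        active = ((t_now >= c.pert_onset) &
                  (t_now < c.pert_onset + c.pert_duration) &
                  (c.pert_magnitude > 0))
        force = self._pert_force * active[:, None]
        if self.curl_b != 0.0:
            curl = curl_field_force(self._state.cartesian.vel, self.curl_b)
            return curl + force
        if not np.any(active):
            return None
        return force

    def _proprioception(self, state):
        l0 = self.effector._l0
        lengths = state.muscle.musculotendon_length / l0
        vels = state.muscle.musculotendon_velocity / l0
        return ad.concatenate([lengths, vels], axis=-1)

    def _delayed(self, buffer, delay_steps):
        # before t = delay the buffer returns the reset entry
        return buffer[max(self.t - delay_steps, 0)]

    def _make_observation(self):
        cfg = self.feedback
        B = self.conditions.batch_size
        perceived = (self.t >= self._gocue_step + self._vis_steps)[:, None]
        target_input = np.where(perceived, self.conditions.target_pos, self._start_pos)
        gocue_channel = np.where(perceived, 0.0, 1.0)
        vis = self._delayed(self._vis_buffer, self._vis_steps)
        if cfg.sigma_v > 0:
            vis = vis + self._rng.normal(0.0, cfg.sigma_v, (B, 2))
        prop = self._delayed(self._prop_buffer, self._prop_steps)
        if cfg.sigma_p > 0:
            prop = prop + self._rng.normal(0.0, cfg.sigma_p, data_of(prop).shape)
        task = np.concatenate([self._start_pos, target_input, gocue_channel], axis=1)
        return ad.concatenate([task, vis, prop], axis=-1)

    def desired_position(self) -> np.ndarray:
        """Instantaneous x*: start until the go-cue, target afterwards."""
        switched = (self.t >= self._gocue_step)[:, None]
        return np.where(switched, self.conditions.target_pos, self._start_pos)

    def _info(self) -> dict:
        info = self.effector.state_dict(self._state)
        info["time"] = self.t * self.dt
        info["desired_position"] = self.desired_position()
        info["goal_reached"] = np.linalg.norm(
            info["cartesian_position"] - self.conditions.target_pos, axis=-1)
        return info


class RandomReach(Environment):
    """The training distribution: uniform start/target over the joint
    space, go-cue uniform over the window, 50% catch trials, optional
    random endpoint perturbations."""

    name = "RandomReach"

    def __init__(self, effector, feedback=None, horizon: float = 0.8,
                 perturbations: bool = False, catch_prob: float = 0.5,
                 pert_prob: float = 0.5, gocue_time: float | None = None):
        super().__init__(effector, feedback, horizon)
        self.perturbations = perturbations
        self.catch_prob = catch_prob
        self.pert_prob = pert_prob
        self.gocue_time = gocue_time  # None = uniform over the window

    def sample_condition(self, batch_size, rng) -> TrialCondition:
        batch_size = batch_size or 1
        start_q = self._sample_uniform_joint(batch_size, rng)
        target = self._joint_to_endpoint(self._sample_uniform_joint(batch_size, rng))
        if self.gocue_time is None:
            gocue = rng.uniform(0.0, self.horizon, size=batch_size)
        else:
            gocue = np.full(batch_size, self.gocue_time)
        catch = rng.uniform(size=batch_size) < self.catch_prob
        gocue = np.where(catch, np.inf, gocue)
        if self.perturbations:
            mag, direction, onset, dur = self._sample_perturbation(
                batch_size, rng, self.pert_prob, catch_mask=catch)
        else:
            mag = np.zeros(batch_size)
            direction = np.zeros(batch_size)
            onset = np.zeros(batch_size)
            dur = np.zeros(batch_size)
        return TrialCondition(start_q, target, gocue, mag, direction, onset, dur)


class DelayedReach(RandomReach):
    """Reaching with a randomly timed go-cue and no catch trials."""

    name = "DelayedReach"

    def __init__(self, effector, feedback=None, horizon: float = 0.8):
        super().__init__(effector, feedback, horizon, perturbations=False,
                         catch_prob=0.0)


class CentreOutReach(Environment):
    """Centre-out reaching: fixed start posture, targets on a circle,
    fixed go-cue, no catch trials."""

    name = "CentreOutReach"

    def __init__(self, effector, feedback=None, horizon: float = 1.0,
                 n_targets: int = 8, target_distance: float = 0.10,
                 gocue_time: float = 0.1, start_joint=None, curl_b: float = 0.0,
                 catch_prob: float = 0.0):
        super().__init__(effector, feedback, horizon, curl_b=curl_b)
        self.n_targets = n_targets
        self.target_distance = target_distance
        self.gocue_time = gocue_time
        self.catch_prob = catch_prob
        if start_joint is None:
            start_joint = (np.deg2rad([45.0, 90.0]) if effector.is_arm
                           else np.zeros(2))
        self.start_joint = np.asarray(start_joint, float)

    def target_angles(self) -> np.ndarray:
        return np.arange(self.n_targets) * (2 * np.pi / self.n_targets)

    def sample_condition(self, batch_size=None, rng=None) -> TrialCondition:
        """Without a batch size: one deterministic trial per target.
        With one: targets drawn at random from the target set, with
        catch trials at ``catch_prob`` (used when training against the
        curl field)."""
        start1 = np.asarray(self.start_joint, float)[None]
        centre = self._joint_to_endpoint(start1)[0]
        ang = self.target_angles()
        all_targets = centre + self.target_distance * np.column_stack(
            [np.cos(ang), np.sin(ang)])
        if batch_size is None or (batch_size == self.n_targets
                                  and self.catch_prob == 0.0):
            n = self.n_targets
            targets = all_targets
            gocue = np.full(n, self.gocue_time)
        else:
            n = batch_size
            if rng is None:
                raise ValueError("random centre-out sampling needs an rng")
            targets = all_targets[rng.integers(0, self.n_targets, size=n)]
            catch = rng.uniform(size=n) < self.catch_prob
            gocue = np.where(catch, np.inf, self.gocue_time)
        start_q = np.tile(self.start_joint, (n, 1))
        zeros = np.zeros(n)
        return TrialCondition(start_q, targets, gocue, zeros, zeros, zeros, zeros)


class Postural(Environment):
    """Postural control: hold the start position against an endpoint
    perturbation; no go-cue is ever given."""

    name = "Postural"

    def __init__(self, effector, feedback=None, horizon: float = 0.8,
                 pert_magnitude: float = 6.0, pert_direction: float = 0.0,
                 pert_onset: float | None = None, pert_duration: float = 0.1,
                 start_joint=None):
        super().__init__(effector, feedback, horizon)
        if pert_onset is None:
            # default onset: 170 ms plus the visual delay
            pert_onset = 0.17 + (feedback.delta_v if feedback else 0.05)
        self.pert_magnitude = pert_magnitude
        self.pert_direction = pert_direction
        self.pert_onset = pert_onset
        self.pert_duration = pert_duration
        if start_joint is None:
            start_joint = (np.deg2rad([45.0, 90.0]) if effector.is_arm
                           else np.zeros(2))
        self.start_joint = np.asarray(start_joint, float)

    def sample_condition(self, batch_size=None, rng=None) -> TrialCondition:
        B = batch_size or 1
        start_q = np.tile(self.start_joint, (B, 1))
        target = self._joint_to_endpoint(start_q)
        return TrialCondition(
            start_q, target, np.full(B, np.inf), np.full(B, self.pert_magnitude),
            np.full(B, self.pert_direction), np.full(B, self.pert_onset),
            np.full(B, self.pert_duration))


_ENVIRONMENTS = {
    "RandomReach": RandomReach,
    "DelayedReach": DelayedReach,
    "CentreOutReach": CentreOutReach,
    "Postural": Postural,
}


def make_environment(name: str, effector: Effector, **kwargs) -> Environment:
    try:
        cls = _ENVIRONMENTS[name]
    except KeyError:
        raise ValueError(f"unknown environment preset {name!r}; "
                         f"available: {sorted(_ENVIRONMENTS)}") from None
    return cls(effector, **kwargs)
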