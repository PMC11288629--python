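"""Batched backpropagation-through-time training of a policy through
the differentiable environment.

Each batch samples fresh trial conditions, unrolls the policy/effector
loop over the full horizon, evaluates the loss and backpropagates
through both the network recurrence and the physics.  The optimizer,
learning rate and gradient clipping are not constrained by the modelled
protocols; community defaults (Adam, 1e-3, global-norm clip 1.0) are
used and configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, data_of
from .losses import LossConfig, total_loss
from .policy import GRUPolicy
from .tasks import Environment, TrialCondition


class Adam:
    """Plain Adam on a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def clip_global_norm(params: list[Tensor], max_norm: float) -> float:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float(np.sum(p.grad * p.grad))
    norm = float(np.sqrt(total))
    if max_norm > 0 and norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


@dataclass
class Rollout:
    """Time-major records of one batched rollout (tensors while a graph
    is alive; call :meth:`detach` for analysis-ready arrays)."""

    positions: list
    velocities: list
    desired: list
    activations: list
    actions: list
    hiddens: list  # length T + 1 (leading entry = initial hidden state)
    infos: list

    def detach(self) -> dict[str, np.ndarray]:
        return {
            "positions": np.stack([data_of(p) for p in self.positions]),
            "velocities": np.stack([data_of(v) for v in self.velocities]),
            "desired": np.stack([np.asarray(d) for d in self.desired]),
            "activations": np.stack([data_of(a) for a in self.activations]),
            "actions": np.stack([data_of(a) for a in self.actions]),
            "hiddens": np.stack([data_of(h) for h in self.hiddens[1:]]),
        }


def run_rollout(env: Environment, policy: GRUPolicy,
                conditions: TrialCondition | None = None,
                batch_size: int | None = None,
                record_info: bool = False) -> Rollout:
    """Unroll the policy through the environment for the full horizon."""
    obs, info = env.reset(conditions=conditions, batch_size=batch_size)
    B = env.conditions.batch_size
    hidden = Tensor(policy.initial_hidden(B))
    out = Rollout([], [], [], [], [], [hidden], [info] if record_info else [])
    truncated = False
    while not truncated:
        action, hidden = policy(obs, hidden)
        obs, _, _, truncated, info = env.step(action)
        out.positions.append(env._state.cartesian.pos)
        out.velocities.append(env._state.cartesian.vel)
        out.desired.append(info["desired_position"])
        out.activations.append(env._state.muscle.activation)
        out.actions.append(action)
        out.hiddens.append(hidden)
        if record_info:
            out.infos.append(info)
    return out


@dataclass
class TrainingResult:
    loss_curve: np.ndarray
    policy: GRUPolicy
    n_batches: int
    batch_size: int
    seed: int | None


def train(env: Environment, policy: GRUPolicy, loss_config: LossConfig | None = None,
          n_batches: int = 500, batch_size: int = 32, seed: int | None = None,
          lr: float = 1e-3, clip_norm: float = 1.0, lr_schedule=None,
          callback=None) -> TrainingResult:
    """Gradient-train ``policy`` on ``env``; returns the per-batch loss
    curve.  Deterministic for a fixed (env, policy, seed) triple.
    ``lr_schedule`` maps batch index -> learning-rate multiplier."""
    loss_config = loss_config or LossConfig()
    opt = Adam(policy.parameters(), lr=lr)
    fmax = env.effector.max_isometric_force
    if seed is not None:
        env._rng = np.random.default_rng(seed)
        policy._rng = np.random.default_rng(seed + 1)
    losses = np.empty(n_batches)
    for batch in range(n_batches):
        opt.zero_grad()
        roll = run_rollout(env, policy, batch_size=batch_size)
        loss = total_loss(roll.positions, roll.desired, roll.activations,
                          roll.hiddens, fmax, loss_config,
                          kernel=policy.input_kernel)
        value = float(data_of(loss))
        if not np.isfinite(value):
            raise ArithmeticError(
                f"NaN/inf loss at batch {batch}; last finite losses: "
                f"{losses[max(batch - 5, 0):batch]}")
        loss.backward()
        clip_global_norm(policy.parameters(), clip_norm)
        if lr_schedule is not None:
            opt.lr = lr * float(lr_schedule(batch))
        opt.step()
        losses[batch] = value
        if callback is not None:
            callback(batch, value)
    return TrainingResult(losses, policy, n_batches, batch_size, seed)


def save_checkpoint(policy: GRUPolicy, path, loss_curve=None, seed=None,
                    n_batches=None) -> None:
    """Flat array archive plus a JSON manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = policy.state_arrays()
    np.savez(path / "weights.npz", **arrays)
    manifest = {
        "n_units": policy.config.n_units,
        "n_inputs": policy.config.n_inputs,
        "n_outputs": policy.config.n_outputs,
        "sigma_h": policy.config.sigma_h,
        "seed": seed,
        "n_batches": n_batches,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if loss_curve is not None:
        np.savetxt(path / "loss_curve.csv", np.asarray(loss_curve),
                   header="loss", comments="")


def save_rollout(rollout: Rollout, path, fmt: str = "csv") -> None:
    """Export a rollout's state trajectories.

    ``csv`` writes one row per (step, trial) with flattened state
    columns; ``npz`` stores the time-major arrays directly.
    """
    data = rollout.detach()
    path = Path(path)
    if fmt == "npz":
        np.savez(path, **data)
        return
    if fmt != "csv":
        raise ValueError("fmt must be 'csv' or 'npz'")
    T, B = data["positions"].shape[:2]
    blocks, names = [], ["step", "trial"]
    grid = np.mgrid[0:T, 0:B].reshape(2, -1).T
    blocks.append(grid)
    for key in ("positions", "velocities", "desired", "activations", "actions"):
        arr = data[key].reshape(T * B, -1)
        blocks.append(arr)
        names += [f"{key}_{i}" for i in range(arr.shape[1])]
    np.savetxt(path, np.column_stack(blocks), delimiter=",",
               header=",".join(names), comments="")


def load_checkpoint(path) -> GRUPolicy:
    from .policy import PolicyConfig

    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    config = PolicyConfig(n_units=manifest["n_units"], n_inputs=manifest["n_inputs"],
                          n_outputs=manifest["n_outputs"],
                          sigma_h=manifest.get("sigma_h", 0.0))
    policy = GRUPolicy(config)
    with np.load(path / "weights.npz") as arrays:
        policy.load_state_arrays(arrays)
    return policy
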