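"""The training loss: a time-averaged sum of positional, muscle and
hidden-activity penalties plus a kernel-regularization term,

``L = mean_t(alpha*Lp + beta*Lm + gamma*Lh) + lambda*||W||``.

* ``Lp`` is 0 inside the target radius (L2 test) and the L1 distance
  outside it;
* ``Lm`` penalizes muscle activation weighted by muscle strength —
  the printed expression is typeset ambiguously, so both readings are
  implemented (see :func:`muscle_loss`);
* ``Lh = h'h/n + kappa * hdot'hdot/n`` penalizes hidden activity and
  its per-step temporal difference (discouraging oscillations);
* ``||W||`` is the Frobenius norm of the GRU input kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import data_of


@dataclass
class LossConfig:
    alpha: float = 2.0            # positional weight
    beta: float = 5.0             # muscle weight
    gamma: float = 0.1            # hidden-activity weight
    kappa: float = 0.05           # hidden-derivative weight
    lam: float = 1e-5             # kernel-regularization penalty
    target_radius: float = 0.01   # r (m)
    muscle_loss_mode: str = "scaled-projection"  # or "normalized-squares"

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma", "kappa", "lam", "target_radius"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.muscle_loss_mode not in ("scaled-projection", "normalized-squares"):
            raise ValueError("unknown muscle_loss_mode")


def positional_loss(x, x_star, target_radius: float = 0.01):
    """Per-trial positional penalty: 0 when the L2 distance to the
    desired position is below the target radius, L1 distance otherwise.
    Shapes (..., 2) -> (..., 1)."""
    d = x - x_star
    dist2 = ad.sqrt(ad.sum(d * d, axis=-1, keepdims=True))
    l1 = ad.sum(ad.abs(d), axis=-1, keepdims=True)
    return ad.where(data_of(dist2) < target_radius, 0.0, l1)


def muscle_loss(u, f, mode: str = "scaled-projection"):
    """Strength-weighted activation penalty, shapes (..., m) -> (..., 1).

    ``scaled-projection`` (default): ``((u.f) / ||f||_2^2)^2``.
    ``normalized-squares``: ``sum((u_i f_i)^2) / ||f||_2^2``.
    """
    f = data_of(f)
    if data_of(u).shape[-1] != f.shape[-1]:
        raise ValueError("u and f must have the same number of muscles")
    if np.any(f <= 0):
        raise ValueError("maximum isometric forces must be positive")
    fsq = float(np.sum(f * f))
    if mode == "scaled-projection":
        proj = ad.sum(u * f, axis=-1, keepdims=True) / fsq
        return proj * proj
    if mode == "normalized-squares":
        uf = u * f
        return ad.sum(uf * uf, axis=-1, keepdims=True) / fsq
    raise ValueError(f"unknown muscle loss mode {mode!r}")


def hidden_loss(h, hdot, kappa: float = 0.05):
    """``h'h/n + kappa * hdot'hdot/n`` with n the number of units;
    ``hdot`` is the per-step hidden difference. Shapes (..., n) -> (..., 1)."""
    n = data_of(h).shape[-1]
    if data_of(hdot).shape[-1] != n:
        raise ValueError("h and hdot must have the same length")
    return (ad.sum(h * h, axis=-1, keepdims=True)
            + kappa * ad.sum(hdot * hdot, axis=-1, keepdims=True)) / float(n)


def kernel_penalty(w, lam: float):
    """``lam * ||W||_F`` (Frobenius norm of the input kernel)."""
    return lam * ad.sqrt(ad.sum(w * w))


def total_loss(positions, desired, activations, hiddens, fmax, config: LossConfig,
               kernel=None):
    """Combine per-timestep records into the scalar training loss.

    Parameters are time-aligned lists (one entry per step) of tensors:
    endpoint positions, desired positions, muscle activations and hidden
    states (``hiddens`` has one extra leading entry, the pre-rollout
    hidden state, used for the first temporal difference).
    """
    T = len(positions)
    if T == 0:
        raise ValueError("empty trajectory")
    if len(hiddens) != T + 1:
        raise ValueError("hiddens must have one more entry than positions")
    # stacked time-major evaluation: identical to summing the per-step
    # terms but far fewer graph nodes
    pos = ad.stack(positions, axis=0)          # (T, B, 2)
    des = np.stack([data_of(d) for d in desired])
    act = ad.stack(activations, axis=0)        # (T, B, m)
    hid = ad.stack(hiddens, axis=0)            # (T+1, B, n)
    lp = positional_loss(pos, des, config.target_radius)
    lm = muscle_loss(act, fmax, config.muscle_loss_mode)
    h = hid[1:]
    lh = hidden_loss(h, h - hid[:-1], config.kappa)
    lt = config.alpha * lp + config.beta * lm + config.gamma * lh
    out = ad.mean(lt)  # mean over time and batch
    if kernel is not None and config.lam > 0:
        out = out + kernel_penalty(kernel, config.lam)
    return out
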