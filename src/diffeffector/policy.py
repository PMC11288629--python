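"""The recurrent policy: a single GRU layer (sigmoid gates, tanh
candidate) feeding a sigmoid output layer, one output per muscle.

Initialization: input kernels Glorot-uniform, recurrent kernels
orthogonal (one orthogonal matrix per gate), biases zero; the output
kernel is drawn N(0, 0.003^2) and its bias set to -5 so that initial
actions sit near logistic(-5) ~ 0.0067, a quiet and stable start.
Gaussian noise of standard deviation ``sigma_h`` is added to the hidden
state after each update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, data_of


@dataclass
class PolicyConfig:
    n_units: int
    n_inputs: int
    n_outputs: int
    output_bias_init: float = -5.0
    output_kernel_sd: float = 0.003
    sigma_h: float = 0.0

    def __post_init__(self):
        if min(self.n_units, self.n_inputs, self.n_outputs) < 1:
            raise ValueError("all sizes must be >= 1")


def _glorot_uniform(rng, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng, n: int) -> np.ndarray:
    a = rng.normal(size=(n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))  # sign fix for a unique, well-spread Q


class GRUPolicy:
    """One GRU layer plus sigmoid readout, on the autodiff tape.

    Parameter layout: ``wx (n_inputs, 3n)``, ``wh (n, 3n)`` and ``b
    (3n,)`` hold the reset / update / candidate blocks side by side;
    ``wo (n, m)``, ``bo (m,)`` form the output layer.
    """

    def __init__(self, config: PolicyConfig, seed: int | None = None):
        self.config = config
        rng = np.random.default_rng(seed)
        n, nin, nout = config.n_units, config.n_inputs, config.n_outputs
        wx = np.concatenate(
            [_glorot_uniform(rng, nin, n, (nin, n)) for _ in range(3)], axis=1)
        wh = np.concatenate([_orthogonal(rng, n) for _ in range(3)], axis=1)
        self.wx = Tensor(wx, requires_grad=True)
        self.wh = Tensor(wh, requires_grad=True)
        self.b = Tensor(np.zeros(3 * n), requires_grad=True)
        self.wo = Tensor(rng.normal(0.0, config.output_kernel_sd, (n, nout)),
                         requires_grad=True)
        self.bo = Tensor(np.full(nout, config.output_bias_init), requires_grad=True)
        self._rng = np.random.default_rng(None if seed is None else seed + 1)

    # -- parameters ----------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return [self.wx, self.wh, self.b, self.wo, self.bo]

    @property
    def input_kernel(self) -> Tensor:
        """The kernel weight matrix W used for regularization."""
        return self.wx

    def initial_hidden(self, batch_size: int) -> np.ndarray:
        return np.zeros((batch_size, self.config.n_units))

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {"wx": self.wx.data.copy(), "wh": self.wh.data.copy(),
                "b": self.b.data.copy(), "wo": self.wo.data.copy(),
                "bo": self.bo.data.copy()}

    def load_state_arrays(self, arrays) -> None:
        for name in ("wx", "wh", "b", "wo", "bo"):
            tensor = getattr(self, name)
            value = np.asarray(arrays[name], dtype=float)
            if value.shape != tensor.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            tensor.data = value

    # -- forward -------------------------------------------------------
    def forward(self, observation, hidden, rng: np.random.Generator | None = None):
        """One step: returns ``(action in (0,1)^m, new hidden)``.

        The gate nonlinearity runs as a fused graph node; see
        :meth:`forward_reference` for the equivalent primitive form.
        """
        from ._fastops import fused_gru_gates
        n = self.config.n_units
        xx = observation @ self.wx + self.b
        hx = hidden @ self.wh
        new_hidden = fused_gru_gates(xx, hx, hidden, n)
        if self.config.sigma_h > 0:
            rng = rng or self._rng
            new_hidden = new_hidden + rng.normal(
                0.0, self.config.sigma_h, data_of(new_hidden).shape)
        action = ad.sigmoid(new_hidden @ self.wo + self.bo)
        return action, new_hidden

    __call__ = forward

    def forward_reference(self, observation, hidden,
                          rng: np.random.Generator | None = None):
        """Primitive-op GRU step (slow path, kept as the oracle for the
        fused gate node)."""
        n = self.config.n_units
        xx = observation @ self.wx + self.b
        hx = hidden @ self.wh
        r = ad.sigmoid(xx[..., 0:n] + hx[..., 0:n])
        z = ad.sigmoid(xx[..., n:2 * n] + hx[..., n:2 * n])
        cand = ad.tanh(xx[..., 2 * n:] + r * hx[..., 2 * n:])
        new_hidden = (1.0 - z) * cand + z * hidden
        if self.config.sigma_h > 0:
            rng = rng or self._rng
            new_hidden = new_hidden + rng.normal(
                0.0, self.config.sigma_h, data_of(new_hidden).shape)
        action = ad.sigmoid(new_hidden @ self.wo + self.bo)
        return action, new_hidden
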