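"""Actuator force generation.

Two actuator families are implemented:

* a linear piecewise ("ReLu") muscle whose force is ``fmax * a`` clamped
  to ``[0, fmax]``;
* a rigid-tendon Hill-type muscle combining active force-length,
  force-velocity and passive-stretch curves scaled by maximum isometric
  force.

Both share the same first-order excitation-to-activation dynamics.  The
Hill curve constants default to the published "young subjects" values of
the classic musculotendon formalizations and can be overridden per
muscle.
All functions are differentiable through :mod:`diffeffector.autodiff`
(piecewise kinks use subgradients).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import autodiff as ad
from .autodiff import data_of


@dataclass
class MuscleParams:
    """Per-muscle constants.

    ``normalized_slack_length`` sets where the passive curve engages, in
    optimal-length units; it is a modelling choice (1.0 reproduces the
    classic curve anchored at optimal length).
    """

    max_isometric_force: float = 1.0      # fmax (N)
    tendon_length: float = 0.0            # (m), inextensible under rigid tendon
    optimal_muscle_length: float = 1.0    # l0 (m)
    normalized_slack_length: float = 1.0  # passive-curve engagement (l0 units)
    # Hill curve constants ("young subjects" defaults)
    fl_gamma: float = 0.45                # active force-length Gaussian shape
    passive_shape: float = 4.0            # passive exponential shape factor
    passive_strain: float = 0.6           # strain at which passive force = fmax
    fv_af: float = 0.25                   # force-velocity curvature
    fv_flen: float = 1.4                  # eccentric force plateau
    vmax: float = 10.0                    # max shortening velocity (l0/s)
    tau_activation: float = 0.015         # (s)
    tau_deactivation: float = 0.05        # (s)
    name: str = "muscle"

    def __post_init__(self):
        if not self.max_isometric_force > 0:
            raise ValueError("max_isometric_force must be strictly positive")
        if self.tendon_length < 0 or self.optimal_muscle_length < 0:
            raise ValueError("lengths must be nonnegative")

    def with_(self, **kwargs) -> "MuscleParams":
        return replace(self, **kwargs)


@dataclass
class MuscleState:
    """Instantaneous per-muscle quantities (batched along the lead axis)."""

    activation: object            # a in [0, 1], shape (..., m)
    musculotendon_length: object  # (m)
    musculotendon_velocity: object
    fiber_length_norm: object     # optimal-length units
    fiber_velocity_norm: object   # vmax units
    force: object                 # (N), nonnegative


# ---------------------------------------------------------------------------
# force production
# ---------------------------------------------------------------------------

def relu_force(activation, fmax):
    """Linear piecewise force: 0 below a=0, ``fmax*a`` on (0,1), ``fmax`` above."""
    if np.any(data_of(fmax) <= 0):
        raise ValueError("fmax must be strictly positive")
    return fmax * ad.clip(activation, 0.0, 1.0)


def activation_derivative(excitation, activation, params: MuscleParams | None = None,
                          scaled_time_constants: bool = True):
    """First-order approach of activation toward (clipped) excitation.

    ``da/dt = (u - a) / tau`` with the activation time constant when
    ``u > a`` and the slower deactivation constant otherwise.  With
    ``scaled_time_constants`` the constants are modulated by the current
    activation level, ``tau_act * (0.5 + 1.5 a)`` and
    ``tau_deact / (0.5 + 1.5 a)``, as in the classic musculotendon
    formalizations; turn it off for a pure linear ODE with closed-form
    solutions.
    """
    if params is None:
        params = MuscleParams()
    u = ad.clip(excitation, 0.0, 1.0)
    rising = data_of(u) > data_of(activation)
    if scaled_time_constants:
        scale = 0.5 + 1.5 * activation
        tau = ad.where(rising, params.tau_activation * scale,
                       params.tau_deactivation / scale)
    else:
        tau = np.where(rising, params.tau_activation, params.tau_deactivation)
    return (u - activation) / tau


def rigid_tendon_fiber_state(musculotendon_length, musculotendon_velocity,
                             params: MuscleParams):
    """Normalized fiber length and velocity under an inextensible tendon.

    Fiber length is ``lmt - tendon_length`` and fiber velocity equals the
    musculotendon velocity; both are normalized by the optimal length (the
    velocity additionally by the maximum shortening velocity).
    """
    if np.any(data_of(musculotendon_length) <= params.tendon_length):
        raise ValueError(
            "degenerate geometry: musculotendon length must exceed tendon length"
        )
    l0 = params.optimal_muscle_length
    lnorm = (musculotendon_length - params.tendon_length) / l0
    vnorm = musculotendon_velocity / (l0 * params.vmax)
    return lnorm, vnorm


def active_force_length(lnorm, params: MuscleParams):
    """Gaussian active force-length curve, maximal (=1) at optimal length."""
    d = lnorm - 1.0
    return ad.exp(-(d * d) / params.fl_gamma)


def passive_force_length(lnorm, params: MuscleParams):
    """Exponential passive-stretch curve; zero at or below slack length."""
    strain = (lnorm - params.normalized_slack_length) / params.passive_strain
    k = params.passive_shape
    raw = (ad.exp(k * strain) - 1.0) / (np.exp(k) - 1.0)
    return ad.maximum(raw, 0.0)


def force_velocity(vnorm, params: MuscleParams):
    """Force-velocity factor; 1 at rest, 0 at max shortening, plateaus
    at ``fv_flen`` for lengthening.  ``vnorm`` is in max-shortening-velocity
    units (shortening negative)."""
    af, flen = params.fv_af, params.fv_flen
    shortening = ad.maximum((1.0 + vnorm) / (1.0 - ad.clip(vnorm, None, 0.0) / af), 0.0)
    c = ad.clip(vnorm, 0.0, None) * (2.0 + 2.0 / af) / (flen - 1.0)
    lengthening = (1.0 + c * flen) / (1.0 + c)
    return ad.where(data_of(vnorm) <= 0.0, shortening, lengthening)


def hill_force(normalized_fiber_length, normalized_fiber_velocity, activation,
               params: MuscleParams, passive_enabled: bool = True):
    """Rigid-tendon Hill-type force:
    ``fmax * (a * FL(l) * FV(v) + FP(l))``, always nonnegative."""
    a = ad.clip(activation, 0.0, 1.0)
    fl = active_force_length(normalized_fiber_length, params)
    fv = force_velocity(normalized_fiber_velocity, params)
    active = a * fl * fv
    if passive_enabled:
        total = active + passive_force_length(normalized_fiber_length, params)
    else:
        total = active
    return params.max_isometric_force * ad.maximum(total, 0.0)
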