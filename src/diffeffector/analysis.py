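"""Analysis utilities: preferred-movement-direction (PMD) estimation
from unit activity, circular statistics, and trajectory metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PMDResult:
    """Per-unit direction-tuning summary for one network.

    ``profiles`` are |regression coefficient| values min-max normalized
    to [0, 1] per unit (max = 1); ``preferred`` holds the argmax target
    index per unit; ``histogram`` counts units per target direction.
    """

    profiles: np.ndarray      # (n_units, n_directions)
    preferred: np.ndarray     # (n_units,)
    histogram: np.ndarray     # (n_directions,)
    directions: np.ndarray    # (n_directions,) angles in rad


def compute_pmd(hidden: np.ndarray, window_start: int, window_len: int = 15,
                directions: np.ndarray | None = None) -> PMDResult:
    """PMD of each unit from per-direction hidden activity.

    Parameters
    ----------
    hidden:
        array (n_directions, T, n_units) — one trajectory per reach
        direction.
    window_start:
        first step of the averaging window (the step at which the go-cue
        reaches the network, i.e. cue time plus the visual delay).
    window_len:
        window length in steps (150 ms at dt = 0.01).

    The per-direction window means are regressed onto a one-hot (diagonal)
    direction design matrix; with one trajectory per direction the
    least-squares coefficients equal the means themselves.  Their absolute
    values are min-max normalized per unit and the argmax (ties broken by
    lowest index) gives the preferred direction.
    """
    hidden = np.asarray(hidden)
    if hidden.ndim != 3:
        raise ValueError("hidden must be (n_directions, T, n_units)")
    n_dir, T, n_units = hidden.shape
    if directions is None:
        directions = np.arange(n_dir) * (2 * np.pi / n_dir)
    if len(directions) != n_dir:
        raise ValueError("fewer trajectories than directions")
    stop = min(window_start + window_len, T)
    means = hidden[:, window_start:stop, :].mean(axis=1)  # (n_dir, n_units)
    beta = np.abs(means).T                                # (n_units, n_dir)
    lo = beta.min(axis=1, keepdims=True)
    hi = beta.max(axis=1, keepdims=True)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    profiles = (beta - lo) / span
    profiles[np.squeeze(hi - lo, axis=1) == 0] = 0.0  # flat units: all-zero profile
    preferred = np.argmax(profiles, axis=1)  # argmax returns the lowest tied index
    histogram = np.bincount(preferred, minlength=n_dir).astype(float)
    return PMDResult(profiles, preferred, histogram, np.asarray(directions))


def rayleigh_test(angles: np.ndarray, weights: np.ndarray | None = None,
                  double: bool = False) -> tuple[float, float]:
    """Rayleigh test of circular uniformity; returns ``(z, p)``.

    With ``double=True`` angles are doubled first, which makes the test
    sensitive to bimodal (axial) concentrations.  The p-value uses the
    standard Zar approximation.
    """
    angles = np.asarray(angles, dtype=float)
    if double:
        angles = 2.0 * angles
    if weights is None:
        weights = np.ones_like(angles)
    n = float(np.sum(weights))
    if n <= 0:
        raise ValueError("empty sample")
    C = float(np.sum(weights * np.cos(angles))) / n
    S = float(np.sum(weights * np.sin(angles))) / n
    rbar = np.hypot(C, S)
    z = n * rbar * rbar
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - (rbar * n) ** 2)) - (1.0 + 2.0 * n))
    return z, float(min(max(p, 0.0), 1.0))


def lateral_deviation(positions: np.ndarray, start: np.ndarray,
                      target: np.ndarray) -> float:
    """Signed maximum perpendicular deviation of a trajectory from the
    straight start-to-target line (positive = left of the movement
    direction)."""
    positions = np.asarray(positions)
    axis = np.asarray(target, float) - np.asarray(start, float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("degenerate reach axis")
    axis = axis / norm
    normal = np.array([-axis[1], axis[0]])
    dev = (positions - start) @ normal
    return float(dev[np.argmax(np.abs(dev))])


def time_to_target(positions: np.ndarray, target: np.ndarray, radius: float,
                   dt: float = 0.01) -> float:
    """First time (s) the endpoint enters and stays within ``radius`` of
    the target; inf if it never settles."""
    dist = np.linalg.norm(np.asarray(positions) - np.asarray(target), axis=-1)
    inside = dist < radius
    for t in range(len(inside)):
        if inside[t:].all():
            return t * dt
    return float("inf")
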