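"""Shape and trajectory metrics: CMI, elongation, Random Index, IEP."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "cmi",
    "elongation",
    "random_index",
    "steady_state_window",
    "iep_estimate",
    "TrajectoryMetrics",
]


def cmi(S: float, S_in: float) -> float:
    """Cell Morphological Index: current over initial membrane area."""
    if S_in <= 0:
        raise ValueError("initial membrane area must be positive")
    return S / S_in


def elongation(l_max: float, l_med: float, l_min: float) -> float:
    """1 - geometric mean of the two shorter dimensions over the longest.

    0 for a sphere, approaching 1 for a filament.
    """
    if l_max <= 0:
        raise ValueError("l_max must be positive")
    if not (l_max >= l_med >= l_min > 0):
        raise ValueError("dimensions must satisfy l_max >= l_med >= l_min > 0")
    return 1.0 - np.sqrt(l_min * l_med) / l_max


def random_index(thetas: np.ndarray) -> float:
    """Mean cosine of the polarization angle to the cue axis."""
    t = np.asarray(thetas, dtype=float)
    if t.size == 0:
        raise ValueError("empty angle window")
    return float(np.cos(t).mean())


def steady_state_window(centroid_x: np.ndarray, L: float, *, frac: float = 0.05,
                        consecutive: int = 20) -> int | None:
    """First step index from which the trajectory has settled.

    The window starts at the first step whose next ``consecutive`` values
    all stay within ``frac * L`` of the final centroid position; None when
    no such stretch exists.
    """
    x = np.asarray(centroid_x, dtype=float)
    if x.size < consecutive:
        return None
    tol = frac * L
    near = np.abs(x - x[-1]) <= tol
    run = 0
    for i in range(x.size - 1, -1, -1):
        if near[i]:
            run += 1
        else:
            return i + 1 if run >= consecutive else None
    return 0 if run >= consecutive else None


def iep_estimate(runs_centroid_x, L: float, *, frac: float = 0.05,
                 consecutive: int = 20):
    """Equilibrium-plane estimate across repeated runs.

    For each run, the tail mean of the centroid x over its steady-state
    window; across runs, (mean, standard deviation).  Runs that never
    settle are excluded (all-excluded raises).
    """
    tails = []
    excluded = 0
    for x in runs_centroid_x:
        x = np.asarray(x, dtype=float)
        start = steady_state_window(x, L, frac=frac, consecutive=consecutive)
        if start is None:
            excluded += 1
            continue
        tails.append(x[start:].mean())
    if not tails:
        raise ValueError("no run reached steady state")
    tails = np.asarray(tails)
    sd = float(tails.std(ddof=1)) if len(tails) > 1 else 0.0
    return float(tails.mean()), sd, excluded


@dataclass
class TrajectoryMetrics:
    """Per-run metric series plus the steady-state summary."""

    centroid: np.ndarray          # (n_steps, 3) um
    S: np.ndarray                 # (n_steps,) membrane area um^2
    S_in: float
    cmi: np.ndarray
    eps_elong: np.ndarray
    theta: np.ndarray             # angle of e_pol to the cue axis (rad)
    steady_start: int | None = None
    ri: float = float("nan")
    iep: float = float("nan")

    @classmethod
    def from_series(cls, centroid, S, S_in, eps_elong, theta, L,
                    frac: float = 0.05, consecutive: int = 20):
        centroid = np.asarray(centroid, dtype=float)
        S = np.asarray(S, dtype=float)
        eps_elong = np.asarray(eps_elong, dtype=float)
        theta = np.asarray(theta, dtype=float)
        m = cls(centroid=centroid, S=S, S_in=S_in, cmi=S / S_in,
                eps_elong=eps_elong, theta=theta)
        start = steady_state_window(centroid[:, 0], L, frac=frac,
                                    consecutive=consecutive)
        m.steady_start = start
        if start is not None:
            m.iep = float(centroid[start:, 0].mean())
        # alignment window: after the initial polarization transient (the
        # elongation-plateau criterion is too noisy on a coarse cell mask
        # to detect reliably, so a fixed burn-in fraction stands in)
        burn_in = max(10, len(theta) // 5)
        if len(theta) > burn_in:
            m.ri = random_index(theta[burn_in:])
        return m
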