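"""Per-step force balance and kinematics.

The traction-derived effective force (redirected by any thermal/chemical
cues), the random protrusion force and the electrical force must be
balanced by drag; the drag magnitude then sets the migration speed
through a shape-corrected Stokes relation, and its direction sets the
cell polarization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import CellDomain, remodel, select_extension_retraction
from .stimuli import StimulusWeights

__all__ = [
    "ForceBalanceState",
    "protrusion_force",
    "effective_force",
    "drag_force",
    "velocity_and_polarization",
    "displacement_matched_remodeling",
]

_FORCE_TOL = 1e-12

#: minutes of real time per simulation step
DT_MINUTES = 10.0


@dataclass
class ForceBalanceState:
    """Forces, speed and direction resolved at one step (model units)."""

    F_net_trac: np.ndarray
    F_eff: np.ndarray
    F_prot: np.ndarray
    F_EF: np.ndarray
    F_drag: np.ndarray
    v: float = 0.0                       # um/min
    e_pol: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    kappa: float = 0.0
    e_rand: np.ndarray = field(default_factory=lambda: np.zeros(3))


def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - essentially impossible
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def protrusion_force(F_net_mag: float, rng: np.random.Generator):
    """Random protrusion force: kappa * ||F_net|| * e_rand, kappa ~ U[0, 1).

    Returns (force vector, kappa, e_rand); the draws always consume the
    same number of variates so seeded runs stay reproducible.
    """
    if F_net_mag < 0:
        raise ValueError("force magnitude must be >= 0")
    kappa = float(rng.uniform(0.0, 1.0))
    e_rand = random_unit_vector(rng)
    return kappa * F_net_mag * e_rand, kappa, e_rand


def effective_force(F_net_mag: float, e_mech: np.ndarray, e_ch: np.ndarray | None,
                    e_th: np.ndarray | None, w: StimulusWeights) -> np.ndarray:
    """Multi-cue effective force.

    ``||F_net|| * (mu_mech e_mech + mu_ch e_ch + mu_th e_th)``.  The
    weight of an inactive cue (vector None) must already have been folded
    into mu_mech by the caller's weight resolution.
    """
    mu_ch = w.mu_ch if e_ch is not None else 0.0
    mu_th = w.mu_th if e_th is not None else 0.0
    mu_mech = 1.0 - mu_ch - mu_th
    if mu_mech < -1e-12:
        raise ValueError("effective factors must sum to 1")
    total = mu_mech * np.asarray(e_mech, dtype=float)
    if e_ch is not None:
        total = total + mu_ch * np.asarray(e_ch, dtype=float)
    if e_th is not None:
        total = total + mu_th * np.asarray(e_th, dtype=float)
    return F_net_mag * total


def drag_force(F_eff: np.ndarray, F_prot: np.ndarray, F_EF: np.ndarray) -> np.ndarray:
    """Drag closing the force balance: -(F_eff + F_prot + F_EF)."""
    return -(np.asarray(F_eff, float) + np.asarray(F_prot, float)
             + np.asarray(F_EF, float))


def velocity_and_polarization(F_drag: np.ndarray, f_shape: float, r: float,
                              eta: float, c_v: float = 1.0,
                              prev_e_pol: np.ndarray | None = None):
    """Speed (um/min) and polarization from the drag force.

    Stokes relation with shape correction: ``v = c_v * ||F_drag|| /
    (f_shape * 6 pi r eta)`` with F_drag in nN, r in um and eta in Pa*s;
    ``c_v`` maps model-force units onto the physical velocity scale.
    The polarization is ``-F_drag/||F_drag||``; for a vanishing drag the
    previous direction is kept and the speed is zero.
    """
    if f_shape < 1.0 - 1e-12:
        raise ValueError("shape factor must be >= 1")
    if r <= 0 or eta <= 0:
        raise ValueError("radius and viscosity must be positive")
    F = np.asarray(F_drag, dtype=float)
    mag = np.linalg.norm(F)
    if mag <= _FORCE_TOL:
        e_pol = prev_e_pol if prev_e_pol is not None else np.array([1.0, 0.0, 0.0])
        return 0.0, np.asarray(e_pol, float)
    # SI: nN -> N, um -> m; result m/s -> um/min
    v_ms = c_v * (mag * 1e-9) / (f_shape * 6.0 * np.pi * (r * 1e-6) * eta)
    return v_ms * 6e7, -F / mag


def displacement_matched_remodeling(cell: CellDomain, v: float, dt: float,
                                    e_pol: np.ndarray, n_swap_max: int = 10,
                                    carry: float = 0.0):
    """Swap extension/retraction pairs until the centroid has advanced v*dt.

    Each swap moves the centroid by (x_ex - x_re)/N_cell; swaps continue
    while the accumulated displacement projected on ``e_pol`` is below
    the target, up to the hard cap ``n_swap_max``.  ``carry`` holds the
    displacement owed from previous steps, so speeds below one swap per
    step advance the cell at the correct average rate instead of being
    rounded up to a full element swap.  Returns (number of swaps,
    displacement vector, new carry); a jammed cell records zero swaps.
    """
    if v < 0:
        raise ValueError("speed must be >= 0")
    target = carry + v * dt
    moved = np.zeros(3)
    advanced = 0.0
    swaps = 0
    # only swap when at least ~half a typical single-swap displacement is
    # owed; the remainder carries over to the next step
    h = (cell.mesh.hx + cell.mesh.hy + cell.mesh.hz) / 3.0
    swap_scale = 2.0 * cell.r / max(cell.n_cell, 1)
    added: set[int] = set()
    removed: set[int] = set()
    while target - advanced >= 0.5 * swap_scale and swaps < n_swap_max:
        # tabu sets prevent a step from undoing its own swaps (cycling in
        # place when the pseudopod budget pins the shape)
        pair = select_extension_retraction(cell, e_pol,
                                           forbidden_ex=removed,
                                           forbidden_re=added)
        if pair is None:
            break
        disp = remodel(cell, *pair)
        added.add(pair[0])
        removed.add(pair[1])
        moved += disp
        advanced += max(float(disp @ e_pol), 0.1 * swap_scale)
        swaps += 1
    new_carry = float(np.clip(target - advanced, 0.0, h))
    return swaps, moved, new_carry
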