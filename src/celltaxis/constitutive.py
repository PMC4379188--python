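"""Active/passive cell stress law, adhesivity and traction forces.

The cell transmits contractile stress to the substrate through membrane
nodes.  The stress carried by a membrane node is a piecewise function of
the directional strain sensed at that node: outside the active strain
window only the passive elements (membrane, microtubules) load, inside it
the actin-myosin machinery adds an active contribution that peaks at the
strain ``eps_tilde = sigma_max / K_act``.

Internal unit system: micrometre, kilopascal, nanonewton (1 kPa * um^2 ==
1 nN).  One simulation step corresponds to 10 minutes of real time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellMechanicalParams",
    "MechanoState",
    "DegeneratePolarization",
    "active_passive_stress",
    "adhesivity",
    "nodal_traction",
    "net_traction",
    "mechanotactic_direction",
]

#: forces below this magnitude (nN, model units) give no usable direction
POLARIZATION_TOL = 1e-12


class DegeneratePolarization(ValueError):
    """Raised when a net force is too small to define a direction."""


@dataclass(frozen=True)
class CellMechanicalParams:
    """Constitutive and adhesion constants of the cell.

    Defaults are the reference parameter set used throughout the
    simulator (stiffnesses in kPa, strains dimensionless, binding
    constant per mol, ligand concentration in mol, radius in um).
    """

    K_pas: float = 2.8
    K_act: float = 2.0
    sigma_max: float = 0.1
    eps_min: float = -0.09
    eps_max: float = 0.09
    k_f: float = 1e8
    k_b: float = 1e8
    n_f: float = 1e5
    n_b: float = 1e5
    psi: float = 1e-5
    r: float = 20.0
    nu: float = 0.3

    def __post_init__(self) -> None:
        if not (self.eps_min < 0.0 < self.eps_max):
            raise ValueError("strain bounds must satisfy eps_min < 0 < eps_max")
        if self.sigma_max <= 0.0 or self.K_act <= 0.0:
            raise ValueError("sigma_max and K_act must be positive")
        if self.K_pas < 0.0:
            raise ValueError("K_pas must be non-negative")
        if not (self.eps_min <= self.eps_tilde <= self.eps_max):
            raise ValueError("sigma_max/K_act must lie within [eps_min, eps_max]")
        if self.r <= 0.0:
            raise ValueError("cell radius must be positive")

    @property
    def eps_tilde(self) -> float:
        """Strain at which the active stress saturates, sigma_max / K_act."""
        return self.sigma_max / self.K_act

    @property
    def zeta_front(self) -> float:
        return adhesivity(self.k_f, self.n_f, self.psi)

    @property
    def zeta_rear(self) -> float:
        return adhesivity(self.k_b, self.n_b, self.psi)


@dataclass
class MechanoState:
    """Per-step mechanosensing result at the membrane nodes."""

    node_ids: np.ndarray            # (n,) global node indices on the membrane
    eps_tensors: np.ndarray         # (n, 3, 3) nodal strain tensors
    e_i: np.ndarray                 # (n, 3) unit vectors node -> centroid
    eps_cell: np.ndarray            # (n,) directional strains
    sigma: np.ndarray               # (n,) nodal stresses (kPa)
    tractions: np.ndarray           # (n, 3) nodal traction forces (nN)
    F_net_trac: np.ndarray = field(default_factory=lambda: np.zeros(3))
    e_mech: np.ndarray | None = None


def active_passive_stress(
    eps_cell: float | np.ndarray, params: CellMechanicalParams
) -> float | np.ndarray:
    """Mean contractile stress (kPa) carried at a membrane node.

    Piecewise in the directional strain ``eps_cell``:

    * purely passive, ``K_pas * eps``, outside ``[eps_min, eps_max]``;
    * passive plus an active branch rising from ``eps_min`` to the
      saturation strain ``eps_tilde``;
    * passive plus an active branch falling from ``eps_tilde`` to
      ``eps_max``.

    The three branches are continuous at the breakpoints.
    """
    eps = np.asarray(eps_cell, dtype=float)
    if not np.all(np.isfinite(eps)):
        raise ValueError("eps_cell must be finite")

    Kp, Ka, sm = params.K_pas, params.K_act, params.sigma_max
    emin, emax = params.eps_min, params.eps_max
    et = params.eps_tilde

    passive = Kp * eps
    rising = Ka * sm * (emin - eps) / (Ka * emin - sm) + passive
    falling = Ka * sm * (emax - eps) / (Ka * emax - sm) + passive

    out = np.where(
        (eps < emin) | (eps > emax),
        passive,
        np.where(eps <= et, rising, falling),
    )
    if np.isscalar(eps_cell) or np.ndim(eps_cell) == 0:
        return float(out)
    return out


def adhesivity(k: float, n_r: float, psi: float) -> float:
    """Dimensionless adhesivity: binding constant x receptors x ligands."""
    if k < 0 or n_r < 0 or psi < 0:
        raise ValueError("adhesivity factors must be non-negative")
    return k * n_r * psi


def nodal_traction(
    sigma_i: float, S_node: float, zeta: float, e_i: np.ndarray
) -> np.ndarray:
    """Traction force (nN) exerted at one membrane node.

    ``sigma_i * S_node * zeta * e_i`` where ``e_i`` is the unit vector
    from the node towards the cell centroid and ``S_node`` the tributary
    membrane area of the node (um^2).
    """
    e = np.asarray(e_i, dtype=float)
    nrm = np.linalg.norm(e)
    if nrm < 1e-12:
        raise ValueError("e_i must be a non-zero unit vector")
    if abs(nrm - 1.0) > 1e-6:
        raise ValueError("e_i must have unit norm")
    if S_node <= 0:
        raise ValueError("S_node must be positive")
    return sigma_i * S_node * zeta * e


def net_traction(tractions) -> np.ndarray:
    """Net traction on the whole cell: minus the sum of nodal tractions."""
    arr = np.asarray(tractions, dtype=float)
    if arr.size == 0:
        raise ValueError("at least one nodal traction is required")
    arr = arr.reshape(-1, 3)
    return -arr.sum(axis=0)


def mechanotactic_direction(F_net: np.ndarray, tol: float = POLARIZATION_TOL) -> np.ndarray:
    """Unit vector of mechanotactic reorientation, F_net / ||F_net||.

    Raises :class:`DegeneratePolarization` when the force magnitude is
    below ``tol``; the caller is expected to keep its previous direction.
    """
    F = np.asarray(F_net, dtype=float)
    nrm = np.linalg.norm(F)
    if nrm <= tol:
        raise DegeneratePolarization(f"net force magnitude {nrm} below {tol}")
    return F / nrm
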