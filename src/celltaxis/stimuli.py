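"""Environmental cue fields: stiffness, temperature, chemoattractant, dcEF.

All guidance fields used in the reference scenarios are linear in x, but
the abstraction accepts any differentiable scalar map.  The direct-current
electric field (dcEF) exerts a body force on the charged cell; thermal and
chemical gradients only redirect the traction-derived effective force.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "LinearField",
    "ElectricField",
    "StimulusField",
    "StimulusWeights",
    "InactiveCue",
    "effective_viscosity",
    "cue_unit_vector",
    "surface_charge",
    "electric_force",
]

_GRAD_TOL = 1e-300


class InactiveCue(ValueError):
    """Raised when a cue has no gradient (or is not configured)."""


@dataclass(frozen=True)
class LinearField:
    """Scalar field linear in x: value(x) = v0 + (vL - v0) * x / Lx."""

    v0: float
    vL: float
    Lx: float

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        pos = np.asarray(x, dtype=float)
        xc = pos[..., 0] if pos.ndim else pos
        return self.v0 + (self.vL - self.v0) * xc / self.Lx

    def gradient(self, x=None) -> np.ndarray:
        return np.array([(self.vL - self.v0) / self.Lx, 0.0, 0.0])


@dataclass(frozen=True)
class ElectricField:
    """Uniform dcEF: strength E (mV/mm == V/m), direction and polarity."""

    strength: float
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    polarity: str = "cathode"  # cathode- or anode-seeking cell

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ValueError("dcEF strength must be >= 0")
        if self.polarity not in ("cathode", "anode"):
            raise ValueError("polarity must be 'cathode' or 'anode'")
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("dcEF direction must be a unit vector")

    @property
    def e_EF(self) -> np.ndarray:
        """Unit vector the cell is attracted along (toward cathode or anode)."""
        d = np.asarray(self.direction, dtype=float)
        return d if self.polarity == "cathode" else -d


@dataclass
class StimulusField:
    """Bundle of substrate cue fields and their material couplings.

    stiffness maps position (um) to Young's modulus (kPa); temperature
    (deg C) and chemoattractant (M) are optional scalar fields; ef is the
    optional dcEF.  eta_min (Pa*s) and lam (Pa*s per kPa) define the
    effective viscosity; omega_satur (C/m^2) and e_satur (mV/mm) the
    surface-charge saturation law.
    """

    stiffness: Callable[[np.ndarray], float]
    temperature: LinearField | None = None
    chemo: LinearField | None = None
    ef: ElectricField | None = None
    eta_min: float = 1000.0
    lam: float = 0.0
    omega_satur: float = 1e-4
    e_satur: float = 100.0
    ef_velocity_saturation: bool = False

    def __post_init__(self) -> None:
        if self.e_satur <= 0:
            raise ValueError("e_satur must be positive")
        if self.omega_satur < 0:
            raise ValueError("omega_satur must be non-negative")

    def viscosity_at(self, x: np.ndarray) -> float:
        return effective_viscosity(float(np.asarray(self.stiffness(x))), self.eta_min, self.lam)


@dataclass(frozen=True)
class StimulusWeights:
    """Effective factors of the mechanotactic, chemotactic and thermotactic cues.

    Each lies in [0, 1] and they sum to one; the mechanotactic weight is
    the remainder of the configured chemical and thermal weights.
    """

    mu_ch: float = 0.0
    mu_th: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu_ch <= 1.0 and 0.0 <= self.mu_th <= 1.0):
            raise ValueError("weights must lie in [0, 1]")
        if self.mu_ch + self.mu_th > 1.0 + 1e-12:
            raise ValueError("mu_ch + mu_th must not exceed 1")

    @property
    def mu_mech(self) -> float:
        return 1.0 - self.mu_ch - self.mu_th


def effective_viscosity(E_sub: float, eta_min: float, lam: float) -> float:
    """Effective medium viscosity (Pa*s): eta_min + lam * E_sub."""
    if E_sub <= 0:
        raise ValueError("substrate stiffness must be positive")
    return eta_min + lam * E_sub


def cue_unit_vector(fld, x) -> np.ndarray:
    """Unit vector along the gradient of a cue field at position x.

    Raises :class:`InactiveCue` for an unset field or a zero gradient;
    the caller folds that cue's weight back into mechanotaxis.
    """
    if fld is None:
        raise InactiveCue("cue field not configured")
    g = np.asarray(fld.gradient(x), dtype=float)
    nrm = np.linalg.norm(g)
    if nrm <= _GRAD_TOL:
        raise InactiveCue("cue field has zero gradient")
    return g / nrm


def surface_charge(E: float, omega_satur: float, e_satur: float) -> float:
    """Cell surface charge density (C/m^2), linear in E up to saturation."""
    if E < 0:
        raise ValueError("dcEF strength must be >= 0")
    if E <= e_satur:
        return omega_satur * E / e_satur
    return omega_satur


def electric_force(E: float, S: float, fld: StimulusField) -> np.ndarray:
    """Electrical force (newtons) on a cell of membrane area S (um^2).

    F = E * Omega(E) * S * e_EF with E in mV/mm (== V/m) and S converted
    to m^2.  With ``ef_velocity_saturation`` the product E * Omega(E) is
    clamped at its saturation value so that the migration speed stops
    growing above e_satur.
    """
    if fld.ef is None or E == 0.0:
        return np.zeros(3)
    if S <= 0:
        raise ValueError("membrane area must be positive")
    omega = surface_charge(E, fld.omega_satur, fld.e_satur)
    e_omega = E * omega
    if fld.ef_velocity_saturation:
        e_omega = min(e_omega, fld.e_satur * fld.omega_satur)
    S_m2 = S * 1e-12
    return e_omega * S_m2 * fld.ef.e_EF
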