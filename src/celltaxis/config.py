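"""Simulation configuration: validation, YAML loading, scenario presets.

All lengths in um, stiffness in kPa, viscosity in Pa*s, dcEF strength in
mV/mm, time in minutes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .constitutive import CellMechanicalParams
from .fem import HexMesh
from .stimuli import ElectricField, LinearField, StimulusField, StimulusWeights

__all__ = ["SimulationConfig", "load_config", "scenario_config", "SCENARIOS"]

_MESH_SCALES = {
    "coarse": (40, 20, 20),   # 10 um elements, desk scale
    "paper": (80, 40, 40),    # 5 um elements, 128,000 elements
}


@dataclass
class SimulationConfig:
    """Validated bundle of everything one run needs."""

    # substrate box and mesh
    Lx: float = 400.0
    Ly: float = 200.0
    Lz: float = 200.0
    mesh_scale: str = "coarse"
    nx: int | None = None
    ny: int | None = None
    nz: int | None = None
    # stiffness gradient endpoints (kPa at x=0 and x=Lx)
    stiffness_kPa_at_x0: float = 1.0
    stiffness_kPa_at_xL: float = 100.0
    # optional thermal / chemical gradients
    temperature_C_at_x0: float | None = None
    temperature_C_at_xL: float | None = None
    chemo_M_at_x0: float | None = None
    chemo_M_at_xL: float | None = None
    # optional dcEF
    ef_strength_mV_per_mm: float = 0.0
    ef_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    ef_polarity: str = "cathode"
    ef_velocity_saturation: bool = False
    # effective factors (mu_mech is the remainder)
    mu_ch: float = 0.0
    mu_th: float = 0.0
    # substrate / charge couplings
    eta_min: float = 1000.0
    lam: float = 0.0
    omega_satur: float = 1e-4
    e_satur: float = 100.0
    # cell
    cell_params: CellMechanicalParams = field(default_factory=CellMechanicalParams)
    cell_center: tuple[float, float, float] = (60.0, 100.0, 100.0)
    # sensing solve
    E_cell: float | None = None    # None: cell keeps the local substrate modulus
    F_sens: float | None = None    # None: calibrated so min eps_cell = eps_min at t=0
    sensing_recalibrate: bool = True   # rescale probing each step (strain homeostasis)
    differential_sensing: bool = True  # subtract same-shape homogeneous reference
    sensing_pad: float = 30.0
    use_window: bool = True
    cg_rtol: float = 1e-6
    # kinematics
    c_v: float | None = None       # None: calibrated from the t=0 net traction
    v_ref: float = 1.6             # um/min speed anchor for the c_v calibration
    ef_force_ratio: float = 0.5    # ||F_EF|| at 10 mV/mm relative to ||F_net(0)||
    n_swap_max: int = 10
    kappa_zero: bool = False       # force kappa = 0 (deterministic runs)
    # stepping
    n_steps: int = 200
    dt: float = 10.0
    # campaign / io
    seed: int = 0
    n_runs: int = 10
    vtk_every: int = 0
    out_dir: str = "celltaxis_out"

    def __post_init__(self) -> None:
        if self.mesh_scale not in _MESH_SCALES and None in (self.nx, self.ny, self.nz):
            raise ValueError(
                f"mesh_scale must be one of {sorted(_MESH_SCALES)} "
                "or explicit nx/ny/nz given"
            )
        if self.nx is None:
            self.nx, self.ny, self.nz = _MESH_SCALES[self.mesh_scale]
        if self.stiffness_kPa_at_x0 <= 0 or self.stiffness_kPa_at_xL <= 0:
            raise ValueError("substrate stiffness must be positive everywhere")
        if (self.temperature_C_at_x0 is None) != (self.temperature_C_at_xL is None):
            raise ValueError("temperature endpoints must be given together")
        if (self.chemo_M_at_x0 is None) != (self.chemo_M_at_xL is None):
            raise ValueError("chemoattractant endpoints must be given together")
        # weight validity (raises on violation)
        StimulusWeights(mu_ch=self.mu_ch, mu_th=self.mu_th)
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    # ---- factories ----------------------------------------------------
    def build_mesh(self) -> HexMesh:
        return HexMesh(self.Lx, self.Ly, self.Lz, self.nx, self.ny, self.nz)

    def build_stimuli(self) -> StimulusField:
        temp = chemo = ef = None
        if self.temperature_C_at_x0 is not None:
            temp = LinearField(self.temperature_C_at_x0, self.temperature_C_at_xL,
                               self.Lx)
        if self.chemo_M_at_x0 is not None:
            chemo = LinearField(self.chemo_M_at_x0, self.chemo_M_at_xL, self.Lx)
        if self.ef_strength_mV_per_mm > 0:
            ef = ElectricField(self.ef_strength_mV_per_mm, self.ef_direction,
                               self.ef_polarity)
        return StimulusField(
            stiffness=LinearField(self.stiffness_kPa_at_x0,
                                  self.stiffness_kPa_at_xL, self.Lx),
            temperature=temp, chemo=chemo, ef=ef,
            eta_min=self.eta_min, lam=self.lam,
            omega_satur=self.omega_satur, e_satur=self.e_satur,
            ef_velocity_saturation=self.ef_velocity_saturation,
        )

    def weights(self) -> StimulusWeights:
        return StimulusWeights(mu_ch=self.mu_ch, mu_th=self.mu_th)

    def substrate_E(self, mesh: HexMesh) -> np.ndarray:
        fld = LinearField(self.stiffness_kPa_at_x0, self.stiffness_kPa_at_xL, self.Lx)
        return np.asarray(fld(mesh.element_centroids), dtype=float)

    # ---- (de)serialization --------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cell_params"] = dataclasses.asdict(self.cell_params)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        cp = d.pop("cell_params", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("cell_center", "ef_direction"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        if cp is not None:
            cfg.cell_params = CellMechanicalParams(**cp)
        return cfg


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimulationConfig.from_dict(data)


def scenario_config(name: str, **overrides) -> SimulationConfig:
    """One of the reference scenarios, optionally overridden."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    d = dict(SCENARIOS[name])
    d.update(overrides)
    return SimulationConfig.from_dict(d)


#: the four example families: stiffness gradient 1 -> 100 kPa over 400 um,
#: plus optionally a thermal gradient, a chemoattractant gradient or a dcEF
SCENARIOS: dict[str, dict] = {
    "mechanotaxis": {},
    "thermotaxis": {
        "temperature_C_at_x0": 36.0, "temperature_C_at_xL": 39.0, "mu_th": 0.2,
    },
    "chemotaxis_035": {
        "chemo_M_at_x0": 0.0, "chemo_M_at_xL": 5e-5, "mu_ch": 0.35,
    },
    "chemotaxis_040": {
        "chemo_M_at_x0": 0.0, "chemo_M_at_xL": 5e-5, "mu_ch": 0.4,
    },
    "electrotaxis_10": {"ef_strength_mV_per_mm": 10.0},
    "electrotaxis_100": {"ef_strength_mV_per_mm": 100.0},
}
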