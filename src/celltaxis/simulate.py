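"""Simulation loop and multi-run campaigns.

Each step: mechano-sensing solve -> directional strains -> stress law ->
nodal tractions -> net traction and mechanotactic direction -> cue
vectors -> effective force -> random protrusion -> electrical force ->
drag/velocity/polarization -> front/rear partition -> extension/
retraction remodeling.  Identical (config, seed) pairs give identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import constitutive as con
from . import metrics as met
from . import motion as mot
from .config import SimulationConfig
from .fem import SensingSolver
from .geometry import (
    CellDomain,
    init_spherical_cell,
    principal_dimensions,
    pseudopod_fraction,
    shape_factor,
)
from .stimuli import InactiveCue, cue_unit_vector, electric_force

log = logging.getLogger("celltaxis")

__all__ = ["StepRecord", "RunResult", "run_simulation", "run_campaign",
           "write_outputs"]


@dataclass
class StepRecord:
    """One row of the trajectory table (units in the column docs)."""

    step: int
    x: float                 # centroid (um)
    y: float
    z: float
    v: float                 # speed (um/min)
    e_pol_x: float
    e_pol_y: float
    e_pol_z: float
    F_net: float             # force magnitudes (model units)
    F_eff: float
    F_prot: float
    F_EF: float
    F_drag: float
    S: float                 # membrane area (um^2)
    cmi: float
    eps_elong: float
    theta: float             # angle of e_pol to the cue axis (rad)
    swaps: int
    no_remodel: bool


@dataclass
class RunResult:
    config: SimulationConfig
    records: list[StepRecord]
    metrics: met.TrajectoryMetrics
    cell: CellDomain
    calibration: dict = field(default_factory=dict)

    def trajectory_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])


def _smooth_over_faces(values, face_nodes, n_passes=2):
    """Jacobi smoothing of a per-face field over node-sharing neighbours.

    Removes single-element lumps from the sensed strain field (the
    membrane's surface roughness) while leaving the cell-scale
    front-to-rear asymmetry — the actual guidance signal — intact.
    """
    n_faces = len(face_nodes)
    node_to_faces: dict[int, list[int]] = {}
    for f, nodes in enumerate(face_nodes):
        for nid in nodes:
            node_to_faces.setdefault(int(nid), []).append(f)
    out = np.asarray(values, dtype=float)
    for _ in range(n_passes):
        acc = out.copy()
        cnt = np.ones(n_faces)
        for flist in node_to_faces.values():
            if len(flist) < 2:
                continue
            s = out[flist].sum()
            for f in flist:
                acc[f] += (s - out[f]) / (len(flist) - 1) * ((len(flist) - 1)
                                                             / len(flist))
                cnt[f] += (len(flist) - 1) / len(flist)
        out = acc / cnt
    return out


def _face_directional_strains(cell, eps_elems):
    """Per-face normal strain from the owning element's centroid tensor."""
    face_nodes, face_normals, _, owners = cell.faces
    eps_stack = np.stack([eps_elems[int(e)] for e in owners])
    return np.einsum("fi,fij,fj->f", face_normals, eps_stack, face_normals)


def _environment_strains(cell, eps_elems, eps_ref):
    """Sensed strains with the cell's own shape response subtracted.

    The reference solve shares shape and loads but lives in a homogeneous
    clamped medium, so the difference isolates the micro-environmental
    asymmetry (stiffness gradient, free surfaces); the reference's mean
    level restores the absolute contraction amplitude the stress law
    expects.
    """
    ec = _face_directional_strains(cell, eps_elems)
    ec_ref = _face_directional_strains(cell, eps_ref)
    return ec - ec_ref + ec_ref.mean()


def _membrane_face_state(mesh, cell, eps_elems, e_pol, params, strain_scale=1.0,
                         smooth_passes=2, ec_face=None):
    """Directional strains, stresses and net traction over membrane faces.

    Each exposed face takes the centroid strain tensor of its owning cell
    element; the directional strain is evaluated along the face normal
    (the compression direction the membrane senses) and smoothed over
    neighbouring faces.  Tractions are integrated face-wise with the
    front/rear adhesivity split by ``e_pol``; a uniform stress integrates
    to exactly zero net force.  ``ec_face`` overrides the raw directional
    strains (differential-sensing path).
    """
    face_nodes, face_normals, face_areas, owners = cell.faces
    if ec_face is None:
        ec_face = _face_directional_strains(cell, eps_elems)
    ec_face = strain_scale * ec_face
    if smooth_passes:
        ec_face = _smooth_over_faces(ec_face, face_nodes, smooth_passes)
    sigma_face = con.active_passive_stress(ec_face, params)
    face_centers = mesh.node_coords[face_nodes].mean(axis=1)
    delta = (face_centers - cell.centroid) @ e_pol
    zeta = np.where(delta >= 0, params.zeta_front, params.zeta_rear)
    # traction on the substrate points toward the centroid (inward)
    tractions = -(sigma_face * face_areas * zeta)[:, None] * face_normals
    return ec_face, sigma_face, con.net_traction(tractions)


def _resolve_cues(stim, weights, x):
    """Active cue unit vectors; inactive cue weights fold into mechanotaxis."""
    try:
        e_ch = cue_unit_vector(stim.chemo, x) if weights.mu_ch > 0 else None
    except InactiveCue:
        e_ch = None
    try:
        e_th = cue_unit_vector(stim.temperature, x) if weights.mu_th > 0 else None
    except InactiveCue:
        e_th = None
    return e_ch, e_th


def run_simulation(config: SimulationConfig, seed=None) -> RunResult:
    """Execute one seeded run and return trajectory plus metrics."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    mesh = config.build_mesh()
    stim = config.build_stimuli()
    weights = config.weights()
    params = config.cell_params
    substrate_E = config.substrate_E(mesh)
    solver = SensingSolver(mesh, substrate_E, nu=params.nu, E_cell=config.E_cell,
                           pad=config.sensing_pad, use_window=config.use_window,
                           cg_rtol=config.cg_rtol, loading="pressure")
    cell = init_spherical_cell(mesh, config.cell_center, params.r)
    S_in = cell.S
    cue_axis = np.array([1.0, 0.0, 0.0])
    if stim.ef is not None:
        cue_axis = stim.ef.e_EF

    # initial polarization: seeded random direction (no force history yet)
    e_pol = mot.random_unit_vector(rng)
    e_mech_prev = e_pol.copy()

    # --- t=0 calibrations (all deterministic) --------------------------
    differential = config.differential_sensing and config.use_window

    def sense(current_cell):
        """One sensing solve; returns the raw per-face directional strains."""
        el = np.array(sorted(current_cell.elements))
        if differential:
            _, eps_el, eps_ref = solver.solve_membrane_strains(
                el, current_cell.membrane_node_ids, current_cell.e_i, 1.0,
                element_strains_too=True, reference_too=True)
            return _environment_strains(current_cell, eps_el, eps_ref)
        _, eps_el = solver.solve_membrane_strains(
            el, current_cell.membrane_node_ids, current_cell.e_i, 1.0,
            element_strains_too=True)
        return _face_directional_strains(current_cell, eps_el)

    ec_unit = sense(cell)
    if config.F_sens is not None:
        F_sens = config.F_sens
    else:
        if ec_unit.min() >= 0:
            raise RuntimeError("sensing calibration failed: no contraction sensed")
        F_sens = params.eps_min / ec_unit.min()
    _, _, F_net0_vec = _membrane_face_state(mesh, cell, None, e_pol, params,
                                            strain_scale=F_sens,
                                            ec_face=ec_unit)
    F_net0 = float(np.linalg.norm(F_net0_vec))
    if F_net0 <= 0:
        raise RuntimeError("degenerate initial net traction")
    f_shape0 = shape_factor(*principal_dimensions(cell))
    eta0 = stim.viscosity_at(cell.centroid)
    if config.c_v is not None:
        c_v = config.c_v
    else:
        v_raw = (F_net0 * 1e-9) / (f_shape0 * 6 * np.pi * (params.r * 1e-6) * eta0) * 6e7
        c_v = config.v_ref / v_raw
    ef_scale = 0.0
    if stim.ef is not None:
        # model-force units per newton, anchored so that a 10 mV/mm field
        # exerts ef_force_ratio x the initial net traction
        F_ref = np.linalg.norm(electric_force(10.0, S_in, stim))
        if F_ref > 0:
            ef_scale = config.ef_force_ratio * F_net0 / F_ref
    calibration = {"F_sens": float(F_sens), "c_v": float(c_v),
                   "F_net0": F_net0, "ef_scale": float(ef_scale)}

    records: list[StepRecord] = []
    carry = 0.0
    for step in range(config.n_steps):
        centroid = cell.centroid
        elems = np.array(sorted(cell.elements))
        n_memb = len(cell.membrane_node_ids)
        e_i = cell.e_i

        # 1-5: sensing solve, face directional strains, stress law and
        # face-integrated tractions (partition by previous e_pol).  With
        # strain homeostasis the probing amplitude is rescaled each step
        # so the deepest sensed strain stays at eps_min regardless of
        # local stiffness; otherwise the t=0 amplitude is kept.
        ec_raw = sense(cell)
        if config.sensing_recalibrate and ec_raw.min() < 0:
            scale = params.eps_min / ec_raw.min()
        else:
            scale = F_sens
        eps_cell, sigma, F_net = _membrane_face_state(
            mesh, cell, None, e_pol, params, strain_scale=scale, ec_face=ec_raw)
        F_net_mag = float(np.linalg.norm(F_net))

        # 6: mechanotactic direction (keep previous when degenerate)
        try:
            e_mech = con.mechanotactic_direction(F_net)
            e_mech_prev = e_mech
        except con.DegeneratePolarization:
            e_mech = e_mech_prev

        # 7-8: cue vectors and effective force
        e_ch, e_th = _resolve_cues(stim, weights, centroid)
        F_eff = mot.effective_force(F_net_mag, e_mech, e_ch, e_th, weights)

        # 9: random protrusion (always drawn; kappa optionally forced to 0)
        F_prot, kappa, e_rand = mot.protrusion_force(F_net_mag, rng)
        if config.kappa_zero:
            F_prot = np.zeros(3)
            kappa = 0.0

        # 10: electrical force (SI newtons scaled into model units)
        if stim.ef is not None:
            F_EF = electric_force(stim.ef.strength, cell.S, stim) * ef_scale
        else:
            F_EF = np.zeros(3)

        # 11: drag, velocity, polarization
        F_drag = mot.drag_force(F_eff, F_prot, F_EF)
        l_max, l_med, l_min = principal_dimensions(cell)
        f_shape = shape_factor(l_max, l_med, l_min)
        eta = stim.viscosity_at(centroid)
        v, e_pol = mot.velocity_and_polarization(F_drag, f_shape, params.r, eta,
                                                 c_v=c_v, prev_e_pol=e_pol)

        # 12-13: remodel toward e_pol
        swaps, _, carry = mot.displacement_matched_remodeling(
            cell, v, config.dt, e_pol, n_swap_max=config.n_swap_max, carry=carry)

        # 14: metrics
        l_max, l_med, l_min = principal_dimensions(cell)
        new_centroid = cell.centroid
        theta = float(np.arccos(np.clip(e_pol @ cue_axis, -1.0, 1.0)))
        records.append(StepRecord(
            step=step, x=new_centroid[0], y=new_centroid[1], z=new_centroid[2],
            v=v, e_pol_x=e_pol[0], e_pol_y=e_pol[1], e_pol_z=e_pol[2],
            F_net=F_net_mag, F_eff=float(np.linalg.norm(F_eff)),
            F_prot=float(np.linalg.norm(F_prot)), F_EF=float(np.linalg.norm(F_EF)),
            F_drag=float(np.linalg.norm(F_drag)), S=cell.S,
            cmi=met.cmi(cell.S, S_in),
            eps_elong=met.elongation(l_max, l_med, l_min),
            theta=theta, swaps=swaps, no_remodel=(swaps == 0 and v > 0),
        ))
        if pseudopod_fraction(cell) > 0.10 + 1e-9:  # pragma: no cover
            raise RuntimeError(f"pseudopod cap violated at step {step}")
        log.info("step %d: x=%.1f v=%.3f cmi=%.3f elong=%.3f",
                 step, new_centroid[0], v, records[-1].cmi, records[-1].eps_elong)

    frame = pd.DataFrame([r.__dict__ for r in records])
    m = met.TrajectoryMetrics.from_series(
        centroid=frame[["x", "y", "z"]].to_numpy(),
        S=frame["S"].to_numpy(), S_in=S_in,
        eps_elong=frame["eps_elong"].to_numpy(),
        theta=frame["theta"].to_numpy(), L=config.Lx)
    return RunResult(config=config, records=records, metrics=m, cell=cell,
                     calibration=calibration)


def run_campaign(conditions: dict[str, SimulationConfig], n_runs: int | None = None,
                 base_seed: int | None = None) -> pd.DataFrame:
    """Repeat each condition n_runs times and summarize.

    Returns one row per condition: IEP mean and sd (um), mean RI, max
    elongation, max CMI, number of settled runs.
    """
    if not conditions:
        raise ValueError("campaign needs at least one condition")
    rows = []
    for name, cfg in conditions.items():
        k = n_runs if n_runs is not None else cfg.n_runs
        seed0 = base_seed if base_seed is not None else cfg.seed
        runs = []
        failures = 0
        for i in range(k):
            try:
                runs.append(run_simulation(cfg, seed=[seed0, i]))
            except Exception:
                log.exception("run %d of condition %s failed", i, name)
                failures += 1
        if not runs:
            rows.append({"condition": name, "n_runs": 0, "failures": failures})
            continue
        xs = [r.metrics.centroid[:, 0] for r in runs]
        try:
            iep_mean, iep_sd, excluded = met.iep_estimate(xs, cfg.Lx)
        except ValueError:  # no run settled (e.g. short smoke campaigns)
            iep_mean, iep_sd, excluded = float("nan"), float("nan"), len(runs)
        ris = [r.metrics.ri for r in runs if np.isfinite(r.metrics.ri)]
        rows.append({
            "condition": name,
            "n_runs": len(runs),
            "failures": failures,
            "iep_mean": iep_mean,
            "iep_sd": iep_sd,
            "runs_excluded": excluded,
            "mean_ri": float(np.mean(ris)) if ris else float("nan"),
            "max_elong": float(np.max([r.metrics.eps_elong.max() for r in runs])),
            "max_cmi": float(np.max([r.metrics.cmi.max() for r in runs])),
        })
    return pd.DataFrame(rows)


def _config_hash(cfg: SimulationConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()


def write_outputs(result: RunResult, out_dir: str | Path,
                  vtk_every: int = 0) -> dict[str, Path]:
    """Write trajectory.csv, metrics.csv, summary.json and a config echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    traj = result.trajectory_frame()
    paths["trajectory"] = out / "trajectory.csv"
    traj.to_csv(paths["trajectory"], index=False)

    m = result.metrics
    mf = pd.DataFrame({
        "step": np.arange(len(m.S)),
        "x_um": m.centroid[:, 0], "y_um": m.centroid[:, 1],
        "z_um": m.centroid[:, 2],
        "S_um2": m.S, "cmi": m.cmi, "eps_elong": m.eps_elong,
        "theta_rad": m.theta,
    })
    paths["metrics"] = out / "metrics.csv"
    mf.to_csv(paths["metrics"], index=False)

    summary = {
        "steady_start": m.steady_start,
        "ri": None if not np.isfinite(m.ri) else m.ri,
        "iep_um": None if not np.isfinite(m.iep) else m.iep,
        "max_elong": float(m.eps_elong.max()),
        "max_cmi": float(m.cmi.max()),
        "S_in_um2": m.S_in,
        "calibration": result.calibration,
        "config_sha256": _config_hash(result.config),
    }
    paths["summary"] = out / "summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=2))

    cfg_echo = result.config.to_dict()
    paths["config"] = out / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg_echo, fh)

    if vtk_every:
        from .vtkio import write_vtk_state
        mesh = result.config.build_mesh()
        E = result.config.substrate_E(mesh)
        paths["vtk"] = out / "final_state.vtk"
        write_vtk_state(paths["vtk"], mesh, E, result.cell.elements)
    return paths
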