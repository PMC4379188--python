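# celltaxis

A 3D single-cell migration simulator. A cell, represented as a connected set
of hexahedral elements embedded in an elastic substrate, probes its
micro-environment mechanically each step, converts the sensed deformation
into membrane tractions through an active/passive stress law, combines the
resulting mechanotactic pull with optional thermotactic, chemotactic and
electrotactic cues into a force balance, and migrates by discrete
extension/retraction remodeling of its element set. Per run it reports the
cell trajectory, membrane area (CMI), elongation, polarization alignment
(Random Index) and the equilibrium position of the centroid.

## Layout

| module | role |
|---|---|
| `celltaxis.constitutive` | active+passive stress law, adhesivity, tractions |
| `celltaxis.stimuli` | stiffness/temperature/chemoattractant fields, dcEF, surface charge, electric force |
| `celltaxis.fem` | trilinear-hex linear elasticity, windowed mechano-sensing solver |
| `celltaxis.geometry` | voxel cell domain, membrane, front/rear split, remodeling, shape measures |
| `celltaxis.motion` | protrusion force, effective multi-cue force, drag, velocity, polarization |
| `celltaxis.metrics` | CMI, elongation, Random Index, equilibrium-position estimate |
| `celltaxis.config` / `celltaxis.simulate` / `celltaxis.cli` | configuration, per-step loop, campaigns, outputs, CLI |
| `celltaxis.vtkio` | minimal legacy-ASCII VTK writer/reader |

Units: µm, kPa, nN (1 kPa·µm² = 1 nN), Pa·s, mV/mm; one step = 10 min.

## CLI

```bash
# one seeded run of a built-in scenario (coarse 40x20x20 mesh by default)
celltaxis simulate --scenario mechanotaxis --seed 1 --out out/

# YAML config instead of a preset; paper-scale mesh; VTK snapshot
celltaxis simulate --config cfg.yaml --mesh-scale paper --vtk-every 1 --out out/

# multi-condition campaign (10 repeats each) and summary table
celltaxis campaign --grid grid.yaml --runs 10 --seed 0 --out out/

# recompute metrics from a written trajectory
celltaxis metrics --trajectory out/trajectory.csv
```

Built-in scenarios (`--scenario`): `mechanotaxis` (1→100 kPa over 400 µm),
`thermotaxis` (+36→39 °C, µ_th=0.2), `chemotaxis_035` / `chemotaxis_040`
(0→5e-5 M, µ_ch=0.35/0.4), `electrotaxis_10` / `electrotaxis_100`
(10/100 mV/mm, cathode-seeking). A grid file maps condition names to either a
scenario name or a config mapping.

Outputs per run: `trajectory.csv` (per-step centroid, speed, polarization,
force magnitudes, membrane area, CMI, elongation, swap count),
`metrics.csv`, `summary.json` (steady-state window, RI, equilibrium x,
maxima, calibration constants, config hash), `config.yaml` echo, optional
`final_state.vtk`.

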