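# callusim

A desk-scale digital twin of long-bone fracture healing under
intramedullary nailing.

`callusim` builds an idealized voxel model of a fractured tibia or femur,
solves small-strain linear elasticity for the daily peak load on a
structured hexahedral grid, evolves the callus tissue composition
(lamellar bone, woven bone, fibrocartilage, fibrous tissue) and a
vascularity field through fuzzy mechano-regulation rules, and classifies
the outcome as **union** or **non-union** by searching for mineralized
cortical bridges in four periosteal quadrants. A full 240-day course at
1.5 mm resolution runs in a few minutes on one CPU core.

## Quick start

```bash
# run a bundled scenario (stabilized transverse tibial shaft fracture)
callusim simulate "$(python -c 'import callusim; print(callusim.bundled_config_path("tibia_shaft"))')" --out runs/tibia

# weight-bearing sweep of the devascularized femoral wedge scenario
callusim sweep "$(python -c 'import callusim; print(callusim.bundled_config_path("femur_wedge_devascularized"))')" --levels 1.0,0.1,0.05 --out runs/sweep

# render a snapshot as a simulated radiograph
callusim render runs/tibia/snapshots/day_040.vtk --axis ap
```

or from Python:

```python
import callusim as cs

cfg = cs.load_bundled_config("tibia_shaft")
result = cs.run(cfg, out_dir="runs/tibia")
print(result.outcome, result.consolidation_day)
```

Every run writes a self-contained artifact directory: `config.yaml`
(sufficient to reproduce the run bit-identically), `daily.csv` (per-day
bridging flags, gap strain, interfragmentary motion, angulation, bone and
vascularity summaries), `report.json`, VTK legacy ASCII field snapshots,
PNG projection images, and `run.log`.

## Bundled scenarios

| name | description |
| --- | --- |
| `tibia_shaft` | transverse tibial shaft fracture, 2 mm gap, 10 mm nail, full weight-bearing; heals by callus bridging |
| `tibia_shaft_destabilized` | same geometry with a 100x softer nail; hypertrophic-style non-union with growing angulation |
| `femur_wedge` | comminuted femoral wedge fracture, vascularized interposed fragment, full weight-bearing; heals |
| `femur_wedge_devascularized` | same wedge with an avascular fragment at 10% partial weight-bearing; atrophic non-union, the fragment progressively resorbs |

## Package layout

- `callusim.config` — typed, validated configuration (scenario geometry,
  material table, fuzzy rule constants, output options), YAML round-trip,
  content digest, bundled scenario loader.
- `callusim.geometry` — voxelization of the fractured, nailed diaphysis
  (transverse / oblique / wedge fracture kinds), quadrant partition,
  boundary patches, initial tissue state.
- `callusim.fem` — voxel-hexahedral linear elasticity: assembly, direct or
  lagged-LU-preconditioned CG solves, centroid strains and their
  distortional/dilatational invariants, physiological load cases.
- `callusim.fuzzy` — trapezoidal membership functions for the strain
  stimuli (partition of unity by construction).
- `callusim.dynamics` — daily tissue-fraction update rules and the
  vascular front propagation; `step_day` couples mechanics and biology.
- `callusim.bridging` — quadrant-wise cortical bridge detection
  (connected-component path search), union/non-union classification,
  interfragmentary metrics.
- `callusim.runner` / `callusim.cli` — artifact-writing driver,
  weight-bearing sweeps, `callusim` command-line interface.
- `callusim.render` / `callusim.vtkio` — simulated radiographs and VTK
  structured-points I/O.

## Verification

`tests/test_acceptance.py` contains one test per acceptance criterion
(finite-element oracles, flood-fill equivalence of the bridging detector,
240-day conservation, the four behavioral scenarios, fixation-stiffness
monotonicity, artifact determinism); `pytest` runs the full suite.
`python scripts/acceptance.py --out results.json` reproduces all
verification quantities in one JSON report.

See `docs/methods.md` for the model description, parameter tables, and
numerical design notes.
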