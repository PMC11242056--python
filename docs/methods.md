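# Methods

`callusim` simulates secondary fracture healing of a nailed long-bone
diaphysis as a daily loop of three coupled sub-models on a structured
voxel grid:

1. **Mechanics** — small-strain linear elasticity under the daily peak
   load, giving per-cell strain invariants.
2. **Fuzzy mechano-regulation** — membership functions translate the
   strain invariants into graded stimuli that activate tissue
   differentiation rules.
3. **Tissue dynamics** — explicit daily update of four tissue fractions
   and a vascularity field per cell.

Outcome classification (union vs non-union) is a connectivity search for
mineralized bridges across the fracture, evaluated daily in four
periosteal quadrants.

All lengths are mm, forces N, moduli MPa, time steps one day.

## 1. Scenario geometry

The bone is an idealized circular diaphysis segment, voxelized on a
regular hexahedral grid (default 1.5 mm). Concentric regions by radius:
intramedullary nail, nail–canal interface annulus, cancellous wall,
cortical wall; a periosteal callus annulus (default 1.4x the outer
diameter) around the fracture zone and the interface cells at gap level
form the *healing domain*, where tissue composition evolves.

Fracture kinds:

- **transverse** — a planar gap of `gap_width` centred mid-segment;
  fragments 0 (proximal) and 1 (distal).
- **oblique** — the same, on an inclined plane.
- **wedge** — a comminuted band of `wedge_height`: an interposed
  butterfly fragment (fragment 2) spanning `wedge_span` degrees, the rest
  of the band plus a gap layer above and below replaced by soft tissue.

The nail–canal clearance is resolved at voxel scale (one-voxel annulus by
default), so the interface modulus genuinely controls how much load the
nail path carries; see "Load-sharing calibration" below.

Cross-sections are partitioned into anterior / posterior / medial /
lateral quadrants by azimuth. The distal face is fixed; loads enter
through proximal surface patches.

Initial state: intact bone is lamellar with vascularity 1; the healing
domain is fibrous tissue with vascularity 0 (revascularized from the
surrounding bone during the run). A scenario can mark fragment 2 as
devascularized (vascularity 0, and it participates in the atrophy rule's
scope). Optional small initial-composition noise is seeded; by default
runs contain no randomness at all.

## 2. Voxel finite elements

Each in-body voxel is a trilinear 8-node hexahedron. The element
stiffness is assembled from two precomputed geometric matrices,
`K_e = lambda*K_L + mu*K_M` (Lamé parameters from the per-cell mixture
modulus and a uniform Poisson ratio 0.3), so daily reassembly is a single
weighted `bincount` over a fixed sparsity pattern. Per-cell modulus is a
volume-fraction mixture of the phase moduli (linear by default, exponent
configurable):

| phase / material | E (MPa) |
| --- | --- |
| lamellar bone | 10000 |
| woven bone | 4000 |
| fibrocartilage | 10 |
| fibrous tissue / granulation | 3 |
| nail (titanium-like) | 110000 |
| nail–canal interface | 30 in the bundled scenarios (see calibration) |

Strains are evaluated at cell centroids. Two invariants drive the
biology: the octahedral (distortional) shear strain and the volumetric
(dilatational) strain.

**Solver.** The reduced system is SPD. Small systems use a sparse LU
directly. Larger systems use conjugate gradients preconditioned with a
*lagged* exact LU factorization: the factorization of an earlier day's
matrix is reused as a preconditioner as long as CG converges quickly
(refresh when the iteration count exceeds 25 or CG stalls). Because the
day-to-day stiffness changes slowly and the residual is always verified
against the requested tolerance (1e-8 relative), staleness can cost
iterations but never accuracy. The previous day's solution seeds CG.

**Load cases.** Daily peak joint loads, applied axially and scaled by
the weight-bearing fraction:

- tibia: 2.2x body weight, split 55% / 45% over medial / lateral
  proximal plateau patches;
- femur: 2.38x body weight as a single proximal resultant.

## 3. Fuzzy stimuli

Trapezoidal membership functions with 0.5 crossings at the band edges
(shoulder width 20% of the edge value) partition the distortional strain
axis into understimulated / low / moderate / high / excessive bands and
the dilatational axis into compressive / neutral / tensile. The
distortional edges (dimensionless strain):

| band edge | value |
| --- | --- |
| minimum effective strain | 5e-4 |
| low → moderate | 0.05 |
| moderate → high | 0.15 |
| high → excessive (tissue destruction) | 0.30 |
| angiogenesis strain limit | 0.06 |
| compression threshold (dilatational) | -0.002 |

The five distortional memberships sum to one everywhere by construction.

## 4. Tissue dynamics

Per-cell state: fractions of lamellar bone, woven bone, fibrocartilage,
fibrous tissue (summing to one) plus vascularity in [0, 1]. Six rules
move mass between phases each day, scaled by rule activation (Mamdani
min/max combination of memberships) and per-day rate constants:

| rule | transfer | activation | rate/day |
| --- | --- | --- | --- |
| R1 intramembranous ossification | fibrous → woven | low AND vascular | 0.03 |
| R2 chondrogenesis | fibrous → cartilage | moderate AND compressive | 0.05 |
| R3 endochondral ossification | cartilage → woven | (low OR moderate) AND vascular | 0.04 |
| R4 remodeling | woven → lamellar | low OR understimulated | 0.02 |
| R5 atrophy / resorption | woven, lamellar → fibrous | understimulated | 0.01 |
| R6 destruction | woven, cartilage, lamellar → fibrous | excessive | 0.10 |

"Vascular" means vascularity ≥ 0.5. R5 applies only in the healing
domain and on an interposed (fragment 2) butterfly fragment — the intact
far-field cortex of the main fragments does not resorb, which keeps the
atrophy rule focused on mechanically shielded callus and fragments.
Outflows per source phase are capped so fractions stay in [0, 1]; the
update conserves the fraction sum to round-off.

Vascularity advances as a front: each evolving cell gains
`v_rate/voxel * max(face-neighbour vascularity)` per day (0.3 mm/day),
damped by excessive-strain membership, blocked entirely above the
angiogenesis strain limit, and never decreases.

## 5. Bridging and outcome

A quadrant is *bridged* on a day when a 6-connected path of cells with
lamellar fraction ≥ 0.5 runs from proximal-fragment cortex to
distal-fragment cortex within that quadrant's bone and healing cells
(connected-component labelling). **Union** = at least three of four
quadrants bridged simultaneously on some day within the horizon (default
240 days); the first such day is the consolidation day. Otherwise:
**non-union**.

Daily interfragmentary metrics: peak distortional strain over the gap,
mean relative displacement of the fragments' gap faces, and angulation —
the transverse component of the relative rigid-body rotation between the
two main fragments, each fitted to the displacement field by least
squares.

## 6. Load-sharing calibration of the bundled scenarios

The bundled scenario dimensions and the interface modulus are the
package's own choices, fixed by a day-0 mechanical analysis rather than
by iterating on outcomes:

- The healed-construct gap strain `F / (A_cortical * E_lamellar + nail
  path)` must stay above the understimulation shoulder (~5e-4), so a
  healing trajectory never stalls in the resorption band after
  ossification begins.
- Any bridging path must cross the high-strain layer: the bundled
  scenarios use a *single-voxel* periosteal callus shell (callus
  diameter = outer diameter + 2 voxels) instead of the library default
  1.4x ring. A thick ring contains mechanically shielded outer cells
  whose strain is set by the ring radius rather than by fixation
  stiffness, and such cells can ossify and bridge around an unstable
  gap. The binding quantity per quadrant is the *minimum* distortional
  strain over the crossing cells of its worst axial layer — a path can
  route through any cell below the angiogenesis limit, including the
  nail-shielded interface annulus.
- The day-0 gap strain of the stabilized tibia must sit in the low
  (ossification) band; with the bundled interface modulus of 30 MPa the
  worst-layer minimum strain in every quadrant is 0.038–0.047 — open for
  ossification, comfortably below the angiogenesis limit of 0.06.
- Dividing the nail modulus by 100 (destabilized variant) must close
  every quadrant: the worst-layer minimum rises to 0.068–0.113, above
  the angiogenesis limit, so no crossing path can vascularize and the
  run is a mechanically sustained non-union with rising angulation.
  This only works with the load-sharing above — at an interface modulus
  of 100 MPa the nail path keeps shielded sub-limit corridors open.
- Because the cancellous wall is lamellar bone at full modulus, intact
  wall stiffness is set by the canal diameter, not the cortical
  thickness. The femoral wedge therefore uses a wide canal (14 mm) and a
  slim nail (8 mm) so that the healed-construct strain floor at full
  weight-bearing (~6e-4) clears the understimulation shoulder and the
  comminuted zone heals, while at 5–10% weight-bearing the entire
  healing domain and the avascular fragment are understimulated
  (atrophic non-union; the devascularized fragment can never ossify
  because woven-bone formation requires vascularity, so it strictly
  resorbs).

## 7. Determinism and artifacts

Geometry, initial state (without noise) and the daily update are fully
deterministic; CSV floats are written with a fixed format, and the JSON
report contains no wall-clock fields, so identical configurations yield
byte-identical `daily.csv`, `report.json` and `config.yaml`. The config
snapshot embeds every parameter and a content digest.

## 8. Limitations

- Idealized circular cross-sections; no patient-specific (CT-derived)
  geometry, no muscle forces, no bending/torsion load components.
- Linear elasticity with a coarse voxel mesh; strain concentrations at
  material discontinuities are mesh-dependent.
- The fuzzy rule set is a deliberately compact six-rule system; rate
  constants are plausible but not individually validated.
- One load case per day (peak load); no load history within a day.
- The nail-bone interaction is a linear-elastic interface annulus, not a
  contact model.
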