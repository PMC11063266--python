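# Methods

## The decision model

The package treats approach selection for the inferior clivus as a
minimum-cost route problem on a corridor graph.  Anatomy enters as a voxel
label map over eight tissue classes; the corridor system enters as
declarative data: windows (landmark triples — triangular apertures), paths
(landmark quadruples — tetrahedral corridor segments with designated entry
and exit faces) and plans (face-adjacent path chains from the entry window
to the clival target window).

For each path the tissue content of its tetrahedron is counted by
voxel-center inclusion and condensed into

* **injury risk** — the sum over tissue classes of volume × risk
  coefficient (weighted mm³),
* **surgical freedom** — the free-space volume (mm³),
* **weight** — injury risk minus surgical freedom.

The optimal plan minimizes the sum of path weights.  Because a roomy
corridor has negative weight, Dijkstra's algorithm in its classical form is
inapplicable; the search is instead single-source relaxation in topological
order over the window-node / path-edge DAG, which is exact for arbitrary
edge signs.  The contract preserved is "minimum sum of weights", and an
exhaustive route enumerator is kept alongside both as a tested oracle and
as the ranking backend.  Exact ties resolve to the lexicographically
smallest path-id sequence during relaxation and to the lexicographically
smallest plan id among equal-total plans.

Approach labelling is geometric: the superior (+z, RAS) coordinate of every
path-tetrahedron centroid is compared with the jugular-tubercle landmark.
All centroids below `tubercle − δ` → ITA; all above `tubercle + δ` → STA;
anything straddling or within the band → TTA.  The band half-width δ
defaults to 2 mm (about two voxels at default resolution: centroids within
discretization reach of the tubercle plane should not force a side) and is
configurable.

## The default corridor topology

The default topology is data (`data/default_topology.yaml`, `schema: 1`),
designed to the documented combinatorial frame of the corridor system — 11
landmarks, 17 windows, 12 paths, 7 plans — as a layered DAG of
face-adjacent tetrahedra from a single posterolateral entry window (`abc`)
to a single clival target window (`ijk`).  Adjacent corridor segments share
a triangular face, so consecutive windows along a route differ in exactly
one landmark; the route enumeration over the 12 retained segments yields
exactly the 7 declared plans.  Three are the named approaches: `ita` runs
below the tubercle via the condylar margin (`d`), `tta` crosses the
tubercle apex (`f`) and traverses the segment `cfij`, `sta` climbs over the
tubercle toward the upper clival face.  The remaining four are hybrid
routes that mix the infra- and trans-tubercle segments.

Of the 17 windows, 9 are the junction faces of the retained segments; the
other 8 are candidate apertures enumerated from the same landmarks whose
pairings were rejected during corridor curation (blocked by bone or
neurovascular tissue).  Two landmarks (`g`, the hypoglossal canal; `h`, the
jugular bulb dome) appear only in such apertures — they mark structures the
retained corridors avoid.  A replacement topology (for example one derived
from a different corridor inventory) can be dropped in as YAML without code
changes; validation is total, with located errors for dangling references,
non-face entry/exit windows, non-adjacent plan steps and cyclic graphs.

## Risk coefficients

Free space is 0 by definition.  The default table ranks classes by the
severity of the structure's consideration in surgical planning: brainstem 5
(retraction carries respiratory/circulatory risk), artery 4 and cranial
nerve 4 (ischemia; palsies of CN VI–XII), vein 3 (troublesome bleeding),
cerebellum 2 (retraction should be minor), bone 1 (drilling is
time-consuming and can destabilise the occipitoatlantal joint), other 1.
All values are overridable via YAML, and every report records the table
used.  Risk and freedom are kept on one scale (mm³ and weighted mm³) so the
subtraction is well defined; no normalization is applied by default.

## The synthetic phantom

`generate_phantom` builds a desk-scale stand-in for the retro-condylar
region on a 96 mm cube at 1 mm isotropic resolution (the smallest grid on
which 1–3 mm vessels survive voxelization; any shape/spacing may be
requested and structures scale with the physical extent).  Structures are
analytic primitives — ellipsoids, capsule tubes along polyline centerlines,
half-space slabs — rasterised by voxel-center inclusion and painted in a
fixed precedence order (bone > artery > vein > nerve > brain > space), so
overlaps resolve deterministically.  The inventory: skull-base floor,
petrous roof, lateral and clival walls, occipital condyle with a jugular
process, jugular tubercle, foramen magnum rim, medulla rising into the
pons, cerebellar hemisphere with tonsil and biventral lobule, vertebral
artery with PICA and AICA, sigmoid sinus descending through the jugular
bulb, inferior petrosal sinus, and thin cranial-nerve tubes (VI through
XII).

Variation parameters, with defaults:

| parameter          | unit | default | meaning                                  |
|--------------------|------|---------|------------------------------------------|
| `va_radius_mm`     | mm   | 2.0     | vertebral-artery caliber (0.8 ≈ hypoplastic, ≥3.5 ≈ grossly dilated) |
| `sinus_dominance`  | –    | 0.5     | sigmoid–jugular caliber, 0 (non-dominant) to 1 (dominant) |
| `cn11_height_mm`   | mm   | 6.0     | superior offset of the CN XI bundle      |
| `tubercle_size_mm` | mm   | 7.0     | jugular-tubercle semi-axis scale         |
| `condyle_size_mm`  | mm   | 10.0    | condyle semi-axis scale                  |
| `jitter_mm`        | mm   | 1.0     | s.d. of seeded Gaussian landmark jitter  |
| `seed`             | –    | 0       | RNG seed; output is bit-reproducible     |

Landmark placements are documented constants (`DEFAULT_LANDMARK_FRACTIONS`)
at parametric anatomical loci, jittered per subject.  The vertebral artery
is routed through the infra-tubercle corridors (its deep course ascends
through the `acdj`/`acij`/`cijk` segments), the sigmoid–jugular system
through the supra-tubercle corridors, and the tubercle sits inside the
trans-tubercle segments — this is what gives the planner its qualitative
sensitivity structure: a hypoplastic artery favours ITA, a dilated artery
pushes the winner to the trans-tubercle exit, and the venous side decides
between TTA (dominant sinus) and STA (non-dominant sinus).

What the phantom is *not*: it has no partial-volume boundaries, no CSF or
dural compartments (unmodelled tissue is free space), no mass lesions or
tissue deformation, no left/right pairing, and its "free space" fraction is
far higher than in a real posterior fossa.  Tests passing on phantoms
demonstrate the machinery (volumetry, weighting, search, classification,
sensitivity) — they do not certify the frequencies or flip points of real
patient anatomy.

## Cohort simulation

`simulate_cohort` draws per-subject phantom parameters from a
`VariationDistribution`: vertebral-artery caliber as a mixture of a
hypoplasia mass point (probability 0.15, radius 0.8 mm) and a truncated
normal (mean 2.1, s.d. 1.0, range 0.5–4.5 mm — a tail heavy enough that
gross dilatation actually occurs in a 50-subject draw); sinus dominance ~
Beta(2.5, 1.5) (dominant-side drainage is the common pattern); CN XI
height, tubercle and condyle sizes as truncated normals.  Per-subject RNG
streams derive from `(master seed, subject index)`, so extending a cohort
never reshuffles earlier subjects.  The bundled distribution was calibrated
once against the qualitative screening pattern — ITA modal, TTA second, STA
rare but present — and then frozen with master seed 7 as a regression
surface; with n = 50 it yields ITA 39 / TTA 7 / STA 4.  The winner of each
subject is tabulated by its geometric ITA/TTA/STA label (the winning
*route* is often one of the hybrid plans whose corridor still runs
infra-tubercle).

## Numerical conventions

* Voxel-center inclusion (not partial-volume weighting) defines tetrahedron
  membership: exact conservation (per-class volumes sum to voxel volume ×
  included centers) and a clean Monte-Carlo cross-check.  Boundary points
  count as inside via an ε-tolerant barycentric test (ε = 1e−9), so shared
  faces of adjacent segments double-count a voxel layer; accepted because
  all plans are scored under the same convention.
* Degenerate (coplanar) tetrahedra contribute zero volumes rather than
  erroring; the point-membership predicate alone rejects them.
* When the voxel count is compared against Monte-Carlo integration (10⁵
  uniform points, classified by nearest voxel), the comparison's standard
  error combines the binomial sampling term with a voxelization term sized
  by the boundary-shell voxel count of the class (the voxel-center estimate
  differs from the exact intersection only in a one-voxel shell around the
  tetra surface); agreement is required within 3 combined standard errors.
* Fisher's exact test uses the "sum of small p" two-sided convention with
  log-space accumulation of hypergeometric point probabilities (no overflow
  or underflow-to-zero for large margins); mid-p and doubling conventions
  differ and are not offered.
* Spearman's rho is the Pearson correlation of average ranks (ties
  averaged); its confidence interval uses the Fisher z-transform with
  s.e. 1/√(n−3) and is tagged `fisher-z` so it is never silently compared
  with intervals from other constructions (e.g. bootstrap).  For the
  deposited trainee data the pairing unit (per-session vs per-trainee) is
  ambiguous; the ingest script therefore requires an explicit column
  mapping and reports n.
* Reports serialise with sorted keys and 6-decimal floats; identical inputs
  produce byte-identical JSON.

## Design choices and limitations

The topology's incidence structure and the coefficient values are design
choices within a documented combinatorial and ordinal frame, not
measurements; both are data files meant to be replaced as better inventories
become available.  The weight model intrinsically rewards longer chains
(each segment subtracts its free space), which is why corridor curation and
realistic tissue density matter; no per-plan length penalty is applied.
Biomechanical stress tolerance of tissues, lesion-specific deformation, and
acquisition/segmentation of real imaging are out of scope.  Sensitivity
conclusions from the phantom are qualitative: the existence and direction
of flips, not their millimetre location.
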