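# Methods

`ly6orient` post-processes molecular-dynamics trajectories of a single
GPI-anchored three-finger (Ly6/uPAR-type) protein above a planar lipid
bilayer. This note records the model, the conventions, the numerical choices
and what the synthetic tests do and do not demonstrate.

## State description: (Z, α, β)

A GPI-anchored protein above a planar membrane has a translational symmetry
in x/y and a rotational symmetry about the membrane normal. The package
therefore reduces each frame to three parameters:

* **Z (nm)** — the mass-weighted centre of mass of the protein's *amino-acid*
  atoms (glycans and the GPI anchor excluded) minus the mean z of the
  *upper-leaflet phosphorus* atoms of the same frame. Negative values
  (protein below the phosphate plane) are reported unclamped.
* **α (deg)** — tilt. With **A** the vector from the β-structural core
  ("head") group COM to the central-loop (loop II) tip COM,
  `α = 90° − ∠(A, Z⃗)` where Z⃗ is the box +z axis. α > 0 means the head dips
  toward the membrane, α < 0 means the fingers do; α = 0 leaves the central
  loop parallel to the surface.
* **β (deg)** — rotation. With **B** the loop III → loop I tip-COM vector and
  **F** a disambiguation vector:

  | condition            | β                |
  |----------------------|------------------|
  | F_z ≥ 0              | 90° − ∠(B, Z⃗)   |
  | B_z ≥ 0 and F_z < 0  | 90° + ∠(B, Z⃗)   |
  | B_z < 0 and F_z < 0  | −270° + ∠(B, Z⃗) |

  mapped into (−180°, 180°]. β ≈ −90° is loop I down, +90° loop III down,
  0° ventral side down, ±180° dorsal side down. Ties B_z = 0 take the middle
  branch, exactly as the inequalities are written.

### The F vector

F is configurable (`f_mode`): `sheet_normal` (default), `a`, or
`custom_groups`. The default is **F = unit(A × B)**, the β-sheet plane
normal. This is a deliberate design decision: with F = A the branch
condition `F_z ≥ 0` is pinned to `sign(sin α)`, the formula collapses to a
single branch per tilt sign, two distinct orientations map to the same β,
and |β| > 90° becomes unreachable whenever α ≥ 0 — no generator could
round-trip through such a measurement. With the sheet normal the formula is
injective: each reachable (α, β) pair corresponds to exactly one orientation
modulo rotation about the membrane normal. Reproducing numbers computed with
a different F definition requires setting `f_mode` accordingly.

### The legal (α, β) domain

A and B are rigidly perpendicular, so B can never make an angle of less than
|α| with the vertical once A is tilted by α. Consequently β values inside
the wedges `(90°−|α|, 90°+|α|)` and `(−90°−|α|, −90°+|α|)` are
geometrically unreachable — for example (α = −45°, β = −90°) describes an
impossible rigid-body orientation under *any* F convention, since β = −90°
requires B to point straight down. The round-trip guarantee
`measure(pose(Z, α, β)) = (Z, α, β)` holds on this legal domain;
`sample_feasible_triple` draws uniformly from it, and `pose_protein` raises
on unreachable pairs. Empirically the round trip is exact to ~1e-13
(guaranteed 1e-6 in the acceptance checks). β has a coordinate singularity
at the poles |α| = 90° (gimbal); the generator clamps |α| ≤ 89.9° and
`pose_protein` refuses poses within numerical reach of the pole.

### Membrane reference

The membrane normal is the box +z axis — the package targets planar
bilayers only; no surface fitting is attempted. Leaflets are assigned once,
from the first frame: a phosphorus-bearing lipid is "upper" iff its P atom
lies above the mean z of all lipid P atoms; cholesterol (no phosphorus) is
excluded. The assignment is frozen for the whole trajectory to avoid
flip-flop artifacts; lipid flip on the microsecond scale is negligible.
Protein coordinates are unwrapped (made whole across periodic boundaries,
minimum-image relative to the protein's first atom) before any COM or
vector computation; membrane atoms stay wrapped.

## Distribution statistics

Histograms are probability-normalised (sum 1). Default bin widths — 0.05 nm
for Z, 2° for α, 4° for β — resolve the narrowest single-mode spreads the
package is designed for (≈0.13 nm, ≈4–9°); all are overridable. The joint
α/β histogram reports its argmax cell as the preferential orientation.

Mode structure is summarised by Gaussian mixtures with k = 1..3 components
fitted by maximum likelihood (scikit-learn, multiple seeded restarts,
`reg_covar = 1e-8`), with k selected by minimal **BIC** — deliberately
conservative, matching an at-most-trimodal description. Each mode is
reported as median ± SD ± weight (median = mean for a normal component);
modes with weight < 0.25 are flagged "low-population" (an explicit,
configurable cutoff). Mixture fits refuse series with fewer than 30 points,
non-finite values, or zero variance.

Rotation angles live on a circle. Before fitting, `recenter_circular` finds
the longest empty arc of the 1°-binned angular histogram and re-expresses
the data on `(offset − 360°, offset]` with the cut at that arc's centre, so
clusters straddling ±180° become contiguous and the Gaussian description is
valid; fitted means are wrapped back. Perfectly gapless (uniform) data are
left untouched. Fitted mode means are invariant (≲0.5°) to any prior
rotation of the data.

## Backbone PCA

Frames are first superposed on a reference **in the xy-plane only**: the
optimal rotation about z plus an x/y translation from the 2×2
cross-covariance SVD (planar Procrustes), z passing through unchanged. This
removes exactly the two symmetries of the problem while keeping
membrane-normal motion in the data. The covariance of the remaining 3N
backbone coordinates about their time mean is eigendecomposed
(`numpy.linalg.eigh`); eigenvalues are reported descending with orthonormal
eigenvectors and per-frame projections. Covariance is **not**
mass-weighted: the analysis operates on plain backbone coordinates.
Extreme-projection frames (the configurations at the ends of each
component) break ties toward the lowest frame index. For a rigid anchored
body the top components recover the rise/pitch/roll motions; a pure rigid z
oscillation yields a first eigenvector with zero x/y components and
eigenvalue `N · var(s)` for N atoms and displacement series s (the
closed-form check used in the tests).

## Contact detection and lifetimes

Contacts are detected between protein-side residues (amino acids, glycans,
GPI residues) and membrane lipids, per frame, in five types. The criteria
are not part of the measured data and are fully configurable; the defaults
are standard geometric conventions:

* hydrogen bond: donor–acceptor heavy distance ≤ 0.35 nm and H–D–A angle
  ≤ 30°;
* ion–ion: minimum distance between atoms of oppositely charged groups
  ≤ 0.45 nm;
* ion–dipole: charged-group atom to *neutral* polar heavy atom (O/N outside
  any charged group) ≤ 0.40 nm, both directions; restricting the partner to
  neutral atoms keeps the type disjoint from ion–ion;
* π–cation: cation centre (Lys NZ, Arg CZ, lipid choline/ethanolamine N)
  within 0.60 nm of an aromatic ring centroid and within 45° of the ring
  normal (sign-agnostic);
* hydrophobic: a pair of positive-MHP heavy atoms within 0.45 nm, counted
  per atom pair. Atomic lipophilicity follows a shipped, swappable
  element-level constant table (C and S positive, N/O/P negative) in the
  spirit of molecular-hydrophobic-potential analyses.

Annotations (charged groups, donors with their hydrogens, acceptors, rings,
cations, MHP signs) are derived from residue + atom names: explicit tables
for the twenty amino acids (CHARMM protonation variants folded in; a donor
is active only if its hydrogen exists in the topology), generic rules for
carbohydrate/GPI residues (oxygens acceptors, phosphates anionic, amines
cationic) and for lipid headgroups. Counting granularity: ionic per group
pair, ion–dipole per (group, partner residue), hydrogen bonds per
donor–acceptor pair, π–cation per (ring, cation), hydrophobic per atom
pair. Distances use minimum-image convention in the orthorhombic box.

The **relative lifetime** of a (residue, lipid class, type) key is the sum
of its per-frame counts divided by the number of analysed frames: 0 = never,
1 = one contact throughout, values above 1 = several simultaneous partners.
Lifetimes are reported per lipid class (cholesterol, sphingomyelin,
phosphatidylcholine, phosphatidylethanolamine, phosphatidylinositol, other)
and aggregated over all classes.

The report lists each residue in exactly one of four columns with inclusion
thresholds of ≥ 10 % (ionic + ion–dipole), ≥ 10 % (hydrogen bonds), ≥ 5 %
(π–cation), and, for the hydrophobic column, ≥ 2 simultaneous pairs with a
total lifetime > 200 %. Precedence is ionic > hbond > π–cation >
hydrophobic (a residue qualifying for several appears only in the foremost;
the hbond-before-π–cation tie-break is this package's choice). Polar
entries are emphasised by their own column lifetime: **bold** at ≥ 50 %,
bold + underline at ≥ 75 %. `count_polar_residues` counts distinct
amino-acid residues in the two polar columns — the statistic behind
"15 vs 8–11" comparisons across proteins. The topology cannot distinguish
N- from O-glycans without connectivity, so both carry a single `glycan`
moiety class; a per-residue override can refine labels where the
distinction matters.

Analysis stride is configurable (the lifetime definition is
stride-invariant in expectation); 1 ns spacing is a reasonable default for
microsecond trajectories.

## Synthetic data: what it emulates, and what it does not

The generator builds a planar patch of five-bead pseudo-lipids (phosphate P,
choline N, ester O2, two tail carbons; nx × ny per leaflet on a 0.8 nm
lattice, phosphate planes 4 nm apart) and a rigid eleven-residue mock of the
three-finger fold whose head/loop-tip marker groups give exactly
perpendicular A and B vectors. Per frame the mock is rigidly posed at a
prescribed (Z, α, β) by inverting the measurement conventions, with a free,
randomised azimuth about the membrane normal (a random walk across frames,
exercising the symmetry the measurement must be blind to).

Each observable follows a **mode-switching Ornstein–Uhlenbeck process**: the
state relaxes toward the current mode mean with timescale τ (default 2 ns at
1 ns frame spacing) and stationary SD equal to the mode SD, while the mode
index resamples from the mixture weights with a per-frame switch probability
(default 0.01). This produces autocorrelated, uni- or multimodal series
resembling anchored-protein trajectories without simulating physics. Note
the autocorrelation inflates the standard error of time averages by
≈ √(2τ/Δt + 1); the generator's own statistical tests use this corrected
bound. Default settings follow reported anchored-protein behaviour — tilt
−31.5 ± 8.7°, rotation −47.9 ± 7.2° — while the default height rides at
2.0 ± 0.10 nm so the mock's protruding side chains stay clear of the
headgroup region. β draws that fall in the unreachable wedge for the
frame's α are projected to the nearest feasible boundary, and the ground
truth records the values actually posed, so recovery is exact by
construction. Headgroup z positions are jittered (SD 0.05 nm) per lipid per
frame; the Z ground truth is referenced to the jittered per-frame phosphate
mean. The membrane is otherwise static: no undulations, no lipid diffusion,
no solvent, no internal protein motion.

**Contact planting** reserves one upper-leaflet lipid per plan entry and, in
exactly ⌈fraction · n_frames⌉ randomly chosen frames, moves it next to the
posed residue in the geometry of the requested contact type (phosphate at
0.30 nm from Lys NZ; acceptor on the Tyr O–H axis at 0.30 nm; choline N on
the Phe ring axis at 0.45 nm; tail beads at van-der-Waals range of the Leu
methyls), parking it on its lattice site otherwise. A second, far-away
lipid mirrors the planted lipid's z displacement each frame so the mean
upper-leaflet phosphorus height — and hence the Z ground truth — is
preserved exactly. Moving lipids rather than protein atoms keeps the
protein rigid and every (Z, α, β) ground-truth value exact. Placements are
verified to stay ≥ 0.65 nm from all non-partner protein atoms, and the
resting protein ≥ 0.65 nm from the membrane in every frame; violations
raise a geometric-infeasibility error rather than silently corrupting the
fixture. Planting fixtures therefore use a calm, elevated pose
(Z = 2.2 ± 0.05 nm) so contact presence is controlled solely by the planted
lipid.

Passing these tests demonstrates that the measurement, statistics and
contact machinery are exact on data satisfying their geometric assumptions.
It does **not** validate behaviour on real trajectories with membrane
undulations, protein flexibility, exotic residue chemistry, or contact
criteria differing from the configured ones.

## Problem sizes and numerical details

Synthetic checks use 6 × 6 lipids per leaflet and 60–8000 frames; mixture
recovery uses 2000 draws and 100 seeded replicates; the pose round trip is
verified on 1000 random legal triples. Angle arithmetic wraps into
(−180°, 180°] with arccos arguments clipped to [−1, 1]; degenerate inputs
(zero-length vectors, parallel A/B markers, empty selections, flat
"bilayers", constant series) raise errors rather than returning garbage.
XTC output quantises coordinates to 10⁻³ nm, which bounds file round-trip
agreement; identical spec + seed reproduce output files byte for byte.

## Known limitations

* Planar membranes only; curved or undulating surfaces are out of scope.
* The default F convention must be overridden to match analyses that define
  F differently; β values near ±90° additionally depend on tilt through the
  reachability wedge.
* Amino-acid annotation tables assume standard CHARMM-style atom naming;
  heavily modified residues need explicit rules.
* The element-level MHP table is a coarse stand-in for atom-type-resolved
  lipophilicity constants; absolute hydrophobic-contact counts on real
  systems depend on the table chosen.
* N-/O-glycan distinction requires user input (no connectivity parsing).
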