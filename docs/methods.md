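# Methods

This note documents the models, conventions and numerical choices behind
`ptmstruct`, and what the synthetic generators do and do not emulate.

## Structure model and I/O

Structures are ordered residue lists keyed by author (PDB) numbering, with
coordinates in Å. Parsing goes through gemmi; alternate locations are
resolved by highest occupancy (ties keep the first listed), waters and
non-polypeptide heteroatoms are dropped on read, hydrogens are kept. The
geometric and surface analyses operate on the polypeptide in vacuo, so
solvent and ligand records would only add noise to the quantities computed
here. Trajectories are multi-MODEL PDB files; every frame must share the
first frame's atom identity ordering, which is asserted on read. Mounted
moiety atoms are written as HETATM records inside their host residue and
round-trip through the reader.

## Helix assignment

Secondary structure uses the Kabsch–Sander electrostatic hydrogen-bond
model, E = 27.888 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bond
recorded when E < −0.5 kcal/mol; both constants are the canonical values.
Amide hydrogens, absent from most deposited structures, are built 1.00 Å
from N along the preceding C=O direction; prolines and chain N-termini get
none. An n-turn (n = 3, 4, 5) at residue i requires the i+n → i bond; two
consecutive turns make residues i..i+n−1 helical, with overlap priority
α > 3₁₀ > π and minimal lengths 4/3/5. Chain breaks (C–N distance > 2.5 Å)
terminate turns and segments. Inter-implementation drift of one residue at
helix caps is expected and tolerated in the cross-checks against mdtraj's
DSSP port. Segments shorter than 5 residues are flagged not fittable for
axis fitting. All three helix types are eligible for pairing by default
(configurable), since the workflow's motif definition is geometric, not
type-restricted.

## Axis fitting

The helix axis minimises the standard deviation of point-to-line radial
distances of the Cα trace: direction parametrised by spherical angles and
the anchor by two in-plane offsets (4 parameters), initialised from the
principal direction of the centred Cα cloud and refined by
Levenberg–Marquardt. The cylinder radius is the mean radial distance of a
chosen atom set — all heavy atoms by default, which includes side chains and
therefore measures the effective packing width used for the silhouette
projection; `fit_rmsd` is the SD of the Cα radial distances and gates motif
selection at 1.0 Å by default. Under isotropic coordinate noise σ the
radial residual is a 1-D projection with four fitted parameters absorbed,
so `fit_rmsd` sits somewhat below σ (≈ 0.21 Å at σ = 0.3 Å on a 12-residue
helix) while remaining proportional to it.

## Pair geometry conventions

* The inter-planar distance d and the plane normal come from the cross
  product of the axis directions (for parallel axes, from the perpendicular
  component of the anchor offset). The normal is signed to point from helix
  1's plane to helix 2's plane.
* r is the exact minimal distance between the finite axis segments
  (convex-quadratic edge enumeration, no iteration). r ≥ d always;
  crossing projections ⇒ r = d.
* α is the angle between the 3-D axis directions folded to [0°, 90°]
  (projection onto the plane would differ by at most asin(d/ℓ) for segment
  length ℓ; the 3-D convention is the simpler and is used throughout).
* θ is the signed dihedral from direction 1 to direction 2 about the signed
  normal, right-hand rule, axes oriented N→C. Swapping the helices flips
  both the cross product and the normal, so θ is swap-invariant; proper
  rigid motions preserve it and reflections negate it (all asserted).
* S and P: each cylinder projects onto the mid-plane as its silhouette
  rectangle (length = axial segment span, width = twice the fitted radius);
  S and P are the area and perimeter of the convex intersection polygon
  (shapely). Any plane parallel to both axes gives identical in-plane
  geometry; the mid-plane is chosen for symmetry. With the all-heavy-atom
  radius the rectangle width for a real α-helix is near 10 Å; the poly-Ala
  synthetic helices are slimmer (≈ 4.5 Å), so absolute S values of real
  motifs are reproduced only with real side chains present.
* Motif selection keeps every same-chain helix pair — any number of
  intervening helices — hosting the modified residue within 2 residues of
  the pair's span, with both axis fits under the RMSD gate, tight contact
  |r − d| ≤ 0.5 Å (axis-fit noise allowance) and r ≤ 16 Å, and non-null
  projection overlap. Crossing pairs split into corners (|θ| < 120°) and
  hairpins (|θ| ≥ 120°); non-crossing pairs into V- (connection ≤ 5
  residues) and L-structures. The |θ| and connection-length cut-offs are
  package conventions (exposed in `MotifConfig`); the corner/hairpin split
  at 120° follows the usual antiparallel-hairpin reading, and the L/V rule
  is a documented stand-in for a discrimination the source workflow never
  states numerically.

## Solvent accessibility

Shrake–Rupley with probe 1.4 Å and a 960-point golden-spiral lattice per
atom; van der Waals radii C 1.76, N 1.65, O 1.40, S 1.85, P 1.90 Å
(unknown elements fall back to 1.70 Å with a warning); hydrogens ignored.
The lattice is deterministic, so areas are bit-reproducible; doubling the
point count moves per-atom areas by under 2 % (plus a small absolute floor
for atoms whose area is only a few lattice points). The active environment
of a modified residue is the set of residues with any heavy atom within
6 Å of its heavy atoms, frozen on the intact structure so the
intact/modified comparison sums over identical residue sets; environment
totals include the centre residue itself, and moiety atoms are attributed
to the modified residue. Reported per-peptide environment counts are
insensitive to the include-the-centre choice as long as it is applied to
both sides, which it is.

## Moiety mounting

Moieties are built heavy-atoms-only from idealised internal coordinates:
acetyl (N–C 1.33 Å, C=O 1.23 Å, C–CH₃ 1.50 Å, planar sp² amide on NZ),
phosphate (O–P 1.61 Å, P–O 1.52 Å, tetrahedral on OG/OG1/OH), and the
di-glycine ubiquitination remnant condensed on NZ. The remnant's formula
is C₄H₆N₂O₂ (+114.0429 Da), i.e. eight heavy atoms — two N, two Cα carbons,
two carbonyl C and two carbonyl O; no atom is lost on amide formation
because the remnant formula already excludes water. Moiety formula masses
reproduce the monoisotopic shifts 42.0106 / 79.9663 / 114.0429 Da to
0.001 Da. The single rotatable anchor dihedral is chosen on a deterministic
30° grid by maximising the minimum distance to all non-target heavy atoms —
a purely steric criterion; no force field is in scope and neighbours are
never relaxed (conformational response is modelled by the trajectory stage
instead). Mounting below a 1.5 Å hard clash floor is refused.

## Trajectory analysis

Axes are re-fitted in every frame and the six descriptors recomputed;
frames with failed fits are flagged, never dropped silently. Summaries are
arithmetic means and population SDs over all usable frames (an
equilibration window can be configured; the default uses every frame).
SDs below the ulp-level residue of pairwise summation are snapped to zero
so constant series report exactly zero spread. The stability verdict
quantifies "acceptable ranges" as: STABLE when ≥ 90 % of frames are in
tight contact and ≥ 90 % have non-null projection; RUPTURED when contact
drops below 50 % of frames or the mean r − d gap opens beyond 2 Å;
FLUCTUATING otherwise. Features whose modified-run mean moves more than
2 intact-run SDs are flagged in the comparison. All thresholds sit in
`StabilityConfig` and are echoed into every report. The reference frame
schedule — 0.5 ns recorded every 0.005 ns, i.e. 100 frames — is the default
emulated by the synthetic trajectory generator.

## Identification curation and abundance

Quality filters (confidence ≥ 98 %, fragment coverage ≥ 80 %, D-score ≥ 10,
proper flanking b/y pair) are applied in a fixed order for the removal log;
the surviving set is a pure conjunction and order-independent (asserted).
Phenotype specificity: a modified peptide — identity (sequence, PTM kind,
site) — belongs to a cancer group when present in ≥ 50 % of that group's
samples, in zero control samples, and in ≥ 20 % of PTM-carrying subjects.
"PTM-carrying subjects" defaults to the whole-cohort denominator (subjects
with any passed modified peptide), switchable to per-group. Peptides may be
shared between the two cancer groups, never with control. Differential
abundance floors missing/zero intensities at 10⁵ counts, takes the median
ratio to control on the log2 scale, tests with a two-sided Wilcoxon rank
sum (exact for untied samples of ≤ 12 per side, tie-corrected normal
approximation otherwise — exactness keeps the planted-truth simulations
deterministic), and calls significance at |log2 FC| > 1, p < 0.05 and
detection frequency > 0.8. Frequency is the fraction of case-group samples
above the floor: the rule certifies that a called protein is reliably
observed in the group being characterised. No multiple-testing correction
is applied at this stage (enrichment analysis, where such correction would
belong, is out of scope). All-constant intensity vectors have an undefined
rank-sum and report p = 1.

## Synthetic data: what it emulates, and what it does not

* **Helices.** `CA_ONLY` places Cα exactly on the requested cylinder
  (defaults radius 2.3 Å, rise 1.5 Å, twist 100°/residue) — the substrate
  for exact axis-fit oracles. `FULL_BACKBONE` builds the chain from ideal
  internal coordinates (φ/ψ = −57°/−47°, ω = 180°; N–CA 1.46, CA–C 1.52,
  C–N 1.33, C=O 1.23 Å) so the hydrogen-bond stage sees real geometry; its
  exact screw axis is computed from the repeating inter-residue rigid
  transform and returned as ground truth. The two constructions cannot
  coincide exactly (ideal internal coordinates imply their own
  radius/rise/twist, ≈ 2.28 Å / 1.55 Å / 99.7°), so the requested cylinder
  parameters govern only `CA_ONLY` mode. Side chains are built extended
  (all-anti) for the residues the PTM stages need (Lys, Ser, Thr, Tyr),
  CB-only otherwise.
* **Pairs.** Helix 1 runs along x in the z = 0 plane; helix 2 lies in the
  plane z = d\* with in-plane direction rotated by θ\*; both are positioned
  so the projections cross at a chosen fraction of each segment (outside
  [0, 1] produces non-crossing L/V geometry). The construction emits its
  analytic ground-truth geometry. The connecting linker is a Cα-only
  interpolation: generated pairs are geometric twins of real motifs, not
  chemically continuous chains.
* **Trajectories.** I.i.d. Gaussian jitter plus optional per-frame linear
  drift of a residue span, seeded and bit-reproducible. This emulates the
  recorded-snapshot statistics of a short dynamics run, not dynamics:
  no correlation between frames, no physical relaxation of the mounted
  moiety. Verdicts on synthetic trajectories therefore validate the
  bookkeeping and thresholds, not force-field behaviour on real proteins.
* **Cohorts.** Default sizes 53 ovarian / 24 breast / 30 control mirror the
  reference demography so the prevalence thresholds operate at realistic
  granularity. Planted peptides carry comfortably passing quality metrics
  at carrier fractions 0.6 (ovarian) / 0.8 (breast; the higher fraction
  keeps a 24-sample group safely above the 20 %-of-carriers rule, whose
  cohort-wide denominator is ≈ 79 here). Each decoy violates exactly one
  curation rule by a wide margin (confidence 88, coverage 55, D-score 3,
  missing b/y, two control appearances, 25 % prevalence, or 55 % of the
  breast group ≈ 16 % of carriers). Intensities are log-normal. Decoy
  sequences are synthetic strings, not real tryptic peptides — the
  curation rules never inspect sequence content.

Passing tests on these generators demonstrate parameter recovery,
invariance and rule correctness under controlled conditions; they do not
demonstrate robustness to the pathologies of real data (missing atoms,
alternate conformers beyond occupancy ties, correlated MD motion,
batch effects in intensities).

## Problem sizes in the reproduction script

`scripts/acceptance.py` uses 1000 random axis pairs for the distance
oracles, 200 Monte-Carlo rectangle pairs at 10⁶ samples each, 200 noise
seeds for axis recovery, one 380-record and one ~730-record synthetic
cohort, 200 abundance replicates, and 100-/30-frame trajectories — sizes at
which every quantity is stable to well within its comparison tolerance
while the whole script completes in about a minute on one CPU.
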