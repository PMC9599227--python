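# Methods

This note records the conventions, defaults and design choices behind the
package, in the order a user meets them: geometry, screening, burial,
ensembles, the scan grid, and the synthetic generators used for testing.

## Six-parameter pair geometry

**Ring frame.** The centroid M is the arithmetic mean of the six ring
carbons. The normal is the smallest-singular-value direction of the
centred ring coordinates (least-squares plane), with its sign fixed by
the right-hand rule on the canonical traversal order
(CG→CD1→CE1→CZ→CE2→CD2 for Phe, C1→…→C6 for benzene/toluene): that order
appears counter-clockwise when viewed from the +normal side. Fixing the
sign this way makes the sign of τ reproducible; flipping a symmetric
ring's atom labels flips the normal and hence τ, which is why
ring-flipping dynamics produce mirrored τ populations. Rings whose
planarity RMS (residual about the best-fit plane) exceeds 0.1 Å are
flagged `is_planar=False` but still usable. Note the RMS is measured
about the *tilted* best-fit plane, so a single atom displaced 0.3 Å out
of an ideal hexagon yields RMS ≈ 0.086 Å, not 0.11 Å.

**Hydrogen placement.** Deposited hydrogens are ignored. Two hydrogens
are constructed at `hydrogen_bond_length` (default 1.0 Å) from the amide
N, in the plane of (carbonyl C, carbonyl O, N), each at 120° from the
N→C bond and on opposite sides of it. This keeps results independent of
whether and how a structure was protonated.

**Parameter conventions.**

* θ is folded to the acute angle in [0°, 90°]; it is therefore identical
  for both normal signs.
* ω is measured at the hydrogen (the N–H···M angle, the hydrogen-bond
  convention) and the maximum over the two amide hydrogens is reported —
  the hydrogen oriented toward the ring is the interacting one. `h_used`
  records which hydrogen won.
* *d*<sub>Cγ–π</sub> defaults to the Cγ→centroid distance. A literal
  "distance to the plane" reading is also available
  (`GeometryConfig(d_cg_pi_mode="plane")`), but the centroid distance is
  the default because it is the only reading consistent with observed
  crystal geometry: a pair with d_NM ≈ 3.3 Å, τ ≈ 61° and
  d_Cγ–π ≈ 5.3 Å implies a Cγ–N separation of ≈ 2.4 Å — the geminal
  Cγ···Nε distance of a glutamine side chain — whereas the
  plane-distance reading would imply an impossible ≈ 4 Å.
* τ = arcsin((Cγ−M)·n̂ / |Cγ−M|) ∈ [−90°, 90°], positive on the +normal
  side.
* χ is the unsigned angle in [0°, 180°] between the projections of Cγ→N
  and of the ring substituent bond Cβ→Cγ onto the ring plane. When the
  donor axis is parallel to the normal (zero-length projection) or the
  ring has no substituent (plain benzene), χ is reported as NaN, never
  silently as 0.
* For acetamide the methyl carbon plays Cγ and the carbonyl carbon plays
  Cδ; for toluene the methyl-C→C1 bond plays Cβ→Cγ.

All six parameters are rigid-motion invariant (verified to 1e-6 under
random rotations/translations) and agree with an independently coded
brute-force implementation to < 1e-9 over 10,000 random placements.

## Screening and collagen register

Candidate pairs are enumerated at d_NM ≤ 4.5 Å (so near-misses remain
available for population statistics) and screened with the strict
inequalities d_NM < 4.3 Å, θ < 25°, ω > 120°. Boundary values fail. A
symmetric −25° < θ < 25° criterion collapses to θ < 25° because θ is
defined acute. Donor and ring sets default to Gln and Phe and are
configurable (Asn donors are supported; His/Trp five-membered rings are
not in v1). No symmetry expansion is performed: pairs across
crystallographic copies are out of scope.

For collagen triple helices, chain roles are inferred from the
one-residue axial stagger: the helix axis is the principal axis of all
Cα atoms oriented N→C, and chains are ranked by mean axial projection
over shared residue numbers — leading first. The ranking is overridable
(`chain_roles=`). Residue positions within the Gly-X-Y repeat come from
the chain's Gly spacing. A Y-position donor paired with an X-position
ring on the *successor* chain (leading→middle→trailing) is labelled
**lateral** for the same triplet and **axial** for the next triplet
(an optional per-chain `triplet_offset_map` aligns numbering schemes);
anything else is `none`, and inputs that are not recognisably a staggered
three-chain Gly-X-Y helix give `n/a`. Register labels and pass flags are
reported independently — the package does not decide which published
pair nomenclature is "correct".

Dataset metadata filters (resolution ≤ 2.0 Å, R ≤ 0.25, minimum chain
length ≥ 40, experimental entries with full coordinates; inclusive
bounds) are applied to an externally supplied entry list. Sequence-identity
clustering is deliberately not implemented; a precomputed
representative-chain list is accepted as input.

## Solvent accessibility and burial

Shrake–Rupley with a deterministic Fibonacci (golden-angle) sphere of 960
points per atom, probe 1.4 Å, NACCESS/Chothia-style element radii
(C 1.70, N 1.55, O 1.52, S 1.80 Å, …), heavy atoms only. A sample point
is accessible when outside every neighbouring expanded sphere; exactly
coincident spheres are resolved by point ownership (lower atom index
keeps boundary points) so total area is conserved in the degenerate
limit. The isolated-atom case reproduces 4π(r+probe)² to well under 1 %
at 960 points.

Pair ASA is the **whole-residue** sum (backbone + side chain) of the
donor and ring residues, computed in the context of the full structure;
a side-chain-only variant would need only a different residue selection.
Burial classes: buried < 30 Å²; 30–60 Å² labelled `intermediate` (a
range the published binning leaves unnamed — it is kept explicit rather
than merged); 60–120 Å² partially exposed; ≥ 120 Å² fully exposed (the
fully-exposed threshold is adopted by continuity with the other bins).
Because this implementation is not DSSP, absolute areas differ from
DSSP's by a few percent; published burial-class *counts* should be
treated as indicative, not reproduced exactly.

## Ensembles, density maps, melting curves

Trajectories are multi-model PDB files (any MD engine can export one);
each frame yields one six-parameter row for a chosen donor/ring address.
Ring superposition uses the orthogonal-Procrustes (Kabsch) solution via
scipy, mapping each ring onto an ideal hexagon and carrying the donor
atoms along; ring-atom correspondence follows the canonical order.
Density maps are normalised 2-D occurrence-fraction histograms, default
bins 0.1 Å for distances and 5° for angles, with a per-bin mean of a
third parameter as the colour channel. The modal bin is the
maximum-fraction bin, ties broken toward smaller first-axis (d_NM)
value. Cutoff occupancy is the mean of the per-frame pass indicator.

Melting curves are reduced by fitting linear baselines to the folded
(low-T) and unfolded (high-T) windows — by default the lowest and
highest quarters of the temperature range, overridable — normalising to
a folded fraction F(T) = (θ−θ_U)/(θ_F−θ_U), and interpolating the
F = 0.5 crossing linearly between samples. A curve whose baselines
coincide (gap below 4× the baseline residual scatter) raises a
no-transition error; multiple crossings warn and report the first;
F outside [−0.2, 1.2] warns about baseline quality. The normalisation is
sign-agnostic, so signals that rise on unfolding work unchanged.

## The acetamide–toluene scan grid

The scan frame is anchored on toluene: origin at the substituted ring
carbon C1, x-axis along the methyl-carbon→C1 bond projected into the
ring plane, z along the ring normal, y right-handed. ("CM" is read as
the methyl carbon; the ring centroid is always called M.) Toluene's
mirror symmetry about the x-axis and the ring plane means one quadrant
(y ≥ 0, z > 0) covers the whole interaction space. The default lattice —
x, y from 0 to 4.8 Å in 0.4 Å steps, z from 2.0 to 5.0 Å in 0.2 Å
steps, endpoints inclusive — holds 13 × 13 × 16 = 2704 sites. Note the
origin is C1, not the centroid: directly above the *centroid* (x = 1.39,
y = 0) the derived θ is exactly 0, whereas above the origin it is not.

At each site an acetamide is posed with its N constrained to the site in
a canonical orientation: N–H bisector toward −z, amide plane containing
the z- and x-axes. Geometries are emitted as XYZ files plus a TSV
manifest (index ↔ filename ↔ N position); energies computed by any
external engine are ingested back by grid index. The package never
computes energies. Real scans relax all non-N atoms at each site, which
a rigid generator cannot reproduce — derived per-point geometry is the
*initial* geometry, a documented limitation. Projections: the global
minimum (first index on ties), a minimum-energy envelope vs d_NM over
points with θ in an open interval (default (0°, 20°), 0.1 Å bins), and
energy vs τ over points filtered on χ or on τ (both conventions appear
in the literature; the filter in force is named in the output).

## Synthetic data: what it emulates and what it does not

`plant_pair_fragment` inverts the six-parameter definitions: N is placed
exactly on the (d_NM, θ, azimuth) cone (on the −normal side when a
negative τ is requested); the hydrogen tilt realising ω is solved in
closed form from the law of cosines; and the two remaining rigid-body
spins (about the N–M axis and about the N–H bond, plus a discrete branch
choice for Cγ) are tuned by damped least squares when τ and/or χ are
requested — with the hydrogen tilt joining the free variables when ω is
not prescribed. Free parameters default to 0 so fixtures are
reproducible. Every plant is verified by measurement; a spec that cannot
be reproduced to 1e-7 is rejected with the violated parameter named
(e.g. a small ω is unreachable because the second amide hydrogen
necessarily reports a larger N–H···M angle). Amide internal geometry is
fixed at N–C 1.33 Å, C–Cγ 1.52 Å, C=O 1.23 Å, sp² angles.

Decoy structures sample passing pairs with ≥ 0.2 Å / 5° margins inside
every cutoff and failing pairs outside at least one (failure modes:
distance, θ, or ω), isolate fragments on a 26 Å lattice (no cross-pair
contact can enter the 4.5 Å enumeration radius), add glycine filler
residues, and are byte-identical per seed. Trajectories plant an exact
⌊fraction·n⌋ subset of frames in-cutoff and add per-frame Gaussian
coordinate jitter (default σ = 0.02 Å, small against the margins).
Melting curves are a logistic two-state transition (default width
1.5 °C, centre 40 °C) over 4–80 °C in 0.5 °C steps with linear
baselines and seeded Gaussian noise; the folded−unfolded gap scales with
the amplitude so zero amplitude degenerates cleanly to "no transition".

These fixtures are geometric idealisations: fragments are isolated and
rigid, with no backbone context, no thermal heterogeneity beyond
isotropic jitter, no realistic collagen packing, and no force-field
relaxation. Passing tests therefore demonstrate correctness of the
*measurement and screening machinery* — recovery of planted geometry,
exact screening counts, planted occupancies and melting temperatures —
not agreement with any particular experimental structure or simulation.

## Problem sizes and numerical tolerances

The test suite and `scripts/acceptance.py` use: 10,000 random placements
for the dual-implementation check (agreement < 1e-9 on all six
parameters), 1000 planted specs for the round-trip check (< 1e-6),
planted screening counts up to 20+20 pairs, 960-point SASA spheres,
2000-frame trajectories for occupancy (±0.02 on a planted 0.22), and 100
noisy curves for Tm recovery (mean |error| < 0.2 °C at 1 % amplitude
noise). PDB coordinates round-trip at the format's 3-decimal precision;
writing rejects coordinates beyond ±999.999 Å (symmetric bound, so sign
changes never overflow the 8.3 column). Degenerate inputs raise typed
errors (`GeometryError`, `PDBParseError`, `NoTransitionError`,
`PlantInfeasibleError`) rather than returning silent defaults.

## Known limitations

* Six-membered carbocycles only; His/Trp rings and backbone N–H donors
  are future work.
* No mmCIF input, no symmetry expansion, no disorder handling beyond the
  altloc policy (highest occupancy, ties to the lexicographically
  smaller altloc).
* SASA is not DSSP-identical; burial classes are convention-dependent.
* The scan generator emits rigid starting geometries; engines that relax
  non-constrained atoms will drift from the derived per-point parameters.
* Chain-role inference assumes a clean one-residue stagger; heavily
  distorted or partial helices should supply explicit roles.
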