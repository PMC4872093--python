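# Methods

This note records the models, conventions, numerical choices and known
limitations behind each stage of the pipeline. Nothing here asserts an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Structure model and the target frame

Coordinates are parsed with gemmi (fixed-column PDB and mmCIF `atom_site`
loops) into a chain → residue → atom hierarchy that keeps author residue
numbering, insertion codes and waters. Alternate locations are collapsed to
the highest-occupancy conformer (ties broken alphabetically by altloc id):
all downstream geometry assumes a single conformer per atom. Residue kind
(protein / nucleotide / water / other) is a deterministic dictionary lookup;
unknown names become `other` and are carried, never dropped.

The *target frame* maps duplex nucleotides to recognition-sequence
positions: the methylated T:A base pair is +1, downstream positions are
positive, upstream negative, and −1 immediately precedes +1 (there is no
position 0). Frames are anchored on an explicit top-strand residue — the
asymmetric unit of a co-crystal may contain several copies of the complex,
and the caller, not the library, chooses which copy to analyse
(`struct_io.find_target` lists candidate anchors). Bottom-strand partners
are assigned geometrically — the anti-parallel nucleotide whose
Watson–Crick pairing atom (purine N1 / pyrimidine N3) lies within
hydrogen-bonding range (3.5 Å), assigned bijectively — and the remainder by
frame arithmetic on the partner chain numbering. The tight geometric
criterion matters: with a looser "nearest pairing atom" rule, a flipped
base's partner is captured by the *neighbouring* base, whose pairing atom
sits only ~3.7 Å away along the helix axis.

## Contact detection

Hydrogen-bond contacts are protein/DNA donor–acceptor heavy-atom pairs
(opposite roles; Ser/Thr/Tyr hydroxyls and His ring nitrogens count as
either) within a cutoff, default **3.5 Å**. The criterion is
distance-only because interface schematics for crystal structures solved
near 2.8 Å resolution are conventionally drawn without hydrogens; chemical
plausibility lives in the role dictionaries (purine N7/O6/N6 toward the
major groove, N3/O2/N2 toward the minor groove, backbone phosphate and
sugar oxygens as acceptors). Detection uses a k-d tree over the DNA polar
atoms; a brute-force all-pairs scan with identical classification is kept
as the test oracle, and the two are asserted set-identical on 50 seeded
fixtures. If one protein atom contacts two atoms of the same base, both
records are kept — bidentate arginine contacts are real signal, not
duplicates.

Water bridges: a record is emitted for each water oxygen within the cutoff
of both a protein donor/acceptor and a DNA *base* donor/acceptor; the
reported distance is the water–base leg and the mediation field names the
water. Intercalation: the planar side-chain groups (Arg guanidinium;
His/Trp/Tyr/Phe rings) are reported when their centroid lies within 4.5 Å
of the base centroids of two consecutive in-stack positions (flipped bases
excluded from the stack) and their plane is within 30° of the mean flanking
base plane.

## DNA geometry

**Axis.** C1' midpoints of intact Watson–Crick pairs are the raw signal.
Windowed (default 5-point) least-squares line fits give a local axis
direction and, from the rotation of the C1'–C1' pair vectors about it, a
local twist estimate Ω. The midpoints of an ideal helix wind around the
axis at ~1.9 Å radius, which a line fit cannot remove; the axis point at
step *i* is therefore the three-point stencil
`(1−2w)·m_i + w·(m_{i−1}+m_{i+1})` with `w = 1/(2(1−cos Ω))`, whose weights
annihilate one helical turn exactly. One refinement pass re-estimates Ω
about the provisional axis tangents. Pairs broken by a flipped base are
excluded; their axis points and the duplex ends are interpolated /
extrapolated from neighbours. On ideal fixtures the axis points are
collinear to < 0.06 Å.

**Bend.** The angle between the principal directions of the axis points of
two user-chosen arms, each ≥ 4 steps, oriented 5'→3'; arms should avoid
the one or two steps flanking the suspected kink, where the stencil mixes
the two arm geometries. Planted kinks of 10°–60° are recovered within
0.1°; the acceptance tolerance (±2°) covers convention sensitivity, not
estimator noise.

**Groove widths.** Cross-strand P–P convention: width at top-strand
position *i* is the minimum `|P_top(i) − P_bottom(i+k)|` over a
groove-specific register window, minus 5.8 Å for two phosphate-group
radii. The minor-groove register spans pair offsets **+2…+6**; the
major-groove register spans **−6…−2**. The mirrored major window is a
geometric necessity: on a B-form helix the chord-plus-rise distance
function has its minor minimum a third of a turn ahead and its major
minimum roughly half a turn behind, so a window centred on zero offset
degenerates to the shared shoulder of the minor groove (the scan that
established this is reproducible from the generator's analytic
`_register_distance`). Positions with incomplete registers, missing
phosphates, or within 3 steps of a duplex end are flagged undefined.

**Flipped bases.** A base is flipped when its base-atom centroid lies more
than a threshold (default **8 Å**, exposed as a parameter) from the axis
polyline *and* it has no Watson–Crick contact (pairing atoms ≤ 3.5 Å) with
its frame partner. 8 Å cleanly separates intra-helical breathing (ideal
centroids sit ~3 Å from the axis) from full extrusion into an enzyme
active site (≥ 10 Å).

## Structure comparison

Superposition is the closed-form least-squares rigid fit (Kabsch via SVD
with a determinant correction; degenerate and collinear inputs are
rejected). Cross-homologue selections are paired by global sequence
alignment, because author numbering drifts by a few residues between
homologues; same-structure selections may pair by number. The inter-domain
rotation between two models is measured by superposing on a reference
domain and reading the residual rotation angle
`arccos((tr R − 1)/2)` of the mobile-domain superposition.

Percent identity uses a global BLOSUM62 alignment (gap open 10, extend
0.5) with free end gaps — homologous constructs often differ by terminal
truncations that should not dilute identity — and the denominator is
alignment columns excluding end-gap columns. Co-optimal alignments can
differ between argument orders; the better of the two orders is reported,
making the measure symmetric. Cα over the stated domain ranges is the
superposition currency throughout; published RMSDs rarely state their
atom selection, which is why the acceptance tolerance on the TRD
superposition is ±0.5 Å.

## Conservation and couplings

Conservation per column is relative entropy (bits) of the
Henikoff-weighted residue distribution against BLOSUM62 background
frequencies, gaps ignored and renormalised; all-gap columns are flagged
undefined. Profiles are also reported on a rescaled axis — raw score
multiplied by −1 and shifted so the minimum is exactly zero — the offset
convention used when conservation and coupling strengths are plotted on a
common axis.

Couplings are mutual information over weighted joint frequencies with a
0.5-per-cell pseudocount, gaps as a 21st symbol, columns > 50% gaps
excluded, followed by average-product correction. The per-residue
evolutionary-coupling strength is the sum of a residue's positive MI-APC
values among the top-L couplings (L = number of scored columns). This is
a deliberate desk-scale stand-in for pseudolikelihood direct-coupling
strengths: the downstream use is rank-based (top-10% selection,
enrichment of contact residues), and on synthetic alignments with planted
covarying pairs the planted columns dominate the top decile across seeds.
No claim is made that the MI-APC ranking numerically reproduces a
large-scale pseudolikelihood ranking on real alignments of hundreds of
homologues; that comparison is out of desk scale and is covered instead by
the synthetic recovery properties plus an exact hypergeometric enrichment
oracle. The analytic 1-bit check for perfectly coupled uniform binary
columns is computed with pseudocount 0 (the plug-in estimator); the
pipeline default pseudocount biases that value down by design.

Top-fraction selection takes `floor(fraction × n)` residues, ties at the
boundary resolved toward the lower residue number. Enrichment reports the
exact hypergeometric tail `P(X ≥ overlap)`.

## Recognition code

Entries (one per enzyme) carry an oriented target over positions −1…+6 —
base pairs are written top:bottom because which strand a residue reads
matters — and the residues at ~25 anchor positions inside seven structural
elements (Loops I–III of the MTase, Loops IV–VI and helix H of the TRD,
LlaGI numbering; the Loop IV–VI windows are extended a few residues to
admit anchors contributed by homologues with drifted numbering).
Degenerate IUPAC letters split their weight evenly over the compatible
pairs; `n` positions are unspecified.

The association score for (anchor residue, base pair) at a position is the
product of the two conditional purities over enzymes specifying that
position. It is symmetric, lies in [0, 1], and adding a consistent enzyme
can only raise it. Entries at score ≥ 0.8 (configurable) with ≥ 2
supporting enzymes are reported; hypothesised entries can be stored but
are flagged `predicted` and never used by the predictor. Prediction sums
matched entry scores per candidate pair and reports the best, or
"unspecified" with zero confidence when nothing matches — positions read
by no element (like +2 at the clamp mouth) stay unspecified.

The synthetic panel generator guarantees every planted cell ≥ 3
supporting enzymes so that leave-one-out folds retain the reporting floor
of 2; this mirrors the real known-target table, where coded cells are
multiply supported. The noise-robustness property (10% of anchor residues
relabeled) is tested on a 500-entry panel: with the hard 0.8 threshold the
expected purity under 10% noise is 0.9, and only at that panel scale is
the fluctuation margin large enough for the property to hold
deterministically across seeds; at 11 entries a single corrupted
supporter in a 3-support cell arithmetically drops the score to ~0.67.

## Kinetics

The displacement model is a linear background `m·t` before the lag and an
offset exponential `A(1−e^{−k(t−T_app)}) + C1` after it, with
`C1 = m·T_app` so the curve is continuous at the lag (an
unconstrained-C1 mode exists behind a flag for robustness comparisons).
Fitting: a derivative-onset heuristic seeds a grid search of candidate lag
times over sample points (inner fit linear in (m, A), small k grid), then
all four parameters are refined jointly by bounded nonlinear least squares
in log k. Noiseless traces recover all parameters to 1e-6 relative error.

A trace is flagged `no_lag` — lag undefined — when the rise actually
developed inside the observation window is ≤ 3× the point noise
(estimated robustly from first differences) **or** when a pure line
explains the trace nearly as well as the lag model (residual ratio ≥ 0.5).
The second clause matters: on a drift-only trace the optimizer otherwise
drifts to a huge-amplitude, tiny-rate exponential whose asymptotic
amplitude passes the naive test.

The stepping rate is `1/slope` of the ordinary least-squares line of lag
time on distance (≥ 3 distinct distances required; non-positive slope is a
"non-translocating" error), with the standard error propagated first-order
from the slope. The intercept C2 is reported, never interpreted as an
initiation time. The full recovery experiment simulates one noisy trace
per distance per replicate, fits everything, and reports the distribution
of recovered rates; replicates with a no-lag trace are excluded and
counted.

Synthetic trace defaults: five distances, amplitude 1, displacement rate
constant 0.05 s⁻¹, 10 Hz sampling, duration 1.5× the largest lag plus five
exponential lifetimes, Gaussian noise with SD 2% of the amplitude. The
noise level and sampling rate of real stopped-flow traces are not public;
2% at 10 Hz is a realistic fluorimeter regime and is declared, not
derived. The acceptance pipeline (five distances 500–3000 bp, 50
replicates, true rate 226 bp/s, intercept 5 s) runs in ~30 s on one CPU.

## Synthetic data: what it does and does not emulate

The duplex generator is analytic: base pairs on an ideal helix (3.4 Å
rise, 36° twist), phosphates at radius 8.9 Å and ±70° from the pseudo-dyad
— placing the minor-groove width at ~5.5 Å and the major at ~11.7 Å,
canonical B-DNA values — and reduced-atom bases (P, C1', glycosidic and
pairing nitrogens, groove-face atoms ~2.2 Å apart, all coplanar). Kinks
rotate the downstream frame about an in-plane axis; flips displace the
base atoms radially ≥ 8 Å while leaving the backbone; groove widening
solves a local 2×2 system (phosphate radius, phase) so that *both* groove
widths grow by the requested amount at their registers. Planted protein
atoms are positioned at exact distances with verified clearance from every
other polar atom, so a detector at the default cutoff sees exactly the
planted contacts; contradictory requests (flip at a kink step, colliding
alignment plants, sub-steric distances) are rejected.

None of this reproduces sequence-dependent mechanics, sugar puckers,
side-chain rotamers, crystallographic disorder or solvent structure.
Passing recovery tests therefore demonstrate that the *estimators* are
correct on geometry whose ground truth is known — not that real
structures are free of the conventions' ambiguities (axis definition,
register choice, selection ranges), which is exactly why the real-structure
tolerances are wider than the synthetic ones.

## Degenerate inputs and tie-breaks

Selection ties in `top_fraction` favour the lower residue number. Equal
candidate base pairs in prediction are broken lexicographically. Duplexes
shorter than 8 bp refuse axis fitting; arms overlapping or shorter than 4
steps refuse bend measurement; alignments with fewer than 30 rows refuse
coupling estimation (frequencies too unstable); fewer than 3 enzymes with
specified positions refuse code derivation.
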