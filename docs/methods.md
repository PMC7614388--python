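# Methods

This note records the models, conventions and numerical choices behind
`insptools`, and what the synthetic-data closed loops do and do not
demonstrate.

## Isomer algebra

A phosphorylation state of the *myo*-inositol ring is a subset of ring
carbons {1..6} carrying phosphate monoesters, optionally with a subset of
those positions carrying diphosphate (pyrophosphate) groups. *myo*-Inositol
has one axial hydroxyl (C2) and an internal mirror plane through C2 and C5,
so the enantiomer operation on 1D position labels is the involution
σ: 1↔3, 4↔6 with 2 and 5 fixed, applied to both the phosphate and
pyrophosphate sets. A state is meso exactly when it is σ-fixed. There are
2⁶ = 64 monoester states, C(6,n) at each level n; meso counts are the
σ-fixed n-subsets (e.g. 4 of the 20 InsP3 isomers, 2 of the 6 InsP5
isomers).

Naming follows the 1D convention used in the inositol phosphate
literature. An isomer and its enantiomer keep their distinct names —
there is no lowest-locant renormalization across mirror images, because
substrate tables distinguish, e.g., Ins(1,4,6)P3 from Ins(3,4,6)P3.
Pyrophosphates use the `kPP-Ins(p,...)Pn` form, with the `Pn` suffix
counting monoester positions only. Chromatographically unresolvable
enantiomer classes (e.g. "1/3-InsP7") are handled as display groupings of
two first-class states, not as objects of their own. Enumeration order is
lexicographic on sorted position tuples. The empty set ("Ins", free
inositol) is a valid state.

Only the *myo* backbone is modelled; chiro-/scyllo-/neo-inositols and
full IUPAC stereo-descriptors are out of scope.

## Reaction engine

Forward hydroxy-kinase steps add a phosphate at a free hydroxyl at the
expense of one ATP; reverse phosphotransfer moves a ring phosphate onto
ADP. Each `ReactionRecord` carries a nucleotide ledger and the phosphate
balance (product P + ΔATP − substrate P) is identically zero — transfer is
stoichiometric. The engine takes an enzyme capability profile; the AtITPK4
profile permits hydroxy-kinase and phosphotransfer-to-ADP but no
phosphate-kinase (pyrophosphorylating) reactions, which are representable
in the types but disabled for this enzyme. Reverse transfers that can
produce either member of an enantiomeric pair return both products,
flagged as a chromatographically unresolvable pair with a note that the
mixture is expected to be of unequal amounts (the forward reaction
prefers one enantiomer).

The measured AtITPK4 substrate/product table ships as package data
(23 kinase rows, 4 phosphotransfer rows). The printed table mixes blank
cells and dashes in its two grade columns; both are encoded as grade
`none`, distinguished only by a provenance note, and the two assay-format
columns (`+` scale for the ATP-regenerating assay, `*` scale for the
standard assay) are kept independent because no quantitative relation
between the scales is defined. Products printed as "Not verified" carry
`verified=False` and are skipped by consistency checks.

## Ring geometry and the face rule

The ring is an ideal cyclohexane chair: C–C bond 1.54 Å, all bond angles
arccos(−1/3) ≈ 109.47°, which fixes the hexagon radius r = L·2√2/3 and
the pucker amplitude z₀ = r/(4√2). Substituent directions at each carbon
are the two exact tetrahedral completions of the ring bonds; the oxygen
substituent is axial at C2 and equatorial elsewhere (*myo*
configuration). Real rings pucker away from ideality, but every
conclusion drawn here depends only on ring topology and face signs, so
the idealization removes force-field dependence at no cost to the
model's claims.

Face conventions: the obverse face is the one carrying the C2 axial
substituent (its normal is the best-fit ring-plane normal signed toward
that substituent); the reverse face is the other side. Carbons C1..C6 are
placed counterclockwise as seen from the obverse side — the unique
handedness under which the subsite labelling convention below reproduces
the published pocket assignments; this was fixed once from those
assignments and is not a tunable.

Two geometric facts carry the specificity model:

1. Equatorial substituents at C1/C3/C5 tilt out of the mean plane toward
   the obverse face (the C2-axial side), those at C4/C6 toward the
   reverse face — with tilt magnitude |cos| = 1/3. The phosphoryl-transfer
   observer (the ATP γ-phosphate) sits on the face *opposite* the target
   hydroxyl's tilt, which yields the face rule: reverse-face presentation
   for transfer at positions 1, 3 or 5; obverse for 4 or 6. Phosphorylation
   at the axial 2-position has no stated rule and is rejected rather than
   guessed.
2. A 180° rotation about the C2–C5 axis exchanges carbons 1↔3 and 4↔6 in
   the projected ring ordering and flips the presented face — it is the
   geometric realization of the σ enantiomer map (the C2–C5 line is not a
   symmetry axis of the chair, so the exchange is exact only in
   projection; nearest-carbon assignment after the turn is unambiguous).

Poses are built in an enzyme frame with the observer on +z and subsite A
on the +x azimuth: an optional C2–C5 flip (when the reverse face is
required) followed by an in-plane rotation about the ring normal.

Rigid superposition uses the Kabsch SVD construction with the determinant
correction, so only proper rotations are returned; a reflection would
silently enantiomerize the ring, and mirror checks must opt in via
`allow_reflection=True`. Degenerate (collinear/coincident, or < 3 point)
inputs are rejected. Tolerances: ring closure 1e-6 Å; RMSD identities are
asserted at 1e-9 Å in tests.

## Subsite model

Subsite A is the catalytic centre holding the hydroxyl being
phosphorylated. Viewed from the γ-phosphate looking at the reverse face,
subsites B–F run clockwise following increasing carbon number, which
combinatorially is B..F = A+1..A+5 (cyclic on 1..6) for reverse-face
poses. For obverse poses the apparent rotational sense mirrors, so
B..F = A−1..A−5; this mirror rule is a design choice validated against
all four published pocket statements (B-pocket phosphate for
Ins(1,4,6)P3@3 and Ins(1,4,5,6)P4@3, B-pocket axial 2-OH for
Ins(3,4,6)P3@1 and Ins(3,4,5,6)P4@1, F-pocket 6-phosphate for
Ins(3,4,5,6)P4@1). The same assignment is recomputed independently from
pose coordinates by signed in-plane angles from the observer's viewpoint,
with a circulation-handedness check that rejects reflected coordinate
sets; combinatorial and geometric routes agree for all 160 valid
(isomer, target) pairs.

The occupancy report grades subsite B only: phosphate → favourable
(it can hydrogen-bond the B-pocket thiol and coordinate Mg²⁺), axial
2-hydroxyl → unfavourable (poorly solvated in the pocket), anything else
neutral. This is a three-level partial rationale, not a predictor — it is
known to mislabel Ins(4,5,6)P3 (inactive despite a B-pocket phosphate in
its 3-kinase pose), and that exception is pinned in the test suite.

## Kinetics

Rate laws: Michaelis–Menten v = Vmax·S/(KM+S) and the standard
substrate-inhibition form v = Vmax·S/(KM + S·(1+S/Ki)) — the form used by
common curve-fitting software; the inhibited curve is unimodal with
maximum at √(KM·Ki) and v→0 at high S. Units are µM and
nmol·min⁻¹·mg⁻¹ internally; Ki is commonly printed in mM and converted.

Fitting is least squares (lmfit/MINPACK) on the logarithms of the
parameters, which enforces positivity without active bounds; standard
errors map back by the delta method (SE = estimate × SE(log)). Initial
values are data-derived and deterministic: Vmax₀ = max observed v, KM₀ =
linearly interpolated S at half-max, Ki₀ = max S. Designs that do not
bracket the fitted KM raise a span warning. Reference constants
(`ITPK4_ATP_KINETICS`: KM 52 µM, Vmax 8.64 nmol·min⁻¹·mg⁻¹, Ki 3.3 mM;
`ITPK1_VMAX` 8640 — the 1000-fold activity gap between the two enzymes)
are exposed for reuse by simulations and the acceptance script.

Assay simulation integrates the progress of an assay with LSODA (Radau
fallback): the ATP-regenerating format treats the
phosphocreatine/creatine-kinase couple as an ideal ATP clamp; the
standard format depletes ATP 1:1 with product and conserves total adenine
nucleotide. Enzyme µM is converted to mg/ml with a nominal 50 kDa mass
unless mg/ml is given. Each run reports whether the <10% substrate
consumption criterion for initial-rate validity held. Percent conversion
is 100·product/(substrate+product), scale-invariant by construction.

## Chromatogram quantification

Baseline: rolling median with a window (default 5 min) much wider than a
peak, refined by two passes that mask points more than 3 noise-SD above
the current baseline, dilate the mask to cover low peak flanks,
interpolate across the masked spans from locally smoothed values, and
re-filter. The refinement is what keeps peak areas unbiased when peaks
occupy a non-negligible fraction of the window; a noise floor of 1e-9 of
the signal range keeps the mask sane on noiseless traces.

Detection: Savitzky–Golay-smoothed local maxima with prominence at least
10× the robust noise SD (1.4826·MAD) by default and a minimum width.
Bounds walk outward from each apex until the signal settles below
max(0.1% of height, 0.5 noise-SD) for three consecutive points, stopping
at the valley before an adjacent peak; areas are trapezoidal integrals of
the corrected (unsmoothed) signal, which converge to the analytic
Gaussian area as the grid refines. Overlapping peaks are split at the
valley, not deconvolved.

Calibration is a single-point response factor (counts·min per pmol) from
an InsP6 standard; amount = area / factor / injected_fraction / mass.
Phosphorus-specific detection makes response proportional to P atoms, so
a per-phosphorus factor can be selected, in which case amounts divide by
the species' phosphate count (from its retention window) to report
per-molecule values; per-molecule calibration is the default and the
alternative is a switch because the convention used for published
per-gram values is not stated. Species are assigned by configurable
retention-time windows since absolute retention depends on the gradient.

Genotype comparison: per-genotype mean ± SD and pairwise two-sided
Welch (unequal-variance) t-tests at α = 0.05, unadjusted — with three
pairwise tests the unadjusted convention is stated rather than hidden.
Single-replicate groups yield descriptive output only.

## Motif scanning

HAD signature motifs are ordered residue-class constraints with bounded
gaps: Motif I canonical D-x-D with the degenerate D-x-x variant reported
as non-canonical (covering the DES replacement seen in ITPK4 N-terminal
domains); Motifs II (Ser/Thr) and III (Lys) as single-residue anchors,
because their true definition is structural (end of strand S2; loop after
S3) and a pure sequence scanner cannot see that context; Motif IV as
(G/S)(D/S)x{3,4}(D/E). Scanning reports every distinct match start
(overlaps included), with canonical hits suppressing the degenerate
variant at the same start. Because a sliding scan of a longer sequence
can start a canonical Motif IV inside a block that fails it at its
alignment position (ASSRKEE contains S-S-RKE-E from its second residue),
the anchored evaluator `match_motif_at` is provided for the
structure-aligned question "is the motif at this position canonical?".

Residue coordinates are 1-based and inclusive everywhere, matching
crystallographic convention; a domain annotated 12–25 has 14 residues.
Cap classification follows the insert location: no cap insert → C0
(capless), insert between the two flap strands → C1, insert immediately
after strand S3 → C2; a bare β-hairpin flap without an insert is C0.

## Synthetic data

Generators draw from a private `numpy` Generator seeded explicitly —
identical arguments and seed give bit-identical output — and every
generator returns a machine-readable truth record.

* Kinetic datasets: v = model(S)·(1 + N(0, cv)) on a 9-point ATP design
  from 10 to 5000 µM (spanning KM and the inhibition optimum
  √(KM·Ki) ≈ 414 µM), cv = 5% by default — the reported assay's
  concentration range and a noise level typical of initial-rate HPLC
  assays.
* Assay chromatograms: two Gaussian peaks (substrate, product) splitting
  a total area by the conversion fraction, on a linearly drifting
  baseline with additive Gaussian noise; exponential tailing is available
  as an option. Gaussian shape is a choice — the real peak shape is not
  identified, only areas matter downstream.
* Genotype panels: per-replicate InsP6 amounts drawn from
  Normal(mean, SD) per genotype — defaults are the reported vegetative
  InsP6 contents (itpk4-1 26 ± 1, Col0 153 ± 39, ITPK4-OE 181 ± 43
  pmol·g⁻¹ fresh weight, n = 3) — converted through the calibration and
  the sample metadata (160 mg tissue, 20% injected) to embedded peak
  areas.
* Motif sequences: uniform random backgrounds with embedded motif
  substrings at recorded positions; canonical Motif I occurs in the
  background at the analytic chance rate (1/20)² per position.

What the closed loops show: that detection, integration, calibration,
normalization and testing are mutually consistent and unbiased under the
stated noise model. What they do not show: robustness to co-eluting
species, tailing/fronting asymmetry, detector saturation, retention drift
between runs, or ICP-MS counting statistics — the generators deliberately
do not model instrument physics.

## Problem sizes and determinism

The recovery experiments use 100 seeded replicates for kinetic parameter
medians, single seeded traces for conversion recovery, and n = 3
replicates per genotype for the panel — the same design sizes as the
study conditions they emulate, and comfortably desk-scale (the whole
acceptance run takes a few seconds). All stochastic tests fix their
seeds; hypothesis-based property tests are bounded and deterministic
under the default profile.

## Known limitations

* The subsite favourability flag is deliberately crude (see the
  Ins(4,5,6)P3 exception); no binding energetics are modelled.
* The obverse-face subsite labelling (mirror rule) is a convention
  choice; the published definition covers only the reverse-face vantage.
* Motif II/III sequence anchors will over-report without structural
  context; they are meant to be filtered by supplied context windows.
* The kinetics module fits each dataset independently; no global fits
  across substrates, and the creatine-kinase regeneration couple is an
  ideal clamp, not a modelled enzyme.
* Overlapping chromatographic peaks are valley-split, not deconvolved.
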