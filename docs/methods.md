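# Methods

## The response-element code

A p53 response element (RE) is two RRRCWWGYYY half-sites (R = A/G, W = A/T,
Y = C/T), optionally separated by a 0–13 bp spacer, bound by a p53
tetramer.  Positions are numbered 1–20 across the concatenated half-sites;
spacer bases are excluded from the numbering so that positions 13 and 18
remain meaningful for spacered REs.  Matching is set-membership per
position — no position-weight scoring — and the number of mismatching
positions is the RE's mismatch load.  Core mismatches are those inside the
CWWG quadruples (positions 4–7 and 14–17); the invariant G/C positions are
4, 7, 14 and 17 (read by Arg280).

The *code positions* are 3, 8, 13 and 18, immediately flanking the two
cores.  Their base-pair content sets local minor-groove width: G·C pairs
place a 2-amino group in the minor groove and widen it; A/T pairs leave it
narrow.  Two readout channels are computed per RE:

* **minor channel** — count of code positions with a G·C pair (0–4).  It
  predicts the Arg248 binding mode: a narrow groove admits the extended,
  hydrophobic, salt-insensitive conformation; a wide groove forces the
  bent, electrostatic, salt-sensitive one.
* **major channel** — count of code positions presenting a G-like
  major-groove face: G·C *plus* I·C pairs.  It predicts sensitivity to the
  cancer-derived K120R mutation, whose arginine clashes with guanine-like
  faces in the major groove.

An inosine-free RE has identical channels.  An I·C pair is G-like in the
major groove but lacks the minor-groove 2-amino group, so inosine
substitution empties the minor channel while leaving the major channel
intact — the in vitro trick that decouples the two predictions.  In
sequence strings the letter I marks an I·C pair at that position,
whichever strand physically carries the inosine; the channel logic is
pair-level, so nothing is lost.

### Decision thresholds

Channel counts map to labels through two thresholds, `low = 1` and
`high = 3`: counts ≤ 1 give hydrophobic / K120R-bound / pro-survival
tendency, counts ≥ 3 give electrostatic / K120R-unbound / pro-apoptotic
tendency, and a count of 2 is reported as *ambiguous*.  The explicit
ambiguity band reflects the observed split behaviour at count 2 (some such
REs bind the K120R mutant well, others poorly); the package reports the
ambiguity rather than guessing a tie-break.  Both thresholds are
configurable.  `fate_tendency` is a tendency label derived from sequence
only; no claim about cellular outcome is asserted by the code.

## Scanner

The scanner slides every (offset, spacer) window over a contig, extracts
the 20-mer (spacer bases excluded), and counts mismatches against the
consensus via a precomputed per-position rejection table; windows at or
under the tolerance are reported.  Implementation is vectorized (two
10-position running sums combined per spacer); the test suite checks it
against a naive per-window enumeration oracle.  Genomic N matches no
symbol.  The consensus is its own reverse complement, so every hit has a
strand mirror on the same interval; `dedupe` collapses the pair to a
canonical `+` record while keeping distinct offsets.  Default tolerance is
3 mismatches, matching the largest load among the in-vitro-verified
reference REs; there is no principled universal cutoff, so the value is
exposed.  Output is BED6 (0-based half-open; score = (20 − mismatches)/20
× 1000).

## Binding isotherm

Titrations follow the single-site hyperbola

    mP(C) = mP_max · C / (Kd + C) + mP_baseline,

with C the total protein concentration, and percent bound is the linear
rescaling ((mP − baseline)/(max − baseline)) × 100.  Fitting is ordinary
least squares with Kd parametrized as log10 Kd to enforce positivity;
initial values are baseline = min(mP), span = max − min, Kd = the
concentration nearest the half-signal reading.  Confidence intervals come
from the covariance of log10 Kd at the optimum (delta method, ±1.96 SE,
exponentiated).  Non-convergence and flat curves are flagged on the result
rather than raised; a fitted Kd above the largest tested concentration
sets `saturation_reached = False`.  Replicates are averaged on Kd, not on
raw curves.  No ligand-depletion (quadratic) correction is applied: the
probe is 2.5 nM, far below the Kd range of interest; estimates for
Kd ≲ 10 nM will be biased and should not be trusted from this model.  The
salt-sensitivity index Kd(275 mM)/Kd(200 mM) summarises the two-salt
contrast; large values indicate the electrostatic mode, values near 1 the
hydrophobic mode, and no fixed cutoff is asserted.  An undetectable Kd on
either side leaves the index undefined (NaN).

## Groove geometry

Groove widths are direct cross-strand phosphate–phosphate distances
(3DNA-style "direct" widths; the method tag on every profile is
`pp-direct`).  Phosphates are indexed by base pair; a cross-strand pair
(a, b) has midpoint (a+b)/2 and signed separation s = a − b.  At each
inter-base-pair level i+½ the candidate pairs are those whose midpoint
lies within half a step of the level; the canonical minor-groove pair is
s = +3 (the El Hassan–Calladine choice) and with window w = 2 the minor
side admits s ∈ [0, 5], the major side s ∈ [−5, −1] (the in-register
s = 0 pair is assigned to the minor side by convention).  The reported
width is the minimum candidate distance; a level is emitted only when its
whole candidate window has coordinates, so a uniform helix yields a
strictly constant profile and 5′-terminal residues lacking phosphates
simply trim edge levels.  Corrected widths subtract exactly 5.8 Å (two
phosphate van-der-Waals radii); raw values are always reported alongside.

The ideal-duplex builder places P atoms on two coaxial helices (defaults:
twist 36°/bp, rise 3.38 Å/bp, P radius 9.4 Å, inter-strand phase 144°) —
values chosen to give a B-like 10 bp/turn helix whose corrected
minor/major widths (≈5.9 / 11.7 Å) sit at textbook B-DNA values.  It
deliberately models no sequence dependence; it exists to provide exact
geometric ground truth (the cross-strand distance has the closed form
sqrt((s·rise)² + 2r²(1 − cos(s·twist − phase)))), against which the
Cartesian implementation is verified to 1e-6 Å.  Real duplexes are read
from PDB (first model, altloc A, P atoms of DA/DC/DG/DT/DI), paired
antiparallel by index when the two chains have equal length.

## Edit design

`propose_mode_flip` enumerates subsets of the code positions in increasing
size and returns all minimal subsets whose substitution reaches the target
mode on reclassification, ordered lexicographically by position tuple for
reproducibility.  Replacement bases are transitions (G↔A, C↔T), the
convention used by all the designed reference variants, which also keeps
every code position compatible with its consensus symbol (R at 3/13, Y at
8/18).  Non-code positions are excluded by default: positions 12–13 also
sit in the Lys120 contact zone and their contribution outside the code is
not quantified, so the designer does not touch them.  `propose_ic_variant`
replaces selected G·C pairs with I·C (written base becomes I), which by
construction lowers the minor channel and preserves the major channel —
predicted mode shifts toward hydrophobic, predicted K120R sensitivity
unchanged.  Applying a plan re-derives the after-profile from the edited
sequence; it is never copied.

## Synthetic data

Three generators supply every input class with known truth:

* **Labeled RE sets** — G/C code counts drawn from a 5-bucket weight
  vector (default 0.13/0.28/0.37/0.18/0.04, the empirical shape of
  genome-wide p53-bound RE sets); code positions realised
  consensus-compatibly; other positions drawn uniformly from their symbol
  sets; mismatches implanted outside code positions at a per-position rate
  (default 0.05).  Labels are Bernoulli with P(unbound) =
  logistic(−2.5 + 1.25·gc_count), the minimal monotone family consistent
  with the observed trend — roughly 8% unbound at count 0 rising to ~78%
  at count 3 and ~92% at count 4.  The parameters are configuration, not
  estimates fitted to external data.
* **Implanted genomes** — i.i.d. background at a stated G/C fraction
  (default 0.41), implants copied verbatim (strand-aware, non-overlapping)
  with a truth table in scanner coordinates.  The i.i.d. background has no
  dinucleotide structure; it is adequate for scanner calibration but does
  not emulate repeat content or chromatin-shaped sequence bias, so scanner
  false-positive rates on real genomes will differ.
* **Titrations** — the hyperbola plus i.i.d. Gaussian noise.  Defaults:
  12 log-spaced concentrations over 1 nM–1 µM (the titrated range),
  baseline 80 mP and span 170 mP — typical readings for a FAM-labeled
  36-bp dsDNA probe (free ≈ 80 mP, saturated ≈ 250 mP) — and noise sd
  5 mP.  Real curves have correlated, concentration-dependent noise and
  pipetting error in C; neither is modeled.

Passing closed-loop tests on these generators demonstrates algorithmic
correctness under the stated statistical model, not performance on ChIP
catalogs or measured binding data.

## Problem sizes and numerical choices

The test and acceptance runs use: 50 random 2-kb contigs across mismatch
tolerances 0–4 for scanner/oracle equivalence; 10,000 random 20-mers for
reverse-complement invariance; 200 noisy titration replicates for the
median-error check and 500 for CI coverage; n = 5,000 labeled REs for
logistic slope recovery (recovered within a few percent; the check allows
15%).  Entropy uses log base 2 with 0·log 0 = 0 and no small-sample
correction by default.  The Benjamini–Hochberg step in `compare_sets` is
verified against statsmodels; the exact-test layer itself is a convenience
beyond the visual motif comparison it quantifies.  All generators take
mandatory seeds and are bit-reproducible.

## Known limitations

* The classifier is sequence-only; chromatin context, spacer-insertion
  penalties and cooperative effects are out of scope, and count-2 REs are
  reported ambiguous by design.
* Kd estimates below ~10 nM are biased without a depletion correction.
* Groove widths use the direct P–P variant; refined/spline widths and
  base-pair step parameters (roll, twist, propeller) are not computed.
* The ideal duplex carries no sequence-dependent shape, so groove
  comparisons between ideal duplexes reflect only their construction
  parameters.
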