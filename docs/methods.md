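# Methods

This note documents the models implemented in `utrfold`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical and design decisions a maintainer should know.

## Coordinates and formats

All positions are 1-based and inclusive over the analyzed transcript
string.  Transcript-level "+1" numbering is recovered through the
`numbering_offset` annotation; reporter constructs that prepend 45 nt of
promoter sequence use offset −45.  Sequences are RNA internally (T → U on
input); ambiguity codes are rejected because the energy model is defined
only over A, C, G, U.  Missing reactivity is NaN in memory and −999 on
disk (both value columns of `.shape` rows).

## Reactivity calling

Raw reactivity is `rateMod − rateUnt`, the two-condition design without a
denatured control.  Positions with fewer than 4000 reads in either
channel are masked (`low_depth`); masking is never an error.  The median
simulated depth, 20 000 reads, mirrors typical MaP experiments, making
the depth filter and significance thresholds operate in a realistic
regime.

Normalization uses the field-standard 2%/8% rule: unmasked values are
ranked descending, the top 2 % are set aside as outliers, and all values
are divided by the mean of the next 8 %, so the mean of that band is 1
afterwards.  The rule is scale-equivariant and retains negative raw
values (the folding stage decides their pseudo-energy treatment).  At
least 20 unmasked positions are required; all-zero profiles are an error.
The exact normalization used by upstream read-processing tools is not
re-implemented; the 2%/8% rule is this package's documented stand-in and
is swappable in code.

Replicate averaging takes the arithmetic mean and SEM per nucleotide and
masks positions where SEM ≥ 0.5·|mean| (`high_replicate_variability`).
With a single replicate the SEM is undefined and the rule cannot fire;
with mean 0 and positive SEM the rule fires (read as SEM ≥ 0.5·|mean|).
Masks only grow along the pipeline.

Direct reactivity is `ln(rateMod/rateUnt)`, masked at low depth or when
either rate is zero.

## Energy model and folding

The nearest-neighbor parameter set (`src/utrfold/data/energy_params.yaml`)
is deliberately reduced: Watson–Crick + GU-wobble dinucleotide stacks,
hairpin/bulge/internal-loop initiation penalties with Jacobson–Stockmayer
extrapolation (1.75·RT·ln(n/n_max)), and an affine multibranch penalty
(offset 3.4, per-branch 0.4, per-unpaired 0 kcal/mol at 37 °C).  Dangling
ends, terminal-pair penalties, special hairpin sequences, and coaxial
stacking are intentionally absent: the analyses this package supports are
threshold- and ranking-based, and correctness is defined by agreement
with exhaustive enumeration under the package's own tables
(`utrfold.exhaustive`), not by numerical agreement with any external
parameter set.  The tables are versioned data: editing them changes
numbers, never invariants.

Constraints: minimum hairpin loop 3 nt (j − i ≥ 4), maximum bulge/internal
loop 30 nt total, maximum pairing distance 600 nt, nested structures only
(no pseudoknots).  Sequences above 1200 nt are refused: the engine folds
one partition window and does not stitch sliding windows, which is valid
for the ~500-nt constructs this pipeline targets.

SHAPE reactivities enter as pseudo-free energies ΔG_SHAPE(S) =
m·ln(S + 1) + b with m = 1.8 and b = −0.6 kcal/mol, added once per paired
nucleotide per helix stack it participates in (helix-internal nucleotides
twice, helix ends once).  Missing data contributes 0, so folding with an
all-missing profile coincides exactly with unguided folding.
Reactivities ≤ −1 are treated as missing with a warning; values in
(−1, 0) are evaluated as written.  Because the pseudo-energy attaches to
stacks, an isolated (lone) pair escapes it; a large positive term at one
position therefore drives its pairing probability down strongly but not
to exactly zero in the limit.

The MFE fold is a Zuker-style dynamic program (pair matrix, multibranch
matrices with the affine penalty, exterior array).  Pair probabilities
come from the McCaskill inside algorithm plus a full outside pass over
the same decomposition, with uniform per-nucleotide rescaling anchored to
the MFE energy so strongly stabilized 500-nt folds stay inside float64
range.  Inner loops are numpy-vectorized; a 501-nt SHAPE-directed
partition function runs in seconds.

Co-optimal structures: the traceback examines options in a fixed order
(hairpin, bulge/internal, stack, multibranch; unpaired before paired in
the exterior and multibranch arrays), which yields a deterministic
structure biased toward fewer pairs.  It does not globally guarantee the
lexicographically smallest co-optimal pair list — a guarantee that would
require counting DPs out of proportion to its value, since ties are
measure-zero for real-valued reactivities.

## Structure comparison

`delta_shape` smooths both profiles and their standard errors over a
centered window (default 5 nt, NaNs dropped from each window mean) and
tests the smoothed difference twice: a Z-factor
1 − 1.96·(SEM_a + SEM_b)/|μ_a − μ_b| must be positive, and the standard
score of the difference against the distribution of all smoothed
differences must reach |Z| ≥ 1.  A position is called significant only
when at least 3 positions in its window pass both tests.  Excluded
intervals (primer-binding regions) can never be significant.  Swapping
the inputs flips directions but not the significant set.

`sens`/`ppv` compare base-pair sets: sens = |shared|/|reference|,
ppv = |shared|/|model|, "overall similarity" their mean.  Pair sets from
probability matrices use an inclusive cutoff (≥ 0.1 by default).  Empty
sets: an empty reference gives sens 1 only against an empty model
(otherwise 0), and symmetrically for ppv.  `overall_similarity` treats
its second argument as the reference; a symmetrized variant (mean over
both orientations) is available because the reference orientation is a
genuine free choice in this metric.

## Structural landscape

The construct panel is summarized as an all-pairs overall-similarity
matrix (pairs restricted to a region of interest, e.g. the 5′-UTR,
diagonal forced to 1).  Rows are projected by PCA; component signs are
fixed by making the largest-magnitude loading positive so the projection
is deterministic.  k-means (100 restarts, fixed seed recorded in the
output) runs on the 2-D projection by default — the projected landscape
is what the analysis visualizes and groups — with a flag to cluster raw
similarity rows instead.

k is chosen from the inertia curve as the largest second difference of
**log** inertia, with inertia below 10⁻³ of the total clamped as noise.
The logarithmic scale matters: with unbalanced groups (one large
native-like group versus several small ones) similarity-row geometry
makes the large group's separation dwarf the small groups' separations,
and a linear-scale elbow collapses to k = 2.  The log-scale elbow is
scale-invariant and recovers the planted k = 4 on archetype panels with
adjusted Rand index 1.0.  k can always be overridden explicitly.

Group labels are canonicalized by each group's first member in label
order, so the grouping is invariant to construct input order; each
group's centroid construct is the member nearest the group mean in the
projected plane.

## Start-codon accessibility and translation

ΔG‡_unfold = ΔG_constrained − ΔG_reference, where the constrained
structure is the reference minus every pair with **either** endpoint
within ±w nt of the start-codon adenosine (w ∈ 13..16, default 15,
matching the mRNA footprint of the initiating ribosome); the RNA is not
allowed to refold, making this a non-equilibrium cost.  Windows are
clipped at sequence bounds with a warning.  Energies are evaluated
thermodynamics-only by default even for SHAPE-directed references
(pseudo-energies describe the probing experiment, not the unfolding
thermodynamics); both choices are switchable.

Two provable contracts hold and are tested: ΔG‡_unfold ≥ 0 whenever the
reference is the MFE structure under the evaluation energy function (any
pair-deleted structure is a valid competitor, so its energy cannot be
below the minimum), and ΔG‡_unfold = 0 exactly when no pair touches the
window.  Two adjacent-looking claims are **not** theorems and are
documented as such: with SHAPE-directed references evaluated
thermodynamics-only, ΔG‡ ≥ 0 holds empirically on this pipeline's
outputs but can in principle fail; and ΔG‡ is not monotone in w — widening
the window removes a superset of pairs (that is monotone), but deleting
the last pairs of a helix fragment can remove a heavily penalized loop
and lower the constrained energy.  The window sweep exists precisely to
check robustness of conclusions to w.

Relative translation: per-replicate NL/FF ratios, construct mean divided
by the native construct's mean, SD propagated across replicate-level
relative values; native ≡ 1.  Replicates with non-positive firefly signal
are dropped with a warning.  Effects are classified at 15 %: relative
≤ 0.85 is a decrease, ≥ 1.15 an increase, the boundary counting as an
effect.  Group comparisons use Welch's two-tailed t-test by default
(group sizes and variances differ between structural groups; Student's
variant available), with degenerate zero-variance cases handled
explicitly (identical groups → t = 0, p = 1).

The uORF scanner reports every AUG or near-cognate (default CUG; GUG,
UUG, ACG optional) start strictly 5′ of the annotated main start whose
in-frame stretch to the first stop reaches 30 nt (start codon through the
last pre-stop nucleotide; stop-less stretches are flagged), noting the
efficient "CUG/G" context.

## Synthetic data: what it does and does not emulate

The generators reproduce the study conditions: 6-nt UUAUUA windows tiled
over positions 1..region_end (42 mutants for a 252-nt region, named
6..252 by 3′-most substituted position; region_end is a parameter, not a
constant, because the panel boundary is construct-specific); random
G/C-rich sequences (58 % G+C); binomial per-read MaP counts at 20 000×
depth with per-read modification probabilities 0.002 (background),
0.004 (paired) and 0.03 (unpaired) — chosen to put the simulated rate
separation in the regime where the depth filter and significance
thresholds are meaningful, and documented as tunable rather than
measured; 43-construct archetype panels (native + 25 native-like, 17
split 6/6/5); and translation panels exp(−β·ΔG‡_unfold)·LogNormal(0, σ)
with β = 0.1, σ = 0.1 and n = 6 replicates (two plasmid × three
biological).

Not emulated: read-level artifacts (alignment, PCR/UMI errors, mutation
classification), reagent chemistry differences, pooled-barcode
deconvolution, cellular context (protein binding, ribosome-induced
unfolding), and real thermodynamic parameter uncertainty.  Passing
recovery tests therefore demonstrates that the pipeline's inference is
correct when the measurement model holds — not that the measurement model
captures every property of real probing data.

## Problem sizes

Validation suites run at sizes chosen to make the checks exhaustive
where possible: folding is compared against complete structure
enumeration on 500 random sequences of length ≤ 12 (where enumeration is
exact and fast); end-to-end probing recovery uses ~100-nt planted
three-hairpin RNAs; landscape recovery uses the full 43-construct panel;
translation-coupling recovery uses 43 constructs and 100 independent
noise draws.

## Known limitations

* The reduced energy model ranks structures sensibly but its absolute
  kcal/mol values are not comparable to full Turner-2004 predictions.
* No pseudoknots, suboptimal sampling, or temperature scanning.
* k-means input-order invariance is guaranteed by canonical relabeling
  only when the underlying partition is stable across restarts, which
  holds for well-separated landscapes.
* The ΔSHAPE-style defaults (window 5, Z-factor > 0, |standard score| ≥ 1,
  ≥ 3 of 5) are exposed as parameters; sites near the profile ends use
  truncated windows.
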