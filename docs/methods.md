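# Methods

## The measurement model

Sequencing an equimolar pool of n known species to depth D should, absent
bias, give every species D/n reads (10⁶/n CPM). Deviations are quantified
per species as Δlog₁₀CPM = log₁₀(CPM + pc) − log₁₀(10⁶/n), with the
pseudo-count pc = 0.5 CPM (a half count at a depth of one million) keeping
zero-count species finite. Replicates are averaged on the log₁₀ scale
before modeling. Note the pseudo-count enters only the observed side of
the error, so a dropped-out species scores exactly log₁₀(pc·n/10⁶), while
log₂ RMSE applies it to both sides so that a perfect table scores exactly
zero; the two conventions differ by at most log(1 + pc/expected), which is
negligible at realistic depths.

The model assumes end biases are *terminal and log-additive*: the error of
a species depends only on its first three and last three bases, one-hot
encoded into 24 indicators (positions +1, +2, +3, −3, −2, −1 × bases
A, C, G, T/U). A random-forest regressor maps these indicators to the
error. The forest is deliberately low-assumption — it captures
interactions between end positions without a parametric form — and with a
fixed seed its refits are bit-identical.

Forest configuration: 500 trees, one-third of the features considered per
split, unlimited depth, default seed 20190528. These are the canonical
regression-forest defaults; results are insensitive to moderate changes.

Correction subtracts the predicted error on the log₁₀ scale and returns
non-integer pseudo-counts; optionally the corrected column is renormalized
to CPM. In-sample correction is the default (the proof-of-concept mode);
`cross_validate` exposes out-of-fold predictions that `correct_counts`
accepts directly for self-fit-free correction (`--cv-correct` in the CLI).

## Evaluating the model

Training R² measures how much of the observed error variance terminal
features absorb. Generalization is assessed by shuffled 8-fold
cross-validation: every species is held out exactly once and scored by
out-of-fold R². The specificity control refits the identical pipeline on
*internal* positions (+4..+6 and −6..−4); since the simulator's biases are
purely terminal, this control should learn nothing.

A caution that shaped the test design: for a full-depth forest the control
must be judged out-of-fold. With ~10³ mostly unique internal hexamers the
forest can isolate nearly every species in its own leaf and reproduce the
training errors verbatim, so an in-sample control R² is close to 1 by
construction and meaningless. Out-of-fold, the same control scores slightly
*below* zero (≈ −0.1 to −0.3): an interpolating forest adds prediction
variance that is uncorrelated with held-out noise. "No signal" therefore
means "out-of-fold R² not meaningfully positive", a one-sided criterion,
not a two-sided band around zero.

Position-level importance sums the four base-indicator impurity
importances per position and normalizes; the 5′ share is the sum over
{+1, +2, +3}. Impurity (variance-reduction) importance matches the default
of the classical random-forest implementations.

## The simulator

`simulate_pool` draws n unique sequences (default 962, the size of the
commercial equimolar miRNA reference set) with i.i.d. uniform bases and
lengths uniform on 19–25 nt, the mature-miRNA size range. `simulate_counts`
samples species with probability p_m ∝ 10^(Σ effects + slope·length) and
draws multinomial counts at a fixed depth (default 10⁶, making counts and
CPM commensurate); technical replicates are independent draws from the
same p, mimicking the near-perfect replicate correlation of real runs.
The truth Δlog₁₀CPM is log₁₀(p_m·n).

The canned `BiasSpec.tgirt_like` encodes the qualitative bias structure of
a template-switching library with single-stranded adapter ligation:
favored 5′ +1 U, +2 G, +3 G with A disfavored at all three (±0.25, ±0.25,
±0.20 log₁₀), a dominant 3′ terminal preference for G over U (±0.45), and
minor −2/−3 effects (±0.10). The magnitudes were chosen once so the
terminal base dominates and the 5′/3′ importance split lands near 40/60,
the regime reported for such libraries; they are study conditions, not
tuning knobs. What the simulator deliberately omits: internal-sequence and
structure effects, PCR duplicates, adapter-dimer reads, cross-mapping
between near-identical species, and concentration-dependent behavior of
biological samples. Passing tests therefore demonstrate that the estimator
recovers the model it assumes — terminal, log-additive bias — not that
real libraries obey that model; applying the corrector to biological
samples requires parallel validation.

## Normalization and summaries

CPM divides by the column total × 10⁶; "median normalization" is the
median-of-ratios construction against a geometric-mean pseudo-reference,
with species having any zero count excluded from the size-factor estimate
(the standard construction, which degenerates correctly on proportional
samples). Errors and correction use log₁₀; ECDF and RMSE summaries use
log₂, following small-RNA benchmarking convention. Representation labels
use a k·SD rule on the error distribution (k = 1 for bias analysis, k = 2
for outlier factor analysis); the labels are invariant to the log base as
long as it is applied consistently.

The end-frequency profile reports observed (abundance-weighted) and
reference (uniform) base frequencies per position and their ratio, so the
no-bias baseline is 1 everywhere. The PCA of end features centers but does
not rescale the one-hot columns: the columns share units, and rescaling
would inflate rare-base positions.

## Saturation curves and rank statistics

Saturation curves shuffle the observed read multiset (seeded, without
replacement), consume it in bins of 200 reads, and report after each bin
how many species have reached 10 cumulative reads, truncated at 3 million
reads. This is the desk-scale analogue of subsampling a library file.

Outlier factor tests compare over- (and under-) represented species
against the rest by two-sided Mann–Whitney tests on six factors: length,
GC fraction, self-fold score, adapter/cDNA co-fold score, and free 5′/3′
end counts. Exact enumeration is used for tie-free groups of ≤ 20,
midrank normal approximation otherwise.

## Folding proxies

Fold factors only enter rank comparisons, which are robust to any monotone
transformation of a stability score. The built-in proxy therefore
maximizes base pairs rather than computing free energies: the self-fold
score is the Nussinov maximum over non-crossing Watson–Crick + GU pairings
with a minimum hairpin loop of 3, and the free-end counts are the
consecutive unpaired terminal bases in one deterministic maximal traceback
(ties broken toward pairing terminal bases). The co-fold score is the
maximum non-crossing antiparallel pairing between the ligating adapter and
the species' cDNA (reverse complement), an LCS-style recursion. A
thermodynamic engine can be plugged in through the provider protocol;
proxy outputs are pair counts and are labeled as such.

## Overhang design and the adapter screen

The compensating 3′-overhang mix multiplies each overhang weight by
expected/recovered for the RNA 3′-base class it captures (dA↔U/T, dC↔G,
dG↔C, dT↔A), clipping the ratio at 10 for unrecovered classes and
renormalizing. This first-order proportional rule is advisory — the
published compensating mix (A:C:G:T = 6.6:0.4:1:1, preset `NTTR`) was
found by titration, not formula — but it is idempotent at the fixpoint and
monotone in the recovery, and closing the loop in the simulator moves the
3′ composition toward the reference. The adapter-dimer screen applies the
single rule with biochemical support: the ssDNA ligase's acceptor
preference at position −3 (A/C high, G medium, T/U low propensity).

## Degenerate inputs and numerical choices

All-zero sample columns, empty subsets, zero-spread error vectors,
constant training targets, unrecovered trinucleotides, and undefined
correlations of constant columns each either raise with the offending
name or warn and return the defined fallback (documented per function).
Trinucleotide reweighting clips weights to [0.1, 10] and rescales each
column to preserve its total abundance. Alignment counting treats a read
as unique if NH == 1 when the tag is present, else MAPQ ≥ 5, counts
primary alignments only, and measures length as the aligned query
(soft-clips excluded), targeting the insert rather than adapter remnants.

## Problem sizes

Tests and the acceptance script use the full study geometry — 962 species,
depth 10⁶, three replicates — for the headline checks, with smaller pools
(n = 200–400) for unit-level simulation tests; convergence checks contrast
depths 10⁵ and 10⁷ on a 200-species pool. These sizes make every
stochastic assertion comfortably stable under the fixed seeds.
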