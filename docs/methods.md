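# Methods

This note records the models, conventions, and numerical choices behind
`polyhic`, and what the synthetic studies do and do not establish.

## Analysis conventions

**Coordinates.** 0-based, half-open throughout; bins are identified by
their start coordinate; overlap means ≥ 1 bp.

**Balancing.** Iterative correction (ICE) per chromosome on the symmetric
count matrix. Bins with zero coverage, or whose log10 marginal falls more
than `mad_max` (default 5) robust SDs below the chromosome median, are
masked. Iteration stops when the coefficient of variation of the balanced
marginals drops below `tol` (default 1e-5; the test suite checks < 1e-4);
weights are scaled so balanced marginals converge to 1, which makes the
procedure scale-invariant (counts × c ⇒ weights × c^−1/2, O/E unchanged).
Masked bins propagate as missing through every downstream statistic; they
never contribute zeros.

**Observed/expected.** expected(s) is the mean balanced signal over all
unmasked pairs at bin distance s, per chromosome, zeros included; O/E is
balanced/expected. By construction the per-diagonal O/E mean is exactly 1,
which the suite asserts to 1e-6.

**Compartments.** First eigenvector of the Pearson correlation of the O/E
matrix per chromosome at 250 kb; sign fixed per chromosome by positive
correlation with an orientation track (active-mark coverage in the
pipeline; planted labels in tests); A = positive. Compartment strength is
log2(mean O/E(AA) × mean O/E(BB) / mean O/E(AB)²) over pixels > 2 Mb
apart, restricted to the top-quantile (default 0.2) most extreme
eigenvector bins per class — a saddle-style convention chosen because the
robust "strength" benchmarks in the field use extreme bins rather than all
bins; the formula itself is unit-tested against a forced O/E pattern
(AA = BB = 2, AB = 0.5 ⇒ strength = 4).

**RCP.** Raw (unbalanced) counts with per-pair normalisation in log-spaced
distance bins, normalised to sum 1 over the analysed range — RCP predates
balancing in the standard toolkits and raw counts keep the comparison
independent of the balancing model. Range ratios are log2 of summed
probabilities; the decay exponent is the least-squares slope of log10 RCP
vs log10 distance over 100 kb–5 Mb.

**Insulation.** Score of bin b = log2(mean balanced signal in the w × w
square [b−w, b−1] × [b+1, b+w] / chromosome mean of such square means);
10 kb bins with a 250 kb window by default — the reading that reconciles
"10 kb resolution" with "250 kb bins", both exposed as knobs. More
negative = more insulating. Differential eligibility: both scores defined
and min(score_WT, score_KO) < −0.2 (the score floor). The stricter
"exclude scores above −1" filter subsumes the floor as written, so it is
exposed as an optional `exclude_above` cutoff, off by default. Gain means
KO more insulating: Δ = KO − WT ≤ −0.2; loss Δ ≥ +0.2; swapping conditions
provably swaps the labels. Adjacent same-category bins merge into regions.

**Pileups.** Mean O/E submatrix over items; 105 kb window at 5 kb
resolution ⇒ 21 × 21 (the window must span an odd bin count). Central
enrichment = mean of the central 3×3 over the mean of the two off-loop
6×6 corners (toward and away from the diagonal); the paper-style figures
print enrichment without a formula, so this is a documented convention and
the stored submatrix allows recomputing alternatives. Aggregate TADs are
rescaled with 50% flanks to a fixed grid by block-mean resampling
(identity when sizes already match). Boundary violation reports mean
inter-TAD O/E pooled over all TAD pairs at separation n.

**Gene and loop classes.** A TSS is NMI iff a BioCap peak overlaps
[TSS−3 kb, TSS+3 kb). Among NMI TSSs: RING1B ∧ SUZ12 ⇒ PRC1/PRC2 target;
RING1B only ⇒ vPRC1 target; no RING1B ⇒ non-PcG (SUZ12 without RING1B is
non-PcG: every PcG class requires PRC1 occupancy); non-NMI ⇒ other. The
four classes partition the gene set. A loop is PcG iff RING1B overlaps
*both* anchors (the symmetric, stricter reading; a single-anchor switch is
provided), and PRC1/PRC2 iff both anchors additionally carry a PRC1/PRC2
TSS within the 3 kb window. A PRC1/PRC2 loop is "up" iff ≥ 1 anchor
harbors an upregulated PRC1/PRC2 gene — one derepressed anchor suffices,
matching the observation that usually only one anchor loses silencing —
"na" (excluded) when neither anchor carries any classified gene. TADs
traversed counts TADs strictly between the anchor midpoints whose majority
compartment label matches the loop's. Distances are bp to the nearest
covered base (0 inside a region). All interval predicates are
property-tested against brute-force all-pairs oracles.

**Spike-in calibration.** factor_i = min_j(spikein_j)/spikein_i — scale
every sample down to the smallest spike-in depth (the standard convention;
the source protocols do not print the formula) — applied by binomial
subsampling. Factors are scale-invariant and max to 1.

**Differential expression.** Deliberately a stand-in, not a reimplementation
of a full negative-binomial framework: genes with total count < 10 are
excluded; counts are normalised by median-of-ratios size factors; a Welch
test on log2(normalised + 0.5) with empirical-Bayes variance moderation
(per-group variances shrunk toward the across-gene mean with prior df 20,
in the limma spirit — plain Welch at n = 3 is underpowered for 2-fold
effects at NB dispersion 0.1) and Benjamini–Hochberg adjustment; status
up/down iff padj ≤ 0.05 and |LFC| ≥ 0.5. Setting `prior_df=0` recovers
plain Welch. An externally computed DE table with the same columns can be
used instead wherever fidelity matters.

## The synthetic study

The generator is the package's test bed: it emulates the *structure* of a
two-condition Hi-C + ChIP + RNA-seq study with known truth, not any real
dataset. Expected counts for pixel (i, j), i < j:

    lambda_ij = depth * nu_i * nu_j * d^(-alpha) * C_ij * T_ij * L_ij / Z

with per-bin log-normal visibility nu (sd 0.1), decay exponent alpha = 1,
compartment factor C (gamma_comp for same-label pairs, 1/gamma_comp
otherwise; WT 1.4, KO 1.15), TAD factor T (gamma_tad = 2 within a TAD;
`leak` for inter-TAD pairs — WT 1.0, KO 1.5), loop factor L (Gaussian
bump, height = amplitude, sigma = 1 bin), and Z normalising each
chromosome to `depth` (1e7). Pixels are independent Poisson draws of the
upper triangle; the diagonal and trans contacts are excluded.

Shape choices that matter:

- **Distance gating.** The compartment factor is a long-range phenomenon;
  it ramps in linearly around 2 Mb (width 1 Mb). The inter-TAD leak fades
  out around 4.5 Mb (finite extrusion processivity), so the > 5 Mb regime
  is leak-free. Hard cutoffs would put O/E steps inside pileup windows and
  bias enrichment ratios; the ramps keep factor gradients negligible
  across a 21-bin window.
- **Heavy-tailed sizes.** TAD sizes are lognormal(0, 1)-weighted with a
  250 kb minimum (80 per 40 Mb chromosome, median ≈ 400 kb), and
  compartment blocks are 0.8 Mb + Exp(1.5 Mb). Realistic tails are also
  functionally necessary: same-TAD pixel pairs must exist at multi-TAD
  distances for the boundary-violation statistic to register leak against
  the per-distance expected, and block-length variance must decorrelate
  compartment labels at long range (quasi-periodic blocks make weakened
  compartments *gain* long-range contacts through anti-correlated A/B
  phasing).
- **The KO perturbation.** KO uses its own boundary set (WT boundaries
  minus `n_removed_boundaries`, plus one ectopic boundary planted 200–500 kb
  inside each ultra-long loop from its "up" anchor), reduced gamma_comp,
  increased leak, and a local 3× contact depletion across each ectopic
  site (±500 kb) — the ectopic site is a *strong new insulation site*, not
  ordinary leak, otherwise the planted gain is sub-threshold by
  construction. Ultra-long loops (span ≥ 10× the median TAD, ≈ 4–5.6 Mb)
  are attenuated to 0.3× their WT amplitude in KO; all other loops are
  condition-independent. Genes at the up anchors carry a planted
  LFC of 3 (strong derepression, as at showcase loci); all other genes 0.
- **Calibration.** Depth 1e7 per chromosome and 20 Polycomb loops (6
  ultra-long) per chromosome were fixed once so that the pileup contrasts
  are measured with ~15% relative sampling error rather than drowned — at
  few-Mb separations the per-pixel intensities are fractions of a count
  and aggregate statistics over a dozen loops need that depth. Feature
  geometry guarantees the classification round trip: peaks are 2 kb,
  centred on bin midpoints, and gene bins are spaced so a ±3 kb window
  never reaches a neighbouring gene's peaks (one bin at ≥ 10 kb bins).
- **Determinism.** Every sampler takes an explicit seed; condition and
  chromosome indices are folded into independent generator streams; no
  global random state is used anywhere.

What passing the synthetic suite shows: the estimators recover planted
compartments, boundaries, differential insulation, loop attenuation and
expression coupling at realistic depths, with the documented thresholds,
and all interval logic is exact. What it does not show: robustness to
features of real Hi-C the forward model omits — restriction-fragment
geometry, ligation artefacts, copy-number and mappability structure beyond
smooth visibility, trans contacts, condition-specific library biases, and
TAD/loop calls that disagree with the intervals supplied (TAD and loop
*calling* is out of scope; interval files are inputs).

## Degenerate inputs and tie-breaks

Duplicate COO pixels are summed with a warning; input may be in either
triangle. Zero-depth simulation returns an empty matrix with a warning;
balancing an empty matrix is an error, non-convergence raises with the
last marginal CV. Distances with no unmasked pairs have undefined expected
values and propagate NaN. Chromosomes shorter than the insulation window,
or with fewer than 10 unmasked compartment bins, are skipped with
warnings. Loops whose pileup window leaves the chromosome are skipped and
counted; a group with no usable loop is dropped from the pipeline bundle
with a warning. Anchors in different compartments take the label covering
more of the span and are flagged. Equal-eigenvector ties in the strength
quantile resolve by stable argsort order.

## Problem sizes

The default study is two 40 Mb chromosomes at 10 kb bins (8,000 bins),
compartments at 250 kb, 1e7 cis contacts per chromosome — the scale at
which all planted effects are comfortably detectable and a full
comparison, including balancing both conditions, runs in about a minute on
one CPU. Dedicated studies use a single 40 Mb chromosome (decay exponent,
insulation recovery), twenty replicates of a 250 kb-resolution genome
(compartment strength ordering), and 2,000 genes × 3 + 3 replicates at NB
dispersion 0.1 (DE power).
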