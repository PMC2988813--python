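# Methods

`rbpscreen` re-implements, as a tested library, the computational analyses
of a protein-microarray screen for RNA-binding proteins (RBPs) in budding
yeast and its downstream target analyses. This note documents the models,
the statistical procedures, the tunable parameters, and the design choices
made where conventions were genuinely open.

## Binder selection from protein microarrays

A protein microarray spots ~4,000 purified proteins in duplicate; probing
with fluorescently labeled RNA yields, per protein and channel, a
background-subtracted median intensity (possibly negative). Duplicate
spots are averaged arithmetically after removing control features and
spots with negative quality flags (GenePix convention: flag < 0 is a bad
spot; the retention rule is flag ≥ 0).

**Z-score mode** (single-RNA probes). Per array,
`Z_i = (x_i − center) / SD` with the sample SD over all finite values and
`center` the array median by default. A protein is a binder when
`Z > z_threshold` (default 3.5) in every replicate. The center is
configurable to the mean because both conventions appear in practice for
this kind of screen; running in mean mode emits a warning. The reported
per-protein score is always the replicate-mean Z.

**Rank mode** (complex RNA pools, where absolute intensities are poorly
reproducible between replicates). Each array's signals become ascending
tie-averaged percentile ranks in (0, 1] (rank / count of finite values, so
the maximum maps to 1.0); the per-protein *median* rank across replicates
is the selection statistic. If some proteins are consistently highly
ranked, the distribution of median ranks is bimodal — a broad background
mode (the median of k i.i.d. uniform ranks concentrates near 0.5) and a
high mode near 1 — and the trough between the modes is a conservative
selection cutoff: `median_rank > cutoff` selects binders (strictly
greater).

**Trough detection.** The published analyses picked the trough by visual
inspection; here it is automated. The median ranks are histogrammed
(default bin width 0.01), lightly smoothed with a 5-bin moving average to
suppress Poisson noise, and the cutoff is the bin in the search interval
(default [0.5, 1]) maximizing the *relative* valley depth
`1 − c(b) / min(max count left of b, max count right of b)`. A literal
"lowest bin between the two highest local maxima" rule is not robust when
a component of the mixture is flat — the two tallest raw maxima then often
fall inside the same component and the rule returns a noise dip — whereas
the deepest relative valley provably prefers a genuinely empty gap. Tied
deepest bins (an empty gap) resolve to the central bin of the tied run. A
valley is only accepted if its bin holds fewer than half the count of the
smaller flanking mode; otherwise the distribution is treated as unimodal
and a `cutoff_override` must be supplied (the override also reproduces
published manually chosen cutoffs exactly). Fewer than 100 median ranks
also require the override.

**Missing data.** Per-array ranks of missing measurements stay missing;
proteins with data in fewer than `min_presence` (default 50%) of the
replicates are excluded from the profile and reported. Missing values are
never imputed as zero.

## RIP-Chip target calling

Transcripts co-purifying with a tagged protein are identified from
two-color log2 ratios (isolate/extract) of a few affinity isolations
(typically 3) versus several mock isolations from untagged cells
(typically 5). QC: a spot is masked unless its extract-channel
signal-over-background is strictly above 1.8, and a feature is kept only
with data in strictly more than 60% of the arrays.

Each feature is tested with a regularized t-statistic in the Cyber-T
style: the per-group variance is shrunk toward a local prior estimated
from features of similar mean signal,

    sigma_hat^2 = (nu0 * sigma0^2 + (n − 1) * s^2) / (nu0 + n − 2),

where `sigma0` is the mean sample SD in a sliding window of `w` features
(default 101) over features sorted by group mean, with windows clamped at
the sorted ends so every window has exactly `w` members, and `nu0`
(default 10) is the prior weight. The statistic is
`t = (mean_IP − mean_mock) / sqrt(v_IP/n_IP + v_mock/n_mock)` referred to
Student's t with `df = n_IP + n_mock − 2 + 2*nu0` (the prior-augmented
degrees of freedom; configurable to the plain `n_IP + n_mock − 2`).

`nu0 = 0` is the "prior off" switch and uses the plain per-group sample
variances, making the statistic exactly the ordinary Welch-style
two-sample t; note the shrinkage formula itself does not reduce to the
sample variance at `nu0 = 0` (it would give `(n−1)s²/(n−2)`), so the
switch is explicit rather than a limit of the formula.

A feature is a target when its fold change `2^(mean_IP − mean_mock)`
(i.e. the geometric-mean convention on ratios) is ≥ 3.0 **and** p < 0.01.
Features with fewer than two post-QC values in either group are excluded
and reported. The original hyperparameters of the published analysis are
unknown; the defaults follow common Cyber-T practice, and the validation
surface for this stage is oracle equivalence plus spike-in recovery, not
bit-reproduction of any particular published target list.

Under a homoscedastic null the shared variance prior makes the calls
slightly conservative at the 1% level (~0.9% empirical false-positive
rate) and correlates features within one dataset; calibration tests
therefore check the nominal level within three binomial standard errors
per dataset, robustly over several independent datasets.

## Term enrichment

Over-representation of GO terms (process/function/compartment) or Pfam
domains in a gene sample is tested with the exact hypergeometric upper
tail `P(X ≥ k)` for a term with `K` carriers in an explicit universe of
size `N` and `k` carriers in a sample of size `n` (scipy's log-space
survival function; stable for universes of ~10^4 genes). Only terms with
at least one sample hit are tested; the Bonferroni multiplier is the
number of tested terms in the namespace, and the universe (all proteins
on the array for domain tests; all features with array data for RIP-target
GO tests) is always explicit and logged. Published annotation-dependent
counts are not reproducible without the original annotation versions, so
the enrichment machinery is validated against enumeration oracles and
null calibration instead.

## Overexpression profiling and target shift

Replicate overexpression/control log2 ratios are QC-filtered (S/B
strictly above 2.0 in both channels; regression correlation of the
two-color spot fit on the kept side of 0.6 — the conventional direction
keeps well-correlated spots, but the opposite reading is available as a
config flag because the filtering description is ambiguous), then
summarized per gene: mean log2 ratio, fold change `2^mean`, and a
two-sided one-sample t-test of mean log2 = 0 (df = n−1). A gene with zero
replicate variance and nonzero mean is reported at the p→0 limit with a
`zero_variance` flag rather than silently; the all-zero case is untested.
Changed genes require p < 0.05 and fold ≥ 1.5 (up) or ≤ 1/1.5 (down,
reciprocal symmetry).

The target-shift analysis compares a protein's experimentally defined
target set against all non-targets: the two-sided Mann-Whitney U test on
per-gene mean log2 ratios, and the *arithmetic* mean of per-gene linear
fold changes as the headline effect size (the back-transformed
`2^(mean of mean-log2)` is also computed, since either convention is
defensible for a printed "mean fold change"). Over-representation of
targets among down-regulated genes uses the two-sided Fisher exact test
(probability-mass convention). Mann-Whitney p-values are exact whenever
both groups have ≤ 50 members with no ties, otherwise the tie-corrected
normal approximation.

## Expression compendium

Gene expression profiles across conditions (RMA-scale log expression) are
clustered with K-means — Lloyd's algorithm, Euclidean distance, k-means++
seeding, 25 restarts keeping the lowest within-cluster sum of squares
(scikit-learn's implementation; deterministic for a fixed seed). The
ambiguity of "clustering across conditions" is resolved as clustering
*genes* by their condition profiles, matching gene-wise heatmap rows.
Cluster structure is reported as sizes and centroid ranges rather than a
rendered heatmap. Expression-level comparisons between gene classes use
per-gene medians across conditions and the two-sided Wilcoxon rank-sum
test; the classes must be disjoint.

## Synthetic data

The generators produce every input the pipeline consumes, with ground
truth, at the study's operating points:

- **Protein arrays** (`gen_protoarray`): non-binders draw i.i.d.
  log-normal intensities (log-mean 6, log-SD 1 — strictly positive,
  right-skewed, the standard fluorescence noise model); binders are
  injected *by rank*, at quantile levels drawn uniformly above
  `binder_rank_floor` of the background law, fixed per binder and
  re-noised multiplicatively per replicate and duplicate spot. The floor
  is a quantile of the *background* distribution: with binder fraction B
  the weakest binder's realized full-array percentile rank is
  ≈ `floor·(1−B)`, since the binders themselves occupy the top ranks (a
  floor interpreted on the mixed array would be unsatisfiable for
  B > 1 − floor). Rank injection, rather than an additive effect, is used
  because the selection statistic is rank-based.
- **RIP-Chip** (`gen_ripchip`): non-target log2 ratios ~ Normal(0,
  noise_sd) in both groups; targets shifted by `log2_enrichment` in the
  IP group; a configurable fraction of spots receives sub-threshold S/B
  to exercise QC. Defaults mirror the study design: 3 IP vs 5 mock
  arrays, 4-fold enrichment, noise SD 0.4.
- **Overexpression** (`gen_overexpression`): non-targets centered at
  log2 0, targets at log2(0.925), the driver gene at log2(4.2), three
  replicates with noise SD 0.2 — the published effect sizes used as
  simulation parameters.
- **Compendium** (`gen_compendium`): 10 equal blocks of genes, block
  centroids ~ Normal(baseline 8, separation²) per condition, unit noise;
  164 genes × 247 conditions by default.

All randomness derives from one integer seed through
`numpy.random.SeedSequence` substreams; identical calls are
byte-identical. The generators do **not** model spatial artifacts, dye
bias, probe-sequence effects, cross-hybridization, or correlated
biological variation between replicates — so passing spike-in tests
demonstrates that the statistics recover truth under idealized noise at
the stated effect sizes, not that real arrays would behave as cleanly.
One consequence: with every target at a subtle 0.925-fold mean shift and
no other perturbed genes, essentially nothing crosses the 1.5-fold
changed-gene threshold, so the changed-gene/Fisher layer is validated by
its enumeration oracle rather than by this simulation.

## Problem sizes and numerical choices

Simulation-based checks use 2,000-protein arrays (5 replicates), 6,000
feature RIP datasets (20 seeds for recovery averages), 6,000-gene
overexpression profiles, and the 164 × 247 compendium — sizes chosen to
match the real data's order of magnitude while keeping the full test
battery fast. TSV round-trips write 17 significant digits and parse with
round-trip float precision, so finite values survive bit-exactly.
Percentile ranks use average ranks for ties (keeps rank sums exact).
Degenerate inputs raise typed errors (zero-variance arrays, unimodal
histograms, empty groups) rather than returning silently wrong numbers.

## Known limitations

- Published target lists cannot be reproduced exactly: the original
  regularized-t hyperparameters, annotation versions, and enrichment
  universe conventions are not fully recoverable.
- The trough detector assumes one dominant valley in the search interval;
  heavily multi-modal rank distributions need a manual override.
- The enrichment module does no GO-DAG propagation beyond what the
  annotation table already encodes.
- The rank-mode screen treats channels independently; channel cross-talk
  is not modeled.
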