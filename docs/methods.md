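# Methods

## The model

R_XY compares the expected probability of sampling an allele private to one
population versus the other. At site *i*, given allele count `d` out of `n`
sampled haploid genomes per population, the probability of drawing the allele
from one random genome of X but not from one of Y (averaging over pairs of
draws, populations sampled independently) is `(d_Xi/n_Xi)(1 − d_Yi/n_Yi)`.
Summing over sites gives `L_X,notY`, and `R_XY = L_X,notY / L_Y,notX`. Whether
`d` counts derived or non-reference alleles is left to the caller — the
arithmetic is identical, only the interpretation changes. Sites monomorphic
absent in both populations contribute 0 to both sums and are retained, which
keeps L exactly additive over any partition of sites; per-site sample sizes
may differ (missing data), since the formula is per-site.

Category comparisons use the standardised form: the focal category's R_XY
divided by a neutral category's R_XY (multiplicative, so a focal class under
the same average selection as the neutral class gives exactly 1). The
standardisation is recomputed *inside every resample* — both the focal and
neutral L sums are restricted to the resampled loci — so resampling
uncertainty propagates through the standardisation.

## Blocks

Loci in physical linkage share evolutionary history, so the resampling unit
is a contiguous block of loci, never spanning a chromosome boundary. Two
dialects are provided:

- `partition_equal_count(sites, g)` (default g = 100): blocks of roughly
  equal locus count. Blocks are apportioned across chromosomes by the
  largest-remainder rule proportional to per-chromosome locus counts, each
  chromosome receiving at least one block; remainder ties break toward the
  chromosome with more loci, then lexicographic label order. Within a
  chromosome, sizes differ by at most one (earlier blocks take the extra
  locus). Deterministic by construction.
- `partition_by_chromosome(sites)`: one block per chromosome.

Blocks are defined by locus count, not physical or genetic distance; there is
no established guidance on optimal block definition, so g is a user
parameter. Centimorgan- and fixed-bp-based blocks are out of scope.

## Resampling estimators

With g blocks of m_j loci (n total), full-data estimate θ̂ and
leave-one-block-out estimates θ̂₋ⱼ:

- **Weighted block jackknife** (the recommended jackknife):
  `θ̂_wbj = g·θ̂ − Σ_j (n − m_j)·θ̂₋ⱼ / n`,
  `SE_wbj = sqrt((1/g)·Σ_j ((n − m_j)/m_j)·(θ̂ − θ̂₋ⱼ)²)`.
  The SE deviance is centred on θ̂, not on the mean of the θ̂₋ⱼ; for
  nonlinear statistics the two centrings differ slightly. The θ̂-centred form
  is implemented as printed in the population-genetics usage this package
  follows; the alternative centring is noted here but not implemented. For
  singleton blocks and the mean statistic both equations collapse to the
  classical delete-one jackknife SE `sqrt(((n−1)/n)·Σ(x₋ⱼ − x̄)²) = s/√n`
  (tested to 1e-12), and for linear statistics with equal blocks the weighted
  estimate returns θ̂ exactly.
- **Block bootstrap**: each replicate draws g block indices uniformly with
  replacement and concatenates their loci (block-level resampling; the w_b =
  total-loci weight compensates for uneven resample sizes). The summary is
  the weighted mean and weighted (population-form) SD of replicate
  statistics. Default B = 1000, with B ∈ {100, 500, 1000} exposed for
  stability assessment. Replicate b's draw derives from the seed pair
  (seed, b), so results are order-independent and any replicate is
  individually reproducible. A replicate on which the statistic is undefined
  (zero denominator) is dropped and counted; the jackknife, by contrast,
  aborts on an undefined leave-one-out replicate, because its equations
  require exactly g values.
- **Naive pseudo-value SD** (retained only to demonstrate the misuse): the
  mean and raw sample SD of the θ̂₋ⱼ. For near-linear statistics this
  underestimates the SE by ≈ √g/(g−1). Every result carries a
  machine-readable `known-biased` flag, the pipeline emits a warning, and the
  CLI requires an explicit `--naive-pseudovalues` opt-in.

The bootstrap stability diagnostic (`bootstrap_cv_trace`) reports, for each
prefix length b ≥ 10, the coefficient of variation of the running SE
estimate: the SD over the last (up to) 10 prefix SE estimates divided by
their mean, defined as 0 when that mean is 0. The trace flattening toward 0
indicates B is sufficient. The window-of-10 definition was an open choice;
it makes the trace sensitive to recent fluctuation rather than to the
(forever-remembered) volatility of the first few replicates.

### Fast paths

Because L is additive over sites, leave-one-block-out and bootstrap values of
(standardised) R_XY are computed from per-block partial L sums in O(n + g)
rather than by re-subsetting the table per replicate
(`rxy_block_jackknife` / `rxy_block_bootstrap`). The generic
statistic-recomputing routines (`block_jackknife` / `block_bootstrap`) accept
any `SiteTable -> float` callable; tests assert the two routes agree to
float precision, with identical bootstrap draws for a given seed.

## Hypothesis tests

The sound test is a two-sided one-sample t of (estimate, SE) against the
neutral value 1, with df defaulting to g − 1 (jackknife) or B − 1
(bootstrap) — the resampling-unit convention; a t- rather than Z-test because
chromosome-block analyses can have very low df. Z-scores are provided, but
for |Z| > 2 the p-value is withheld and a flag set, since normality of
jackknife Z-scores degrades in the tails. The paired t-test on pseudo-values
(pairing the j-th leave-one-out values of two categories computed on the same
partition) is implemented purely as a demonstration of anticonservatism and
always carries a warning flag. Tests are two-sided; no multiple-testing
correction is applied — category-wise results are reported raw.

## Bias simulation

`simulate_bias_curve` quantifies the three estimators' bias for the mean of
Normal(mu=10, sigma=1) samples: per sample, (a) the SD of delete-one
pseudo-values of the mean, (b) the SD of B bootstrap replicate means, (c) the
proper jackknife SE; each divided by the standard error and averaged over
replicates. The denominator defaults to the known truth σ/√n (the generative
parameters are known, which removes one layer of Monte-Carlo noise); the
fully empirical alternative (SD of replicate sample means) is available via
`empirical_se="monte_carlo"`. Closed forms make this module self-checking:
the pseudo-value SD of the mean is s/(n−1), so the naive ratio is
√n/(n−1)·E[s]/σ ≈ 0.101 at n = 100, and the log-log OLS slope over
n ∈ {10, …, 1000} is ≈ −0.51 (the small departure from −1/2 comes from the
(n−1) denominator and the finite-sample bias of s). Defaults — grid
{10, 20, 50, 100, 200, 500, 1000}, 1000 replicates, B = 500 — bracket the
n = 100 anchor; the grid and replicate count are this package's choices.

## Synthetic data

`generate_site_table(SimConfig)` draws, per site, a baseline frequency
p ~ Beta(freq_alpha, freq_beta); the reference population Y carries p, the
focal population X carries clip(effect_c · p, 0, 1) for the site's category
c; allele counts are Binomial(n, p) draws. Sample frequencies are unbiased
for the true frequencies and populations are independent, so the expected
per-site L contributions are p_x(1−p_y) and p_y(1−p_x), and the ground truth
`expected_rxy = E[p_x(1−p_y)] / E[p_y(1−p_x)]` is evaluated by Monte Carlo
(200k draws by default; `fixed_freq` gives a degenerate p for closed-form
checks). Y as baseline matches the usual captive-vs-wild framing where the
wild population is the reference.

Default study conditions, chosen once: 16 chromosomes of unequal size
totalling 50,000 loci; category proportions intergenic 0.70 / low 0.15 /
moderate 0.10 / high 0.05 (high-impact annotations are rare); n = 40 haploid
genomes per population (20 diploids, a typical conservation-genomics sample);
rare-allele-heavy baseline Beta(0.5, 2); purging scenarios use
effect(high) = 0.7. Simulation-study tests run 200 datasets at these sizes
(the null-calibration check uses a 0.4× locus count, 20k loci, which does not
affect calibration).

What the generator does *not* emulate: linkage disequilibrium within blocks
(sites are independent), so passing coverage tests here show the estimator
algebra and its calibration are correct under independence — not that any
particular g captures the LD structure of a real genome. Real-data SEs will
be larger at the same locus count, and block size matters in ways these
simulations cannot probe. It also does not simulate ancestral-state
misassignment, genotyping error, or the parameters of any particular
empirical dataset.

## Numerical and interface choices

- Coordinates are 1-based inclusive everywhere (site positions, block
  spans), matching VCF convention.
- Tables are sorted lexicographically by chromosome, numerically by
  position; unsorted input files are sorted on load with a logged notice;
  duplicate (chrom, pos) rows are an error (except inside bootstrap
  resamples, where repeats are the point).
- R_XY with a zero denominator raises a dedicated error rather than
  returning inf/NaN; the jackknife propagates it naming the offending block,
  the bootstrap drops and counts the replicate.
- All randomness flows through numpy Generators keyed by explicit seed
  pairs; identical seeds give byte-identical pipeline outputs (floats are
  written with %.10g).
- Pipeline logs record the seed, g or B, an MD5 checksum of the block map,
  and failed-replicate counts for audit.

## Known limitations

- No LD-aware simulation or guidance on optimal block count; g = 100 is a
  convention, not an optimum.
- The jackknife SE can be conservative for strongly nonlinear statistics;
  the bootstrap is the recommended default when compute allows.
- Jackknifing over individuals (rather than loci) is not implemented;
  neither are studentised/BCa bootstrap intervals, VCF parsing, or
  ancestral-state inference.
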