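# Methods

## The enrichment statistic and its uncertainty

The pipeline's core quantity contrasts one taxonomic class between two RT
conditions. With A and B the class's mean relative abundance in the two
conditions (means over biological replicates, computed per sample as class
reads / sample total on the rarefied table), the normalized enrichment is
e = (A − B)/(A + B): antisymmetric under swapping the conditions, bounded
in [−1, 1], scale-invariant, zero iff A = B, and ±1 when the class is
observed in only one condition. When A + B = 0 the statistic is undefined;
such classes are excluded from downstream regression rather than imputed,
since the contrast carries no information there.

Uncertainty is propagated by the first-order delta method. With
∂e/∂A = 2B/(A+B)² and ∂e/∂B = −2A/(A+B)², independent replicate
dispersions δA, δB give

    δe = 2 √(B²δA² + A²δB²) / (A + B)².

δA, δB are the sample standard deviations (n−1 denominator) of the
replicate-level relative abundances — dispersions of the category, not
standard errors of its mean; a `dispersion` option can switch to SE. The
delta-method formula is first-order: with four replicates and classes near
the ±1 boundary it understates the (skewed) true sampling distribution,
which is why it feeds error bars, not the hypothesis tests.

## Regression of enrichment on GC

For each unordered pair of conditions (all C(k,2) pairs; six for the
four-condition design), per-class enrichment is regressed by OLS on the
abundance-weighted class GC content. Pair orientation is fixed by sorting
conditions by (enzyme, temperature), and every output row names both
conditions, since the sign of e depends on it. "Unclassified" is excluded
throughout: it pools unrelated taxa, so neither its enrichment nor its GC
is interpretable.

The report carries slope, intercept, adjusted R², the slope t and its
two-sided p, and stars at p < 0.05/0.01/0.001. Residuals are checked with
Shapiro–Wilk (normality) and Breusch–Pagan (homoscedasticity); the row's
`assumptions_ok` is true only when both p ≥ 0.05, and failing rows carry a
`•` caveat. On numerically constant residuals (the exactly collinear
limit) both diagnostics are undefined and are reported as p = 1 so the
limit stays well-defined. P-values are reported raw by default, matching
common practice for a single pre-planned family of six comparisons; Holm
step-down adjustment is available behind a flag.

The statistic is compositional: class proportions sum to one, so class
enrichments within a pair are negatively coupled, and classical OLS
inference is approximate. Simulation (below) shows the practical effect is
a mild conservatism of the test, not inflation.

## GC content

Per-OTU GC is computed from the representative amplicon sequence (V3–V4),
with IUPAC ambiguity codes contributing their expected GC share
(#{G,C} in the code's expansion / expansion size: S→1, N→0.5, B,V→2/3,
D,H→1/3, …), which avoids the length bias of dropping ambiguous positions.
Class GC is the abundance-weighted mean over member OTUs; the default
weight basis is each OTU's grand-mean relative abundance over all retained
samples, giving a single covariate per class across all pairwise
regressions (one bar color per class, in figure terms). Amplicon GC is a
proxy for genomic GC; the two are correlated but not identical, and this
caveat is inherited by any interpretation of the slope.

## Preprocessing

The stage order is fixed and logged: rarefy → outlier scoring → replicate
equalization.

* **Rarefaction** draws, per sample, a single multivariate hypergeometric
  subsample of exactly `depth` reads (default 9,000) — subsampling without
  replacement, one draw per sample rather than an average over repeated
  rarefactions. Samples shallower than the depth are dropped and listed.
* **Outlier scoring**: each sample's score is its mean Bray–Curtis
  dissimilarity (on relative abundances) to same-condition replicates; a
  sample is flagged when its score exceeds the within-condition median by
  more than k = 3 median absolute deviations. Flagging is deliberately
  report-only — outlier removal in small designs is a judgment call, so
  removal requires either an explicit flag or an explicit sample list,
  keeping the audit trail reproducible.
* **Equalization** removes uniformly random samples from over-represented
  conditions until all hold the same replicate count (default: the current
  minimum), deterministic given its own named seed. Rarefaction,
  equalization and simulation each have an independent seed recorded in
  the run manifest.

Alpha diversity (richness as OTUs with nonzero reads, Shannon H in nats,
Pielou J = H/ln richness, undefined at richness 1) is computed at the OTU
level on the rarefied table; a Kruskal–Wallis p per index across
conditions is reported as a descriptive convenience, not a claim. The
stacked-bar summary keeps the top 15% of classes *by rank* of grand-mean
abundance (⌈0.15·K⌉ classes, ties broken lexicographically) and pools the
rest into "Low abundance groups" (mean = sum of member means, sd =
root-sum-square); "rank fraction" is one of two defensible readings of a
"top 15% of the most abundant classes" summary, and the fraction is
configurable.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes — it
is the package's ground-truth instrument, not a sequence simulator. One
base community of `n_classes` classes (default 40) with log-normal
abundances (σ = 1, normalized) spans a GC gradient (linspace over
0.35–0.75, per-OTU jitter sd 0.02). A condition's capture efficiency is
e0·exp(−λ·gc): the simplest strictly monotone one-parameter family
consistent with "low reaction temperature penalizes GC-rich templates";
it is a modeling choice, not a mechanistic claim. Effective class weights
are base × efficiency, renormalized (so e0 cancels unless conditions
differ in it). Replicate proportions are Dirichlet(θ·w) with a single
concentration θ = 200 — the standard two-parameter Dirichlet-multinomial
noise model for microbiome counts, giving per-class replicate CVs of
roughly 15–45% at the default abundances, comparable to biological
replicates of soil communities. Counts are multinomial at fixed depth
9,000. The default four conditions mirror the studied design — ImProm-II
42 °C (λ = 3.0), ImProm-II 55 °C (0.8), SuperScript IV 55 °C (0.4), TGIRT
57 °C (0.4) — with four replicates each and ~2% of reads assigned to OTUs
lacking a class rank. GC-independent enzyme effects (per-condition,
per-class log-normal multipliers) can be toggled to create differences GC
cannot explain, emulating processivity-type bias. Representative sequences
are composition-exact shuffles of length 450 nt whose GC matches the OTU's
assigned value to the nearest base.

What the generator does *not* emulate: phylogenetic correlation between
abundance, taxonomy and GC; chimeras, primer mismatch or PCR-cycle
effects; library-size variation (depth is fixed by design); any coupling
between a class's abundance and its GC beyond the imposed bias. Passing
tests therefore demonstrate that the pipeline's inference is correct under
its own noise model, not that real RT bias is exponential in GC.

## Validation experiments and problem sizes

* Delta-method SD: checked against a symbolic-gradient oracle (sympy) on
  1,000 random tuples at 1e−12 relative tolerance, and against Monte Carlo
  (10⁵ Gaussian perturbations at 1% noise) within 3× the MC error.
* Rarefaction: retained samples hit the depth exactly; the subsample mean
  over 10,000 seeds on a two-OTU toy matches the hypergeometric
  expectation within 3 standard errors.
* Null calibration: with identical λ in both arms (20 classes, depth
  2,000), the regression's rejection rate at α = 0.05 over 5,000 simulated
  datasets is 0.051, inside the 95% binomial band of a 1,000-dataset
  calibration experiment. Where the test deviates from nominal it runs
  mildly conservative, consistent with compositional coupling and bounded
  heteroscedastic errors; it does not anti-conserve.
* Power and direction: injecting a GC-efficiency deficit into the
  low-temperature arm (40 classes, depth 9,000, 4 replicates, 120 datasets
  per grid point under common random numbers) gives power rising
  monotonically over Δλ ∈ {0.5, 1, 2, 3} to ≈0.97, with the fitted slope
  negative — high-GC classes depleted — in every detected dataset.

These sizes were chosen so each experiment measures its quantity with
Monte-Carlo error well below the tolerance being asserted.

## Numerical and degenerate-input choices

* Counts are validated as non-negative integers at load; NaN, fractional
  and negative cells are rejected naming the offending row/column, and
  cross-reference failures (OTU without taxonomy/sequence, sample without
  metadata) are reported as a complete list, not first-failure.
* The loader applies no abundance filter (no singleton removal); whatever
  upstream clustering produced is analyzed as-is.
* Conditions with a single replicate are an error for profile SDs unless
  explicitly allowed; conditions with < 2 samples are skipped by outlier
  scoring with a warning.
* Regression requires ≥ 3 usable classes and a non-degenerate GC
  covariate; fewer points or zero GC variance raise errors rather than
  returning fragile fits.
* All randomness flows through named numpy Generators (rarefy, equalize,
  simulate); identical config + seeds reproduce every output byte-for-byte,
  and the run manifest records seeds, parameters and SHA-256 checksums of
  all inputs and outputs.

## Known limitations

The statistic ignores compositional constraints (no log-ratio transform),
exactly as defined; its inference is correspondingly approximate, erring
conservative in our simulations. GC is measured on amplicons, not genomes.
The outlier rule is a reproducible surrogate for what is, in practice,
visual curation. The exponential efficiency family is a declared modeling
convenience; only the monotone GC-bias direction, not the functional form,
is identified by the analysis.
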