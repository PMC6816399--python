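# rtshift

Reverse transcription (RT) is a necessary step when microbial communities
are profiled from ribosomal RNA rather than rDNA, and it is not neutral:
the enzyme used and the reaction temperature change which taxa are captured
into cDNA, with template GC content a prime suspect because GC-rich rRNA
folds into more stable secondary structure at low reaction temperatures.
`rtshift` is an analysis pipeline for quantifying that bias from a 16S
amplicon OTU count table. It is aimed at microbial ecologists comparing
rRNA-based community profiles produced under different RT protocols
(e.g. ImProm-II at 42 °C vs 55 °C, SuperScript IV, TGIRT).

## The statistic

For a taxonomic class with mean relative abundance *A* in one condition and
*B* in another (means over biological replicates), the pipeline computes
the normalized enrichment

```
e = (A − B) / (A + B)
```

which is 0 when the class is equally proportional in both conditions and
±1 when it is present in only one of them. Its uncertainty is propagated
from the replicate standard deviations δA, δB by the first-order delta
method:

```
δe = 2 √(B² δA² + A² δB²) / (A + B)²
```

For each pair of conditions, per-class enrichment is regressed by ordinary
least squares on the abundance-weighted class GC content (computed from
representative amplicon sequences); the report carries adjusted R², the
slope *t* value and *p*-value, significance stars (\*, \*\*, \*\*\* at
*p* < 0.05, 0.01, 0.001) and residual diagnostics (Shapiro–Wilk,
Breusch–Pagan), flagging pairs that violate the regression assumptions.
A negative slope means high-GC classes are depleted in the first condition
of the pair.

Upstream of the statistic, the pipeline rarefies all samples to an even
depth (default 9,000 reads), scores within-condition Bray–Curtis outliers,
equalizes replicate counts across conditions, aggregates OTUs to class
(unassigned OTUs pool into "Unclassified"), and reports per-sample
richness, Shannon diversity and Pielou evenness.

Because no public per-study OTU table ships with the package, a synthetic
generator (`rtshift.simulate`) produces complete experiments — a shared
community read through condition-specific GC-dependent capture efficiency
`e0·exp(−λ·gc)` with Dirichlet-multinomial replicate noise — so the whole
pipeline, including the regression's calibration and power, is validated
against known ground truth.

## Worked example

Simulate a four-condition experiment and analyze it:

```
rtshift simulate --out sim/ --seed 3
rtshift run --otu-table sim/otu_table.tsv --taxonomy sim/taxonomy.tsv \
    --metadata sim/metadata.tsv --sequences sim/rep_seqs.fasta --out out/
```

The same workflow, as a scripted narrative, lives in `analysis/01…05`.
Running those scripts prints, among other things, the six pairwise
regressions (here from the seed-20240917 simulation, where the ImProm-II
42 °C arm was generated with the strongest GC penalty, λ = 3.0, against
0.8/0.4/0.4 for the 55–57 °C arms):

```
       condition_a        condition_b  adjusted_r2  t_value   p_value significance caveat
     ImProm-II 42C      ImProm-II 55C      0.08044     -2.1   0.04239            *
     ImProm-II 42C SuperScript IV 55C        0.282   -4.039 0.0002511          ***
     ImProm-II 42C          TGIRT 57C       0.1452   -2.761  0.008813           **
     ImProm-II 55C SuperScript IV 55C      0.09118   -2.216   0.03272            *      •
     ImProm-II 55C          TGIRT 57C     0.002083    -1.04     0.305
SuperScript IV 55C          TGIRT 57C      0.03899    1.607    0.1163                   •
```

Every pair involving the 42 °C condition shows a significant negative
GC slope — high-GC classes are depleted at the low reaction temperature —
while the two similarly-biased high-temperature pairs do not separate.
Rows marked `•` fail at least one residual diagnostic and should be read
with caution. `analysis/05_recovery_power.py` additionally reports the
regression's null rejection rate (≈0.05 when both conditions share λ) and
a power curve rising to ≈0.97 at Δλ = 3 with the fitted slope negative in
every detected dataset.

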