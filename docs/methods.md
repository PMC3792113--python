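# Methods

## The screening model

`oncoscreen` treats a *study* as a genes × samples matrix of linear-scale
expression intensities with every sample labelled `cancer` or `normal`
(each group ≥ 2 samples). Within a study, every measured gene receives:

* a two-sided two-sample Student's t-test with pooled variance, computed
  on log2 intensities (scipy's `ttest_ind`; Welch's correction available
  via `welch=True`);
* a signed linear fold change `mean(cancer)/mean(normal)`, with ratios
  below one reported as the negative reciprocal so that the magnitude is
  always ≥ 1 and the sign carries the direction;
* a gene rank R (position of its p-value among the N measured genes,
  smallest first), an integer percentile ⌈100·R/N⌉, and the rank-based
  FDR estimate Q = N·P/R.

Testing on the log scale while reporting fold change on the linear scale
is deliberate: log2 microarray intensities are approximately normal with
stabilised variance, which is what the t-test assumes, while "2-fold" is
a statement about linear abundance. A `log_transform=False` switch runs
the test on linear values for data already symmetrised upstream.

An analysis is **above threshold** when it passes the three-criterion
Boolean-AND gate. Boundary conventions, fixed once:

| criterion | default | boundary |
|---|---|---|
| p-value | 0.05 | strict (`p < p_max`) |
| linear fold change | 2.0 | inclusive on the magnitude (`|fc| ≥ fold_min`) |
| gene rank percentile | 10 | inclusive after ceiling (`pct ≤ percentile_max`) |

The inclusive fold and percentile boundaries make printed borderline
analyses such as |fc| = 2.05 or percentile = 10 pass, which is how the
published record sets shipped in `reference_data` behave. The gate uses
the raw p-value; Q is reported alongside but not gated on, since the
conventional threshold statement is in terms of p.

**Comparative meta-analysis** summarises one gene in one cancer subtype by
the median p-value and median gene rank across *all* n datasets that
measured the gene — not only the above-threshold ones — and is performed
only when n ≥ 5. The subtype trend is called significant when the median
p ≤ 0.05. Medians use the standard convention (mean of the two central
values for even n, so median ranks can be half-integers). Ranks, not
percentiles, are medianed: a median rank of ~10,000 against a ~14,000-gene
platform is directly interpretable as "not near the top".

**Fold aggregation** reports mean ± SEM of |fc| over the above-threshold
analyses of one gene/subtype/direction (SEM = sample SD with k−1
denominator over √k; undefined and reported as missing for k = 1).
Magnitudes are aggregated and direction is carried separately, so a mean
fold *decrease* keeps its natural magnitude.

**Gene-summary matrices** condense the records into two gene × cancer-type
matrices (over / under); each cell is the best (lowest) percentile among
that cell's above-threshold analyses, binned for display into 1% / 5% /
10% classes. A cell is empty exactly when no above-threshold analysis
exists.

## Numerical and degenerate-input choices

* p-values are clamped into (0, 1]; two identical constant groups are a
  defined no-difference outcome (t = 0, p = 1), and constant groups with
  different means give p at the smallest positive float, not an error.
* Ties in p are broken by lexicographic gene id, so ranks are a
  deterministic permutation of 1..N on every platform.
* Genes left with fewer than two finite values in either group after
  missing-value removal are treated as not measured in that study: they
  are excluded from the results and from N.
* A non-positive group mean makes the linear fold change undefined; the
  gene keeps its test result but can never pass the gate.
* Raw Q = N·P/R is the default (it may exceed 1); `monotone=True` applies
  the step-up running minimum from the largest rank downward and caps at
  1, which coincides with Benjamini–Hochberg q-values.
* All internal arithmetic is double precision; rounding (2 decimals,
  scientific p) is confined to display, and the writers emit full-precision
  round-tripping TSV.

## The synthetic-data generator

`SimulationConfig`/`generate_collection` emulate the corpus this screen
targets: several independent two-group microarray studies per cancer
subtype with partially overlapping gene panels. Intensities are
log-normal:

```
expression = 2 ** (mu_g + delta_g * [sample is cancer] + eps),
eps ~ Normal(0, within_group_log2_sd)
```

with per-(subtype, gene) baselines mu_g ~ Uniform(baseline range) and
delta_g = ±planted_log2_effect for a planted minority of genes, 0
otherwise. Planted direction is shared by all studies of a subtype
(homogeneous effects); an `effect_jitter_sd` knob adds per-study
heterogeneity and defaults to 0. Each study independently drops each gene
with probability `platform_dropout`, emulating platform gene-panel
differences.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| studies_per_subtype | 7 | enough that the n ≥ 5 meta-analysis rule survives dropout |
| genes_per_platform | 14000 | the platform size typical of the screened microarrays |
| samples_per_group | 10 | a modest clinical cohort; the source group sizes are unknown |
| baseline_log2_mean_range | [4, 12] | the usual dynamic range of log2 array intensities |
| within_group_log2_sd | 0.5 | typical biological + technical spread on log2 arrays |
| planted_fraction | 0.01 | differential expression is the exception, not the rule |
| planted_log2_effect | 1.5 | ≈ 2.8-fold, comfortably above the 2-fold gate |
| platform_dropout | 0.05 | a few percent of genes absent per platform |
| n_subtypes | 3 | several subtypes without inflating runtime |

Randomness derives from one seed through `numpy.random.SeedSequence`
children keyed by study position, so collections are bit-identical for a
given config regardless of generation order.

What the generator does *not* model: probe-level effects, batch and
normalisation artefacts, between-study platform biases, correlated genes,
heavy-tailed outliers. Passing recovery tests on this generator therefore
demonstrates that the pipeline's statistics and gate are implemented
correctly and calibrated under the stated model — not that the screen is
robust to the messiness of real compendium data.

## Validation strategy and observed behaviour

The test suite checks each operation against an independent oracle
(textbook pooled-t, argsort ranking, direct substitution into Q = N·P/R,
an independent step-up FDR, statsmodels' Benjamini–Hochberg for the
monotone mode) and the shipped published record set provides worked
examples for the gate, counting and mean ± SEM aggregation. On synthetic
collections the suite verifies: null calibration (uniform p under no
effect, gated set near-empty), ≥ 95% gate sensitivity at the default
planted effect with 100% direction agreement, and meta-analysis
significance for planted genes across replicates. Simulation-based tests
run at reduced problem sizes (typically 300–2000 genes per platform,
which the suite completes in well under a minute) — the statistics being
checked do not depend on the platform size beyond sampling resolution.

## Known limitations

* The linear-scale assumption for on-disk matrices is a convention
  (`scale: log2` per study in the manifest handles log-scale inputs).
* One ranking per study from the two-sided test, with direction taken from
  the fold-change sign; separate one-sided over/under rankings would give
  slightly different percentiles for under-expressed genes.
* No between-study random-effects model or heterogeneity statistics: the
  meta-analysis is medians only, by design.
* No multiple-testing control across the genes × cancers grid of the final
  summary; Q addresses within-study multiplicity only.
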