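# Methods

## Scope and data model

`lactoseq` analyzes a gene-level count matrix from a multi-stage lactation
design. The backbone container (`ExpressionMatrix`) is a validated genes ×
samples DataFrame carrying each sample's stage label; the canonical design
has three stages — peak lactation (L), dry-off (D), non-lactating/
non-pregnant involution (NP) — with three biological replicates each.
Everything upstream of the count matrix (read QC, assembly, alignment,
counting, database annotation) is out of scope; counts, gene lengths and a
GMT-style term annotation are inputs.

## Normalization and abundance classes

RPKM is used throughout: `10⁹ · c[g,s] / (N[s] · L[g])` with library size
`N[s]` taken as the column sum of counted reads (the total of *mapped*
reads is not recoverable from a count matrix, so counted reads stand in
for it). Abundance classes use half-open bins low = [0, 10), medium =
[10, 500), high = [500, ∞) RPKM. The printed class definitions in common
usage overlap at the boundaries (10 belongs to "low" and to "10–500");
the half-open convention keeps the bins a true partition while preserving
the ≥ 500 edge for "high".

A gene is "present" in a stage when its stage-mean RPKM exceeds a
threshold τ (default 0: any positive stage mean counts as detected, the
natural convention for sparse tag-count data). Stage means are arithmetic
means of replicate RPKM (per-sample normalization first, then averaging).
Genes present in exactly one stage are "unique" to it; the full Venn
partition over stages is reported.

## Differential testing

For each stage pair (reference, target) — canonically (L, D), (L, NP),
(D, NP), with log2 fold change = log2(target / reference) so positive
values mean up-regulation in the later stage — the primary test is a
random-variance-model (RVM) moderated t-test on log2(RPKM + 0.125):

- Per-gene inverse variances are modeled as exchangeable draws,
  1/σ² ~ Gamma(shape a, scale b). The marginal law of a sample variance
  s² on d degrees of freedom is then `a·b·s² ~ F(d, 2a)`, giving a
  closed-form likelihood for (a, b), maximized by Nelder–Mead from a fixed
  moment-based start (a₀ = 2, b₀ matching the mean variance). Zero
  variances are excluded from the fit; at least 50 positive values are
  required.
- The moderated variance `s̃² = (d·s² + 2/b)/(d + 2a)` shrinks the pooled
  two-group variance toward the prior; the t statistic uses `d + 2a`
  degrees of freedom. With 3 vs 3 replicates (d = 4) the prior typically
  contributes 2a ≈ 6 extra degrees of freedom — the entire point of the
  moderation.
- A 2×2 Pearson chi-square (1 df, no continuity correction) on per-group
  summed counts versus library totals is computed alongside, as a
  count-level complement. By default DEG calls gate on the moderated p
  only (p < 0.05 and BH FDR < 0.05, FDR computed within each comparison
  since comparisons are reported separately); a strict mode additionally
  requires the chi-square p < 0.05. How the two tests combine is a
  genuinely open design point; gating on the better-calibrated moderated
  test and reporting the chi-square is the least surprising choice.
- The pathway-scoring input filter is stricter: |fold change| > 2
  (strict inequality on the fold scale) and p < 0.001.

The pseudocount 0.125 (configurable) keeps fold changes finite for
stage-absent genes.

## Temporal model profiles

Temporal patterns are integer "model profiles" of length t starting at 0
with at most c units of change between adjacent stages — (2c+1)^(t−1)
candidates, identified by the lexicographic order of their step vectors
(ids are stable). Defaults t = 3, c = 2 give 25 candidates, of which
m = 20 representatives are kept by greedy max–min selection: seed with the
flat profile, repeatedly add the candidate whose minimum distance
(1 − Pearson correlation of level vectors) to the chosen set is largest,
ties to the lowest id. Correlation with the flat profile is undefined
(zero variance); by convention its distance to any non-flat profile is 1.

Each gene's stage means are transformed to log2 ratios against the first
stage and assigned to the most-correlated profile, ties to the lowest id;
constant trajectories go to the flat profile. Because correlation is
scale-invariant, profiles with proportional levels (e.g. (0,1,0) and
(0,2,0)) are indistinguishable; the tie-break makes the lowest-id member
of each such class the canonical sink.

Profile significance uses the exact permutation null: all t! orderings of
the stage columns (6 for three stages — exactness is free at this scale),
re-anchoring and re-assigning every gene under each, averaging per-profile
counts to get expectations, and a binomial tail P(X ≥ observed) with
success probability expected/total, Bonferroni-corrected across profiles.
Significant profiles whose level vectors correlate at ≥ 0.7 (configurable)
are grouped by single linkage (connected components).

Note that a shift planted in *every* gene cannot be detected through
RPKM: relative normalization cancels transcriptome-wide changes. Tests of
the extreme all-genes-one-template case therefore construct stage means
directly.

## Co-expression network

Pearson correlations of log2(RPKM + 0.125) are computed across all
samples jointly (co-expression along the whole lactation trajectory is
the signal of interest), in gene blocks so peak memory is O(block × n)
for DEG sets up to ~10⁴ genes; blocked and all-at-once computation are
bitwise-identical. An edge is kept when |r| ≥ 0.92 (inclusive); negative
correlations count as correlated by default, with a positive-only mode in
config. Zero-variance genes yield no edges and are listed in diagnostics.
Node genes are ranked by degree, ties by gene id; the top-k cut keeps all
genes tied at the boundary degree rather than truncating hubs arbitrarily.

## Dynamic Impact Approach

For term T with k measured member genes and filtered DEG set D (the
|FC| > 2, p < 0.001 filter above):

    impact = (|D|/k) · mean_D |log2FC| · mean_D (−log₁₀ p)

with the same formula on the up- and down-regulated subsets (proportions
|D_up|/k, |D_down|/k) and flux = impact_up − impact_down. The three
factors are combined multiplicatively — the only combination that is zero
exactly when a term has no filtered DEG and scales with both magnitude
and significance; an additive variant is available behind
`dia_combination: sum` for sensitivity analysis. −log uses base 10
(configurable). Proportion denominators count *measured* members only:
unmeasured genes cannot contribute evidence. Impacts are normalized to
[0, 100] within each comparison (max → 100; an all-zero table stays
zero). Category and subcategory summaries are unweighted means of term
impact and flux; the overall most-impacted ranking averages impact across
comparisons, ties by term id. Terms with no measured member are skipped
and logged. It always holds that |flux| ≤ impact_up + impact_down and
impact = 0 iff no filtered DEG is in the term.

## Synthetic-data generator

The generator emulates the 3-stage × 3-replicate design:

- **Baselines**: per-gene lognormal means (log-mean 4.0, log-sd 1.5;
  median ≈ 55 counts with a long right tail, typical of bulk tag counts).
- **Counts**: negative binomial with a single shared dispersion
  α = 0.05 (var = μ + αμ²), i.e. ~22% biological CV at high expression —
  a realistic within-stage replicate spread that also keeps the RVM's
  exchangeable-variance assumption approximately satisfied. Per-gene
  dispersions can be supplied instead.
- **Planted differential expression**: a fraction `frac_de` = 0.2 of genes
  receives an integer temporal template; the stage mean is
  baseline · 2^(level × effect), effect = 2 log2 units per level. The
  four default templates — (0,1,1), (0,−2,−2), (0,1,0), (0,−2,0) with
  weights 5/42, 8/21, 5/42, 8/21 — were chosen under two constraints:
  (i) each is the lowest-id member of its correlation class, so profile
  assignment can recover it despite the scale-invariance of correlation;
  (ii) the weights make the expected total RNA output of planted genes
  identical in every stage. The second constraint is the compositional
  balance that justifies global library-size normalization; without it the
  planted genes shift every null gene's relative abundance between stages
  and the false-discovery rate of *any* relative-abundance test is
  inflated by construction, not by a defect of the test.
- **Annotation**: `n_terms` = 50 terms of 10–40 members; 10% of terms are
  "enriched" and sample members with probability weight
  `enrichment_odds` = 10 on planted DE genes.
- **Determinism**: every output is a pure function of the config,
  including its seed (annotation uses an independent stream derived from
  the same seed). `write_fixture` emits the TSV/GMT dialects plus a
  manifest from which the dataset regenerates exactly.

What the generator does *not* emulate: read-level artifacts (sequencing
error, mapping ambiguity, positional bias), per-gene dispersion trends,
correlated gene programs beyond the planted templates, batch structure,
and annotation noise. Passing tests therefore demonstrate correctness of
the statistical machinery under its stated assumptions, not robustness to
real-data pathologies such as unbalanced global shifts (where
composition-aware normalization would be required upstream).

## Numerical and design choices

- RVM optimization in log-parameter space, Nelder–Mead, fixed start;
  non-convergence raises with the optimizer trace.
- Assignment/selection tie tolerance 1e-12; all ties resolve to the
  lowest id, making every stage deterministic and order-invariant.
- `report.json` uses sorted keys and 9-significant-digit floats, and its
  config echo omits filesystem paths, so identical (inputs, config, seed)
  give byte-identical reports regardless of output location; timings are
  logged, not reported.
- Problem sizes in the test-suite simulations (e.g. 2000-gene default
  datasets, 20-run calibration loops, 300-gene permutation nulls) were
  chosen to make Monte-Carlo checks stable at comfortable margins while
  the whole suite stays fast.
- Degenerate inputs raise early with the offending gene/sample/field
  named: negative counts, zero library sizes, missing lengths, duplicate
  ids, malformed GMT lines (with line number), stages without samples.

## Known limitations

- RPKM with counted-read library sizes inherits composition bias; no
  TMM/median-of-ratios correction is applied (the abundance classes and
  the published thresholds are defined on RPKM).
- The chi-square count test treats replicates as pooled libraries and is
  anti-conservative under biological overdispersion; it is reported, not
  gated on, by default.
- The permutation null for profile significance treats genes as
  exchangeable and independent; correlated gene programs make it
  approximate.
- The identifier level of the analysis is whatever the input matrix uses
  (transcript clusters vs annotated genes); mapping between levels is
  upstream annotation work, out of scope.
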