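# lactoseq

Stage-resolved transcriptome analysis for lactation studies in ruminants.

Mammary gland function changes drastically across the lactation cycle —
peak lactation (L), dry-off (D, cessation of milking), and the
non-lactating/non-pregnant involution period (NP). Given gene-level read
counts from such a multi-stage design (e.g. digital gene expression tag
sequencing of dairy goat mammary tissue, three biological replicates per
stage), `lactoseq` runs the full downstream analysis:

1. **Abundance classification** — RPKM normalization
   (`RPKM = 10⁹·c / (N·L)` for count *c*, library size *N*, gene length *L*
   bp), three abundance classes (high ≥ 500, medium 10–500, low < 10 RPKM),
   stage-presence Venn partition, and stage-unique gene tallies.
2. **Differential expression** — random variance model (RVM) moderated
   t-test per stage pair (L vs D, L vs NP, D vs NP). The per-gene inverse
   variances are modeled as exchangeable Gamma(a, b) draws, giving the
   shrunken variance `s̃² = (d·s² + 2/b)/(d + 2a)` and `d + 2a` degrees of
   freedom — a large power gain with 3 replicates per group. A 2×2 Pearson
   chi-square on summed counts per group is reported alongside.
   Benjamini–Hochberg FDR within each comparison; DEGs at P < 0.05 and
   FDR < 0.05.
3. **Temporal patterns** — STEM-style integer model profiles (levels start
   at 0, at most ±2 units change per step; 25 candidates for 3 stages, of
   which 20 representatives are kept by greedy max–min selection). Each
   DEG's log2-ratio trajectory is assigned to its most-correlated profile;
   per-profile gene counts are tested against an exact stage-permutation
   null with Bonferroni correction.
4. **Co-expression network** — Pearson correlation of log2(RPKM + 0.125)
   over all samples, edges at |r| ≥ 0.92, "node genes" (hubs) ranked by
   the number of correlated partners.
5. **Pathway impact (Dynamic Impact Approach, DIA)** — for each annotated
   term and comparison, with the strictly filtered DEGs D (|fold change|
   > 2, P < 0.001) among k measured members:
   `impact = (|D|/k) · mean|log2FC| · mean(−log₁₀ p)`, and
   `flux = impact(up-regulated) − impact(down-regulated)`; impacts are
   normalized to 0–100 within a comparison and rolled up into
   category/subcategory means.

A seeded synthetic-data generator (negative-binomial counts, planted fold
changes, planted temporal templates, terms enriched in planted DEGs) makes
every stage testable end-to-end against known ground truth.

## Worked example

Generate a 2000-gene synthetic dataset and run everything:

```bash
lactoseq simulate --seed 11 --n-genes 2000 --out demo_fix
cat > demo.yaml <<EOF
counts: demo_fix/counts.tsv
samples: demo_fix/samples.tsv
lengths: demo_fix/lengths.tsv
terms: demo_fix/terms.gmt
out_dir: demo_out
seed: 11
EOF
lactoseq all --config demo.yaml
```

prints

```
report written to demo_out/report.json
D_vs_NP: 163 DEGs (121 up, 42 down)
L_vs_D: 350 DEGs (93 up, 257 down)
L_vs_NP: 166 DEGs (44 up, 122 down)
```

`demo_out/` then contains `rpkm.tsv`, `deg_results.tsv`, `patterns.tsv`,
`profiles.tsv`, `network_edges.tsv`, `network_degrees.tsv`,
`dia_impacts.tsv`, `dia_categories.tsv` and a machine-readable
`report.json`. In this run the report shows, for example, 1996 of 2000
genes detected in stage L with abundance classes high/medium/low =
244/1509/247; 368 DEGs assigned across the 20 model profiles with 3
profiles holding significantly more genes than the stage-permutation null;
an 11,435-edge co-expression network whose top node gene has 131 correlated
partners; and the DIA ranking whose most-impacted term (T0024,
mean impact 6.65, flux −4.02) is the term the simulator enriched with
planted DEGs. Rerunning with the same seed reproduces `report.json`
byte-for-byte.

The same stages are available as library functions
(`lactoseq.compute_rpkm`, `lactoseq.run_deg_analysis`,
`lactoseq.assign_genes`, `lactoseq.build_network`,
`lactoseq.term_impact`, ...) and as standalone subcommands
(`lactoseq rpkm|deg|patterns|network|dia`).

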