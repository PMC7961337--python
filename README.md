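# intronrank

Rank-based prioritization of intronic cis-regulatory elements from
per-variant functional scores, with a seeded synthetic-data generator and a
luciferase reporter-assay statistics layer.

## The problem

Large genes can harbour enhancers deep inside their introns. One way to find
the introns worth testing at the bench is to take all common variants that
fall in a gene's introns, attach a precomputed per-variant functional-impact
score (e.g. a GWAS3D score from a regBase-style compendium, where higher
means more likely functional), and ask which introns are *enriched* in
high-scoring variants relative to the rest of the gene. `intronrank`
implements that analysis for people doing regulatory-genomics triage:

1. **Coordinate layer** — parse one transcript's exon chain from GFF3 or
   BED12, derive introns in transcription order, and assign VCF variants to
   introns (1-based inclusive coordinates throughout; exonic boundary bases
   are excluded; genome-build tags are checked, never lifted over).
2. **Global gate** — a tie-corrected Kruskal–Wallis test over the per-intron
   score distributions, H ~ χ²(k−1), asks whether anything differs at all.
3. **Sequential exclusion ranking** — repeatedly test each remaining intron's
   scores against the pooled scores of all other remaining introns with a
   one-sided Mann–Whitney U test (upper tail), remove the most significant
   intron and record its p-value, and stop when no intron clears the fixed
   Bonferroni threshold α/m (m = number of introns at the start). Removed
   introns, in removal order, are the prioritized candidates; survivors are
   ranked by their final-round p-value.

The U test uses the tie-corrected variance and a continuity correction in
its normal approximation, and switches to exact enumeration of all
C(n₁+n₂, n₁) group assignments for small tie-free comparisons; the method
used is recorded in every result. For a 26-intron gene at α = 0.05 the
threshold is 0.05/26 ≈ 1.92 × 10⁻³.

The **reporter layer** analyses the wet-lab follow-up: firefly-luciferase
signals normalized per well to a co-transfected β-galactosidase control,
expressed as fold change over a promoter-only reference construct (defined
as 1), with SEM, unpaired t-tests against the reference and the usual star
annotation (`*` p < 0.002, `**` p < 10⁻¹⁰).

## Worked example

```python
import intronrank as ir

# 6 introns, 40 scored variants each, standard-normal background,
# a +1.5 score shift planted in intron 3
cfg = ir.SyntheticConfig(n_introns=6, variants_per_intron=40,
                         planted={3: ir.Effect("shift", delta=1.5)}, seed=11)
ds = ir.generate(cfg)
res = ir.IntronEnrichment(ds.score_sets).fit(alpha=0.05)
print(res.summary())
```

```
Intron enrichment (sequential one-sided Wilcoxon exclusion)
============================================================
Introns (m): 6    alpha: 0.05    threshold: 0.00833
Global Kruskal-Wallis: H = 55.53, df = 5, p = 1.02e-10
Significant introns: 1 [3]

 rank  intron_index  legacy_index       p_last  round_assigned  significant  n_variants        method
    1             3          <NA> 1.427597e-13               1         True          40 normal_approx
    2             2          <NA> 9.845335e-02               2        False          40 normal_approx
    3             4          <NA> 3.439774e-01               2        False          40 normal_approx
    4             6          <NA> 5.516397e-01               2        False          40 normal_approx
    5             1          <NA> 7.217139e-01               2        False          40 normal_approx
    6             5          <NA> 8.369345e-01               2        False          40 normal_approx
```

The gate confirms a global difference (p ≈ 10⁻¹⁰); round 1 removes the
planted intron 3 at p ≈ 1.4 × 10⁻¹³ (below the 0.05/6 threshold); in round 2
nothing clears the threshold, so the remaining five introns keep their
round-2 p-values and the procedure stops with exactly one significant
intron — the planted one.

The same analysis runs from files via the CLI:

```sh
intronrank make-fixtures --outdir fx --n-introns 6 --n-variants 40 \
    --planted 3 --delta 1.5 --seed 11
intronrank enrich --annotation fx/gene.gff3 --vcf fx/variants.vcf \
    --scores fx/scores.tsv --id SYNGENE.t1 --build synthetic --outdir run
```

which writes `ranking.tsv`, `boxplot_summary.tsv` and a `manifest.json`
with input/output checksums. `intronrank simulate` runs calibration
experiments and `intronrank reporter` summarizes a luciferase/β-gal table.

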