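# Methods

## Model and procedure

The analysis treats the variants of one gene as grouped observations: intron
i contributes a set of nᵢ real-valued functional scores, one per scored
variant. The question "which introns are enriched in high-scoring variants?"
is answered nonparametrically, on ranks, so nothing is assumed about the
score distribution's shape.

**Global gate.** A Kruskal–Wallis test over all non-empty introns,
H = 12/(N(N+1)) Σ Rᵢ²/nᵢ − 3(N+1), divided by the tie-correction factor
C = 1 − Σ(t³−t)/(N³−N) over pooled tie groups, referred to χ² with k−1
degrees of freedom. It is reported before the sequential procedure as the
"is anything different at all?" statistic; it does not gate execution.

**Sequential exclusion.** Each round tests every remaining intron's scores
against the pooled scores of all *other remaining* introns with a one-sided
Mann–Whitney U (upper tail: the intron's scores tend higher). The intron
with the smallest p-value is removed if p < α/m and keeps that p-value and
round number; the background of later rounds therefore excludes previously
removed introns' variants, so a strong intron cannot mask the next one. The
threshold α/m uses the number of introns at the start (m counts every
intron supplied, including ones without scored variants) and is never
recomputed — removing introns does not shrink the family the correction
protects against. When no remaining intron clears the threshold the
procedure stops and every survivor keeps its final-round p-value; survivors
are ranked by that p-value. This is a greedy step-down scheme, not a closed
test: the calibration experiments, not a proof, establish its family-wise
error behaviour.

**Mann–Whitney details.** U counts pairs with x > y plus half the tied
pairs (equivalently the rank-sum form). The normal approximation uses mean
n₁n₂/2, the tie-corrected variance n₁n₂/12·[(n+1) − Σ(t³−t)/(n(n−1))], and
a 0.5 continuity correction — matching the default behaviour of the common
R implementation. When n₁+n₂ ≤ 12 and no value occurs in both groups, the
p-value is instead exact: the proportion of all C(n₁+n₂, n₁) group
assignments with U at least the observed value. The method used is recorded
in every result object. When every pooled value is identical the test is
uninformative and returns p = 1 with a warning rather than raising, so the
sequential driver never aborts mid-run. p-values are floored at 10⁻³⁰⁰ so
ranking by p is always strict.

Note one boundary case: for two identical small groups with cross-group
ties (e.g. x = y = {1, 2}) the corrected normal approximation gives
p ≈ 0.67, not the naive symmetry value 0.5 — the continuity and tie
corrections deliberately bias small-sample p upward. U still equals
n₁n₂/2 there.

**Tie-breaks.** Two introns tied at the round minimum are resolved toward
the larger variant count, then the lower intron index; every such event is
recorded in the result (`tie_events`) so a run can be audited. With
continuous scores ties at the minimum essentially never occur; the rule
exists to make the ranking deterministic on discretized inputs.

## Coordinate conventions

Internal coordinates are 1-based inclusive everywhere (the VCF convention);
BED12 blocks are converted on read. Intron i spans (end of exon i)+1 to
(start of exon i+1)−1; exonic boundary bases are excluded, and indels are
assigned by their VCF position only. On the minus strand, intron numbering
follows transcription order (intron 1 has the highest genomic coordinates).
Abutting exons produce a zero-length intron: the index is consumed, the
record omitted, a warning logged. Genome build is a mandatory tag on
variants and models; mismatches are hard errors (liftover is out of scope).

The legacy element label "C + O kb" names an intronic position by C, the
CDS ordinal of the last coding base of the exon immediately upstream in
transcription order, and O, the distance in kb (one decimal) from the first
intronic base to the queried position. The anchor for an element interval
is a genuine ambiguity in historical usage; this package measures to the
queried position, and callers wanting the conventional interval label
should pass the element's 5′-most base in transcription order. Only the
published legacy correspondences 12↔11, 24↔21, 26↔23 ship as defaults;
anything else must be user-supplied.

## Score table

The join key is the full (chrom, pos, ref, alt) tuple — positional matching
would mis-join multi-allelic sites. The score column is selected by name
(default "GWAS3D"); duplicate keys keep the first record, non-numeric
scores are dropped, and both counts are reported. All scored allele records
are kept by default (no SNV-only filter); scores are consumed as opaque
real values and never recomputed.

## Synthetic data

The generator emulates the real input stack — a multi-exon transcript, a
variant set with positions drawn uniformly without replacement within each
intron, and a score TSV — with a known truth. Defaults are the study-scale
configuration: 26 introns of 10 kb, variant density 10/kb (so 100 variants
per intron), standard-normal background scores, nothing planted. The real
score distribution is not characterized well enough to hard-code, so the
background is a family + parameters (normal, or a two-component normal
mixture; a heavy-tailed preset, 0.9·N(0,1) + 0.1·N(3,2), is included for
robustness checks). Planted effects are location shifts δ or a high-score
mixture component. One PCG64 stream per dataset makes regeneration
bit-identical; fixture writers emit plain-text GFF3/VCF/TSV plus a truth
manifest.

What the generator does *not* emulate: linkage structure between variants,
allele-frequency realism, score–position correlation, and build-specific
coordinates. Passing calibration therefore shows the procedure's behaviour
under independent scores — the exchangeability the rank tests assume — not
robustness to correlated variants.

**Calibration.** `calibration_experiment` reruns generation + sequential
enrichment with per-replicate seed = base seed + replicate index, and
reports the family-wise false-significance rate (null configs) or the
planted-recovery rates (planted configs) with a binomial standard error.
Replicates regenerate only the score layer: variant coordinates never enter
the rank tests, and the file/coordinate path is verified separately by a
write → read → identical-score-sets round-trip test. At the default scale,
2000 null replicates run in about half a minute.

## Reporter assay

Per well, the firefly signal is divided by the β-galactosidase signal
(transfection-efficiency control); per-well folds are that ratio divided by
the *mean* reference-construct ratio (mean, not median — a deliberate
choice, as the upstream convention is unstated), so reference folds average
to exactly 1. SEM is the n−1 sample SD over √n. Construct-vs-reference
comparisons use Student's pooled-variance unpaired t by default with a
Welch option; tests operate on well-level folds (n = 9 wells from 3
transfections × 3 wells is treated as n = 9 — transfection-level averaging
is a known alternative this package does not implement). Stars follow the
figure convention: `**` p < 10⁻¹⁰, `*` p < 0.002. Published fold changes
from the literature are observations, not recomputable targets, since raw
luminescence is generally unpublished.

## Numerical choices and problem sizes

- Exact-enumeration cutoff n₁+n₂ ≤ 12 bounds the enumeration at
  C(12,6) = 924 assignments.
- Quartiles in the per-intron summaries use linear interpolation
  (inclusive order statistics).
- Comparisons of U against its permutation null use a 10⁻⁹ slack to absorb
  float noise in rank sums.
- The test suite and the acceptance script run the Monte-Carlo experiments
  at 2000 null and 500 planted replicates (26 introns × 100 scores), sizes
  at which the binomial standard error on the reported rates is below 0.01
  while the whole suite stays fast on a single CPU; the permutation oracle
  for the asymptotic U p-value uses 10⁵ draws at n = 100 per group.

## Known limitations

- The sequential scheme controls family-wise error conservatively via a
  single Bonferroni threshold; it is not an FDR procedure and offers no
  alpha-spending across rounds.
- Introns without scored variants can never be declared significant but
  still inflate m, making the procedure slightly more conservative.
- Ranking of non-significant introns uses their final-round p-values; introns
  eliminated from contention in earlier rounds are not re-ranked by the
  round in which they last competed.
- Multi-transcript genes must be reduced to one transcript upstream;
  UTR-aware intron subdivision is not performed.
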