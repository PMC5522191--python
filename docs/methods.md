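# Methods

## Scope and coordinate conventions

The package covers the downstream half of a lncRNA study: it consumes
assembled transcript models (GTF), expression tables, coding-potential
verdicts, QTL interval tables and term annotations; it does not align
reads, assemble transcripts, or re-implement coding-potential
classifiers. All internal coordinates are 0-based half-open; external
tables (GTF, QTL) are 1-based inclusive and converted exactly once at the
I/O boundary, so off-by-one drift cannot accumulate. The one deliberate
exception: `QtlRegion` keeps the printed 1-based coordinates because the
QTL score is defined on them (below).

## Identification

The candidate cascade retains a transcript iff spliced length > 200 bp
(strict), exon count ≥ 2, mean per-base fragment coverage ≥ 3, and FPKM
≥ 0.1 in at least one sample. Choices made where conventions differ:

- *≥ 2 exons*, not exactly 2 — the standard multi-exon filter; an
  exactly-2 reading would be incompatible with real isoform-length
  distributions. Configurable via `FilterParams`.
- Coverage is the assembler-reported mean read depth per spliced base
  (the `cov` GTF attribute); the statistic is not standardized across
  assemblers, so it is taken as supplied.
- FPKM ≥ 0.1 as max-over-samples (expressed anywhere ⇒ kept); a
  per-sample mode exists (`fpkm_per_sample=True`).
- The rejection tally attributes each failing transcript to the *first*
  failing rule in cascade order (length, exons, coverage, fpkm).

A transcript is a lncRNA candidate only when all four coding-potential
tools call it noncoding; transcripts missing from any tool's output are
unclassifiable and excluded (with a logged report) rather than silently
kept. Venn cells are reported keyed by the subset of tools voting
noncoding.

Positional classification precedence: (1) exonic overlap with a gene's
exons on the opposite strand → antisense; (2) same strand → sense;
(3) wholly inside a single intron, no exonic overlap → intronic;
(4) otherwise → lincRNA. "Adjacent" is implemented as overlap, not
proximity. When several genes match the winning category the nearest by
midpoint distance is reported (ties by lexicographic gene id); the
category itself never depends on the tie-break. A transcript on a
chromosome absent from the annotation is a lincRNA with a warning.

## Differential expression without replicates

FPKM = fragments × 10⁹ / (spliced length × library size); gene FPKM is
the sum over member transcripts. Fold change is
(FPKM₁ + c)/(FPKM₂ + c) with pseudocount c = 0.01 FPKM, which keeps
zero-expression ratios finite and symmetric (0 vs 0 → FC = 1).

With a single library per condition no dispersion is estimable, so the
p-value engine is the exact conditional binomial test: given total count
n = x₁ + x₂ for a feature, x₁ ~ Binomial(n, p₀) under the null with
p₀ the first library's share of the pooled depth. This is exactly
calibrated when counts are Poisson; real RNA-seq is overdispersed across
biological replicates, so on real data these p-values are
anti-conservative and should be read as a ranking (external per-feature
p-values can be supplied instead). Multiple testing uses
Benjamini–Hochberg (statsmodels step-up, clipped to 1).

Two threshold presets ship because the two natural conventions differ:
`results_text` (default): q < 0.05 and FC ≥ 2 or ≤ 0.5, boundaries
inclusive; `methods_text`: q < 0.01 and |log₂FC| > 1, strict — a feature
with FC exactly 2 is "up" under the first and "ns" under the second.

## Cis targets and QTL colocalization

A gene is a cis target of a lncRNA when the gap between their genomic
bodies is ≤ 100 kb (body-to-body, not TSS-anchored — the window
definition carries no anchor). Upstream/downstream is genome-coordinate
based by default; a strand-aware flag reorients by the lncRNA's strand.

QTL mapping uses any-overlap (≥ 1 bp) of the feature body with the
interval; containment is available by flag. Each QTL is scored as
(# DE lncRNAs)/(span) with span = end − start on the printed 1-based
coordinates. End − start versus end − start + 1 is indistinguishable at
the 3-significant-figure precision such scores are reported at; one
convention was fixed and documented. Ranking is descending by raw
(unrounded) score with ties broken by ascending QTL id. Per-QTL counts
multiply-count a feature overlapping several QTLs, while per-trait
tallies count distinct features; a trait's "number of QTL ids" counts
its QTLs containing at least one DE lncRNA. This is the only reading
under which per-trait totals can exceed the number of distinct DE
lncRNAs while the QTL-id accounting stays coherent.

## Enrichment

Flat hypergeometric over-representation: p = P(X ≥ k) for X ~
Hypergeom(N, K, n), BH across tested terms, fold enrichment
(k/n)/(K/N). The background defaults to all genes with ≥ 1 annotation
(configurable); no ontology-graph propagation or elim-style pruning is
done — this is a generic stand-in for tool-specific GO/KEGG pipelines,
whose term lists depend on external database versions.

## Synthetic data

The generator plants, by construction: positional categories (placements
satisfy the precedence definitions exactly, so recovery is 100% at zero
noise); coding labels with per-tool flip noise (default 5% each way,
typical of tool disagreement); DE effects (|log₂FC| = 2 on 10% of
features, applied to the Luchuan column); and QTL memberships recorded
from the same overlap rule the pipeline uses.

Expression: relative abundances are log-normal(μ=2, σ=1.2) and rescaled
so that Σ FPKMᵢ·lengthᵢ = 10⁹, i.e. expected fragment totals equal the
library size — the FPKM normalization identity for a closed
transcriptome. Because the simulated features *are* the whole
transcriptome, per-feature depth is library_size/n on average; simulated
FPKM values are correspondingly higher than in a real transcriptome of
~10⁵ transcripts, which matters for realism of printed FPKMs but not for
the count statistics the tests exercise. Fragment counts are Poisson
(matching the exact test's calibration); a negative-binomial mode
(dispersion parameter `nb_dispersion`) exists to stress robustness.
Lengths follow the observed mix (mostly 600–1200 bp, a middle band, a
≥ 3 kb tail). Coverage is derived from the deepest sample's fragments at
2×150 bp per fragment.

Default problem sizes — 120 genes, 100 lncRNAs, 3 chromosomes of 30 Mb,
24 QTLs spanning 50 kb–5 Mb, two samples at 2×10⁷ fragments — are chosen
so a full pipeline run takes seconds while every stage sees non-trivial
input; the DE power analysis uses 2000 features at 10⁶ fragments per
library. What the simulation does **not** emulate: biological replicate
variability (hence no claim that the exact test's error control
transfers to real replicated designs), isoform structure shared across
transcripts of one gene (each simulated gene has one transcript, so
gene-level aggregation is exercised structurally, not statistically),
positional correlation between DE status and QTL locations, and
realistic term-to-gene ontology structure.

## Numerical choices and degenerate inputs

- Scores are reported as `%.2E` (3 significant digits); ranking uses the
  unrounded value.
- Library-summary averages: metrics whose values are all integral round
  to the nearest integer, others to 2 decimals.
- Percentages: 100·count/total rounded to 2 decimals; they may sum to
  100 ± 0.05 by rounding.
- A feature with zero fragments in both libraries has p = 1; a term with
  no background gene is skipped; an empty category census is an error.
- Determinism: all simulation randomness flows from one seeded
  generator; pipeline reruns on identical inputs are byte-identical.

## Known limitations

The exact conditional test is valid only per-library (technical, not
biological inference). Proximity-based sense/antisense classification is
out of scope (overlap only). Trans-target prediction by co-expression is
deliberately absent: with two conditions a correlation is meaningless.
QTL coordinate basis in public databases is assumed 1-based inclusive;
if a source differs the single conversion point in `lincqtl.io` is the
place to change it.
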