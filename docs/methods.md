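# Methods

## Coordinates and formats

All internal coordinates are 0-based half-open on named chromosomes, so
overlap length is `max(0, min(e1, e2) − max(s1, s2))` with no ±1
bookkeeping; GTF input/output shifts at the boundary (1-based inclusive) and
BED output needs no shift. Assembled transcripts are read from exon-grouped
GTF (lines sharing a `transcript_id`); parsing is order-invariant and
round-trips exactly. Expression is a long-format TSV
(`transcript_id, time_point, genotype, replicate, fpkm`) rather than any
assembler's native tracking dialect; converting a tracking file means
mapping its columns onto these five. Duplicate keys, negative FPKM and
unknown time-point/genotype labels are rejected at load; missing conditions
stay missing (no silent zeros).

Result tables are written with a fixed column order:

| table | columns |
|---|---|
| candidates | transcript_id, chrom, start, end, strand, length |
| novelty | transcript_id, verdict, matched_id, d5, d3 |
| coding | transcript_id, orf_length, orf_coverage, score, verdict |
| de_matrix | transcript_id, de_t1..de_t5 |
| calls | transcript_id, call_t1..call_t5, is_differential, is_tml |
| correlation | lncrna_id, gene_id, side, gap, n, r, r2, p, q, sign, strong, significant |
| enrichment | term, k, K, n, N, fold_enrichment, p, q |

## Novelty filter

Gene-body overlap is tested first, then UTR-extension overlap, then end
proximity to known noncoding transcripts; verdicts partition the input.
Overlap is counted at ≥ 1 bp with no fractional threshold, and is
strand-blind by default: antisense transcripts overlapping coding genes are
outside the intergenic analysis either way, so rejecting them regardless of
strand reproduces that exclusion. A strand-aware mode exists; unstranded
records match both strands.

The end-divergence rule is interpreted per known transcript with
conjunction: a candidate *matches* a known ncRNA iff both
`|start_cand − start_known| ≤ 50` and `|end_cand − end_known| ≤ 50`
(absolute genomic offsets, orientation-independent); novelty requires no
match. Because the wording "ends more than 50 bp different" is ambiguous, an
`either` end-rule is available in which one close end suffices to match
(stricter against candidates). Containment inside a longer known transcript
with both ends distant does not reject — the ends govern. Different
chromosome means infinite divergence. The interval index (interval trees
per chromosome) is contractually identical to a brute-force scan, and a
brute-force classifier is kept in the package as the cross-check.

## Coding-potential screen

The screen is a deliberately small, fully documented classifier, not a
reimplementation of SVM-based coding-potential tools: from the longest
ATG-initiated, stop-terminated ORF (stop codon included, so length ≡ 0
mod 3; codons containing N are neither starts nor stops; ties broken by
smaller offset then lower frame),

```
score = 0.5 * min(ORF_nt / 300, 1) + 0.5 * ORF_nt / transcript_nt
coding-like  iff  score > 0.5  and  ORF_nt >= 300
```

Three frames are scanned on the annotated strand (assembled transcripts are
stranded); a 6-frame mode handles unstranded input. The 300-nt (100-codon)
ORF threshold and the 0.5 weights/threshold are configurable. External
scorer output can be substituted via a TSV hook, which bypasses the internal
score entirely. The lncRNA length convention is strict: retained transcripts
have length > 200 nt (so a 200-nt transcript is excluded).

## Differential expression and TML calls

Replicate FPKMs are averaged per (time point, genotype) *before* the ratio;
`de_t = log2((mut_t + c)/(wt_t + c))` with pseudocount `c = 1` FPKM by
default. The pseudocount is mandatory in spirit: many of these transcripts
are undetectable in wild type, and `c = 1` is a conventional, documented
choice (with `c = 0` a zero wild-type mean is a hard error). The two-fold
threshold is inclusive (`|de| ≥ 1`). A TML is `(∃t: up) ∧ (∀t: ¬down)`.
"Detected" means mutant mean FPKM ≥ 1 (configurable); it controls the
stage-membership bookkeeping and the FPKM summary, not the calls.

Stage sets are computed from up-memberships over the five stages
(presenescence, early senescence, late senescence, early survivor,
survivor): upregulated anywhere; in > 1 time point; senescence-exclusive
(non-empty membership ⊆ {early, late senescence}); survivor-specific
(membership exactly {survivor}); all five. The groupings are configurable
because reasonable alternatives exist (e.g. folding early survivor into the
survivor class); the defaults are the two senescence stages and the final
survivor stage only.

Summary statistics: median candidate length, and the median over candidates
of each candidate's median mutant FPKM across its detected time points.

## Correlation analysis

Adjacency is strand-blind nearest-gene-by-gap on each genomic side (`5p` =
lower coordinates, `3p` = higher), ties broken by lower gene start then id;
a chromosome end yields an absent neighbor; no distance cap by default. An
lncRNA overlapping a gene violates the precondition (it cannot have passed
the filter) and raises.

Pearson `r` uses the standard product-moment formula; the two-sided p comes
from the t transform with n − 2 df (`scipy.stats.pearsonr`), with p = 0
reported as the limiting value at |r| = 1 and zero-variance vectors excluded
and logged. Two observation modes: the five per-time-point DE values
(default for tables; df = 3) and per-replicate DE values (n = 10; df = 8),
the latter retained because five observations give very little power.
Per-time-point 2D scatter tables of (lncRNA DE, neighbor DE) are emitted
alongside the across-time-point fits, since "correlation at a time point"
and "correlation across time points" are both meaningful summaries of such
a design. "Strong" flags `R²` inside `[0.79, 0.99]` (configurable band);
"significant" is raw `p < 0.05` and a Benjamini–Hochberg `q` over the tested
pairs is always emitted alongside — raw p mirrors the headline analysis,
`q` guards the multiple-testing question.

At n = 5 the t-based p tracks the exact permutation p (all 120 orderings)
with no ensemble bias and near-perfect rank agreement, but individual
vectors can differ noticeably because the permutation null is discrete and
lumpy; the test suite checks exactly this calibration statement rather than
a per-vector identity that small-sample statistics cannot deliver.

The genome-wide matrix holds Pearson r between every retained lncRNA and
every expressed gene; rows and columns are ordered by average-linkage
agglomerative clustering on the `1 − r` distance between profiles, with
ids pre-sorted so leaf order is deterministic.

## Enrichment

Standard hypergeometric upper tail
`p = Σ_{i≥k} C(K,i)·C(N−K,n−i)/C(N,n)` (computed via the stable survival
function), BH adjustment across terms, fold enrichment `(k/n)/(K/N)`. The
universe defaults to genes carrying an expression profile — the standard
guard against detection bias — and term files are user-supplied; no
ontology snapshot is bundled and no term-redundancy clustering is
attempted. This is a deliberately transparent surrogate for web-service
enrichment tools: the scientific claim it supports is qualitative
over-representation.

## Synthetic study generator

The generator emulates the statistical structure of the real study at desk
scale and is the test bed for every stage. Defaults (all in
`SimulationConfig`):

* **Genome/annotation** — 2 chromosomes × 250 kb; 48 genes of 0.9–2.4 kb
  with ≥ 2.5 kb gaps, UTR extents 100 bp (5′) and 150 bp (3′), one long
  planted ORF per gene; 10 known noncoding transcripts (320–700 nt) placed
  intergenically with 200 bp clearance.
* **Candidates** — 14 truly novel (lognormal lengths, median 467 nt, the
  reported median for this transcript class; clipped to ≥ 230 nt so the
  length gate is not the tested variable), 4 gene-overlapping, 3
  UTR-overlapping, 3 gene-extension decoys abutting a gene end with gap 0,
  and 5 near-duplicates of known ncRNAs with end offsets cycling through
  (10,10), (49,49), (50,50), (51,0), (120,120) — straddling the 50-bp
  boundary so the rule itself is exercised. Duplicate ground-truth labels
  are computed by applying the documented end rule to the planted offsets.
  Truly novel candidates occupy distinct gene-bounded gaps so that
  adjacency-based ground truth stays unambiguous. Candidates are single-exon
  (the transcript class under study shows single bands on blots);
  noncoding candidates are rejection-sampled to carry no ORF ≥ 300 nt.
* **Expression** — wild-type FPKM = baseline × lognormal noise
  (σ = 0.25, natural log — a mild bulk-RNA-seq replicate dispersion;
  replicates independent); mutant = baseline × 2^fold × noise. Profile
  classes among the truly novel: 8 broad TMLs (each time point up with
  probability 0.6 at log2 fold U(2, 4.5), i.e. 4–23-fold — consistent with
  transcripts undetectable in wild type), 4 stage-specific transcripts
  (wild-type baseline 0.4 FPKM below the detection threshold, ~12-fold up
  only in their stage), 1 up-and-down decoy (never a TML), 1 flat.
  lncRNA baselines are log-uniform 1.5–7 FPKM (low, as observed for this
  class); gene baselines 20–200 FPKM.
* **Planted correlations** — 8 lncRNA–neighbor pairs with signed targets
  |r| ∈ 0.96–0.99 (the strongly correlated class). The partner profile is
  constructed in the centered 5-dimensional space as
  `g = r·û₁ + √(1−r²)·û₂` with `û₁` the lncRNA's standardized profile and
  `û₂` a random orthogonal direction, so the noise-free sample correlation
  equals the target exactly; measurement noise then attenuates it, which is
  the realistic regime. Partner genes are chosen uniquely adjacent to one
  variance-bearing lncRNA.
* **Enrichment fixture** — 8 terms; each gene gets one uniform base term,
  and planted partner genes additionally join "membrane" with
  probability 0.9.

Everything derives from `numpy.random.default_rng([seed, stream])` streams
and reproduces byte-for-byte.

What the generator does **not** emulate: read-level sampling noise and its
length/GC biases, assembler boundary errors, multi-exon structures (behind
no flag currently — candidates are single-exon), correlated replicate
effects (batches), antisense transcription, and overdispersion beyond
log-normal. Passing tests therefore demonstrate correctness of the
operators and adequate power under a clean generative model, not
performance on real libraries.

## Operating characteristics and problem sizes

Design-time power analysis under the default conditions (per-replicate
correlation mode, n = 10, df = 8): planted |r| 0.96–0.99 attenuates to
≈ 0.87–0.90 observed, giving per-pair raw-p power ≈ 0.95; TML calls have
per-transcript error well below 1%. The regression tests assert, aggregated
over 20 seeds: TML recall and precision ≥ 0.9, significant-pair
(raw p < 0.05) recall ≥ 0.9, and FDR-controlled (q < 0.05) pair precision
≥ 0.9. Raw-p precision is *not* asserted: with ~20 null neighbor pairs per
study, a 5% type-I rate puts expected raw-p precision near 0.85 for any
correct implementation — the BH column is the precision-bearing call.
Noise-free runs recover every planted label exactly.

Test-suite problem sizes were chosen so the whole suite runs in well under
a minute of pure Python/numpy: 1,000 transcripts × 200 features for the
filter oracle, 200 random 300-nt sequences for the ORF oracle, exhaustive
enumeration of all hypergeometric instances with N ≤ 50, all 120
permutations × 100 vectors for p calibration, and 20 simulated studies for
the recovery regression.

## Known limitations

* The coding screen is ORF-geometry only; a transcript with a long ORF and
  no homology evidence is still called coding-like, and short peptides are
  invisible. The external-scores hook is the escape hatch.
* Five (or ten) observations per correlation keep power low and confidence
  intervals wide; the raw p < 0.05 flag is exploratory by construction.
* The transcript length used everywhere is the genomic span; for the
  default single-exon transcripts this equals mature length, but multi-exon
  input would need a spliced-length refinement of the length gate.
* UTR extents are user-supplied constants per gene, not inferred from data.
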