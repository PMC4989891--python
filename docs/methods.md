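# Methods

This note records the statistical procedures, the defaults and the design
choices behind `mirnetppi`, in the spirit of a model-description chapter:
what is computed, under which assumptions, and what the synthetic
benchmarks do and do not demonstrate.

## SAM differential expression (miRNA arrays)

The two-class unpaired SAM statistic for feature *i* is
d_i = (x̄₂ᵢ − x̄₁ᵢ)/(sᵢ + s₀) with the pooled standard error
sᵢ = √[(1/n₁ + 1/n₂)(SS₁ᵢ + SS₂ᵢ)/(n₁ + n₂ − 2)]. Class 1 is the
reference (e.g. WT) and class 2 the treatment (e.g. KO); positive d means
up in the treatment. Assumptions: exchangeable samples within class,
roughly symmetric noise on the (log-scale) intensities; no distributional
form is imposed because the null is permutation-based.

**s₀ (fudge constant).** Candidates are the 0th–100th percentiles (step 5)
of s. For each candidate, features are split into up to 100 equal-count
windows by s, the median absolute deviation of d is computed per window,
and the candidate minimizing the coefficient of variation of these MADs
wins (ties → smaller s₀). This stabilizes d for low-variance features;
the search is deterministic. A fixed s₀ can be supplied instead.

**Permutation null.** Class labels are permuted; for each permutation the
full d vector is recomputed (same s₀) and sorted. The expected order
statistic d̄₍ᵢ₎ is the mean of the i-th sorted value over permutations.
When the requested permutation count is at least C(n, n₁) the distinct
assignments are enumerated exhaustively — for the default 4-vs-4 design
that is 70 assignments, so "1000 permutations" is exact there. Sampled
mode uses a seeded generator and is reproducible.

**Calling and FDR.** With observed d sorted against d̄, the walk from the
top continues while d₍ᵢ₎ − d̄₍ᵢ₎ > delta; the smallest observed d in that
run is the up cut (ties at the cut are all called), symmetrically below.
π₀ is estimated as #{observed d inside the 25th–75th percentile band of
all permuted d}/(0.5·p), capped at 1. The median FDR is
π₀ · median_b #{permuted d outside the cuts}/#called, capped at 1. Calls
are nested in delta by construction (larger delta ⊆ smaller delta).
`tune_delta` reproduces the interactive use of the delta slider: it scans
a grid and returns the delta whose call count is closest to a requested
size (ties → larger delta). Defaults: 1000 permutations, delta 2.

**mRNA side.** RNA-seq designs with one library per condition cannot
support a permutation test, so the gene table uses
log2((x̄_KO + c)/(x̄_WT + c)) with pseudocount c = 1.0 and a call
threshold of 1.0 (|log2FC| ≥ 1); q-values are not reported there. Count
models (DESeq-style) are out of scope: the input is an FPKM-like matrix,
not read counts.

## Target integration and negative-correlation screen

Predictor tables are normalized to (miRNA, gene, source, score); within a
source, duplicate pairs keep the best score (most negative context score
for TargetScan-dialect, highest otherwise). After restriction to the
called miRNAs the module computes per-source pair sets, their union and
intersection, gene-level projections and multi-targeted genes
(genes hit by ≥ 2 distinct miRNAs). The union policy is the default —
predictors disagree too much for the intersection to be the primary
object. *Shared gene percentage* is floor(100·|∩ genes|/|∪ genes|), where
the gene-level intersection means "named as a target by every predictor,
via any called miRNA".

Screening: with ≥ 3 shared samples between the miRNA and mRNA matrices,
a pair passes iff Pearson (or Spearman) correlation across shared samples
is strictly below the threshold (default 0 — strict negativity; there is
no canonical cutoff, so the weakest defensible one is the default and is
configurable). With < 3 shared samples the screen degenerates to
direction opposition (miRNA up & gene down, or vice versa), which is the
behaviour a two-sample design induces. Pairs with a constant expression
vector have undefined correlation and fail the screen. Pairs whose gene
or miRNA lacks an expression row are reported in a `missing` list, never
silently dropped.

## Over-representation analysis

p = P(X ≥ k), X ~ Hypergeom(N, K, n): N = universe size, K = set size
within the universe, n = query size, k = hits. EASE mode evaluates the
tail at k−1 (floored at 0), which is strictly conservative and mirrors
DAVID's modified Fisher score; the unmodified test is the default for
transparency. The universe defaults to all genes with expression data
rather than all genes in the GMT — enrichment should be judged against
what could have been observed. BH q-values use the standard step-up.
The report filter keeps sets with ≥ 8 hits (the workflow's reporting
convention) ordered by (p, name). The term–term view is reduced to a
Jaccard overlap network on hit-gene lists (edge iff J ≥ 0.4); a full
kappa-statistic term clustering is deliberately not implemented.

## PPI neighborhood concordance

One-hop neighbors of the seed with combined score ≥ 0.9 (STRING's
"highest confidence"), ranked by score (ties by name), truncated to the
top 20. Expression calls are joined onto neighbors; the concordance rule
table, evaluated in order, is a *total* function:

1. either direction unknown → uninformative
2. inhibition-flagged neighbor up, seed down → inhibitor-up_seed-down
   (loss-of-function consistent)
3. inhibition-flagged neighbor down, seed up → inhibitor-down_seed-up
4. remaining inhibition-flagged → inhibitor-concordant
5. binding-flagged neighbor moving with the seed → complex co-regulation
6. binding-flagged neighbor moving against the seed → binding-discordant
7. no action annotation → unannotated

Classes 4 and 7 are this package's additions: the classical narrative
(rules 1–3, 5, 6) does not cover inhibitors moving with the seed or
unannotated edges, and a classifier that silently skips rows would make
the summary counts lie. Inhibition takes precedence when both flags are
present, matching curated tables where inhibitors also bind. The
vocabulary is an artifact-defined convention formalizing the G-protein
reading: RGS-like inhibitors up while Gα is down ⇒ consistent with lost
seed activity; Gβ-like partners co-down ⇒ the complex is not formed.

## Adapter trimming

The adapter (default Illumina TruSeq R1/R2 sequences) is scanned at every
start position left to right; interior positions require the full adapter
with ≤ 2 mismatches (N always mismatches), 3'-end positions allow a
prefix overhang of ≥ 8 bases (min_overlap) under the same budget — 8
keeps random partial hits near 4⁻⁸ per position. The leftmost hit wins;
the read and quality are cut at the hit. A pair is discarded when either
trimmed mate is ≤ 18 bp (the boundary is exclusive: 18 discarded, 19
kept); whole-pair discarding keeps mates synchronized for downstream
aligners, and a single-mate mode is available. Quality-based trimming and
alignment are out of scope.

## Synthetic studies

`generate_study` emulates the two-class design end to end: miRNA
intensities are baseline (U(6,10)) plus a class shift of ±3 within-class
SD for 10 up / 5 down planted miRNAs plus N(0,1) noise, 4 samples per
class; each of the 30 targets per DE miRNA is
baseline − β·centered(miRNA) + noise with β = 1 (genes with several
regulators couple to their mean), other genes independent; FPKM-mode
values are clipped at 0. Predictor tables contain every true pair
(assigned to both tables with probability 0.36, else to one at random),
plus 0.25 decoy pairs per true pair (uncoupled genes, emulating predictor
false positives) and two background pairs per non-DE miRNA. One gene set
of 40 is planted with 75 % true-target genes among 30 random background
sets; the PPI graph realizes a seed with 3 co-moving binders, 2
counter-moving inhibitors, 1 co-moving inhibitor, 1 counter-moving
binder, 1 unannotated and 2 expression-absent neighbors (directions are
forced into the mRNA matrix as ±1.2 log2 fold changes so the overlay
sees them through the ordinary caller), plus 20 background edges. The
truth record lists every planted object; identical seeds give
byte-identical files.

What the generator does **not** emulate: count-level sequencing noise and
library-size effects (values are Gaussian on an FPKM-like scale),
miRNA-family seed-sequence structure, correlated co-expression modules,
batch effects, and realistic predictor score distributions. Passing the
planted-recovery benchmarks therefore shows the pipeline's logic and
statistics are correct under its own model, not that the defaults are
tuned for any particular real platform.

With these conditions, a planted effect of 3 SD sits inside the
permutation null's tails (the null is computed over all features,
including planted ones), so the fixed delta = 2 is conservative on the
synthetic arrays; the recovery benchmarks follow the interactive-SAM
usage and tune delta to ≈ 15 calls before scoring, while the pure-null
benchmark keeps delta = 2.

## Numerical and degenerate-input choices

- Zero pooled SE: d uses s + s₀ in the denominator; if that is 0 the
  statistic is defined as 0 (constant feature).
- All-zero s vector → s₀ = 0 with a warning; < 10 features → the s₀
  search warns that it is unreliable.
- Nothing called → median FDR is reported as None, never 0.
- Expression TSVs are written with `repr` floats, so read(write(X)) is
  bit-exact; report JSON is key-sorted, so identical configs and seeds
  produce byte-identical reports.
- STRING scores given as integers are detected by any value > 1 and
  divided by 1000; undirected edges are canonicalized lexicographically,
  duplicates keep the max score and the union of action flags.
- Identifiers are opaque and case-sensitive; an optional normalization
  hook trims whitespace (default) and can uppercase.

## Known limitations

- SAM here is two-class unpaired only (no paired, multiclass or survival
  designs).
- The mRNA caller is a fold-change heuristic without inference; with
  replication a count-based model should replace it upstream.
- The EASE/hypergeometric tests assume a well-chosen universe; enrichment
  against a mis-specified background is not detectable from within.
- Concordance classes are descriptive labels, not causal claims; they
  depend on the completeness of the action annotations in the edge list.
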