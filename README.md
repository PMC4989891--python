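# mirnetppi

Integrated miRNA–target mRNA and protein–protein interaction (PPI) network
analysis for two-class omics studies.

When a multi-functional transcription factor is knocked out, a plain
differentially-expressed-gene list rarely explains what the gene does: the
signal is spread across transcription, post-transcriptional (miRNA)
regulation and protein-complex activity. `mirnetppi` implements a
three-level workflow for exactly this situation — e.g. spinal-cord miRNA
arrays and RNA-seq from knockout (KO) vs wild-type (WT) mice:

1. **Differential miRNA calling (SAM).** Two-class unpaired Significance
   Analysis of Microarrays: per-feature moderated statistic

   d_i = (x̄₂ᵢ − x̄₁ᵢ) / (sᵢ + s₀),  sᵢ = √[(1/n₁ + 1/n₂) · (SS₁ᵢ + SS₂ᵢ)/(n₁+n₂−2)]

   with the fudge constant s₀ chosen by percentile search, a
   permutation-derived expected-order-statistic null (exhaustive
   enumeration whenever the permutation budget covers all C(n, n₁) label
   assignments), delta-band calling on the observed-vs-expected plot, and
   a median-FDR estimate π₀ · median_b #{d*_b outside cuts} / #called.
2. **Target integration (MMIA-style).** Predicted targets of the called
   miRNAs are merged across predictor tables (TargetScan- and
   miRDB-dialect parsers included; union policy by default), then screened
   for anti-concordant expression: a pair (miRNA m, gene g) survives iff
   corr(m, g) < 0 across shared samples (Pearson by default), degenerating
   to strict direction opposition when fewer than three samples are
   shared. The surviving pairs form a bipartite miRNA–mRNA network
   exported as SIF/GraphML for Cytoscape.
3. **Pathway over-representation.** Hypergeometric upper-tail test of the
   screened genes against a GMT collection, P(X ≥ k) with X ~
   Hypergeom(N, K, n), optional EASE variant (tail evaluated at k−1, the
   DAVID convention), Benjamini–Hochberg q-values, the ≥8-hit report
   filter, and KEGG-mapper-style coloring (up = red, down = blue, other =
   light green).
4. **PPI neighborhood concordance.** The top-k STRING neighbors of a seed
   gene (combined score ≥ 0.9, k = 20) are overlaid with expression calls
   and classified by a total rule table: an up-regulated *inhibitor* of a
   down-regulated seed is loss-of-function consistent (the Rgs1/Rgs19 vs
   Gnai1 configuration), a co-down-regulated *binding* partner indicates
   the complex is not formed (the Gnb1/Gnb2/Gnb4 configuration).

A FASTQ adapter-trimming stage (2-mismatch adapter search, pairs discarded
when a trimmed mate is ≤ 18 bp) and a synthetic-study generator with
planted ground truth round out the toolkit, so every stage can be
exercised and scored without downloads.

## Worked example

Generate a synthetic study (200 miRNAs with 10 up / 5 down planted at 3 SD,
2 000 genes with 30 negatively coupled targets per DE miRNA, 4 vs 4
samples, a planted pathway and a planted Gnai1 neighborhood), then run the
whole workflow:

```sh
mirnetppi synth --out-dir fx --seed 11
mirnetppi run --config study.yaml     # paths to fx/, seed 3, delta tuned to ~15 calls
```

prints (abridged):

```json
"de_mirna":    {"n_features": 200, "n_called": 15, "n_up": 9, "n_down": 6,
                "delta": 0.284, "s0": 1.474, "pi0": 0.88, "fdr_median": 0.059}
"integration": {"n_union_pairs": 456, "n_intersection_pairs": 182,
                "n_union_genes": 423, "shared_gene_percentage": 42,
                "n_passed": 391, "method": "pearson"}
"ppi":         {"seed": "Gnai1", "seed_direction": "down", "n_neighbors": 10,
                "n_per_class": {"inhibitor-up_seed-down (loss-of-function consistent)": 2,
                                "complex co-regulation": 3, "binding-discordant": 1,
                                "inhibitor-concordant": 1, "unannotated": 1,
                                "uninformative": 2}}
```

Reading: SAM called 15 miRNAs at the tuned delta with an estimated median
FDR of 5.9 %; 456 predicted miRNA–target pairs were screened and 391
passed the negative-correlation filter; around the down-regulated seed the
two planted up-regulated inhibitors classify as loss-of-function
consistent and the three co-down binding partners as complex
co-regulation. Each stage is also exposed individually (`mirnetppi trim |
de-mirna | integrate | enrich | ppi | synth`).

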