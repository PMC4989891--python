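"""miRNA-target integration (MMIA-style).

Merges target-prediction tables from several predictors for the called
miRNAs, screens each miRNA-gene pair for expression anti-concordance
(a repressing miRNA should move opposite to its target), and builds the
bipartite miRNA-mRNA network for export.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DECall, log2fc_table
from .io_formats import ExpressionMatrix, IntegrityError, TargetPredictionTable

Pair = tuple[str, str]


def shared_percentage(n_intersection: int, n_union: int) -> int:
    """floor(100 * intersection / union); 0 for an empty union."""
    if n_union == 0:
        return 0
    return math.floor(100 * n_intersection / n_union)


@dataclass
class MergedTargets:
    """Set algebra over predictor tables restricted to called miRNAs.

    ``union_genes`` projects the union pair set to genes;
    ``intersection_genes`` is the intersection of the per-source gene
    projections (a gene counts as shared when every predictor names it
    as a target of some called miRNA, not necessarily the same one).
    """

    union_pairs: set[Pair]
    per_source: dict[str, set[Pair]]
    intersection_pairs: set[Pair]
    union_genes: set[str]
    intersection_genes: set[str]
    multi_targeted_genes: set[str]
    restrict_to: set[str]
    policy: str = "union"

    @property
    def pairs(self) -> set[Pair]:
        return self.union_pairs if self.policy == "union" else self.intersection_pairs

    @property
    def shared_gene_percentage(self) -> int:
        return shared_percentage(len(self.intersection_genes), len(self.union_genes))

    def summary(self) -> dict:
        return {
            "n_union_pairs": len(self.union_pairs),
            "n_intersection_pairs": len(self.intersection_pairs),
            "n_union_genes": len(self.union_genes),
            "n_intersection_genes": len(self.intersection_genes),
            "n_multi_targeted_genes": len(self.multi_targeted_genes),
            "shared_gene_percentage": self.shared_gene_percentage,
            "per_source_genes": {s: len({g for _, g in p}) for s, p in self.per_source.items()},
            "policy": self.policy,
        }


def merge_predictions(
    tables: Sequence[TargetPredictionTable],
    restrict_to: set[str],
    policy: str = "union",
) -> MergedTargets:
    """Merge predictor tables, keeping only pairs whose miRNA was called.

    The union policy (default) carries every predicted pair downstream;
    intersection keeps only pairs named by all predictors.
    """
    if not restrict_to:
        raise ValueError("restrict_to must be a non-empty set of called miRNAs")
    if policy not in ("union", "intersection"):
        raise ValueError(f"unknown merge policy {policy!r}")
    per_source: dict[str, set[Pair]] = {}
    for t in tables:
        for src, grp in t.rows.groupby("source", sort=True):
            pairs = {
                (m, g)
                for m, g in zip(grp["mirna_id"], grp["gene_id"])
                if m in restrict_to
            }
            per_source.setdefault(src, set()).update(pairs)
    union_pairs: set[Pair] = set().union(*per_source.values()) if per_source else set()
    if per_source:
        intersection_pairs = set.intersection(*per_source.values())
        gene_sets = [{g for _, g in p} for p in per_source.values()]
        intersection_genes = set.intersection(*gene_sets)
    else:
        intersection_pairs, intersection_genes = set(), set()
    union_genes = {g for _, g in union_pairs}
    counts: dict[str, set[str]] = {}
    for m, g in union_pairs:
        counts.setdefault(g, set()).add(m)
    multi = {g for g, ms in counts.items() if len(ms) >= 2}
    if not union_pairs:
        import warnings

        warnings.warn("no predicted pairs left after restricting to called miRNAs")
    return MergedTargets(
        union_pairs, per_source, intersection_pairs, union_genes, intersection_genes,
        multi, set(restrict_to), policy,
    )


# ---------------------------------------------------------------------------
# Negative-correlation screening
# ---------------------------------------------------------------------------

@dataclass
class ScreenedPair:
    mirna: str
    gene: str
    mirna_direction: str
    gene_direction: str
    gene_log2fc: float | None
    correlation: float | None
    method: str  # pearson | spearman | direction-opposition
    passed: bool


@dataclass
class ScreenResult:
    pairs: list[ScreenedPair]
    missing: list[tuple[str, str, str]]  # (mirna, gene, reason) — reported, not dropped silently
    method: str

    @property
    def passed_pairs(self) -> list[ScreenedPair]:
        return [p for p in self.pairs if p.passed]

    def summary(self) -> dict:
        return {
            "n_screened": len(self.pairs),
            "n_passed": len(self.passed_pairs),
            "n_missing_data": len(self.missing),
            "method": self.method,
        }


def screen_negative_pairs(
    merged: MergedTargets,
    mirna_calls: Sequence[DECall],
    mirna_matrix: ExpressionMatrix,
    mrna_matrix: ExpressionMatrix,
    method: str = "auto",
    threshold: float = 0.0,
    pseudocount: float = 1.0,
) -> ScreenResult:
    """Keep miRNA-gene pairs whose expression is anti-concordant.

    With at least 3 shared samples the pair passes iff the chosen
    correlation (default Pearson) across shared samples is strictly
    below ``threshold`` (default 0).  With fewer shared samples the
    screen degenerates to direction opposition: miRNA up & gene down,
    or miRNA down & gene up (gene direction from the log2 fold change).
    Pairs whose gene (or miRNA) lacks an expression row are reported in
    ``missing`` rather than silently dropped.  Output is sorted by
    (mirna, gene).
    """
    call_by_id = {c.feature_id: c for c in mirna_calls}
    shared = [s for s in mirna_matrix.sample_ids if s in set(mrna_matrix.sample_ids)]
    if method == "auto":
        method = "pearson" if len(shared) >= 3 else "direction-opposition"
    if method in ("pearson", "spearman") and len(shared) == 0:
        raise IntegrityError("miRNA and mRNA matrices share no samples")
    gene_fc = {c.feature_id: c for c in log2fc_table(mrna_matrix, pseudocount=pseudocount)}
    mirna_feats = set(mirna_matrix.feature_ids)
    mrna_feats = set(mrna_matrix.feature_ids)

    out: list[ScreenedPair] = []
    missing: list[tuple[str, str, str]] = []
    for mirna, gene in sorted(merged.pairs):
        call = call_by_id.get(mirna)
        if call is None:
            missing.append((mirna, gene, "no miRNA call"))
            continue
        if mirna not in mirna_feats:
            missing.append((mirna, gene, "no miRNA expression row"))
            continue
        if gene not in mrna_feats:
            missing.append((mirna, gene, "no gene expression row"))
            continue
        gcall = gene_fc[gene]
        if method in ("pearson", "spearman"):
            x = mirna_matrix.values.loc[mirna, shared].to_numpy(dtype=float)
            y = mrna_matrix.values.loc[gene, shared].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                corr = None  # constant vector: correlation undefined
                passed = False
            else:
                if method == "pearson":
                    corr = float(stats.pearsonr(x, y).statistic)
                else:
                    corr = float(stats.spearmanr(x, y).statistic)
                passed = corr < threshold
        else:
            corr = None
            passed = (call.direction == "up" and gcall.direction == "down") or (
                call.direction == "down" and gcall.direction == "up"
            )
        out.append(
            ScreenedPair(
                mirna, gene, call.direction, gcall.direction,
                float(gcall.score), corr, method, bool(passed),
            )
        )
    return ScreenResult(out, missing, method)


def screened_pairs_frame(result: ScreenResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (p.mirna, p.gene, p.mirna_direction, p.gene_direction,
             p.gene_log2fc, "" if p.correlation is None else p.correlation,
             p.method, int(p.passed))
            for p in result.pairs
        ],
        columns=["mirna", "gene", "mirna_direction", "gene_direction",
                 "gene_log2fc", "correlation", "method", "passed"],
    )


# ---------------------------------------------------------------------------
# Bipartite network
# ---------------------------------------------------------------------------

def build_mir_mrna_network(
    passed_pairs: Sequence[ScreenedPair],
    mirna_calls: Sequence[DECall],
    gene_calls: Sequence[DECall],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attributed bipartite miRNA-mRNA network (nodes, edges) tables.

    miRNA nodes are colored red and gene nodes blue; the intensity
    attribute is |score| rescaled to [0,1] within each node class.
    Edges are the passed pairs with relation ``targets``.  Feed the
    result to :func:`mirnetppi.io_formats.write_network`.
    """
    mirna_score = {c.feature_id: abs(c.score) for c in mirna_calls}
    gene_score = {c.feature_id: abs(c.score) for c in gene_calls}
    mirnas = sorted({p.mirna for p in passed_pairs})
    genes = sorted({p.gene for p in passed_pairs})
    max_m = max((mirna_score.get(m, 0.0) for m in mirnas), default=0.0)
    max_g = max((gene_score.get(g, 0.0) for g in genes), default=0.0)
    node_rows = []
    for m in mirnas:
        sc = mirna_score.get(m, 0.0)
        node_rows.append((m, "mirna", "red", sc / max_m if max_m else 0.0))
    for g in genes:
        sc = gene_score.get(g, 0.0)
        node_rows.append((g, "gene", "blue", sc / max_g if max_g else 0.0))
    nodes = pd.DataFrame(node_rows, columns=["id", "type", "color", "intensity"])
    edges = pd.DataFrame(
        [(p.mirna, "targets", p.gene) for p in sorted(passed_pairs, key=lambda p: (p.mirna, p.gene))],
        columns=["source", "relation", "target"],
    )
    return nodes, edges
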