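"""Over-representation analysis of gene lists against gene-set collections.

The p-value is the upper-tail hypergeometric probability of seeing at
least the observed number of query genes inside a set, given the
universe; the EASE variant (the conservative modified Fisher test used
by DAVID) recomputes it with one hit removed.  Benjamini-Hochberg
controls the FDR across the collection, and the minimum-hit filter plus
KEGG-mapper-style node coloring reproduce the downstream reporting
conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations as _combs
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DECall
from .io_formats import ConfigError, GeneSetCollection


@dataclass
class EnrichmentRow:
    set_name: str
    hits: int  # k
    query_size: int  # n
    set_size: int  # K (restricted to the universe)
    universe_size: int  # N
    p_value: float
    q_value: float | None
    hit_genes: list[str]


def _hypergeom_upper(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora_test(
    query: set[str],
    collection: GeneSetCollection,
    universe: set[str],
    mode: str = "hypergeometric",
    include_zero_hits: bool = False,
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Query genes outside the universe are dropped with a warning count;
    set members are restricted to the universe before counting.  In
    ``ease`` mode the upper tail is evaluated at k-1 (floored at 0).
    Rows are returned for every set with at least one hit (all sets if
    ``include_zero_hits``), sorted by ascending p then set name.
    """
    if mode not in ("hypergeometric", "ease"):
        raise ConfigError(f"unknown ORA mode {mode!r}")
    if not universe:
        raise ConfigError("empty universe")
    outside = query - universe
    if outside:
        warnings.warn(f"{len(outside)} query gene(s) outside the universe were dropped")
    q = query & universe
    N, n = len(universe), len(q)
    rows: list[EnrichmentRow] = []
    for name in sorted(collection.sets):
        members = set(collection.sets[name].genes) & universe
        K = len(members)
        hit_genes = sorted(q & members)
        k = len(hit_genes)
        if k == 0 and not include_zero_hits:
            continue
        k_eval = max(0, k - 1) if mode == "ease" else k
        p = _hypergeom_upper(k_eval, N, K, n)
        rows.append(EnrichmentRow(name, k, n, K, N, p, None, hit_genes))
    rows.sort(key=lambda r: (r.p_value, r.set_name))
    return rows


def adjust_bh(rows: Sequence[EnrichmentRow]) -> list[EnrichmentRow]:
    """Benjamini-Hochberg step-up q-values over the collection (in place)."""
    rows = list(rows)
    if not rows:
        return rows
    p = np.array([r.p_value for r in rows])
    q = stats.false_discovery_control(p, method="bh")
    for r, qi in zip(rows, q):
        r.q_value = float(qi)
    return rows


def filter_min_hits(rows: Sequence[EnrichmentRow], min_hits: int = 8) -> list[EnrichmentRow]:
    """Keep rows with at least ``min_hits`` gene hits, ordered by (p, name)."""
    kept = [r for r in rows if r.hits >= min_hits]
    kept.sort(key=lambda r: (r.p_value, r.set_name))
    return kept


def enrichment_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.set_name, r.hits, r.query_size, r.set_size, r.universe_size,
             r.p_value, "" if r.q_value is None else r.q_value, ",".join(r.hit_genes))
            for r in rows
        ],
        columns=["set_name", "hits", "query_size", "set_size", "universe_size",
                 "p_value", "q_value", "hit_genes"],
    )


# ---------------------------------------------------------------------------
# KEGG-mapper-style node coloring
# ---------------------------------------------------------------------------

def color_nodes(
    gene_calls: Sequence[DECall], genes_in_view: set[str]
) -> pd.DataFrame:
    """Color table for a pathway view: up=red, down=blue, other=light green.

    The intensity column is |score| rescaled to [0,1] within the view.
    Genes without a call are colored light green and counted in the
    ``uncalled`` attribute of the returned frame.
    """
    call_by_id = {c.feature_id: c for c in gene_calls}
    in_view = sorted(genes_in_view)
    scores = [abs(call_by_id[g].score) for g in in_view if g in call_by_id]
    max_score = max(scores) if scores else 0.0
    rows = []
    n_uncalled = 0
    for g in in_view:
        c = call_by_id.get(g)
        if c is None:
            n_uncalled += 1
            rows.append((g, "light green", 0.0))
            continue
        color = {"up": "red", "down": "blue"}.get(c.direction, "light green")
        intensity = abs(c.score) / max_score if max_score else 0.0
        rows.append((g, color, intensity))
    frame = pd.DataFrame(rows, columns=["id", "color", "intensity"])
    frame.attrs["uncalled"] = n_uncalled
    return frame


# ---------------------------------------------------------------------------
# Term-term overlap network (ClueGO-style view, reduced to Jaccard)
# ---------------------------------------------------------------------------

def term_overlap_edges(
    rows: Sequence[EnrichmentRow], min_jaccard: float = 0.4
) -> pd.DataFrame:
    """Edges between enriched terms whose hit-gene Jaccard overlap passes.

    A lightweight stand-in for a full kappa-statistic term network: two
    terms are linked iff |hits_a & hits_b| / |hits_a | hits_b| >= the
    threshold.
    """
    recs = []
    for a, b in _combs(sorted(rows, key=lambda r: r.set_name), 2):
        sa, sb = set(a.hit_genes), set(b.hit_genes)
        union = sa | sb
        if not union:
            continue
        j = len(sa & sb) / len(union)
        if j >= min_jaccard:
            recs.append((a.set_name, b.set_name, j))
    return pd.DataFrame(recs, columns=["term_a", "term_b", "jaccard"])
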