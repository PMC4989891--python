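"""Seed-gene PPI neighborhood analysis.

Extracts the one-hop STRING neighborhood of a seed gene (highest
confidence first), overlays differential-expression calls, and
classifies each neighbor's expression change against its annotated
action.  The classifier formalizes the G-protein narrative: when the
seed (Gnai1-like G-alpha) is down, up-regulated inhibitors (RGS-like)
are consistent with loss of seed function, and co-down-regulated
binding partners (Gnb-like complex subunits) indicate the complex is
not formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import pandas as pd

from .diffexpr import DECall
from .io_formats import PPIEdgeList

# Concordance classes.  (a)-(e) plus two artifact-defined classes that
# make the rule table total over every (seed, flags, neighbor) combination.
CLASS_INHIBITOR_UP_SEED_DOWN = "inhibitor-up_seed-down (loss-of-function consistent)"
CLASS_INHIBITOR_DOWN_SEED_UP = "inhibitor-down_seed-up"
CLASS_COMPLEX_COREGULATION = "complex co-regulation"
CLASS_BINDING_DISCORDANT = "binding-discordant"
CLASS_UNINFORMATIVE = "uninformative"
CLASS_INHIBITOR_CONCORDANT = "inhibitor-concordant"
CLASS_UNANNOTATED = "unannotated"

ALL_CLASSES = (
    CLASS_INHIBITOR_UP_SEED_DOWN,
    CLASS_INHIBITOR_DOWN_SEED_UP,
    CLASS_COMPLEX_COREGULATION,
    CLASS_BINDING_DISCORDANT,
    CLASS_UNINFORMATIVE,
    CLASS_INHIBITOR_CONCORDANT,
    CLASS_UNANNOTATED,
)


@dataclass
class NeighborRow:
    gene: str
    combined_score: float
    binding: bool
    inhibition: bool
    log2fc: float | None = None
    direction: str = "none"
    concordance: str | None = None


@dataclass
class NeighborhoodReport:
    seed: str
    seed_direction: str
    rows: list[NeighborRow] = field(default_factory=list)

    def summary(self) -> dict:
        counts: dict[str, int] = {}
        for r in self.rows:
            if r.concordance is not None:
                counts[r.concordance] = counts.get(r.concordance, 0) + 1
        return {
            "seed": self.seed,
            "seed_direction": self.seed_direction,
            "n_neighbors": len(self.rows),
            "n_binding": sum(r.binding for r in self.rows),
            "n_inhibition": sum(r.inhibition for r in self.rows),
            "n_per_class": counts,
        }


def extract_neighborhood(
    edges: PPIEdgeList,
    seed: str,
    min_score: float = 0.9,
    top_k: int = 20,
) -> list[NeighborRow]:
    """Top-k neighbors of ``seed`` by combined score (descending, ties by name).

    Only edges with combined_score >= ``min_score`` qualify (default 0.9,
    the STRING "highest confidence" convention).  A seed absent from the
    edge list yields an empty result with a warning.
    """
    if seed not in edges.nodes():
        warnings.warn(f"seed gene {seed!r} not present in the PPI edge list")
        return []
    inc = edges.incident(seed)
    rows: list[NeighborRow] = []
    for _, r in inc.iterrows():
        if r["combined_score"] < min_score:
            continue
        other = r["gene_b"] if r["gene_a"] == seed else r["gene_a"]
        rows.append(
            NeighborRow(
                other,
                float(r["combined_score"]),
                binding="binding" in r["actions"],
                inhibition="inhibition" in r["actions"],
            )
        )
    rows.sort(key=lambda nr: (-nr.combined_score, nr.gene))
    return rows[:top_k]


def overlay_expression(
    rows: Sequence[NeighborRow],
    gene_calls: Sequence[DECall],
    seed_call: DECall | None,
    seed: str | None = None,
) -> NeighborhoodReport:
    """Annotate neighbors with log2 fold change and direction.

    Neighbors without a call get direction ``none`` (kept, counted via
    the summary).  ``seed`` is only needed when ``seed_call`` is None.
    """
    call_by_id = {c.feature_id: c for c in gene_calls}
    seed_name = seed_call.feature_id if seed_call is not None else (seed or "")
    seed_dir = seed_call.direction if seed_call is not None else "none"
    out = []
    for r in rows:
        c = call_by_id.get(r.gene)
        if c is None:
            out.append(replace(r, log2fc=None, direction="none"))
        else:
            out.append(replace(r, log2fc=float(c.score), direction=c.direction))
    return NeighborhoodReport(seed_name, seed_dir, out)


def classify_row(
    seed_direction: str, binding: bool, inhibition: bool, neighbor_direction: str
) -> str:
    """Total concordance rule, evaluated in order.

    1. either direction unknown -> uninformative
    2. inhibitor up while seed down -> loss-of-function consistent
    3. inhibitor down while seed up -> inhibitor-down_seed-up
    4. inhibitor moving with the seed -> inhibitor-concordant
    5. binding partner moving with the seed -> complex co-regulation
    6. binding partner moving against the seed -> binding-discordant
    7. no action annotation -> unannotated

    When a neighbor carries both binding and inhibition flags the
    inhibition rules take precedence.
    """
    if seed_direction == "none" or neighbor_direction == "none":
        return CLASS_UNINFORMATIVE
    if inhibition:
        if neighbor_direction == "up" and seed_direction == "down":
            return CLASS_INHIBITOR_UP_SEED_DOWN
        if neighbor_direction == "down" and seed_direction == "up":
            return CLASS_INHIBITOR_DOWN_SEED_UP
        return CLASS_INHIBITOR_CONCORDANT
    if binding:
        if neighbor_direction == seed_direction:
            return CLASS_COMPLEX_COREGULATION
        return CLASS_BINDING_DISCORDANT
    return CLASS_UNANNOTATED


def classify_concordance(report: NeighborhoodReport) -> NeighborhoodReport:
    """Fill the concordance class of every neighbor row (total function)."""
    rows = [
        replace(r, concordance=classify_row(report.seed_direction, r.binding, r.inhibition, r.direction))
        for r in report.rows
    ]
    return NeighborhoodReport(report.seed, report.seed_direction, rows)


def report_frame(report: NeighborhoodReport) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.gene, r.combined_score, int(r.binding), int(r.inhibition),
             "" if r.log2fc is None else r.log2fc, r.direction, r.concordance or "")
            for r in report.rows
        ],
        columns=["gene", "combined_score", "binding", "inhibition",
                 "log2fc", "direction", "concordance"],
    )


def neighborhood_network(report: NeighborhoodReport) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Star network of the seed and its neighbors for export."""
    color = {"up": "red", "down": "blue", "none": "light green"}
    nodes = [(report.seed, "seed", color[report.seed_direction])]
    edge_rows = []
    for r in report.rows:
        nodes.append((r.gene, "neighbor", color[r.direction]))
        relation = "inhibition" if r.inhibition else ("binding" if r.binding else "interacts")
        edge_rows.append((report.seed, relation, r.gene, r.combined_score))
    nodes_df = pd.DataFrame(nodes, columns=["id", "role", "color"])
    edges_df = pd.DataFrame(edge_rows, columns=["source", "relation", "target", "combined_score"])
    return nodes_df, edges_df
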