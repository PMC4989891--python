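"""Readers and writers for the external formats the pipeline touches.

Every format used by the workflow — expression TSV, target-prediction
tables (TargetScan / miRDB / generic dialects), GMT gene-set collections,
STRING-dialect PPI edge lists, SIF / GraphML network exports and 4-line
FASTQ — comes through this module, with strict validation on read and
deterministic, bit-stable output on write.

Identifiers (genes, miRNAs, samples) are opaque case-sensitive strings.
A lightweight normalization hook (:func:`id_normalizer`) can trim
whitespace and optionally uppercase them at parse time.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator


class ParseError(ValueError):
    """Malformed content in an input file (carries file/line context)."""


class ConfigError(ValueError):
    """Inconsistent or incomplete configuration of a reader/operation."""


class IntegrityError(ValueError):
    """Cross-object inconsistency, e.g. an edge naming an unknown node."""


def id_normalizer(strip: bool = True, uppercase: bool = False) -> Callable[[str], str]:
    """Return an identifier-normalization hook for the readers.

    The default hook only trims surrounding whitespace; identifiers are
    otherwise treated as opaque and case-sensitive.
    """

    def norm(s: str) -> str:
        if strip:
            s = s.strip()
        if uppercase:
            s = s.upper()
        return s

    return norm


_DEFAULT_NORM = id_normalizer()


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A features x samples numeric expression table with two-class labels.

    Parameters
    ----------
    values:
        DataFrame indexed by feature id with one column per sample.
        Units are FPKM (``mode="fpkm"``, non-negative) or array
        intensities (``mode="intensity"``, any finite real).
    condition_labels:
        Series mapping each sample id to one of exactly two class
        labels.  ``classes`` fixes the (reference, treatment) order;
        directions downstream are treatment-vs-reference.
    """

    values: pd.DataFrame
    condition_labels: pd.Series
    mode: str = "intensity"
    classes: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        feats = self.values.index
        if feats.has_duplicates:
            dup = feats[feats.duplicated()][0]
            raise ParseError(f"duplicate feature id {dup!r}")
        missing = [s for s in self.values.columns if s not in self.condition_labels.index]
        if missing:
            raise ConfigError(f"samples without a class label: {missing}")
        self.condition_labels = self.condition_labels.reindex(self.values.columns)
        uniq = list(dict.fromkeys(self.condition_labels))
        if len(uniq) != 2:
            raise ConfigError(f"expected exactly two classes, got {uniq}")
        if self.classes is None:
            # reference = class of the first sample (input order)
            self.classes = (uniq[0], uniq[1])
        elif set(self.classes) != set(uniq):
            raise ConfigError(f"classes {self.classes} do not match labels {uniq}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ParseError(
                f"non-finite value at feature {feats[i]!r}, sample {self.values.columns[j]!r}"
            )
        if self.mode == "fpkm" and (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ParseError(
                f"negative FPKM at feature {feats[i]!r}, sample {self.values.columns[j]!r}"
            )

    # -- convenience accessors ------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def class_columns(self, cls: str) -> list[str]:
        return [s for s in self.values.columns if self.condition_labels[s] == cls]

    def class_values(self, cls: str) -> np.ndarray:
        """Values restricted to one class, as a features x n array."""
        return self.values[self.class_columns(cls)].to_numpy(dtype=float)


def read_expression_matrix(
    path: str | Path,
    label_map: dict[str, str],
    mode: str = "intensity",
    classes: tuple[str, str] | None = None,
    normalize: Callable[[str], str] = _DEFAULT_NORM,
) -> ExpressionMatrix:
    """Read a TSV expression matrix (header = sample ids, first column = feature ids).

    Feature order is preserved; duplicate feature ids, unlabeled samples
    and non-numeric cells are rejected with the offending coordinate.
    """
    path = Path(path)
    with _maybe_gz(path, "rt") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        cols = [normalize(c) for c in header.split("\t")]
        samples = cols[1:]
        if len(set(samples)) != len(samples):
            raise ParseError(f"{path}: duplicate sample ids in header")
        seen: set[str] = set()
        feats: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(samples) + 1:
                raise ParseError(f"{path}:{lineno}: expected {len(samples) + 1} fields, got {len(parts)}")
            fid = normalize(parts[0])
            if fid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate feature id {fid!r}")
            seen.add(fid)
            try:
                row = [float(x) for x in parts[1:]]
            except ValueError:
                bad = next(i for i, x in enumerate(parts[1:]) if not _is_number(x))
                raise ParseError(
                    f"{path}:{lineno}: non-numeric cell at column {samples[bad]!r}"
                ) from None
            feats.append(fid)
            rows.append(row)
    unlabeled = [s for s in samples if s not in label_map]
    if unlabeled:
        raise ConfigError(f"{path}: samples without labels: {unlabeled}")
    values = pd.DataFrame(rows, index=feats, columns=samples, dtype=float)
    labels = pd.Series({s: label_map[s] for s in samples})
    return ExpressionMatrix(values, labels, mode=mode, classes=classes)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the expression TSV (``repr``-exact floats; round-trips bit-stably)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for fid, row in matrix.values.iterrows():
            fh.write(fid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def _is_number(x: str) -> bool:
    try:
        float(x)
        return True
    except ValueError:
        return False


def _maybe_gz(path: Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Target-prediction tables
# ---------------------------------------------------------------------------

TARGET_DIALECTS = ("generic", "targetscan", "mirdb")


@dataclass
class TargetPredictionTable:
    """Normalized (mirna_id, gene_id, source, score) prediction rows."""

    rows: pd.DataFrame  # columns: mirna_id, gene_id, source, score

    def __post_init__(self) -> None:
        key = self.rows[["mirna_id", "gene_id", "source"]]
        if key.duplicated().any():
            raise ParseError("duplicate (mirna, gene, source) rows after normalization")
        if (self.rows["mirna_id"] == "").any():
            raise ParseError("empty mirna_id")

    @property
    def source(self) -> str:
        srcs = self.rows["source"].unique()
        return srcs[0] if len(srcs) == 1 else "mixed"

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.rows["mirna_id"], self.rows["gene_id"]))


def read_target_table(
    path: str | Path,
    dialect: str = "generic",
    normalize: Callable[[str], str] = _DEFAULT_NORM,
) -> TargetPredictionTable:
    """Read a miRNA->gene prediction table in one of three dialects.

    generic     mirna_id <TAB> gene_id [<TAB> score]
    targetscan  gene_id <TAB> mirna_family <TAB> site_type <TAB> context_score
    mirdb       mirna_id <TAB> gene_id <TAB> target_score (0-100)

    Duplicate (mirna, gene) pairs within one source collapse keeping the
    best score: the most negative context score for TargetScan, the
    highest score otherwise.
    """
    if dialect not in TARGET_DIALECTS:
        raise ConfigError(f"unknown target-table dialect {dialect!r}")
    path = Path(path)
    recs: list[tuple[str, str, float | None]] = []
    with _maybe_gz(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if dialect == "generic":
                    if len(parts) < 2:
                        raise ValueError
                    mirna, gene = normalize(parts[0]), normalize(parts[1])
                    score = float(parts[2]) if len(parts) > 2 and parts[2] != "" else None
                elif dialect == "targetscan":
                    if len(parts) < 4:
                        raise ValueError
                    gene, mirna = normalize(parts[0]), normalize(parts[1])
                    score = float(parts[3]) if parts[3] != "" else None
                else:  # mirdb
                    if len(parts) < 3:
                        raise ValueError
                    mirna, gene = normalize(parts[0]), normalize(parts[1])
                    score = float(parts[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed {dialect} row") from None
            if not mirna:
                raise ParseError(f"{path}:{lineno}: empty mirna id")
            recs.append((mirna, gene, score))
    best: dict[tuple[str, str], float | None] = {}
    lower_is_better = dialect == "targetscan"
    for mirna, gene, score in recs:
        key = (mirna, gene)
        if key not in best:
            best[key] = score
        else:
            old = best[key]
            if score is not None and (
                old is None or (score < old if lower_is_better else score > old)
            ):
                best[key] = score
    rows = pd.DataFrame(
        [(m, g, dialect, s) for (m, g), s in best.items()],
        columns=["mirna_id", "gene_id", "source", "score"],
    )
    return TargetPredictionTable(rows)


# ---------------------------------------------------------------------------
# Gene-set collections (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]  # unique, input order preserved


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with an optional explicit universe."""

    sets: dict[str, GeneSet] = field(default_factory=dict)
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if not gs.genes:
                raise ParseError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets and self.universe == other.universe


def read_gene_sets_gmt(
    path: str | Path, normalize: Callable[[str], str] = _DEFAULT_NORM
) -> GeneSetCollection:
    """Parse a standard GMT file: name TAB description TAB gene TAB gene ..."""
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    with _maybe_gz(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = normalize(parts[0])
            genes = list(dict.fromkeys(normalize(g) for g in parts[2:] if normalize(g)))
            sets[name] = GeneSet(name, parts[1], genes)
    return GeneSetCollection(sets)


def write_gene_sets_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection.sets.values():
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# PPI edge lists (STRING dialect)
# ---------------------------------------------------------------------------

PPI_ACTIONS = ("binding", "inhibition", "activation")


@dataclass
class PPIEdgeList:
    """Undirected PPI edges with combined scores in [0,1] and action flags.

    Endpoints are canonicalized lexicographically; duplicate edges keep
    the maximum score and the union of action flags.
    """

    edges: pd.DataFrame  # columns: gene_a, gene_b, combined_score, actions (frozenset)

    def __post_init__(self) -> None:
        e = self.edges
        if (e["gene_a"] == e["gene_b"]).any():
            bad = e.loc[e["gene_a"] == e["gene_b"], "gene_a"].iloc[0]
            raise ParseError(f"self-loop on {bad!r}")
        sc = e["combined_score"].to_numpy(dtype=float)
        if ((sc < 0) | (sc > 1)).any():
            raise ParseError("combined_score outside [0,1] after normalization")

    def nodes(self) -> set[str]:
        return set(self.edges["gene_a"]) | set(self.edges["gene_b"])

    def incident(self, gene: str) -> pd.DataFrame:
        e = self.edges
        return e[(e["gene_a"] == gene) | (e["gene_b"] == gene)]


def _canon_edges(
    recs: Iterable[tuple[str, str, float, frozenset[str]]]
) -> pd.DataFrame:
    merged: dict[tuple[str, str], tuple[float, frozenset[str]]] = {}
    for a, b, score, actions in recs:
        if a == b:
            raise ParseError(f"self-loop on {a!r}")
        key = (a, b) if a < b else (b, a)
        if key in merged:
            old_score, old_actions = merged[key]
            merged[key] = (max(old_score, score), old_actions | actions)
        else:
            merged[key] = (score, actions)
    return pd.DataFrame(
        [(a, b, s, acts) for (a, b), (s, acts) in merged.items()],
        columns=["gene_a", "gene_b", "combined_score", "actions"],
    )


def read_ppi_edges(
    path: str | Path, normalize: Callable[[str], str] = _DEFAULT_NORM
) -> PPIEdgeList:
    """Read STRING-dialect edges: gene_a TAB gene_b TAB score [TAB actions].

    Scores are auto-detected: any value above 1 switches the whole file
    to the 0-999 integer convention, normalized by /1000.
    """
    path = Path(path)
    raw: list[tuple[str, str, float, frozenset[str]]] = []
    with _maybe_gz(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 fields")
            a, b = normalize(parts[0]), normalize(parts[1])
            try:
                score = float(parts[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric score") from None
            actions: frozenset[str] = frozenset()
            if len(parts) > 3 and parts[3].strip():
                acts = {normalize(x).lower() for x in parts[3].split(",") if x.strip()}
                unknown = acts - set(PPI_ACTIONS)
                if unknown:
                    raise ParseError(f"{path}:{lineno}: unknown actions {sorted(unknown)}")
                actions = frozenset(acts)
            raw.append((a, b, score, actions))
    if raw and max(r[2] for r in raw) > 1.0:
        raw = [(a, b, s / 1000.0, acts) for a, b, s, acts in raw]
    return PPIEdgeList(_canon_edges(raw))


def write_ppi_edges(edges: PPIEdgeList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for _, r in edges.edges.iterrows():
            acts = ",".join(sorted(r["actions"]))
            fh.write(f"{r['gene_a']}\t{r['gene_b']}\t{repr(float(r['combined_score']))}\t{acts}\n")


# ---------------------------------------------------------------------------
# Network export (SIF / GraphML)
# ---------------------------------------------------------------------------

def write_network(
    nodes: pd.DataFrame,
    edges: pd.DataFrame,
    fmt: str,
    path: str | Path,
) -> None:
    """Export an attributed network for Cytoscape.

    ``nodes`` must have an ``id`` column (other columns become node
    attributes, e.g. the expression color class); ``edges`` must have
    ``source``, ``relation`` and ``target`` columns.  SIF writes one
    ``source<TAB>relation<TAB>target`` line per edge, with the node
    attribute side-table as ``<path>.nodes.tsv``.  GraphML goes through
    networkx and is well-formed XML.
    """
    path = Path(path)
    known = set(nodes["id"])
    for col in ("source", "target"):
        bad = set(edges[col]) - known
        if bad:
            raise IntegrityError(f"edge references unknown node(s): {sorted(bad)}")
    if fmt.upper() == "SIF":
        with open(path, "w") as fh:
            for _, r in edges.iterrows():
                fh.write(f"{r['source']}\t{r['relation']}\t{r['target']}\n")
        attr_cols = [c for c in nodes.columns if c != "id"]
        with open(str(path) + ".nodes.tsv", "w") as fh:
            fh.write("id\t" + "\t".join(attr_cols) + "\n")
            for _, r in nodes.iterrows():
                fh.write(r["id"] + "\t" + "\t".join(str(r[c]) for c in attr_cols) + "\n")
    elif fmt.upper() == "GRAPHML":
        g = nx.Graph()
        for _, r in nodes.iterrows():
            g.add_node(r["id"], **{c: r[c] for c in nodes.columns if c != "id"})
        for _, r in edges.iterrows():
            attrs = {c: r[c] for c in edges.columns if c not in ("source", "target")}
            g.add_edge(r["source"], r["target"], **attrs)
        nx.write_graphml(g, path)
    else:
        raise ConfigError(f"unknown network format {fmt!r}")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

@dataclass
class FastqRead:
    read_id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ParseError(
                f"read {self.read_id!r}: sequence/quality length mismatch "
                f"({len(self.sequence)} vs {len(self.quality)})"
            )
        if set(self.sequence) - set("ACGTN"):
            raise ParseError(f"read {self.read_id!r}: invalid sequence alphabet")


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    """Stream 4-line FASTQ records (gzip transparent)."""
    with _maybe_gz(Path(path), "rt") as fh:
        for rid, seq, qual in FastqGeneralIterator(fh):
            yield FastqRead(rid, seq.upper(), qual)


def read_fastq_pairs(
    r1_path: str | Path, r2_path: str | Path
) -> Iterator[tuple[FastqRead, FastqRead]]:
    it1, it2 = read_fastq(r1_path), read_fastq(r2_path)
    for r1 in it1:
        r2 = next(it2, None)
        if r2 is None:
            raise ParseError("R2 file has fewer records than R1")
        yield r1, r2
    if next(it2, None) is not None:
        raise ParseError("R2 file has more records than R1")


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with _maybe_gz(Path(path), "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")
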