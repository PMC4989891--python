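"""Synthetic studies with the structure every pipeline stage assumes.

``generate_study`` plants a known truth — differentially expressed
miRNAs, target genes negatively coupled to their regulators, two
partially overlapping predictor tables, one enriched pathway, and a
seeded PPI neighborhood with binder/inhibitor roles — so the whole
workflow can be exercised and scored against ground truth without any
external download.  ``table1_fixture`` loads the packaged top-20
Gnai1 STRING neighborhood with its published scores and action flags,
plus the G-protein direction fixture (Gnb1/2/4 down, Rgs1/Rgs19 up,
Gnai1 down).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import DECall
from .io_formats import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    PPIEdgeList,
    TargetPredictionTable,
    _canon_edges,
    write_expression_matrix,
    write_gene_sets_gmt,
    write_ppi_edges,
)


@dataclass
class PPINeighborSpec:
    """Planted one-hop neighborhood around the seed gene.

    Directions are realized in the mRNA matrix (forced fold changes),
    so the overlay step sees them through the ordinary log2FC caller.
    ``n_uncalled`` neighbors exist only in the PPI graph, exercising the
    direction-none path.
    """

    seed_gene: str = "Gnai1"
    seed_direction: str = "down"
    n_binding_concordant: int = 3  # complex partners moving with the seed
    n_binding_discordant: int = 1
    n_inhibitor_discordant: int = 2  # inhibitors moving against the seed
    n_inhibitor_concordant: int = 1
    n_unannotated: int = 1
    n_uncalled: int = 2
    n_background_edges: int = 20


@dataclass
class SynthConfig:
    """Study-design parameters of the synthetic two-class experiment.

    Effect size (``de_shift``) is in within-class SD units; coupling is
    ``gene = baseline - coupling_beta * centered(miRNA) + noise``.
    ``predictor_overlap`` is the fraction of true pairs listed by both
    predictor tables (0.36 mirrors the observed TargetScan/miRDB
    gene-level agreement); ``decoy_pair_rate`` adds uncoupled predicted
    pairs per true pair, emulating predictor false positives.
    """

    n_mirnas: int = 200
    n_genes: int = 2000
    n_samples_per_class: int = 4
    n_de_up: int = 10
    n_de_down: int = 5
    de_shift: float = 3.0
    targets_per_de_mirna: int = 30
    coupling_beta: float = 1.0
    noise_sd: float = 1.0
    predictor_overlap: float = 0.36
    decoy_pair_rate: float = 0.25
    planted_pathway_size: int = 40
    n_background_sets: int = 30
    ppi_neighbor_spec: PPINeighborSpec = field(default_factory=PPINeighborSpec)
    rng_seed: int = 11

    def __post_init__(self) -> None:
        errors = []
        if self.n_de_up + self.n_de_down > self.n_mirnas:
            errors.append("more planted DE miRNAs than miRNAs")
        if self.targets_per_de_mirna > self.n_genes:
            errors.append("targets_per_de_mirna exceeds n_genes")
        if self.planted_pathway_size > self.n_genes:
            errors.append("planted_pathway_size exceeds n_genes")
        if not 0.0 <= self.predictor_overlap <= 1.0:
            errors.append("predictor_overlap outside [0,1]")
        if min(self.n_mirnas, self.n_genes, self.n_samples_per_class) < 1:
            errors.append("counts must be positive")
        if self.de_shift < 0 or self.noise_sd < 0 or self.decoy_pair_rate < 0:
            errors.append("de_shift, noise_sd, decoy_pair_rate must be non-negative")
        if errors:
            raise ValueError("inconsistent SynthConfig: " + "; ".join(errors))


@dataclass
class StudyTruth:
    """Everything that was planted, for scoring recovery."""

    de_up: list[str]
    de_down: list[str]
    true_pairs: list[tuple[str, str]]
    decoy_pairs: list[tuple[str, str]]
    background_pairs: list[tuple[str, str]]
    planted_set_name: str
    planted_set_genes: list[str]
    seed_gene: str
    seed_direction: str
    neighbor_roles: dict[str, str]  # gene -> planted role
    rng_seed: int

    def as_dict(self) -> dict:
        d = asdict(self)
        d["true_pairs"] = [list(p) for p in self.true_pairs]
        d["decoy_pairs"] = [list(p) for p in self.decoy_pairs]
        d["background_pairs"] = [list(p) for p in self.background_pairs]
        return d


@dataclass
class Study:
    mirna_matrix: ExpressionMatrix
    mrna_matrix: ExpressionMatrix
    targetscan: TargetPredictionTable
    mirdb: TargetPredictionTable
    gene_sets: GeneSetCollection
    ppi_edges: PPIEdgeList
    truth: StudyTruth


# forced fold change (log2 units) for seed / directional PPI neighbors
_FORCED_LOG2FC = 1.2


def generate_study(config: SynthConfig | None = None) -> Study:
    """Generate one fully reproducible synthetic study from the config seed."""
    config = config or SynthConfig()
    rng = np.random.default_rng(config.rng_seed)
    spec = config.ppi_neighbor_spec

    mirnas = [f"miR-{i:03d}" for i in range(1, config.n_mirnas + 1)]
    genes = [f"GENE{i:04d}" for i in range(1, config.n_genes + 1)]
    n = config.n_samples_per_class
    samples = [f"WT{i}" for i in range(1, n + 1)] + [f"KO{i}" for i in range(1, n + 1)]
    labels = pd.Series(["WT"] * n + ["KO"] * n, index=samples)
    ko_mask = np.array([False] * n + [True] * n)

    # --- planted DE miRNAs and the miRNA intensity matrix -------------------
    de_idx = rng.choice(config.n_mirnas, size=config.n_de_up + config.n_de_down, replace=False)
    de_up = sorted(mirnas[i] for i in de_idx[: config.n_de_up])
    de_down = sorted(mirnas[i] for i in de_idx[config.n_de_up :])
    shift = {m: config.de_shift for m in de_up}
    shift.update({m: -config.de_shift for m in de_down})
    base_m = rng.uniform(6, 10, size=config.n_mirnas)
    M = np.empty((config.n_mirnas, 2 * n))
    for i, m in enumerate(mirnas):
        mu = base_m[i] + shift.get(m, 0.0) * ko_mask
        M[i] = mu + rng.normal(0, config.noise_sd, size=2 * n)
    mirna_matrix = ExpressionMatrix(
        pd.DataFrame(M, index=mirnas, columns=samples), labels.copy(),
        mode="intensity", classes=("WT", "KO"),
    )

    # --- true target pairs and the coupled mRNA matrix ----------------------
    true_pairs: list[tuple[str, str]] = []
    regulators: dict[str, list[str]] = {}
    for m in de_up + de_down:
        tgt_idx = rng.choice(config.n_genes, size=config.targets_per_de_mirna, replace=False)
        for j in tgt_idx:
            g = genes[j]
            true_pairs.append((m, g))
            regulators.setdefault(g, []).append(m)
    true_pairs = sorted(set(true_pairs))

    # named PPI genes are appended to the gene universe
    nbr: dict[str, str] = {}  # gene -> role
    def _mk(prefix: str, count: int, role: str) -> list[str]:
        names = [f"{prefix}{i}" for i in range(1, count + 1)]
        for g in names:
            nbr[g] = role
        return names

    binding_conc = _mk("GnbL", spec.n_binding_concordant, "binding-concordant")
    binding_disc = _mk("PlcL", spec.n_binding_discordant, "binding-discordant")
    inhib_disc = _mk("RgsL", spec.n_inhibitor_discordant, "inhibitor-discordant")
    inhib_conc = _mk("InhC", spec.n_inhibitor_concordant, "inhibitor-concordant")
    unannot = _mk("UnA", spec.n_unannotated, "unannotated")
    uncalled = _mk("NoCall", spec.n_uncalled, "uncalled")

    seed_sign = 1.0 if spec.seed_direction == "up" else -1.0
    forced: dict[str, float] = {spec.seed_gene: seed_sign * _FORCED_LOG2FC}
    for g in binding_conc + inhib_conc:
        forced[g] = seed_sign * _FORCED_LOG2FC  # moves with the seed
    for g in binding_disc + inhib_disc:
        forced[g] = -seed_sign * _FORCED_LOG2FC
    for g in unannot:
        forced[g] = -seed_sign * _FORCED_LOG2FC

    all_genes = genes + [spec.seed_gene] + binding_conc + binding_disc + inhib_disc + inhib_conc + unannot
    mirna_values = mirna_matrix.values
    G = np.empty((len(all_genes), 2 * n))
    base_g = rng.uniform(5, 15, size=len(all_genes))
    for i, g in enumerate(all_genes):
        if g in forced:
            mu = base_g[i] * np.where(ko_mask, 2.0 ** forced[g], 1.0)
            G[i] = mu + rng.normal(0, config.noise_sd, size=2 * n)
        elif g in regulators:
            regs = np.vstack([mirna_values.loc[m].to_numpy() for m in regulators[g]])
            centered = (regs - regs.mean(axis=1, keepdims=True)).mean(axis=0)
            G[i] = base_g[i] - config.coupling_beta * centered + rng.normal(0, config.noise_sd, size=2 * n)
        else:
            G[i] = base_g[i] + rng.normal(0, config.noise_sd, size=2 * n)
    G = np.maximum(G, 0.0)
    mrna_matrix = ExpressionMatrix(
        pd.DataFrame(G, index=all_genes, columns=samples), labels.copy(),
        mode="fpkm", classes=("WT", "KO"),
    )

    # --- predictor tables: true pairs + decoys, split by overlap ------------
    non_target = sorted(set(genes) - set(regulators))
    n_decoys = round(config.decoy_pair_rate * len(true_pairs))
    de_all = de_up + de_down
    decoy_pairs: set[tuple[str, str]] = set()
    while len(decoy_pairs) < n_decoys:
        m = de_all[rng.integers(len(de_all))]
        g = non_target[rng.integers(len(non_target))]
        decoy_pairs.add((m, g))
    decoys = sorted(decoy_pairs)
    non_de = sorted(set(mirnas) - set(de_all))
    background_pairs = sorted(
        {(m, genes[rng.integers(config.n_genes)]) for m in non_de for _ in range(2)}
    )

    ts_rows, db_rows = [], []
    for m, g in true_pairs + decoys + background_pairs:
        u = rng.random()
        in_both = u < config.predictor_overlap
        to_ts = in_both or rng.random() < 0.5
        to_db = in_both or not to_ts
        if to_ts:
            ts_rows.append((m, g, "targetscan", float(np.round(rng.uniform(-0.6, -0.05), 3))))
        if to_db:
            db_rows.append((m, g, "mirdb", float(np.round(rng.uniform(50, 100), 1))))
    cols = ["mirna_id", "gene_id", "source", "score"]
    targetscan = TargetPredictionTable(pd.DataFrame(ts_rows, columns=cols))
    mirdb = TargetPredictionTable(pd.DataFrame(db_rows, columns=cols))

    # --- gene sets: one planted pathway enriched in true targets ------------
    true_target_genes = sorted(regulators)
    n_from_targets = min(int(0.75 * config.planted_pathway_size), len(true_target_genes))
    planted = list(
        np.array(true_target_genes)[
            rng.choice(len(true_target_genes), size=n_from_targets, replace=False)
        ]
    )
    filler_pool = sorted(set(genes) - set(planted))
    n_filler = config.planted_pathway_size - n_from_targets
    planted += list(
        np.array(filler_pool)[rng.choice(len(filler_pool), size=n_filler, replace=False)]
    )
    sets = {"PLANTED_PATHWAY": GeneSet("PLANTED_PATHWAY", "planted enriched pathway", sorted(planted))}
    for i in range(1, config.n_background_sets + 1):
        size = int(rng.integers(20, 61))
        members = list(np.array(genes)[rng.choice(config.n_genes, size=size, replace=False)])
        name = f"BACKGROUND_{i:02d}"
        sets[name] = GeneSet(name, "random background set", sorted(members))
    gene_sets = GeneSetCollection(sets)

    # --- PPI edges around the seed -------------------------------------------
    edge_recs: list[tuple[str, str, float, frozenset]] = []
    def _edge(g: str, actions: frozenset) -> None:
        score = float(np.round(rng.uniform(0.92, 0.995), 3))
        edge_recs.append((spec.seed_gene, g, score, actions))

    for g in binding_conc + binding_disc + uncalled:
        _edge(g, frozenset({"binding"}))
    for g in inhib_disc + inhib_conc:
        _edge(g, frozenset({"binding", "inhibition"}))
    for g in unannot:
        _edge(g, frozenset())
    for g in uncalled:
        nbr[g] = "uncalled"
    others = [g for g in genes if g not in nbr and g != spec.seed_gene]
    for _ in range(spec.n_background_edges):
        a, b = (others[i] for i in rng.choice(len(others), size=2, replace=False))
        edge_recs.append((a, b, float(np.round(rng.uniform(0.4, 0.9), 3)), frozenset()))
    ppi_edges = PPIEdgeList(_canon_edges(edge_recs))

    truth = StudyTruth(
        de_up, de_down, true_pairs, decoys, background_pairs,
        "PLANTED_PATHWAY", sorted(planted), spec.seed_gene, spec.seed_direction,
        dict(sorted(nbr.items())), config.rng_seed,
    )
    return Study(mirna_matrix, mrna_matrix, targetscan, mirdb, gene_sets, ppi_edges, truth)


def write_study(study: Study, out_dir: str | Path) -> dict[str, str]:
    """Write every fixture format plus truth.json; byte-stable per seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirna_matrix": out / "mirna_matrix.tsv",
        "mrna_matrix": out / "mrna_matrix.tsv",
        "targetscan": out / "targets_targetscan.tsv",
        "mirdb": out / "targets_mirdb.tsv",
        "gene_sets": out / "pathways.gmt",
        "ppi_edges": out / "ppi_edges.tsv",
        "labels": out / "labels.tsv",
        "truth": out / "truth.json",
    }
    write_expression_matrix(study.mirna_matrix, paths["mirna_matrix"])
    write_expression_matrix(study.mrna_matrix, paths["mrna_matrix"])
    for tbl, key in ((study.targetscan, "targetscan"), (study.mirdb, "mirdb")):
        with open(paths[key], "w") as fh:
            for _, r in tbl.rows.iterrows():
                if key == "targetscan":
                    fh.write(f"{r['gene_id']}\t{r['mirna_id']}\t7mer\t{r['score']}\n")
                else:
                    fh.write(f"{r['mirna_id']}\t{r['gene_id']}\t{r['score']}\n")
    write_gene_sets_gmt(study.gene_sets, paths["gene_sets"])
    write_ppi_edges(study.ppi_edges, paths["ppi_edges"])
    with open(paths["labels"], "w") as fh:
        fh.write("sample\tlabel\n")
        for s in study.mirna_matrix.sample_ids:
            fh.write(f"{s}\t{study.mirna_matrix.condition_labels[s]}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(study.truth.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# Packaged Gnai1 / STRING fixture
# ---------------------------------------------------------------------------

_SEED = "Gnai1"
_DOWN = ("Gnai1", "Gnb1", "Gnb2", "Gnb4")
_UP = ("Rgs1", "Rgs19")


def table1_fixture() -> tuple[PPIEdgeList, list[DECall], DECall]:
    """The packaged top-20 Gnai1 STRING neighborhood and direction fixture.

    Returns (edge list, neighbor expression calls, seed call).  Scores
    and binding/inhibition flags come from the shipped transcription;
    the direction fixture encodes Gnb1/Gnb2/Gnb4 down and Rgs1/Rgs19 up
    against a down-regulated seed, with synthetic unit fold changes
    standing in for the unpublished expression values.
    """
    with resources.files("mirnetppi.data").joinpath("gnai1_string_top20.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    recs = []
    for _, r in table.iterrows():
        actions = set()
        if r["binding"]:
            actions.add("binding")
        if r["inhibition"]:
            actions.add("inhibition")
        recs.append((_SEED, r["gene"], float(r["score"]), frozenset(actions)))
    edges = PPIEdgeList(_canon_edges(recs))
    calls = [DECall(g, -1.0, "down", None, True) for g in _DOWN if g != _SEED]
    calls += [DECall(g, 1.0, "up", None, True) for g in _UP]
    seed_call = DECall(_SEED, -1.0, "down", None, True)
    return edges, calls, seed_call
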