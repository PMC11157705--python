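"""Seeded synthetic inputs with a planted proximity-plus-multiplicity signal.

Real herb/disease annotation repositories are not redistributable, so this
module generates inputs whose statistical shape mirrors them: a heavy-tailed
connected interactome, diseases whose gene sets form small connected
neighbourhoods (disease modules), herbs holding a skewed number of compounds
each targeting several genes, multi-database evidence labels, and a sparse
herb–disease gold standard.

The gold standard is not decorative: for each known-positive (herb, disease)
pair the herb's compound targets are biased toward the disease module
(``module_locality``) and a small focus set of module-proximal genes receives
``multiplicity_boost`` extra compounds, raising those genes' weights. The
association signal is therefore partly encoded in compound multiplicity, which
is exactly what the weighted measure (WACP) — and not the unweighted ones —
can exploit. With both knobs at zero, positive pairs are statistically
indistinguishable from negatives and any evaluator must return chance-level
AUROC.

All randomness flows from one :class:`numpy.random.Generator`; the same config
and seed reproduce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import associations as assoc
from .associations import AssociationTable, RelationKind
from .evaluation import GoldStandard, auroc, label_and_orient
from .interactome import DistanceOracle, build_graph, largest_connected_component
from .proximity import Measure, score_all_pairs

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate",
    "summarize",
    "benchmark_measures",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults give a desk-sized benchmark.

    Shape parameters (module sizes, compounds per herb) follow the skewed
    distributions seen in curated repositories, scaled down so a full pipeline
    run takes seconds. ``module_locality`` is the probability that a target
    draw of a gold-positive herb lands within ``locality_radius`` hops of its
    disease module; ``multiplicity_boost`` is the number of extra compounds
    aimed at a module-proximal focus gene set of each gold disease.
    """

    seed: int = 0
    n_nodes: int = 500
    attachment: int = 4  # preferential-attachment edges per new node
    er_edge_prob: float | None = None  # set for the Erdős–Rényi fallback mode
    n_diseases: int = 12
    disease_module_size: tuple[int, int] = (2, 74)
    disease_module_mean: float = 6.26
    n_herbs: int = 60
    compounds_per_herb: tuple[int, int] = (1, 80)
    compounds_per_herb_mean: float = 34.5
    targets_per_compound: tuple[int, int] = (1, 8)
    n_source_databases: int = 4
    evidence_prob: float = 0.5  # per-database membership probability
    fraction_positive_herbs: float = 0.1
    diseases_per_positive_herb: tuple[int, int] = (1, 3)
    module_locality: float = 0.8
    multiplicity_boost: int = 3
    locality_radius: int = 1

    def validate(self) -> None:
        counts = {
            "n_nodes": self.n_nodes,
            "attachment": self.attachment,
            "n_diseases": self.n_diseases,
            "n_herbs": self.n_herbs,
            "n_source_databases": self.n_source_databases,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        for name, p in (
            ("evidence_prob", self.evidence_prob),
            ("fraction_positive_herbs", self.fraction_positive_herbs),
            ("module_locality", self.module_locality),
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.multiplicity_boost < 0:
            raise ValueError("multiplicity_boost must be >= 0")
        if self.attachment >= self.n_nodes:
            raise ValueError("attachment parameter must be smaller than n_nodes")
        for name, (lo, hi) in (
            ("disease_module_size", self.disease_module_size),
            ("compounds_per_herb", self.compounds_per_herb),
            ("targets_per_compound", self.targets_per_compound),
            ("diseases_per_positive_herb", self.diseases_per_positive_herb),
        ):
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must be a 1 <= lo <= hi range, got {(lo, hi)}")
        if self.disease_module_size[0] > self.n_nodes:
            raise ValueError("disease modules cannot be larger than the graph")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "SyntheticConfig":
        kwargs = dict(data)
        for key in (
            "disease_module_size",
            "compounds_per_herb",
            "targets_per_compound",
            "diseases_per_positive_herb",
        ):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def digest(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()


@dataclass
class SyntheticDataset:
    """Everything one pipeline run consumes, held in memory."""

    config: SyntheticConfig
    edges: list[tuple[str, str]]
    tables: dict[RelationKind, AssociationTable]
    gold: GoldStandard

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write the TSV/JSON files and return path→sha256 of each."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        edge_path = outdir / "edges.tsv"
        with open(edge_path, "w", encoding="utf-8") as fh:
            fh.write("gene_a\tgene_b\n")
            for a, b in sorted(self.edges):
                fh.write(f"{a}\t{b}\n")
        paths["edges"] = edge_path
        for kind, table in self.tables.items():
            path = outdir / f"{kind.value}.tsv"
            table.to_tsv(path)
            paths[kind.value] = path
        config_path = outdir / "config.json"
        with open(config_path, "w", encoding="utf-8") as fh:
            json.dump(self.config.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths["config"] = config_path
        checksums = {name: _sha256(p) for name, p in paths.items()}
        manifest = {
            "seed": self.config.seed,
            "config_sha256": self.config.digest(),
            "files": {name: str(p.name) for name, p in paths.items()},
            "sha256": checksums,
        }
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return checksums


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _sample_module(
    graph: nx.Graph, seed_node: str, size: int, rng: np.random.Generator
) -> list[str]:
    """A connected node set: the first ``size`` nodes of a randomised BFS."""
    seen = {seed_node}
    order = [seed_node]
    queue = deque([seed_node])
    while queue and len(order) < size:
        current = queue.popleft()
        neighbours = sorted(graph.neighbors(current))
        for i in rng.permutation(len(neighbours)):
            node = neighbours[i]
            if node not in seen:
                seen.add(node)
                order.append(node)
                queue.append(node)
                if len(order) == size:
                    break
    return order  # may be shorter than size on tiny graphs


def _ball(graph: nx.Graph, nodes: Sequence[str], radius: int) -> list[str]:
    pool = set(nodes)
    frontier = set(nodes)
    for _ in range(radius):
        frontier = {n for f in frontier for n in graph.neighbors(f)} - pool
        pool |= frontier
    return sorted(pool)


def _draw_sources(rng: np.random.Generator, labels: list[str], p: float) -> list[str]:
    k = int(rng.binomial(len(labels), p))
    if k == 0:
        k = 1  # every record needs at least one reporting database
    idx = rng.choice(len(labels), size=k, replace=False)
    return [labels[i] for i in sorted(idx)]


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one synthetic dataset (graph, four tables, gold standard)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    graph_seed = int(rng.integers(0, 2**31 - 1))
    if config.er_edge_prob is not None:
        raw = nx.gnp_random_graph(config.n_nodes, config.er_edge_prob, seed=graph_seed)
    else:
        raw = nx.barabasi_albert_graph(config.n_nodes, config.attachment, seed=graph_seed)
    width = len(str(config.n_nodes))
    relabelled = nx.relabel_nodes(raw, {i: f"G{i:0{width}d}" for i in raw.nodes})
    graph = largest_connected_component(build_graph(list(relabelled.edges())))
    nodes = sorted(graph.nodes)
    db_labels = [f"DB{i + 1}" for i in range(config.n_source_databases)]

    # --- disease modules -------------------------------------------------
    lo, hi = config.disease_module_size
    geom_p = 1.0 / max(config.disease_module_mean - lo + 1, 1.0)
    disease_genes: dict[str, list[str]] = {}
    for i in range(config.n_diseases):
        disease_id = f"D{i + 1:03d}"
        size = int(np.clip(lo + rng.geometric(geom_p) - 1, lo, hi))
        seed_node = nodes[int(rng.integers(len(nodes)))]
        disease_genes[disease_id] = _sample_module(graph, seed_node, size, rng)
    disease_ids = sorted(disease_genes)

    # --- gold-standard assignment ---------------------------------------
    herb_ids = [f"H{i + 1:03d}" for i in range(config.n_herbs)]
    n_positive = int(round(config.fraction_positive_herbs * config.n_herbs))
    pos_idx = sorted(rng.choice(config.n_herbs, size=n_positive, replace=False))
    gold_map: dict[str, list[str]] = {}
    d_lo, d_hi = config.diseases_per_positive_herb
    for i in pos_idx:
        k = int(rng.integers(d_lo, min(d_hi, len(disease_ids)) + 1))
        chosen = rng.choice(len(disease_ids), size=k, replace=False)
        gold_map[herb_ids[i]] = [disease_ids[j] for j in sorted(chosen)]

    pools = {
        d: _ball(graph, genes, config.locality_radius)
        for d, genes in disease_genes.items()
    }

    # --- herbs, compounds and targets -----------------------------------
    sigma = 0.8
    mu = float(np.log(config.compounds_per_herb_mean)) - sigma**2 / 2
    c_lo, c_hi = config.compounds_per_herb
    t_lo, t_hi = config.targets_per_compound
    herb_compound_rows: list[tuple[str, str, list[str]]] = []
    compound_gene_rows: list[tuple[str, str, list[str]]] = []
    compound_counter = 0

    def new_compound(herb_id: str, targets: Sequence[str]) -> None:
        nonlocal compound_counter
        compound_counter += 1
        compound_id = f"C{compound_counter:06d}"
        herb_compound_rows.append(
            (herb_id, compound_id, _draw_sources(rng, db_labels, config.evidence_prob))
        )
        for gene in sorted(set(targets)):
            compound_gene_rows.append(
                (compound_id, gene, _draw_sources(rng, db_labels, config.evidence_prob))
            )

    for herb_id in herb_ids:
        gold_diseases = gold_map.get(herb_id, [])
        herb_pool: list[str] = sorted(
            {g for d in gold_diseases for g in pools[d]}
        )
        n_compounds = int(np.clip(round(rng.lognormal(mu, sigma)), c_lo, c_hi))
        for _ in range(n_compounds):
            n_targets = int(rng.integers(t_lo, t_hi + 1))
            targets = []
            for _ in range(n_targets):
                if herb_pool and rng.random() < config.module_locality:
                    targets.append(herb_pool[int(rng.integers(len(herb_pool)))])
                else:
                    targets.append(nodes[int(rng.integers(len(nodes)))])
            new_compound(herb_id, targets)
        # multiplicity signal: a focus set per gold disease receives extra
        # compounds, raising those genes' weights well above background
        if config.multiplicity_boost > 0:
            for disease_id in gold_diseases:
                pool = pools[disease_id]
                focus_size = min(int(rng.integers(t_lo, t_hi + 1)), len(pool))
                idx = rng.choice(len(pool), size=focus_size, replace=False)
                focus = [pool[i] for i in sorted(idx)]
                for _ in range(config.multiplicity_boost):
                    new_compound(herb_id, focus)

    # --- assemble tables -------------------------------------------------
    disease_gene_rows = [
        (d, g, _draw_sources(rng, db_labels, config.evidence_prob))
        for d in disease_ids
        for g in disease_genes[d]
    ]
    gold_rows = [
        (h, d, _draw_sources(rng, db_labels, config.evidence_prob))
        for h in sorted(gold_map)
        for d in gold_map[h]
    ]
    tables = {
        RelationKind.DISEASE_GENE: AssociationTable.from_rows(
            RelationKind.DISEASE_GENE, disease_gene_rows
        ),
        RelationKind.HERB_COMPOUND: AssociationTable.from_rows(
            RelationKind.HERB_COMPOUND, herb_compound_rows
        ),
        RelationKind.COMPOUND_GENE: AssociationTable.from_rows(
            RelationKind.COMPOUND_GENE, compound_gene_rows
        ),
        RelationKind.HERB_DISEASE: AssociationTable.from_rows(
            RelationKind.HERB_DISEASE, gold_rows
        ),
    }
    gold = GoldStandard.from_table(tables[RelationKind.HERB_DISEASE])
    logger.info(
        "generated synthetic dataset: %d nodes, %d diseases, %d herbs, "
        "%d compounds, %d gold pairs",
        graph.number_of_nodes(),
        len(disease_ids),
        len(herb_ids),
        compound_counter,
        len(gold),
    )
    return SyntheticDataset(config, sorted(graph.edges()), tables, gold)


def summarize(
    tables: Mapping[RelationKind, AssociationTable], graph: nx.Graph
) -> pd.DataFrame:
    """Descriptive statistics of the generated (or loaded) inputs.

    One row per quantity — genes per disease, compounds per herb, genes per
    herb, node degree — with mean/min/max/n columns.
    """

    def describe(counts: Sequence[int]) -> dict:
        if len(counts) == 0:
            return {"mean": np.nan, "min": np.nan, "max": np.nan, "n": 0}
        arr = np.asarray(counts)
        return {
            "mean": float(arr.mean()),
            "min": int(arr.min()),
            "max": int(arr.max()),
            "n": len(arr),
        }

    rows = {}
    dg = tables.get(RelationKind.DISEASE_GENE)
    rows["disease_genes"] = describe(
        [p.n_genes for p in assoc.build_disease_profiles(dg)] if dg and len(dg) else []
    )
    hc = tables.get(RelationKind.HERB_COMPOUND)
    cg = tables.get(RelationKind.COMPOUND_GENE)
    if hc and len(hc):
        per_herb: dict[str, int] = {}
        for r in hc:
            per_herb[r.subject] = per_herb.get(r.subject, 0) + 1
        rows["herb_compounds"] = describe(list(per_herb.values()))
    else:
        logger.warning("empty herb-compound table: herb statistics unavailable")
        rows["herb_compounds"] = describe([])
    if hc and cg and len(hc) and len(cg):
        profiles = assoc.build_herb_profiles(hc, cg)
        rows["herb_genes"] = describe([p.n_genes for p in profiles])
    else:
        rows["herb_genes"] = describe([])
    rows["node_degree"] = describe(
        [d for _, d in graph.degree()] if graph is not None else []
    )
    return pd.DataFrame.from_dict(rows, orient="index")[["mean", "min", "max", "n"]]


def benchmark_measures(
    config: SyntheticConfig,
    seeds: Sequence[int],
    min_sources: int = 2,
    measures: Sequence[Measure | str] = (Measure.ASP, Measure.ACP, Measure.WACP),
) -> pd.DataFrame:
    """Global AUROC of each measure over a sweep of generator seeds.

    Each seed runs the full pipeline: generate, evidence-filter, build
    profiles, score every pair on the LCC, and rank against the generated gold
    standard. Returns a seed × measure DataFrame of AUROC values.
    """
    records = {}
    for seed in seeds:
        dataset = generate(dataclasses.replace(config, seed=int(seed)))
        dg = assoc.filter_by_evidence(
            dataset.tables[RelationKind.DISEASE_GENE], min_sources
        )
        hc = assoc.filter_by_evidence(
            dataset.tables[RelationKind.HERB_COMPOUND], min_sources
        )
        cg = assoc.filter_by_evidence(
            dataset.tables[RelationKind.COMPOUND_GENE], min_sources
        )
        diseases = assoc.build_disease_profiles(dg)
        herbs = assoc.build_herb_profiles(hc, cg)
        graph = largest_connected_component(build_graph(dataset.edges))
        oracle = DistanceOracle(graph)
        row = {}
        for measure in measures:
            matrix = score_all_pairs(herbs, diseases, oracle, measure)
            scores, labels = label_and_orient(matrix, dataset.gold)
            row[Measure(measure).value] = auroc(scores, labels)
        records[int(seed)] = row
    return pd.DataFrame.from_dict(records, orient="index")
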