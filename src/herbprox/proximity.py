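"""Network proximity measures between herb and disease gene sets.

Three measures quantify how close a herb's target genes ``H = {h_1..h_N}`` lie
to a disease's genes ``D = {d_1..d_M}`` on the interactome, where
``spl(a, b)`` is the unweighted shortest path length. Lower values predict
stronger association.

* ASP, average shortest path length::

      ASP(H, D) = (1 / (N*M)) * sum_n sum_m spl(h_n, d_m)

* ACP, average closest path length — each herb gene only needs to reach its
  nearest disease gene (asymmetric in H vs D)::

      ACP(H, D) = (1 / N) * sum_n min_m spl(h_n, d_m)

* WACP, weighted average closest path length — each herb gene's closest
  distance is scaled by the inverse of its weight ``w_n``, the number of the
  herb's compounds targeting it, so genes hit by many compounds pull the score
  down::

      WACP(H, D) = (1 / N) * sum_n (1 / w_n) * min_m spl(h_n, d_m)

Genes absent from the interactome are dropped before scoring and the
denominators use the restricted counts; a pair whose restricted herb or
disease set is empty has no finite faithful value and is reported as
undefined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .associations import DiseaseProfile, HerbProfile
from .interactome import DistanceOracle

logger = logging.getLogger(__name__)

__all__ = [
    "Measure",
    "UndefinedScoreError",
    "asp",
    "acp",
    "wacp",
    "score_all_pairs",
    "ScoreMatrix",
]


class Measure(str, Enum):
    ASP = "ASP"
    ACP = "ACP"
    WACP = "WACP"


class UndefinedScoreError(ValueError):
    """A gene set is empty after restriction to the interactome."""


def _restrict(genes: Iterable[str], oracle: DistanceOracle, label: str) -> list[str]:
    kept = sorted(g for g in genes if g in oracle.graph)
    if not kept:
        raise UndefinedScoreError(f"no {label} genes remain on the interactome")
    return kept


def asp(H: Iterable[str], D: Iterable[str], oracle: DistanceOracle) -> float:
    """Average shortest path length over all (herb gene, disease gene) pairs."""
    Hr = _restrict(H, oracle, "herb")
    Dr = _restrict(D, oracle, "disease")
    total = 0
    for d in Dr:
        dists = oracle.distances_from(d)
        total += sum(dists[h] for h in Hr)
    return total / (len(Hr) * len(Dr))


def _closest(Hr: Sequence[str], Dr: Sequence[str], oracle: DistanceOracle) -> list[int]:
    """For each herb gene, its distance to the nearest disease gene."""
    mins = [None] * len(Hr)
    for d in Dr:
        dists = oracle.distances_from(d)
        for i, h in enumerate(Hr):
            dist = dists[h]
            if mins[i] is None or dist < mins[i]:
                mins[i] = dist
    return mins


def acp(H: Iterable[str], D: Iterable[str], oracle: DistanceOracle) -> float:
    """Average, over herb genes, of the distance to the closest disease gene."""
    Hr = _restrict(H, oracle, "herb")
    Dr = _restrict(D, oracle, "disease")
    return sum(_closest(Hr, Dr, oracle)) / len(Hr)


def wacp(
    H_weights: Mapping[str, float], D: Iterable[str], oracle: DistanceOracle
) -> float:
    """Weight-scaled average closest path length.

    ``H_weights`` maps each herb gene to its compound-multiplicity weight
    (a positive number; counts in practice). With all weights equal to 1 the
    value coincides with :func:`acp`.
    """
    for g, w in H_weights.items():
        if w <= 0:
            raise ValueError(f"weight of gene {g!r} must be positive, got {w}")
    Hr = _restrict(H_weights, oracle, "herb")
    Dr = _restrict(D, oracle, "disease")
    mins = _closest(Hr, Dr, oracle)
    return sum(m / H_weights[h] for h, m in zip(Hr, mins)) / len(Hr)


@dataclass
class ScoreMatrix:
    """Herb × disease values for one proximity measure.

    ``values`` is a float DataFrame indexed by herb id with disease-id columns;
    undefined cells (an empty restricted gene set on either side) hold NaN.
    The per-entity gene counts after restriction to the interactome are kept
    alongside for diagnostics.
    """

    measure: Measure
    values: pd.DataFrame
    n_herb_genes: pd.Series
    n_disease_genes: pd.Series

    @property
    def herb_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def disease_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_defined(self) -> int:
        return int(self.values.notna().sum().sum())

    def to_tsv(self, path: str | Path) -> None:
        """Write the long-format score table; undefined cells as ``NA``."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("herb\tdisease\tmeasure\tvalue\tn_herb_genes\tn_disease_genes\n")
            for herb in self.values.index:
                nh = int(self.n_herb_genes[herb])
                for disease in self.values.columns:
                    v = self.values.at[herb, disease]
                    text = "NA" if pd.isna(v) else format(float(v), ".12g")
                    fh.write(
                        f"{herb}\t{disease}\t{self.measure.value}\t{text}"
                        f"\t{nh}\t{int(self.n_disease_genes[disease])}\n"
                    )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScoreMatrix":
        df = pd.read_csv(
            path, sep="\t", dtype={"herb": str, "disease": str, "measure": str},
            na_values=["NA"], keep_default_na=False,
        )
        measures = df["measure"].unique()
        if len(measures) != 1:
            raise ValueError(f"expected a single measure per file, got {list(measures)}")
        values = (
            df.pivot(index="herb", columns="disease", values="value")
            .astype(float)
            .rename_axis(index=None, columns=None)
        )
        n_herb = df.groupby("herb")["n_herb_genes"].first().astype(int)
        n_dis = df.groupby("disease")["n_disease_genes"].first().astype(int)
        return cls(
            Measure(measures[0]),
            values.sort_index(axis=0).sort_index(axis=1),
            n_herb.sort_index(),
            n_dis.sort_index(),
        )


def score_all_pairs(
    herbs: Sequence[HerbProfile],
    diseases: Sequence[DiseaseProfile],
    oracle: DistanceOracle,
    measure: Measure | str,
) -> ScoreMatrix:
    """Score every herb–disease pair with one measure.

    Equivalent to calling :func:`asp`/:func:`acp`/:func:`wacp` per pair, but
    runs one BFS per distinct in-graph disease gene and vectorises the herb
    side. Profiles are ordered by identifier, so the result is independent of
    input ordering; undefined cells are NaN and their count is logged.
    """
    measure = Measure(measure)
    herbs = sorted(herbs, key=lambda h: h.herb_id)
    diseases = sorted(diseases, key=lambda d: d.disease_id)
    node_index = {g: i for i, g in enumerate(oracle.graph)}
    n_nodes = len(node_index)

    rows: dict[str, np.ndarray] = {}

    def distance_row(gene: str) -> np.ndarray:
        arr = rows.get(gene)
        if arr is None:
            # unreachable nodes (possible only off the LCC) keep a sentinel
            arr = np.full(n_nodes, np.iinfo(np.int32).max, dtype=np.int32)
            for g, dist in oracle.distances_from(gene).items():
                arr[node_index[g]] = dist
            rows[gene] = arr
        return arr

    herb_cols: list[np.ndarray] = []
    herb_w: list[np.ndarray] = []
    n_herb_genes = {}
    for h in herbs:
        genes = sorted(g for g in h.gene_weights if g in node_index)
        herb_cols.append(np.array([node_index[g] for g in genes], dtype=np.intp))
        herb_w.append(np.array([h.gene_weights[g] for g in genes], dtype=float))
        n_herb_genes[h.herb_id] = len(genes)

    values = np.full((len(herbs), len(diseases)), np.nan)
    n_disease_genes = {}
    for j, dprof in enumerate(diseases):
        dgenes = sorted(g for g in dprof.genes if g in node_index)
        n_disease_genes[dprof.disease_id] = len(dgenes)
        if not dgenes:
            continue
        dmat = np.vstack([distance_row(g) for g in dgenes])  # (M, n_nodes)
        dmin = dmat.min(axis=0)
        for i in range(len(herbs)):
            cols = herb_cols[i]
            if cols.size == 0:
                continue
            if measure is Measure.ASP:
                values[i, j] = dmat[:, cols].mean()
            elif measure is Measure.ACP:
                values[i, j] = dmin[cols].mean()
            else:
                values[i, j] = (dmin[cols] / herb_w[i]).mean()

    n_undefined = int(np.isnan(values).sum())
    if n_undefined:
        logger.info(
            "%s score matrix: %d of %d cells undefined (empty restricted gene set)",
            measure.value,
            n_undefined,
            values.size,
        )
    herb_ids = [h.herb_id for h in herbs]
    disease_ids = [d.disease_id for d in diseases]
    return ScoreMatrix(
        measure,
        pd.DataFrame(values, index=herb_ids, columns=disease_ids),
        pd.Series(n_herb_genes, dtype=int).reindex(herb_ids),
        pd.Series(n_disease_genes, dtype=int).reindex(disease_ids),
    )
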