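"""Ranking evaluation against a gold standard, diagnostics and discovery rules.

Herb–disease pairs are ranked by a proximity measure (smaller value = stronger
predicted association) and compared with a set of known-positive pairs. The
module provides:

* global AUROC (rank/midrank formulation) and AUPRC (step-wise average
  precision) with the positive-rate baseline;
* per-herb and per-disease AUROC, each computed inside the entity's own
  row/column of the score matrix;
* Pearson correlation between per-entity AUROC and the entity's number of
  known partners (a sanity check that performance is not an artefact of
  annotation density);
* an FPR-anchored score threshold (conservative: the achieved false-positive
  rate never exceeds the target);
* case-study helpers — selection of reliably predicted herbs and a
  rank-sum comparison of known vs other scores;
* rule-based discovery of candidate novel associations.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve

from .associations import AssociationTable, RelationKind, load_association_table
from .proximity import ScoreMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationError",
    "UndefinedCorrelationError",
    "GoldStandard",
    "label_and_orient",
    "auroc",
    "auprc",
    "baseline_precision",
    "roc_points",
    "ThresholdResult",
    "threshold_at_fpr",
    "per_entity_auroc",
    "auroc_vs_count_correlation",
    "select_reliable_herbs",
    "DiscoveryResult",
    "discover_novel",
    "rank_sum_compare",
    "EvalReport",
    "evaluate",
]


class EvaluationError(ValueError):
    """The inputs do not admit the requested evaluation."""


class UndefinedCorrelationError(EvaluationError):
    """A correlation is requested on a zero-variance axis."""


@dataclass(frozen=True)
class GoldStandard:
    """Known-positive (herb, disease) pairs."""

    pairs: frozenset[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def diseases_of(self, herb_id: str) -> set[str]:
        return {d for h, d in self.pairs if h == herb_id}

    def herbs_of(self, disease_id: str) -> set[str]:
        return {h for h, d in self.pairs if d == disease_id}

    @classmethod
    def from_table(cls, table: AssociationTable) -> "GoldStandard":
        if table.relation_kind is not RelationKind.HERB_DISEASE:
            raise ValueError(
                f"expected a herb_disease table, got {table.relation_kind.value}"
            )
        return cls(frozenset(table.pairs()))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GoldStandard":
        return cls.from_table(load_association_table(path, RelationKind.HERB_DISEASE))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("herb\tdisease\n")
            for h, d in sorted(self.pairs):
                fh.write(f"{h}\t{d}\n")


def label_and_orient(
    matrix: ScoreMatrix, gold: GoldStandard
) -> tuple[np.ndarray, np.ndarray]:
    """Flatten the defined cells of a score matrix into (scores, labels).

    Scores stay on the original measure scale, where smaller means a stronger
    predicted association; downstream metrics handle the orientation. Gold
    pairs that reference an unscored herb or disease are excluded with a log
    message.
    """
    herb_ids = matrix.herb_ids
    disease_ids = matrix.disease_ids
    herb_set, disease_set = set(herb_ids), set(disease_ids)
    unmatched = [
        p for p in gold.pairs if p[0] not in herb_set or p[1] not in disease_set
    ]
    if unmatched:
        logger.warning(
            "%d of %d gold pairs reference unscored entities and are excluded",
            len(unmatched),
            len(gold),
        )
    values = matrix.values.to_numpy()
    label_grid = np.zeros(values.shape, dtype=bool)
    for h, d in gold.pairs:
        if h in herb_set and d in disease_set:
            label_grid[herb_ids.index(h), disease_ids.index(d)] = True
    defined = ~np.isnan(values)
    if not defined.any():
        raise EvaluationError("score matrix has no defined cells")
    scores = values[defined]
    labels = label_grid[defined].astype(int)
    if labels.sum() == 0:
        raise EvaluationError("no gold-standard positives match the score matrix")
    return scores, labels


def auroc(
    scores: np.ndarray, labels: np.ndarray, *, smaller_is_stronger: bool = True
) -> float:
    """Area under the ROC curve of a scored binary labelling.

    Uses the rank/midrank (Mann–Whitney) formulation: the probability that a
    random positive outranks a random negative, with ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise EvaluationError("AUROC needs both a positive and a negative class")
    oriented = -scores if smaller_is_stronger else scores
    return float(roc_auc_score(labels, oriented))


def auprc(
    scores: np.ndarray, labels: np.ndarray, *, smaller_is_stronger: bool = True
) -> float:
    """Area under the precision-recall curve by step-wise summation.

    Step-wise (rectangular) integration — identical to average precision —
    avoids the optimistic bias of trapezoidal interpolation between recall
    levels. The no-skill baseline is ``positives / total``
    (:func:`baseline_precision`).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise EvaluationError("AUPRC needs at least one positive")
    oriented = -scores if smaller_is_stronger else scores
    return float(average_precision_score(labels, oriented))


def baseline_precision(n_positives: int, n_total: int) -> float:
    """The positive rate — AUPRC of a random ranking."""
    if n_total <= 0 or n_positives < 0 or n_positives > n_total:
        raise ValueError(f"invalid counts: {n_positives} positives of {n_total}")
    return n_positives / n_total


def roc_points(
    scores: np.ndarray, labels: np.ndarray, *, smaller_is_stronger: bool = True
) -> list[tuple[float, float, float]]:
    """The full ROC as (fpr, tpr, threshold) with thresholds on the score scale.

    With the smaller-is-stronger orientation a cell is called positive when its
    score is <= the threshold; the first point (nothing called) carries
    threshold ``-inf``.
    """
    scores = np.asarray(scores, dtype=float)
    oriented = -scores if smaller_is_stronger else scores
    fpr, tpr, thr = roc_curve(labels, oriented, drop_intermediate=False)
    if smaller_is_stronger:
        thr = -thr
    return [(float(f), float(t), float(c)) for f, t, c in zip(fpr, tpr, thr)]


class ThresholdResult(NamedTuple):
    threshold: float
    recall: float
    fpr: float


def threshold_at_fpr(
    roc_pts: Sequence[tuple[float, float, float]], target_fpr: float = 0.05
) -> ThresholdResult:
    """Largest score threshold whose achieved FPR does not exceed the target.

    Conservative by construction: among all ROC operating points with
    ``fpr <= target_fpr`` the most permissive one is returned, together with
    the recall and FPR attained there. ``target_fpr=1.0`` therefore yields the
    maximum score (everything called positive).
    """
    if not 0 < target_fpr <= 1:
        raise ValueError(f"target_fpr must lie in (0, 1], got {target_fpr}")
    best: ThresholdResult | None = None
    for fpr, tpr, thr in roc_pts:
        if fpr <= target_fpr and (best is None or thr > best.threshold):
            best = ThresholdResult(float(thr), float(tpr), float(fpr))
    if best is None:
        raise EvaluationError("ROC has no operating point at or below the target FPR")
    return best


def _entity_views(matrix: ScoreMatrix, axis: str):
    if axis == "herb":
        return matrix.values
    if axis == "disease":
        return matrix.values.T
    raise ValueError(f"axis must be 'herb' or 'disease', got {axis!r}")


def _is_gold(gold: GoldStandard, entity: str, partner: str, axis: str) -> bool:
    return ((entity, partner) if axis == "herb" else (partner, entity)) in gold


def per_entity_auroc(
    matrix: ScoreMatrix, gold: GoldStandard, axis: str = "herb"
) -> dict[str, float]:
    """AUROC within each herb's row (or disease's column) of the matrix.

    Entities are included only when their defined cells contain at least one
    positive and at least one negative; the rest are omitted with a logged
    tally (AUROC is ill-defined on a single class).
    """
    views = _entity_views(matrix, axis)
    result: dict[str, float] = {}
    n_no_pos = n_no_neg = 0
    for entity, row in views.iterrows():
        defined = row.dropna()
        if defined.empty:
            n_no_pos += 1
            continue
        labels = np.array(
            [_is_gold(gold, entity, partner, axis) for partner in defined.index],
            dtype=int,
        )
        if labels.sum() == 0:
            n_no_pos += 1
            continue
        if labels.sum() == len(labels):
            n_no_neg += 1
            continue
        result[entity] = auroc(defined.to_numpy(), labels)
    if n_no_pos or n_no_neg:
        logger.info(
            "per-%s AUROC: kept %d entities; omitted %d without positives "
            "and %d without negatives",
            axis,
            len(result),
            n_no_pos,
            n_no_neg,
        )
    return result


def auroc_vs_count_correlation(
    per_entity: Mapping[str, float], gold: GoldStandard, axis: str = "herb"
) -> tuple[float, float]:
    """Pearson correlation of per-entity AUROC with gold-partner count.

    Returns ``(r, p)`` with the standard two-sided t-distributed p-value.
    Raises :class:`UndefinedCorrelationError` when either axis has zero
    variance.
    """
    if axis not in ("herb", "disease"):
        raise ValueError(f"axis must be 'herb' or 'disease', got {axis!r}")
    entities = sorted(per_entity)
    if len(entities) < 3:
        raise EvaluationError("correlation needs at least three entities")
    aurocs = np.array([per_entity[e] for e in entities], dtype=float)
    counts = np.array(
        [
            len(gold.diseases_of(e) if axis == "herb" else gold.herbs_of(e))
            for e in entities
        ],
        dtype=float,
    )
    if np.ptp(aurocs) == 0 or np.ptp(counts) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined: zero variance on one axis"
        )
    r, p = stats.pearsonr(aurocs, counts)
    return float(r), float(p)


def select_reliable_herbs(
    per_herb_auroc: Mapping[str, float],
    matrix: ScoreMatrix,
    gold: GoldStandard,
    auroc_min: float = 0.9,
    min_known: int = 3,
    wacp_threshold: float = None,
) -> list[tuple[str, float]]:
    """Herbs whose known associations are both well ranked and strongly scored.

    A herb qualifies when (i) its per-herb AUROC exceeds ``auroc_min``,
    (ii) it has at least ``min_known`` known diseases with a defined score, and
    (iii) every one of those known-disease scores lies below
    ``wacp_threshold`` (typically the FPR-anchored threshold). Sorted by AUROC
    descending, then herb id.
    """
    if wacp_threshold is None:
        raise ValueError("wacp_threshold must be supplied (see threshold_at_fpr)")
    selected: list[tuple[str, float]] = []
    for herb, value in per_herb_auroc.items():
        if not value > auroc_min or herb not in matrix.values.index:
            continue
        known = [
            matrix.values.at[herb, d]
            for d in gold.diseases_of(herb)
            if d in matrix.values.columns and not pd.isna(matrix.values.at[herb, d])
        ]
        if len(known) < min_known:
            continue
        if all(s < wacp_threshold for s in known):
            selected.append((herb, float(value)))
    selected.sort(key=lambda item: (-item[1], item[0]))
    return selected


@dataclass(frozen=True)
class DiscoveryResult:
    """Candidate novel associations proposed from reliably predicted herbs."""

    reliable_herbs: tuple[tuple[str, float], ...]
    candidates: tuple[tuple[str, str, float], ...]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("herb\tdisease\tvalue\n")
            for herb, disease, value in self.candidates:
                fh.write(f"{herb}\t{disease}\t{format(value, '.12g')}\n")


def discover_novel(
    matrix: ScoreMatrix,
    gold: GoldStandard,
    per_disease_auroc: Mapping[str, float],
    herbs: Sequence[str | tuple[str, float]],
    disease_auroc_min: float,
) -> DiscoveryResult:
    """Propose novel (herb, disease) pairs by the two discovery rules.

    For each selected herb, a non-gold disease becomes a candidate when its
    score is lower than the mean score of the herb's known diseases AND the
    disease's own AUROC exceeds ``disease_auroc_min`` (typically the mean
    per-disease AUROC of the current run, not a fixed constant). Candidates
    are disjoint from the gold standard by construction.
    """
    reliable: list[tuple[str, float]] = []
    for item in herbs:
        if isinstance(item, tuple):
            reliable.append((item[0], float(item[1])))
        else:
            reliable.append((item, float("nan")))
    candidates: list[tuple[str, str, float]] = []
    for herb, _ in reliable:
        if herb not in matrix.values.index:
            raise EvaluationError(f"herb {herb!r} is not in the score matrix")
        known = [
            matrix.values.at[herb, d]
            for d in gold.diseases_of(herb)
            if d in matrix.values.columns and not pd.isna(matrix.values.at[herb, d])
        ]
        if not known:
            raise EvaluationError(
                f"herb {herb!r} has no known disease with a defined score"
            )
        mean_known = float(np.mean(known))
        for disease in matrix.values.columns:
            if (herb, disease) in gold:
                continue
            value = matrix.values.at[herb, disease]
            if pd.isna(value):
                continue
            disease_perf = per_disease_auroc.get(disease)
            if disease_perf is None:
                continue
            if value < mean_known and disease_perf > disease_auroc_min:
                candidates.append((herb, disease, float(value)))
    candidates.sort(key=lambda c: (c[0], c[2], c[1]))
    return DiscoveryResult(tuple(reliable), tuple(candidates))


def rank_sum_compare(
    known_scores: Sequence[float], other_scores: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) comparison of two samples.

    Ties are handled by midranks. The exact null distribution is used when
    both samples have at most 8 untied observations; otherwise the normal
    approximation (with continuity correction) applies. Returns the
    Mann–Whitney U statistic of the first sample and the two-sided p-value.
    """
    x = np.asarray(known_scores, dtype=float)
    y = np.asarray(other_scores, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "asymptotic"
    result = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(result.statistic), float(result.pvalue)


@dataclass
class EvalReport:
    """Global and per-entity evaluation of one score matrix."""

    measure: str
    auroc: float
    auprc: float
    baseline_auprc: float
    n_pairs: int
    n_positives: int
    roc: list[tuple[float, float, float]]
    threshold: ThresholdResult
    target_fpr: float
    per_herb_auroc: dict[str, float]
    per_disease_auroc: dict[str, float]
    pcc_herb: tuple[float, float] | None
    pcc_disease: tuple[float, float] | None

    def to_json(self, path: str | Path) -> None:
        def finite(x: float) -> float | None:
            return float(x) if math.isfinite(x) else None

        payload = {
            "measure": self.measure,
            "auroc": self.auroc,
            "auprc": self.auprc,
            "baseline_auprc": self.baseline_auprc,
            "n_pairs": self.n_pairs,
            "n_positives": self.n_positives,
            "target_fpr": self.target_fpr,
            "threshold": finite(self.threshold.threshold),
            "recall_at_threshold": self.threshold.recall,
            "fpr_at_threshold": self.threshold.fpr,
            "mean_per_herb_auroc": (
                float(np.mean(list(self.per_herb_auroc.values())))
                if self.per_herb_auroc
                else None
            ),
            "mean_per_disease_auroc": (
                float(np.mean(list(self.per_disease_auroc.values())))
                if self.per_disease_auroc
                else None
            ),
            "n_herbs_evaluated": len(self.per_herb_auroc),
            "n_diseases_evaluated": len(self.per_disease_auroc),
            "pcc_herb": list(self.pcc_herb) if self.pcc_herb else None,
            "pcc_disease": list(self.pcc_disease) if self.pcc_disease else None,
            "roc": [[f, t, finite(c)] for f, t, c in self.roc],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def write_per_entity_tsv(per_entity: Mapping[str, float], path: str | Path) -> None:
    """Write an entity→AUROC map as a two-column TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("entity\tauroc\n")
        for entity in sorted(per_entity):
            fh.write(f"{entity}\t{format(per_entity[entity], '.12g')}\n")


def evaluate(
    matrix: ScoreMatrix, gold: GoldStandard, target_fpr: float = 0.05
) -> EvalReport:
    """Run the full evaluation battery on one score matrix."""
    scores, labels = label_and_orient(matrix, gold)
    roc = roc_points(scores, labels)
    per_herb = per_entity_auroc(matrix, gold, axis="herb")
    per_disease = per_entity_auroc(matrix, gold, axis="disease")

    def correlation(per_entity, axis):
        try:
            return auroc_vs_count_correlation(per_entity, gold, axis)
        except EvaluationError as exc:
            logger.info("per-%s correlation unavailable: %s", axis, exc)
            return None

    return EvalReport(
        measure=matrix.measure.value,
        auroc=auroc(scores, labels),
        auprc=auprc(scores, labels),
        baseline_auprc=baseline_precision(int(labels.sum()), int(labels.size)),
        n_pairs=int(labels.size),
        n_positives=int(labels.sum()),
        roc=roc,
        threshold=threshold_at_fpr(roc, target_fpr),
        target_fpr=target_fpr,
        per_herb_auroc=per_herb,
        per_disease_auroc=per_disease,
        pcc_herb=correlation(per_herb, "herb"),
        pcc_disease=correlation(per_disease, "disease"),
    )
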