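"""Evidence-annotated association tables and herb/disease gene-set profiles.

A natural herb acts through the compounds it contains, each of which may bind
several protein targets — the multi-compound multi-target (MCMT) picture. The
raw material for network scoring is therefore a set of association tables:
disease–gene, herb–compound, compound–gene, and (for evaluation) herb–disease.
Each record carries the set of source databases that reported it; records
supported by fewer than a configurable number of independent databases are
discarded before profiles are built.

From the filtered tables, two kinds of gene-set profile are derived:

* :class:`DiseaseProfile` — the set ``D_k`` of genes associated with a
  disease.
* :class:`HerbProfile` — the union ``H_i`` of the target genes of the herb's
  compounds, with a per-gene weight ``w`` counting how many of the herb's
  compounds target that gene. The weights feed the weighted average closest
  path length (WACP) measure.

Identifiers are opaque, case-sensitive strings; joining is exact-string and no
nomenclature validation is attempted.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationFormatError",
    "EmptyTableError",
    "RelationKind",
    "AssociationRecord",
    "AssociationTable",
    "DiseaseProfile",
    "HerbProfile",
    "load_association_table",
    "filter_by_evidence",
    "build_disease_profiles",
    "build_herb_profiles",
]


class AssociationFormatError(ValueError):
    """An association file or record violates the expected format."""


class EmptyTableError(AssociationFormatError):
    """An association file contains no records."""


class RelationKind(str, Enum):
    """The semantics of the (subject, object) columns of a table."""

    DISEASE_GENE = "disease_gene"
    HERB_COMPOUND = "herb_compound"
    COMPOUND_GENE = "compound_gene"
    HERB_DISEASE = "herb_disease"


@dataclass(frozen=True)
class AssociationRecord:
    """One subject→object link with its supporting source-database labels."""

    subject: str
    object: str
    sources: frozenset[str]


@dataclass(frozen=True)
class AssociationTable:
    """A deduplicated set of evidence-annotated association records.

    Records are stored sorted by (subject, object) so that any two tables
    built from the same links compare equal regardless of input row order.
    """

    relation_kind: RelationKind
    records: tuple[AssociationRecord, ...]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AssociationRecord]:
        return iter(self.records)

    def pairs(self) -> set[tuple[str, str]]:
        """The set of (subject, object) pairs in the table."""
        return {(r.subject, r.object) for r in self.records}

    @classmethod
    def from_rows(
        cls,
        relation_kind: RelationKind | str,
        rows: Iterable[tuple[str, str, Iterable[str]]],
    ) -> "AssociationTable":
        """Build a table from (subject, object, sources) rows.

        Duplicate (subject, object) pairs are merged by unioning their source
        sets. Empty identifiers or an empty source set raise
        :class:`AssociationFormatError`.
        """
        merged: dict[tuple[str, str], set[str]] = {}
        for subject, obj, sources in rows:
            if not subject or not obj:
                raise AssociationFormatError(
                    "identifiers must be non-empty strings "
                    f"(got subject={subject!r}, object={obj!r})"
                )
            labels = {str(s) for s in sources if str(s)}
            if not labels:
                raise AssociationFormatError(
                    f"record ({subject!r}, {obj!r}) carries no source label"
                )
            merged.setdefault((subject, obj), set()).update(labels)
        records = tuple(
            AssociationRecord(s, o, frozenset(labels))
            for (s, o), labels in sorted(merged.items())
        )
        return cls(RelationKind(relation_kind), records)

    def to_tsv(self, path: str | Path) -> None:
        """Write the table in the ``subject<TAB>object<TAB>sources`` dialect."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("subject\tobject\tsources\n")
            for r in self.records:
                fh.write(f"{r.subject}\t{r.object}\t{'|'.join(sorted(r.sources))}\n")


def _split_sources(text: str) -> list[str]:
    # the sources field splits on "|" first, then ","
    labels: list[str] = []
    for chunk in str(text).split("|"):
        for label in chunk.split(","):
            label = label.strip()
            if label:
                labels.append(label)
    return labels


def load_association_table(
    path: str | Path, relation_kind: RelationKind | str
) -> AssociationTable:
    """Load a TSV association table.

    The file must carry a header line with columns ``subject``, ``object`` and
    ``sources`` (extra columns are ignored); lines beginning with ``#`` are
    skipped. The sources field holds one or more database labels separated by
    ``|`` or ``,``.

    Raises
    ------
    EmptyTableError
        If the file holds no records.
    AssociationFormatError
        If required columns are missing or a record has no source label.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", dtype=str, keep_default_na=False
        )
    except pd.errors.EmptyDataError:
        raise EmptyTableError(f"association file {path} is empty") from None
    missing = {"subject", "object", "sources"} - set(df.columns)
    if missing:
        raise AssociationFormatError(
            f"association file {path} lacks required columns: {sorted(missing)}"
        )
    if df.empty:
        raise EmptyTableError(f"association file {path} holds no records")
    rows = (
        (subject, obj, _split_sources(sources))
        for subject, obj, sources in zip(df["subject"], df["object"], df["sources"])
    )
    return AssociationTable.from_rows(relation_kind, rows)


def filter_by_evidence(table: AssociationTable, min_sources: int = 2) -> AssociationTable:
    """Keep only records supported by at least ``min_sources`` databases.

    The filter counts distinct source labels, not record multiplicity. It is
    idempotent, and with ``min_sources=1`` it is the identity on any loaded
    table (every record carries at least one label by construction).
    """
    if min_sources < 1:
        raise ValueError(f"min_sources must be >= 1, got {min_sources}")
    kept = tuple(r for r in table.records if len(r.sources) >= min_sources)
    if len(kept) < len(table.records):
        logger.info(
            "evidence filter (>=%d sources) kept %d of %d %s records",
            min_sources,
            len(kept),
            len(table.records),
            table.relation_kind.value,
        )
    return AssociationTable(table.relation_kind, kept)


@dataclass(frozen=True)
class DiseaseProfile:
    """The gene set D_k of one disease."""

    disease_id: str
    genes: frozenset[str]

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class HerbProfile:
    """The gene set H_i of one herb with compound-multiplicity weights.

    ``gene_weights[g]`` is the number of the herb's compounds that target gene
    ``g`` (always >= 1); the gene set is the union of the compounds' target
    sets.
    """

    herb_id: str
    compounds: frozenset[str]
    gene_weights: Mapping[str, int] = field(hash=False)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.gene_weights)

    @property
    def n_genes(self) -> int:
        return len(self.gene_weights)


def build_disease_profiles(disease_gene: AssociationTable) -> list[DiseaseProfile]:
    """Group a disease–gene table into one profile per disease.

    The table is assumed already evidence-filtered; this is not re-checked.
    The sum of profile sizes equals the number of table records.
    """
    if disease_gene.relation_kind is not RelationKind.DISEASE_GENE:
        raise ValueError(
            f"expected a disease_gene table, got {disease_gene.relation_kind.value}"
        )
    genes: dict[str, set[str]] = defaultdict(set)
    for r in disease_gene:
        genes[r.subject].add(r.object)
    return [
        DiseaseProfile(disease_id, frozenset(gs))
        for disease_id, gs in sorted(genes.items())
    ]


def build_herb_profiles(
    herb_compound: AssociationTable, compound_gene: AssociationTable
) -> list[HerbProfile]:
    """Join herb–compound and compound–gene tables into herb profiles.

    For each herb, ``gene_weights[g]`` counts the herb's compounds whose target
    set contains ``g``. Herbs whose compounds collectively target no gene are
    dropped with a logged warning — they have no footprint on the interactome
    and cannot be scored.
    """
    if herb_compound.relation_kind is not RelationKind.HERB_COMPOUND:
        raise ValueError(
            f"expected a herb_compound table, got {herb_compound.relation_kind.value}"
        )
    if compound_gene.relation_kind is not RelationKind.COMPOUND_GENE:
        raise ValueError(
            f"expected a compound_gene table, got {compound_gene.relation_kind.value}"
        )
    targets: dict[str, set[str]] = defaultdict(set)
    for r in compound_gene:
        targets[r.subject].add(r.object)
    herb_compounds: dict[str, set[str]] = defaultdict(set)
    for r in herb_compound:
        herb_compounds[r.subject].add(r.object)

    profiles: list[HerbProfile] = []
    n_dropped = 0
    for herb_id in sorted(herb_compounds):
        weights: Counter[str] = Counter()
        for compound in sorted(herb_compounds[herb_id]):
            for gene in targets.get(compound, ()):  # a compound counts once per gene
                weights[gene] += 1
        if not weights:
            n_dropped += 1
            continue
        profiles.append(
            HerbProfile(
                herb_id,
                frozenset(herb_compounds[herb_id]),
                dict(sorted(weights.items())),
            )
        )
    if n_dropped:
        logger.warning(
            "dropped %d of %d herbs whose compounds target no genes",
            n_dropped,
            len(herb_compounds),
        )
    return profiles
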