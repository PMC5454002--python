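"""MITE-gene association, sub-region classification and insertion polymorphism.

A MITE interacts with a gene when the gap between their nearest ends is at
most ``max_distance`` (40 bp by default, inclusive; distance 0 means
overlap).  Overlapping hits are classified by the gene sub-regions they
touch, strand-aware: 5'/3' and "last exon" follow transcription direction.
Cross-accession comparison of interactions at homologous genes yields the
MITE insertion polymorphism (MIP) sharing histogram, and the interaction
value of a sharing class is gene_count x k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .homology import MITEHit
from .models import GeneModel, GenomicInterval

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InteractionParams:
    max_distance: int = 40  # inclusive
    include_novel_genes: bool = True

    def __post_init__(self) -> None:
        if self.max_distance < 0:
            raise ValueError("max_distance must be >= 0")


@dataclass
class InteractionRecord:
    """One MITE-gene association."""

    hit: MITEHit
    gene_id: str
    gene_is_novel: bool
    distance: int
    relation: str  # "single:<region>", "spanning:<r1+r2+..>", "adjacent-*", "gene"
    spans_last_exon: bool
    multi_gene: bool = False

    @property
    def accession_name(self) -> str:
        return self.hit.accession_name


def classify_relation(
    hit_interval: GenomicInterval, gene: GeneModel
) -> tuple[str, bool]:
    """Relation class of a hit overlapping a gene.

    Returns (relation, spans_last_exon).  Sub-regions are reported 5'->3' in
    transcription direction; a hit touching exactly one sub-region is
    "single:<region>", one touching several is "spanning:<ordered list>".
    """
    touched = [
        (label, iv)
        for label, iv in gene.subregions()
        if iv.overlaps(hit_interval)
    ]
    if not touched:
        # overlaps the gene locus but no annotated sub-region
        logger.warning(
            "%s: hit overlaps gene but no annotated sub-region", gene.gene_id
        )
        return "gene", False
    last = gene.last_exon
    touches_last_exon = any(iv == last for label, iv in touched if label == "CDS-exon")
    touches_3utr = any(label == "3'UTR" for label, _ in touched)
    spans_last = touches_last_exon and touches_3utr
    if len(touched) == 1:
        return f"single:{touched[0][0]}", spans_last
    return "spanning:" + "+".join(label for label, _ in touched), spans_last


def associate(
    hits: list[MITEHit],
    genes: list[GeneModel],
    params: InteractionParams = InteractionParams(),
) -> list[InteractionRecord]:
    """Associate hits with genes within ``max_distance`` (one record per gene).

    A hit overlapping/near two genes yields one record per gene, flagged
    ``multi_gene``.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        pad = params.max_distance + 1
        trees.setdefault(g.locus.chromosome, IntervalTree()).addi(
            g.locus.start - pad, g.locus.end + pad + 1, g
        )
    records: list[InteractionRecord] = []
    for hit in hits:
        tree = trees.get(hit.interval.chromosome)
        if tree is None:
            continue
        nearby = sorted(
            (iv.data for iv in tree.overlap(hit.interval.start, hit.interval.end + 1)),
            key=lambda g: (g.locus.start, g.gene_id),
        )
        matched: list[InteractionRecord] = []
        for gene in nearby:
            if gene.is_novel and not params.include_novel_genes:
                continue
            dist = hit.interval.distance_to(gene.locus)
            if dist > params.max_distance:
                continue
            if dist == 0:
                relation, spans_last = classify_relation(hit.interval, gene)
            else:
                spans_last = False
                before_gene = hit.interval.end < gene.locus.start
                upstream = before_gene == (gene.strand != "-")
                relation = "adjacent-upstream" if upstream else "adjacent-downstream"
            matched.append(
                InteractionRecord(
                    hit=hit,
                    gene_id=gene.gene_id,
                    gene_is_novel=gene.is_novel,
                    distance=dist,
                    relation=relation,
                    spans_last_exon=spans_last,
                )
            )
        if len(matched) > 1:
            for rec in matched:
                rec.multi_gene = True
        records += matched
    return records


def records_to_frame(records: list[InteractionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "accession": r.accession_name,
                "chromosome": r.hit.interval.chromosome,
                "mite_start": r.hit.interval.start,
                "mite_end": r.hit.interval.end,
                "cluster_id": r.hit.cluster_id,
                "superfamily": r.hit.superfamily_name,
                "gene_id": r.gene_id,
                "gene_is_novel": int(r.gene_is_novel),
                "distance": r.distance,
                "relation": r.relation,
                "spans_last_exon": int(r.spans_last_exon),
                "multi_gene": int(r.multi_gene),
            }
            for r in records
        ],
        columns=[
            "accession", "chromosome", "mite_start", "mite_end", "cluster_id",
            "superfamily", "gene_id", "gene_is_novel", "distance", "relation",
            "spans_last_exon", "multi_gene",
        ],
    )


def presence_from_frame(
    frame: pd.DataFrame, accessions: list[str]
) -> pd.DataFrame:
    """Presence matrix from an exported interactions table."""
    genes = sorted(frame["gene_id"].unique())
    mat = pd.DataFrame(0.0, index=pd.Index(genes, name="gene_id"), columns=accessions)
    for r in frame.itertuples():
        if r.accession in mat.columns:
            mat.at[r.gene_id, r.accession] = 1.0
    return mat


# ---------------------------------------------------------------------------
# Summaries


def relation_summary_from_counts(
    n_single: int,
    n_single_intron: int,
    n_spanning: int,
    n_spanning_last_exon: int,
) -> dict[str, float]:
    """Percentage statistics from relation class counts.

    Shares within a class are rounded to one decimal; shares of the combined
    single+spanning population to two decimals.
    """
    total = n_single + n_spanning
    out = {
        "n_single": n_single,
        "n_single_intron": n_single_intron,
        "n_spanning": n_spanning,
        "n_spanning_last_exon": n_spanning_last_exon,
        "pct_single_in_intron": (
            round(100 * n_single_intron / n_single, 1) if n_single else 0.0
        ),
        "pct_spanning_last_exon": (
            round(100 * n_spanning_last_exon / n_spanning, 1) if n_spanning else 0.0
        ),
        "pct_intron_of_embedded": (
            round(100 * n_single_intron / total, 2) if total else 0.0
        ),
        "pct_last_exon_of_embedded": (
            round(100 * n_spanning_last_exon / total, 2) if total else 0.0
        ),
    }
    return out


def relation_summary(records: list[InteractionRecord]) -> dict[str, object]:
    """Counts per relation class plus the headline percentages."""
    by_relation: dict[str, int] = {}
    for rec in records:
        by_relation[rec.relation] = by_relation.get(rec.relation, 0) + 1
    n_single = sum(v for k, v in by_relation.items() if k.startswith("single:"))
    n_spanning = sum(v for k, v in by_relation.items() if k.startswith("spanning:"))
    n_adjacent = sum(v for k, v in by_relation.items() if k.startswith("adjacent"))
    n_single_intron = by_relation.get("single:intron", 0)
    n_spanning_last = sum(
        1 for rec in records if rec.relation.startswith("spanning:") and rec.spans_last_exon
    )
    out: dict[str, object] = relation_summary_from_counts(
        n_single, n_single_intron, n_spanning, n_spanning_last
    )
    out["n_adjacent"] = n_adjacent
    out["n_records"] = len(records)
    out["by_relation"] = by_relation
    return out


def build_presence_matrix(
    records_by_accession: dict[str, list[InteractionRecord]],
    accessions: list[str] | None = None,
    annotated_genes: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Gene x accession binary matrix of MITE-gene interaction presence.

    Rows are MITE-related genes (>=1 interaction in >=1 accession).  When
    ``annotated_genes`` is given, a gene missing from an accession's
    annotation gets NaN there and that accession does not count toward the
    gene's sharing class.
    """
    if accessions is None:
        accessions = sorted(records_by_accession)
    genes = sorted(
        {rec.gene_id for recs in records_by_accession.values() for rec in recs}
    )
    mat = pd.DataFrame(0.0, index=pd.Index(genes, name="gene_id"), columns=accessions)
    if annotated_genes is not None:
        for acc in accessions:
            known = annotated_genes.get(acc, set())
            missing = [g for g in genes if g not in known]
            mat.loc[missing, acc] = float("nan")
    for acc in accessions:
        for rec in records_by_accession.get(acc, []):
            mat.at[rec.gene_id, acc] = 1.0
    return mat


def sharing_histogram(presence: pd.DataFrame) -> pd.DataFrame:
    """Sharing classes k=1..n with gene counts and interaction values.

    The interaction value of class k is gene_count * k — the number of
    MITE-related genes shared by exactly k accessions, weighted by k.
    """
    n_acc = presence.shape[1]
    k_per_gene = presence.sum(axis=1, skipna=True).astype(int)
    rows = []
    for k in range(1, n_acc + 1):
        gene_count = int((k_per_gene == k).sum())
        rows.append(
            {"k": k, "gene_count": gene_count, "interaction_value": gene_count * k}
        )
    return pd.DataFrame(rows, columns=["k", "gene_count", "interaction_value"])
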