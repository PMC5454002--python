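"""Pooled cross-accession clustering and family annotation of canonical MITEs.

Canonical elements from every accession are pooled and clustered greedily at
80% identity (CD-HIT-style semantics: sequences sorted longest-first, each
joins the first cluster whose representative it matches at the threshold,
identity measured over the shorter sequence; otherwise it founds a new
cluster).  Cluster representatives — the longest member by construction —
are then aligned against a labelled reference library; a sufficiently good
local alignment inherits that record's family and superfamily (cross-species
hits allowed, the source species is recorded), everything else is
"unclassified".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import pandas as pd
from Bio import Align

from .detect import CanonicalMITE

logger = logging.getLogger(__name__)

SUPERFAMILIES = (
    "hAT",
    "PIF/Harbinger",
    "Mutator",
    "Tc1/Mariner",
    "CACTA",
    "P-element",
    "Novosib",
)
UNCLASSIFIED = "unclassified"


@dataclass
class MITECluster:
    cluster_id: str
    members: list[CanonicalMITE] = field(default_factory=list)
    representative: str = ""
    family_name: str | None = None
    superfamily_name: str = UNCLASSIFIED
    source_species: str | None = None


def sequence_identity(a: str, b: str) -> float:
    """Identity of the best alignment of the shorter inside the longer.

    Computed as 1 - edit_distance / len(shorter) with the shorter sequence
    aligned semi-globally (free end gaps on the longer), so a decayed or
    shorter family member scores against the full representative.
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    if not short:
        return 0.0
    d = edlib.align(short, long_, mode="HW", task="distance")["editDistance"]
    return max(0.0, 1.0 - d / len(short))


def pool_and_cluster(
    mites: list[CanonicalMITE], identity_threshold: float = 0.8
) -> list[MITECluster]:
    """Greedy longest-first clustering of pooled canonical MITEs.

    Deterministic: ties in length break lexicographically by sequence, then
    by (accession, chromosome, start).
    """
    if not mites:
        return []
    ordered = sorted(
        mites,
        key=lambda m: (
            -len(m.sequence),
            m.sequence,
            m.accession_name,
            m.interval.chromosome,
            m.interval.start,
        ),
    )
    clusters: list[MITECluster] = []
    for m in ordered:
        placed = False
        for cl in clusters:
            if sequence_identity(m.sequence, cl.representative) >= identity_threshold:
                cl.members.append(m)
                placed = True
                break
        if not placed:
            clusters.append(
                MITECluster(
                    cluster_id=f"MC{len(clusters) + 1:04d}",
                    members=[m],
                    representative=m.sequence,
                )
            )
    return clusters


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="local")
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def annotate_cluster(
    cluster: MITECluster,
    library: list[dict],
    min_identity: float = 0.8,
    min_coverage: float = 0.5,
) -> MITECluster:
    """Inherit family/superfamily from the best qualifying library alignment.

    ``library`` records are dicts with sequence/family/superfamily/species
    (see readwrite.read_library_fasta).  A record qualifies when the local
    alignment identity is >= min_identity over >= min_coverage of the
    representative; the best identity wins.  No qualifying record leaves the
    cluster unclassified.
    """
    if not cluster.representative:
        raise ValueError(f"{cluster.cluster_id}: empty representative")
    if not library:
        logger.warning("empty reference library: all clusters unclassified")
        cluster.family_name = None
        cluster.superfamily_name = UNCLASSIFIED
        return cluster
    aligner = _local_aligner()
    rep = cluster.representative
    best: tuple[float, float, dict] | None = None
    for rec in library:
        alignments = aligner.align(rep, rec["sequence"])
        if len(alignments) == 0:
            continue
        aln = alignments[0]
        counts = aln.counts()
        aligned_cols = counts.identities + counts.mismatches + counts.gaps
        if aligned_cols == 0:
            continue
        identity = counts.identities / aligned_cols
        rep_blocks = aln.aligned[0]
        rep_span = sum(int(b - a) for a, b in rep_blocks)
        coverage = rep_span / len(rep)
        if identity >= min_identity and coverage >= min_coverage:
            if best is None or identity > best[0]:
                best = (identity, coverage, rec)
    if best is None:
        cluster.family_name = None
        cluster.superfamily_name = UNCLASSIFIED
        cluster.source_species = None
    else:
        _, _, rec = best
        cluster.family_name = rec["family"]
        cluster.superfamily_name = rec["superfamily"]
        cluster.source_species = rec.get("species")
    return cluster


def annotate_clusters(
    clusters: list[MITECluster],
    library: list[dict],
    min_identity: float = 0.8,
    min_coverage: float = 0.5,
) -> list[MITECluster]:
    return [
        annotate_cluster(cl, library, min_identity, min_coverage) for cl in clusters
    ]


def summarize_family_composition(clusters: list[MITECluster]) -> pd.DataFrame:
    """Distinct family counts per superfamily plus the unclassified tally.

    One row per superfamily with the number of distinct families and of
    clusters; the "unclassified" row counts clusters (no family names exist
    there).
    """
    rows = []
    for sf in list(SUPERFAMILIES) + [UNCLASSIFIED]:
        members = [cl for cl in clusters if cl.superfamily_name == sf]
        families = {cl.family_name for cl in members if cl.family_name}
        rows.append(
            {
                "superfamily": sf,
                "n_families": len(families),
                "n_clusters": len(members),
            }
        )
    return pd.DataFrame(rows, columns=["superfamily", "n_families", "n_clusters"])


def representatives_table(clusters: list[MITECluster]) -> dict[str, tuple[str, str | None, str]]:
    """cluster_id -> (sequence, family, superfamily), as the scan stage wants."""
    return {
        cl.cluster_id: (cl.representative, cl.family_name, cl.superfamily_name)
        for cl in clusters
    }
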