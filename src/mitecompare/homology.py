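"""Homology recovery of the full MITE population.

Canonical detection only surfaces structurally perfect elements; most real
copies are degraded.  This second pass scans every accession genome with the
annotated cluster representatives and keeps every sufficiently similar hit,
whether or not it retains TIR/TSD structure — structure only upgrades the
category label (canonical vs diverse vs partial).

The scan is a seeded, ungapped diagonal search: exact k-mer matches between
a representative and the genome nominate diagonals; along each diagonal the
best-scoring contiguous segment (match +1, mismatch penalised so that
segments below ``min_identity`` score negatively) becomes a hit.  This
matches the substitution-and-truncation decay model the synthetic generator
implements; copies decayed by indels would need a gapped extension (a known
limitation, see docs/methods.md).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from ._seq import best_diagonal_segment, encode, revcomp
from .detect import DetectionParams, TIRCandidate, validate_tsd, _GenomeIndex
from .models import GeneModel, GenomeAccession, GenomicInterval

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanParams:
    min_identity: float = 0.7
    min_hit_length: int = 50
    merge_gap: int = 10
    partial_coverage: float = 0.8
    seed_k: int = 11


@dataclass
class MITEHit:
    """One MITE copy found by homology in one accession."""

    interval: GenomicInterval
    accession_name: str
    cluster_id: str
    family_name: str | None
    superfamily_name: str
    percent_identity: float
    coverage_of_representative: float
    category: str = "unknown"

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass
class HomologGroup:
    """Positionally corresponding hits across accessions.

    ``anchor`` is the gene-context key the hits share: (gene_id, relation)
    for gene-associated hits, or the flanking-gene pair for intergenic ones.
    """

    cluster_id: str
    anchor: tuple
    hits: dict[str, list[MITEHit]] = field(default_factory=dict)

    def presence(self, accessions: list[str]) -> dict[str, bool]:
        return {a: a in self.hits for a in accessions}


def scan_genome(
    genome: GenomeAccession,
    representatives: dict[str, tuple[str, str | None, str]],
    params: ScanParams = ScanParams(),
) -> list[MITEHit]:
    """Scan one accession with every cluster representative.

    ``representatives`` maps cluster_id -> (sequence, family, superfamily).
    Hits below the identity/length thresholds are dropped; overlapping hits
    from the same cluster (gap <= merge_gap, same strand) are merged;
    overlapping hits from different clusters resolve to the higher identity.
    """
    index = _GenomeIndex(genome, params.seed_k)
    hits: list[MITEHit] = []
    for chrom in sorted(genome.chromosomes):
        codes = index.codes[chrom]
        n = len(codes)
        for cluster_id in sorted(representatives):
            rep_seq, family, superfamily = representatives[cluster_id]
            raw: list[MITEHit] = []
            for strand in ("+", "-"):
                q = rep_seq if strand == "+" else revcomp(rep_seq)
                qcodes = encode(q)
                lq = len(q)
                if lq > n:
                    continue
                diags = index.match_diagonals(chrom, qcodes)
                for d in sorted(diags):
                    gs = max(0, d)
                    ge = min(n, d + lq)
                    if ge - gs < params.min_hit_length:
                        continue
                    qs = gs - d
                    match = (codes[gs:ge] == qcodes[qs : qs + (ge - gs)]) & (
                        codes[gs:ge] != 4
                    )
                    penalty = params.min_identity / (1 - params.min_identity)
                    seg = best_diagonal_segment(match, penalty)
                    if seg is None:
                        continue
                    a, b, n_match = seg
                    seg_len = b - a
                    identity = n_match / seg_len
                    if seg_len < params.min_hit_length or identity < params.min_identity:
                        continue
                    raw.append(
                        MITEHit(
                            interval=GenomicInterval(
                                chrom, gs + a + 1, gs + b, strand
                            ),
                            accession_name=genome.accession_name,
                            cluster_id=cluster_id,
                            family_name=family,
                            superfamily_name=superfamily,
                            percent_identity=identity,
                            coverage_of_representative=seg_len / len(rep_seq),
                        )
                    )
            hits += _merge_same_cluster(raw, len(rep_seq), params)
    return _resolve_cross_cluster(hits)


def _merge_same_cluster(
    raw: list[MITEHit], rep_len: int, params: ScanParams
) -> list[MITEHit]:
    """Merge same-cluster hits with gap <= merge_gap on the same strand."""
    out: list[MITEHit] = []
    for strand in ("+", "-"):
        group = sorted(
            (h for h in raw if h.strand == strand),
            key=lambda h: (h.interval.start, h.interval.end),
        )
        merged: list[MITEHit] = []
        for h in group:
            if merged and h.interval.start <= merged[-1].interval.end + 1 + params.merge_gap:
                prev = merged[-1]
                span = GenomicInterval(
                    prev.interval.chromosome,
                    prev.interval.start,
                    max(prev.interval.end, h.interval.end),
                    strand,
                )
                # weighted identity over the merged span, coverage re-derived
                n_prev = prev.percent_identity * prev.interval.length
                n_new = h.percent_identity * h.interval.length
                merged[-1] = replace(
                    prev,
                    interval=span,
                    percent_identity=min(
                        1.0, (n_prev + n_new) / (prev.interval.length + h.interval.length)
                    ),
                    coverage_of_representative=min(1.0, span.length / rep_len),
                )
            else:
                merged.append(h)
        out += merged
    return out


def _resolve_cross_cluster(hits: list[MITEHit]) -> list[MITEHit]:
    """Overlapping hits from different clusters keep the higher identity."""
    chosen: list[MITEHit] = []
    ordered = sorted(
        hits,
        key=lambda h: (
            -h.percent_identity,
            -h.interval.length,
            h.cluster_id,
            h.interval.chromosome,
            h.interval.start,
        ),
    )
    for h in ordered:
        clash = any(
            h.interval.overlaps(c.interval) and c.cluster_id != h.cluster_id
            for c in chosen
        )
        if not clash:
            chosen.append(h)
    chosen.sort(
        key=lambda h: (h.interval.chromosome, h.interval.start, h.cluster_id)
    )
    return chosen


def categorize_hit(
    hit: MITEHit,
    genome: GenomeAccession,
    detection_params: DetectionParams = DetectionParams(),
    scan_params: ScanParams = ScanParams(),
) -> str:
    """Assign canonical / diverse / partial from structure and coverage.

    canonical: the structural validator (perfect TSD + qualifying TIR +
    length bounds) passes at the hit locus; partial: representative coverage
    below the partial threshold; diverse: everything else.
    """
    if _structurally_canonical(hit, genome, detection_params):
        return "canonical"
    if hit.coverage_of_representative < scan_params.partial_coverage:
        return "partial"
    return "diverse"


def _structurally_canonical(
    hit: MITEHit, genome: GenomeAccession, params: DetectionParams
) -> bool:
    seq = genome.chromosomes[hit.interval.chromosome]
    L = hit.interval.length
    if not params.min_length <= L <= params.max_length:
        return False
    s0 = hit.interval.start - 1
    e0 = hit.interval.end
    elem = seq[s0:e0]
    # maximal qualifying TIR at this exact locus
    best_t = 0
    mm_cum = 0
    suffix_rc = revcomp(elem[max(0, L - params.max_tir):])
    for t in range(1, min(params.max_tir, L // 2) + 1):
        if elem[t - 1] != suffix_rc[t - 1]:
            mm_cum += 1
        if t >= params.min_tir and mm_cum <= params.max_tir_mismatch_fraction * t + 1e-9:
            best_t = t
    if best_t < params.min_tir:
        return False
    cand = TIRCandidate(hit.interval.start, hit.interval.end, best_t, 0)
    return validate_tsd(seq, cand, params) is not None


def categorize_hits(
    hits: list[MITEHit],
    genome: GenomeAccession,
    detection_params: DetectionParams = DetectionParams(),
    scan_params: ScanParams = ScanParams(),
) -> list[MITEHit]:
    for h in hits:
        h.category = categorize_hit(h, genome, detection_params, scan_params)
    return hits


def hits_to_frame(hits: list[MITEHit]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "accession": h.accession_name,
                "chromosome": h.interval.chromosome,
                "start": h.interval.start,
                "end": h.interval.end,
                "strand": h.strand,
                "cluster_id": h.cluster_id,
                "family": h.family_name or "",
                "superfamily": h.superfamily_name,
                "identity": round(h.percent_identity, 6),
                "coverage": round(h.coverage_of_representative, 6),
                "category": h.category,
            }
            for h in hits
        ],
        columns=[
            "accession", "chromosome", "start", "end", "strand", "cluster_id",
            "family", "superfamily", "identity", "coverage", "category",
        ],
    )


def hits_from_frame(frame) -> list[MITEHit]:
    import pandas as pd

    return [
        MITEHit(
            interval=GenomicInterval(r.chromosome, int(r.start), int(r.end), r.strand),
            accession_name=r.accession,
            cluster_id=r.cluster_id,
            family_name=(None if pd.isna(r.family) or r.family == "" else r.family),
            superfamily_name=r.superfamily,
            percent_identity=float(r.identity),
            coverage_of_representative=float(r.coverage),
            category=r.category,
        )
        for r in frame.itertuples()
    ]


def build_homolog_groups(
    hits_by_accession: dict[str, list[MITEHit]],
    genes_by_accession: dict[str, list[GeneModel]],
    max_distance: int = 40,
) -> list[HomologGroup]:
    """Group positionally corresponding hits across accessions.

    Hits from different accessions are grouped when they share a cluster and
    the same anchor-gene context: (gene_id, relation kind) when a gene lies
    within ``max_distance``, else the reciprocal flanking-gene pair.  Genes
    are used as positional markers because accession assemblies share gene
    IDs but not coordinates.
    """
    from .interactions import InteractionParams, associate

    groups: dict[tuple[str, tuple], HomologGroup] = {}
    iparams = InteractionParams(max_distance=max_distance)
    for accession in sorted(hits_by_accession):
        hits = hits_by_accession[accession]
        genes = genes_by_accession[accession]
        records = associate(hits, genes, iparams)
        anchored: dict[int, tuple] = {}
        for rec in records:
            key = (rec.gene_id, rec.relation.split(":")[0])
            anchored.setdefault(id(rec.hit), key)
        gene_order = sorted(genes, key=lambda g: (g.locus.chromosome, g.locus.start))
        for h in hits:
            anchor = anchored.get(id(h))
            if anchor is None:
                left = right = None
                for g in gene_order:
                    if g.locus.chromosome != h.interval.chromosome:
                        continue
                    if g.locus.end < h.interval.start:
                        left = g.gene_id
                    elif g.locus.start > h.interval.end and right is None:
                        right = g.gene_id
                anchor = ("intergenic", left, right)
            key = (h.cluster_id, anchor)
            grp = groups.setdefault(
                key, HomologGroup(cluster_id=h.cluster_id, anchor=anchor)
            )
            grp.hits.setdefault(accession, []).append(h)
    return sorted(groups.values(), key=lambda g: (g.cluster_id, str(g.anchor)))
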