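"""De novo structural detection of canonical MITEs in a single genome.

A canonical MITE is a 50-800 bp element whose 5' prefix matches the reverse
complement of its 3' suffix (terminal inverted repeat, TIR, 10-56 bp with at
most 10% mismatches and no indels), flanked by a perfect 2-10 bp target site
duplication (TSD), with at least ``min_copies`` near-identical full-length
copies elsewhere in the genome whose flanking sequences are distinct (so
tandem or segmental duplications do not count as transposition evidence).

Candidate enumeration seeds TIR pairs with exact complementary k-mer pairs
and verifies each candidate exhaustively over all TIR lengths.  The two-tier
seed (5-mers expanded at TIR offsets 0..5, 10-mers at offsets 0..46) is
lossless for the mismatch model above: any TIR of length t with at most
floor(0.1*t) mismatches contains either an exact complementary 5-run within
its first ten positions or an exact complementary 10-run somewhere (a
pigeonhole argument, spelled out in docs/methods.md), so seeded enumeration
returns exactly the candidates an exhaustive scan over all (start, end, tir)
triples would.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import edlib
import numpy as np

from ._seq import encode, kmer_codes, revcomp
from .models import GenomeAccession, GenomicInterval

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionParams:
    """Structural and copy-number thresholds for canonical MITE detection."""

    min_length: int = 50
    max_length: int = 800
    min_tir: int = 10
    max_tir: int = 56
    min_tsd: int = 2
    max_tsd: int = 10
    max_tir_mismatch_fraction: float = 0.1
    min_copies: int = 3
    flank_window: int = 60
    flank_max_identity: float = 0.6
    min_copy_identity: float = 0.9
    min_copy_coverage: float = 0.95
    copy_seed_k: int = 11

    def __post_init__(self) -> None:
        if not (0 < self.min_length <= self.max_length):
            raise ValueError("invalid length bounds")
        if not (0 < self.min_tir <= self.max_tir):
            raise ValueError("invalid TIR bounds")
        if not (0 < self.min_tsd <= self.max_tsd):
            raise ValueError("invalid TSD bounds")
        if not 0 <= self.max_tir_mismatch_fraction <= 1:
            raise ValueError("mismatch fraction outside [0,1]")
        if not 0 <= self.flank_max_identity <= 1:
            raise ValueError("flank identity outside [0,1]")


@dataclass(frozen=True)
class TIRCandidate:
    """A TIR-bounded candidate element (coordinates 1-based inclusive)."""

    start: int
    end: int
    tir_length: int
    tir_mismatches: int


@dataclass
class CanonicalMITE:
    """A structurally validated MITE locus (TSDs excluded from the interval)."""

    interval: GenomicInterval
    sequence: str
    tir_length: int
    tir_mismatches: int
    tsd_sequence: str
    copy_count: int
    accession_name: str

    @property
    def tsd_length(self) -> int:
        return len(self.tsd_sequence)


def _complementary_kmer_pairs(
    codes: np.ndarray, k: int, min_span: int, max_span: int
) -> tuple[np.ndarray, np.ndarray]:
    """All (p, q) with seq[p:p+k] == revcomp(seq[q:q+k]) and q-p in span range."""
    n = len(codes)
    empty = np.empty(0, dtype=np.int64)
    if n < k or max_span < min_span:
        return empty, empty
    c = codes.astype(np.int64)
    fwd = np.zeros(n - k + 1, dtype=np.int64)
    rc = np.zeros(n - k + 1, dtype=np.int64)
    bad = np.zeros(n - k + 1, dtype=bool)
    for i in range(k):
        w = c[i : n - k + 1 + i]
        fwd = fwd * 4 + np.where(w == 4, 0, w)
        # revcomp code accumulates complements with reversed significance
        rc = rc + np.where(w == 4, 0, 3 - w) * (4**i)
        bad |= w == 4
    fwd[bad] = -1
    rc[bad] = -2  # never equal to a valid fwd code
    ps: list[np.ndarray] = []
    qs: list[np.ndarray] = []
    m = len(fwd)
    for delta in range(max(min_span, 0), max_span + 1):
        if delta >= m:
            break
        hit = np.flatnonzero(fwd[: m - delta] == rc[delta:])
        if len(hit):
            ps.append(hit)
            qs.append(hit + delta)
    if not ps:
        return empty, empty
    return np.concatenate(ps), np.concatenate(qs)


def enumerate_tir_candidates(
    sequence: str, params: DetectionParams = DetectionParams()
) -> list[TIRCandidate]:
    """Enumerate TIR-bounded candidate elements in one chromosome sequence.

    Returns, for every (start, end) locus that admits a qualifying TIR, one
    candidate carrying the maximal qualifying TIR length and its mismatch
    count, sorted by position.  Elements overlapping N runs are discarded.
    """
    codes = encode(sequence.upper())
    n = len(codes)
    if n < params.min_length:
        return []

    # --- seed expansion into candidate (start, end) pairs (0-based half-open)
    cand_s: list[np.ndarray] = []
    cand_e: list[np.ndarray] = []
    p5, q5 = _complementary_kmer_pairs(
        codes, 5, params.min_length - 5 - 10, params.max_length - 5
    )
    for j in range(6):
        cand_s.append(p5 - j)
        cand_e.append(q5 + 5 + j)
    p10, q10 = _complementary_kmer_pairs(
        codes, 10, 0, params.max_length - 10
    )
    for j in range(params.max_tir - 10 + 1):
        cand_s.append(p10 - j)
        cand_e.append(q10 + 10 + j)
    S = np.concatenate(cand_s)
    E = np.concatenate(cand_e)
    L = E - S
    keep = (
        (S >= 0)
        & (E <= n)
        & (L >= params.min_length)
        & (L <= params.max_length)
    )
    S, E = S[keep], E[keep]
    if len(S) == 0:
        return []
    uniq = np.unique(S * np.int64(n + 1) + E)
    S = uniq // (n + 1)
    E = uniq % (n + 1)

    # --- discard candidates overlapping N runs
    n_prefix = np.concatenate(([0], np.cumsum(codes == 4)))
    keep = (n_prefix[E] - n_prefix[S]) == 0
    S, E = S[keep], E[keep]
    if len(S) == 0:
        return []

    frac = params.max_tir_mismatch_fraction
    c64 = codes.astype(np.int64)

    # --- maximal-TIR verification with progressive pruning: a candidate is
    # abandoned once its running mismatch count exceeds the largest budget
    # any admissible TIR length could grant it
    n_cand = len(S)
    t_cap = np.minimum((E - S) // 2, params.max_tir)
    max_budget = np.floor(frac * t_cap + 1e-9).astype(np.int64)
    best_t = np.zeros(n_cand, dtype=np.int64)
    best_mm = np.zeros(n_cand, dtype=np.int64)
    mism = np.zeros(n_cand, dtype=np.int64)
    alive = np.arange(n_cand)
    for t in range(1, params.max_tir + 1):
        if len(alive) == 0:
            break
        i = t - 1
        mism[alive] += (c64[S[alive] + i] + c64[E[alive] - 1 - i]) != 3
        if t >= params.min_tir:
            ok = mism[alive] <= np.floor(frac * t + 1e-9)
            sel = alive[ok]
            best_t[sel] = t
            best_mm[sel] = mism[sel]
        keep = (mism[alive] <= max_budget[alive]) & (t_cap[alive] > t)
        alive = alive[keep]
    qual = np.flatnonzero(best_t >= params.min_tir)
    if len(qual) == 0:
        return []
    S, E, best_t, best_mm = S[qual], E[qual], best_t[qual], best_mm[qual]

    order = np.lexsort((E, S))
    return [
        TIRCandidate(
            start=int(S[i]) + 1,
            end=int(E[i]),
            tir_length=int(best_t[i]),
            tir_mismatches=int(best_mm[i]),
        )
        for i in order
    ]


def validate_tsd(
    sequence: str, candidate: TIRCandidate, params: DetectionParams = DetectionParams()
) -> str | None:
    """Return the longest perfect TSD flanking a candidate, or None.

    The TSD is the longest k in [min_tsd, max_tsd] such that the k bases
    immediately left of the element exactly equal the k bases immediately
    right of it.  Candidates too close to a chromosome edge for a given k
    simply cannot qualify at that k.
    """
    s0 = candidate.start - 1
    e0 = candidate.end
    n = len(sequence)
    for k in range(params.max_tsd, params.min_tsd - 1, -1):
        if s0 - k < 0 or e0 + k > n:
            continue
        left = sequence[s0 - k : s0]
        right = sequence[e0 : e0 + k]
        if left == right and "N" not in left:
            return left
    logger.debug("no TSD for candidate %s-%s", candidate.start, candidate.end)
    return None


def _flank_identity(a: str, b: str) -> float:
    """Alignment identity between two flank sequences (edit-distance based)."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


class _GenomeIndex:
    """Per-chromosome sorted k-mer indexes, built lazily and cached."""

    def __init__(self, genome: GenomeAccession, k: int):
        self.k = k
        self.codes = {name: encode(seq) for name, seq in genome.chromosomes.items()}
        self._idx: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def index(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(sorted k-mer codes, position order) for one chromosome."""
        if chrom not in self._idx:
            kc = kmer_codes(self.codes[chrom], self.k)
            order = np.argsort(kc, kind="stable").astype(np.int64)
            self._idx[chrom] = (kc[order], order)
        return self._idx[chrom]

    def match_diagonals(self, chrom: str, query_codes: np.ndarray) -> set[int]:
        """Diagonals (genome_pos - query_offset) of exact k-mer matches."""
        sorted_codes, order = self.index(chrom)
        qk = kmer_codes(query_codes, self.k)
        valid = np.flatnonzero(qk >= 0)
        lo = np.searchsorted(sorted_codes, qk[valid])
        hi = np.searchsorted(sorted_codes, qk[valid], side="right")
        diags: set[int] = set()
        for off, l, h in zip(valid, lo, hi):
            if h > l:
                for pos in order[l:h]:
                    diags.add(int(pos) - int(off))
        return diags


def _batch_occurrences(
    index: _GenomeIndex, queries: list[str], min_identity: float
) -> list[list[tuple[str, int, str, float]]]:
    """Full-length near-identical occurrences of each query on both strands.

    Candidate loci are seeded by exact k-mer matches (batched across all
    queries per chromosome); each candidate window (ungapped, full query
    length) is scored by per-base identity.  Per query, returns
    (chromosome, start0, strand, identity) tuples with overlapping
    qualifying windows collapsed to the best one (identity, then + strand,
    then leftmost).
    """
    if not queries:
        return []
    qcodes_by_strand = [
        (encode(q), encode(revcomp(q))) for q in queries
    ]
    code_chunks = []
    meta_q = []
    meta_s = []
    meta_off = []
    for qi, (qf, qr) in enumerate(qcodes_by_strand):
        for si, qc in enumerate((qf, qr)):
            kc = kmer_codes(qc, index.k)
            code_chunks.append(kc)
            meta_q.append(np.full(len(kc), qi, dtype=np.int64))
            meta_s.append(np.full(len(kc), si, dtype=np.int64))
            meta_off.append(np.arange(len(kc), dtype=np.int64))
    all_codes = np.concatenate(code_chunks)
    q_idx = np.concatenate(meta_q)
    s_idx = np.concatenate(meta_s)
    offs = np.concatenate(meta_off)
    valid = all_codes >= 0
    all_codes, q_idx, s_idx, offs = (
        all_codes[valid], q_idx[valid], s_idx[valid], offs[valid],
    )
    q_order = np.argsort(all_codes, kind="stable")
    q_sorted = all_codes[q_order]

    results: list[list[tuple[str, int, str, float]]] = [[] for _ in queries]
    for chrom in sorted(index.codes):
        codes = index.codes[chrom]
        n = len(codes)
        sorted_codes, order = index.index(chrom)
        # join from the genome side: each genome k-mer looks up its equal
        # range among the (sorted) query k-mers
        lo = np.searchsorted(q_sorted, sorted_codes)
        hi = np.searchsorted(q_sorted, sorted_codes, side="right")
        counts = hi - lo
        nz = np.flatnonzero(counts)
        if len(nz) == 0:
            continue
        c_nz = counts[nz]
        total = int(c_nz.sum())
        within = np.arange(total) - np.repeat(np.cumsum(c_nz) - c_nz, c_nz)
        qrows = q_order[np.repeat(lo[nz], c_nz) + within]
        gpos = np.repeat(order[nz], c_nz)
        diag = gpos - offs[qrows]
        # one scalar key per (query, strand, diagonal)
        span = 2 * n + 1
        key = (q_idx[qrows] * 2 + s_idx[qrows]) * span + (diag + n)
        uniq = np.unique(key)
        u_qs, u_diag = np.divmod(uniq, span)
        u_diag -= n
        u_q, u_s = np.divmod(u_qs, 2)
        group_vals, group_starts = np.unique(u_q, return_index=True)
        bounds = np.append(group_starts, len(uniq))
        for gi, qi in enumerate(group_vals):
            lq = len(queries[qi])
            if n < lq:
                continue
            windows: list[tuple[int, str, float]] = []
            sl = slice(bounds[gi], bounds[gi + 1])
            sub_s = u_s[sl]
            sub_d = u_diag[sl]
            for si, strand in ((0, "+"), (1, "-")):
                starts = sub_d[sub_s == si]
                starts = starts[(starts >= 0) & (starts <= n - lq)]
                if len(starts) == 0:
                    continue
                qc = qcodes_by_strand[qi][si]
                win = codes[starts[:, None] + np.arange(lq)[None, :]]
                ident = np.mean(win == qc[None, :], axis=1)
                for d, i in zip(starts, ident):
                    if i >= min_identity:
                        windows.append((int(d), strand, float(i)))
            windows.sort(key=lambda w: w[0])
            merged: list[tuple[int, str, float]] = []
            for w in windows:
                if merged and w[0] < merged[-1][0] + lq:
                    best = merged[-1]
                    if (w[2], w[1] == "+", -w[0]) > (
                        best[2], best[1] == "+", -best[0]
                    ):
                        merged[-1] = w
                else:
                    merged.append(w)
            results[qi] += [(chrom, d, strand, i) for d, strand, i in merged]
    return results


def _occurrence_windows(
    index: _GenomeIndex, query: str, min_identity: float
) -> list[tuple[str, int, str, float]]:
    return _batch_occurrences(index, [query], min_identity)[0]


def count_full_length_copies(
    genome: GenomeAccession,
    candidate_sequence: str,
    params: DetectionParams = DetectionParams(),
    index: _GenomeIndex | None = None,
) -> int:
    """Count full-length copies of a candidate with distinctive flanks.

    Near-identical full-length occurrences (>= ``min_copy_identity`` over the
    full candidate length, both strands) are enumerated; an occurrence whose
    ``flank_window`` flanks both align at > ``flank_max_identity`` to a
    previously counted occurrence's flanks is collapsed, so tandem and
    segmental duplicates contribute a single copy.
    """
    if index is None:
        index = _GenomeIndex(genome, params.copy_seed_k)
    occs = _occurrence_windows(index, candidate_sequence, params.min_copy_identity)
    return _count_distinct_flank_occurrences(
        genome, len(candidate_sequence), occs, params
    )


def _count_distinct_flank_occurrences(
    genome: GenomeAccession,
    query_length: int,
    occurrences: list[tuple[str, int, str, float]],
    params: DetectionParams,
) -> int:
    occs = sorted(occurrences, key=lambda o: (o[0], o[1]))
    w = params.flank_window
    counted_flanks: list[tuple[str, str]] = []
    count = 0
    for chrom, start0, _strand, _ident in occs:
        seq = genome.chromosomes[chrom]
        left = seq[max(0, start0 - w) : start0]
        right = seq[start0 + query_length : start0 + query_length + w]
        dup = any(
            _flank_identity(left, fl) > params.flank_max_identity
            and _flank_identity(right, fr) > params.flank_max_identity
            for fl, fr in counted_flanks
        )
        if dup:
            continue
        counted_flanks.append((left, right))
        count += 1
    return count


def resolve_overlaps(mites: list[CanonicalMITE]) -> list[CanonicalMITE]:
    """Among overlapping elements keep the best-supported one.

    Preference order: longest TSD, then longest element, then leftmost
    start.  TSD length ranks first because the element/TSD boundary is
    ambiguous under the structural definition: an element with a k-bp TSD
    expanded by one base on each side always exhibits a valid (k-2)-bp TSD
    (both expanded flanks are interior bases of the same duplication) and a
    TIR still within the mismatch budget, so ranking by element length
    alone would systematically report boundary-inflated loci that absorb
    TSD bases into the element.
    """
    chosen: list[CanonicalMITE] = []
    ordered = sorted(
        mites,
        key=lambda m: (-m.tsd_length, -m.interval.length, m.interval.chromosome,
                       m.interval.start, m.interval.end),
    )
    for m in ordered:
        if not any(m.interval.overlaps(c.interval) for c in chosen):
            chosen.append(m)
    chosen.sort(key=lambda m: (m.interval.chromosome, m.interval.start))
    return chosen


def detect_canonical_mites(
    genome: GenomeAccession, params: DetectionParams = DetectionParams()
) -> list[CanonicalMITE]:
    """Full structural detection for one accession.

    Composition of TIR candidate enumeration, TSD validation, the
    copy-number filter, and overlap resolution; output is deterministic,
    sorted by (chromosome, start).
    """
    index = _GenomeIndex(genome, params.copy_seed_k)
    validated: list[tuple[str, TIRCandidate, str, str]] = []
    for chrom in sorted(genome.chromosomes):
        seq = genome.chromosomes[chrom]
        for cand in enumerate_tir_candidates(seq, params):
            tsd = validate_tsd(seq, cand, params)
            if tsd is None:
                continue
            validated.append((chrom, cand, tsd, seq[cand.start - 1 : cand.end]))
    occ_lists = _batch_occurrences(
        index, [elem for _, _, _, elem in validated], params.min_copy_identity
    )
    survivors: list[CanonicalMITE] = []
    for (chrom, cand, tsd, elem), occs in zip(validated, occ_lists):
        copies = _count_distinct_flank_occurrences(genome, len(elem), occs, params)
        if copies < params.min_copies:
            continue
        survivors.append(
            CanonicalMITE(
                interval=GenomicInterval(chrom, cand.start, cand.end, "+"),
                sequence=elem,
                tir_length=cand.tir_length,
                tir_mismatches=cand.tir_mismatches,
                tsd_sequence=tsd,
                copy_count=copies,
                accession_name=genome.accession_name,
            )
        )
    logger.info(
        "%s: %d canonical MITEs", genome.accession_name, len(survivors)
    )
    return resolve_overlaps(survivors)


def mites_to_frame(mites: list[CanonicalMITE]):
    """Canonical MITE records as a DataFrame (TSDs in their own column)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "accession": m.accession_name,
                "chromosome": m.interval.chromosome,
                "start": m.interval.start,
                "end": m.interval.end,
                "tir_length": m.tir_length,
                "tir_mismatches": m.tir_mismatches,
                "tsd_sequence": m.tsd_sequence,
                "tsd_length": m.tsd_length,
                "copy_count": m.copy_count,
                "sequence": m.sequence,
            }
            for m in mites
        ],
        columns=[
            "accession", "chromosome", "start", "end", "tir_length",
            "tir_mismatches", "tsd_sequence", "tsd_length", "copy_count",
            "sequence",
        ],
    )


def mites_from_frame(frame) -> list[CanonicalMITE]:
    return [
        CanonicalMITE(
            interval=GenomicInterval(r.chromosome, int(r.start), int(r.end), "+"),
            sequence=r.sequence,
            tir_length=int(r.tir_length),
            tir_mismatches=int(r.tir_mismatches),
            tsd_sequence=r.tsd_sequence,
            copy_count=int(r.copy_count),
            accession_name=r.accession,
        )
        for r in frame.itertuples()
    ]


def revalidate(mite: CanonicalMITE, genome: GenomeAccession,
               params: DetectionParams = DetectionParams()) -> bool:
    """Recompute the structural predicates of an emitted record from FASTA."""
    seq = genome.chromosomes[mite.interval.chromosome]
    s0, e0 = mite.interval.start - 1, mite.interval.end
    elem = seq[s0:e0]
    if elem != mite.sequence:
        return False
    L = len(elem)
    if not params.min_length <= L <= params.max_length:
        return False
    t = mite.tir_length
    if not params.min_tir <= t <= min(params.max_tir, L // 2):
        return False
    mm = sum(
        1 for i in range(t) if revcomp(elem[L - t :])[i] != elem[i]
    )
    if mm > params.max_tir_mismatch_fraction * t + 1e-9:
        return False
    k = len(mite.tsd_sequence)
    if not params.min_tsd <= k <= params.max_tsd:
        return False
    return (
        seq[s0 - k : s0] == mite.tsd_sequence == seq[e0 : e0 + k]
        and s0 - k >= 0
        and e0 + k <= len(seq)
    )
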