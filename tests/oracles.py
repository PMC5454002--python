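"""Independent brute-force reference implementations.

These share the structural *definitions* with the pipeline (what a
canonical MITE is) but none of its search machinery: candidate TIRs are
found by exhaustive scanning over every (start, end) pair, copy occurrences
by sliding a window over every genome position.  Only practical on small
genomes; used to certify the seeded implementations.
"""

from __future__ import annotations

import edlib
import numpy as np

from mitecompare._seq import encode, revcomp
from mitecompare.detect import CanonicalMITE, DetectionParams, TIRCandidate
from mitecompare.models import GenomeAccession, GenomicInterval


def brute_force_tir_candidates(
    sequence: str, params: DetectionParams = DetectionParams()
) -> list[TIRCandidate]:
    """Exhaustive scan over all (start, end, tir) triples."""
    codes = encode(sequence).astype(np.int64)
    n = len(codes)
    out = []
    n_cum = np.concatenate(([0], np.cumsum(codes == 4)))
    for L in range(params.min_length, min(params.max_length, n) + 1):
        starts = np.arange(0, n - L + 1)
        if len(starts) == 0:
            continue
        has_n = (n_cum[starts + L] - n_cum[starts]) > 0
        t_cap = min(params.max_tir, L // 2)
        mism = np.zeros(len(starts), dtype=np.int64)
        best_t = np.zeros(len(starts), dtype=np.int64)
        best_mm = np.zeros(len(starts), dtype=np.int64)
        for t in range(1, t_cap + 1):
            i = t - 1
            mism += (codes[starts + i] + codes[starts + L - 1 - i]) != 3
            if t >= params.min_tir:
                ok = mism <= np.floor(params.max_tir_mismatch_fraction * t + 1e-9)
                best_t[ok] = t
                best_mm[ok] = mism[ok]
        for idx in np.flatnonzero((best_t >= params.min_tir) & ~has_n):
            out.append(
                TIRCandidate(
                    start=int(starts[idx]) + 1,
                    end=int(starts[idx]) + L,
                    tir_length=int(best_t[idx]),
                    tir_mismatches=int(best_mm[idx]),
                )
            )
    out.sort(key=lambda c: (c.start, c.end))
    return out


def brute_force_tsd(
    sequence: str, candidate: TIRCandidate, params: DetectionParams = DetectionParams()
) -> str | None:
    s0 = candidate.start - 1
    e0 = candidate.end
    for k in range(params.max_tsd, params.min_tsd - 1, -1):
        if s0 - k < 0 or e0 + k > len(sequence):
            continue
        left = sequence[s0 - k : s0]
        if left == sequence[e0 : e0 + k] and "N" not in left:
            return left
    return None


def brute_force_occurrences(
    genome: GenomeAccession, query: str, min_identity: float
) -> list[tuple[str, int, str, float]]:
    """Sliding-window full-length occurrence scan over every position."""
    lq = len(query)
    q = encode(query)
    qr = encode(revcomp(query))
    out = []
    for chrom in genome.chromosomes:
        codes = encode(genome.chromosomes[chrom])
        n = len(codes)
        if n < lq:
            continue
        win = np.lib.stride_tricks.sliding_window_view(codes, lq)
        ident_f = np.mean((win == q) & (win != 4), axis=1)
        ident_r = np.mean((win == qr) & (win != 4), axis=1)
        windows = []
        for s in np.flatnonzero(ident_f >= min_identity):
            windows.append((int(s), "+", float(ident_f[s])))
        for s in np.flatnonzero(ident_r >= min_identity):
            windows.append((int(s), "-", float(ident_r[s])))
        windows.sort(key=lambda w: w[0])
        merged: list[tuple[int, str, float]] = []
        for w in windows:
            if merged and w[0] < merged[-1][0] + lq:
                best = merged[-1]
                if (w[2], w[1] == "+", -w[0]) > (best[2], best[1] == "+", -best[0]):
                    merged[-1] = w
            else:
                merged.append(w)
        out += [(chrom, s, st, i) for s, st, i in merged]
    return out


def brute_force_copy_count(
    genome: GenomeAccession, query: str, params: DetectionParams = DetectionParams()
) -> int:
    occs = brute_force_occurrences(genome, query, params.min_copy_identity)
    occs.sort(key=lambda o: (o[0], o[1]))
    lq = len(query)
    w = params.flank_window

    def flank_identity(a: str, b: str) -> float:
        if not a or not b:
            return 0.0
        d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
        return 1.0 - d / max(len(a), len(b))

    counted = []
    count = 0
    for chrom, s, _strand, _ident in occs:
        seq = genome.chromosomes[chrom]
        left = seq[max(0, s - w) : s]
        right = seq[s + lq : s + lq + w]
        if any(
            flank_identity(left, fl) > params.flank_max_identity
            and flank_identity(right, fr) > params.flank_max_identity
            for fl, fr in counted
        ):
            continue
        counted.append((left, right))
        count += 1
    return count


def brute_force_detect(
    genome: GenomeAccession, params: DetectionParams = DetectionParams()
) -> list[CanonicalMITE]:
    """Exhaustive composition: triple scan + TSD check + naive copy count,
    with the same overlap-resolution definition as the pipeline (longest
    TSD, then longest element, then leftmost)."""
    survivors = []
    for chrom in sorted(genome.chromosomes):
        seq = genome.chromosomes[chrom]
        for cand in brute_force_tir_candidates(seq, params):
            tsd = brute_force_tsd(seq, cand, params)
            if tsd is None:
                continue
            elem = seq[cand.start - 1 : cand.end]
            copies = brute_force_copy_count(genome, elem, params)
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
    chosen: list[CanonicalMITE] = []
    for m in sorted(
        survivors,
        key=lambda m: (-m.tsd_length, -m.interval.length, m.interval.chromosome,
                       m.interval.start, m.interval.end),
    ):
        if not any(m.interval.overlaps(c.interval) for c in chosen):
            chosen.append(m)
    chosen.sort(key=lambda m: (m.interval.chromosome, m.interval.start))
    return chosen


def enumerate_mann_whitney(a, b):
    """Exact two-sided Mann-Whitney p by complete enumeration (handles ties)."""
    import itertools

    from scipy.stats import rankdata

    a = list(a)
    b = list(b)
    combined = np.array(a + b, dtype=float)
    ranks = rankdata(combined)
    n_a = len(a)
    n = len(combined)
    prod = n_a * (n - n_a)
    r_obs = ranks[:n_a].sum()
    u_obs = r_obs - n_a * (n_a + 1) / 2
    u_obs_min = min(u_obs, prod - u_obs)
    extreme = total = 0
    for idx in itertools.combinations(range(n), n_a):
        u = ranks[list(idx)].sum() - n_a * (n_a + 1) / 2
        if min(u, prod - u) <= u_obs_min + 1e-9:
            extreme += 1
        total += 1
    return extreme / total
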