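"""Summary artifacts: per-accession count tables, sequence characterization
and chromosome distribution profiles.

Every table here is a pure function of hit/canonical records, so re-running
a summary on exported TSVs reproduces it exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cluster import SUPERFAMILIES, UNCLASSIFIED
from .detect import CanonicalMITE
from .homology import MITEHit


def summarize_counts(hits: list[MITEHit]) -> pd.DataFrame:
    """Per-accession hit counts by chromosome and by superfamily.

    One row per accession: chromosome columns, one column per superfamily
    present, and an unclassified column.  Chromosome counts and
    superfamily+unclassified counts both sum to the accession total.
    """
    chroms = sorted({h.interval.chromosome for h in hits})
    superfamilies = [
        sf for sf in SUPERFAMILIES if any(h.superfamily_name == sf for h in hits)
    ]
    accessions = sorted({h.accession_name for h in hits})
    rows = []
    for acc in accessions:
        acc_hits = [h for h in hits if h.accession_name == acc]
        row: dict[str, object] = {"accession": acc}
        for c in chroms:
            row[c] = sum(1 for h in acc_hits if h.interval.chromosome == c)
        for sf in superfamilies:
            row[sf] = sum(1 for h in acc_hits if h.superfamily_name == sf)
        row[UNCLASSIFIED] = sum(
            1 for h in acc_hits if h.superfamily_name == UNCLASSIFIED
        )
        row["total"] = len(acc_hits)
        rows.append(row)
    cols = ["accession"] + chroms + superfamilies + [UNCLASSIFIED, "total"]
    return pd.DataFrame(rows, columns=cols)


def gc_fraction(sequence: str) -> float:
    if not sequence:
        return float("nan")
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


def characterize_sequences(
    mites: list[CanonicalMITE],
    superfamily_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Length / TIR / TSD / GC summary statistics of canonical MITEs.

    Returns one "all" row plus, when ``superfamily_of`` maps an accession-
    qualified locus key ("accession:chrom:start") to a superfamily, one row
    per superfamily.
    """
    if not mites:
        raise ValueError("no canonical MITEs to characterize")

    def key(m: CanonicalMITE) -> str:
        return f"{m.accession_name}:{m.interval.chromosome}:{m.interval.start}"

    def stats_row(label: str, subset: list[CanonicalMITE]) -> dict:
        lengths = np.array([m.interval.length for m in subset])
        tirs = np.array([m.tir_length for m in subset])
        tsds = np.array([m.tsd_length for m in subset])
        gcs = np.array([gc_fraction(m.sequence) for m in subset])
        return {
            "group": label,
            "n": len(subset),
            "length_min": int(lengths.min()),
            "length_max": int(lengths.max()),
            "length_mean": float(lengths.mean()),
            "tir_min": int(tirs.min()),
            "tir_max": int(tirs.max()),
            "tir_mean": float(tirs.mean()),
            "tsd_min": int(tsds.min()),
            "tsd_max": int(tsds.max()),
            "tsd_mean": float(tsds.mean()),
            "gc_mean": float(gcs.mean()),
        }

    rows = [stats_row("all", mites)]
    if superfamily_of:
        for sf in sorted(set(superfamily_of.values())):
            subset = [m for m in mites if superfamily_of.get(key(m)) == sf]
            if subset:
                rows.append(stats_row(sf, subset))
    return pd.DataFrame(rows)


def per_record_gc(mites: list[CanonicalMITE]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "accession": [m.accession_name for m in mites],
            "chromosome": [m.interval.chromosome for m in mites],
            "start": [m.interval.start for m in mites],
            "end": [m.interval.end for m in mites],
            "gc": [gc_fraction(m.sequence) for m in mites],
        }
    )


def distribution_profile(hits: list[MITEHit], bin_size: int = 100_000) -> pd.DataFrame:
    """Binned hit counts per superfamily along each chromosome.

    Long format suitable for plotting: accession, chromosome, bin_start
    (1-based), superfamily, count.  Bins are indexed by hit start position.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows: dict[tuple, int] = {}
    for h in hits:
        b = ((h.interval.start - 1) // bin_size) * bin_size + 1
        key = (h.accession_name, h.interval.chromosome, b, h.superfamily_name)
        rows[key] = rows.get(key, 0) + 1
    frame = pd.DataFrame(
        [
            {
                "accession": k[0],
                "chromosome": k[1],
                "bin_start": k[2],
                "superfamily": k[3],
                "count": v,
            }
            for k, v in sorted(rows.items())
        ],
        columns=["accession", "chromosome", "bin_start", "superfamily", "count"],
    )
    return frame
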