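"""Readers and writers for the standard formats the pipeline consumes.

FASTA for genomes and MITE libraries, GFF3 for gene annotation, BED6 and TSV
for loci and stage outputs, TSV for expression tables.  Internal coordinates
are 1-based inclusive; BED export converts to 0-based half-open at this
boundary and nowhere else.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

from .models import (
    ExpressionTable,
    FormatError,
    GeneModel,
    GenomeAccession,
    GenomicInterval,
    ValidationError,
    VALID_BASES,
)


def _validate_fasta_text(path: str | os.PathLike) -> None:
    """Line-level FASTA validation so errors can name the offending line."""
    n_records = 0
    record_len = 0
    header_line = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if n_records and record_len == 0:
                    raise FormatError(
                        f"{path}: empty record before line {lineno} "
                        f"(header at line {header_line})"
                    )
                if len(line) == 1:
                    raise FormatError(f"{path}: malformed header at line {lineno}")
                n_records += 1
                record_len = 0
                header_line = lineno
            else:
                if n_records == 0:
                    raise FormatError(
                        f"{path}: sequence before first header at line {lineno}"
                    )
                bad = set(line.upper()) - VALID_BASES
                if bad:
                    raise FormatError(
                        f"{path}: invalid symbol(s) {','.join(sorted(bad))} "
                        f"at line {lineno}"
                    )
                record_len += len(line)
    if n_records == 0:
        raise FormatError(f"{path}: no FASTA records found")
    if record_len == 0:
        raise FormatError(
            f"{path}: empty record (header at line {header_line})"
        )


def read_fasta(path: str | os.PathLike, accession_name: str | None = None) -> GenomeAccession:
    """Load a genome FASTA into a :class:`GenomeAccession`.

    Sequences are uppercased on load.  ``accession_name`` defaults to the
    filename stem.
    """
    _validate_fasta_text(path)
    name = accession_name or Path(path).stem
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise FormatError(f"{path}: duplicate chromosome name {rec.id!r}")
        chroms[rec.id] = str(rec.seq).upper()
    return GenomeAccession(accession_name=name, chromosomes=chroms)


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike,
                width: int = 70) -> None:
    """Write (name, sequence) pairs as FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_library_fasta(path: str | os.PathLike):
    """Load a reference MITE library FASTA (family/superfamily in headers).

    Header convention: ``>family_id superfamily=<name> species=<name>``;
    returns a list of dicts.  Defined here so library files written by
    :func:`write_library_fasta` round-trip.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        attrs = {}
        for token in rec.description.split()[1:]:
            if "=" in token:
                k, v = token.split("=", 1)
                attrs[k] = v
        if "superfamily" not in attrs:
            raise FormatError(
                f"{path}: library record {rec.id!r} lacks a superfamily label"
            )
        records.append(
            {
                "family": rec.id,
                "superfamily": attrs["superfamily"],
                "species": attrs.get("species", "unknown"),
                "sequence": str(rec.seq).upper(),
            }
        )
    return records


def write_library_fasta(records, path: str | os.PathLike) -> None:
    write_fasta(
        (
            (
                f"{r['family']} superfamily={r['superfamily']} "
                f"species={r.get('species', 'unknown')}",
                r["sequence"],
            )
            for r in records
        ),
        path,
    )


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Parse a GFF3 gene annotation into :class:`GeneModel` objects.

    When a gene carries several mRNAs, the longest transcript defines the
    sub-regions.  Introns are derived from CDS exon gaps; minus-strand genes
    get their sub-regions ordered in transcription direction.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if mrnas:
            mrna = max(mrnas, key=lambda m: m.end - m.start + 1)
            parent = mrna
        else:
            parent = gene
        locus = GenomicInterval(gene.seqid, gene.start, gene.end, gene.strand)

        def intervals(ftypes: tuple[str, ...]) -> list[GenomicInterval]:
            out = []
            for f in db.children(parent, featuretype=ftypes, order_by="start"):
                if f.start < gene.start or f.end > gene.end:
                    raise ValidationError(
                        f"{gene.id}: {f.featuretype} {f.start}-{f.end} outside "
                        f"gene bounds {gene.start}-{gene.end}"
                    )
                out.append(GenomicInterval(f.seqid, f.start, f.end, gene.strand))
            return out

        is_novel = gene.attributes.get("is_novel", ["0"])[0] in ("1", "true", "True")
        genes.append(
            GeneModel(
                gene_id=gene.id,
                locus=locus,
                five_prime_utr=intervals(("five_prime_UTR",)),
                cds_exons=intervals(("CDS",)),
                three_prime_utr=intervals(("three_prime_UTR",)),
                is_novel=is_novel,
            )
        )
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as GFF3 (gene + one mRNA + CDS/UTR features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            novel = ";is_novel=1" if g.is_novel else ""
            fh.write(
                f"{g.locus.chromosome}\tmitecompare\tgene\t{g.locus.start}\t"
                f"{g.locus.end}\t.\t{g.strand}\t.\tID={g.gene_id}{novel}\n"
            )
            mrna_id = f"{g.gene_id}.1"
            fh.write(
                f"{g.locus.chromosome}\tmitecompare\tmRNA\t{g.locus.start}\t"
                f"{g.locus.end}\t.\t{g.strand}\t.\tID={mrna_id};Parent={g.gene_id}\n"
            )
            for ftype, ivs in (
                ("five_prime_UTR", g.five_prime_utr),
                ("CDS", g.cds_exons),
                ("three_prime_UTR", g.three_prime_utr),
            ):
                for iv in sorted(ivs, key=lambda x: x.start):
                    fh.write(
                        f"{iv.chromosome}\tmitecompare\t{ftype}\t{iv.start}\t"
                        f"{iv.end}\t.\t{g.strand}\t.\tParent={mrna_id}\n"
                    )


# ---------------------------------------------------------------------------
# BED / TSV


def write_bed(
    intervals: Iterable[tuple[GenomicInterval, str]], path: str | os.PathLike
) -> None:
    """Write (interval, name) pairs as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for iv, name in intervals:
            fh.write(
                f"{iv.chromosome}\t{iv.start - 1}\t{iv.end}\t{name}\t0\t"
                f"{iv.strand if iv.strand != '.' else '.'}\n"
            )


def read_bed(path: str | os.PathLike) -> list[tuple[GenomicInterval, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}: expected BED6, got {len(fields)} fields")
            chrom, start0, end, name, _score, strand = fields[:6]
            out.append(
                (GenomicInterval(chrom, int(start0) + 1, int(end), strand), name)
            )
    return out


def write_tsv(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_expression_tsv(path: str | os.PathLike) -> ExpressionTable:
    """Read a gene x accession RPKM table (first column = gene_id)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionTable(frame)


def write_expression_tsv(table: ExpressionTable, path: str | os.PathLike) -> None:
    table.frame.to_csv(path, sep="\t")
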