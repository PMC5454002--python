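"""Synthetic multi-accession genomes with planted MITEs and ground truth.

The generator emulates the four inputs the comparative pipeline consumes:
per-accession genome FASTAs descended from a common ancestor, consistent
GFF3 gene annotation (shared gene IDs, per-accession coordinates), a
labelled reference MITE library covering a subset of the planted families,
and a gene x accession RPKM table with a configurable multiplicative
MITE-presence effect.  Every planted element is recorded in a TruthRecord.

Planted copies come in three categories.  "canonical" copies are the family
consensus inserted verbatim with a perfect target-site duplication, so they
pass the structural detector by construction.  "diverse" copies are
full-length but substitution-decayed; when the decay rate is positive, a
few of the substitutions are deliberately placed in the 5' TIR and one in
the right TSD copy so structural degradation is certain rather than merely
likely (at decay 0 a diverse copy is identical to a canonical one).
"partial" copies are truncated 5' or 3' fragments.  Decay is drawn once per
insertion, so accessions sharing an insertion share its sequence — the
copies are homologous by descent.

Accessions differ by background substitutions (outside a protected window
around each insertion site, so the local structural context of a planted
element is identical in every carrier) and by insertion presence: the first
``min_copies`` canonical copies of each family are present in every
accession (the copy-number filter is a per-accession constraint), the rest
follow independent Bernoulli(presence_probability) draws.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import encode, revcomp
from .detect import DetectionParams, enumerate_tir_candidates, validate_tsd
from .models import (
    ExpressionTable,
    GeneModel,
    GenomeAccession,
    GenomicInterval,
)

logger = logging.getLogger(__name__)

ACCESSION_NAMES = (
    "col", "bur", "can", "ct", "edi", "hi", "kn", "ler", "mt", "no",
    "oy", "po", "rsch", "sf", "tsu", "wil", "ws", "wu", "zu",
)
CORE_SUPERFAMILIES = ("hAT", "PIF/Harbinger", "Mutator", "Tc1/Mariner")
RELATIONS = ("intron", "last-exon-spanning", "upstream", "none")

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class MiteFamilyConfig:
    family_id: str
    element_length: int
    tir_length: int
    tsd_length: int
    copy_number: int  # canonical full-length copies
    extra_copies: int  # additional diverse/partial copies
    decay_rate: float
    truncation_probability: float
    classified: bool
    superfamily: str
    species: str = "Arabidopsis thaliana"

    def __post_init__(self) -> None:
        if not 50 <= self.element_length <= 800:
            raise ValueError("element_length outside [50, 800]")
        if self.tir_length < 10 or 2 * self.tir_length > self.element_length:
            raise ValueError("infeasible tir_length")
        if not 2 <= self.tsd_length <= 10:
            raise ValueError("tsd_length outside [2, 10]")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic multi-accession dataset."""

    n_accessions: int = 19
    chromosome_lengths: tuple[int, ...] = (200_000,) * 5
    n_gene_families: int = 200
    n_mite_families: int = 10
    families: tuple[MiteFamilyConfig, ...] | None = None
    element_length_range: tuple[int, int] = (120, 600)
    tir_length_range: tuple[int, int] = (10, 20)
    tsd_length_range: tuple[int, int] = (2, 6)
    copy_number_range: tuple[int, int] = (3, 6)
    extra_copies_range: tuple[int, int] = (4, 8)
    decay_rate: float = 0.05
    truncation_probability: float = 0.35
    presence_probability: float = 0.8
    classified_fraction: float = 0.5
    heterochromatin_fraction: float = 0.2
    placement_bias: float = 0.8
    relation_weights: tuple[float, float, float, float] = (0.35, 0.2, 0.2, 0.25)
    background_divergence: float = 0.002
    expression_log_mean: float = math.log(10.0)
    expression_log_sd: float = 0.6
    gene_log_sd: float = 0.3
    mite_effect: float = 1.5
    novel_gene_fraction: float = 0.15
    min_fragment_length: int = 60
    min_guaranteed_copies: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accessions < 1 or self.n_gene_families < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.presence_probability <= 1:
            raise ValueError("presence_probability outside [0,1]")
        if not 0 <= self.decay_rate < 1:
            raise ValueError("decay_rate outside [0,1)")
        if abs(sum(self.relation_weights) - 1) > 1e-9:
            raise ValueError("relation_weights must sum to 1")
        if not 0 <= self.heterochromatin_fraction < 1:
            raise ValueError("heterochromatin_fraction outside [0,1)")


@dataclass
class TruthRecord:
    """Ground truth for one planted MITE copy in one accession."""

    accession: str
    interval: GenomicInterval
    family_id: str
    category: str  # canonical | diverse | partial
    tsd_sequence: str
    associated_gene_id: str | None
    relation: str  # intron | last-exon-spanning | upstream | none
    element_sequence: str
    insertion_id: int
    fraction: float = 1.0


@dataclass
class _Insertion:
    insertion_id: int
    family_id: str
    chrom: str
    x: int  # ancestral 0-based insertion point
    category: str
    relation: str
    gene_id: str | None
    j_split: int  # for last-exon-spanning
    element: str  # materialised (possibly decayed/truncated) element
    right_tsd_mutations: list[tuple[int, int]]  # (offset, new code)
    fraction: float
    presence: np.ndarray  # bool per accession


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    accessions: dict[str, GenomeAccession]
    genes: dict[str, list[GeneModel]]
    library: list[dict]
    expression: ExpressionTable
    truth: list[TruthRecord]

    @property
    def accession_names(self) -> list[str]:
        return list(self.accessions)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "accession": t.accession,
                    "chromosome": t.interval.chromosome,
                    "start": t.interval.start,
                    "end": t.interval.end,
                    "family_id": t.family_id,
                    "category": t.category,
                    "tsd_sequence": t.tsd_sequence,
                    "gene_id": t.associated_gene_id or "",
                    "relation": t.relation,
                    "insertion_id": t.insertion_id,
                    "fraction": t.fraction,
                }
                for t in self.truth
            ]
        )

    def write(self, outdir) -> None:
        from pathlib import Path

        from .readwrite import (
            write_expression_tsv,
            write_fasta,
            write_gff3,
            write_library_fasta,
            write_tsv,
        )

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, genome in self.accessions.items():
            write_fasta(genome.chromosomes.items(), out / f"{name}.fa")
            write_gff3(self.genes[name], out / f"{name}.gff3")
        write_library_fasta(self.library, out / "library.fa")
        write_expression_tsv(self.expression, out / "expression.tsv")
        write_tsv(self.truth_frame(), out / "truth.tsv")


# ---------------------------------------------------------------------------
# Element construction


def make_mite_family(
    element_length: int, tir_length: int, rng: np.random.Generator
) -> tuple[str, tuple[str, str]]:
    """Random MITE consensus: TIR prefix, random interior, revcomp suffix.

    Returns (sequence, (5' TIR, 3' TIR)); the first ``tir_length`` bases
    equal the reverse complement of the last ``tir_length``.
    """
    if tir_length < 10:
        raise ValueError("tir_length must be >= 10")
    if not 50 <= element_length <= 800 or 2 * tir_length > element_length:
        raise ValueError("infeasible element/TIR lengths")
    codes = rng.integers(0, 4, size=element_length)
    seq = _decode(codes.astype(np.uint8))
    tir5 = seq[:tir_length]
    seq = tir5 + seq[tir_length : element_length - tir_length] + revcomp(tir5)
    return seq, (tir5, revcomp(tir5))


def _mutate(seq: str, positions: list[int], rng: np.random.Generator) -> str:
    codes = encode(seq).copy()
    for p in positions:
        codes[p] = (codes[p] + rng.integers(1, 4)) % 4
    return _decode(codes.astype(np.uint8))


def _materialize_element(
    consensus: str,
    category: str,
    family: MiteFamilyConfig,
    rng: np.random.Generator,
    min_fragment: int,
) -> tuple[str, list[tuple[int, int]], float]:
    """Element sequence, right-TSD mutations and retained fraction."""
    L = len(consensus)
    if category == "canonical":
        return consensus, [], 1.0
    if category == "diverse":
        if family.decay_rate == 0:
            return consensus, [], 1.0
        n_sub = int(rng.binomial(L, family.decay_rate))
        # three substitutions inside the first ten TIR positions guarantee the
        # mismatch budget is blown at every TIR length; their suffix partners
        # are excluded from the random pool so decay cannot restore a pair
        forced = [1, 5, 8]
        excluded = set(forced) | {L - 1 - p for p in forced}
        rest = max(0, n_sub - len(forced))
        pool = [p for p in range(L) if p not in excluded]
        extra = list(rng.choice(pool, size=min(rest, len(pool)), replace=False))
        elem = _mutate(consensus, forced + extra, rng)
        tsd_mut = [(int(rng.integers(0, family.tsd_length)), int(rng.integers(1, 4)))]
        return elem, tsd_mut, 1.0
    if category == "partial":
        f = float(rng.uniform(0.2, 0.8))
        frag_len = min(L, max(min_fragment, int(round(f * L))))
        five_prime = bool(rng.integers(0, 2))
        frag = consensus[:frag_len] if five_prime else consensus[L - frag_len :]
        n_sub = int(rng.binomial(frag_len, family.decay_rate))
        pos = list(rng.choice(frag_len, size=min(n_sub, frag_len), replace=False))
        return _mutate(frag, pos, rng), [], frag_len / L
    raise ValueError(f"unknown category {category!r}")


def plant_insertion(
    sequence: str,
    element: str,
    site: int,
    tsd_length: int,
    right_tsd_mutations: list[tuple[int, int]] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[str, GenomicInterval, str]:
    """Insert an element at 0-based point ``site`` with TSD duplication.

    The ``tsd_length`` bases at the site are duplicated on both flanks; the
    TSDs are not part of the element.  Returns (new sequence, 1-based
    element interval on an unnamed chromosome, left TSD sequence).
    """
    if not 0 <= site <= len(sequence) - tsd_length:
        raise ValueError("site outside chromosome")
    tsd = sequence[site : site + tsd_length]
    right = tsd
    if right_tsd_mutations:
        assert rng is not None
        codes = encode(right).copy()
        for off, delta in right_tsd_mutations:
            codes[off] = (codes[off] + delta) % 4
        right = _decode(codes.astype(np.uint8))
    new = sequence[: site + tsd_length] + element + right + sequence[site + tsd_length :]
    start = site + tsd_length + 1
    return new, GenomicInterval("", start, start + len(element) - 1), tsd


# ---------------------------------------------------------------------------
# Gene layout (ancestral coordinates)


@dataclass
class _AncGene:
    gene_id: str
    chrom: str
    strand: str
    is_novel: bool
    locus: tuple[int, int]  # 1-based
    five_prime_utr: list[tuple[int, int]]
    cds_exons: list[tuple[int, int]]
    three_prime_utr: list[tuple[int, int]]

    def introns(self) -> list[tuple[int, int]]:
        exons = sorted(self.cds_exons)
        return [
            (a_end + 1, b_start - 1)
            for (_, a_end), (b_start, _) in zip(exons, exons[1:])
            if b_start > a_end + 1
        ]

    def last_exon(self) -> tuple[int, int]:
        exons = sorted(self.cds_exons)
        return exons[0] if self.strand == "-" else exons[-1]


_GENE_PARTS = (100, 200, 150, 150, 200, 250, 150)  # 5'UTR,E1,I1,E2,I2,E3,3'UTR
_GENE_SPAN = sum(_GENE_PARTS)


def _layout_genes(
    config: SimulationConfig,
    chrom_names: list[str],
    het: dict[str, tuple[int, int]],
    rng: np.random.Generator,
) -> list[_AncGene]:
    genes: list[_AncGene] = []
    per_chrom = [
        config.n_gene_families // len(chrom_names)
        + (1 if i < config.n_gene_families % len(chrom_names) else 0)
        for i in range(len(chrom_names))
    ]
    for ci, chrom in enumerate(chrom_names):
        length = config.chromosome_lengths[ci]
        h_lo, h_hi = het[chrom]
        pos = 1500
        for gi in range(per_chrom[ci]):
            pos += int(rng.integers(1000, 2500))
            if pos < h_hi and pos + _GENE_SPAN + 1000 >= h_lo:
                pos = h_hi + 1000  # skip heterochromatin
            if pos + _GENE_SPAN + 1500 > length:
                logger.warning("%s: ran out of space after %d genes", chrom, gi)
                break
            strand = "+" if rng.integers(0, 2) else "-"
            b = []
            cur = pos
            for part in _GENE_PARTS:
                b.append((cur, cur + part - 1))
                cur += part
            if strand == "+":
                utr5, e1, i1, e2, i2, e3, utr3 = b
            else:
                utr3, e3, i2, e2, i1, e1, utr5 = b
            genes.append(
                _AncGene(
                    gene_id=f"AT{ci + 1}G{(gi + 1) * 10:05d}",
                    chrom=chrom,
                    strand=strand,
                    is_novel=bool(rng.random() < config.novel_gene_fraction),
                    locus=(pos, cur - 1),
                    five_prime_utr=[utr5],
                    cds_exons=[e1, e2, e3],
                    three_prime_utr=[utr3],
                )
            )
            pos = cur
    return genes


# ---------------------------------------------------------------------------
# Full dataset generation


def _sample_families(config: SimulationConfig, rng: np.random.Generator) -> list[MiteFamilyConfig]:
    if config.families is not None:
        return list(config.families)
    n_classified = int(round(config.classified_fraction * config.n_mite_families))
    fams = []
    for i in range(config.n_mite_families):
        fams.append(
            MiteFamilyConfig(
                family_id=f"MF{i + 1:03d}",
                element_length=int(rng.integers(*config.element_length_range)),
                tir_length=int(rng.integers(config.tir_length_range[0],
                                            config.tir_length_range[1] + 1)),
                tsd_length=int(rng.integers(config.tsd_length_range[0],
                                            config.tsd_length_range[1] + 1)),
                copy_number=int(rng.integers(config.copy_number_range[0],
                                             config.copy_number_range[1] + 1)),
                extra_copies=int(rng.integers(config.extra_copies_range[0],
                                              config.extra_copies_range[1] + 1)),
                decay_rate=config.decay_rate,
                truncation_probability=config.truncation_probability,
                classified=i < n_classified,
                superfamily=CORE_SUPERFAMILIES[i % len(CORE_SUPERFAMILIES)],
            )
        )
    return fams


def _competitor_would_win(
    window: str, elem_start0: int, elem_len: int, dparams: DetectionParams
) -> bool:
    """True when an overlapping structural candidate would outrank the
    planted element under the detector's overlap-resolution rule
    (longest TSD, then longest element, then leftmost start)."""
    planted = (elem_start0 + 1, elem_start0 + elem_len)
    candidates = enumerate_tir_candidates(window, dparams)
    planted_tsd = None
    for cand in candidates:
        if (cand.start, cand.end) == planted:
            planted_tsd = validate_tsd(window, cand, dparams)
    if planted_tsd is None:
        return True  # planted element does not validate here at all
    planted_rank = (len(planted_tsd), elem_len, -planted[0])
    for cand in candidates:
        if cand.end < planted[0] or cand.start > planted[1]:
            continue
        if (cand.start, cand.end) == planted:
            continue
        tsd = validate_tsd(window, cand, dparams)
        if tsd is None:
            continue
        rank = (len(tsd), cand.end - cand.start + 1, -cand.start)
        if rank > planted_rank:
            return True
    return False


def _internal_candidates(
    element: str, dparams: DetectionParams, rng: np.random.Generator
) -> bool:
    """True when an element's interior admits a TIR+TSD candidate of its own.

    The element is embedded in a throwaway random context; only candidates
    strictly inside it count (boundary-crossing ones depend on the real
    insertion context and are guarded per site).
    """
    ctx_l = _decode(rng.integers(0, 4, size=80).astype(np.uint8))
    ctx_r = _decode(rng.integers(0, 4, size=80).astype(np.uint8))
    window = ctx_l + element + ctx_r
    lo, hi = len(ctx_l) + 1, len(ctx_l) + len(element)
    for cand in enumerate_tir_candidates(window, dparams):
        if cand.start > lo and cand.end < hi:
            if validate_tsd(window, cand, dparams) is not None:
                return True
    return False


def _clean_consensus(
    fam: MiteFamilyConfig, dparams: DetectionParams, rng: np.random.Generator
) -> str:
    """A family consensus whose interior is free of chance TIR+TSD structure.

    Interior structure would replicate across every planted copy of the
    family (copy-number support included), planting unlabelled canonical
    MITEs the ground truth knows nothing about.
    """
    for _ in range(80):
        seq, _ = make_mite_family(fam.element_length, fam.tir_length, rng)
        if not _internal_candidates(seq, dparams, rng):
            return seq
    raise RuntimeError(f"{fam.family_id}: could not draw a structure-free consensus")


def generate_accession_set(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full synthetic multi-accession dataset.

    Deterministic: the seed fully determines every output byte.
    """
    rng = np.random.default_rng(config.seed)
    dparams = DetectionParams()
    n_chrom = len(config.chromosome_lengths)
    chrom_names = [f"Chr{i + 1}" for i in range(n_chrom)]
    acc_names = [
        ACCESSION_NAMES[i] if i < len(ACCESSION_NAMES) else f"acc{i + 1}"
        for i in range(config.n_accessions)
    ]

    ancestral = {
        name: rng.integers(0, 4, size=length).astype(np.int8)
        for name, length in zip(chrom_names, config.chromosome_lengths)
    }
    het = {}
    for name, length in zip(chrom_names, config.chromosome_lengths):
        h = int(config.heterochromatin_fraction * length)
        c = length // 2
        het[name] = (c - h // 2, c + h - h // 2)

    genes = _layout_genes(config, chrom_names, het, rng)
    genes_by_chrom: dict[str, list[_AncGene]] = {c: [] for c in chrom_names}
    for g in genes:
        genes_by_chrom[g.chrom].append(g)

    families = _sample_families(config, rng)
    consensi = {
        fam.family_id: _clean_consensus(fam, dparams, rng) for fam in families
    }
    library = [
        {
            "family": fam.family_id,
            "superfamily": fam.superfamily,
            "species": fam.species,
            "sequence": consensi[fam.family_id],
        }
        for fam in families
        if fam.classified
    ]

    insertions = _plan_insertions(
        config, families, consensi, ancestral, genes, genes_by_chrom, het,
        dparams, rng,
    )

    # presence draws, in insertion order
    for ins in insertions:
        fam = next(f for f in families if f.family_id == ins.family_id)
        guaranteed = (
            ins.category == "canonical"
            and _canonical_rank(insertions, ins) < min(
                config.min_guaranteed_copies, fam.copy_number
            )
        )
        if guaranteed or config.presence_probability >= 1.0:
            ins.presence = np.ones(config.n_accessions, dtype=bool)
        else:
            ins.presence = rng.random(config.n_accessions) < config.presence_probability

    # protected windows: no background substitutions near any insertion site
    protected = {c: np.zeros(len(a), dtype=bool) for c, a in ancestral.items()}
    for ins in insertions:
        lo = max(0, ins.x - 130)
        hi = min(len(protected[ins.chrom]), ins.x + 130)
        protected[ins.chrom][lo:hi] = True

    accessions: dict[str, GenomeAccession] = {}
    gene_models: dict[str, list[GeneModel]] = {}
    truth: list[TruthRecord] = []
    for ai, acc in enumerate(acc_names):
        chroms: dict[str, str] = {}
        acc_truth: list[TruthRecord] = []
        shifts_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in chrom_names:
            codes = ancestral[chrom].copy()
            if config.background_divergence > 0:
                mask = (
                    rng.random(len(codes)) < config.background_divergence
                ) & ~protected[chrom]
                idx = np.nonzero(mask)[0]
                codes[idx] = (codes[idx] + rng.integers(1, 4, size=len(idx))) % 4
            seq = _decode(codes.astype(np.uint8))
            present = sorted(
                (ins for ins in insertions if ins.chrom == chrom and ins.presence[ai]),
                key=lambda i: i.x,
            )
            parts: list[str] = []
            prev = 0
            offset = 0
            xs, shifts = [], []
            fam_tsd = {f.family_id: f.tsd_length for f in families}
            for ins in present:
                k = fam_tsd[ins.family_id]
                tsd = seq[ins.x : ins.x + k]
                right = tsd
                if ins.right_tsd_mutations:
                    rcodes = encode(right).copy()
                    for off, delta in ins.right_tsd_mutations:
                        rcodes[off] = (rcodes[off] + delta) % 4
                    right = _decode(rcodes.astype(np.uint8))
                parts.append(seq[prev : ins.x + k])
                parts.append(ins.element)
                parts.append(right)
                prev = ins.x + k
                elem_start0 = ins.x + k + offset
                offset += k + len(ins.element)
                xs.append(ins.x)
                shifts.append(offset)
                acc_truth.append(
                    TruthRecord(
                        accession=acc,
                        interval=GenomicInterval(
                            chrom, elem_start0 + 1, elem_start0 + len(ins.element), "+"
                        ),
                        family_id=ins.family_id,
                        category=ins.category,
                        tsd_sequence=tsd,
                        associated_gene_id=ins.gene_id,
                        relation=ins.relation,
                        element_sequence=ins.element,
                        insertion_id=ins.insertion_id,
                        fraction=ins.fraction,
                    )
                )
            parts.append(seq[prev:])
            chroms[chrom] = "".join(parts)
            shifts_by_chrom[chrom] = (
                np.array(xs, dtype=np.int64),
                np.array([0] + shifts, dtype=np.int64),
            )
        accessions[acc] = GenomeAccession(accession_name=acc, chromosomes=chroms)
        gene_models[acc] = _map_gene_models(
            genes, shifts_by_chrom, insertions, ai, acc_truth
        )
        truth += acc_truth

    expression = _draw_expression(config, genes, truth, acc_names, rng)
    return SyntheticDataset(
        config=config,
        accessions=accessions,
        genes=gene_models,
        library=library,
        expression=expression,
        truth=truth,
    )


def _canonical_rank(insertions: list[_Insertion], ins: _Insertion) -> int:
    rank = 0
    for other in insertions:
        if other.family_id == ins.family_id and other.category == "canonical":
            if other.insertion_id == ins.insertion_id:
                return rank
            rank += 1
    raise AssertionError("insertion not found")


def _plan_insertions(
    config, families, consensi, ancestral, genes, genes_by_chrom, het, dparams, rng
) -> list[_Insertion]:
    used_sites: dict[str, list[int]] = {c: [] for c in ancestral}
    used_genes: set[str] = set()
    insertions: list[_Insertion] = []
    weights = np.asarray(config.relation_weights, dtype=float)
    extra_weights = weights.copy()
    extra_weights[1] = 0.0  # extras never span the last exon
    extra_weights /= extra_weights.sum()
    insertion_id = 0
    for fam in families:
        consensus = consensi[fam.family_id]
        plan = ["canonical"] * fam.copy_number
        for _ in range(fam.extra_copies):
            plan.append(
                "partial"
                if rng.random() < fam.truncation_probability
                else "diverse"
            )
        for category in plan:
            w = weights if category == "canonical" else extra_weights
            placed = False
            for _attempt in range(200):
                # decay is re-drawn together with the site: a rejected
                # attempt may be rejected because decay itself created
                # chance TIR+TSD structure inside the copy
                element, tsd_mut, fraction = _materialize_element(
                    consensus, category, fam, rng, config.min_fragment_length
                )
                relation = str(rng.choice(RELATIONS, p=w))
                # a diverse copy at decay 0 is structurally canonical
                guard_cat = (
                    "canonical"
                    if category == "canonical"
                    or (category == "diverse" and fam.decay_rate == 0)
                    else category
                )
                site = _sample_site(
                    relation, fam, element, tsd_mut, config, ancestral, genes,
                    genes_by_chrom, het, used_sites, used_genes, dparams,
                    guard_cat, rng,
                )
                if site is None:
                    continue
                chrom, x, gene_id, j_split = site
                used_sites[chrom].append(x)
                if gene_id is not None:
                    used_genes.add(gene_id)
                insertions.append(
                    _Insertion(
                        insertion_id=insertion_id,
                        family_id=fam.family_id,
                        chrom=chrom,
                        x=x,
                        category=category,
                        relation=relation,
                        gene_id=gene_id,
                        j_split=j_split,
                        element=element,
                        right_tsd_mutations=tsd_mut,
                        fraction=fraction,
                        presence=np.empty(0, dtype=bool),
                    )
                )
                insertion_id += 1
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    "could not place insertion: genome too crowded for config"
                )
    insertions.sort(key=lambda i: (i.chrom, i.x))
    return insertions


_MIN_SPACING = 900
_EDGE_MARGIN = 900


def _site_clear(used: list[int], x: int) -> bool:
    return all(abs(x - u) >= _MIN_SPACING for u in used)


def _guard_ok(
    ancestral, chrom, x, element, tsd_len, category, dparams,
    right_tsd_mutations=(),
) -> bool:
    """Reject sites (and decay draws) that confound the structural truth.

    For a canonical copy: no overlapping candidate may outrank the planted
    element under the detector's resolution rule.  For a diverse or partial
    copy: no structural candidate (TIR + valid TSD) may overlap the copy at
    all — such chance structure, replicated by the family's copy-number
    support, would be an unlabelled canonical MITE.
    """
    W = 120
    seq = _decode(ancestral[chrom][max(0, x - W) : x + W].astype(np.uint8))
    cut = min(W, x)
    right = seq[cut : cut + tsd_len]
    if right_tsd_mutations:
        rcodes = encode(right).copy()
        for off, delta in right_tsd_mutations:
            rcodes[off] = (rcodes[off] + delta) % 4
        right = _decode(rcodes.astype(np.uint8))
    window = seq[: cut + tsd_len] + element + right + seq[cut + tsd_len :]
    elem_start0 = cut + tsd_len
    if category == "canonical":
        return not _competitor_would_win(window, elem_start0, len(element), dparams)
    planted = (elem_start0 + 1, elem_start0 + len(element))
    for cand in enumerate_tir_candidates(window, dparams):
        if cand.end < planted[0] or cand.start > planted[1]:
            continue
        if validate_tsd(window, cand, dparams) is not None:
            return False
    return True


def _sample_site(
    relation, fam, element, right_tsd_mutations, config, ancestral, genes,
    genes_by_chrom, het, used_sites, used_genes, dparams, category, rng,
):
    """One candidate site for a planted insertion, or None to retry."""
    k = fam.tsd_length
    if relation in ("intron", "last-exon-spanning", "upstream"):
        candidates = [g for g in genes if g.gene_id not in used_genes]
        if not candidates:
            return None
        gene = candidates[int(rng.integers(0, len(candidates)))]
        chrom = gene.chrom
        n = len(ancestral[chrom])
        j_split = 0
        if relation == "intron":
            introns = gene.introns()
            a, b = introns[int(rng.integers(0, len(introns)))]
            lo, hi = (a - 1) + 3, (b - 1) - k - 3
        elif relation == "last-exon-spanning":
            a, b = gene.last_exon()
            lo, hi = (a - 1) + 12, (b - 1) - k - 12
            j_split = int(rng.integers(10, len(element) - 9))
        else:  # upstream in transcription direction; d stays comfortably
            # inside the 40 nt rule so end-trimming of decayed copies cannot
            # push a homologous copy over the threshold
            d = int(rng.integers(k + 2, 31))
            if gene.strand == "+":
                x = gene.locus[0] - 1 - d
            else:
                x = gene.locus[1] + d - k
            lo = hi = x
        if hi < lo:
            return None
        x = int(rng.integers(lo, hi + 1))
        if not (_EDGE_MARGIN <= x <= n - _EDGE_MARGIN):
            return None
        if not _site_clear(used_sites[chrom], x):
            return None
        if relation == "upstream" and not _far_from_other_genes(
            genes_by_chrom[chrom], gene, x, len(element), k
        ):
            return None
        if not _guard_ok(ancestral, chrom, x, element, k, category, dparams,
                         right_tsd_mutations):
            return None
        return chrom, x, gene.gene_id, j_split

    # relation == "none": intergenic / heterochromatin placement
    lengths = np.array([len(ancestral[c]) for c in ancestral], dtype=float)
    chrom = list(ancestral)[int(rng.choice(len(lengths), p=lengths / lengths.sum()))]
    n = len(ancestral[chrom])
    in_het = (not fam.classified) and (rng.random() < config.placement_bias)
    if in_het:
        lo, hi = het[chrom]
        x = int(rng.integers(lo + 100, hi - 100))
    else:
        x = int(rng.integers(_EDGE_MARGIN, n - _EDGE_MARGIN))
        h_lo, h_hi = het[chrom]
        if h_lo - 900 <= x <= h_hi + 900 and fam.classified:
            return None
    if not _site_clear(used_sites[chrom], x):
        return None
    # stay clear of every gene so no interaction arises (element-interval
    # distances to genes are insertion-invariant: downstream genes shift
    # together with the element)
    elem_lo, elem_hi = x, x + k + len(element)
    for g in genes_by_chrom[chrom]:
        if g.locus[0] - 1 <= elem_hi + 60 and elem_lo - 60 <= g.locus[1] - 1:
            return None
    if not _guard_ok(ancestral, chrom, x, element, k, category, dparams,
                     right_tsd_mutations):
        return None
    return chrom, x, None, 0


def _far_from_other_genes(chrom_genes, gene, x, elem_len, k) -> bool:
    lo = x - 60
    hi = x + k + elem_len + 60
    for g in chrom_genes:
        if g.gene_id == gene.gene_id:
            continue
        if g.locus[0] <= hi and lo <= g.locus[1]:
            return False
    return True


def _map_coord(c1: int, xs: np.ndarray, shifts: np.ndarray) -> int:
    """Map a 1-based ancestral coordinate through the insertion shifts."""
    i = int(np.searchsorted(xs, c1 - 1, side="right"))
    return c1 + int(shifts[i])


def _map_gene_models(
    genes: list[_AncGene],
    shifts_by_chrom,
    insertions: list[_Insertion],
    ai: int,
    acc_truth: list[TruthRecord],
) -> list[GeneModel]:
    spanning = {
        t.associated_gene_id: t
        for t in acc_truth
        if t.relation == "last-exon-spanning"
    }
    j_by_insertion = {i.insertion_id: i.j_split for i in insertions}
    out: list[GeneModel] = []
    for g in genes:
        xs, shifts = shifts_by_chrom[g.chrom]

        def mp(pair):
            return (_map_coord(pair[0], xs, shifts), _map_coord(pair[1], xs, shifts))

        locus = mp(g.locus)
        utr5 = [mp(p) for p in g.five_prime_utr]
        exons = [mp(p) for p in g.cds_exons]
        utr3 = [mp(p) for p in g.three_prime_utr]
        t = spanning.get(g.gene_id)
        if t is not None:
            j = j_by_insertion[t.insertion_id]
            junction = t.interval.start + j - 1  # last element base in CDS part
            exons_sorted = sorted(exons)
            if g.strand == "+":
                a, _b = exons_sorted[-1]
                exons = exons_sorted[:-1] + [(a, junction)]
                utr3 = [(junction + 1, utr3[0][1])]
            else:
                _a, b = exons_sorted[0]
                exons = [(junction + 1, b)] + exons_sorted[1:]
                utr3 = [(utr3[0][0], junction)]
        out.append(
            GeneModel(
                gene_id=g.gene_id,
                locus=GenomicInterval(g.chrom, locus[0], locus[1], g.strand),
                five_prime_utr=[
                    GenomicInterval(g.chrom, a, b, g.strand) for a, b in utr5
                ],
                cds_exons=[
                    GenomicInterval(g.chrom, a, b, g.strand) for a, b in exons
                ],
                three_prime_utr=[
                    GenomicInterval(g.chrom, a, b, g.strand) for a, b in utr3
                ],
                is_novel=g.is_novel,
            )
        )
    return out


def _draw_expression(
    config: SimulationConfig,
    genes: list[_AncGene],
    truth: list[TruthRecord],
    acc_names: list[str],
    rng: np.random.Generator,
) -> ExpressionTable:
    associated: set[tuple[str, str]] = {
        (t.associated_gene_id, t.accession)
        for t in truth
        if t.associated_gene_id is not None
    }
    gene_mu = {
        g.gene_id: config.expression_log_mean + rng.normal(0, config.gene_log_sd)
        for g in genes
    }
    data = {}
    for acc in acc_names:
        col = []
        for g in genes:
            v = math.exp(rng.normal(gene_mu[g.gene_id], config.expression_log_sd))
            if (g.gene_id, acc) in associated:
                v *= config.mite_effect
            col.append(v)
        data[acc] = col
    frame = pd.DataFrame(data, index=pd.Index([g.gene_id for g in genes], name="gene_id"))
    return ExpressionTable(frame)
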