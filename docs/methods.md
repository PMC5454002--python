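# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `mitecompare`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The structural model of a canonical MITE

A canonical MITE is an interval [s, e] of length L ∈ [50, 800] such that

* **TIR** — for some t ∈ [10, 56] with 2t ≤ L, the prefix of length t
  matches the reverse complement of the suffix of length t with at most
  ⌊0.1·t⌋ mismatches and no indels. The detector reports the *maximal*
  qualifying t at each locus. Note that a perfect planted TIR of length t₀
  is typically reported at t ≥ t₀: the budget at t₀+1 already absorbs one
  mismatching pair, so the maximal qualifying length extends until the
  running mismatch count exceeds the budget. Truth comparisons therefore
  assert on intervals, never on exact TIR lengths.
* **TSD** — the longest k ∈ [2, 10] such that the k bases immediately left
  of the element exactly equal the k bases immediately right. TSDs must be
  perfect; they are never part of the element.
* **Copy number** — at least 3 near-identical full-length occurrences in
  the same genome. An occurrence is a full-query-length window (either
  strand) with per-base identity ≥0.9 (ungapped; see "decay model" below).
  Occurrences whose 60-bp left *and* right flanks both align at >0.6
  identity (edit-distance identity) to an already-counted occurrence are
  collapsed, so tandem or segmental duplications contribute one copy:
  dispersed copies with distinct flanks are the transposition evidence.
  The "mostly perfect TIR" budget (10%, no indels) and the flank
  distinctness rule (60 bp, 0.6) are this package's quantifications of
  qualitative criteria; both are exposed in `DetectionParams`.

### Candidate enumeration is seeded but lossless

Scanning all (start, end, tir) triples is quadratic in genome length.
Instead, candidate (s, e) pairs are seeded by exact complementary k-mer
pairs and verified exhaustively over all TIR lengths. The seed set is
provably complete for the mismatch model above:

For a qualifying TIR of length t with m ≤ ⌊0.1·t⌋ mismatches, either
(i) some exact complementary run of length ≥5 starts within the first six
TIR positions, or (ii) an exact complementary run of length ≥10 occurs
somewhere in the TIR. Sketch: if the first ten TIR pairs contain ≤1
mismatch, a clean 5-run starting at offset ≤5 exists (case i). If they
contain ≥2, the remaining t−10 pairs carry at most m−2 mismatches, and for
every admissible (t, m) combination the pigeonhole bound
⌈(t−10−(m−2))/(m−1)⌉ ≥ 10 guarantees a clean 10-run (case ii).

Tier (i) expands each exact complementary 5-mer pair at offsets j = 0…5;
tier (ii) expands each exact 10-mer pair at offsets j = 0…46. Every
expanded (s, e) candidate is then verified by an iterative maximal-TIR
search that abandons a candidate once its running mismatch count exceeds
the largest budget any admissible TIR length could grant. The exhaustive
triple scan survives as the test oracle only
(`tests/oracles.brute_force_detect`), and the acceptance suite asserts
record-level equality between the two on random and element-bearing
genomes.

### Overlap resolution prefers the longest TSD

Among overlapping surviving candidates the detector keeps the one with the
longest TSD, then the longest element, then the leftmost start. Length
alone is the wrong primary key: for any element with a TSD of k ≥ 4, the
interval expanded by one base on each side necessarily shows a valid
(k−2)-bp TSD — both expanded flanks are interior bases of the *same*
duplication — and a TIR still within the mismatch budget, so a
longest-element rule would systematically absorb TSD bases into elements.
Ranking by TSD length first keeps the element/TSD boundary where the
duplication mechanism puts it.

## Clustering and annotation

Pooled canonical elements are clustered greedily: sort by length
descending (ties: sequence lexicographically, then accession/position); each
sequence joins the first cluster whose representative it matches at ≥80%
identity, else founds a new cluster. Identity is 1 − d/|shorter| where d is
the edit distance of the best semi-global alignment of the shorter sequence
inside the longer (edlib); this matches the "identity over the shorter
sequence" convention of greedy incremental clusterers at the contract
level without binding to any tool's word-filter heuristics. Longest-first
order makes the founder the longest member, so the representative invariant
holds by construction.

Annotation aligns each representative against every library record with
plain local alignment (match +1, mismatch −1, gap −2, via Biopython's
PairwiseAligner); a record qualifies at identity ≥0.8 over ≥50% of the
representative, the best identity wins, and family/superfamily are
inherited (cross-species records allowed; the source species is recorded).
No qualifying record ⇒ unclassified.

## Homology scan and the decay model

The second pass deliberately drops all structural requirements — most real
MITE copies have decayed past them — and keeps any region similar to a
representative: exact 11-mer seeds nominate diagonals; along each diagonal
the best-scoring contiguous segment (match +1, mismatch −μ with
μ = i/(1−i) at identity threshold i, Kadane's algorithm, flanking
mismatches trimmed) becomes a hit if it is ≥50 bp at ≥70% identity.
Same-cluster hits within 10 bp on one strand are merged; overlapping hits
from different clusters resolve to the higher identity. Structure is then
*re*-checked only to label categories: canonical (validator passes at the
locus), partial (representative coverage <0.8), else diverse.

The ungapped diagonal model matches the decay the generator implements:
substitutions and truncations, no indels. Copies decayed by indels would
fragment across diagonals and need a gapped extension; this is the main
known limitation for real data (v1 scope). Seed sensitivity: with 11-mer
seeds, a copy at identity q contains a clean seed with probability
≈1−(1−q¹¹)^(L−10), negligible miss rates for q ≥ 0.9 and L ≥ 50; the
worst-case guarantee (adversarially spaced mismatches) holds only for
q ≳ 0.98, which is why the oracle-equality tests plant perfect or lightly
decayed copies.

Homologous loci across accessions are matched by gene context, not
whole-genome alignment: hits grouped by (cluster, anchor gene + relation
kind), or by the flanking-gene pair for intergenic hits. Genes are the
positional markers because accession assemblies share gene IDs but not
coordinates.

## Interactions, MIP and expression

The association threshold is 40 nt *inclusive* between nearest interval
ends (0 = overlap), measured from element-only boundaries (TSDs excluded).
Sub-region classification is strand-aware: 5′/3′ and "last exon" follow
transcription direction; a hit touching exactly one sub-region is single,
several is spanning, with `spans_last_exon` set when both the last CDS exon
and the 3′UTR are touched. A hit near two genes yields one flagged record
per gene. Interactions with novel genes (absent from the reference
catalogue) are tracked via `gene_is_novel` and can be excluded by config.

The sharing histogram counts MITE-related genes by the number k of
accessions exhibiting the interaction; a gene absent from an accession's
annotation is excluded from that gene's k. Interaction value = gene
count × k.

Mann–Whitney U: the two-sided p is P(min(U_A, U_B) ≤ observed min) under
the permutation null. For combined n ≤ 20 without ties this is computed
from the exact null distribution of U (the standard counting recurrence);
with ties, by complete enumeration of the ≤ C(20,10) = 184 756 group
assignments; beyond, by scipy's normal approximation with tie and
continuity corrections. Both U_A and U_B are reported; the statistic is
their minimum. Per-gene p-values get Benjamini–Hochberg adjustment (raw
p-values are kept alongside). Normalization equalises per-accession medians
over the genes expressed in every accession (upper-quartile and identity
variants available); it preserves within-accession rank order. The pooled
comparison's unit is the (gene, accession) RPKM value; a per-gene-mean
variant is available.

## The synthetic generator

The generator is first-class study apparatus, not a fixture. One ancestral
genome (uniform random ACGT) carries a common gene layout (one transcript
per gene: 100 bp 5′UTR, three CDS exons of 200/150/250 bp, introns of
150/200 bp, 150 bp 3′UTR; strands random; TAIR-style shared IDs; a
configurable fraction flagged novel) and a pericentromeric
"heterochromatin" interval (central 20% by default, gene-free). Each
accession applies independent background substitutions (0.002/bp) and then
receives a per-insertion subset of the planted elements.

Defaults emulate the comparative study conditions: 19 accessions, five
chromosomes, ten MITE families with element lengths 120–600 bp (the
canonical range is 50–800; the lower end is raised so truncated fragments
stay detectable), TIRs 10–20 bp, TSDs 2–6 bp (short TSDs dominate in real
MITEs), 3–6 canonical copies plus 4–8 degenerate extras per family,
substitution decay 0.05, truncation probability 0.35, presence probability
0.8, half the families present in the reference library. Planted relations:
intron (0.35), spanning the last exon into the 3′UTR (0.20), upstream
within 40 nt (0.20), intergenic/none (0.25); unclassified families'
intergenic insertions fall in the heterochromatin interval with probability
0.8. Expression is log-normal (gene-level means log 10 ± 0.3, residual SD
0.6 on the log scale) with a 1.5× multiplicative shift for gene×accession
pairs carrying an association — calibrated so the with/without group means
land near the mid-teens vs ~11 RPKM regime typical of seedling
transcriptomes.

Choices the study conditions force, made once and documented here:

* **TSD semantics** — the TSD is sampled from the target site (duplication
  mechanism), not random, so flanks are biologically coherent. Insertion:
  `new = seq[:x+k] + element + seq[x:]`.
* **Guaranteed copies** — the first three canonical copies of each family
  are present in every accession. The copy-number filter is a
  *per-accession* constraint; without this floor, presence sampling would
  silently push accessions below three copies and detection of a perfectly
  planted element would rightly fail there.
* **Partial-fragment floor** — truncation fractions are uniform on
  [0.2, 0.8] of the element, floored at 60 bp: a fragment below the scan's
  50-bp minimum is invisible to any homology method at these thresholds.
* **Certain degradation of diverse copies** — at positive decay rates,
  three of a diverse copy's substitutions are placed at TIR offsets 1, 5
  and 8 (blowing the mismatch budget at every TIR length; suffix partners
  are excluded from the random substitution pool so decay cannot restore a
  pair) and one in the right TSD copy. This makes the
  canonical/diverse truth labels exact rather than probabilistic. At decay
  0 a diverse copy is identical to a canonical one, as the degenerate
  parameter demands.
* **Structure-clean planting** — decayed interiors and insertion contexts
  occasionally contain *chance* TIR+TSD structures which, replicated by a
  family's copy-number support, would be real canonical MITEs the truth
  table knows nothing about. The generator therefore (a) redraws family
  consensuses whose interiors admit any internal TIR+TSD candidate,
  (b) redraws decay and site when a diverse/partial copy would carry such a
  structure, and (c) rejects canonical sites where an overlapping candidate
  would outrank the planted element under the detector's resolution rule
  (including the mutated right TSD in the simulated context). Background
  substitutions are suppressed within ±130 bp of insertion points so these
  guarantees hold identically in every accession.
* **One insertion per gene** — gene-targeted insertions use distinct genes,
  keeping gene-level presence/absence equal to the per-insertion design
  (the MIP fidelity contract). Same-family intergenic insertions inside the
  gene-free heterochromatin block share a flanking-gene anchor and are
  intentionally conflated by the anchor-based grouping; group-level truth
  comparisons therefore use gene-anchored groups.
* **Decay drawn once per insertion** — carriers share the decayed sequence
  (homology by descent), which also makes spanning patterns consistent
  across accessions.

What the generator does **not** emulate, hence what passing tests do not
show about real data: indel decay and nested/fragmented insertions; element
families related to each other (families are drawn independently, so
between-family identity is ~random); assembly errors and N-runs;
RNA-seq count noise beyond log-normal dispersion (RPKM values are consumed,
never computed from reads); and real heterochromatin composition beyond a
single placement-bias interval.

## Numerical and determinism notes

* All coordinates are 1-based inclusive internally; BED export converts to
  0-based half-open at the boundary and nowhere else.
* Sequence identity conventions: Hamming (per-base over a full-length
  window) for copy counting and scan segments; edit-distance identity over
  the shorter sequence for clustering and flank comparisons; aligned-column
  identity for library annotation.
* Budgets use a 1e-9 epsilon before flooring so a mismatch fraction of
  exactly 0.1 qualifies.
* Mismatch fractions at exactly the boundary (1/10 TIR pairs, distance
  exactly 40) are accepted — thresholds are inclusive, covered by boundary
  tests either way.
* Every stochastic component takes a NumPy `Generator` or integer seed;
  identical seeds give byte-identical outputs (asserted in tests). Greedy
  procedures define total tie-break orders (documented at each function) so
  outputs are deterministic regardless of input order.
* Problem sizes in the test and acceptance runs — 19 accessions with five
  200-kb (tests) or 120-kb (acceptance script) chromosomes, ten families,
  twenty 8-kb oracle genomes, 300–500 calibration replicates — are desk
  scale by design: large enough for every pipeline behaviour to be
  exercised and calibrated, small enough to re-run anywhere. Genome-scale
  inputs are supported through the same API via external FASTA/GFF3 inputs.
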