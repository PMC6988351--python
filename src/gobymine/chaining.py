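"""Chain translated-homology hits (HSPs) into multi-exon gene models.

The mining procedure: drop weak hits by e-value, keep only the best hit
per genomic locus, then join hits from the same query protein into one
gene model when their protein coordinates advance with at most a small
overlap and their genomic spacing stays below an intron-scale bound.
Joined models are translated and length-filtered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

from Bio.Seq import Seq

from .io import GenomicInterval, HspRecord, SequenceRecord


@dataclass
class ChainingConfig:
    """Thresholds for hit filtering and exon chaining.

    ``max_evalue`` gates the input hit table; ``max_query_overlap_aa`` is
    the largest tolerated overlap (inclusive) between protein coordinate
    ranges of consecutive exons; ``max_genomic_gap_bp`` is a strict upper
    bound on the genomic distance between adjacent exons;
    ``min_protein_len_aa`` drops short predicted peptides.
    """

    max_evalue: float = 1e-50
    max_query_overlap_aa: int = 15
    max_genomic_gap_bp: int = 10_000
    min_protein_len_aa: int = 250

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be > 0")
        if min(self.max_query_overlap_aa, self.max_genomic_gap_bp,
               self.min_protein_len_aa) <= 0:
            raise ValueError("all chaining thresholds must be > 0")


@dataclass
class HomologFilter:
    """Homolog acceptance filter: coverage and identity are inclusive
    bounds, the e-value bound is strict."""

    min_query_coverage: float = 0.70
    min_identity: float = 0.40
    max_evalue: float = 1e-20

    def __post_init__(self) -> None:
        for frac in (self.min_query_coverage, self.min_identity):
            if not 0 < frac <= 1:
                raise ValueError("filter fractions must be in (0, 1]")


@dataclass
class GeneModel:
    """An ordered set of exons on one strand, with derived CDS/protein.

    ``exons`` are in transcription order: ascending genomic position on
    the plus strand, descending on the minus strand.
    """

    model_id: str
    contig: str
    strand: str
    exons: list[GenomicInterval]
    source_hsps: list[HspRecord] = field(default_factory=list)
    query_id: str = ""
    cds: Optional[str] = None
    protein: Optional[str] = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("a gene model needs at least one exon")
        if any(iv.contig != self.contig for iv in self.exons):
            raise ValueError("all exons must share the model's contig")
        starts = [iv.start for iv in self.exons]
        expected = sorted(starts, reverse=(self.strand == "-"))
        if starts != expected:
            raise ValueError("exons must be in transcription order")
        by_pos = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(by_pos, by_pos[1:]):
            if a.end > b.start:
                raise ValueError("exons must be pairwise disjoint")

    @property
    def genomic_span(self) -> GenomicInterval:
        return GenomicInterval(
            self.contig,
            min(iv.start for iv in self.exons),
            max(iv.end for iv in self.exons),
            self.strand,
        )


def _hsp_priority(h: HspRecord) -> tuple:
    # bit score desc, then evalue asc, query_id asc, genomic start asc
    return (-h.bit_score, h.evalue, h.query_id, h.interval.start)


def select_best_per_locus(
    hsps: Iterable[HspRecord], cfg: ChainingConfig
) -> list[HspRecord]:
    """Keep only the highest-scoring hit at each genomic locus.

    Hits above the configured e-value threshold are dropped first. Then,
    working from the highest bit score down, a hit is kept only if its
    genomic footprint overlaps no already-kept hit on the same contig
    (strand is ignored for the overlap test). Output is sorted by
    (contig, genomic start). Idempotent.
    """
    survivors: list[HspRecord] = []
    kept_by_contig: dict[str, list[GenomicInterval]] = {}
    for hsp in sorted((h for h in hsps if h.evalue <= cfg.max_evalue),
                      key=_hsp_priority):
        iv = hsp.interval
        if any(iv.overlaps(kept) for kept in kept_by_contig.get(iv.contig, [])):
            continue
        survivors.append(hsp)
        kept_by_contig.setdefault(iv.contig, []).append(iv)
    survivors.sort(key=lambda h: (h.interval.contig, h.interval.start))
    return survivors


def _transcription_sorted(hsps: list[HspRecord], strand: str) -> list[HspRecord]:
    return sorted(hsps, key=lambda h: h.interval.start, reverse=(strand == "-"))


def _joinable(prev: HspRecord, nxt: HspRecord, strand: str, cfg: ChainingConfig) -> bool:
    # (i) protein coordinates advance, overlap within bound
    if nxt.q_start <= prev.q_start:
        return False
    overlap = prev.q_end - nxt.q_start + 1
    if overlap > cfg.max_query_overlap_aa:
        return False
    # (ii) genomic gap strictly below the bound, measured between adjacent
    # exon boundaries in half-open coordinates, strand-aware
    if strand == "+":
        gap = nxt.interval.start - prev.interval.end
    else:
        gap = prev.interval.start - nxt.interval.end
    return 0 <= gap < cfg.max_genomic_gap_bp


def chain_hsps(hsps: Iterable[HspRecord], cfg: ChainingConfig) -> list[GeneModel]:
    """Join deduplicated HSPs into gene models.

    Hits are grouped by (contig, strand, query protein) and sorted in
    transcription order; each maximal run of consecutive hits satisfying
    the overlap and gap rules becomes one model. Singleton hits become
    single-exon models.
    """
    groups: dict[tuple[str, str, str], list[HspRecord]] = {}
    for h in hsps:
        groups.setdefault((h.subject_id, h.strand, h.query_id), []).append(h)

    models: list[GeneModel] = []
    for (contig, strand, query_id) in sorted(groups):
        ordered = _transcription_sorted(groups[(contig, strand, query_id)], strand)
        run: list[HspRecord] = [ordered[0]]
        runs: list[list[HspRecord]] = [run]
        for prev, nxt in zip(ordered, ordered[1:]):
            if _joinable(prev, nxt, strand, cfg):
                run.append(nxt)
            else:
                run = [nxt]
                runs.append(run)
        for i, members in enumerate(runs, start=1):
            model_id = f"{query_id}.{contig}.{strand}{i}"
            models.append(
                GeneModel(
                    model_id=model_id,
                    contig=contig,
                    strand=strand,
                    exons=[h.interval for h in members],
                    source_hsps=list(members),
                    query_id=query_id,
                )
            )
    models.sort(key=lambda m: (m.contig, m.genomic_span.start, m.model_id))
    return models


_STOPS = {"TAA", "TAG", "TGA"}


def _codons(seq: str) -> list[str]:
    return [seq[i : i + 3] for i in range(0, len(seq) - 2, 3)]


def _orfs(cds: str) -> list[tuple[int, int, bool, bool]]:
    """All ATG-initiated ORFs (start, end, has_start, has_stop) in 3 frames;
    end is exclusive and excludes the stop codon."""
    found = []
    for frame in range(3):
        start = None
        for i in range(frame, len(cds) - 2, 3):
            codon = cds[i : i + 3]
            if codon in _STOPS:
                if start is not None:
                    found.append((start, i, True, True))
                    start = None
            elif codon == "ATG" and start is None:
                start = i
        if start is not None:
            end = start + 3 * ((len(cds) - start) // 3)
            found.append((start, end, True, False))
    return found


def extract_and_translate(
    model: GeneModel, genome: Iterable[SequenceRecord]
) -> GeneModel:
    """Fill in the model's CDS and protein from the genome sequence.

    The CDS is the exon subsequences concatenated in transcription order
    (reverse-complemented on the minus strand). The protein is the
    translation of the longest ATG-initiated open reading frame across
    the three frames of the CDS; if no ATG exists, the longest stop-free
    stretch of frame 0 is used and ``no_start`` is flagged. ``internal_stop``
    flags a stop before the last codon of the frame-0 translation;
    ``no_stop`` flags a missing terminal stop for the chosen reading.
    """
    by_id = {rec.id: rec for rec in genome}
    if model.contig not in by_id:
        raise KeyError(f"contig {model.contig!r} not found in genome")
    contig_seq = by_id[model.contig].residues
    for iv in model.exons:
        if iv.end > len(contig_seq):
            raise ValueError(
                f"exon [{iv.start}, {iv.end}) beyond end of contig "
                f"{model.contig} (length {len(contig_seq)})"
            )
    pieces = [contig_seq[iv.start : iv.end] for iv in
              sorted(model.exons, key=lambda iv: iv.start)]
    cds = "".join(pieces)
    if model.strand == "-":
        cds = str(Seq(cds).reverse_complement())

    flags: set[str] = set()
    frame0 = _codons(cds)
    stop_positions = [i for i, c in enumerate(frame0) if c in _STOPS]
    if any(i < len(frame0) - 1 for i in stop_positions):
        flags.add("internal_stop")

    orfs = _orfs(cds)
    if orfs:
        start, end, _, has_stop = max(orfs, key=lambda o: (o[1] - o[0], -o[0]))
        protein = str(Seq(cds[start:end]).translate())
        if not has_stop:
            flags.add("no_stop")
    else:
        flags.add("no_start")
        # longest stop-free stretch of frame 0
        best, cur = (0, 0), [0, 0]
        for i, codon in enumerate(frame0 + ["TAA"]):
            if codon in _STOPS:
                if cur[1] - cur[0] > best[1] - best[0]:
                    best = tuple(cur)
                cur = [i + 1, i + 1]
            else:
                cur[1] = i + 1
        if not stop_positions or stop_positions[-1] != len(frame0) - 1:
            flags.add("no_stop")
        protein = str(
            Seq(cds[3 * best[0] : 3 * best[1]]).translate()
        )

    updated = replace(model)
    updated.cds = cds
    updated.protein = protein
    updated.flags = flags
    return updated


def filter_models(models: Iterable[GeneModel], cfg: ChainingConfig) -> list[GeneModel]:
    """Drop models whose predicted peptide is shorter than the minimum.

    A model of exactly ``min_protein_len_aa`` residues is retained; order
    is preserved. Untranslated models are an error.
    """
    out = []
    for m in models:
        if m.protein is None:
            raise ValueError(
                f"model {m.model_id} has no protein; run extract_and_translate first"
            )
        if len(m.protein) >= cfg.min_protein_len_aa:
            out.append(m)
    return out


def filter_orthologs(
    hsps: Iterable[HspRecord],
    query_lengths: Mapping[str, int],
    flt: HomologFilter,
) -> list[HspRecord]:
    """Apply the homolog acceptance filter to a hit table.

    Retains hits covering at least ``min_query_coverage`` of the query
    (inclusive), with percent identity at least ``min_identity``
    (inclusive), and e-value strictly below ``max_evalue``.
    """
    out = []
    for h in hsps:
        if h.query_id not in query_lengths:
            raise KeyError(f"no length recorded for query {h.query_id!r}")
        qlen = query_lengths[h.query_id]
        coverage_ok = (h.q_end - h.q_start + 1) / qlen >= flt.min_query_coverage
        identity_ok = h.pct_identity / 100.0 >= flt.min_identity
        evalue_ok = h.evalue < flt.max_evalue
        if coverage_ok and identity_ok and evalue_ok:
            out.append(h)
    return out
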