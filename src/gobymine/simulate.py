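"""Synthetic data generators for every pipeline stage.

These generators emit genomes with implanted multi-exon gene-family
members (plus the matching translated-search hit tables), phylogenies
with planted same-species clades, and RAD count matrices with optional
sex-linked loci — each a pure function of its spec and seed, with the
ground truth returned alongside so analysis results can be checked
exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenomicInterval, HspRecord, PresenceMatrix, SequenceRecord
from .chaining import GeneModel

_BASES = np.array(list("ACGT"))
#: the 61 sense codons of the standard code
_SENSE_CODONS = [
    "".join(c) for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in ("TAA", "TAG", "TGA")
]


# ---------------------------------------------------------------------------
# genomes with implanted gene families


@dataclass
class GeneFamilySpec:
    """One implanted family: copy number, exon structure, strand policy."""

    family: str
    n_copies: int = 1
    n_exons: int = 3
    exon_len_aa: tuple[int, int] = (60, 120)
    intron_len_bp: tuple[int, int] = (200, 2000)
    strand_policy: str = "random"  # random | + | -

    def __post_init__(self) -> None:
        if self.exon_len_aa[0] <= 0 or self.intron_len_bp[0] <= 0:
            raise ValueError("exon and intron length ranges must be positive")
        if self.strand_policy not in ("random", "+", "-"):
            raise ValueError(f"bad strand policy {self.strand_policy!r}")


@dataclass
class GenomeSimSpec:
    seed: int = 0
    n_contigs: int = 2
    contig_length_bp: int = 100_000
    gc_fraction: float = 0.41
    genes: list[GeneFamilySpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")


@dataclass
class ImplantedGene:
    """Ground truth for one implanted gene copy.

    ``exons`` are in transcription order; the final exon carries the
    stop codon, so extracting and translating the intervals reproduces
    ``protein`` exactly.
    """

    gene_id: str
    family: str
    contig: str
    strand: str
    exons: list[GenomicInterval]
    exon_aa_bounds: list[tuple[int, int]]  # 0-based aa [start, end) per exon
    protein: str


@dataclass
class ImplantTruth:
    genes: list[ImplantedGene]
    contig_lengths: dict[str, int]

    def as_models(self) -> list[GeneModel]:
        return [
            GeneModel(
                model_id=g.gene_id,
                contig=g.contig,
                strand=g.strand,
                exons=list(g.exons),
                query_id=g.gene_id,
                protein=g.protein,
            )
            for g in self.genes
        ]


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=length, p=probs))


def simulate_genome_with_families(
    spec: GenomeSimSpec,
) -> tuple[list[SequenceRecord], ImplantTruth]:
    """Generate a genome FASTA with implanted multi-exon genes plus truth.

    Implanted coding sequence is built codon-first (ATG, then sense
    codons, then a stop), split into exons at codon boundaries and
    interleaved with introns; copies are placed left to right with
    random intergenic spacers and never overlap. Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    contigs = {
        f"ctg{i + 1}": list(_random_dna(rng, spec.contig_length_bp, spec.gc_fraction))
        for i in range(spec.n_contigs)
    }
    cursors = {name: 0 for name in contigs}
    contig_cycle = itertools.cycle(sorted(contigs))
    genes: list[ImplantedGene] = []

    for fam in spec.genes:
        for copy in range(fam.n_copies):
            gene_id = f"{fam.family}_{copy + 1}"
            exon_aa = [
                int(rng.integers(fam.exon_len_aa[0], fam.exon_len_aa[1] + 1))
                for _ in range(fam.n_exons)
            ]
            n_aa = sum(exon_aa)
            codons = ["ATG"] + [
                _SENSE_CODONS[i]
                for i in rng.integers(0, len(_SENSE_CODONS), size=n_aa - 1)
            ]
            cds = "".join(codons)
            stop = "TAA"
            bounds = []
            aa_cursor = 0
            for e in exon_aa:
                bounds.append((aa_cursor, aa_cursor + e))
                aa_cursor += e
            # exon nucleotide pieces; stop codon rides on the last exon
            pieces = [cds[3 * a : 3 * b] for a, b in bounds]
            pieces[-1] += stop
            introns = [
                _random_dna(
                    rng,
                    int(rng.integers(fam.intron_len_bp[0], fam.intron_len_bp[1] + 1)),
                    spec.gc_fraction,
                )
                for _ in range(fam.n_exons - 1)
            ]
            block_parts = [pieces[0]]
            local_exons = [(0, len(pieces[0]))]
            offset = len(pieces[0])
            for intron, piece in zip(introns, pieces[1:]):
                offset += len(intron)
                block_parts.append(intron)
                block_parts.append(piece)
                local_exons.append((offset, offset + len(piece)))
                offset += len(piece)
            block = "".join(block_parts)

            strand = fam.strand_policy
            if strand == "random":
                strand = "+" if rng.random() < 0.5 else "-"
            # placement
            contig = next(contig_cycle)
            spacer = int(rng.integers(500, 1501))
            start = cursors[contig] + spacer
            if start + len(block) > len(contigs[contig]):
                raise ValueError(
                    f"cannot place {gene_id} on {contig}: out of space; "
                    "use longer contigs or fewer/smaller genes"
                )
            if strand == "-":
                placed = _revcomp(block)
                exon_ivs = [
                    GenomicInterval(
                        contig,
                        start + len(block) - e_end,
                        start + len(block) - e_start,
                        "-",
                    )
                    for e_start, e_end in local_exons
                ]
            else:
                placed = block
                exon_ivs = [
                    GenomicInterval(contig, start + a, start + b, "+")
                    for a, b in local_exons
                ]
            contigs[contig][start : start + len(block)] = list(placed)
            cursors[contig] = start + len(block)
            protein = _translate(cds)
            genes.append(
                ImplantedGene(
                    gene_id=gene_id,
                    family=fam.family,
                    contig=contig,
                    strand=strand,
                    exons=exon_ivs,
                    exon_aa_bounds=bounds,
                    protein=protein,
                )
            )

    records = [
        SequenceRecord(id=name, residues="".join(seq), alphabet="dna")
        for name, seq in sorted(contigs.items())
    ]
    truth = ImplantTruth(
        genes=genes,
        contig_lengths={name: len(seq) for name, seq in contigs.items()},
    )
    return records, truth


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _translate(cds: str) -> str:
    from Bio.Seq import Seq

    protein = str(Seq(cds).translate())
    return protein.rstrip("*")


# ---------------------------------------------------------------------------
# HSP emission


def emit_truth_hsps(
    truth: ImplantTruth,
    split_prob: float = 0.0,
    spurious_rate: float = 0.0,
    score_jitter: float = 0.0,
    seed: int = 0,
) -> list[HspRecord]:
    """Emit the translated-search hit table implied by the truth.

    One hit per exon, with protein coordinates matching the exon's amino
    acid span. With probability ``split_prob`` an exon's hit is split in
    two genomically abutting pieces whose query ranges overlap by up to
    15 aa (still chainable). ``spurious_rate`` is the expected number of
    decoy hits, placed in intergenic background with weak scores and
    e-values above the default chaining gate; true-hit bit scores always
    exceed spurious ones by construction.
    """
    rng = np.random.default_rng(seed)
    hsps: list[HspRecord] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for gene in truth.genes:
        exon_order = gene.exons  # transcription order
        for iv, (aa_start, aa_end) in zip(exon_order, gene.exon_aa_bounds):
            occupied.setdefault(gene.contig, []).append((iv.start, iv.end))
            pieces = [((aa_start, aa_end), iv)]
            aa_len = aa_end - aa_start
            if rng.random() < split_prob and aa_len >= 30:
                m = int(rng.integers(10, aa_len - 10))
                overlap = int(rng.integers(1, 16))
                overlap = min(overlap, m - 1)
                if gene.strand == "+":
                    iv1 = GenomicInterval(iv.contig, iv.start, iv.start + 3 * m, "+")
                    iv2 = GenomicInterval(iv.contig, iv.start + 3 * m, iv.end, "+")
                else:
                    iv1 = GenomicInterval(iv.contig, iv.end - 3 * m, iv.end, "-")
                    iv2 = GenomicInterval(iv.contig, iv.start, iv.end - 3 * m, "-")
                pieces = [
                    ((aa_start, aa_start + m), iv1),
                    ((aa_start + m - overlap, aa_end), iv2),
                ]
            for (qa, qb), piv in pieces:
                n_aa = qb - qa
                bit = 2.0 * n_aa + float(rng.uniform(0, score_jitter or 1e-9))
                evalue = float(10 ** (-80 + rng.uniform(0, 10)))
                if gene.strand == "+":
                    s_start, s_end = piv.start + 1, piv.end
                else:
                    s_start, s_end = piv.end, piv.start + 1
                hsps.append(
                    HspRecord(
                        query_id=gene.gene_id,
                        subject_id=gene.contig,
                        pct_identity=100.0,
                        aln_len=n_aa,
                        q_start=qa + 1,
                        q_end=qb,
                        s_start=s_start,
                        s_end=s_end,
                        evalue=evalue,
                        bit_score=round(bit, 1),
                    )
                )
    n_spurious = int(rng.poisson(spurious_rate))
    contig_names = sorted(truth.contig_lengths)
    for i in range(n_spurious):
        contig = contig_names[int(rng.integers(0, len(contig_names)))]
        clen = truth.contig_lengths[contig]
        span = int(rng.integers(90, 300))
        for _ in range(50):
            start = int(rng.integers(0, max(1, clen - span)))
            if not any(
                start < e and s < start + span
                for s, e in occupied.get(contig, [])
            ):
                break
        else:  # pragma: no cover - saturated contig
            continue
        hsps.append(
            HspRecord(
                query_id=f"decoy_{i + 1}",
                subject_id=contig,
                pct_identity=float(rng.uniform(25, 40)),
                aln_len=span // 3,
                q_start=1,
                q_end=span // 3,
                s_start=start + 1,
                s_end=start + span,
                evalue=float(10 ** rng.uniform(-8, -2)),
                bit_score=round(float(rng.uniform(25, 35)), 1),
            )
        )
    return hsps


def write_hsp_table(hsps: Sequence[HspRecord], path) -> None:
    """Write hits as 12-column BLAST tabular (outfmt 6)."""
    with open(path, "w") as fh:
        for h in hsps:
            mismatches = int(round(h.aln_len * (1 - h.pct_identity / 100)))
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.1f}\t"
                f"{h.aln_len}\t{mismatches}\t0\t{h.q_start}\t{h.q_end}\t"
                f"{h.s_start}\t{h.s_end}\t{h.evalue:.2e}\t{h.bit_score:.1f}\n"
            )


# ---------------------------------------------------------------------------
# expansion trees


@dataclass
class PlantedClade:
    species: str
    leaves: list[str]


@dataclass
class SimulatedTree:
    newick: str
    leaf_to_species: dict[str, str]
    planted: list[PlantedClade]


def _random_binary(
    rng: np.random.Generator, leaf_names: list[str]
) -> str:
    """Random binary topology (successive random joins), newick body."""
    nodes = [name for name in leaf_names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        bl_a, bl_b = rng.uniform(0.05, 1.0, size=2)
        joined = f"({a}:{bl_a:.4f},{b}:{bl_b:.4f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(joined)
    return nodes[0]


def simulate_expansion_tree(
    species: Sequence[str],
    plant: Sequence[tuple[str, int]] = (),
    background_leaves: int = 20,
    seed: int = 0,
) -> SimulatedTree:
    """Random species-labeled gene tree with planted monospecific clades.

    Background leaves draw species uniformly; each planted clade is a
    random monospecific subtree grafted onto the backbone as a unit, so
    it is monophyletic by construction. Deterministic per seed.
    """
    if not species and not plant:
        raise ValueError("need at least one species")
    rng = np.random.default_rng(seed)
    leaf_to_species: dict[str, str] = {}
    units: list[str] = []
    for i in range(background_leaves):
        sp = species[int(rng.integers(0, len(species)))]
        name = f"bg{i + 1}"
        leaf_to_species[name] = sp
        units.append(name)
    planted: list[PlantedClade] = []
    for k, (sp, size) in enumerate(plant, start=1):
        if size < 1:
            raise ValueError("planted clade sizes must be >= 1")
        leaves = [f"{sp}_exp{k}_{i + 1}" for i in range(size)]
        for leaf in leaves:
            leaf_to_species[leaf] = sp
        units.append(_random_binary(rng, leaves) if size > 1 else leaves[0])
        planted.append(PlantedClade(species=sp, leaves=leaves))
    newick = _random_binary(rng, units) + ";"
    return SimulatedTree(
        newick=newick, leaf_to_species=leaf_to_species, planted=planted
    )


# ---------------------------------------------------------------------------
# RAD matrices


@dataclass
class RadSimSpec:
    """Emulates a two-sex RAD design (default 47 males / 45 females)."""

    seed: int = 0
    n_males: int = 47
    n_females: int = 45
    n_loci: int = 1000
    mean_reads_per_sample: int = 500_000
    dropout_rate: float = 0.0
    n_sex_linked: int = 0
    linked_sex: str = "male"

    def __post_init__(self) -> None:
        if self.n_sex_linked > self.n_loci:
            raise ValueError("n_sex_linked must not exceed n_loci")
        if self.linked_sex not in ("male", "female"):
            raise ValueError("linked_sex must be male or female")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


def simulate_rad_matrix(spec: RadSimSpec) -> tuple[PresenceMatrix, list[str]]:
    """RAD locus x sample count matrix with optional sex-linked loci.

    Background loci are present in every sample (count at least 1) apart
    from random dropout; sex-linked loci have positive counts in samples
    of the linked sex and zeros in the other sex (dropout is applied to
    background loci only). Returns the matrix and the truth list of
    sex-linked locus ids.
    """
    rng = np.random.default_rng(spec.seed)
    samples = [f"m{i + 1}" for i in range(spec.n_males)] + [
        f"f{i + 1}" for i in range(spec.n_females)
    ]
    sex = {s: ("male" if s.startswith("m") else "female") for s in samples}
    loci = [f"locus{i + 1:06d}" for i in range(spec.n_loci)]
    lam = max(spec.mean_reads_per_sample / spec.n_loci - 1.0, 0.0)
    counts = 1 + rng.poisson(lam, size=(spec.n_loci, len(samples)))

    linked_idx = sorted(
        int(i) for i in rng.choice(spec.n_loci, size=spec.n_sex_linked, replace=False)
    )
    linked_set = set(linked_idx)
    if spec.dropout_rate > 0:
        drop = rng.random(counts.shape) < spec.dropout_rate
        drop[linked_idx, :] = False
        counts[drop] = 0
    linked_cols = np.array(
        [sex[s] != spec.linked_sex for s in samples], dtype=bool
    )
    for i in linked_set:
        counts[i, linked_cols] = 0

    matrix = PresenceMatrix(
        counts=pd.DataFrame(counts, index=loci, columns=samples),
        sex=sex,
    )
    return matrix, [loci[i] for i in linked_idx]


def write_counts_tsv(matrix: PresenceMatrix, counts_path, sex_path) -> None:
    """Write a dense counts TSV and the two-column sex TSV."""
    out = matrix.counts.copy()
    out.index.name = "locus"
    out.to_csv(counts_path, sep="\t")
    with open(sex_path, "w") as fh:
        for sample in matrix.samples:
            fh.write(f"{sample}\t{matrix.sex[sample]}\n")
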