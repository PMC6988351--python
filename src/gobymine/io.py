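"""Readers and writers for the standard formats the toolkit touches.

All internal coordinates are 0-based, half-open, on the forward strand.
Formats that use 1-based inclusive coordinates (BLAST tabular, GFF3)
are converted at the I/O boundary and nowhere else.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Optional, Union

import pandas as pd
from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .chaining import GeneModel

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

# IUPAC alphabets, ambiguity codes included; '*' marks a stop in protein
# FASTA and '-' an alignment gap.
DNA_ALPHABET = set("ACGTUNRYSWKMBDHV-")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBJXZUO*-")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class NewickParseError(FormatError):
    """Newick syntax error; carries the character offset of the problem."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


# ---------------------------------------------------------------------------
# sequences


@dataclass
class SequenceRecord:
    """A named nucleotide or amino-acid sequence."""

    id: str
    residues: str
    description: str = ""
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        allowed = DNA_ALPHABET if self.alphabet == "dna" else PROTEIN_ALPHABET
        bad = sorted(set(self.residues.upper()) - allowed)
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains characters outside the "
                f"{self.alphabet} alphabet: {''.join(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: PathLike, alphabet: str = "dna") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Residues are concatenated across wrapped lines; record order is
    preserved. Duplicate ids, empty sequences and residues outside the
    declared alphabet are errors.
    """
    if alphabet not in ("dna", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=str(rec.seq).upper(),
                description=desc,
                alphabet=alphabet,
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# genomic intervals and HSPs


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a contig, with strand."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class HspRecord:
    """One translated-homology local alignment (protein query vs genomic subject).

    Coordinates are kept in the native BLAST convention (1-based inclusive);
    a subject start greater than the subject end encodes the minus strand.
    ``interval`` exposes the normalized forward-strand genomic footprint.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(
                f"q_start {self.q_start} > q_end {self.q_end} for {self.query_id}"
            )
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if self.bit_score < 0:
            raise ValueError("bit score must be non-negative")

    @property
    def strand(self) -> str:
        return "+" if self.s_start <= self.s_end else "-"

    @property
    def interval(self) -> GenomicInterval:
        lo, hi = sorted((self.s_start, self.s_end))
        return GenomicInterval(self.subject_id, lo - 1, hi, self.strand)


_OUTFMT6_COLS = 12


def read_hsp_table(path: PathLike) -> list[HspRecord]:
    """Parse a 12-column BLAST tabular (outfmt 6) file.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore. ``#`` comment lines are skipped; the
    mismatch and gapopen columns are parsed but not retained.
    """
    records: list[HspRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _OUTFMT6_COLS:
                raise FormatError(
                    f"expected {_OUTFMT6_COLS} columns at line {lineno}, "
                    f"got {len(fields)}"
                )
            try:
                records.append(
                    HspRecord(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        aln_len=int(fields[3]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        evalue=float(fields[10]),
                        bit_score=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(
                    f"malformed numeric field at line {lineno}: {exc}"
                ) from exc
    return records


def write_gff3(models: "Iterable[GeneModel]", path: PathLike, source: str = "gobymine") -> None:
    """Write gene models as GFF3 (gene/mRNA/exon features, 1-based inclusive).

    Models are emitted sorted by (contig, genomic start) for determinism.
    Overlapping exons within one model are an upstream invariant violation
    and rejected here as a last line of defense.
    """
    models = list(models)
    for m in models:
        ivs = sorted(m.exons, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if a.end > b.start:
                raise ValueError(f"model {m.model_id} has overlapping exons")
    models.sort(key=lambda m: (m.contig, min(iv.start for iv in m.exons)))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            g_start = min(iv.start for iv in m.exons) + 1
            g_end = max(iv.end for iv in m.exons)
            attrs = f"ID={m.model_id}"
            fh.write(
                f"{m.contig}\t{source}\tgene\t{g_start}\t{g_end}\t.\t"
                f"{m.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{m.contig}\t{source}\tmRNA\t{g_start}\t{g_end}\t.\t"
                f"{m.strand}\t.\tID={m.model_id}.t1;Parent={m.model_id}\n"
            )
            for i, iv in enumerate(sorted(m.exons, key=lambda iv: iv.start), 1):
                fh.write(
                    f"{m.contig}\t{source}\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{m.strand}\t.\tID={m.model_id}.e{i};Parent={m.model_id}.t1\n"
                )


# ---------------------------------------------------------------------------
# trees


@dataclass
class TreeNode:
    """Node of a rooted tree; leaves have a name, internals may carry one."""

    name: Optional[str] = None
    branch_length: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        stack = [self]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return out

    @property
    def support(self) -> Optional[float]:
        """Internal-node label interpreted as a support value, if numeric."""
        if self.is_leaf or not self.name:
            return None
        try:
            return float(self.name)
        except ValueError:
            return None


@dataclass
class SpeciesTree:
    """A rooted tree with (optionally) species-labeled leaves."""

    root: TreeNode
    leaf_species: dict[str, str] = field(default_factory=dict)

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def leaf_names(self) -> list[str]:
        return [leaf.name or "" for leaf in self.leaves()]

    def to_newick(self) -> str:
        return serialize_newick(self)


_NWK_SPECIAL = set("(),:;[]'")


def parse_newick(text: str) -> SpeciesTree:
    """Parse a Newick string into a :class:`SpeciesTree`.

    Supports branch lengths, internal labels (used for bootstrap support)
    and single-quoted labels. Syntax errors raise
    :class:`NewickParseError` with the character offset.
    """
    pos = 0
    n = len(text)

    def skip_ws() -> None:
        nonlocal pos
        while pos < n and text[pos].isspace():
            pos += 1

    def parse_label() -> Optional[str]:
        nonlocal pos
        skip_ws()
        if pos < n and text[pos] == "'":
            end = text.find("'", pos + 1)
            if end < 0:
                raise NewickParseError("unterminated quoted label", pos)
            label = text[pos + 1 : end]
            pos = end + 1
            return label
        start = pos
        while pos < n and not text[pos].isspace() and text[pos] not in _NWK_SPECIAL:
            pos += 1
        return text[start:pos] if pos > start else None

    def parse_branch_length() -> Optional[float]:
        nonlocal pos
        skip_ws()
        if pos < n and text[pos] == ":":
            pos += 1
            start = pos
            while pos < n and (text[pos].isdigit() or text[pos] in ".eE+-"):
                pos += 1
            try:
                return float(text[start:pos])
            except ValueError:
                raise NewickParseError("malformed branch length", start) from None
        return None

    def parse_subtree() -> TreeNode:
        nonlocal pos
        skip_ws()
        if pos < n and text[pos] == "(":
            open_at = pos
            pos += 1
            children = [parse_subtree()]
            skip_ws()
            while pos < n and text[pos] == ",":
                pos += 1
                children.append(parse_subtree())
                skip_ws()
            if pos >= n or text[pos] != ")":
                raise NewickParseError("unbalanced parentheses", open_at)
            pos += 1
            node = TreeNode(name=parse_label(), children=children)
        else:
            name = parse_label()
            if name is None:
                raise NewickParseError("expected a leaf label", pos)
            node = TreeNode(name=name)
        node.branch_length = parse_branch_length()
        return node

    root = parse_subtree()
    skip_ws()
    if pos >= n or text[pos] != ";":
        raise NewickParseError("expected ';' at end of tree", pos)
    pos += 1
    skip_ws()
    if pos != n:
        raise NewickParseError("trailing characters after ';'", pos)

    names = [leaf.name for leaf in root.leaves()]
    dupes = {x for x in names if names.count(x) > 1}
    if dupes:
        raise FormatError(f"duplicate leaf names: {sorted(dupes)}")
    return SpeciesTree(root=root)


def _min_leaf(node: TreeNode) -> str:
    return min(leaf.name or "" for leaf in node.leaves())


def serialize_newick(tree: SpeciesTree) -> str:
    """Serialize with children ordered by smallest descendant leaf name."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            body = node.name or ""
        else:
            parts = sorted(node.children, key=_min_leaf)
            body = "(" + ",".join(fmt(c) for c in parts) + ")"
            if node.name:
                body += node.name
        if node.branch_length is not None:
            body += f":{node.branch_length:g}"
        return body

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# RAD count matrices


@dataclass
class PresenceMatrix:
    """RAD locus x sample read counts with per-sample sex labels."""

    counts: pd.DataFrame  # index: loci, columns: samples
    sex: dict[str, str]  # sample -> male | female | unknown

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("read counts must be non-negative")
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate locus id {dup!r}")
        for sample in self.counts.columns:
            if sample not in self.sex:
                self.sex[sample] = "unknown"
        bad = {s for s in self.sex.values()} - {"male", "female", "unknown"}
        if bad:
            raise ValueError(f"invalid sex labels: {sorted(bad)}")

    @property
    def loci(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of_sex(self, sex: str) -> list[str]:
        return [s for s in self.samples if self.sex.get(s) == sex]


_LONG_HEADERS = {("locus", "sample", "count"), ("locus_id", "sample_id", "count")}


def read_counts_matrix(path: PathLike, sex_path: PathLike) -> PresenceMatrix:
    """Read a locus x sample read-count table plus a two-column sex file.

    Accepts either a dense TSV (locus ids in the first column, sample ids
    in the header) or a long-format (locus, sample, count) triple file,
    auto-detected from the header. Samples missing from the sex file are
    labeled ``unknown`` with a logged warning.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if tuple(h.strip().lower() for h in header) in _LONG_HEADERS:
        long_df = pd.read_csv(path, sep="\t")
        long_df.columns = [c.strip().lower() for c in long_df.columns]
        if (long_df["count"] < 0).any():
            raise ValueError("read counts must be non-negative")
        counts = (
            long_df.pivot_table(
                index="locus", columns="sample", values="count",
                aggfunc="sum", fill_value=0,
            )
            .astype(int)
        )
        counts = counts.loc[
            pd.unique(long_df["locus"]), pd.unique(long_df["sample"])
        ]
    else:
        counts = pd.read_csv(path, sep="\t", index_col=0)
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()][0]
            raise FormatError(f"duplicate locus id {dup!r}")
        counts = counts.astype(int)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)

    sex = {}
    with open(sex_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"expected 2 columns in sex file at line {lineno}"
                )
            value = fields[1].strip().lower()
            if lineno == 1 and value not in ("male", "female", "unknown"):
                continue  # header line
            sex[fields[0].strip()] = value
    missing = [s for s in counts.columns if s not in sex]
    if missing:
        logger.warning(
            "samples missing from sex file, labeled unknown: %s", ", ".join(missing)
        )
        warnings.warn(
            f"samples missing from sex file labeled unknown: {missing}",
            stacklevel=2,
        )
    return PresenceMatrix(counts=counts, sex=sex)
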