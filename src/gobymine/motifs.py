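"""PROSITE-style motif scanning and motif/domain-based gene classification.

Covers the cytochrome P450 completeness calls (four conserved motifs:
I-helix, K-helix, meander coil, heme loop), NLR-C group assignment by
Walker A motif plus PYD/B30.2 domain presence, top-scoring-domain
assignment, and the PYD-followed-by-adjacent-CARD (ASC) architecture
screen.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .io import SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"


class PatternSyntaxError(ValueError):
    """Raised for an unparseable motif pattern, quoting the bad token."""


@dataclass(frozen=True)
class PrositePattern:
    """A deterministic sequence motif in PROSITE syntax.

    Elements are separated by ``-``: a literal residue, the wildcard
    ``x``, ``[..]`` alternatives, ``{..}`` exclusions, repetition
    ``(n)`` / ``(n,m)`` after an element, and ``<`` / ``>`` anchors.
    One extension beyond standard PROSITE: a standalone ``(AB/CD)``
    element matches one of several multi-residue alternatives, which the
    Walker A group motifs require.
    """

    name: str
    pattern: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "_regex", _compile_prosite(self.pattern))

    @property
    def regex(self) -> "re.Pattern[str]":
        return self._regex  # type: ignore[attr-defined]


_ELEMENT_RE = re.compile(
    r"(?P<body>x|[A-WYZ]|\[[A-Z]+\]|\{[A-Z]+\}|\((?P<alts>[A-Z]+(/[A-Z]+)+)\))"
    r"(\((?P<lo>\d+)(,(?P<hi>\d+))?\))?$"
)


def _compile_prosite(pattern: str) -> "re.Pattern[str]":
    text = pattern.strip().rstrip(".")
    if not text:
        raise PatternSyntaxError("empty pattern")
    anchored_start = text.startswith("<")
    anchored_end = text.endswith(">")
    text = text.lstrip("<").rstrip(">").strip("-")
    parts: list[str] = []
    for token in text.split("-"):
        m = _ELEMENT_RE.match(token)
        if not m:
            raise PatternSyntaxError(f"unparseable pattern element {token!r}")
        body = m.group("body")
        if body == "x":
            piece = "."
        elif body.startswith("["):
            piece = body
        elif body.startswith("{"):
            piece = "[^" + body[1:-1] + "]"
        elif m.group("alts"):
            piece = "(?:" + "|".join(m.group("alts").split("/")) + ")"
        else:
            piece = body
        lo, hi = m.group("lo"), m.group("hi")
        if lo and hi:
            piece += f"{{{lo},{hi}}}"
        elif lo:
            piece += f"{{{lo}}}"
        parts.append(piece)
    regex = "".join(parts)
    if anchored_start:
        regex = r"\A" + regex
    if anchored_end:
        regex += r"\Z"
    return re.compile(regex)


@dataclass(frozen=True)
class MotifHit:
    """A located motif match on a protein; 0-based half-open coordinates."""

    motif_name: str
    protein_id: str
    start: int
    end: int
    matched_text: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("invalid motif hit coordinates")
        if len(self.matched_text) != self.end - self.start:
            raise ValueError("matched_text length disagrees with coordinates")


def scan_motifs(
    protein: SequenceRecord, patterns: Iterable[PrositePattern]
) -> list[MotifHit]:
    """Report all non-overlapping leftmost matches of each pattern."""
    if protein.alphabet != "protein":
        raise ValueError("scan_motifs expects a protein sequence")
    hits: list[MotifHit] = []
    seq = protein.residues
    for pat in patterns:
        for m in pat.regex.finditer(seq):
            if m.end() == m.start():
                continue
            hits.append(
                MotifHit(
                    motif_name=pat.name,
                    protein_id=protein.id,
                    start=m.start(),
                    end=m.end(),
                    matched_text=m.group(0),
                )
            )
    return hits


# ---------------------------------------------------------------------------
# cytochrome P450 completeness


#: Surrogate patterns with the canonical consensus shapes of the four
#: conserved CYP motifs; override from config for a specific curation.
DEFAULT_CYP_MOTIFS = [
    PrositePattern("I-helix", "[AG]-G-x-[DE]-T-[TS]"),
    PrositePattern("K-helix", "E-x-x-R"),
    PrositePattern("meander", "P-x-R-[FWH]"),
    PrositePattern("heme-loop", "F-x-x-G-x-x-x-C-x-G"),
]


@dataclass
class CypCallRules:
    """Completeness rules: ~full_length_aa (+/- tolerance) with start and
    stop plus an HMM match is "complete"; all four motifs present but
    clearly shorter is "partial"; a missing motif makes a "fragment"."""

    required_motifs: frozenset[str] = frozenset(
        {"I-helix", "K-helix", "meander", "heme-loop"}
    )
    full_length_aa: int = 500
    tolerance_aa: int = 50
    core_region_aa: int = 120
    require_start: bool = True
    require_stop: bool = True

    def __post_init__(self) -> None:
        if self.core_region_aa >= self.full_length_aa:
            raise ValueError("core_region_aa must be < full_length_aa")


def classify_cyp(
    protein: SequenceRecord,
    hits: Sequence[MotifHit],
    rules: CypCallRules,
    has_hmm_match: bool,
    flags: frozenset[str] = frozenset(),
) -> str:
    """Classify one candidate CYP as complete, partial or fragment.

    ``flags`` carries translation flags of the underlying gene model
    (``no_stop`` in particular); a protein not beginning with M counts
    as missing its start codon.
    """
    present = {h.motif_name for h in hits if h.protein_id == protein.id}
    if not rules.required_motifs <= present:
        return "fragment"
    length = len(protein.residues)
    in_band = abs(length - rules.full_length_aa) <= rules.tolerance_aa
    has_start = protein.residues.startswith("M") or not rules.require_start
    has_stop = "no_stop" not in flags or not rules.require_stop
    if in_band and has_start and has_stop and has_hmm_match:
        return "complete"
    return "partial"


# ---------------------------------------------------------------------------
# domain-based calls


@dataclass
class DomainAnnotation:
    """Ordered domain matches (name, start, end, score) on one protein."""

    protein_id: str
    domains: list[tuple[str, int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.domains = sorted(self.domains, key=lambda d: (d[1], d[2], d[0]))

    def names(self) -> list[str]:
        return [d[0] for d in self.domains]


def assign_best_domain(ann: DomainAnnotation) -> str:
    """Name of the maximum-score domain; ties break by start, then name."""
    if not ann.domains:
        raise ValueError(f"no domains annotated on {ann.protein_id!r}")
    return min(ann.domains, key=lambda d: (-d[3], d[1], d[0]))[0]


# ---------------------------------------------------------------------------
# NLR-C groups (Walker A motif + PYD/B30.2 allowances)


@dataclass(frozen=True)
class NlrGroupSpec:
    """One NLR-C group: its conserved Walker A motif and whether members
    may carry an N-terminal PYD and/or a C-terminal B30.2 domain."""

    group_id: int
    walker_a_pattern: PrositePattern
    pyd_allowed: bool
    b30_2_allowed: bool


#: The six NLR-C groups. Variable positions written (A/V) in the source
#: notation become [AV]; multi-residue alternatives like (IP/TA) use the
#: extended alternation element; a leading x is one arbitrary residue.
DEFAULT_NLR_GROUPS = [
    NlrGroupSpec(1, PrositePattern(
        "walkerA-g1", "G-I-A-G-V-G-K-T-L-[IM]-P-V-V-K-N-T-[TR]-R-A"),
        pyd_allowed=True, b30_2_allowed=True),
    NlrGroupSpec(2, PrositePattern(
        "walkerA-g2", "G-V-A-G-I-G-K-S-L-S-A-V-I-K-T-S-K-R-A"),
        pyd_allowed=True, b30_2_allowed=True),
    NlrGroupSpec(3, PrositePattern(
        "walkerA-g3", "G-I-A-G-I-G-K-T-L-(IP/TA)-A-V-[RS]-N-C-(RK/TR/RR)-A"),
        pyd_allowed=False, b30_2_allowed=True),
    NlrGroupSpec(4, PrositePattern(
        "walkerA-g4", "G-V-A-G-I-G-K-T-L-P-V-[IV]-x-x-x-x-[AV]-x"),
        pyd_allowed=False, b30_2_allowed=False),
    NlrGroupSpec(5, PrositePattern(
        "walkerA-g5", "x-G-V-A-G-[VI]-G-K-T-[LM]-P-V-[VI]-K-A-S-x-K-[AV]"),
        pyd_allowed=True, b30_2_allowed=True),
    NlrGroupSpec(6, PrositePattern(
        "walkerA-g6", "x-G-V-A-G-V-G-K-T-L-[IV]-P-[AV]-V-R-N-C-R-K-A"),
        pyd_allowed=False, b30_2_allowed=False),
]


def classify_nlr_group(
    walker_a_region: str,
    has_pyd: bool,
    has_b30_2: bool,
    specs: Sequence[NlrGroupSpec] = tuple(DEFAULT_NLR_GROUPS),
):
    """Assign an NLR-C group from the Walker A region and domain flags.

    A group matches when its Walker A pattern occurs in the region and
    no domain present on the protein is disallowed by the group. Returns
    the unique matching group id, or ``"unassigned"`` when zero or
    several groups are consistent (the ambiguous case warns).
    """
    if not walker_a_region:
        raise ValueError("empty Walker A region")
    consistent = []
    for spec in specs:
        if not spec.walker_a_pattern.regex.search(walker_a_region):
            continue
        if has_pyd and not spec.pyd_allowed:
            continue
        if has_b30_2 and not spec.b30_2_allowed:
            continue
        consistent.append(spec.group_id)
    if len(consistent) == 1:
        return consistent[0]
    if len(consistent) > 1:
        warnings.warn(
            f"Walker A region consistent with groups {consistent}; unassigned",
            stacklevel=2,
        )
    return "unassigned"


# ---------------------------------------------------------------------------
# ASC (PYD-CARD) architecture screen


@dataclass(frozen=True)
class AscCandidate:
    """A protein whose annotation shows a PYD immediately followed by a CARD."""

    protein_id: str
    pyd: tuple[int, int]
    card: tuple[int, int]


def find_pyd_card_architectures(
    annotations: Iterable[DomainAnnotation],
    max_gap_aa: Optional[int] = None,
) -> list[AscCandidate]:
    """Find PYD-followed-by-adjacent-CARD architectures.

    Adjacency means no other annotated domain lies between the PYD and
    the CARD; ``max_gap_aa`` optionally also bounds the residue gap
    (default unlimited). The canonical inflammasome adaptor (ASC) carries
    exactly one PYD and one CARD and nothing else between them.
    """
    out: list[AscCandidate] = []
    for ann in annotations:
        doms = ann.domains
        for (name_a, sa, ea, _), (name_b, sb, eb, _) in zip(doms, doms[1:]):
            if name_a != "PYD" or name_b != "CARD":
                continue
            if sa >= sb:
                continue
            if max_gap_aa is not None and sb - ea > max_gap_aa:
                continue
            out.append(AscCandidate(ann.protein_id, (sa, ea), (sb, eb)))
    return out
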