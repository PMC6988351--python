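"""Additive spectral tuning (lambda-max) prediction for LWS opsins.

Long-wavelength-sensitive opsin absorbance is tuned largely by five key
amino-acid sites, conventionally numbered against bovine rhodopsin
(164, 181, 261, 269, 292). Under the additive five-sites rule, each
substitution away from the ancestral residue shifts the predicted
absorbance maximum by a fixed amount in nm; the classic example is
Y261F, a -10 nm shift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .io import SequenceRecord

#: Bovine-rhodopsin numbering of the five LWS key tuning sites.
DEFAULT_REFERENCE_SITES = (164, 181, 261, 269, 292)

#: Ancestral LWS residues at the key sites and their lambda-max.
DEFAULT_BASELINE_RESIDUES = "SHYTA"
DEFAULT_BASELINE_LAMBDA_MAX = 560.0

#: Literature default shifts of the five-sites rule (nm per substitution).
DEFAULT_SHIFTS: dict[tuple[int, str, str], float] = {
    (164, "S", "A"): -7.0,
    (181, "H", "Y"): -28.0,
    (261, "Y", "F"): -10.0,
    (269, "T", "A"): -15.0,
    (292, "A", "S"): -27.0,
}


@dataclass
class TuningModel:
    """Additive tuning model over a fixed set of key sites.

    ``shifts`` maps (reference site, baseline residue, observed residue)
    to a wavelength delta in nm. Substitutions without an entry
    contribute 0 nm and are reported as untabulated.
    """

    sites: Sequence[int] = DEFAULT_REFERENCE_SITES
    baseline_residues: str = DEFAULT_BASELINE_RESIDUES
    baseline_lambda_max: float = DEFAULT_BASELINE_LAMBDA_MAX
    shifts: dict[tuple[int, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_SHIFTS)
    )

    def __post_init__(self) -> None:
        if len(self.baseline_residues) != len(self.sites):
            raise ValueError("one baseline residue is needed per key site")
        for site, _, _ in self.shifts:
            if site not in self.sites:
                raise ValueError(f"shift entry references unknown site {site}")


@dataclass
class KeySiteMap:
    """Maps reference-numbered key sites onto a query sequence.

    Either ``query_sites`` gives the (1-based) query positions directly,
    or ``alignment`` is a gapped (reference, query) sequence pair from
    which the mapping is derived column-wise.
    """

    reference_sites: Sequence[int] = DEFAULT_REFERENCE_SITES
    query_sites: Optional[Sequence[int]] = None
    alignment: Optional[tuple[str, str]] = None

    def __post_init__(self) -> None:
        if self.query_sites is None and self.alignment is None:
            raise ValueError("provide query_sites or an alignment")
        if self.query_sites is not None and len(self.query_sites) != len(
            self.reference_sites
        ):
            raise ValueError("query_sites and reference_sites must align")
        if self.alignment is not None and len(self.alignment[0]) != len(
            self.alignment[1]
        ):
            raise ValueError("alignment sequences must be equal length")


def extract_key_residues(site_map: KeySiteMap, query: SequenceRecord) -> str:
    """Extract the query residues at the key tuning sites.

    With a pairwise alignment, reference numbering is counted along the
    ungapped reference row and the aligned query column is taken; a gap
    at a key site yields ``-`` with a warning.
    """
    residues: list[str] = []
    if site_map.alignment is not None:
        ref_row, query_row = site_map.alignment
        by_ref_pos: dict[int, str] = {}
        ref_pos = 0
        for ref_char, q_char in zip(ref_row, query_row):
            if ref_char != "-":
                ref_pos += 1
                by_ref_pos[ref_pos] = q_char
        for site in site_map.reference_sites:
            if site not in by_ref_pos:
                raise ValueError(
                    f"reference site {site} lies outside the alignment"
                )
            residues.append(by_ref_pos[site])
    else:
        assert site_map.query_sites is not None
        for site in site_map.query_sites:
            if not 1 <= site <= len(query.residues):
                raise ValueError(
                    f"query site {site} outside sequence {query.id!r} "
                    f"(length {len(query.residues)})"
                )
            residues.append(query.residues[site - 1])
    extracted = "".join(residues)
    if "-" in extracted:
        warnings.warn(
            f"gap at a key tuning site in {query.id!r}: {extracted}",
            stacklevel=2,
        )
    return extracted


def predict_lambda_max(
    key_residues: str,
    model: Optional[TuningModel] = None,
    notes: Optional[list[str]] = None,
) -> float:
    """Predict lambda-max (nm) from the key-site residues.

    Adds the tabulated shift for every site whose residue differs from
    the baseline; substitutions without a tabulated shift contribute
    0 nm and are appended to ``notes`` when given (and warned otherwise).
    """
    model = model or TuningModel()
    if "-" in key_residues:
        raise ValueError("gap in key residues; cannot predict lambda-max")
    if len(key_residues) != len(model.sites):
        raise ValueError(
            f"expected {len(model.sites)} key residues, got {len(key_residues)}"
        )
    value = model.baseline_lambda_max
    for site, base, observed in zip(
        model.sites, model.baseline_residues, key_residues
    ):
        if observed == base:
            continue
        key = (site, base, observed)
        if key in model.shifts:
            value += model.shifts[key]
        else:
            message = f"untabulated substitution {base}{site}{observed}: 0 nm"
            if notes is not None:
                notes.append(message)
            else:
                warnings.warn(message, stacklevel=2)
    return value


def tuning_shift(
    residues_a: str, residues_b: str, model: Optional[TuningModel] = None
) -> float:
    """Predicted lambda-max difference (nm) between two residue sets.

    Antisymmetric: ``tuning_shift(a, b) == -tuning_shift(b, a)``.
    """
    model = model or TuningModel()
    notes: list[str] = []
    return predict_lambda_max(residues_a, model, notes) - predict_lambda_max(
        residues_b, model, notes
    )
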