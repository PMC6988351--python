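"""YAML-backed configuration: packaged defaults, user overridable."""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml

from .motifs import CypCallRules, NlrGroupSpec, PrositePattern
from .opsins import TuningModel

PathLike = Union[str, Path]


def _load_yaml(name: str, path: Optional[PathLike]) -> dict:
    if path is not None:
        with open(path) as fh:
            return yaml.safe_load(fh)
    ref = resources.files("gobymine.data") / name
    return yaml.safe_load(ref.read_text())


def load_cyp_motifs(
    path: Optional[PathLike] = None,
) -> tuple[list[PrositePattern], CypCallRules]:
    """The four conserved CYP motif patterns and the completeness rules."""
    raw = _load_yaml("cyp_motifs.yaml", path)
    patterns = [
        PrositePattern(name, pattern) for name, pattern in raw["motifs"].items()
    ]
    rules_raw = raw.get("rules", {})
    rules = CypCallRules(
        required_motifs=frozenset(raw["motifs"]),
        full_length_aa=int(rules_raw.get("full_length_aa", 500)),
        tolerance_aa=int(rules_raw.get("tolerance_aa", 50)),
        core_region_aa=int(rules_raw.get("core_region_aa", 120)),
        require_start=bool(rules_raw.get("require_start", True)),
        require_stop=bool(rules_raw.get("require_stop", True)),
    )
    return patterns, rules


def load_nlr_groups(path: Optional[PathLike] = None) -> list[NlrGroupSpec]:
    raw = _load_yaml("nlr_groups.yaml", path)
    specs = [
        NlrGroupSpec(
            group_id=int(g["id"]),
            walker_a_pattern=PrositePattern(f"walkerA-g{g['id']}", g["walker_a"]),
            pyd_allowed=bool(g["pyd"]),
            b30_2_allowed=bool(g["b30_2"]),
        )
        for g in raw["groups"]
    ]
    ids = [s.group_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate NLR group ids in config")
    return specs


def load_tuning_model(path: Optional[PathLike] = None) -> TuningModel:
    raw = _load_yaml("lws_tuning.yaml", path)
    shifts = {
        (int(s["site"]), str(s["from"]), str(s["to"])): float(s["delta_nm"])
        for s in raw.get("shifts", [])
    }
    return TuningModel(
        sites=tuple(int(s) for s in raw["sites"]),
        baseline_residues=str(raw["baseline_residues"]),
        baseline_lambda_max=float(raw["baseline_lambda_max"]),
        shifts=shifts,
    )
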