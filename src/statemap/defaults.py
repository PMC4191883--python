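"""Load segment/gate/region/template definitions from YAML config.

The package ships LeuT defaults (``data/leut.yaml``); user configs with
the same schema can override any part of the analysis.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from statemap.structio import SelectionSpec
from statemap.geometry import SegmentDef, GateDef
from statemap.solvation import RegionDef
from statemap.classify import StateTemplate, StateTemplateSet


class AnalysisConfig:
    """Parsed analysis definitions: segments, descriptor pairs, gates,
    regions, state templates and the canonical cycle order."""

    def __init__(self, raw: dict):
        self.raw = raw
        self.segments: dict[str, SegmentDef] = {
            name: SegmentDef(name, SelectionSpec(
                first=int(d["first"]), last=int(d["last"]),
                atom_names=frozenset(d.get("atoms", ["CA"])),
                chain=d.get("chain")))
            for name, d in raw["segments"].items()
        }
        self.descriptor_pairs: list[tuple[str, str]] = [
            tuple(p) for p in raw["descriptor_pairs"]]
        self.gates: dict[str, GateDef] = {
            name: GateDef(
                name=name,
                sel_a=_sel(d["a"]), sel_b=_sel(d["b"]),
                cutoff=float(d["cutoff"]), kind=d.get("kind", "salt_bridge"))
            for name, d in raw["gates"].items()
        }
        self.ec_gates: list[str] = list(raw.get("ec_gates", []))
        self.regions: dict[str, RegionDef] = {
            name: RegionDef(name=name, anchors=tuple(d["anchors"]),
                            radius=float(d["radius"]))
            for name, d in raw.get("regions", {}).items()
        }
        self.templates = StateTemplateSet([
            StateTemplate(
                name=name,
                means=tuple(float(x) for x in d["means"]),
                sds=tuple(float(x) for x in d["sds"]),
                substrate_bound=bool(d["substrate_bound"]),
                ec_rule=d.get("ec_rule", "at_least_one_closed"),
                gate_requirements={g: v for g, v in
                                   d.get("gates", {}).items()},
                tilt=float(d.get("tilt", 0.0)))
            for name, d in raw["templates"].items()
        ], ec_gates=self.ec_gates)
        self.cycle_order: list[str] = list(raw.get("cycle_order", []))
        self.crystal_reference: dict = raw.get("crystal_reference", {})


def _sel(d: dict) -> SelectionSpec:
    return SelectionSpec(first=int(d["first"]), last=int(d["last"]),
                         atom_names=frozenset(d.get("atoms", ["CA"])),
                         chain=d.get("chain"))


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load an analysis config; with no path, the shipped LeuT defaults."""
    if path is None:
        text = (resources.files("statemap") / "data" / "leut.yaml").read_text()
    else:
        text = Path(path).read_text()
    return AnalysisConfig(yaml.safe_load(text))


def leut_defaults() -> AnalysisConfig:
    """The shipped LeuT segment/gate/template defaults."""
    return load_config(None)
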