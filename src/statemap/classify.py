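"""Six-state classification of transporter conformers.

Per-frame descriptors (interhelical CoM distances, TM1a tilt, gate
distances, hydration counts, ligand position) are matched against state
templates: hard gate/substrate constraints filter the candidate states,
and among those a Gaussian likelihood over the three interhelical
distances picks the winner.  Run-length summaries of the label series
and ligand-release tracking turn frame labels into a transport-cycle
narrative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from statemap.structio import StructureModel, Trajectory, SelectionSpec, \
    select_atoms
from statemap.geometry import SegmentDef, GateDef, center_of_mass, \
    com_distance, helix_axis, tilt_angle, gate_distance, gate_is_closed
from statemap.solvation import RegionDef, count_waters

UNASSIGNED = "unassigned"

#: ligand counts as bound when its CoM is within this distance (Å) of the
#: binding-site center (mean of the five segment CoMs)
BINDING_SITE_RADIUS = 6.0


@dataclass
class DescriptorFrame:
    """Per-frame descriptor vector."""

    distances: tuple[float, float, float]   # (TM1b-TM10ec, TM6a-TM10ec, TM1a-TM6b), Å
    tilt_tm1a: float                        # deg vs membrane normal
    gate_distances: dict[str, float]        # Å per gate
    gate_closed: dict[str, bool]
    n_water_ec: int = 0
    n_water_ic: int = 0
    cavity_volume: float | None = None      # Å^3
    substrate_bound: bool = False
    na1_bound: bool = False
    na2_bound: bool = False
    ligand_z: float | None = None           # Å

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.distances):
            raise ValueError("interhelical distances must be >= 0")


@dataclass(frozen=True)
class StateTemplate:
    """One transport-cycle state: Gaussian templates over the three
    interhelical distances plus hard gate/substrate requirements."""

    name: str
    means: tuple[float, float, float]
    sds: tuple[float, float, float]
    substrate_bound: bool
    ec_rule: str = "at_least_one_closed"    # or "both_open"
    gate_requirements: dict = field(default_factory=dict)  # gate -> "closed"/"open"
    tilt: float = 0.0                        # nominal TM1a tilt (deg), reporting only

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sds):
            raise ValueError(f"state {self.name}: SDs must be > 0")
        if self.ec_rule not in ("both_open", "at_least_one_closed"):
            raise ValueError(f"unknown ec_rule {self.ec_rule!r}")

    def constraints_satisfied(self, frame: DescriptorFrame,
                              ec_gates: list[str]) -> bool:
        if frame.substrate_bound != self.substrate_bound:
            return False
        for gate, req in self.gate_requirements.items():
            if gate not in frame.gate_closed:
                return False
            closed = frame.gate_closed[gate]
            if req == "closed" and not closed:
                return False
            if req == "open" and closed:
                return False
        ec_closed = [frame.gate_closed[g] for g in ec_gates
                     if g in frame.gate_closed]
        if ec_closed:
            if self.ec_rule == "both_open" and any(ec_closed):
                return False
            if self.ec_rule == "at_least_one_closed" and not any(ec_closed):
                return False
        return True

    def log_likelihood(self, frame: DescriptorFrame) -> float:
        ll = 0.0
        for d, mu, sd in zip(frame.distances, self.means, self.sds):
            ll += -0.5 * ((d - mu) / sd) ** 2 - math.log(sd)
        return ll


class StateTemplateSet:
    """The template collection driving classification."""

    def __init__(self, templates: list[StateTemplate],
                 ec_gates: list[str] | None = None):
        self.templates = {t.name: t for t in templates}
        if len(self.templates) != len(templates):
            raise ValueError("duplicate state names")
        self.ec_gates = list(ec_gates or [])

    def __iter__(self):
        return iter(self.templates.values())

    def __getitem__(self, name: str) -> StateTemplate:
        return self.templates[name]

    def __len__(self) -> int:
        return len(self.templates)

    def names(self) -> list[str]:
        return list(self.templates)


@dataclass
class ClassificationResult:
    label: str
    scores: dict[str, float]       # log-likelihood per constraint-passing state
    margin: float                  # best minus runner-up (inf if unique)
    nearest: str | None = None     # for unassigned frames: best ignoring constraints


def classify_frame(frame: DescriptorFrame, templates: StateTemplateSet
                   ) -> ClassificationResult:
    """Assign a frame to the best constraint-satisfying state template.

    Frames satisfying no template's hard constraints get the label
    ``unassigned`` with a nearest-state annotation.
    """
    passing = {t.name: t.log_likelihood(frame) for t in templates
               if t.constraints_satisfied(frame, templates.ec_gates)}
    if not passing:
        all_ll = {t.name: t.log_likelihood(frame) for t in templates}
        nearest = max(all_ll, key=all_ll.get)
        return ClassificationResult(label=UNASSIGNED, scores={},
                                    margin=0.0, nearest=nearest)
    ordered = sorted(passing.items(), key=lambda kv: kv[1], reverse=True)
    margin = (ordered[0][1] - ordered[1][1]) if len(ordered) > 1 \
        else float("inf")
    return ClassificationResult(label=ordered[0][0], scores=passing,
                                margin=margin)


def descriptor_frame(model: StructureModel,
                     segments: dict[str, SegmentDef],
                     descriptor_pairs: list[tuple[str, str]],
                     gates: dict[str, GateDef],
                     regions: dict[str, RegionDef] | None = None,
                     ligand_selections: dict[str, SelectionSpec] | None = None,
                     tilt_segment: str = "TM1a",
                     weighting: str = "uniform_ca") -> DescriptorFrame:
    """Compute the full descriptor vector for one conformer.

    Composes the geometry and solvation operations; deterministic.
    ``ligand_selections`` may provide ``substrate``, ``na1``, ``na2``
    selections; a ligand is "bound" when its CoM lies within
    ``BINDING_SITE_RADIUS`` of the binding-site center (the mean of the
    segment CoMs).
    """
    coms = {name: center_of_mass(model, select_atoms(model, seg.spec),
                                 weighting)
            for name, seg in segments.items()}
    dists = tuple(
        com_distance(model, segments[a], segments[b], weighting)
        for a, b in descriptor_pairs)
    tilt = tilt_angle(helix_axis(model, segments[tilt_segment]))
    gate_d, gate_c = {}, {}
    for name, gate in gates.items():
        d = gate_distance(model, gate)
        gate_d[name] = d
        gate_c[name] = gate_is_closed(d, gate)
    n_ec = n_ic = 0
    if regions:
        if "EC_vestibule" in regions:
            n_ec = count_waters(model, regions["EC_vestibule"], coms)
        if "IC_vestibule" in regions:
            n_ic = count_waters(model, regions["IC_vestibule"], coms)
    site_center = np.mean(list(coms.values()), axis=0)
    bound = {"substrate": False, "na1": False, "na2": False}
    ligand_z = None
    if ligand_selections:
        for key, sel in ligand_selections.items():
            idx = select_atoms(model, sel)
            if len(idx) == 0:
                continue
            com = center_of_mass(model, idx, "uniform_ca")
            bound[key] = bool(
                np.linalg.norm(com - site_center) <= BINDING_SITE_RADIUS)
            if key == "substrate":
                ligand_z = float(com[2])
    return DescriptorFrame(
        distances=tuple(float(d) for d in dists), tilt_tm1a=float(tilt),
        gate_distances=gate_d, gate_closed=gate_c,
        n_water_ec=n_ec, n_water_ic=n_ic,
        substrate_bound=bound["substrate"], na1_bound=bound["na1"],
        na2_bound=bound["na2"], ligand_z=ligand_z)


def smooth_labels(labels: list[str], window: int = 5) -> list[str]:
    """Majority smoothing over a centered window (ties keep the current
    label); suppresses single-frame flicker."""
    if window <= 1:
        return list(labels)
    n = len(labels)
    half = window // 2
    out = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        votes: dict[str, int] = {}
        for lab in labels[lo:hi]:
            votes[lab] = votes.get(lab, 0) + 1
        best = max(votes.values())
        winners = [k for k, v in votes.items() if v == best]
        out.append(labels[i] if labels[i] in winners else winners[0])
    return out


def transition_summary(labels: list[str], window: int = 5
                       ) -> list[tuple[str, int, int]]:
    """Run-length encoding of the (smoothed) state-label series.

    Returns ``[(state, first_frame, dwell_length), ...]`` in visit order.
    """
    if len(labels) == 0:
        raise ValueError("empty label series")
    sm = smooth_labels(labels, window)
    runs = []
    start = 0
    for i in range(1, len(sm) + 1):
        if i == len(sm) or sm[i] != sm[start]:
            runs.append((sm[start], start, i - start))
            start = i
    return runs


def track_release(traj: Trajectory, ligand_sel: SelectionSpec,
                  z_threshold: float, direction: str = "down",
                  persistence: int = 10) -> int | None:
    """First frame at which the ligand CoM z crosses the threshold and
    stays beyond it for ``persistence`` frames (transient dips do not
    count).  Returns ``None`` if no release occurs.
    """
    idx = select_atoms(traj.topology, ligand_sel)
    if len(idx) == 0:
        raise ValueError("ligand selection matches no atoms in topology")
    z = np.array([frame[idx, 2].mean() for frame in traj.frames])
    if direction == "down":
        beyond = z < z_threshold
    elif direction == "up":
        beyond = z > z_threshold
    else:
        raise ValueError("direction must be 'down' or 'up'")
    n = len(z)
    for i in range(n):
        if beyond[i]:
            hi = min(n, i + persistence)
            if beyond[i:hi].all() and (hi - i) == min(persistence, n - i):
                # require full persistence unless the series ends beyond
                if hi - i >= persistence or beyond[i:].all():
                    return i
    return None
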