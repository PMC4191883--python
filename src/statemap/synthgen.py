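"""Synthetic conformer generator.

Builds minimal LeuT-like Cα bundles — five helix segments with the
native residue numbering, gate side-chain pseudo-atoms, pseudo-water
oxygens and substrate/ion markers — whose descriptors follow the
per-state statistics the classifier assumes: interhelical CoM distances
drawn from each state's Gaussian template, gates placed in open/closed
geometry, EC/IC hydration by state, TM1a tilt excursions, and a scripted
ligand-release path along z.  Every analysis stage is therefore testable
end-to-end with known ground truth and no structure downloads.

This is not a physical protein model: helices are ideal spirals, gate
side chains are single atoms, and waters are placed uniformly in the
vestibule spheres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from statemap.structio import StructureModel, Trajectory

# layered geometry (Å): EC descriptor segments live near z = EC_Z, the
# IC pair near IC_Z, gates just beyond their vestibules
EC_Z = 12.0
IC_Z = -8.0
EC_GATE_Z = 15.0
IC_GATE_Z = -11.0
BULK_Z = -30.0        # IC bulk destination for released ligands
EC_BULK_Z = 35.0      # EC bulk, where ligands sit before binding
SITE_Z = 4.0          # binding-site elevation (mean of the layer z's)
RELEASE_Z = -10.0     # a ligand below this z counts as released
RESERVOIR_Z = 80.0    # parking layer for waters not in any vestibule
TM6A_ANGLE = np.deg2rad(130.0)

SEGMENT_RESIDUES = {
    "TM1a": (11, 22), "TM1b": (25, 35), "TM6a": (242, 255),
    "TM6b": (259, 268), "TM10ec": (398, 412),
}

#: gate pseudo-atoms: (residue id, residue name, atom name, layer z, base xy)
GATE_ATOM_LAYOUT = {
    "r5_d369": ((5, "ARG", "NH1"), (369, "ASP", "OD1"), IC_GATE_Z, (6.0, -6.0)),
    "e6_r375": ((6, "GLU", "OE1"), (375, "ARG", "NH1"), IC_GATE_Z, (-6.0, -6.0)),
    "r30_d404": ((30, "ARG", "NH1"), (404, "ASP", "OD1"), EC_GATE_Z, (6.0, 6.0)),
    "w8_y268": ((8, "TRP", "NE1"), (268, "TYR", "OH"), IC_GATE_Z, (0.0, -8.0)),
    "f253_y108": ((253, "PHE", "CZ"), (108, "TYR", "OH"), EC_GATE_Z, (-6.0, 6.0)),
}

CLOSED_SEPARATION = 3.0
OPEN_SEPARATION = 10.0

#: per-state construction truth: gate closed-flags, hydration, tilt (deg)
STATE_GEOMETRY = {
    # state:        r5   e6   r30  w8   f253  substrate  (ec, ic) waters  tilt
    "OFo":          (True, True, False, True, False, False, (30, 0), 5.0),
    "OFo_star":     (True, True, False, True, False, True, (30, 0), 5.0),
    "OFc_star":     (True, True, True, True, True, True, (15, 0), 5.0),
    "holo_occluded": (False, False, True, True, True, True, (2, 2), 10.0),
    "IFo_star":     (False, False, True, False, True, True, (5, 25), 45.0),
    "IFo":          (False, False, True, False, True, False, (5, 30), 45.0),
    "apo_occluded": (True, True, True, True, True, False, (2, 2), 10.0),
}

DEFAULT_CYCLE = ["OFo", "OFc_star", "holo_occluded", "IFo_star", "IFo",
                 "apo_occluded"]

#: substrate-bound state -> its ligand-free twin (same helix packing);
#: once the scripted substrate leaves mid-state, the frame IS the twin
UNBOUND_TWIN = {"IFo_star": "IFo", "OFo_star": "OFo"}

TABLE_MEANS = {
    "OFo": (18.0, 16.8, 11.6), "OFo_star": (18.0, 16.8, 11.6),
    "OFc_star": (16.8, 13.8, 11.7), "holo_occluded": (15.8, 12.5, 12.8),
    "IFo_star": (14.3, 12.2, 20.5), "IFo": (14.3, 12.2, 20.5),
    "apo_occluded": (14.5, 13.2, 12.2),
}
TABLE_SDS = {
    "OFo": (0.6, 0.4, 0.2), "OFo_star": (0.6, 0.4, 0.2),
    "OFc_star": (0.3, 0.3, 0.2), "holo_occluded": (0.4, 0.4, 0.4),
    "IFo_star": (0.4, 0.4, 2.0), "IFo": (0.4, 0.4, 2.0),
    "apo_occluded": (0.4, 0.3, 0.3),
}

N_WATER_TOTAL = 60    # fixed topology: unused waters park in the reservoir


@dataclass
class SyntheticSpec:
    """Generator settings; the defaults are the study conditions."""

    means: dict = field(default_factory=lambda: dict(TABLE_MEANS))
    sds: dict = field(default_factory=lambda: dict(TABLE_SDS))
    frames_per_state: int = 50
    states: list[str] = field(default_factory=lambda: list(DEFAULT_CYCLE))
    n_transition_frames: int = 3      # linear interpolation at boundaries
    #: ligand -> (state, frame offset within that state) at which the
    #: 5-frame release ramp toward the IC bulk starts
    release_schedule: dict = field(default_factory=lambda: {
        "substrate": ("IFo_star", 10),
        "na1": ("IFo_star", 14),
        "na2": ("IFo", 5),
    })
    closed_separation: float = CLOSED_SEPARATION
    open_separation: float = OPEN_SEPARATION
    water_jitter: float = 3.0         # placement radius within vestibule


def make_ideal_helix(n_res: int, rise: float = 1.5, twist: float = 100.0,
                     radius: float = 2.3,
                     axis: np.ndarray = (0.0, 0.0, 1.0),
                     origin: np.ndarray = (0.0, 0.0, 0.0)) -> np.ndarray:
    """Cα coordinates of an ideal α-helical spiral along ``axis``.

    rise in Å/residue, twist in deg/residue, radius = Cα distance from
    the helix axis.
    """
    if n_res < 3:
        raise ValueError("helix needs >= 3 residues")
    t = np.arange(n_res)
    ang = np.deg2rad(twist) * t
    local = np.stack([radius * np.cos(ang), radius * np.sin(ang),
                      rise * t], axis=1)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    rot = _rotation_to(np.array([0.0, 0.0, 1.0]), axis)
    return local @ rot.T + np.asarray(origin, dtype=float)


def _rotation_to(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180° about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        v = np.cross(a, perp)
        v /= np.linalg.norm(v)
        return 2.0 * np.outer(v, v) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _helix_at(n_res: int, com: np.ndarray, tilt_deg: float = 0.0
              ) -> np.ndarray:
    """Ideal helix whose Cα centroid sits exactly at ``com``; the helix
    axis is tilted ``tilt_deg`` from +z (about the x axis)."""
    tilt = np.deg2rad(tilt_deg)
    axis = np.array([0.0, np.sin(tilt), np.cos(tilt)])
    xyz = make_ideal_helix(n_res, axis=axis)
    return xyz + (np.asarray(com, dtype=float) - xyz.mean(axis=0))


def _segment_coms(d1: float, d2: float, d3: float
                  ) -> dict[str, np.ndarray]:
    """Segment CoM positions realizing the three target distances.

    The targets constrain disjoint pairs, so a direct placement is
    exact: TM10ec at the EC origin, TM1b at distance d1, TM6a at
    distance d2 (fixed azimuth), TM6b directly below TM6a on the IC
    layer, and TM1a at in-plane distance d3 from TM6b.
    """
    tm10 = np.array([0.0, 0.0, EC_Z])
    tm1b = np.array([d1, 0.0, EC_Z])
    tm6a = np.array([d2 * np.cos(TM6A_ANGLE), d2 * np.sin(TM6A_ANGLE), EC_Z])
    tm6b = np.array([tm6a[0], tm6a[1], IC_Z])
    u = tm1b[:2] - tm6b[:2]
    u = u / np.linalg.norm(u)
    tm1a = np.array([tm6b[0] + d3 * u[0], tm6b[1] + d3 * u[1], IC_Z])
    return {"TM1a": tm1a, "TM1b": tm1b, "TM6a": tm6a, "TM6b": tm6b,
            "TM10ec": tm10}


def _uniform_ball(rng: np.random.Generator, n: int, center: np.ndarray,
                  radius: float) -> np.ndarray:
    pts = rng.standard_normal((n, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return center + pts * r[:, None]


def make_state_conformer(state: str, spec: SyntheticSpec | None = None,
                         seed: int | np.random.Generator = 0,
                         ligand_z: float | None = None,
                         na1_z: float | None = None,
                         na2_z: float | None = None) -> StructureModel:
    """A single conformer of the given state.

    Interhelical distances are drawn from the state's Gaussian template
    (set the spec SDs to zero for an exact-means conformer); gate
    pseudo-atoms are placed at closed/open separation per the state's
    gate logic; vestibule waters and ligand markers follow the state's
    hydration/binding pattern.  Ligand z positions can be overridden to
    script release paths.
    """
    spec = spec or SyntheticSpec()
    if state not in STATE_GEOMETRY:
        raise ValueError(f"unknown state {state!r}; "
                         f"choose from {sorted(STATE_GEOMETRY)}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    means = np.asarray(spec.means[state], dtype=float)
    sds = np.asarray(spec.sds[state], dtype=float)
    d1, d2, d3 = rng.normal(means, sds) if sds.any() else means
    d1, d2, d3 = abs(d1), abs(d2), abs(d3)
    coms = _segment_coms(d1, d2, d3)

    (r5_c, e6_c, r30_c, w8_c, f253_c, substrate,
     (n_ec, n_ic), tilt) = STATE_GEOMETRY[state]
    gate_closed = {"r5_d369": r5_c, "e6_r375": e6_c, "r30_d404": r30_c,
                   "w8_y268": w8_c, "f253_y108": f253_c}

    serial, names, resnames, resids, chains, elements, hetero, xyz = \
        [], [], [], [], [], [], [], []

    def add(name, resname, resid, chain, element, pos, het=False):
        serial.append(len(serial) + 1)
        names.append(name); resnames.append(resname); resids.append(resid)
        chains.append(chain); elements.append(element); hetero.append(het)
        xyz.append(np.asarray(pos, dtype=float))

    # helix segments (Cα only), TM1a tilted by the state's excursion
    for seg, (first, last) in SEGMENT_RESIDUES.items():
        n_res = last - first + 1
        seg_tilt = tilt if seg == "TM1a" else 0.0
        coords = _helix_at(n_res, coms[seg], seg_tilt)
        for i in range(n_res):
            add("CA", "GLY", first + i, "A", "C", coords[i])

    # gate side-chain pseudo-atoms
    for gname, (part_a, part_b, z, (bx, by)) in GATE_ATOM_LAYOUT.items():
        sep = (spec.closed_separation if gate_closed[gname]
               else spec.open_separation)
        base = np.array([bx, by, z])
        ra, na_, aa = part_a
        rb, nb, ab = part_b
        el_a = "N" if aa.startswith("N") else ("O" if aa.startswith("O") else "C")
        el_b = "N" if ab.startswith("N") else ("O" if ab.startswith("O") else "C")
        add(aa, na_, ra, "A", el_a, base)
        add(ab, nb, rb, "A", el_b, base + np.array([sep, 0.0, 0.0]))

    # vestibule waters + reservoir (fixed total for a constant topology)
    ec_center = (coms["TM1b"] + coms["TM10ec"]) / 2
    ic_center = (coms["TM1a"] + coms["TM6b"]) / 2
    placed = 0
    for center, count in ((ec_center, n_ec), (ic_center, n_ic)):
        pts = _uniform_ball(rng, count, center, spec.water_jitter)
        for p in pts:
            placed += 1
            add("O", "HOH", placed, "W", "O", p, het=True)
    for j in range(N_WATER_TOTAL - placed):
        spot = np.array([4.0 * (j % 8), 4.0 * (j // 8), RESERVOIR_Z])
        add("O", "HOH", placed + j + 1, "W", "O", spot, het=True)

    # substrate + Na markers; bound position = binding-site center.
    # Without an explicit z override, unbound ligands sit in the EC bulk
    # for OF-open states (pre-binding) and in the IC bulk otherwise
    # (post-release).
    site = np.mean(list(coms.values()), axis=0)
    unbound_z = EC_BULK_Z if state == "OFo" else BULK_Z
    sub_pos = site.copy()
    if ligand_z is not None:
        sub_pos = np.array([site[0], site[1], ligand_z])
    elif not substrate:
        sub_pos = np.array([site[0], site[1], unbound_z])
    add("CA", "ALA", 601, "S", "C", sub_pos, het=True)
    for resid, zval in ((701, na1_z), (702, na2_z)):
        pos = site + np.array([1.5 if resid == 701 else -1.5, 0.0, 0.0])
        if zval is not None:
            pos = np.array([pos[0], pos[1], zval])
        elif not substrate:
            pos = np.array([pos[0], pos[1], unbound_z])
        add("NA", "NA", resid, "I", "NA", pos, het=True)

    return StructureModel(
        serial=np.array(serial), atom_name=np.array(names),
        res_name=np.array(resnames), res_id=np.array(resids),
        chain_id=np.array(chains), element=np.array(elements),
        coords=np.stack(xyz), hetero=np.array(hetero))


def make_cycle_trajectory(spec: SyntheticSpec | None = None, seed: int = 0
                          ) -> tuple[Trajectory, list[str], dict[str, int]]:
    """A multi-state trajectory through the transport cycle.

    Returns ``(trajectory, ground_truth_labels, release_frames)``.
    Consecutive states are joined by linear coordinate interpolation over
    ``n_transition_frames`` frames, labelled with the destination state;
    the substrate's z ramps to the IC bulk at the scripted release frame.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(seed)
    frames: list[np.ndarray] = []
    labels: list[str] = []
    release_frames: dict[str, int] = {}
    topology: StructureModel | None = None

    # first state of the arc in which each ligand is bound
    first_bound = next((i for i, s in enumerate(spec.states)
                        if STATE_GEOMETRY[s][5]), None)
    sched = {}
    for lig, (st, off) in spec.release_schedule.items():
        sched[lig] = (spec.states.index(st), off) if st in spec.states \
            else None

    def ligand_z_for(lig: str, si: int, fi: int) -> float:
        if first_bound is None or si < first_bound:
            return EC_BULK_Z
        when = sched.get(lig)
        if when is None:
            return SITE_Z
        ri, roff = when
        k = (fi - roff) if si == ri else (
            -1 if si < ri else 10)           # before / long after
        if si > ri:
            return BULK_Z
        if k < 0:
            return SITE_Z
        if k >= 5:
            return BULK_Z
        return _ramp_z(k)

    prev_coords = None
    frame_counter = 0
    for si, state in enumerate(spec.states):
        for fi in range(spec.frames_per_state):
            zs = {lig: ligand_z_for(lig, si, fi)
                  for lig in ("substrate", "na1", "na2")}
            model = make_state_conformer(
                state, spec, rng, ligand_z=zs["substrate"],
                na1_z=zs["na1"], na2_z=zs["na2"])
            truth = state
            if (STATE_GEOMETRY[state][5]
                    and abs(zs["substrate"] - SITE_Z) > 6.0):
                truth = UNBOUND_TWIN.get(state, state)
            if topology is None:
                topology = model
            coords = model.coords
            if prev_coords is not None and fi == 0 and \
                    spec.n_transition_frames > 0:
                for j in range(1, spec.n_transition_frames + 1):
                    w = j / (spec.n_transition_frames + 1)
                    frames.append((1 - w) * prev_coords + w * coords)
                    labels.append(truth)
                    frame_counter += 1
            for lig, z in zs.items():
                if z < RELEASE_Z and lig not in release_frames:
                    release_frames[lig] = frame_counter
            frames.append(coords)
            labels.append(truth)
            frame_counter += 1
            prev_coords = coords
    traj = Trajectory(topology=topology.with_coords(frames[0]),
                      frames=frames)
    return traj, labels, release_frames


def _ramp_z(k: int) -> float:
    """Linear 5-frame descent from the binding site to the IC bulk."""
    return SITE_Z + (BULK_Z - SITE_Z) * (k + 1) / 5.0


def ligand_selections():
    """Default selections for the synthetic substrate and Na markers."""
    from statemap.structio import SelectionSpec
    return {
        "substrate": SelectionSpec(first=601, last=601,
                                   atom_names=frozenset({"CA"}), chain="S"),
        "na1": SelectionSpec(first=701, last=701,
                             atom_names=frozenset({"NA"}), chain="I"),
        "na2": SelectionSpec(first=702, last=702,
                             atom_names=frozenset({"NA"}), chain="I"),
    }
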