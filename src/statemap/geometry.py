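"""Geometric descriptors of transporter conformers.

Interhelical center-of-mass (CoM) distances, helix axis / tilt angles,
Kabsch superposition RMSD and gate contact distances.  The five default
helix segments and four gate pairs of the LeuT alternating-access
analysis ship with :mod:`statemap.defaults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from statemap.structio import StructureModel, SelectionSpec, select_atoms


@dataclass(frozen=True)
class SegmentDef:
    """A named helical segment, e.g. TM1a = Cα of residues 11-22."""

    name: str
    spec: SelectionSpec


@dataclass(frozen=True)
class GateDef:
    """A gate contact: two partner atom selections plus a closed-state cutoff.

    kind: ``salt_bridge`` (side-chain N x carboxylate O, min cross-pair
    distance), ``hbond`` (donor/acceptor heavy atoms), ``cation_pi``
    (cation N to aromatic ring centroid) or ``contact`` (generic min
    heavy-atom distance, used for aromatic EC gate pairs).
    """

    name: str
    sel_a: SelectionSpec
    sel_b: SelectionSpec
    cutoff: float
    kind: str = "salt_bridge"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("gate cutoff must be > 0")
        if self.kind not in ("salt_bridge", "hbond", "cation_pi", "contact"):
            raise ValueError(f"unknown gate kind {self.kind!r}")


def center_of_mass(model: StructureModel, indices: np.ndarray,
                   weighting: str = "uniform_ca") -> np.ndarray:
    """CoM of the selected atoms: plain mean (``uniform_ca``) or
    mass-weighted mean (``mass``)."""
    indices = np.asarray(indices, dtype=int)
    if len(indices) == 0:
        raise ValueError("center_of_mass of an empty selection")
    xyz = model.coords[indices]
    if weighting == "uniform_ca":
        return xyz.mean(axis=0)
    if weighting == "mass":
        w = model.get_masses()[indices]
        return (xyz * w[:, None]).sum(axis=0) / w.sum()
    raise ValueError(f"unknown weighting {weighting!r}")


def com_distance(model: StructureModel, seg_a: SegmentDef, seg_b: SegmentDef,
                 weighting: str = "uniform_ca") -> float:
    """Euclidean distance (Å) between the CoMs of two segments."""
    ia = select_atoms(model, seg_a.spec)
    ib = select_atoms(model, seg_b.spec)
    if len(ia) == 0 or len(ib) == 0:
        empty = seg_a.name if len(ia) == 0 else seg_b.name
        raise ValueError(f"segment {empty!r} selects no atoms")
    return float(np.linalg.norm(center_of_mass(model, ia, weighting)
                                - center_of_mass(model, ib, weighting)))


def helix_axis(model_or_coords, seg: SegmentDef | None = None) -> np.ndarray:
    """Principal axis (unit vector) of a helix's Cα cloud.

    The first principal component of the coordinates, oriented so the
    N-terminal-half -> C-terminal-half CoM direction has positive
    projection.  Accepts either ``(model, seg)`` or a raw (N, 3) array
    ordered N- to C-terminus.
    """
    if seg is not None:
        idx = select_atoms(model_or_coords, seg.spec)
        xyz = model_or_coords.coords[idx]
    else:
        xyz = np.asarray(model_or_coords, dtype=float)
    if xyz.shape[0] < 3:
        raise ValueError("helix axis needs at least 3 atoms")
    centered = xyz - xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    half = xyz.shape[0] // 2
    direction = xyz[half:].mean(axis=0) - xyz[:half].mean(axis=0)
    if np.dot(axis, direction) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def tilt_angle(axis: np.ndarray, reference: np.ndarray = (0.0, 0.0, 1.0)
               ) -> float:
    """Angle (degrees, [0, 180)) between a helix axis and a reference
    direction; the default reference is the membrane normal +z."""
    a = np.asarray(axis, dtype=float)
    r = np.asarray(reference, dtype=float)
    na, nr = np.linalg.norm(a), np.linalg.norm(r)
    if na == 0 or nr == 0:
        raise ValueError("zero-norm vector in tilt_angle")
    c = np.clip(np.dot(a, r) / (na * nr), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray,
                subset: np.ndarray | None = None
                ) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares superposition of B onto A.

    Returns ``(rmsd, R, t)`` with the optimal rotation ``R`` and
    translation ``t`` such that ``coords_b @ R.T + t`` best fits
    ``coords_a`` over the subset (default: all atoms).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if subset is not None:
        subset = np.asarray(subset, dtype=int)
        a, b = a[subset], b[subset]
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    if a.shape[0] < 3:
        raise ValueError("need >= 3 atoms for a unique superposition")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = b0.T @ a0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    b_fit = b0 @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((b_fit - a0) ** 2, axis=1))))
    trans = ca - cb @ rot.T
    return rmsd, rot, trans


def _ring_centroid(model: StructureModel, idx: np.ndarray) -> np.ndarray:
    return model.coords[idx].mean(axis=0)


def gate_distance(model: StructureModel, gate: GateDef) -> float:
    """Gate contact distance (Å).

    salt_bridge / hbond / contact: minimum over all cross pairs of
    partner-atom distances.  cation_pi: cation N atom to ring centroid
    (minimum over cation atoms).
    """
    ia = select_atoms(model, gate.sel_a)
    ib = select_atoms(model, gate.sel_b)
    if len(ia) == 0 or len(ib) == 0:
        side = "A" if len(ia) == 0 else "B"
        sel = gate.sel_a if len(ia) == 0 else gate.sel_b
        raise ValueError(
            f"gate {gate.name!r}: partner {side} (residues "
            f"{sel.first}-{sel.last}, atoms {sorted(sel.atom_names)}) "
            f"selects no atoms — missing side-chain atoms?")
    pa = model.coords[ia]
    if gate.kind == "cation_pi":
        centroid = _ring_centroid(model, ib)
        return float(np.min(np.linalg.norm(pa - centroid, axis=1)))
    pb = model.coords[ib]
    diff = pa[:, None, :] - pb[None, :, :]
    return float(np.min(np.linalg.norm(diff, axis=-1)))


def gate_is_closed(distance: float, gate: GateDef) -> bool:
    """Closed means distance <= cutoff (inclusive)."""
    if distance < 0:
        raise ValueError("gate distance must be >= 0")
    return distance <= gate.cutoff
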