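"""Hydration, cavity and pore metrics.

Water counts in anchored vestibule regions, grid flood-fill cavity
volume (POVME-style: 1.0-Å grid, points not occluded by protein atoms
and connected to the binding-site seed), and a HOLE-style pore-radius
profile along the membrane normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from statemap.structio import StructureModel

#: Bondi van der Waals radii (Å) by element; fallback 1.7 Å (carbon-like)
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "NA": 2.27, "K": 2.75,
}
DEFAULT_VDW = 1.70


def vdw_radii(model: StructureModel,
              override: float | None = None) -> np.ndarray:
    """Per-atom vdW radii; a uniform override is used for pseudo-atom tests."""
    if override is not None:
        return np.full(model.n_atoms, float(override))
    return np.array([BONDI_RADII.get(str(e).upper(), DEFAULT_VDW)
                     for e in model.element])


@dataclass(frozen=True)
class RegionDef:
    """A tracked solvent region: sphere around the midpoint of segment
    CoM anchors, optionally clipped to a z-slab."""

    name: str
    anchors: tuple[str, ...]          # segment names; center = CoM midpoint
    radius: float
    z_min: float | None = None        # optional slab clip, absolute Å
    z_max: float | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("region radius must be > 0")
        if (self.z_min is not None and self.z_max is not None
                and self.z_min >= self.z_max):
            raise ValueError("region slab needs z_min < z_max")

    def center(self, segment_coms: dict[str, np.ndarray]) -> np.ndarray:
        try:
            pts = [segment_coms[a] for a in self.anchors]
        except KeyError as exc:
            raise ValueError(
                f"region {self.name!r}: anchor {exc} unresolved") from exc
        return np.mean(pts, axis=0)


def count_waters(model: StructureModel, region: RegionDef,
                 segment_coms: dict[str, np.ndarray]) -> int:
    """Number of water oxygen atoms inside the region."""
    mask = model.is_water & (np.char.upper(
        model.element.astype(str)) == "O")
    if not mask.any():
        return 0
    xyz = model.coords[mask]
    center = region.center(segment_coms)
    inside = np.linalg.norm(xyz - center, axis=1) <= region.radius
    if region.z_min is not None:
        inside &= xyz[:, 2] >= region.z_min
    if region.z_max is not None:
        inside &= xyz[:, 2] <= region.z_max
    return int(inside.sum())


@dataclass
class CavityParams:
    """Flood-fill cavity parameters.

    Grid spacing 1.0 Å by default; a grid point is occluded when it lies
    within (vdW + probe) of any atom; cavity = the set of unoccluded
    points grid-connected to the seed.
    """

    spacing: float = 1.0
    probe: float = 1.4
    connectivity: int = 6             # 6 (face) or 26 (face+edge+corner)
    margin: float = 2.0               # grid padding beyond the atom bbox
    radius_override: float | None = None

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be > 0")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")


@dataclass
class CavityResult:
    volume: float                     # Å^3
    n_points: int
    touches_boundary: bool            # cavity reaches the grid edge (open)


class SeedOccludedError(ValueError):
    """The flood-fill seed point lies inside an atom's occlusion sphere."""


def cavity_volume(model: StructureModel, seed: np.ndarray,
                  params: CavityParams | None = None) -> CavityResult:
    """Flood-fill cavity volume from a seed point.

    volume = (number of reachable unoccluded grid points) x spacing^3.
    """
    params = params or CavityParams()
    seed = np.asarray(seed, dtype=float)
    radii = vdw_radii(model, params.radius_override) + params.probe
    coords = model.coords
    lo = coords.min(axis=0) - params.margin
    hi = coords.max(axis=0) + params.margin
    if np.any(hi - lo <= params.spacing):
        raise ValueError("degenerate grid bounds")
    axes = [np.arange(lo[d], hi[d] + params.spacing / 2, params.spacing)
            for d in range(3)]
    shape = tuple(len(a) for a in axes)
    occluded = np.zeros(shape, dtype=bool)
    # stamp each atom's occlusion sphere onto the grid
    for center, r in zip(coords, radii):
        ilo = [np.searchsorted(axes[d], center[d] - r, "left")
               for d in range(3)]
        ihi = [np.searchsorted(axes[d], center[d] + r, "right")
               for d in range(3)]
        if any(ilo[d] >= ihi[d] for d in range(3)):
            continue
        sub = np.meshgrid(*[axes[d][ilo[d]:ihi[d]] for d in range(3)],
                          indexing="ij")
        dist2 = sum((sub[d] - center[d]) ** 2 for d in range(3))
        occluded[ilo[0]:ihi[0], ilo[1]:ihi[1], ilo[2]:ihi[2]] |= \
            dist2 <= r * r
    seed_idx = tuple(
        int(np.clip(round((seed[d] - lo[d]) / params.spacing), 0,
                    shape[d] - 1))
        for d in range(3))
    if occluded[seed_idx]:
        raise SeedOccludedError(
            f"seed point {seed} is occluded by protein atoms")
    structure = (ndimage.generate_binary_structure(3, 1)
                 if params.connectivity == 6
                 else ndimage.generate_binary_structure(3, 3))
    labels, _ = ndimage.label(~occluded, structure=structure)
    cavity = labels == labels[seed_idx]
    n = int(cavity.sum())
    touches = bool(cavity[0, :, :].any() or cavity[-1, :, :].any()
                   or cavity[:, 0, :].any() or cavity[:, -1, :].any()
                   or cavity[:, :, 0].any() or cavity[:, :, -1].any())
    return CavityResult(volume=n * params.spacing ** 3, n_points=n,
                        touches_boundary=touches)


@dataclass
class PoreParams:
    max_radius: float = 15.0          # cap in open vestibules
    radius_override: float | None = None
    n_perimeter_starts: int = 8
    perimeter_offset: float = 2.0     # Å ring of extra search starts


@dataclass
class PoreProfile:
    """Pore radius as a function of elevation z."""

    z: np.ndarray
    radius: np.ndarray
    center_x: np.ndarray
    center_y: np.ndarray
    blocked: np.ndarray               # bool per slice

    def to_table(self) -> str:
        lines = ["z\tradius\tx\ty"]
        for z, r, x, y in zip(self.z, self.radius, self.center_x,
                              self.center_y):
            lines.append(f"{z:.3f}\t{r:.3f}\t{x:.3f}\t{y:.3f}")
        return "\n".join(lines) + "\n"


def pore_profile(model: StructureModel, z_min: float, z_max: float,
                 step: float = 1.0, params: PoreParams | None = None,
                 start_xy: np.ndarray | None = None) -> PoreProfile:
    """HOLE-style pore profile.

    For each z slice, the radius of the largest sphere centered at
    (x, y, z) that overlaps no atom: r(c) = min_i(|c - r_i| - vdW_i),
    maximized over (x, y) by multi-start Nelder-Mead local search seeded
    from the previous slice's center (an approximation to HOLE's
    simulated annealing, adequate for smooth channels).
    """
    params = params or PoreParams()
    radii = vdw_radii(model, params.radius_override)
    coords = model.coords
    if z_min > z_max:
        raise ValueError("z_min must be <= z_max")
    zs = np.arange(z_min, z_max + step / 2, step)
    if start_xy is None:
        start_xy = coords[:, :2].mean(axis=0)
    center = np.asarray(start_xy, dtype=float)

    out_r, out_x, out_y, out_b = [], [], [], []
    max_vdw = radii.max() if len(radii) else DEFAULT_VDW
    for z in zs:
        near = np.abs(coords[:, 2] - z) <= params.max_radius + max_vdw
        sub_c = coords[near]
        sub_r = radii[near]

        if len(sub_c) == 0:
            out_r.append(params.max_radius)
            out_x.append(center[0]); out_y.append(center[1])
            out_b.append(False)
            continue

        def neg_clearance(xy, _c=sub_c, _r=sub_r, _z=z):
            p = np.array([xy[0], xy[1], _z])
            d = np.linalg.norm(_c - p, axis=1) - _r
            return -min(d.min(), params.max_radius)

        starts = [center]
        ang = np.linspace(0, 2 * np.pi, params.n_perimeter_starts,
                          endpoint=False)
        starts += [center + params.perimeter_offset *
                   np.array([np.cos(a), np.sin(a)]) for a in ang]
        best = None
        for s in starts:
            res = minimize(neg_clearance, s, method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-6,
                                    "maxiter": 400})
            if best is None or res.fun < best.fun:
                best = res
        r = min(-best.fun, params.max_radius)
        blocked = r <= 0
        if not blocked:
            center = np.asarray(best.x, dtype=float)
        out_r.append(max(r, 0.0))
        out_x.append(best.x[0]); out_y.append(best.x[1])
        out_b.append(blocked)
    return PoreProfile(z=zs, radius=np.array(out_r),
                       center_x=np.array(out_x), center_y=np.array(out_y),
                       blocked=np.array(out_b, dtype=bool))
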