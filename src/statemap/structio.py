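"""Structure/ensemble I/O and residue-range atom selection.

Structures are exchanged as fixed-column PDB text (single- or
multi-model); multi-model files stand in for trajectories.  Parsing and
serialisation are delegated to :mod:`biotite.structure.io.pdb`; this
module exposes a flat, array-backed view suited to the descriptor
calculations downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
from biotite.structure.info import mass as _element_mass

WATER_RESNAMES = frozenset({"HOH", "TIP3", "TIP", "WAT", "SOL", "H2O"})

#: fallback mass (Da) when the element is unknown
DEFAULT_MASS = 12.0


class StructureError(ValueError):
    """Raised on malformed or unusable structure input."""


@dataclass
class StructureModel:
    """A single conformer: flat per-atom records plus an (N, 3) coordinate array (Å)."""

    serial: np.ndarray          # int, PDB atom serial
    atom_name: np.ndarray       # str
    res_name: np.ndarray        # str
    res_id: np.ndarray          # int
    chain_id: np.ndarray        # str
    element: np.ndarray         # str
    coords: np.ndarray          # (N, 3) float, Å
    occupancy: np.ndarray | None = None
    hetero: np.ndarray | None = None      # bool, HETATM flag
    is_water: np.ndarray | None = None    # bool
    masses: np.ndarray | None = None      # Da, lazily filled

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError("coordinates must be an (N, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("coordinates must be finite")
        n = self.coords.shape[0]
        if n == 0:
            raise StructureError("empty structure (zero atoms)")
        if any(len(a) != n for a in (self.serial, self.atom_name, self.res_name,
                                     self.res_id, self.chain_id, self.element)):
            raise StructureError("per-atom record arrays have inconsistent lengths")
        if any(len(str(nm)) == 0 for nm in self.atom_name):
            raise StructureError("every atom must have a nonempty name")
        if self.hetero is None:
            self.hetero = np.zeros(n, dtype=bool)
        if self.is_water is None:
            self.is_water = np.isin(self.res_name, list(WATER_RESNAMES))

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def get_masses(self) -> np.ndarray:
        """Element-based atomic masses (Da); unknown elements default to 12.0 Da."""
        if self.masses is None:
            out = np.empty(self.n_atoms)
            warned = set()
            for i, el in enumerate(self.element):
                m = None
                if el:
                    try:
                        m = _element_mass(str(el).capitalize())
                    except KeyError:
                        m = None
                if m is None:
                    if el not in warned:
                        warnings.warn(
                            f"unknown element {el!r}: using {DEFAULT_MASS} Da")
                        warned.add(el)
                    m = DEFAULT_MASS
                out[i] = m
            self.masses = out
        return self.masses

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        """Copy of this model sharing topology but holding new coordinates."""
        return StructureModel(
            serial=self.serial, atom_name=self.atom_name, res_name=self.res_name,
            res_id=self.res_id, chain_id=self.chain_id, element=self.element,
            coords=np.asarray(coords, dtype=float).copy(),
            occupancy=self.occupancy, hetero=self.hetero,
            is_water=self.is_water, masses=self.masses)


@dataclass
class Trajectory:
    """Ordered conformer frames sharing one topology."""

    topology: StructureModel
    frames: list[np.ndarray]                 # each (N, 3), Å
    frame_times: np.ndarray | None = None    # ns

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        for i, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise StructureError(
                    f"frame {i} has shape {f.shape}, expected ({n}, 3)")
            self.frames[i] = f
        if self.frame_times is not None:
            t = np.asarray(self.frame_times, dtype=float)
            if len(t) != len(self.frames):
                raise StructureError("frame_times length mismatch")
            if np.any(np.diff(t) <= 0):
                raise StructureError("frame_times must be strictly increasing")
            self.frame_times = t

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_model(self, i: int) -> StructureModel:
        return self.topology.with_coords(self.frames[i])

    def __iter__(self):
        for f in self.frames:
            yield self.topology.with_coords(f)


@dataclass(frozen=True)
class SelectionSpec:
    """Chain / residue-range / atom-name selection (range inclusive)."""

    first: int
    last: int
    atom_names: frozenset[str] = frozenset({"CA"})
    chain: str | None = None

    def __post_init__(self) -> None:
        if self.first > self.last:
            raise ValueError(
                f"residue range [{self.first}, {self.last}] has first > last")
        if not self.atom_names:
            raise ValueError("atom-name set must be nonempty")
        object.__setattr__(self, "atom_names", frozenset(self.atom_names))


def _model_from_atom_array(arr: struc.AtomArray) -> StructureModel:
    if np.any(arr.ins_code != ""):
        bad = np.nonzero(arr.ins_code != "")[0][0]
        raise StructureError(
            f"residue insertion codes are unsupported (first at atom serial "
            f"{arr.atom_id[bad]}, residue {arr.res_id[bad]})")
    return StructureModel(
        serial=arr.atom_id.copy(),
        atom_name=arr.atom_name.copy(),
        res_name=arr.res_name.copy(),
        res_id=arr.res_id.copy(),
        chain_id=arr.chain_id.copy(),
        element=arr.element.copy(),
        coords=arr.coord.astype(float).copy(),
        occupancy=getattr(arr, "occupancy", None),
        hetero=arr.hetero.copy(),
    )


def read_structure(path: str | Path,
                   dialect: str = "pdb") -> StructureModel | Trajectory:
    """Read a PDB file into a :class:`StructureModel` or, for multi-model
    files read with ``dialect="pdb-multimodel"``, a :class:`Trajectory`.

    Waters (HOH/TIP3/...) and hetero groups are retained and flagged.
    Alternate locations: first altloc kept, others dropped.
    """
    if dialect not in ("pdb", "pdb-multimodel"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pfile = pdbio.PDBFile.read(str(path))
    except Exception as exc:  # biotite reports the offending line
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    try:
        n_models = pfile.get_model_count()
    except Exception as exc:
        raise StructureError(f"{path} contains no parseable models: {exc}") from exc
    if n_models == 0:
        raise StructureError(f"{path} contains zero atoms")

    def _get(model: int) -> struc.AtomArray:
        try:
            return pfile.get_structure(
                model=model, extra_fields=["atom_id", "occupancy"],
                altloc="first")
        except Exception as exc:
            raise StructureError(f"cannot parse {path}: {exc}") from exc

    if dialect == "pdb" or n_models == 1:
        model = _model_from_atom_array(_get(1))
        if dialect == "pdb-multimodel":
            return Trajectory(topology=model, frames=[model.coords])
        return model
    first = _model_from_atom_array(_get(1))
    frames = [first.coords]
    for m in range(2, n_models + 1):
        arr = _get(m)
        if arr.array_length() != first.n_atoms:
            raise StructureError(
                f"MODEL {m} has {arr.array_length()} atoms, expected "
                f"{first.n_atoms}")
        frames.append(arr.coord.astype(float).copy())
    return Trajectory(topology=first, frames=frames)


def _atom_array_from_model(model: StructureModel,
                           coords: np.ndarray | None = None) -> struc.AtomArray:
    n = model.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords if coords is not None else model.coords,
                           dtype=np.float32)
    arr.atom_name = model.atom_name
    arr.res_name = model.res_name
    arr.res_id = model.res_id
    arr.chain_id = model.chain_id
    arr.element = model.element
    arr.hetero = (model.hetero if model.hetero is not None
                  else np.zeros(n, bool))
    arr.set_annotation("atom_id", np.asarray(model.serial, dtype=int))
    if model.occupancy is not None:
        arr.set_annotation("occupancy", np.asarray(model.occupancy, float))
    return arr


def write_structure(obj: StructureModel | Trajectory, path: str | Path,
                    dialect: str = "pdb") -> None:
    """Write a model (one MODEL block) or trajectory (one block per frame).

    PDB fixed columns limit coordinates to (-999.999, 9999.999] Å; values
    outside raise a format-overflow error.
    """
    if isinstance(obj, Trajectory):
        coords_list = obj.frames
        model = obj.topology
    else:
        coords_list = [obj.coords]
        model = obj
    for coords in coords_list:
        if np.any(coords > 9999.999) or np.any(coords < -999.999):
            raise StructureError(
                "coordinate out of PDB fixed-column range (±999.999/9999.999 Å)")
    pfile = pdbio.PDBFile()
    if len(coords_list) == 1 and not isinstance(obj, Trajectory):
        pfile.set_structure(_atom_array_from_model(model))
    else:
        stack = struc.stack(
            [_atom_array_from_model(model, c) for c in coords_list])
        pfile.set_structure(stack)
    pfile.write(str(path))


def select_atoms(model: StructureModel, spec: SelectionSpec) -> np.ndarray:
    """Indices of atoms matching *spec*, ordered by serial.

    An empty result is returned (with a warning) rather than raised, so
    callers can decide; duplicate serials among the matched atoms are an
    error since they make the selection ambiguous.
    """
    mask = (model.res_id >= spec.first) & (model.res_id <= spec.last)
    mask &= np.isin(model.atom_name, list(spec.atom_names))
    if spec.chain is not None:
        mask &= model.chain_id == spec.chain
    idx = np.nonzero(mask)[0]
    idx = idx[np.argsort(model.serial[idx], kind="stable")]
    if len(idx) == 0:
        warnings.warn(
            f"selection [{spec.first}-{spec.last}] {sorted(spec.atom_names)} "
            f"matched no atoms")
        return idx
    serials = model.serial[idx]
    if len(np.unique(serials)) != len(serials):
        raise StructureError("duplicate atom serials in selection")
    return idx
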