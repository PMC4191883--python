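"""Biased-sampling machinery at desk scale.

Implements the accelerated-MD dihedral boost potential
``ΔV = (E − V)² / (α + E − V)`` (applied when V < E) with exponential
reweighting, and the targeted-MD steering force
``F = ½ (k/N) (RMSD(t) − RMSD*(t))`` with a linearly decaying RMSD
setpoint.  Both are exercised by overdamped Langevin toy integrators —
a 1-D periodic dihedral potential for aMD and a small elastic bead
chain for tMD.  The formulas and their contracts are the point; the
toys make them testable without all-atom trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from statemap.structio import StructureModel, Trajectory
from statemap.geometry import kabsch_rmsd

#: Boltzmann constant, kcal/(mol·K)
KB = 0.0019872041


@dataclass
class AmdParams:
    """Accelerated-MD boost parameters (kcal/mol)."""

    E: float = 18600.0       # boost threshold energy
    alpha: float = 210.0     # smoothing parameter
    temperature: float = 310.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")

    @property
    def kbt(self) -> float:
        return KB * self.temperature


def amd_boost(V, params: AmdParams):
    """Boost potential ΔV; zero when V >= E, else (E−V)²/(α+E−V).

    Vectorized over V.  The boosted surface V* = V + ΔV satisfies
    V* <= E and is C¹-continuous at V = E.
    """
    V = np.asarray(V, dtype=float)
    gap = params.E - V
    safe = np.where(gap > 0, gap, 0.0)
    dv = safe * safe / (params.alpha + safe)
    return float(dv) if dv.ndim == 0 else dv


def amd_force_factor(V, params: AmdParams):
    """dV*/dV on the boosted surface: (α/(α+E−V))² below threshold, 1 above.

    The boosted force is the unbiased force scaled by this factor.
    """
    V = np.asarray(V, dtype=float)
    gap = params.E - V
    safe = np.where(gap > 0, gap, 0.0)
    fac = (params.alpha / (params.alpha + safe)) ** 2
    fac = np.where(gap > 0, fac, 1.0)
    return float(fac) if fac.ndim == 0 else fac


def amd_reweight(boost_series: np.ndarray, temperature: float = 310.0
                 ) -> np.ndarray:
    """Normalized frame weights w_i ∝ exp(ΔV_i / kBT) (max-shifted)."""
    dv = np.asarray(boost_series, dtype=float)
    if not np.all(np.isfinite(dv)):
        raise ValueError("boost series must be finite")
    x = dv / (KB * temperature)
    x = x - x.max()
    w = np.exp(x)
    return w / w.sum()


@dataclass
class TmdParams:
    """Targeted-MD steering parameters."""

    k: float = 200.0         # spring constant, kcal/(mol·Å²)
    n_atoms: int = 1         # number of targeted atoms N
    rmsd0: float = 0.0       # schedule start RMSD(0), Å
    duration: float = 1.0    # schedule length (time units of the run)

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.n_atoms < 1:
            raise ValueError("N must be >= 1")


def tmd_target_rmsd(t: float, params: TmdParams) -> float:
    """Linear-decay setpoint RMSD*(t) = RMSD(0) · (1 − t/duration)."""
    if t < 0 or t > params.duration:
        raise ValueError(f"t={t} outside schedule [0, {params.duration}]")
    return params.rmsd0 * (1.0 - t / params.duration)


def tmd_force_magnitude(rmsd_now: float, t: float, params: TmdParams
                        ) -> float:
    """Steering force magnitude ½ (k/N)(RMSD(t) − RMSD*(t)), kcal/(mol·Å).

    Negative values mean the two-sided restraint pushes the structure
    *away* from the target (it is ahead of schedule).
    """
    if rmsd_now < 0:
        raise ValueError("rmsd_now must be >= 0")
    return 0.5 * (params.k / params.n_atoms) * (
        rmsd_now - tmd_target_rmsd(t, params))


def tmd_restraint_energy(rmsd_now: float, t: float, params: TmdParams
                         ) -> float:
    """Restraint energy ½ (k/N)(RMSD − RMSD*)², minimized on-schedule."""
    return 0.5 * (params.k / params.n_atoms) * (
        rmsd_now - tmd_target_rmsd(t, params)) ** 2


def tmd_forces(coords: np.ndarray, target: np.ndarray, t: float,
               params: TmdParams) -> tuple[np.ndarray, float]:
    """Per-atom tMD restraint forces (negative energy gradient).

    The target is rotated onto the instantaneous structure (Kabsch) each
    step; for RMSD > 0 the gradient of RMSD w.r.t. atom i is
    (r_i − r'_target,i) / (N · RMSD), the rotation's own derivative
    vanishing at the optimum.  Returns (forces, current RMSD).
    """
    rmsd, rot, trans = kabsch_rmsd(coords, target)
    fitted_target = target @ rot.T + trans
    n = coords.shape[0]
    if rmsd < 1e-12:
        return np.zeros_like(coords), rmsd
    grad_rmsd = (coords - fitted_target) / (n * rmsd)
    dedr = (params.k / params.n_atoms) * (
        rmsd - tmd_target_rmsd(t, params)) * grad_rmsd
    return -dedr, rmsd


@dataclass
class IntegratorSettings:
    """Overdamped (Brownian) Langevin integrator settings."""

    dt: float = 0.01               # time step (toy units)
    friction: float = 1.0          # gamma
    temperature: float = 310.0     # K
    n_steps: int = 5000
    record_every: int = 10


def _elastic_network(coords: np.ndarray, cutoff: float
                     ) -> tuple[np.ndarray, np.ndarray]:
    n = coords.shape[0]
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                pairs.append((i, j))
    pairs = np.array(pairs, dtype=int)
    eq = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    return pairs, eq


def _network_forces(coords: np.ndarray, pairs: np.ndarray, eq: np.ndarray,
                    k_net: float) -> np.ndarray:
    f = np.zeros_like(coords)
    d = coords[pairs[:, 0]] - coords[pairs[:, 1]]
    dist = np.linalg.norm(d, axis=1)
    mag = -k_net * (dist - eq)          # force along the bond
    unit = d / dist[:, None]
    contrib = mag[:, None] * unit
    np.add.at(f, pairs[:, 0], contrib)
    np.add.at(f, pairs[:, 1], -contrib)
    return f


def run_toy_tmd(start: np.ndarray, target: np.ndarray,
                params: TmdParams | None = None,
                settings: IntegratorSettings | None = None,
                seed: int = 0, network_cutoff: float = 6.0,
                k_network: float = 0.05,
                external_force_z: float = 0.0
                ) -> tuple[Trajectory, np.ndarray, np.ndarray]:
    """Steer a bead chain from start to target coordinates.

    Overdamped Langevin on a soft elastic network (springs with
    equilibrium at the start geometry keep the chain intact) plus the
    two-sided tMD restraint.  An optional constant z-force emulates a
    weak external membrane-normal potential.

    Returns (trajectory, times, rmsd_series); RMSD is measured to the
    target after Kabsch superposition.
    """
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    if start.shape != target.shape:
        raise ValueError("start/target topology mismatch")
    settings = settings or IntegratorSettings()
    if params is None:
        r0, _, _ = kabsch_rmsd(start, target)
        params = TmdParams(k=200.0, n_atoms=start.shape[0], rmsd0=r0,
                           duration=settings.dt * settings.n_steps)
    rng = np.random.default_rng(seed)
    pairs, eq = _elastic_network(start, network_cutoff)
    coords = start.copy()
    kbt = KB * settings.temperature
    noise_scale = np.sqrt(2.0 * kbt * settings.dt / settings.friction)
    frames, rmsds, times = [], [], []
    for step in range(settings.n_steps + 1):
        t = min(step * settings.dt, params.duration)
        f_tmd, rmsd = tmd_forces(coords, target, t, params)
        if step % settings.record_every == 0:
            frames.append(coords.copy())
            rmsds.append(rmsd)
            times.append(t)
        if step == settings.n_steps:
            break
        f = f_tmd + _network_forces(coords, pairs, eq, k_network)
        f[:, 2] += external_force_z
        if not np.all(np.isfinite(f)):
            raise FloatingPointError(
                f"non-finite forces at step {step}: reduce the time step")
        coords = (coords + settings.dt / settings.friction * f
                  + noise_scale * rng.standard_normal(coords.shape))
    topo = _bead_topology(start.shape[0])
    traj = Trajectory(topology=topo.with_coords(frames[0]), frames=frames)
    return traj, np.array(times), np.array(rmsds)


def _bead_topology(n: int) -> StructureModel:
    return StructureModel(
        serial=np.arange(1, n + 1),
        atom_name=np.array(["CA"] * n),
        res_name=np.array(["GLY"] * n),
        res_id=np.arange(1, n + 1),
        chain_id=np.array(["A"] * n),
        element=np.array(["C"] * n),
        coords=np.zeros((n, 3)),
    )


@dataclass
class DihedralPotential:
    """1-D periodic potential V(φ) = Σ_m h_m (1 − cos(m φ − δ_m))."""

    terms: tuple[tuple[float, int, float], ...] = ((5.0, 2, 0.0),)

    def energy(self, phi):
        phi = np.asarray(phi, dtype=float)
        v = sum(h * (1.0 - np.cos(m * phi - d)) for h, m, d in self.terms)
        return float(v) if np.ndim(v) == 0 else v

    def gradient(self, phi):
        phi = np.asarray(phi, dtype=float)
        g = sum(h * m * np.sin(m * phi - d) for h, m, d in self.terms)
        return float(g) if np.ndim(g) == 0 else g


@dataclass
class AmdRunResult:
    phi: np.ndarray
    energy: np.ndarray        # V(φ) per recorded step
    boost: np.ndarray         # ΔV per recorded step
    weights: np.ndarray       # reweighting weights (normalized)


def run_toy_amd(potential: DihedralPotential, params: AmdParams,
                n_steps: int = 100_000, dt: float = 0.005,
                friction: float = 1.0, seed: int = 0,
                phi0: float = 0.0) -> AmdRunResult:
    """Boosted overdamped Langevin sampling of a 1-D dihedral potential.

    The boosted force is the unbiased force scaled by
    (α/(α+E−V))² wherever V < E.  With E at or below the global
    minimum the boost never activates (a warning is emitted) and the
    run reduces to unbiased dynamics.
    """
    phi_grid = np.linspace(-np.pi, np.pi, 721)
    vmin = potential.energy(phi_grid).min()
    if params.E <= vmin:
        import warnings
        warnings.warn("aMD threshold E is below the potential minimum: "
                      "boost is inactive everywhere")
    rng = np.random.default_rng(seed)
    kbt = params.kbt
    noise = np.sqrt(2.0 * kbt * dt / friction)
    phi = float(phi0)
    phis = np.empty(n_steps)
    for i in range(n_steps):
        v = potential.energy(phi)
        fac = amd_force_factor(v, params)
        force = -potential.gradient(phi) * fac
        phi += dt / friction * force + noise * rng.standard_normal()
        phi = (phi + np.pi) % (2 * np.pi) - np.pi
        phis[i] = phi
    energies = potential.energy(phis)
    boosts = amd_boost(energies, params)
    weights = amd_reweight(boosts, params.temperature)
    return AmdRunResult(phi=phis, energy=energies, boost=boosts,
                        weights=weights)


def count_well_crossings(phi: np.ndarray,
                         boundary: float = np.pi / 2) -> int:
    """Transitions between the |φ| < boundary well and its complement."""
    in_a = np.abs(phi) < boundary
    return int(np.sum(in_a[1:] != in_a[:-1]))


def boltzmann_well_population(potential: DihedralPotential,
                              temperature: float = 310.0,
                              boundary: float = np.pi / 2,
                              n_grid: int = 20001) -> float:
    """Boltzmann probability of the |φ| < boundary well by quadrature."""
    phi = np.linspace(-np.pi, np.pi, n_grid)
    v = potential.energy(phi)
    w = np.exp(-(v - v.min()) / (KB * temperature))
    inside = np.abs(phi) < boundary
    return float(np.trapezoid(w * inside, phi) / np.trapezoid(w, phi))


def weighted_population(phi: np.ndarray, weights: np.ndarray,
                        boundary: float = np.pi / 2) -> float:
    """Reweighted occupancy of the |φ| < boundary well."""
    inside = np.abs(phi) < boundary
    return float(np.sum(weights * inside))


def block_bootstrap_se(phi: np.ndarray, boost: np.ndarray,
                       temperature: float, boundary: float = np.pi / 2,
                       n_blocks: int = 50, n_boot: int = 200,
                       seed: int = 0) -> float:
    """Standard error of the reweighted well population by block bootstrap
    (blocks preserve the sample's serial correlation)."""
    rng = np.random.default_rng(seed)
    n = len(phi)
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    blocks = [(phi[a:b], boost[a:b]) for a, b in zip(edges[:-1], edges[1:])]
    stats = []
    for _ in range(n_boot):
        pick = rng.integers(0, n_blocks, n_blocks)
        p = np.concatenate([blocks[i][0] for i in pick])
        b = np.concatenate([blocks[i][1] for i in pick])
        w = amd_reweight(b, temperature)
        stats.append(weighted_population(p, w, boundary))
    return float(np.std(stats, ddof=1))
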