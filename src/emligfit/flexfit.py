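"""Density-guided flexible fitting by Langevin dynamics.

Atoms evolve under the structure-native restraint forces plus an external
density force: the gradient of the masked model-to-map cross-correlation,
scaled by a force constant k (kJ/mol).  Following common practice for
density-guided simulation, the density force is recomputed every N
integration steps (default 2) and held constant in between, and k grows
adaptively whenever the similarity stops improving.  Dynamics are in
vacuum with a v-rescale-like Langevin thermostat at 310 K; solvent is
irrelevant to the map-force mechanics this engine exercises.

Units: kJ/mol, Angstrom, ps, amu, K.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .densmap import MapSimParams, cc_with_gradient, entity_ccs
from .fflite import FFParams, derive_params, energy_forces, plie
from .structio import (DensityGrid, Selection, Structure, heavy_atoms,
                       protein_selection, select_ligand, select_pocket)

KB = 0.008314462618        # kJ/mol/K
FORCE_TO_ACC = 100.0       # (kJ/mol/A)/amu -> A/ps^2
VEL_UNIT = 10.0            # sqrt(kJ/mol/amu) -> A/ps


class FlexFitError(RuntimeError):
    """Dynamics aborted; carries the last valid trajectory for diagnosis."""

    def __init__(self, message: str, trajectory=None, trace=None):
        super().__init__(message)
        self.trajectory = trajectory
        self.trace = trace


@dataclass
class AdaptiveScaling:
    """Grow k by ``growth_factor`` when cc improves less than ``cc_epsilon``
    over ``check_interval`` consecutive density-force applications."""

    enabled: bool = True
    check_interval: int = 50
    cc_epsilon: float = 1e-4
    growth_factor: float = 1.05
    k_max: float = 1e5

    def __post_init__(self) -> None:
        if self.check_interval < 2:
            raise ValueError("check_interval must be >= 2")
        if self.growth_factor < 1.0:
            raise ValueError("growth_factor must be >= 1")


@dataclass
class PreRelax:
    """Restrained energy minimisation before dynamics.

    Restraint constants are in kJ/mol/nm^2 (the conventional unit for
    position restraints); backbone means protein N/CA/C atoms.
    """

    enabled: bool = True
    minimize_steps: int = 5000
    backbone_restraint: float = 400.0
    sidechain_restraint: float = 40.0


@dataclass
class FitConfig:
    """All knobs of a density-guided fitting run."""

    timestep_fs: float = 2.0
    temperature: float = 310.0
    friction: float = 1.0               # 1/ps
    force_constant_k: float = 1e3       # kJ/mol
    density_force_interval: int = 2     # steps between density-force updates
    adaptive: AdaptiveScaling = field(default_factory=AdaptiveScaling)
    duration_ps: float = 50.0
    seed: int = 0
    force_cap: float = 1e4              # kJ/mol/A per atom
    trace_interval_fs: float = 50.0
    frame_interval_ps: float = 1.0
    pre_relax: PreRelax = field(default_factory=PreRelax)
    ligand_name: str = "auto"
    pocket_cutoff: float = 4.0

    def __post_init__(self) -> None:
        if self.timestep_fs <= 0:
            raise ValueError("timestep must be positive")
        if self.force_constant_k < 0:
            raise ValueError("force constant must be non-negative")
        if self.density_force_interval < 1:
            raise ValueError("density_force_interval must be >= 1")
        if self.adaptive.k_max < self.force_constant_k:
            raise ValueError("k_max must be >= the initial force constant")


@dataclass
class Trace:
    """Monitoring series sampled on a fixed time grid during fitting."""

    time: np.ndarray
    cc_ligand: np.ndarray
    cc_pocket: np.ndarray
    cc_protein: np.ndarray
    plie_per_heavy_atom: np.ndarray
    k_current: np.ndarray
    events: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("cc_ligand", "cc_pocket", "cc_protein",
                     "plie_per_heavy_atom", "k_current"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"trace series {name} has wrong length")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("trace times must be strictly increasing")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time_ps", "cc_ligand", "cc_pocket", "cc_protein",
                        "plie_per_heavy_atom", "k_current"])
            for row in zip(self.time, self.cc_ligand, self.cc_pocket,
                           self.cc_protein, self.plie_per_heavy_atom,
                           self.k_current):
                w.writerow([f"{v:.10g}" for v in row])

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trace":
        data = np.genfromtxt(path, delimiter=",", names=True)
        data = np.atleast_1d(data)
        return cls(time=data["time_ps"], cc_ligand=data["cc_ligand"],
                   cc_pocket=data["cc_pocket"], cc_protein=data["cc_protein"],
                   plie_per_heavy_atom=data["plie_per_heavy_atom"],
                   k_current=data["k_current"])


@dataclass
class Trajectory:
    """Saved frames with timestamps (ps)."""

    frames: list[Structure]
    times: list[float]
    save_interval_ps: float

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.times):
            raise ValueError("frames/times length mismatch")


def density_force(structure: Structure, selection: Selection,
                  target_map: DensityGrid, params: MapSimParams,
                  k: float, force_cap: Optional[float] = None
                  ) -> np.ndarray:
    """External map force: k times the cc gradient, on heavy atoms only.

    When ``force_cap`` is given, per-atom force norms are clipped to it.
    """
    _, grad = cc_with_gradient(structure, selection, target_map, params)
    forces = k * grad
    if force_cap is not None:
        norms = np.linalg.norm(forces, axis=1)
        over = norms > force_cap
        if over.any():
            forces[over] *= (force_cap / norms[over])[:, None]
    return forces


def adaptive_scale(cc_window: np.ndarray, k_current: float,
                   config: FitConfig) -> float:
    """One adaptive-force-scaling decision.

    If the cc improvement over the window is below ``cc_epsilon`` the force
    constant grows by ``growth_factor`` (capped at ``k_max``); k never
    decreases.
    """
    ad = config.adaptive
    cc_window = np.asarray(cc_window, dtype=float)
    if len(cc_window) != ad.check_interval:
        raise ValueError("window length must equal check_interval")
    improvement = cc_window[-1] - cc_window[0]
    if improvement < ad.cc_epsilon:
        return min(k_current * ad.growth_factor, ad.k_max)
    return k_current


def _minimize(coords: np.ndarray, ffp: FFParams, anchors: np.ndarray,
              restraint_k: np.ndarray, max_steps: int) -> np.ndarray:
    """Steepest-descent minimisation with harmonic position restraints."""
    def eval_at(x):
        e, f = energy_forces(x, ffp)
        dr = x - anchors
        e += float((restraint_k[:, None] * dr ** 2).sum())
        f = f - 2.0 * restraint_k[:, None] * dr
        return e, f

    step = 0.01  # max per-step displacement, A
    x = coords.copy()
    e, f = eval_at(x)
    for _ in range(max_steps):
        fmax = np.abs(f).max()
        if fmax < 10.0:
            break
        x_new = x + step * f / fmax
        e_new, f_new = eval_at(x_new)
        if e_new < e:
            x, e, f = x_new, e_new, f_new
            step = min(step * 1.2, 0.05)
        else:
            step *= 0.5
            if step < 1e-8:
                break
    return x


def run_flexfit(structure: Structure, target_map: DensityGrid,
                config: FitConfig, params: MapSimParams,
                ff_params: Optional[FFParams] = None
                ) -> tuple[Trajectory, Trace]:
    """Density-guided Langevin dynamics; returns trajectory and trace.

    Deterministic given the config seed.  The run terminates gracefully
    with an event ``force_cap_exceeded`` when more than 1% of atoms feel a
    raw density force above ``force_cap``, keeping the last valid frame.
    """
    n = len(structure)
    if ff_params is None:
        ff_params = derive_params(structure)

    lig_sel = select_ligand(structure, config.ligand_name)
    pocket_sel = select_pocket(structure, lig_sel, cutoff=config.pocket_cutoff)
    prot_sel = protein_selection(structure)
    all_sel = Selection(np.arange(n), label="custom")
    heavy_sel = heavy_atoms(all_sel, structure)

    masses = structure.masses()
    coords = structure.coords()

    # restrained pre-relaxation (energy minimisation)
    if config.pre_relax.enabled and config.pre_relax.minimize_steps > 0:
        is_backbone = np.array(
            [(not a.is_hetero) and a.name in {"N", "CA", "C"}
             for a in structure.atoms])
        restraint_k = np.where(is_backbone,
                               config.pre_relax.backbone_restraint / 100.0,
                               config.pre_relax.sidechain_restraint / 100.0)
        coords = _minimize(coords, ff_params, coords.copy(), restraint_k,
                           config.pre_relax.minimize_steps)

    dt = config.timestep_fs * 1e-3           # ps
    n_steps = int(round(config.duration_ps / dt))
    trace_stride = max(1, int(round(config.trace_interval_fs
                                    / config.timestep_fs)))
    frame_stride = max(1, int(round(config.frame_interval_ps / dt)))

    rng = np.random.default_rng(config.seed)
    gamma = config.friction
    a_coef = np.exp(-gamma * dt)
    sigma_v = VEL_UNIT * np.sqrt(KB * config.temperature / masses)
    b_coef = np.sqrt(max(0.0, 1.0 - a_coef * a_coef))

    k_current = config.force_constant_k
    cc_window: list[float] = []
    events: list[tuple[float, str]] = []

    t_time: list[float] = []
    t_ccl: list[float] = []
    t_ccp: list[float] = []
    t_ccpr: list[float] = []
    t_plie: list[float] = []
    t_k: list[float] = []
    frames: list[Structure] = []
    frame_times: list[float] = []

    sels = {"ligand": lig_sel, "protein": prot_sel}
    if len(pocket_sel):
        sels["pocket"] = pocket_sel

    def sample_trace(time_ps: float, x: np.ndarray) -> None:
        posed = structure.with_coords(x)
        ccs = entity_ccs(posed, sels, target_map, params)
        t_time.append(time_ps)
        t_ccl.append(ccs["ligand"].cc)
        t_ccp.append(ccs["pocket"].cc if "pocket" in ccs else float("nan"))
        t_ccpr.append(ccs["protein"].cc)
        t_plie.append(plie(posed, prot_sel, lig_sel, ff_params).per_heavy_atom)
        t_k.append(k_current)

    def save_frame(time_ps: float, x: np.ndarray) -> None:
        frames.append(structure.with_coords(x))
        frame_times.append(time_ps)

    sample_trace(0.0, coords)
    save_frame(0.0, coords)

    if n_steps == 0:
        return (Trajectory(frames, frame_times, config.frame_interval_ps),
                Trace(np.array(t_time), np.array(t_ccl), np.array(t_ccp),
                      np.array(t_ccpr), np.array(t_plie), np.array(t_k),
                      events))

    velocities = np.zeros((n, 3))
    dens_forces = np.zeros((n, 3))
    terminated = False

    def total_force(x: np.ndarray) -> np.ndarray:
        _, f = energy_forces(x, ff_params)
        return f + dens_forces

    def update_density_force(x: np.ndarray, time_ps: float) -> bool:
        """Recompute density force; returns False on graceful termination."""
        nonlocal dens_forces, k_current
        posed = structure.with_coords(x)
        cc, grad = cc_with_gradient(posed, heavy_sel, target_map, params)
        raw = k_current * grad
        norms = np.linalg.norm(raw, axis=1)
        over = norms > config.force_cap
        if over.sum() > 0.01 * n:
            events.append((time_ps, "force_cap_exceeded"))
            return False
        if over.any():
            raw[over] *= (config.force_cap / norms[over])[:, None]
        dens_forces = raw
        if config.adaptive.enabled and k_current > 0:
            cc_window.append(cc)
            if len(cc_window) >= config.adaptive.check_interval:
                k_new = adaptive_scale(
                    np.array(cc_window[-config.adaptive.check_interval:]),
                    k_current, config)
                if k_new > k_current:
                    k_current = k_new
                cc_window.clear()
        return True

    if k_current > 0:
        if not update_density_force(coords, 0.0):
            return (Trajectory(frames, frame_times, config.frame_interval_ps),
                    Trace(np.array(t_time), np.array(t_ccl), np.array(t_ccp),
                          np.array(t_ccpr), np.array(t_plie), np.array(t_k),
                          events))

    forces = total_force(coords)
    inv_m = (FORCE_TO_ACC / masses)[:, None]

    for step in range(1, n_steps + 1):
        time_ps = step * dt
        velocities += 0.5 * dt * forces * inv_m
        coords += 0.5 * dt * velocities
        noise = rng.standard_normal((n, 3))
        velocities = a_coef * velocities + b_coef * sigma_v[:, None] * noise
        coords += 0.5 * dt * velocities

        if not np.all(np.isfinite(coords)):
            traj = Trajectory(frames, frame_times, config.frame_interval_ps)
            raise FlexFitError(
                f"non-finite coordinates at step {step}; last valid frame "
                f"saved at t = {frame_times[-1]} ps", trajectory=traj)

        if k_current > 0 and step % config.density_force_interval == 0:
            if not update_density_force(coords, time_ps):
                terminated = True
        forces = total_force(coords)
        velocities += 0.5 * dt * forces * inv_m

        if step % trace_stride == 0 or step == n_steps or terminated:
            sample_trace(time_ps, coords)
        if step % frame_stride == 0 or step == n_steps or terminated:
            save_frame(time_ps, coords)
        if terminated:
            break

    return (Trajectory(frames, frame_times, config.frame_interval_ps),
            Trace(np.array(t_time), np.array(t_ccl), np.array(t_ccp),
                  np.array(t_ccpr), np.array(t_plie), np.array(t_k),
                  events))


def last_n_mean(trace: Trace, trajectory: Trajectory, n: int = 20,
                field: str = "cc_ligand") -> tuple[float, float]:
    """Mean and standard error of a trace field over the final n saved frames.

    With fewer than n frames the reduction covers all of them and a warning
    event is appended to the trace.
    """
    if field not in {"cc_ligand", "cc_pocket", "cc_protein",
                     "plie_per_heavy_atom", "k_current"}:
        raise ValueError(f"unknown trace field {field!r}")
    series = np.asarray(getattr(trace, field), dtype=float)
    times = np.asarray(trace.time, dtype=float)
    frame_times = np.asarray(trajectory.times, dtype=float)
    if len(frame_times) < n:
        trace.events.append((float(times[-1]) if len(times) else 0.0,
                             f"last_n_mean over {len(frame_times)} < {n} frames"))
        chosen = frame_times
    else:
        chosen = frame_times[-n:]
    idx = []
    for t in chosen:
        j = int(np.argmin(np.abs(times - t)))
        if abs(times[j] - t) < 1e-6:
            idx.append(j)
    if not idx:
        raise ValueError("no trace samples coincide with trajectory frames")
    vals = series[idx]
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return mean, se
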