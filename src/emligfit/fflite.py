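"""Structure-native restraints and the protein-ligand interaction energy.

During density-guided fitting the internal force field only has to keep
stereochemistry intact — the density term dominates — so instead of a
transferable force field this module derives harmonic bond/angle restraints
whose equilibrium values are the observed geometry of a reference model
("structure-native" restraints), plus an element-based Lennard-Jones term
and optional cutoff Coulomb electrostatics.  The same nonbonded machinery
yields the protein-ligand interaction energy (PLIE) monitor, reported per
ligand heavy atom.  Energies are in kJ/mol, distances in Angstrom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .structio import Selection, Structure, heavy_atoms

#: Coulomb constant e^2/(4 pi eps0), in kJ/mol * Angstrom / e^2.
COULOMB_KE = 1389.35457644382

#: Per-element Lennard-Jones parameters (sigma in Angstrom, epsilon kJ/mol).
LJ_TABLE: dict[str, tuple[float, float]] = {
    "H": (2.50, 0.066), "C": (3.40, 0.36), "N": (3.25, 0.71),
    "O": (3.00, 0.88), "S": (3.56, 1.05), "P": (3.74, 0.84),
    "F": (3.12, 0.25), "Cl": (3.40, 1.10), "Br": (3.60, 1.25),
    "I": (3.80, 1.40),
}
_LJ_DEFAULT = (3.40, 0.40)

#: Covalent radii (Angstrom) for distance-based bond inference.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "Cl": 1.02, "Br": 1.20, "I": 1.39, "D": 0.31,
}
_RCOV_DEFAULT = 1.0

#: Bond inference tolerance: bonded if d < BOND_SCALE * (r_i + r_j).
BOND_SCALE = 1.3

DEFAULT_KB = 2000.0    # kJ/mol/A^2
DEFAULT_KTHETA = 200.0  # kJ/mol/rad^2


@dataclass
class FFParams:
    """Restraint-field parameters for one structure.

    ``pair_code[i, j]`` encodes the nonbonded status of a pair:
    0 full, 1 excluded (1-2 / 1-3), 2 scaled 1-4 (factor 0.5).
    """

    bond_idx: np.ndarray          # (nb, 2) int
    bond_r0: np.ndarray           # (nb,) A
    bond_k: np.ndarray            # (nb,) kJ/mol/A^2
    angle_idx: np.ndarray         # (na, 3) int, vertex at column 1
    angle_theta0: np.ndarray      # (na,) rad
    angle_k: np.ndarray           # (na,) kJ/mol/rad^2
    lj_sigma: np.ndarray          # (n,) A
    lj_eps: np.ndarray            # (n,) kJ/mol
    charges: np.ndarray           # (n,) e
    pair_code: np.ndarray         # (n, n) int8
    dielectric: float = 15.0
    metadata: dict = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return int(self.lj_sigma.size)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "bonds": [[int(i), int(j), float(r0), float(k)] for (i, j), r0, k
                      in zip(self.bond_idx, self.bond_r0, self.bond_k)],
            "angles": [[int(i), int(j), int(k), float(t0), float(kt)]
                       for (i, j, k), t0, kt
                       in zip(self.angle_idx, self.angle_theta0, self.angle_k)],
            "lj_sigma": self.lj_sigma.tolist(),
            "lj_eps": self.lj_eps.tolist(),
            "charges": self.charges.tolist(),
            "scaled14": [[int(i), int(j)] for i, j in
                         zip(*np.nonzero(np.triu(self.pair_code == 2)))],
            "excluded": [[int(i), int(j)] for i, j in
                         zip(*np.nonzero(np.triu(self.pair_code == 1)))],
            "dielectric": self.dielectric,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FFParams":
        doc = json.loads(Path(path).read_text())
        n = len(doc["lj_sigma"])
        bonds = np.array([b[:2] for b in doc["bonds"]], dtype=int).reshape(-1, 2)
        angles = np.array([a[:3] for a in doc["angles"]], dtype=int).reshape(-1, 3)
        pair_code = np.zeros((n, n), dtype=np.int8)
        for i, j in doc["excluded"]:
            pair_code[i, j] = pair_code[j, i] = 1
        for i, j in doc["scaled14"]:
            pair_code[i, j] = pair_code[j, i] = 2
        return cls(
            bond_idx=bonds,
            bond_r0=np.array([b[2] for b in doc["bonds"]], dtype=float),
            bond_k=np.array([b[3] for b in doc["bonds"]], dtype=float),
            angle_idx=angles,
            angle_theta0=np.array([a[3] for a in doc["angles"]], dtype=float),
            angle_k=np.array([a[4] for a in doc["angles"]], dtype=float),
            lj_sigma=np.array(doc["lj_sigma"], dtype=float),
            lj_eps=np.array(doc["lj_eps"], dtype=float),
            charges=np.array(doc["charges"], dtype=float),
            pair_code=pair_code,
            dielectric=float(doc.get("dielectric", 15.0)),
            metadata=doc.get("metadata", {}),
        )


@dataclass
class InteractionEnergy:
    """Protein-ligand nonbonded energy, also normalised per heavy atom."""

    total: float
    lj_term: float
    coulomb_term: float
    per_heavy_atom: float


def infer_bonds(coords: np.ndarray, elements: list[str]) -> np.ndarray:
    """Distance-cutoff bond inference: d < 1.3 (rcov_i + rcov_j)."""
    rcov = np.array([COVALENT_RADII.get(e, _RCOV_DEFAULT) for e in elements])
    max_cut = BOND_SCALE * 2.0 * rcov.max()
    tree = cKDTree(coords)
    pairs = sorted(tree.query_pairs(max_cut))
    bonds = []
    for i, j in pairs:
        d = np.linalg.norm(coords[i] - coords[j])
        if d < BOND_SCALE * (rcov[i] + rcov[j]):
            bonds.append((i, j))
    return np.array(bonds, dtype=int).reshape(-1, 2)


def derive_params(structure: Structure,
                  reference_geometry: Structure | None = None,
                  kb: float = DEFAULT_KB, ktheta: float = DEFAULT_KTHETA,
                  dielectric: float = 15.0) -> FFParams:
    """Build structure-native restraints from a reference geometry.

    Bonds are inferred by element-dependent distance cutoffs on the
    reference; equilibrium bond lengths and angles are the observed values,
    so the bonded energy of the reference itself is exactly zero.  1-2 and
    1-3 pairs are excluded from nonbonded terms, 1-4 pairs scaled by 0.5.
    """
    ref = reference_geometry if reference_geometry is not None else structure
    if len(ref) != len(structure):
        raise ValueError("reference geometry must match the structure atom count")
    coords = ref.coords()
    n = len(structure)
    elements = [a.element for a in structure]

    if n > 1:
        tree = cKDTree(coords)
        close = tree.query_pairs(0.7)
        if close:
            i, j = sorted(close)[0]
            raise ValueError(
                f"reference geometry has overlapping atoms {i} and {j} "
                f"(d < 0.7 A); not chemically sensible"
            )

    bond_idx = infer_bonds(coords, elements)
    bond_r0 = np.array([np.linalg.norm(coords[i] - coords[j])
                        for i, j in bond_idx], dtype=float)
    bond_k = np.full(len(bond_idx), kb)

    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in bond_idx:
        adj[i].append(j)
        adj[j].append(i)

    angles = []
    theta0 = []
    for j in range(n):
        nb = sorted(adj[j])
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                i, k = nb[a], nb[b]
                v1 = coords[i] - coords[j]
                v2 = coords[k] - coords[j]
                cosv = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angles.append((i, j, k))
                theta0.append(float(np.arccos(np.clip(cosv, -1.0, 1.0))))
    angle_idx = np.array(angles, dtype=int).reshape(-1, 3)
    angle_theta0 = np.array(theta0, dtype=float)
    angle_k = np.full(len(angle_idx), ktheta)

    pair_code = np.zeros((n, n), dtype=np.int8)
    for i, j in bond_idx:                       # 1-2
        pair_code[i, j] = pair_code[j, i] = 1
    for i, j, k in angle_idx:                   # 1-3
        pair_code[i, k] = pair_code[k, i] = 1
    for i, j in bond_idx:                       # 1-4: neighbours of a bond
        for a in adj[i]:
            for b in adj[j]:
                if a != j and b != i and a != b and pair_code[a, b] == 0:
                    pair_code[a, b] = pair_code[b, a] = 2
    np.fill_diagonal(pair_code, 1)

    lj = np.array([LJ_TABLE.get(e, _LJ_DEFAULT) for e in elements], dtype=float)
    charges = np.array([a.charge for a in structure], dtype=float)

    metadata: dict = {}
    lonely = [i for i in range(n) if not adj[i]]
    if lonely:
        # single-atom hetero residues are ions and expected to be unbonded
        real = [i for i in lonely
                if not (structure.atoms[i].is_hetero and
                        sum(1 for a in structure.atoms
                            if (a.chain, a.residue_seq) ==
                            (structure.atoms[i].chain,
                             structure.atoms[i].residue_seq)) == 1)]
        if real:
            metadata["warnings"] = [
                f"atom {i} ({structure.atoms[i].name}) has no inferred bonds"
                for i in real
            ]

    return FFParams(bond_idx=bond_idx, bond_r0=bond_r0, bond_k=bond_k,
                    angle_idx=angle_idx, angle_theta0=angle_theta0,
                    angle_k=angle_k, lj_sigma=lj[:, 0], lj_eps=lj[:, 1],
                    charges=charges, pair_code=pair_code,
                    dielectric=dielectric, metadata=metadata)


def _switch(r2: np.ndarray, ron2: float, roff2: float) -> tuple[np.ndarray, np.ndarray]:
    """CHARMM-style potential switch S(r) and dS/dr (vectorised)."""
    denom = (roff2 - ron2) ** 3
    s = np.ones_like(r2)
    ds = np.zeros_like(r2)
    on = r2 > ron2
    u = roff2 - r2[on]
    s[on] = u ** 2 * (roff2 + 2.0 * r2[on] - 3.0 * ron2) / denom
    r = np.sqrt(r2[on])
    ds[on] = 12.0 * r * u * (ron2 - r2[on]) / denom
    off = r2 >= roff2
    s[off] = 0.0
    ds[off] = 0.0
    return s, ds


def _nonbonded_numpy(coords, lj_sigma, lj_eps, charges, pair_code,
                     r_on, r_off, coulomb_k):
    n = coords.shape[0]
    diff = coords[:, None, :] - coords[None, :, :]
    r2 = (diff ** 2).sum(axis=-1)
    iu = np.triu_indices(n, k=1)
    r2p = r2[iu]
    code = pair_code[iu]
    act = (code != 1) & (r2p < r_off ** 2)
    if not act.any():
        return 0.0, np.zeros((n, 3)), float(np.sqrt(r2p.min())) if r2p.size else 1e30
    ii, jj = iu[0][act], iu[1][act]
    r2a = r2p[act]
    r = np.sqrt(r2a)
    sig = 0.5 * (lj_sigma[ii] + lj_sigma[jj])
    eps = np.sqrt(lj_eps[ii] * lj_eps[jj])
    sr6 = (sig ** 2 / r2a) ** 3
    v = 4.0 * eps * (sr6 ** 2 - sr6)
    dv = 4.0 * eps * (-12.0 * sr6 ** 2 + 6.0 * sr6) / r
    qq = coulomb_k * charges[ii] * charges[jj]
    v = v + qq / r
    dv = dv - qq / r2a
    scale = np.where(pair_code[ii, jj] == 2, 0.5, 1.0)
    v *= scale
    dv *= scale
    s, ds = _switch(r2a, r_on ** 2, r_off ** 2)
    dv = dv * s + v * ds
    v = v * s
    energy = float(v.sum())
    f = (-dv / r)[:, None] * diff[ii, jj]
    forces = np.zeros((n, 3))
    np.add.at(forces, ii, f)
    np.add.at(forces, jj, -f)
    return energy, forces, float(np.sqrt(r2p.min()))


def _bonded_numpy(coords, bond_idx, bond_r0, bond_k, angle_idx, angle_t0, angle_k):
    # without numba the kernel module exposes the plain-python function,
    # which is exact (if slow) and fine for the small systems handled here
    return _kernels.bonded_energy_forces(coords, bond_idx, bond_r0, bond_k,
                                         angle_idx, angle_t0, angle_k)


def energy_forces(structure_or_coords, params: FFParams,
                  r_switch: float = 10.0, r_cutoff: float = 12.0
                  ) -> tuple[float, np.ndarray]:
    """Total restraint energy and forces (exact negative gradient).

    Harmonic bonds and angles, plus LJ and cutoff Coulomb smoothed to zero
    between ``r_switch`` and ``r_cutoff``.  Atom pairs closer than 0.1 A
    are reported as an error.
    """
    if isinstance(structure_or_coords, Structure):
        coords = structure_or_coords.coords()
    else:
        coords = np.ascontiguousarray(structure_or_coords, dtype=float)
    if coords.shape[0] != params.n_atoms:
        raise ValueError("params do not match structure size")

    coulomb_k = COULOMB_KE / params.dielectric
    if _kernels.HAVE_NUMBA:
        e_nb, f_nb, min_d = _kernels.nonbonded_energy_forces(
            coords, params.lj_sigma, params.lj_eps, params.charges,
            params.pair_code, r_switch, r_cutoff, coulomb_k)
        e_b, f_b = _kernels.bonded_energy_forces(
            coords, params.bond_idx, params.bond_r0, params.bond_k,
            params.angle_idx, params.angle_theta0, params.angle_k)
    else:
        e_nb, f_nb, min_d = _nonbonded_numpy(
            coords, params.lj_sigma, params.lj_eps, params.charges,
            params.pair_code, r_switch, r_cutoff, coulomb_k)
        e_b, f_b = _bonded_numpy(
            coords, params.bond_idx, params.bond_r0, params.bond_k,
            params.angle_idx, params.angle_theta0, params.angle_k)

    if min_d < 0.1:
        tree = cKDTree(coords)
        i, j = sorted(tree.query_pairs(0.1 + 1e-12))[0]
        raise ValueError(f"atoms {i} and {j} overlap (d = {min_d:.3f} A < 0.1 A)")
    return float(e_nb + e_b), f_nb + f_b


def plie(structure: Structure, protein: Selection, ligand: Selection,
         params: FFParams, r_switch: float = 10.0,
         r_cutoff: float = 12.0) -> InteractionEnergy:
    """Protein-ligand interaction energy: nonbonded terms across the
    interface only, normalised by the ligand heavy-atom count."""
    if np.intersect1d(protein.indices, ligand.indices).size:
        raise ValueError("protein and ligand selections overlap")
    coords = structure.coords()
    pi = protein.indices
    li = ligand.indices
    diff = coords[pi][:, None, :] - coords[li][None, :, :]
    r2 = (diff ** 2).sum(axis=-1)
    act = r2 < r_cutoff ** 2
    n_heavy = len(heavy_atoms(ligand, structure))
    if n_heavy == 0:
        raise ValueError("ligand selection has no heavy atoms")
    if not act.any():
        return InteractionEnergy(0.0, 0.0, 0.0, 0.0)
    ii, jj = np.nonzero(act)
    gi, gj = pi[ii], li[jj]
    r2a = r2[ii, jj]
    r = np.sqrt(r2a)
    sig = 0.5 * (params.lj_sigma[gi] + params.lj_sigma[gj])
    eps = np.sqrt(params.lj_eps[gi] * params.lj_eps[gj])
    sr6 = (sig ** 2 / r2a) ** 3
    v_lj = 4.0 * eps * (sr6 ** 2 - sr6)
    v_c = (COULOMB_KE / params.dielectric) * params.charges[gi] \
        * params.charges[gj] / r
    s, _ = _switch(r2a, r_switch ** 2, r_cutoff ** 2)
    lj_term = float((v_lj * s).sum())
    c_term = float((v_c * s).sum())
    total = lj_term + c_term
    return InteractionEnergy(total=total, lj_term=lj_term, coulomb_term=c_term,
                             per_heavy_atom=total / n_heavy)
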