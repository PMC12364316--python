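"""Structures, density grids and atom selections.

Atomic models are read from PDB or (minimal) mmCIF files and written as PDB;
density maps are MRC/CCP4 mode-2 volumes.  Every other module consumes the
light-weight containers defined here: :class:`Structure` (an ordered list of
:class:`Atom`), :class:`Selection` (indices into a structure) and
:class:`DensityGrid` (an origin + voxel-size annotated scalar field).

Conventions
-----------
* Coordinates are in Angstrom throughout.
* Hydrogens are kept on input but all density and cross-correlation work
  downstream uses heavy atoms only; maps in the 2.7-3.7 A range carry no
  hydrogen signal.
* "Protein" means polymer (non-HETATM) atoms; waters and ions are excluded
  from every selection helper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree


class ParseError(ValueError):
    """A structure or map file could not be interpreted."""


class MapFormatError(ValueError):
    """A density map uses an unsupported MRC/CCP4 variant."""


_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD", "TIP", "TIP3", "SOL"}

#: Hydrogen-like element symbols excluded by :func:`heavy_atoms`.
_HYDROGEN = {"H", "D", "T"}


def _element_info(symbol: str) -> tuple[str, float, int]:
    """Return (canonical symbol, mass, atomic number); raise if unknown."""
    el = gemmi.Element(symbol.capitalize() if len(symbol) <= 2 else symbol)
    if el.atomic_number == 0:
        raise ParseError(f"unknown element symbol {symbol!r}")
    return el.name, float(el.weight), int(el.atomic_number)


def guess_element(atom_name: str) -> str:
    """Infer an element symbol from a PDB atom name.

    Tries the standard two-letter reading first (columns 13-14), falling
    back to the first alphabetic character.
    """
    name = atom_name.strip()
    if not name:
        raise ParseError("empty atom name, cannot infer element")
    stripped = name.lstrip("0123456789")
    if len(stripped) >= 2 and gemmi.Element(stripped[:2].capitalize()).atomic_number > 0:
        two = stripped[:2].capitalize()
        # prefer single-letter reading for names like "CA" (alpha carbon),
        # which are carbon in protein context; two-letter symbols are only
        # trusted when the first letter alone is not an element.
        if gemmi.Element(stripped[0]).atomic_number == 0:
            return two
    if gemmi.Element(stripped[0]).atomic_number > 0:
        return stripped[0]
    raise ParseError(f"cannot infer element from atom name {atom_name!r}")


@dataclass
class Atom:
    """One atom record.

    ``mass`` is filled from the element table when omitted; ``charge`` is in
    elementary charges and defaults to zero (electrostatics are opt-in).
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain: str
    position: np.ndarray
    occupancy: float = 1.0
    is_hetero: bool = False
    mass: float = 0.0
    charge: float = 0.0
    atomic_number: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        symbol, mass, z = _element_info(self.element)
        self.element = symbol
        if self.mass <= 0.0:
            self.mass = mass
        if self.atomic_number == 0:
            self.atomic_number = z

    @property
    def is_hydrogen(self) -> bool:
        return self.element in _HYDROGEN


class Structure:
    """An ordered collection of atoms with free-form metadata."""

    def __init__(self, atoms: Sequence[Atom], metadata: dict | None = None):
        atoms = list(atoms)
        if not atoms:
            raise ValueError("a Structure needs at least one atom")
        serials = [a.serial for a in atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique")
        self.atoms: list[Atom] = atoms
        self.metadata: dict = dict(metadata or {})

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def coords(self) -> np.ndarray:
        """All positions as an (n, 3) float array (a copy)."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """A new structure with the same atoms at new positions."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = []
        for a, xyz in zip(self.atoms, coords):
            atoms.append(
                Atom(a.serial, a.name, a.element, a.residue_name, a.residue_seq,
                     a.chain, xyz.copy(), a.occupancy, a.is_hetero, a.mass,
                     a.charge, a.atomic_number)
            )
        return Structure(atoms, dict(self.metadata))

    def copy(self) -> "Structure":
        return self.with_coords(self.coords())

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def atomic_numbers(self) -> np.ndarray:
        return np.array([a.atomic_number for a in self.atoms], dtype=int)

    def hydrogen_mask(self) -> np.ndarray:
        return np.array([a.is_hydrogen for a in self.atoms], dtype=bool)

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Per-atom (chain, residue_seq, residue_name) keys."""
        return [(a.chain, a.residue_seq, a.residue_name) for a in self.atoms]


@dataclass
class Selection:
    """Ordered, unique atom indices into a structure plus a semantic label."""

    indices: np.ndarray
    label: str = "custom"

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int).ravel()
        if idx.size != np.unique(idx).size:
            raise ValueError("selection indices must be unique")
        self.indices = idx
        if self.label not in {"ligand", "pocket", "protein", "custom"}:
            raise ValueError(f"unknown selection label {self.label!r}")

    def __len__(self) -> int:
        return int(self.indices.size)

    def validate(self, structure: Structure) -> None:
        if len(self) and (self.indices.min() < 0 or self.indices.max() >= len(structure)):
            raise IndexError("selection indices out of range for structure")


@dataclass
class DensityGrid:
    """A scalar density field on a regular orthogonal grid.

    The voxel with index (i, j, k) is centred at ``origin + (i, j, k) *
    voxel_size``.  Anisotropic voxel sizes are allowed.
    """

    origin: np.ndarray
    voxel_size: np.ndarray
    values: np.ndarray
    nominal_resolution: float | None = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel sizes must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def copy(self) -> "DensityGrid":
        return DensityGrid(self.origin.copy(), self.voxel_size.copy(),
                           self.values.copy(), self.nominal_resolution)


# ---------------------------------------------------------------------------
# structure I/O


def _structure_from_gemmi(st: gemmi.Structure) -> Structure:
    if len(st) == 0:
        raise ParseError("file contains no models")
    model = st[0]
    atoms: list[Atom] = []
    serial = 0
    for chain in model:
        for res in chain:
            # altloc collapse: keep the highest occupancy, ties -> first seen
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for a in res:
                key = a.name
                if key not in best:
                    best[key] = a
                    order.append(key)
                elif a.occ > best[key].occ + 1e-9:
                    best[key] = a
            for key in order:
                a = best[key]
                serial += 1
                if a.element.atomic_number > 0:
                    element = a.element.name
                else:
                    element = guess_element(a.name)
                atoms.append(
                    Atom(
                        serial=serial,
                        name=a.name,
                        element=element,
                        residue_name=res.name,
                        residue_seq=res.seqid.num,
                        chain=chain.name,
                        position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        occupancy=float(a.occ),
                        is_hetero=(res.het_flag == "H"),
                    )
                )
    if not atoms:
        raise ParseError("file contains no atoms")
    return Structure(atoms)


def _read_mmcif_minimal(path: Path) -> Structure:
    """Minimal mmCIF reader: the atom_site loop only."""
    try:
        doc = gemmi.cif.read(str(path))
        block = doc.sole_block()
    except Exception as exc:  # gemmi raises RuntimeError with line info
        raise ParseError(f"cannot parse mmCIF {path}: {exc}") from exc
    table = block.find(
        "_atom_site.",
        ["group_PDB", "id", "type_symbol", "label_atom_id", "label_comp_id",
         "label_asym_id", "Cartn_x", "Cartn_y", "Cartn_z"],
    )
    if len(table) == 0:
        raise ParseError(f"{path}: no _atom_site loop with required tags")
    seq_col = block.find("_atom_site.", ["auth_seq_id"])
    if len(seq_col) != len(table):
        seq_col = block.find("_atom_site.", ["label_seq_id"])
    occ_col = block.find("_atom_site.", ["occupancy"])
    alt_col = block.find("_atom_site.", ["label_alt_id"])

    raw: list[dict] = []
    for i, row in enumerate(table):
        seq_s = seq_col[i][0] if len(seq_col) == len(table) else "1"
        try:
            seq = int(seq_s)
        except ValueError:
            seq = 1
        occ = 1.0
        if len(occ_col) == len(table):
            try:
                occ = float(occ_col[i][0])
            except ValueError:
                occ = 1.0
        try:
            xyz = np.array([float(row[6]), float(row[7]), float(row[8])])
        except ValueError as exc:
            raise ParseError(f"{path}: bad coordinates in atom_site row {i + 1}") from exc
        raw.append({
            "group": row[0].upper(),
            "symbol": gemmi.cif.as_string(row[2]).strip(".?") or None,
            "name": gemmi.cif.as_string(row[3]),
            "resname": gemmi.cif.as_string(row[4]),
            "chain": gemmi.cif.as_string(row[5]),
            "seq": seq,
            "xyz": xyz,
            "occ": occ,
        })

    # altloc collapse on (chain, seq, atom name): highest occupancy wins
    best: dict[tuple, dict] = {}
    order: list[tuple] = []
    for rec in raw:
        key = (rec["chain"], rec["seq"], rec["name"])
        if key not in best:
            best[key] = rec
            order.append(key)
        elif rec["occ"] > best[key]["occ"] + 1e-9:
            best[key] = rec
    atoms = []
    for serial, key in enumerate(order, start=1):
        rec = best[key]
        element = rec["symbol"] or guess_element(rec["name"])
        atoms.append(
            Atom(serial=serial, name=rec["name"], element=element,
                 residue_name=rec["resname"], residue_seq=rec["seq"],
                 chain=rec["chain"], position=rec["xyz"], occupancy=rec["occ"],
                 is_hetero=(rec["group"] == "HETATM"))
        )
    return Structure(atoms)


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Element symbols come from the element column when present, otherwise
    they are inferred from the atom name.  Alternate locations are collapsed
    to the highest-occupancy conformer (ties keep the first encountered).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        suffix = path.suffix.lower()
        format = "mmcif" if suffix in {".cif", ".mmcif"} else "pdb"
    if format == "pdb":
        try:
            st = gemmi.read_pdb(str(path))
        except (RuntimeError, ValueError) as exc:
            raise ParseError(f"cannot parse PDB {path}: {exc}") from exc
        return _structure_from_gemmi(st)
    if format == "mmcif":
        return _read_mmcif_minimal(path)
    raise ValueError(f"unknown format {format!r}")


_PDB_ATOM_FMT = (
    "{record:<6s}{serial:>5d} {name:<4s}{altloc:1s}{resname:<4s}{chain:1s}"
    "{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          "
    "{element:>2s}\n"
)


def _pdb_atom_line(a: Atom) -> str:
    name = a.name
    # wwPDB alignment: 1-3 char names of 1-letter elements start in col 14
    if len(name) < 4 and len(a.element) == 1:
        name = " " + name
    if a.residue_seq > 9999 or a.residue_seq < -999:
        raise ValueError(f"residue number {a.residue_seq} does not fit PDB format")
    return _PDB_ATOM_FMT.format(
        record="HETATM" if a.is_hetero else "ATOM",
        serial=a.serial % 100000,
        name=name[:4],
        altloc=" ",
        resname=a.residue_name[:4],
        chain=a.chain,
        resseq=a.residue_seq,
        x=a.position[0], y=a.position[1], z=a.position[2],
        occ=a.occupancy, b=0.0,
        element=a.element.upper(),
    )


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a structure in PDB format (wwPDB v3.3 columns).

    Chain identifiers longer than one character do not fit the format and
    raise instead of being silently truncated.
    """
    for a in structure:
        if len(a.chain) != 1:
            raise ValueError(
                f"chain id {a.chain!r} is not a single character; "
                "PDB output requires 1-char chain ids"
            )
    lines = [_pdb_atom_line(a) for a in structure.atoms]
    lines.append("END\n")
    Path(path).write_text("".join(lines))


def write_multi_model_pdb(frames: Iterable[Structure], path: str | Path) -> None:
    """Write a trajectory as a multi-MODEL PDB file."""
    chunks = []
    for i, frame in enumerate(frames, start=1):
        chunks.append(f"MODEL     {i:>4d}\n")
        chunks.extend(_pdb_atom_line(a) for a in frame.atoms)
        chunks.append("ENDMDL\n")
    chunks.append("END\n")
    Path(path).write_text("".join(chunks))


# ---------------------------------------------------------------------------
# map I/O


def read_map(path: str | Path) -> DensityGrid:
    """Read an MRC/CCP4 mode-2 map into a :class:`DensityGrid`.

    The axis order is normalised to x, y, z and the origin is taken from the
    ORIGIN header words when set, otherwise from the start indices times the
    voxel size.  Non-orthogonal cells and data modes other than 2 are
    rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"cannot read map {path}: {exc}") from exc
    mode = m.header_i32(4)
    if mode != 2:
        raise MapFormatError(f"unsupported MRC data mode {mode}; only mode 2 "
                             "(32-bit float) is supported")
    cell = m.grid.unit_cell
    if not (math.isclose(cell.alpha, 90.0, abs_tol=1e-3)
            and math.isclose(cell.beta, 90.0, abs_tol=1e-3)
            and math.isclose(cell.gamma, 90.0, abs_tol=1e-3)):
        raise MapFormatError("non-orthogonal unit cell is not supported")

    axis_map = [m.header_i32(17), m.header_i32(18), m.header_i32(19)]  # mapc/r/s
    start_file = [m.header_i32(5), m.header_i32(6), m.header_i32(7)]
    sampling = [m.header_i32(8), m.header_i32(9), m.header_i32(10)]  # mx,my,mz
    origin_words = np.array([m.header_float(50), m.header_float(51),
                             m.header_float(52)], dtype=float)

    values = np.array(m.grid, copy=True).astype(float)
    # values axes are (fast, medium, slow) = crs; permute to x,y,z
    if sorted(axis_map) != [1, 2, 3]:
        raise MapFormatError(f"invalid axis correspondence {axis_map}")
    perm = [axis_map.index(i + 1) for i in range(3)]  # crs position of x,y,z
    values = np.transpose(values, axes=perm)
    start = np.array([start_file[perm[0]], start_file[perm[1]], start_file[perm[2]]],
                     dtype=float)

    voxel = np.array([cell.a / sampling[0], cell.b / sampling[1],
                      cell.c / sampling[2]], dtype=float)
    if np.any(origin_words != 0.0):
        origin = origin_words
    else:
        origin = start * voxel
    if not np.all(np.isfinite(values)):
        raise MapFormatError(f"{path}: map contains non-finite values")
    return DensityGrid(origin=origin, voxel_size=voxel, values=values)


def write_map(grid: DensityGrid, path: str | Path) -> None:
    """Write a :class:`DensityGrid` as an MRC mode-2 map (x,y,z axis order)."""
    if not np.all(np.isfinite(grid.values)):
        raise ValueError("grid contains NaN or infinite values; refusing to write")
    nx, ny, nz = grid.dims
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    m.grid.set_unit_cell(gemmi.UnitCell(nx * grid.voxel_size[0],
                                        ny * grid.voxel_size[1],
                                        nz * grid.voxel_size[2],
                                        90.0, 90.0, 90.0))
    m.update_ccp4_header()
    for i, word in enumerate((50, 51, 52)):
        m.set_header_float(word, float(grid.origin[i]))
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# selections


def _is_water(resname: str) -> bool:
    return resname.strip().upper() in _WATER_NAMES


def protein_selection(structure: Structure) -> Selection:
    """All polymer (non-hetero) atoms; waters and ions never qualify."""
    idx = [i for i, a in enumerate(structure) if not a.is_hetero]
    return Selection(np.array(idx, dtype=int), label="protein")


def select_ligand(structure: Structure, ligand_name: str = "auto") -> Selection:
    """Select a ligand by residue name, or the largest hetero residue.

    ``"auto"`` picks the non-water, non-ion hetero residue with the most
    heavy atoms; single-atom residues are treated as ions and skipped.
    """
    groups: dict[tuple[str, int, str], list[int]] = {}
    order: list[tuple[str, int, str]] = []
    for i, a in enumerate(structure):
        if not a.is_hetero:
            continue
        key = (a.chain, a.residue_seq, a.residue_name)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(i)

    candidates = [k for k in order if not _is_water(k[2])]
    if ligand_name == "auto":
        def heavy_count(key):
            return sum(1 for i in groups[key] if not structure.atoms[i].is_hydrogen)
        candidates = [k for k in candidates if heavy_count(k) > 1]  # drop ions
        if not candidates:
            names = sorted({k[2] for k in order})
            raise ValueError(f"no ligand-like hetero residue found; hetero "
                             f"residues present: {names or 'none'}")
        best = max(candidates, key=heavy_count)
        return Selection(np.array(groups[best], dtype=int), label="ligand")

    matches = [k for k in candidates if k[2] == ligand_name]
    if not matches:
        names = sorted({k[2] for k in order})
        raise ValueError(f"no hetero residue named {ligand_name!r}; present: {names}")
    return Selection(np.array(groups[matches[0]], dtype=int), label="ligand")


def select_pocket(structure: Structure, ligand: Selection,
                  cutoff: float = 4.0) -> Selection:
    """All protein residues with any atom within ``cutoff`` of the ligand.

    Whole residues are included; an empty pocket is a valid result.
    """
    if len(ligand) == 0:
        raise ValueError("ligand selection is empty")
    coords = structure.coords()
    lig_xyz = coords[ligand.indices]
    prot = protein_selection(structure)
    if len(prot) == 0:
        return Selection(np.array([], dtype=int), label="pocket")
    prot_xyz = coords[prot.indices]
    tree = cKDTree(lig_xyz)
    dists, _ = tree.query(prot_xyz, k=1)
    near = prot.indices[dists <= cutoff]

    keys = structure.residue_keys()
    near_res = {keys[i] for i in near}
    idx = [i for i in prot.indices if keys[i] in near_res]
    return Selection(np.array(idx, dtype=int), label="pocket")


def heavy_atoms(selection: Selection, structure: Structure) -> Selection:
    """The subset of a selection excluding hydrogen (and deuterium) atoms."""
    selection.validate(structure)
    idx = [i for i in selection.indices if not structure.atoms[i].is_hydrogen]
    return Selection(np.array(idx, dtype=int), label=selection.label)
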