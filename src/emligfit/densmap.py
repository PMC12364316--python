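"""Simulated density, masked cross-correlation and its atomic gradient.

A model density is built by placing an isotropic 3-D Gaussian on every
selected heavy atom.  The Gaussian width is tied to the nominal map
resolution through the FWHM convention (``sigma = resolution / 2.355``),
and each atom's amplitude is its atomic number by default, approximating
its scattering mass.  The similarity between a model density and a target
map is the Pearson correlation restricted to the model-support mask (all
voxels within the truncation radius of any selected atom), and the analytic
gradient of that similarity with respect to the atomic coordinates is the
engine that drives both rigid-body and flexible fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates

from . import _kernels
from .structio import DensityGrid, Selection, Structure, heavy_atoms

#: FWHM-to-sigma conversion: FWHM = 2*sqrt(2*ln 2) * sigma.
_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class MapSimParams:
    """Parameters of the model-to-density rasterisation.

    ``sigma`` is derived from ``resolution`` unless set explicitly;
    ``grid_spec`` names the grid geometry to rasterise onto (usually the
    target map).
    """

    resolution: float = 3.2
    amplitude_mode: str = "atomic_number"
    truncation_radius: float = 4.0
    grid_spec: Optional[DensityGrid] = None
    sigma_override: Optional[float] = None
    mean_subtract: bool = True

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.truncation_radius < 2:
            raise ValueError("truncation_radius must be at least 2 sigma")
        if self.amplitude_mode not in {"uniform", "atomic_number"}:
            raise ValueError(f"unknown amplitude mode {self.amplitude_mode!r}")

    @property
    def sigma(self) -> float:
        if self.sigma_override is not None:
            return self.sigma_override
        return self.resolution / _FWHM_FACTOR


@dataclass
class SimilarityResult:
    """A masked model-to-map cross-correlation."""

    cc: float
    mask_voxels: int
    entity: str = "global"

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.cc <= 1.0 + 1e-9:
            raise ValueError(f"cc {self.cc} outside [-1, 1]")
        if self.mask_voxels <= 0:
            raise ValueError("mask_voxels must be positive")


def grid_like(coords: np.ndarray, voxel_size: float | np.ndarray = 1.0,
              pad: float = 6.0) -> DensityGrid:
    """An empty grid covering ``coords`` with a padding margin on all sides."""
    coords = np.asarray(coords, dtype=float)
    voxel = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,)).copy()
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    dims = np.ceil((hi - lo) / voxel).astype(int) + 1
    return DensityGrid(origin=lo, voxel_size=voxel, values=np.zeros(dims))


def _amplitudes(structure: Structure, idx: np.ndarray, mode: str) -> np.ndarray:
    if mode == "uniform":
        return np.ones(idx.size, dtype=float)
    z = structure.atomic_numbers()
    return z[idx].astype(float)


class _AtomBoxes:
    """Per-atom voxel neighbourhoods for Gaussian stamping.

    Precomputes, for every atom, the cube of voxel indices within the
    truncation radius, the Gaussian weight of each voxel and the
    centre-minus-atom displacement needed for gradients.  The Gaussian is
    evaluated separably per axis and truncated on the sphere r <= R.
    """

    def __init__(self, coords: np.ndarray, amps: np.ndarray,
                 grid: DensityGrid, sigma: float, trunc_radius: float):
        origin, voxel = grid.origin, grid.voxel_size
        dims = np.array(grid.dims)
        R = trunc_radius * sigma
        hw = np.ceil(R / voxel + 0.5).astype(int)
        n = coords.shape[0]

        base = np.floor((coords - origin) / voxel + 0.5).astype(int)
        # per-axis index offsets and 1-D Gaussians, evaluated separably
        axes_idx = []
        axes_gauss = []
        axes_disp = []
        axes_inb = []
        for ax in range(3):
            off = np.arange(-hw[ax], hw[ax] + 1)
            idx = base[:, ax:ax + 1] + off[None, :]              # (n, m_ax)
            centers = origin[ax] + idx * voxel[ax]
            d = centers - coords[:, ax:ax + 1]
            axes_idx.append(idx)
            axes_gauss.append(np.exp(-0.5 * (d / sigma) ** 2))
            axes_disp.append(d)
            axes_inb.append((idx >= 0) & (idx < dims[ax]))

        norm = 1.0 / ((2.0 * math.pi) ** 1.5 * sigma ** 3)
        w = np.einsum("ni,nj,nk->nijk", axes_gauss[0], axes_gauss[1],
                      axes_gauss[2]).reshape(n, -1)
        w *= norm * amps[:, None]

        r2 = (axes_disp[0][:, :, None, None] ** 2
              + axes_disp[1][:, None, :, None] ** 2
              + axes_disp[2][:, None, None, :] ** 2).reshape(n, -1)
        inb = (axes_inb[0][:, :, None, None]
               & axes_inb[1][:, None, :, None]
               & axes_inb[2][:, None, None, :]).reshape(n, -1)
        valid = inb & (r2 <= R * R)

        flat = ((axes_idx[0][:, :, None, None] * dims[1]
                 + axes_idx[1][:, None, :, None]) * dims[2]
                + axes_idx[2][:, None, None, :]).reshape(n, -1)

        self.n = n
        self.sigma = sigma
        self.dims = tuple(int(d) for d in dims)
        self.w = np.where(valid, w, 0.0)
        self.valid = valid
        self.flat = np.where(valid, flat, 0)
        self._axes_disp = axes_disp

    def displacements(self) -> np.ndarray:
        """(n, m, 3) voxel-centre minus atom-position vectors."""
        n = self.n
        dx, dy, dz = self._axes_disp
        m = self.w.shape[1]
        out = np.empty((n, m, 3))
        out[:, :, 0] = np.broadcast_to(
            dx[:, :, None, None], (n, dx.shape[1], dy.shape[1], dz.shape[1])
        ).reshape(n, -1)
        out[:, :, 1] = np.broadcast_to(
            dy[:, None, :, None], (n, dx.shape[1], dy.shape[1], dz.shape[1])
        ).reshape(n, -1)
        out[:, :, 2] = np.broadcast_to(
            dz[:, None, None, :], (n, dx.shape[1], dy.shape[1], dz.shape[1])
        ).reshape(n, -1)
        return out

    def scatter_density(self) -> np.ndarray:
        size = int(np.prod(self.dims))
        vals = np.bincount(self.flat.ravel(), weights=self.w.ravel(),
                           minlength=size)
        return vals.reshape(self.dims)

    def support_mask(self) -> np.ndarray:
        size = int(np.prod(self.dims))
        mask = np.zeros(size, dtype=bool)
        mask[self.flat[self.valid]] = True
        return mask.reshape(self.dims)


def _density_and_mask(coords: np.ndarray, amps: np.ndarray, grid: DensityGrid,
                      sigma: float, trunc_radius: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Stamped density and support mask, via numba when available."""
    if _kernels.HAVE_NUMBA:
        return _kernels.density_and_mask(
            np.ascontiguousarray(coords), np.ascontiguousarray(amps),
            grid.origin, grid.voxel_size,
            np.array(grid.dims, dtype=np.int64), sigma, trunc_radius * sigma)
    boxes = _AtomBoxes(coords, amps, grid, sigma, trunc_radius)
    return boxes.scatter_density(), boxes.support_mask()


def _grad_atoms(coords: np.ndarray, amps: np.ndarray, grid: DensityGrid,
                sigma: float, trunc_radius: float,
                dccdf: np.ndarray) -> np.ndarray:
    if _kernels.HAVE_NUMBA:
        return _kernels.cc_grad_atoms(
            np.ascontiguousarray(coords), np.ascontiguousarray(amps),
            grid.origin, grid.voxel_size, sigma, trunc_radius * sigma,
            np.ascontiguousarray(dccdf))
    boxes = _AtomBoxes(coords, amps, grid, sigma, trunc_radius)
    coeff = boxes.w * dccdf.ravel()[boxes.flat]
    disp = boxes.displacements()
    return np.einsum("nm,nmd->nd", coeff, disp) / (sigma ** 2)


def _resolve_grid(params: MapSimParams, target: Optional[DensityGrid],
                  coords: np.ndarray) -> DensityGrid:
    if params.grid_spec is not None:
        return params.grid_spec
    if target is not None:
        return target
    return grid_like(coords, 1.0, pad=params.truncation_radius * params.sigma + 2.0)


def _heavy_coords(structure: Structure, selection: Selection,
                  params: MapSimParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Heavy-atom indices, coordinates and amplitudes for a selection."""
    selection.validate(structure)
    heavy = heavy_atoms(selection, structure)
    if len(heavy) == 0:
        raise ValueError("selection contains no heavy atoms")
    coords = structure.coords()[heavy.indices]
    amps = _amplitudes(structure, heavy.indices, params.amplitude_mode)
    return heavy.indices, coords, amps


def simulate_density(structure: Structure, selection: Selection,
                     params: MapSimParams) -> DensityGrid:
    """Rasterise the selected heavy atoms as truncated Gaussians.

    Each atom contributes ``A / ((2 pi)^{3/2} sigma^3) * exp(-r^2 / 2 sigma^2)``
    evaluated at voxel centres, truncated on the sphere
    ``r <= truncation_radius * sigma``; contributions sum.
    """
    if len(selection) == 0:
        raise ValueError("cannot simulate density for an empty selection")
    _, coords, amps = _heavy_coords(structure, selection, params)
    grid = _resolve_grid(params, None, coords)
    values, _ = _density_and_mask(coords, amps, grid, params.sigma,
                                  params.truncation_radius)
    return DensityGrid(origin=grid.origin.copy(), voxel_size=grid.voxel_size.copy(),
                       values=values, nominal_resolution=params.resolution)


def _check_same_geometry(a: DensityGrid, b: DensityGrid) -> None:
    if a.dims != b.dims or not np.allclose(a.origin, b.origin, atol=1e-6) \
            or not np.allclose(a.voxel_size, b.voxel_size, atol=1e-9):
        raise ValueError("grids have different geometry; resample_onto first")


def _masked_pearson(f: np.ndarray, g: np.ndarray,
                    mean_subtract: bool) -> float:
    if mean_subtract:
        f = f - f.mean()
        g = g - g.mean()
    nf = np.linalg.norm(f)
    ng = np.linalg.norm(g)
    if nf == 0.0 or ng == 0.0:
        raise ValueError("degenerate mask: zero variance inside the mask")
    return float(np.dot(f, g) / (nf * ng))


def cross_correlation(model_map: DensityGrid, target_map: DensityGrid,
                      mask: Optional[np.ndarray] = None,
                      mean_subtract: bool = True,
                      entity: str = "global") -> SimilarityResult:
    """Pearson correlation of two maps restricted to a voxel mask.

    ``mask`` is a boolean array of the grids' shape, or ``None`` for all
    voxels.  Pass ``mean_subtract=False`` for the uncentred overlap dialect.
    """
    _check_same_geometry(model_map, target_map)
    if mask is None:
        mask = np.ones(model_map.dims, dtype=bool)
    if mask.shape != model_map.values.shape:
        raise ValueError("mask shape does not match grid")
    nvox = int(mask.sum())
    if nvox == 0:
        raise ValueError("degenerate mask: no voxels selected")
    cc = _masked_pearson(model_map.values[mask], target_map.values[mask],
                         mean_subtract)
    return SimilarityResult(cc=float(np.clip(cc, -1.0, 1.0)),
                            mask_voxels=nvox, entity=entity)


def support_mask(structure: Structure, selection: Selection,
                 target_map: DensityGrid, params: MapSimParams) -> np.ndarray:
    """Model-support mask: voxels within the truncation radius of any
    selected heavy atom."""
    _, coords, amps = _heavy_coords(structure, selection, params)
    return _density_and_mask(coords, amps, target_map, params.sigma,
                             params.truncation_radius)[1]


def entity_cc(structure: Structure, selection: Selection,
              target_map: DensityGrid, params: MapSimParams,
              context: str | Selection = "selection") -> SimilarityResult:
    """Model-to-map CC of one entity (ligand / pocket / protein / custom).

    By default the entity's own heavy atoms are rasterised and correlated
    with the target over the entity's model-support mask — the semantics
    of per-selection CC checks in density-fitting practice, under which a
    perfectly placed entity still scores below 1 wherever neighbouring
    density (or map noise) falls inside its mask.  Passing
    ``context="full"`` (or an explicit context selection) instead
    simulates that context's density over the same mask, a local-fit
    variant for which a perfect full model scores exactly 1.
    """
    return entity_ccs(structure, {"_": selection}, target_map, params,
                      context=context)["_"]


def entity_ccs(structure: Structure, selections: dict[str, Selection],
               target_map: DensityGrid, params: MapSimParams,
               context: str | Selection = "selection"
               ) -> dict[str, SimilarityResult]:
    """Entity CCs for several selections (see :func:`entity_cc`).

    With a shared context ("full" or an explicit selection) the context
    density is simulated once and reused across entities.
    """
    shared_values: Optional[np.ndarray] = None
    if isinstance(context, Selection):
        _, coords, amps = _heavy_coords(structure, context, params)
        shared_values, _ = _density_and_mask(coords, amps, target_map,
                                             params.sigma,
                                             params.truncation_radius)
    elif context == "full":
        full = Selection(np.arange(len(structure)), label="custom")
        _, coords, amps = _heavy_coords(structure, full, params)
        shared_values, _ = _density_and_mask(coords, amps, target_map,
                                             params.sigma,
                                             params.truncation_radius)
    elif context != "selection":
        raise ValueError(f"unknown context {context!r}")

    out: dict[str, SimilarityResult] = {}
    for name, sel in selections.items():
        _, sel_coords, sel_amps = _heavy_coords(structure, sel, params)
        sel_values, mask = _density_and_mask(sel_coords, sel_amps, target_map,
                                             params.sigma,
                                             params.truncation_radius)
        model_values = shared_values if shared_values is not None else sel_values
        nvox = int(mask.sum())
        if nvox == 0:
            raise ValueError(f"degenerate mask: selection {name!r} lies "
                             "outside the map")
        cc = _masked_pearson(model_values[mask], target_map.values[mask],
                             params.mean_subtract)
        out[name] = SimilarityResult(
            cc=float(np.clip(cc, -1.0, 1.0)), mask_voxels=nvox,
            entity=sel.label if sel.label != "custom" else "global")
    return out


def cc_with_gradient(structure: Structure, selection: Selection,
                     target_map: DensityGrid, params: MapSimParams,
                     mask: Optional[np.ndarray] = None
                     ) -> tuple[float, np.ndarray]:
    """Masked CC and its analytic gradient w.r.t. selected atom positions.

    Returns ``(cc, grad)`` where ``grad`` has shape (n_atoms_in_structure, 3)
    with zeros on unselected (and hydrogen) atoms.  When ``mask`` is None
    the model-support mask of the selection is used; passing an explicit
    mask keeps it fixed, which is what finite-difference checks need.
    """
    _, coords, amps = _heavy_coords(structure, selection, params)
    f_grid, support = _density_and_mask(coords, amps, target_map,
                                        params.sigma, params.truncation_radius)
    if mask is None:
        mask = support
    nvox = int(mask.sum())
    if nvox == 0:
        raise ValueError("degenerate mask: selection lies outside the map")

    f = f_grid[mask]
    g = target_map.values[mask]
    if params.mean_subtract:
        fc = f - f.mean()
        gc = g - g.mean()
    else:
        fc, gc = f, g
    nf = np.linalg.norm(fc)
    ng = np.linalg.norm(gc)
    if nf == 0.0 or ng == 0.0:
        raise ValueError("degenerate mask: zero variance inside the mask")
    cc = float(np.dot(fc, gc) / (nf * ng))

    # d cc / d f_v on masked voxels; the mean-subtraction chain term sums to
    # zero because both centred fields have zero mask mean.
    dccdf_mask = gc / (nf * ng) - cc * fc / (nf * nf)
    dccdf = np.zeros(f_grid.shape)
    dccdf[mask] = dccdf_mask

    # d f_v / d x_a = w_av * (centre - x_a) / sigma^2
    grad_sel = _grad_atoms(coords, amps, target_map, params.sigma,
                           params.truncation_radius, dccdf)

    # re-select heavy atoms to place gradients at the right rows
    heavy = heavy_atoms(selection, structure)
    grad = np.zeros((len(structure), 3))
    grad[heavy.indices] = grad_sel
    return float(np.clip(cc, -1.0, 1.0)), grad


def cc_gradient(structure: Structure, selection: Selection,
                target_map: DensityGrid, params: MapSimParams,
                mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Gradient of the masked model-to-map CC (see :func:`cc_with_gradient`)."""
    return cc_with_gradient(structure, selection, target_map, params, mask)[1]


def export_mask(mask: np.ndarray, reference: DensityGrid,
                path) -> None:
    """Write a voxel mask as a 0/1-valued MRC map for visual debugging."""
    from .structio import write_map
    if mask.shape != reference.values.shape:
        raise ValueError("mask shape does not match the reference grid")
    write_map(DensityGrid(reference.origin.copy(),
                          reference.voxel_size.copy(),
                          mask.astype(float)), path)


def resample_onto(grid: DensityGrid, reference: DensityGrid) -> DensityGrid:
    """Trilinear resampling of ``grid`` onto the geometry of ``reference``.

    Voxels of the reference outside the extent of ``grid`` are set to zero;
    zero spatial overlap is an error.
    """
    ref_dims = reference.dims
    idx = np.indices(ref_dims, dtype=float)
    centers = reference.origin[:, None, None, None] \
        + idx * reference.voxel_size[:, None, None, None]
    frac = (centers - grid.origin[:, None, None, None]) \
        / grid.voxel_size[:, None, None, None]

    dims = np.array(grid.dims, dtype=float)
    inside = np.all((frac >= 0) & (frac <= dims[:, None, None, None] - 1), axis=0)
    if not inside.any():
        raise ValueError("grids do not overlap spatially")
    values = map_coordinates(grid.values, frac.reshape(3, -1), order=1,
                             mode="constant", cval=0.0).reshape(ref_dims)
    return DensityGrid(origin=reference.origin.copy(),
                       voxel_size=reference.voxel_size.copy(),
                       values=values,
                       nominal_resolution=grid.nominal_resolution)
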