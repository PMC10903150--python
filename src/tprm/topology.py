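"""Local Minkowski measures of binary PRM class maps.

Two Minkowski functionals are computed for each PRM class mask: the volume
density ``V`` (local fraction of lung occupied by the class) and the
Euler-Poincaré characteristic ``chi`` (alternating sum of cell counts of the
cubical complex spanned by the foreground voxels).  Both are evaluated in a
moving cubic window (default 21^3 voxels) on a coarse stride grid (default
every 5th voxel), normalised by the lung content of the same window, and
linearly interpolated back to every lung voxel.

Sign convention for ``chi``: many isolated pockets give a positive value
(one per component), while a coalesced mesh threaded by tunnels gives a
negative value (each independent tunnel subtracts one).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "TPRMMaps",
    "euler_characteristic",
    "minkowski_window_maps",
    "interpolate_to_grid",
    "whole_lung_means",
    "compute_tprm",
]


def _chi_cell_counts(occ: np.ndarray) -> np.ndarray:
    """Euler characteristic of the closed-voxel cubical complex.

    ``occ`` is a boolean array whose last three axes are spatial; leading axes
    are treated as batch dimensions.  The complex is the union of closed unit
    cubes centred on foreground voxels (foreground 26-connectivity), and
    chi = n0 - n1 + n2 - n3 over vertices, edges, faces and cubes.
    """
    occ = np.asarray(occ, dtype=bool)
    a, b, c = occ.shape[-3:]
    batch = occ.shape[:-3]
    pad = [(0, 0)] * len(batch) + [(1, 1)] * 3
    p = np.pad(occ, pad)
    sp = (-3, -2, -1)

    # vertices: lattice points touched by any of their <=8 incident voxels
    v = np.zeros(batch + (a + 1, b + 1, c + 1), dtype=bool)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                v |= p[..., dx:dx + a + 1, dy:dy + b + 1, dz:dz + c + 1]
    n0 = v.sum(axis=sp)

    # edges along each axis: touched by any of 4 incident voxels
    e = np.zeros(batch + (a, b + 1, c + 1), dtype=bool)
    for dy in (0, 1):
        for dz in (0, 1):
            e |= p[..., 1:1 + a, dy:dy + b + 1, dz:dz + c + 1]
    n1 = e.sum(axis=sp)
    e = np.zeros(batch + (a + 1, b, c + 1), dtype=bool)
    for dx in (0, 1):
        for dz in (0, 1):
            e |= p[..., dx:dx + a + 1, 1:1 + b, dz:dz + c + 1]
    n1 = n1 + e.sum(axis=sp)
    e = np.zeros(batch + (a + 1, b + 1, c), dtype=bool)
    for dx in (0, 1):
        for dy in (0, 1):
            e |= p[..., dx:dx + a + 1, dy:dy + b + 1, 1:1 + c]
    n1 = n1 + e.sum(axis=sp)

    # faces normal to each axis: touched by either of 2 incident voxels
    f = p[..., 0:a + 1, 1:1 + b, 1:1 + c] | p[..., 1:a + 2, 1:1 + b, 1:1 + c]
    n2 = f.sum(axis=sp)
    f = p[..., 1:1 + a, 0:b + 1, 1:1 + c] | p[..., 1:1 + a, 1:b + 2, 1:1 + c]
    n2 = n2 + f.sum(axis=sp)
    f = p[..., 1:1 + a, 1:1 + b, 0:c + 1] | p[..., 1:1 + a, 1:1 + b, 1:c + 2]
    n2 = n2 + f.sum(axis=sp)

    n3 = occ.sum(axis=sp)
    return n0 - n1 + n2 - n3


def euler_characteristic(binary_volume: np.ndarray) -> int:
    """Euler-Poincaré characteristic of a 3D binary volume.

    Computed on the cubical complex formed by the union of closed unit
    voxels (26-connected foreground).  Additive over disjoint unions.

    Raises
    ------
    ValueError
        If the input is not 3D or contains values other than 0/1.
    """
    vol = np.asarray(binary_volume)
    if vol.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={vol.ndim}")
    if vol.dtype != bool and not np.isin(vol, (0, 1)).all():
        raise ValueError("input volume must be binary (0/1)")
    return int(_chi_cell_counts(vol.astype(bool)))


def _window_view(mask: np.ndarray, window: int, stride: int) -> np.ndarray:
    """Clipped moving windows on the stride grid, as a zero-copy view.

    Zero-padding by the half-window makes the full-window view at grid node
    ``i`` identical to the window centred on voxel ``i*stride`` clipped at
    the volume boundary (the padding contributes no foreground).
    """
    hw = window // 2
    padded = np.pad(mask, hw)
    wins = sliding_window_view(padded, (window, window, window))
    return wins[::stride, ::stride, ::stride]


def minkowski_window_maps(
    class_mask: np.ndarray,
    lung_mask: np.ndarray,
    window_vox: int = 21,
    stride_vox: int = 5,
):
    """Windowed V and chi of ``class_mask`` on the stride grid.

    At each grid centre ``c`` (every ``stride_vox``-th voxel per axis,
    anchored at index 0):

    * ``V(c)``   = |class ∩ W_c| / |lung ∩ W_c|  (cell-counting volume
      measure of both numerator and denominator),
    * ``chi(c)`` = chi(class ∩ W_c) / |lung ∩ W_c|.

    Windows are clipped at the volume boundary.  Grid nodes whose window
    contains no lung voxel are NaN (filled later by interpolation).

    Returns
    -------
    (V_grid, chi_grid, grid_coords)
        Two float arrays on the stride grid and a tuple of per-axis grid
        coordinate vectors (voxel indices of the window centres).
    """
    class_mask = np.asarray(class_mask, dtype=bool)
    lung_mask = np.asarray(lung_mask, dtype=bool)
    if class_mask.shape != lung_mask.shape:
        raise ValueError("class_mask and lung_mask must share shape")
    if window_vox % 2 != 1:
        raise ValueError("window_vox must be odd")
    if stride_vox < 1:
        raise ValueError("stride_vox must be >= 1")
    if (class_mask & ~lung_mask).any():
        raise ValueError("class_mask must be a subset of lung_mask")

    cw = _window_view(class_mask, window_vox, stride_vox)
    lw = _window_view(lung_mask, window_vox, stride_vox)

    g0, g1, g2 = cw.shape[:3]
    v_grid = np.full((g0, g1, g2), np.nan)
    chi_grid = np.full((g0, g1, g2), np.nan)
    # chunk over the leading grid axis to bound the working set
    for i in range(g0):
        lung_cnt = lw[i].sum(axis=(-3, -2, -1))
        class_cnt = cw[i].sum(axis=(-3, -2, -1))
        chi_i = _chi_cell_counts(cw[i])
        ok = lung_cnt > 0
        v_grid[i][ok] = class_cnt[ok] / lung_cnt[ok]
        chi_grid[i][ok] = chi_i[ok] / lung_cnt[ok]

    coords = tuple(
        np.arange(0, n, stride_vox) for n in class_mask.shape
    )
    return v_grid, chi_grid, coords


def _fill_invalid_nearest(grid_map: np.ndarray) -> np.ndarray:
    """Replace NaN grid nodes with the value of the nearest valid node."""
    invalid = ~np.isfinite(grid_map)
    if not invalid.any():
        return grid_map
    if invalid.all():
        raise ValueError("grid map has no valid nodes")
    idx = ndimage.distance_transform_edt(
        invalid, return_distances=False, return_indices=True
    )
    return grid_map[tuple(idx)]


def interpolate_to_grid(
    grid_map: np.ndarray,
    grid_coords,
    lung_mask: np.ndarray,
) -> np.ndarray:
    """Trilinear interpolation of a stride-grid map to every lung voxel.

    Lung voxels outside the grid hull take the value of the nearest node
    (implemented by clipping query coordinates into the hull, i.e. constant
    extension).  The returned field is zero outside ``lung_mask``.
    """
    lung_mask = np.asarray(lung_mask, dtype=bool)
    filled = _fill_invalid_nearest(np.asarray(grid_map, dtype=float))
    interp = RegularGridInterpolator(grid_coords, filled, method="linear")
    pts = np.argwhere(lung_mask).astype(float)
    for ax, cv in enumerate(grid_coords):
        np.clip(pts[:, ax], cv[0], cv[-1], out=pts[:, ax])
    out = np.zeros(lung_mask.shape)
    out[lung_mask] = interp(pts)
    return out


@dataclass
class TPRMMaps:
    """Full-resolution V and chi fields per PRM class, plus metadata."""

    V: dict[str, np.ndarray]
    chi: dict[str, np.ndarray]
    lung_mask: np.ndarray
    window_vox: int = 21
    stride_vox: int = 5
    whole_lung_means: dict[str, tuple[float, float]] = field(default_factory=dict)

    def classes(self) -> list[str]:
        return list(self.V)


def whole_lung_means(tprm: TPRMMaps, lung_mask: np.ndarray | None = None):
    """Arithmetic mean of each interpolated V and chi field over the lung.

    Returns a mapping ``class -> (V_mean, chi_mean)``.  The mean of V equals
    the class percent volume / 100 up to window discretisation.
    """
    mask = tprm.lung_mask if lung_mask is None else np.asarray(lung_mask, bool)
    means = {}
    for cls in tprm.V:
        means[cls] = (
            float(tprm.V[cls][mask].mean()),
            float(tprm.chi[cls][mask].mean()),
        )
    tprm.whole_lung_means = means
    return means


def compute_tprm(
    labels: np.ndarray,
    lung_mask: np.ndarray,
    class_codes: dict[str, int],
    classes=("Norm", "fSAD"),
    window_vox: int = 21,
    stride_vox: int = 5,
) -> TPRMMaps:
    """Windowed V/chi maps for the requested classes, interpolated to the lung.

    ``labels`` is an integer PRM label volume, ``class_codes`` maps class
    names to their integer codes.
    """
    lung_mask = np.asarray(lung_mask, dtype=bool)
    V: dict[str, np.ndarray] = {}
    chi: dict[str, np.ndarray] = {}
    for cls in classes:
        mask = (labels == class_codes[cls]) & lung_mask
        v_g, chi_g, coords = minkowski_window_maps(
            mask, lung_mask, window_vox, stride_vox
        )
        V[cls] = interpolate_to_grid(v_g, coords, lung_mask)
        chi[cls] = interpolate_to_grid(chi_g, coords, lung_mask)
    maps = TPRMMaps(V=V, chi=chi, lung_mask=lung_mask,
                    window_vox=window_vox, stride_vox=stride_vox)
    whole_lung_means(maps)
    return maps
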