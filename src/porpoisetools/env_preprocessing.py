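"""Eco-geographical variable (EGV) preprocessing.

Derives static terrain layers from bathymetry (Horn slope, Euclidean
distance to coast), harmonises point data onto the analysis grid with
inverse-distance-weighted interpolation, and screens collinear predictors
with a pairwise Pearson threshold so that the retained variable set is
constant across survey years.

Land cells are NaN in every layer; statistics are computed over sea cells
only, pairwise-complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .rasters import GridSpec

__all__ = [
    "EGVStack",
    "ScreenResult",
    "slope_from_bathymetry",
    "distance_to_coast",
    "idw_interpolate",
    "correlation_screen",
    "DEFAULT_KEEP_PRIORITY",
]

#: Keep order used when a correlated pair must lose a member: the core
#: porpoise habitat drivers first, everything else after, in stack order.
DEFAULT_KEEP_PRIORITY: tuple[str, ...] = ("bathymetry", "slope", "sst", "chla", "ammonium")


@dataclass
class EGVStack:
    """Named, co-registered gridded predictors on one :class:`GridSpec`.

    ``provenance`` tags each layer ``static`` or ``dynamic`` (optionally with
    a lag label such as ``dynamic:lag-1``).
    """

    grid: GridSpec
    layers: dict[str, np.ndarray]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, layer in self.layers.items():
            if np.asarray(layer).shape != self.grid.shape:
                raise ValueError(f"layer {name!r} shape does not match grid {self.grid.shape}")
        for name in self.layers:
            self.provenance.setdefault(name, "static")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def sea_mask(self) -> np.ndarray:
        """Cells finite in every layer."""
        mask = np.ones(self.grid.shape, dtype=bool)
        for layer in self.layers.values():
            mask &= np.isfinite(layer)
        return mask

    def subset(self, names: Sequence[str]) -> "EGVStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return EGVStack(
            grid=self.grid,
            layers={n: self.layers[n] for n in names},
            provenance={n: self.provenance[n] for n in names},
        )

    def values_at(self, x: np.ndarray, y: np.ndarray) -> pd.DataFrame:
        """Layer values at the cells containing planar points (NaN outside)."""
        row, col = self.grid.cell_of(x, y)
        inside = row >= 0
        out = {}
        for name, layer in self.layers.items():
            vals = np.full(len(np.atleast_1d(row)), np.nan)
            r = np.atleast_1d(row)
            c = np.atleast_1d(col)
            vals[inside] = np.asarray(layer)[r[inside], c[inside]]
            out[name] = vals
        return pd.DataFrame(out)


def _fill_nearest(layer: np.ndarray) -> np.ndarray:
    """Replace NaN cells with the value of the nearest finite cell."""
    finite = np.isfinite(layer)
    if finite.all():
        return layer
    _, (ri, ci) = ndimage.distance_transform_edt(~finite, return_indices=True)
    return layer[ri, ci]


def slope_from_bathymetry(bathymetry: np.ndarray, cell_size_km: float = 1.0) -> np.ndarray:
    """Terrain slope (degrees) from a depth layer via the Horn 3x3 gradient.

    Depth is metres, cell size kilometres. Border cells are handled by edge
    replication; land (NaN) cells are filled from the nearest sea cell for
    the gradient stencil and re-masked afterwards.
    """
    z = np.asarray(bathymetry, dtype=float)
    if z.ndim != 2 or min(z.shape) < 3:
        raise ValueError("bathymetry must be at least 3x3")
    if not np.isfinite(z).any():
        raise ValueError("bathymetry layer is all nodata")
    land = ~np.isfinite(z)
    zf = np.pad(_fill_nearest(z), 1, mode="edge")
    dx = cell_size_km * 1000.0  # gradient in m per m
    # Horn (1981) third-order finite difference weights
    gx = (
        (zf[:-2, 2:] + 2 * zf[1:-1, 2:] + zf[2:, 2:])
        - (zf[:-2, :-2] + 2 * zf[1:-1, :-2] + zf[2:, :-2])
    ) / (8 * dx)
    gy = (
        (zf[2:, :-2] + 2 * zf[2:, 1:-1] + zf[2:, 2:])
        - (zf[:-2, :-2] + 2 * zf[:-2, 1:-1] + zf[:-2, 2:])
    ) / (8 * dx)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    slope[land] = np.nan
    return slope


def distance_to_coast(bathymetry: np.ndarray, cell_size_km: float = 1.0) -> np.ndarray:
    """Euclidean distance (km) from each sea cell centre to the nearest
    land cell centre. Land cells (NaN in the input) are 0."""
    z = np.asarray(bathymetry, dtype=float)
    sea = np.isfinite(z)
    if sea.all():
        raise ValueError("no land cells in bathymetry layer")
    if not sea.any():
        raise ValueError("no sea cells in bathymetry layer")
    return ndimage.distance_transform_edt(sea, sampling=cell_size_km)


def idw_interpolate(
    points: np.ndarray,
    values: np.ndarray,
    grid: GridSpec,
    power: float = 2.0,
    k: int = 12,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Inverse-distance-weighted interpolation of scattered points onto a grid.

    Each target cell centre takes ``sum(w_i v_i) / sum(w_i)`` with
    ``w_i = d_i**-power`` over its ``k`` nearest source points; a target
    coincident with a source takes the source value exactly. The output is
    therefore bounded by the min/max of the sources used. ``mask`` (optional
    boolean sea mask) restricts which cells are interpolated; others are NaN.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    values = np.asarray(values, dtype=float)
    if len(points) < 1:
        raise ValueError("at least one source point required")
    if len(points) != len(values):
        raise ValueError("points and values length mismatch")
    k = min(k, len(points))
    xx, yy = np.meshgrid(grid.x_centers, grid.y_centers)
    targets = np.column_stack([xx.ravel(), yy.ravel()])
    if mask is not None:
        sel = np.asarray(mask, dtype=bool).ravel()
        targets = targets[sel]
    tree = cKDTree(points)
    d, idx = tree.query(targets, k=k)
    d = np.atleast_2d(d.reshape(len(targets), k))
    idx = np.atleast_2d(idx.reshape(len(targets), k))
    exact = d[:, 0] == 0.0
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    w[~np.isfinite(w)] = 0.0
    num = (w * values[idx]).sum(axis=1)
    den = w.sum(axis=1)
    den[den == 0] = np.nan
    est = num / den
    est[exact] = values[idx[exact, 0]]
    out = np.full(grid.shape, np.nan).ravel()
    if mask is not None:
        out[np.asarray(mask, dtype=bool).ravel()] = est
    else:
        out[:] = est
    return out.reshape(grid.shape)


def _pairwise_correlations(stack: EGVStack, names: Sequence[str]) -> pd.DataFrame:
    """Pearson r over sea cells, pairwise-complete."""
    mat = pd.DataFrame(index=list(names), columns=list(names), dtype=float)
    flat = {n: np.asarray(stack.layers[n], dtype=float).ravel() for n in names}
    for i, a in enumerate(names):
        mat.loc[a, a] = 1.0
        for b in names[i + 1 :]:
            ok = np.isfinite(flat[a]) & np.isfinite(flat[b])
            if ok.sum() < 3 or flat[a][ok].std() == 0 or flat[b][ok].std() == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(flat[a][ok], flat[b][ok])[0, 1])
            mat.loc[a, b] = r
            mat.loc[b, a] = r
    return mat


@dataclass
class ScreenResult:
    retained: list[str]
    stacks: list[EGVStack]
    correlations: list[pd.DataFrame]
    dropped: list[tuple[str, str, float]]  # (dropped, because_of, worst |r|)


def correlation_screen(
    stacks: EGVStack | Sequence[EGVStack],
    threshold: float = 0.7,
    keep_priority: Sequence[str] | None = None,
) -> ScreenResult:
    """Iteratively drop the lower-priority member of every layer pair whose
    absolute Pearson correlation exceeds ``threshold`` (strict ``>``) in any
    of the supplied yearly stacks, so the retained set is constant across
    years. Returns the subset stacks plus the per-year correlation matrices.
    """
    single = isinstance(stacks, EGVStack)
    stack_list = [stacks] if single else list(stacks)
    if not stack_list:
        raise ValueError("no stacks supplied")
    names = stack_list[0].names
    for st in stack_list[1:]:
        if st.names != names:
            raise ValueError("all yearly stacks must share the same layer names")
    if len(names) < 2:
        raise ValueError("at least two layers required to screen")

    priority = list(keep_priority) if keep_priority is not None else list(DEFAULT_KEEP_PRIORITY)

    def rank(name: str) -> tuple[int, int]:
        # listed names first (by list position), then unlisted in stack order
        if name in priority:
            return (0, priority.index(name))
        return (1, names.index(name))

    mats = [_pairwise_correlations(st, names) for st in stack_list]
    worst = pd.DataFrame(
        np.max([m.abs().to_numpy() for m in mats], axis=0), index=names, columns=names
    )

    retained = list(names)
    dropped: list[tuple[str, str, float]] = []
    while True:
        failing = [
            (worst.loc[a, b], a, b)
            for i, a in enumerate(retained)
            for b in retained[i + 1 :]
            if worst.loc[a, b] > threshold
        ]
        if not failing:
            break
        r, a, b = max(failing)
        loser, keeper = (a, b) if rank(a) > rank(b) else (b, a)
        retained.remove(loser)
        dropped.append((loser, keeper, float(r)))

    out_stacks = [st.subset(retained) for st in stack_list]
    return ScreenResult(retained=retained, stacks=out_stacks, correlations=mats, dropped=dropped)
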