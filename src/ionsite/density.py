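"""Voxelized ion density maps, grid free energy (GFE), site detection,
and overlap-coefficient map comparison.

The occupancy -> GFE conversion follows

    GFE(v) = min(-R T ln(occ(v) / <bulk occ>), cap)

with R = 1.9872e-3 kcal/(mol K), default T = 300 K and cap = 3 kcal/mol;
zero occupancy maps to the cap. Binding sites are face-connected components
of voxels at or above an isovalue in the counts-per-frame density.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .io import Topology, Trajectory

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DensityGrid",
    "GFEMap",
    "SiteCall",
    "accumulate_density",
    "normalize_density",
    "denormalize_density",
    "gfe_from_density",
    "overlap_coefficient",
    "detect_sites",
    "estimate_bulk",
]

GAS_CONSTANT_KCAL = 1.9872e-3  # kcal / (mol K)

_NORMALIZATIONS = ("raw_counts", "counts_per_frame", "probability")


@dataclass
class DensityGrid:
    """Voxelized ion density on a regular lattice.

    ``origin`` is the coordinate of the center of voxel (0,0,0); values are
    indexed [ix, iy, iz]. ``normalization`` is one of raw_counts,
    counts_per_frame, probability.
    """

    values: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray
    normalization: str = "raw_counts"
    n_frames: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.atleast_1d(np.asarray(self.spacing, dtype=float))
        if self.spacing.size == 1:
            self.spacing = np.repeat(self.spacing, 3)
        if self.values.ndim != 3:
            raise ValueError("grid values must be 3-D")
        if np.any(self.values < 0):
            raise ValueError("density values must be non-negative")
        if self.normalization not in _NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers(self, idx: np.ndarray) -> np.ndarray:
        """Cartesian centers (n, 3) of integer voxel indices (n, 3)."""
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def same_lattice(self, other: "DensityGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
        )


@dataclass
class GFEMap:
    """Grid free energy (kcal/mol) on the source density's lattice."""

    values: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray
    temperature: float = 300.0
    cap: float = 3.0
    bulk: float = 1.0

    @property
    def shape(self):
        return self.values.shape


@dataclass
class SiteCall:
    """One detected binding site: a face-connected voxel component."""

    site_id: int
    voxels: np.ndarray          # (n, 3) integer indices
    centroid: np.ndarray        # density-weighted, Angstrom
    peak_value: float
    integrated_density: float


def accumulate_density(traj: Trajectory, topology: Topology,
                       species: list[str] | None = None,
                       spacing: float | np.ndarray = 1.0,
                       extent: tuple[np.ndarray, np.ndarray] | None = None,
                       padding: float = 2.0) -> DensityGrid:
    """Bin ion positions into voxels (nearest-voxel / top-hat binning).

    Each in-extent ion position increments exactly one voxel per frame, so
    the total count equals the summed per-frame in-extent ion count exactly.
    ``extent`` is (lower_corner, upper_corner); when omitted it is the
    bounding box of the selected positions plus ``padding``.
    """
    if traj.n_frames == 0:
        raise ValueError("cannot accumulate density over zero frames")
    if species is None:
        idx = topology.ion_indices()
    else:
        idx = np.concatenate([topology.ion_indices(sp) for sp in species])
    if idx.size == 0:
        raise ValueError("ion selection is empty")
    spacing = np.atleast_1d(np.asarray(spacing, dtype=float))
    if spacing.size == 1:
        spacing = np.repeat(spacing, 3)
    pts = traj.coords[:, idx, :].reshape(-1, 3)
    if extent is None:
        lo = pts.min(axis=0) - padding
        hi = pts.max(axis=0) + padding
    else:
        lo = np.asarray(extent[0], dtype=float)
        hi = np.asarray(extent[1], dtype=float)
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    origin = lo + spacing / 2.0  # voxel centers
    vox = np.round((pts - origin) / spacing).astype(int)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    vox = vox[inside]
    values = np.zeros(tuple(shape), dtype=float)
    np.add.at(values, (vox[:, 0], vox[:, 1], vox[:, 2]), 1.0)
    return DensityGrid(values=values, origin=origin, spacing=spacing,
                       normalization="raw_counts", n_frames=traj.n_frames)


def normalize_density(grid: DensityGrid, mode: str) -> DensityGrid:
    """Convert a raw_counts grid to counts_per_frame or probability."""
    if grid.normalization != "raw_counts":
        raise ValueError("normalize_density expects a raw_counts grid")
    if mode == "counts_per_frame":
        if grid.n_frames <= 0:
            raise ValueError("grid has no accumulated frames")
        return replace(grid, values=grid.values / grid.n_frames,
                       normalization="counts_per_frame")
    if mode == "probability":
        total = grid.values.sum()
        if total == 0:
            raise ValueError("cannot normalize an all-zero grid to probability")
        return replace(grid, values=grid.values / total,
                       normalization="probability")
    raise ValueError(f"unknown normalization mode {mode!r}")


def denormalize_density(grid: DensityGrid) -> DensityGrid:
    """Recover the raw_counts grid from a normalized one."""
    if grid.normalization == "raw_counts":
        return grid
    if grid.normalization == "counts_per_frame":
        return replace(grid, values=grid.values * grid.n_frames,
                       normalization="raw_counts")
    raise ValueError("probability grids cannot be denormalized without totals")


def estimate_bulk(grid: DensityGrid, mask: np.ndarray) -> float:
    """Mean counts-per-frame over a designated bulk-shell voxel mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError("bulk mask shape must match the grid")
    if not mask.any():
        raise ValueError("bulk mask selects no voxels")
    return float(grid.values[mask].mean())


def gfe_from_density(grid: DensityGrid, bulk: float,
                     temperature: float = 300.0, cap: float = 3.0) -> GFEMap:
    """Occupancy -> grid free energy with capping.

    GFE = min(-R T ln(occ/bulk), cap); occ = 0 (and any occ with
    occ/bulk <= exp(-cap/RT)) maps exactly to the cap.
    """
    if grid.normalization != "counts_per_frame":
        raise ValueError("gfe_from_density expects a counts_per_frame grid")
    if bulk <= 0:
        raise ValueError("bulk occupancy must be positive")
    rt = GAS_CONSTANT_KCAL * temperature
    with np.errstate(divide="ignore"):
        gfe = -rt * np.log(grid.values / bulk)
    gfe = np.minimum(gfe, cap)          # +inf at occ=0 hits the cap
    return GFEMap(values=gfe, origin=grid.origin.copy(),
                  spacing=grid.spacing.copy(), temperature=temperature,
                  cap=cap, bulk=bulk)


def overlap_coefficient(map_a: DensityGrid, map_b: DensityGrid,
                        exclusion_threshold: float = 0.0) -> float:
    """Similarity of two density maps on the same lattice, in [0, 1].

    Each map is restricted to voxels above the exclusion threshold and
    normalized to sum 1; the coefficient is sum_v min(a_v, b_v). Symmetric,
    1 for proportional maps, 0 for disjoint supports.
    """
    if not map_a.same_lattice(map_b):
        raise ValueError("overlap coefficient requires identical lattices")
    a = np.where(map_a.values > exclusion_threshold, map_a.values, 0.0)
    b = np.where(map_b.values > exclusion_threshold, map_b.values, 0.0)
    ta, tb = a.sum(), b.sum()
    if ta == 0 or tb == 0:
        raise ValueError("a map has no voxels above the exclusion threshold")
    return float(np.minimum(a / ta, b / tb).sum())


def detect_sites(grid: DensityGrid, isovalue: float = 0.1,
                 min_voxels: int = 1) -> list[SiteCall]:
    """Face-connected components of voxels >= isovalue.

    Components smaller than ``min_voxels`` are dropped; sites are sorted by
    integrated density (sum of values x voxel volume) descending. Each site
    reports a density-weighted centroid (Angstrom) and its peak value.
    """
    if grid.normalization != "counts_per_frame":
        raise ValueError("detect_sites expects a counts_per_frame grid")
    mask = grid.values >= isovalue
    # default structure = 6-connectivity (faces only) in 3-D
    labels, n = ndimage.label(mask)
    sites = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labels == lab)
        if len(vox) < min_voxels:
            continue
        vals = grid.values[vox[:, 0], vox[:, 1], vox[:, 2]]
        centers = grid.voxel_centers(vox)
        centroid = (centers * vals[:, None]).sum(axis=0) / vals.sum()
        sites.append(
            SiteCall(
                site_id=0,
                voxels=vox,
                centroid=centroid,
                peak_value=float(vals.max()),
                integrated_density=float(vals.sum() * grid.voxel_volume),
            )
        )
    sites.sort(key=lambda s: s.integrated_density, reverse=True)
    for i, s in enumerate(sites):
        s.site_id = i
    return sites
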