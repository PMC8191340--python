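"""Region definitions and occupancy / visit / residence / entry statistics.

A region is a union of spheres around anchor atoms (optionally intersected
with a slab along one axis). Membership is evaluated per frame with
minimum-image distances under the frame's orthorhombic box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Topology, Trajectory

__all__ = [
    "Region",
    "OccupancyTable",
    "make_region",
    "occupancy_counts",
    "occupancy_fractions",
    "extract_visits",
    "residence_stats",
    "count_entries",
]


def min_image_dist(points: np.ndarray, refs: np.ndarray,
                   box: np.ndarray) -> np.ndarray:
    """Minimum-image distance matrix (n_points, n_refs)."""
    d = points[:, None, :] - refs[None, :, :]
    d -= box * np.round(d / box)
    return np.sqrt(np.sum(d * d, axis=-1))


@dataclass
class Region:
    """Named membership volume: union of spheres around anchor positions.

    ``anchor_groups`` is a list of atom-index arrays; each group's anchor
    position is the mean of its atoms' coordinates (a single atom for the
    Lys/Arg/Asp/Glu reference-atom rule, the whole residue for the centroid
    fallback), re-resolved from the current frame's coordinates.
    """

    name: str
    anchor_groups: list = field(default_factory=list)
    radius: float = 6.0
    slab_axis: int | None = None          # 0/1/2 for x/y/z
    slab_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("region radius must be positive")
        if (self.slab_axis is None) != (self.slab_bounds is None):
            raise ValueError("slab needs both axis and bounds")

    def anchor_positions(self, frame_coords: np.ndarray) -> np.ndarray:
        return np.array(
            [frame_coords[g].mean(axis=0) for g in self.anchor_groups]
        )

    def contains(self, points: np.ndarray, frame_coords: np.ndarray,
                 box: np.ndarray) -> np.ndarray:
        """Boolean membership for an (n, 3) point array."""
        points = np.atleast_2d(points)
        anchors = self.anchor_positions(frame_coords)
        dist = min_image_dist(points, anchors, box)
        inside = np.any(dist <= self.radius, axis=1)
        if self.slab_axis is not None:
            lo, hi = self.slab_bounds
            coord = points[:, self.slab_axis]
            inside &= (coord >= lo) & (coord <= hi)
        return inside


_REFERENCE_ATOM = {"LYS": "NZ", "ARG": "CZ", "ASP": "CG", "GLU": "CD"}


def _parse_selector(sel) -> tuple[str | None, int]:
    """Accept "LYS:539", "539", (resname, resid), or int."""
    if isinstance(sel, (int, np.integer)):
        return None, int(sel)
    if isinstance(sel, (tuple, list)):
        return str(sel[0]), int(sel[1])
    s = str(sel)
    if ":" in s:
        rn, rid = s.split(":", 1)
        return rn.strip() or None, int(rid)
    return None, int(s)


def make_region(topology: Topology, residue_selectors, radius: float = 6.0,
                slab_axis: int | None = None,
                slab_bounds: tuple[float, float] | None = None,
                name: str = "region") -> Region:
    """Resolve residue selectors into a :class:`Region`.

    Anchor atom per residue: the side-chain reference atom for Lys/Arg/
    Asp/Glu when present, otherwise all atoms of the residue (centroid
    rule). Unmatched selectors raise, listing every failure.
    """
    res_atoms = topology.residue_atoms()
    groups, missing = [], []
    for sel in residue_selectors:
        want_name, want_id = _parse_selector(sel)
        matched = False
        for (chain, rid), idx in res_atoms.items():
            rn = str(topology.resnames[idx[0]])
            if rid != want_id:
                continue
            if want_name is not None and rn != want_name:
                continue
            ref = _REFERENCE_ATOM.get(rn)
            if ref is not None:
                hit = idx[np.asarray(topology.names[idx]) == ref]
                groups.append(hit if hit.size else idx)
            else:
                groups.append(idx)
            matched = True
        if not matched:
            missing.append(str(sel))
    if missing:
        raise ValueError(
            "region selectors matched no residues: " + ", ".join(missing)
        )
    return Region(name=name, anchor_groups=groups, radius=radius,
                  slab_axis=slab_axis, slab_bounds=slab_bounds)


@dataclass
class OccupancyTable:
    """Per-frame ion counts: counts[frame, region, species]."""

    counts: np.ndarray
    regions: list[str]
    species: list[str]
    dt: float

    @property
    def n_frames(self) -> int:
        return self.counts.shape[0]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for ri, region in enumerate(self.regions):
            for si, sp in enumerate(self.species):
                for f in range(self.n_frames):
                    recs.append((f, region, sp, int(self.counts[f, ri, si])))
        return pd.DataFrame(recs, columns=["frame", "region", "species", "count"])


def _species_atom_indices(topology: Topology, species: list[str]) -> dict[str, np.ndarray]:
    known = set(np.unique(topology.species)) - {""}
    out = {}
    for sp in species:
        if sp not in known:
            raise ValueError(
                f"unknown species tag {sp!r}; topology has {sorted(known)}"
            )
        out[sp] = topology.ion_indices(sp)
    return out


def occupancy_counts(traj: Trajectory, topology: Topology,
                     regions: list[Region], species: list[str]) -> OccupancyTable:
    """Count ions of each species inside each region, per frame."""
    sp_idx = _species_atom_indices(topology, species)
    counts = np.zeros((traj.n_frames, len(regions), len(species)), dtype=int)
    for f in range(traj.n_frames):
        frame = traj.coords[f]
        box = traj.box[f]
        for ri, region in enumerate(regions):
            for si, sp in enumerate(species):
                idx = sp_idx[sp]
                if idx.size:
                    counts[f, ri, si] = int(
                        region.contains(frame[idx], frame, box).sum()
                    )
    return OccupancyTable(counts=counts, regions=[r.name for r in regions],
                          species=list(species), dt=traj.dt)


def occupancy_fractions(table: OccupancyTable,
                        max_bin: int = 3) -> pd.DataFrame:
    """Percent of frames with 0, 1, ..., >=max_bin ions per (region, species).

    Rows sum to 100% within 1e-9.
    """
    if table.n_frames == 0:
        raise ValueError("empty occupancy table")
    rows = []
    bins = [str(i) for i in range(max_bin)] + [f"{max_bin}+"]
    for ri, region in enumerate(table.regions):
        for si, sp in enumerate(table.species):
            c = table.counts[:, ri, si]
            pct = [100.0 * np.mean(c == i) for i in range(max_bin)]
            pct.append(100.0 * np.mean(c >= max_bin))
            rows.append([region, sp] + pct)
    return pd.DataFrame(rows, columns=["region", "species"] + bins)


def membership_series(traj: Trajectory, region: Region,
                      atom_index: int) -> np.ndarray:
    """Per-frame membership of one atom, shape (n_frames,), bool.

    Vectorized over frames; equivalent to calling ``region.contains`` on
    each frame (anchors re-resolved per frame).
    """
    pts = traj.coords[:, atom_index, :]
    anchors = np.stack(
        [traj.coords[:, g, :].mean(axis=1) for g in region.anchor_groups],
        axis=1,
    )  # (n_frames, n_anchors, 3)
    box = traj.box[:, None, :]
    d = pts[:, None, :] - anchors
    d -= box * np.round(d / box)
    dist2 = np.sum(d * d, axis=-1)
    inside = np.any(dist2 <= region.radius**2, axis=1)
    if region.slab_axis is not None:
        lo, hi = region.slab_bounds
        coord = pts[:, region.slab_axis]
        inside &= (coord >= lo) & (coord <= hi)
    return inside


def visits_from_membership(member: np.ndarray, gap_tolerance: int = 0,
                           min_duration: int = 1) -> list[tuple[int, int]]:
    """Maximal in-region runs with gap bridging and a duration floor.

    Out-of-region gaps of <= gap_tolerance frames between runs are bridged;
    merged runs shorter than min_duration frames are discarded.
    """
    if gap_tolerance < 0:
        raise ValueError("gap_tolerance must be >= 0")
    if min_duration < 1:
        raise ValueError("min_duration must be >= 1")
    member = np.asarray(member, dtype=bool)
    idx = np.flatnonzero(member)
    if idx.size == 0:
        return []
    # raw maximal runs
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    # bridge gaps
    merged = [(int(starts[0]), int(ends[0]))]
    for s, e in zip(starts[1:], ends[1:]):
        ps, pe = merged[-1]
        if s - pe - 1 <= gap_tolerance:
            merged[-1] = (ps, int(e))
        else:
            merged.append((int(s), int(e)))
    return [(s, e) for s, e in merged if e - s + 1 >= min_duration]


def extract_visits(traj: Trajectory, topology: Topology, region: Region,
                   species: list[str] | None = None,
                   gap_tolerance: int = 2,
                   min_duration: int = 1) -> pd.DataFrame:
    """Tabulate per-ion visits to a region.

    Columns: ion (atom index), species, region, start, end (inclusive
    frames), duration_ns, censored_start, censored_end. Visits truncated by
    either trajectory end are flagged censored.
    """
    if species is None:
        species = sorted(set(topology.species) - {""})
    sp_idx = _species_atom_indices(topology, species)
    rows = []
    last = traj.n_frames - 1
    for sp in species:
        for atom in sp_idx[sp]:
            member = membership_series(traj, region, int(atom))
            for s, e in visits_from_membership(member, gap_tolerance, min_duration):
                rows.append(
                    (int(atom), sp, region.name, s, e,
                     (e - s + 1) * traj.dt, s == 0, e == last)
                )
    return pd.DataFrame(
        rows,
        columns=["ion", "species", "region", "start", "end", "duration_ns",
                 "censored_start", "censored_end"],
    )


_UNDEFINED = float("nan")


def residence_stats(visits: pd.DataFrame,
                    include_censored: bool = False) -> pd.DataFrame:
    """Mean/median/max residence and visit counts per (region, species).

    Censored visits are excluded from the statistics by default but counted
    in ``n_censored``. With zero usable visits the statistics are NaN
    sentinels, never 0.
    """
    cols = ["region", "species", "n_visits", "n_censored", "mean_ns",
            "median_ns", "max_ns"]
    if visits.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    for (region, sp), grp in visits.groupby(["region", "species"], sort=True):
        censored = grp["censored_start"] | grp["censored_end"]
        use = grp if include_censored else grp[~censored]
        dur = use["duration_ns"].to_numpy()
        if dur.size == 0:
            rows.append((region, sp, 0, int(censored.sum()),
                         _UNDEFINED, _UNDEFINED, _UNDEFINED))
        else:
            rows.append((region, sp, int(dur.size), int(censored.sum()),
                         float(dur.mean()), float(np.median(dur)),
                         float(dur.max())))
    return pd.DataFrame(rows, columns=cols)


def count_entries(visits: pd.DataFrame, n_frames: int) -> pd.DataFrame:
    """Entry and exchange bookkeeping per (region, species).

    Entries = visits not censored at the start (the ion demonstrably came in
    from outside). An exchange is a frame at which the identity of the
    region-occupying ions changes — some ion leaves AND some ion arrives —
    without the occupancy dropping to zero in between.
    """
    cols = ["region", "species", "n_entries", "n_exchanges"]
    if visits.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    for (region, sp), grp in visits.groupby(["region", "species"], sort=True):
        entries = int((~grp["censored_start"]).sum())
        occupants: list[set] = [set() for _ in range(n_frames)]
        for _, v in grp.iterrows():
            for f in range(int(v["start"]), int(v["end"]) + 1):
                occupants[f].add(int(v["ion"]))
        exchanges = 0
        for f in range(1, n_frames):
            a, b = occupants[f - 1], occupants[f]
            if a and b and (a - b) and (b - a):
                exchanges += 1
        rows.append((region, sp, entries, exchanges))
    return pd.DataFrame(rows, columns=cols)
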