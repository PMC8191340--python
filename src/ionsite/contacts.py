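"""Per-residue ion contact frequencies and binding-site residue ranking.

A residue is "in contact" in a frame when any of its non-hydrogen atoms
lies within the cutoff (default 5 A) of at least one ion of the species,
using minimum-image distances; the frequency is the fraction of analyzed
frames with a contact (per-frame binary, not atom-pair weighted).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import Topology, Trajectory
from .regions import min_image_dist

__all__ = ["contact_frequencies", "rank_site_residues"]

DEFAULT_CUTOFF = 5.0  # Angstrom


def contact_frequencies(traj: Trajectory, topology: Topology,
                        species: list[str],
                        cutoff: float = DEFAULT_CUTOFF,
                        frame_filter: np.ndarray | None = None) -> pd.DataFrame:
    """Contact frequency of every non-ion residue with each ion species.

    ``frame_filter`` is an optional boolean mask restricting the analysis,
    e.g. to frames where the ion occupies a particular region, so that
    site-bound frames can be tabulated separately or cumulatively.

    Returns columns: chain, resid, resname, species, frequency, n_frames.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    for sp in species:
        if not np.any(topology.species == sp):
            raise ValueError(f"ion selection is empty for species {sp!r}")
    if frame_filter is None:
        frames = np.arange(traj.n_frames)
    else:
        frame_filter = np.asarray(frame_filter, dtype=bool)
        if frame_filter.shape != (traj.n_frames,):
            raise ValueError("frame_filter must be a per-frame boolean mask")
        frames = np.flatnonzero(frame_filter)
    if frames.size == 0:
        raise ValueError("frame filter selects no frames")

    heavy = np.array([not e.upper().startswith("H") for e in topology.elements])
    res_atoms = {
        key: idx[heavy[idx]]
        for key, idx in topology.residue_atoms().items()
        if topology.species[idx[0]] == ""  # non-ion residues only
    }
    res_atoms = {k: v for k, v in res_atoms.items() if v.size}

    hits = {
        (key, sp): 0 for key in res_atoms for sp in species
    }
    for f in frames:
        frame = traj.coords[f]
        box = traj.box[f]
        for sp in species:
            ions = frame[topology.ion_indices(sp)]
            for key, idx in res_atoms.items():
                d = min_image_dist(frame[idx], ions, box)
                if np.any(d <= cutoff):
                    hits[(key, sp)] += 1

    rows = []
    for (chain, rid), idx in res_atoms.items():
        rn = str(topology.resnames[idx[0]])
        for sp in species:
            rows.append(
                (chain, rid, rn, sp,
                 hits[((chain, rid), sp)] / frames.size, int(frames.size))
            )
    return pd.DataFrame(
        rows,
        columns=["chain", "resid", "resname", "species", "frequency", "n_frames"],
    )


def rank_site_residues(table: pd.DataFrame,
                       threshold: float = 0.5) -> dict[str, pd.DataFrame]:
    """Residues with contact frequency >= threshold, per species.

    Sorted by frequency descending; ties broken by residue id ascending.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    out = {}
    for sp, grp in table.groupby("species", sort=True):
        sel = grp[grp["frequency"] >= threshold].copy()
        sel = sel.sort_values(
            ["frequency", "resid"], ascending=[False, True]
        ).reset_index(drop=True)
        out[str(sp)] = sel
    return out
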