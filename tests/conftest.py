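"""Shared fixtures and independent brute-force oracles.

The oracle helpers here deliberately re-derive results by exhaustive
enumeration (O(frames * ions * atoms) scans, left-to-right interval
merging) so the package implementations are checked against independent
code paths, not against themselves.
"""

from __future__ import annotations

import numpy as np
import pytest

from ionsite.io import Topology, Trajectory


def make_topology(n_ions: int, species: str = "Cl-",
                  anchors=(("LYS", 539, "NZ"),),
                  box=(50.0, 50.0, 50.0)) -> Topology:
    """Tiny hand-built topology: anchor residues (chain A) + ions (chain I)."""
    names, resnames, resids, chains, sp, elements = [], [], [], [], [], []
    for rn, rid, atom in anchors:
        names.append(atom)
        resnames.append(rn)
        resids.append(rid)
        chains.append("A")
        sp.append("")
        elements.append(atom[:1])
    for i in range(n_ions):
        names.append("CL")
        resnames.append("CLA")
        resids.append(1000 + i)
        chains.append("I")
        sp.append(species)
        elements.append("C")
    return Topology(
        names=np.array(names, dtype="U4"),
        resnames=np.array(resnames, dtype="U4"),
        resids=np.array(resids, dtype=int),
        chains=np.array(chains, dtype="U1"),
        species=np.array(sp, dtype="U8"),
        elements=np.array(elements, dtype="U2"),
        box=np.asarray(box, dtype=float),
    )


def pattern_system(patterns, anchor_pos=(25.0, 25.0, 25.0),
                   outside_pos=(5.0, 5.0, 5.0), dt=0.1, box=(50.0, 50.0, 50.0)):
    """Build (topology, trajectory) where ion i sits at the anchor when
    patterns[i][frame] is truthy, far away otherwise."""
    patterns = [np.asarray(p, dtype=bool) for p in patterns]
    n_frames = len(patterns[0])
    top = make_topology(len(patterns), box=box)
    coords = np.empty((n_frames, top.n_atoms, 3))
    coords[:, 0, :] = anchor_pos
    for i, pat in enumerate(patterns):
        coords[:, 1 + i, :] = np.where(
            pat[:, None], np.asarray(anchor_pos), np.asarray(outside_pos)
        )
    return top, Trajectory(coords=coords, dt=dt, box=np.asarray(box, dtype=float))


def oracle_visits(member, gap_tolerance: int, min_duration: int):
    """Left-to-right scan oracle for visit extraction with gap bridging."""
    member = list(bool(m) for m in member)
    runs, i, n = [], 0, len(member)
    while i < n:
        if member[i]:
            j = i
            while j + 1 < n and member[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] - 1 <= gap_tolerance:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if e - s + 1 >= min_duration]


def oracle_min_image(p, q, box):
    """Scalar minimum-image distance by explicit image enumeration."""
    p, q, box = np.asarray(p, float), np.asarray(q, float), np.asarray(box, float)
    best = np.inf
    for ix in (-1, 0, 1):
        for iy in (-1, 0, 1):
            for iz in (-1, 0, 1):
                shift = np.array([ix, iy, iz]) * box
                best = min(best, float(np.linalg.norm(p - q + shift)))
    return best


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_site_markov():
    """Two bound states + bulk, the synthetic stand-in for a two-site cavity."""
    from ionsite.synthetic import MarkovModel, MarkovState

    return MarkovModel(
        states=[
            MarkovState("bulk", kind="bulk"),
            MarkovState("S1", center=[30.0, 30.0, 24.0], jitter_sd=0.5),
            MarkovState("S2", center=[30.0, 30.0, 36.0], jitter_sd=0.5),
        ],
        transition=np.array(
            [[0.8, 0.1, 0.1], [0.05, 0.95, 0.0], [0.05, 0.0, 0.95]]
        ),
        dt=0.1,
        ions={"Cl-": 5},
        box=np.array([60.0, 60.0, 60.0]),
        seed=42,
    )
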