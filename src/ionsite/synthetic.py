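"""Synthetic scaffolds and ion trajectories with analytically known kinetics.

The generators here are the ground-truth oracles for every downstream
estimator: a discrete Markov jump process whose per-state residence times
follow the geometric closed form dt/(1 - P[s,s]), and an overdamped-Langevin
(Euler-Maruyama) integrator whose free diffusion obeys MSD = 6*D*t.

Units: Angstrom, ns, kcal/mol throughout. All randomness is seeded;
identical specs give bit-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import DEFAULT_SPECIES_MAP, Topology, Trajectory

__all__ = [
    "ScaffoldSpec",
    "MarkovState",
    "MarkovModel",
    "BrownianSpec",
    "build_scaffold",
    "simulate_markov_ions",
    "simulate_brownian_ions",
]

_SPECIES_TO_RESNAME = {v: k for k, v in DEFAULT_SPECIES_MAP.items()}
# default anchor reference atom per residue type (side-chain charge carrier)
_ANCHOR_ATOM = {"LYS": "NZ", "ARG": "CZ", "ASP": "CG", "GLU": "CD"}


@dataclass
class ScaffoldSpec:
    """Static cylindrical-cavity scaffold with named anchor residues.

    ``anchor_residues`` entries are (residue_name, residue_id, position[3]).
    Wall pseudo-atoms are laid out on the cylinder surface at
    ``wall_atom_spacing`` so that no wall atom comes closer than
    ``cavity_radius`` to the cavity axis.
    """

    box: np.ndarray
    cavity_radius: float = 10.0
    cavity_depth: float = 20.0
    cavity_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    anchor_residues: list = field(default_factory=list)
    wall_atom_spacing: float = 2.0

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")
        if self.cavity_radius <= 0:
            raise ValueError("cavity_radius must be positive")
        if self.cavity_depth <= 0:
            raise ValueError("cavity_depth must be positive")
        if self.wall_atom_spacing <= 0:
            raise ValueError("wall_atom_spacing must be positive")
        axis = np.asarray(self.cavity_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("cavity_axis must be nonzero")
        self.cavity_axis = axis / norm
        seen_ids = set()
        for resname, resid, pos in self.anchor_residues:
            pos = np.asarray(pos, dtype=float)
            if np.any(pos < 0) or np.any(pos > self.box):
                raise ValueError(
                    f"anchor residue {resname} {resid} lies outside the box"
                )
            if resid in seen_ids:
                raise ValueError(f"duplicate anchor residue id {resid}")
            seen_ids.add(resid)


def _axis_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to ``axis`` (deterministic)."""
    probe = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(probe, axis)) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, probe)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def build_scaffold(spec: ScaffoldSpec) -> tuple[Topology, np.ndarray]:
    """Construct the scaffold topology and its reference coordinates.

    Wall pseudo-atoms ("WAL" residues, chain W, one ring per residue) form a
    cylinder of the requested radius/depth centered in the box; anchor
    residues (chain A) sit exactly at their requested positions.
    Deterministic for a given spec.
    """
    center = spec.box / 2.0
    axis = spec.cavity_axis
    u, v = _axis_frame(axis)

    n_rings = max(2, int(np.ceil(spec.cavity_depth / spec.wall_atom_spacing)) + 1)
    circumference = 2.0 * np.pi * spec.cavity_radius
    n_per_ring = max(6, int(np.ceil(circumference / spec.wall_atom_spacing)))
    heights = np.linspace(-spec.cavity_depth / 2.0, spec.cavity_depth / 2.0, n_rings)
    angles = 2.0 * np.pi * np.arange(n_per_ring) / n_per_ring

    names, resnames, resids, chains, elements = [], [], [], [], []
    coords = []

    max_anchor_id = max((rid for _, rid, _ in spec.anchor_residues), default=0)
    for rname, rid, pos in spec.anchor_residues:
        names.append(_ANCHOR_ATOM.get(rname, "CA"))
        resnames.append(rname)
        resids.append(int(rid))
        chains.append("A")
        elements.append(names[-1][:1])
        coords.append(np.asarray(pos, dtype=float))

    wall_resid = max_anchor_id
    for h in heights:
        wall_resid += 1
        ring_center = center + h * axis
        for ang in angles:
            offset = spec.cavity_radius * (np.cos(ang) * u + np.sin(ang) * v)
            names.append("W")
            resnames.append("WAL")
            resids.append(wall_resid)
            chains.append("W")
            elements.append("X")
            coords.append(ring_center + offset)

    species = np.array([""] * len(names), dtype="U8")
    top = Topology(
        names=np.array(names, dtype="U4"),
        resnames=np.array(resnames, dtype="U4"),
        resids=np.array(resids, dtype=int),
        chains=np.array(chains, dtype="U1"),
        species=species,
        elements=np.array(elements, dtype="U2"),
        box=spec.box.copy(),
    )
    return top, np.asarray(coords, dtype=float)


@dataclass
class MarkovState:
    """One kinetic state and its spatial placement rule.

    kind "site": position = center + Gaussian jitter (sd ``jitter_sd``).
    kind "bulk": position resampled uniformly in the solvent shell each frame
    (at least ``bulk_exclusion`` away from every site center).
    """

    name: str
    kind: str = "site"
    center: np.ndarray | None = None
    jitter_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("site", "bulk"):
            raise ValueError(f"unknown state kind {self.kind!r}")
        if self.kind == "site":
            if self.center is None:
                raise ValueError(f"site state {self.name!r} needs a center")
            self.center = np.asarray(self.center, dtype=float)


@dataclass
class MarkovModel:
    """Discrete-time Markov jump process shared by all ions.

    The expected residence of state s is dt/(1 - P[s,s]) ns (geometric law);
    this closed form is recorded in the ground truth for estimator tests.
    """

    states: list[MarkovState]
    transition: np.ndarray           # row-stochastic (n_states, n_states)
    dt: float                        # ns per step
    ions: dict[str, int]             # species label -> ion count
    box: np.ndarray
    seed: int = 0
    initial_state: int = 0
    bulk_exclusion: float = 12.0
    exclusive_sites: bool = False    # single-occupancy bound states

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        n = len(self.states)
        if self.transition.shape != (n, n):
            raise ValueError("transition matrix shape must match state count")
        if np.any(self.transition < 0) or np.any(
            np.abs(self.transition.sum(axis=1) - 1.0) > 1e-12
        ):
            raise ValueError("transition matrix must be row-stochastic (1e-12)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.box = np.asarray(self.box, dtype=float)
        if not self.ions:
            raise ValueError("at least one ion required")

    def expected_residence(self) -> dict[str, float]:
        """Closed-form mean residence per state in ns (inf for absorbing)."""
        out = {}
        for i, st in enumerate(self.states):
            stay = self.transition[i, i]
            out[st.name] = float("inf") if stay >= 1.0 else self.dt / (1.0 - stay)
        return out


def _ion_topology(ions: dict[str, int], box: np.ndarray,
                  start_resid: int = 1) -> Topology:
    names, resnames, resids, chains, species, elements = [], [], [], [], [], []
    rid = start_resid
    for label, count in ions.items():
        resname = _SPECIES_TO_RESNAME.get(label, label[:4].upper())
        for _ in range(count):
            names.append(resname[:2])
            resnames.append(resname)
            resids.append(rid)
            chains.append("I")
            species.append(label)
            elements.append(resname[:1])
            rid += 1
    return Topology(
        names=np.array(names, dtype="U4"),
        resnames=np.array(resnames, dtype="U4"),
        resids=np.array(resids, dtype=int),
        chains=np.array(chains, dtype="U1"),
        species=np.array(species, dtype="U8"),
        elements=np.array(elements, dtype="U2"),
        box=np.asarray(box, dtype=float),
    )


def _sample_bulk(rng: np.random.Generator, box: np.ndarray,
                 site_centers: np.ndarray, exclusion: float) -> np.ndarray:
    """Uniform point in the box at least ``exclusion`` from all site centers."""
    for _ in range(1000):
        p = rng.uniform(0.0, box)
        if site_centers.size == 0:
            return p
        if np.all(np.linalg.norm(site_centers - p, axis=1) >= exclusion):
            return p
    raise RuntimeError("could not sample a bulk position; exclusion too large")


def simulate_markov_ions(
    model: MarkovModel, n_steps: int
) -> tuple[Topology, Trajectory, dict]:
    """Simulate ions hopping through the Markov model's states.

    Returns the ion topology, the trajectory (one coordinate per ion per
    frame, placed by the current state's rule), and a ground-truth record
    with the exact per-ion state sequence and the closed-form expected
    residence times.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(model.seed)
    states = model.states
    n_states = len(states)
    site_centers = np.array(
        [st.center for st in states if st.kind == "site"]
    ).reshape(-1, 3)

    labels = [lb for lb, cnt in model.ions.items() for _ in range(cnt)]
    n_ions = len(labels)
    cum = np.cumsum(model.transition, axis=1)

    state_seq = np.empty((n_steps, n_ions), dtype=int)
    cur = np.full(n_ions, model.initial_state, dtype=int)
    coords = np.empty((n_steps, n_ions, 3), dtype=float)

    site_idx = {i for i, st in enumerate(states) if st.kind == "site"}
    if model.exclusive_sites and model.initial_state in site_idx and n_ions > 1:
        bulk_states = [i for i, st in enumerate(states) if st.kind == "bulk"]
        if not bulk_states:
            raise ValueError(
                "exclusive_sites with a site initial state needs a bulk state"
            )
        cur[1:] = bulk_states[0]  # only one ion may start in the site

    for step in range(n_steps):
        if step > 0:
            u = rng.random(n_ions)
            proposed = np.array(
                [np.searchsorted(cum[cur[i]], u[i], side="right") for i in range(n_ions)]
            )
            proposed = np.minimum(proposed, n_states - 1)
            if model.exclusive_sites:
                # a site frees up only on the step after its holder leaves,
                # so per-frame occupancy never exceeds one ion per site
                held = {int(s) for s in cur if int(s) in site_idx}
                claimed: set[int] = set()
                for ion in range(n_ions):
                    tgt, src = int(proposed[ion]), int(cur[ion])
                    if tgt in site_idx and tgt != src:
                        if tgt in held or tgt in claimed:
                            proposed[ion] = src  # site busy: stay put
                        else:
                            claimed.add(tgt)
            cur = proposed
        state_seq[step] = cur
        for ion in range(n_ions):
            st = states[cur[ion]]
            if st.kind == "bulk":
                coords[step, ion] = _sample_bulk(
                    rng, model.box, site_centers, model.bulk_exclusion
                )
            else:
                coords[step, ion] = st.center + rng.normal(
                    0.0, st.jitter_sd, size=3
                )
    coords %= model.box  # periodic wrap

    top = _ion_topology(model.ions, model.box)
    traj = Trajectory(coords=coords, dt=model.dt, box=model.box)
    truth = {
        "state_names": [st.name for st in states],
        "state_sequence": state_seq.T.tolist(),   # per ion
        "ion_species": labels,
        "expected_residence_ns": model.expected_residence(),
        "site_centers": {
            st.name: st.center.tolist() for st in states if st.kind == "site"
        },
        "dt_ns": model.dt,
        "seed": model.seed,
    }
    return top, traj, truth


@dataclass
class BrownianSpec:
    """Overdamped Langevin dynamics in a sum-of-Gaussian-wells potential.

    U(x) = -sum_w depth_w * exp(-|x - c_w|^2 / (2 width_w^2)), so wells are
    attractive basins of the stated depth (kcal/mol).

    Construction enforces the explicit-Euler stability contract: the largest
    deterministic drift step D*dt*|grad U|_max / kT must stay well below the
    narrowest well width.
    """

    wells: list                       # (center[3], depth, width)
    diffusion_coefficient: float      # A^2/ns
    kT: float                         # kcal/mol
    dt: float                         # ns
    n_steps: int
    box: np.ndarray
    n_ions: int = 1
    seed: int = 0
    start: np.ndarray | None = None   # optional fixed start (3,) for all ions
    wrap: bool = True

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        if self.dt <= 0 or self.kT <= 0 or self.diffusion_coefficient < 0:
            raise ValueError("dt and kT must be positive; D non-negative")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        parsed = []
        for center, depth, width in self.wells:
            if depth < 0:
                raise ValueError("well depth must be >= 0")
            if width <= 0:
                raise ValueError("well width must be positive")
            parsed.append((np.asarray(center, dtype=float), float(depth), float(width)))
        self.wells = parsed
        # max |grad U| of a Gaussian well is depth/(width*sqrt(e)), at r=width
        for _, depth, width in self.wells:
            grad_max = depth / (width * np.exp(0.5))
            drift = self.diffusion_coefficient * self.dt * grad_max / self.kT
            if drift > 0.1 * width:
                raise ValueError(
                    f"unstable integration: drift step {drift:.3g} A exceeds "
                    f"10% of well width {width} A; reduce dt"
                )


def _force(pos: np.ndarray, wells) -> np.ndarray:
    """-grad U at each position, (n, 3)."""
    f = np.zeros_like(pos)
    for center, depth, width in wells:
        d = pos - center
        r2 = np.sum(d * d, axis=1, keepdims=True)
        # U = -depth*exp(-r^2/2w^2); F = -grad U = -depth/w^2 * d * exp(...)
        f -= (depth / width**2) * d * np.exp(-r2 / (2.0 * width**2))
    return f


def simulate_brownian_ions(spec: BrownianSpec) -> Trajectory:
    """Euler-Maruyama integration of independent Brownian ions.

    x(t+dt) = x + (D/kT) F dt + sqrt(2 D dt) xi, with periodic wrapping
    unless spec.wrap is False (useful for MSD checks).
    """
    rng = np.random.default_rng(spec.seed)
    D, kT, dt = spec.diffusion_coefficient, spec.kT, spec.dt
    if spec.start is not None:
        pos = np.tile(np.asarray(spec.start, dtype=float), (spec.n_ions, 1))
    else:
        pos = rng.uniform(0.0, spec.box, size=(spec.n_ions, 3))
    coords = np.empty((spec.n_steps, spec.n_ions, 3), dtype=float)
    sigma = np.sqrt(2.0 * D * dt)
    for step in range(spec.n_steps):
        coords[step] = pos % spec.box if spec.wrap else pos
        drift = (D / kT) * _force(pos, spec.wells) * dt
        pos = pos + drift + sigma * rng.normal(size=pos.shape)
    return Trajectory(coords=coords, dt=dt, box=spec.box)
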