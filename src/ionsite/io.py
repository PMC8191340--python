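"""Structure, trajectory, and grid file I/O.

Formats: PDB (topology), multi-frame XYZ (text trajectory, canonical fixture
format), DCD (optional, via MDAnalysis if installed), OpenDX (grids), CSV
(tables), JSON (metadata / ground truth).

Conventions: Angstrom coordinates, right-handed axes, PDB taken as-is with no
implicit recentering; 0-based atom and frame indices everywhere.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from gridData import Grid

__all__ = [
    "Topology",
    "Trajectory",
    "DEFAULT_SPECIES_MAP",
    "read_topology",
    "write_topology",
    "read_trajectory",
    "write_trajectory",
    "read_grid_file",
    "write_grid_file",
]

#: CHARMM-style ion residue names -> species tag.
DEFAULT_SPECIES_MAP = {
    "CLA": "Cl-",
    "SOD": "Na+",
    "BIC": "HCO3-",
    "CO3": "CO3 2-",
    "POT": "K+",
}

_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "HSP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR",
    "TRP", "TYR", "VAL",
}
#: residue names never treated as ions (scaffold walls, water, protein).
_NON_ION_RESNAMES = _AMINO_ACIDS | {"WAL", "HOH", "TIP3", "WAT", "SOL"}


@dataclass
class Topology:
    """Static atom/residue metadata for one system.

    Arrays are parallel, one entry per atom; indices are contiguous from 0.
    ``species`` is the ion species tag ("" for non-ion atoms, "other" for
    unrecognized single-atom ion-like residues).
    """

    names: np.ndarray          # atom names, dtype=U
    resnames: np.ndarray
    resids: np.ndarray         # int
    chains: np.ndarray
    species: np.ndarray
    elements: np.ndarray
    box: np.ndarray            # orthorhombic lengths (3,), Angstrom

    def __post_init__(self) -> None:
        n = len(self.names)
        for attr in ("resnames", "resids", "chains", "species", "elements"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"topology field {attr!r} length mismatch")
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape != (3,):
            raise ValueError("box must have three orthorhombic lengths")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered unique (chain, resid) keys."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chains, self.resids):
            seen.setdefault((str(c), int(r)), None)
        return list(seen)

    def residue_atoms(self) -> dict[tuple[str, int], np.ndarray]:
        """Map (chain, resid) -> atom index array, in atom order."""
        out: dict[tuple[str, int], list[int]] = {}
        for i, (c, r) in enumerate(zip(self.chains, self.resids)):
            out.setdefault((str(c), int(r)), []).append(i)
        return {k: np.asarray(v, dtype=int) for k, v in out.items()}

    def ion_indices(self, species: str | None = None) -> np.ndarray:
        mask = self.species != ""
        if species is not None:
            mask = self.species == species
        return np.flatnonzero(mask)

    def concat(self, other: "Topology") -> "Topology":
        """Append another topology's atoms (same box)."""
        return Topology(
            names=np.concatenate([self.names, other.names]),
            resnames=np.concatenate([self.resnames, other.resnames]),
            resids=np.concatenate([self.resids, other.resids]),
            chains=np.concatenate([self.chains, other.chains]),
            species=np.concatenate([self.species, other.species]),
            elements=np.concatenate([self.elements, other.elements]),
            box=self.box.copy(),
        )


@dataclass
class Trajectory:
    """Per-frame coordinates (n_frames, n_atoms, 3) in Angstrom."""

    coords: np.ndarray
    dt: float                         # ns per frame
    box: np.ndarray = field(default=None)  # (n_frames, 3) or (3,)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.box is None:
            raise ValueError("trajectory requires box lengths")
        box = np.asarray(self.box, dtype=float)
        if box.shape == (3,):
            box = np.tile(box, (self.n_frames, 1))
        if box.shape != (self.n_frames, 3):
            raise ValueError("box must broadcast to (n_frames, 3)")
        self.box = box

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


def _species_for(resname: str, n_atoms_in_residue: int,
                 species_map: dict[str, str]) -> str:
    if resname in species_map:
        return species_map[resname]
    if resname in _NON_ION_RESNAMES:
        return ""
    if n_atoms_in_residue == 1:
        warnings.warn(
            f"unknown ion residue name {resname!r}; tagging species as 'other'",
            stacklevel=3,
        )
        return "other"
    return ""


def read_topology(path: str | Path,
                  species_map: dict[str, str] | None = None,
                  box: np.ndarray | None = None) -> Topology:
    """Parse ATOM/HETATM records of a PDB file into a :class:`Topology`.

    Box lengths come from a CRYST1 record if present, else from ``box``.
    Unreadable records raise with the offending 1-based line number.
    """
    species_map = DEFAULT_SPECIES_MAP if species_map is None else species_map
    path = Path(path)
    names, resnames, resids, chains, elements = [], [], [], [], []
    file_box = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "CRYST1":
                try:
                    file_box = np.array(
                        [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                    )
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: bad CRYST1 record at line {lineno}"
                    ) from exc
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ValueError(
                    f"{path}: truncated {rec} record at line {lineno}"
                )
            try:
                names.append(line[12:16].strip())
                resnames.append(line[17:21].strip())
                chains.append(line[21].strip() or "A")
                resids.append(int(line[22:26]))
                # coordinates validated here even though stored by the caller
                float(line[30:38]), float(line[38:46]), float(line[46:54])
                elements.append(line[76:78].strip() or names[-1][:1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: unreadable {rec} record at line {lineno}: {exc}"
                ) from exc
    if file_box is not None:
        box = file_box
    if box is None:
        raise ValueError(f"{path}: no CRYST1 record and no box provided")
    resnames_arr = np.array(resnames, dtype="U4")
    resids_arr = np.array(resids, dtype=int)
    chains_arr = np.array(chains, dtype="U1")
    # residue sizes for the single-atom-ion heuristic
    counts: dict[tuple[str, int], int] = {}
    for c, r in zip(chains_arr, resids_arr):
        counts[(str(c), int(r))] = counts.get((str(c), int(r)), 0) + 1
    species = np.array(
        [
            _species_for(rn, counts[(str(c), int(r))], species_map)
            for rn, c, r in zip(resnames_arr, chains_arr, resids_arr)
        ],
        dtype="U8",
    )
    return Topology(
        names=np.array(names, dtype="U4"),
        resnames=resnames_arr,
        resids=resids_arr,
        chains=chains_arr,
        species=species,
        elements=np.array(elements, dtype="U2"),
        box=np.asarray(box, dtype=float),
    )


def read_pdb_coords(path: str | Path) -> np.ndarray:
    """Coordinates (n_atoms, 3) from a PDB file's ATOM/HETATM records."""
    coords = []
    with open(path) as fh:
        for line in fh:
            if line[:6].strip() in ("ATOM", "HETATM"):
                coords.append(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
    return np.asarray(coords, dtype=float)


def write_topology(path: str | Path, top: Topology, coords: np.ndarray) -> None:
    """Write a PDB: scaffold/ions as HETATM, protein residues as ATOM."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (top.n_atoms, 3):
        raise ValueError(
            f"coords shape {coords.shape} does not match {top.n_atoms} atoms"
        )
    with open(path, "w") as fh:
        fh.write(
            "CRYST1"
            f"{top.box[0]:9.3f}{top.box[1]:9.3f}{top.box[2]:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
        )
        for i in range(top.n_atoms):
            rec = "ATOM  " if top.resnames[i] in _AMINO_ACIDS else "HETATM"
            name = top.names[i]
            name_f = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = coords[i]
            fh.write(
                f"{rec}{(i % 99999) + 1:5d} {name_f:<4s} {top.resnames[i]:<4s}"
                f"{top.chains[i]:1s}{top.resids[i]:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {top.elements[i]:>2s}\n"
            )
        fh.write("END\n")


def write_trajectory(path: str | Path, traj: Trajectory,
                     labels: np.ndarray | list[str] | None = None) -> None:
    """Write a multi-frame XYZ trajectory (text, 3 decimals)."""
    path = Path(path)
    if path.suffix.lower() == ".dcd":
        raise ValueError("DCD writing not supported; use .xyz")
    n_at = traj.n_atoms
    if labels is None:
        labels = ["X"] * n_at
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            bx = traj.box[f]
            fh.write(f"{n_at}\n")
            fh.write(
                f"frame={f} dt_ns={traj.dt:.6g} "
                f"box={bx[0]:.4f},{bx[1]:.4f},{bx[2]:.4f}\n"
            )
            for a in range(n_at):
                x, y, z = traj.coords[f, a]
                fh.write(f"{labels[a]:<4s} {x:12.3f} {y:12.3f} {z:12.3f}\n")


def _read_xyz(path: Path, dt: float, box: np.ndarray | None):
    frames, boxes = [], []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n_at = int(lines[i].strip())
        comment = lines[i + 1]
        frame_box = box
        for tok in comment.split():
            if tok.startswith("box="):
                frame_box = np.array([float(v) for v in tok[4:].split(",")])
        if frame_box is None:
            raise ValueError(f"{path}: no box in XYZ comment and none provided")
        rows = []
        for j in range(n_at):
            parts = lines[i + 2 + j].split()
            rows.append([float(parts[1]), float(parts[2]), float(parts[3])])
        frames.append(rows)
        boxes.append(frame_box)
        i += 2 + n_at
    return np.asarray(frames, dtype=float), np.asarray(boxes, dtype=float)


def read_trajectory(path: str | Path, topology: Topology, dt: float,
                    box: np.ndarray | None = None) -> Trajectory:
    """Read a multi-frame XYZ (or DCD, if MDAnalysis is available) trajectory.

    The per-frame atom count must equal the topology's atom count.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    path = Path(path)
    if path.suffix.lower() == ".dcd":
        import MDAnalysis as mda  # optional dependency

        u = mda.Universe.empty(topology.n_atoms, trajectory=True)
        u.load_new(str(path))
        coords = np.array([ts.positions.copy() for ts in u.trajectory])
        boxes = np.tile(topology.box, (len(coords), 1))
    else:
        coords, boxes = _read_xyz(path, dt, box)
    if coords.shape[1] != topology.n_atoms:
        raise ValueError(
            f"{path}: atom-count mismatch: expected {topology.n_atoms}, "
            f"found {coords.shape[1]}"
        )
    return Trajectory(coords=coords, dt=dt, box=boxes)


def write_grid_file(grid, path: str | Path) -> None:
    """Serialize a density/GFE grid to OpenDX via gridData."""
    values = np.asarray(grid.values, dtype=float)
    if values.size == 0:
        raise ValueError("refusing to write an empty grid")
    g = Grid(values, origin=np.asarray(grid.origin, dtype=float),
             delta=np.asarray(grid.spacing, dtype=float))
    g.export(str(path), file_format="dx", type="double")


def read_grid_file(path: str | Path):
    """Read an OpenDX grid -> (values, origin, spacing)."""
    g = Grid(str(path))
    delta = np.asarray(g.delta, dtype=float)
    if delta.ndim == 2:
        delta = np.diag(delta)
    return np.asarray(g.grid, dtype=float), np.asarray(g.origin, dtype=float), delta


def write_json(path: str | Path, obj) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
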