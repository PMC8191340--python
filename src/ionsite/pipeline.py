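"""End-to-end orchestration: simulate -> occupancy/visits -> contacts ->
density -> GFE -> sites -> report, from a single YAML-able config.

All randomness is funnelled through one seed; two runs with the same config
and seed produce byte-identical text artifacts.
"""

from __future__ import annotations

import difflib
import logging
import time as _time
from pathlib import Path

import numpy as np

from . import __version__
from .contacts import contact_frequencies
from .density import (
    accumulate_density,
    detect_sites,
    gfe_from_density,
    normalize_density,
)
from .io import (
    Trajectory,
    write_grid_file,
    write_json,
    write_topology,
    write_trajectory,
)
from .regions import (
    count_entries,
    extract_visits,
    make_region,
    occupancy_counts,
    occupancy_fractions,
    residence_stats,
)
from .synthetic import (
    BrownianSpec,
    MarkovModel,
    MarkovState,
    ScaffoldSpec,
    build_scaffold,
    simulate_brownian_ions,
    simulate_markov_ions,
)

__all__ = ["ConfigError", "StageError", "validate_config", "run_pipeline",
           "DEFAULTS"]

log = logging.getLogger("ionsite")

#: analysis parameter defaults; where a published value exists it is used
#: (contact cutoff 5 A, grid spacing 1 A, isovalue 0.1, 300 K, 3 kcal/mol cap).
DEFAULTS = {
    "cutoff": 5.0,
    "spacing": 1.0,
    "isovalue": 0.1,
    "temperature": 300.0,
    "cap": 3.0,
    "gap_tolerance": 2,
    "min_duration": 1,
    "rate_window": [0.0, 12.5],
    "min_site_voxels": 1,
    "bulk_occupancy": None,
    "contact_threshold": 0.5,
}

_TOP_KEYS = {"synthetic", "regions", "analysis", "seed", "out"}
_POSITIVE_KEYS = {"cutoff", "spacing", "temperature", "cap"}


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def validate_config(config: dict) -> dict:
    """Fill defaults, check types/ranges, report unknown keys.

    Returns the normalized config; raises :class:`ConfigError` listing every
    problem found (nothing is silently coerced). Unknown keys produce a
    did-you-mean warning in the log but are not fatal at the top level.
    """
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    errors: list[str] = []
    norm = {
        "synthetic": config.get("synthetic"),
        "regions": config.get("regions", {}),
        "analysis": dict(DEFAULTS),
        "seed": config.get("seed", 0),
        "out": config.get("out"),
    }
    known = _TOP_KEYS
    for key in config:
        if key not in known:
            hint = difflib.get_close_matches(key, known | set(DEFAULTS), n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            log.warning("unknown config key %r%s", key, suffix)
    analysis = config.get("analysis", {})
    if not isinstance(analysis, dict):
        errors.append("analysis section must be a mapping")
        analysis = {}
    for key, value in analysis.items():
        if key not in DEFAULTS:
            hint = difflib.get_close_matches(key, DEFAULTS, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            log.warning("unknown analysis key %r%s", key, suffix)
            continue
        default = DEFAULTS[key]
        if key == "rate_window":
            try:
                value = [float(value[0]), float(value[1])]
            except (TypeError, ValueError, IndexError):
                errors.append("analysis.rate_window must be [start_s, end_s]")
                continue
        elif isinstance(default, int) and not isinstance(default, bool):
            if not isinstance(value, int) or isinstance(value, bool):
                errors.append(f"analysis.{key} must be an integer, got {value!r}")
                continue
        elif key != "bulk_occupancy":
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                errors.append(f"analysis.{key} must be a number, got {value!r}")
                continue
            value = float(value)
        if key in _POSITIVE_KEYS and value <= 0:
            errors.append(f"analysis.{key} must be positive, got {value}")
            continue
        norm["analysis"][key] = value
    if not isinstance(norm["regions"], dict):
        errors.append("regions section must be a mapping of name -> definition")
    else:
        for name, rdef in norm["regions"].items():
            if not isinstance(rdef, dict) or "residues" not in rdef:
                errors.append(f"regions.{name} must define 'residues'")
                continue
            radius = rdef.get("radius", 6.0)
            if not isinstance(radius, (int, float)) or radius <= 0:
                errors.append(f"regions.{name}.radius must be positive")
    if not isinstance(norm["seed"], int) or isinstance(norm["seed"], bool):
        errors.append(f"seed must be an integer, got {norm['seed']!r}")
    if errors:
        raise ConfigError("; ".join(errors))
    return norm


def _build_markov(syn: dict, seed: int) -> MarkovModel:
    mk = syn["markov"]
    states = []
    for sdef in mk["states"]:
        states.append(
            MarkovState(
                name=sdef["name"],
                kind=sdef.get("kind", "site"),
                center=sdef.get("center"),
                jitter_sd=sdef.get("jitter_sd", 0.5),
            )
        )
    return MarkovModel(
        states=states,
        transition=np.asarray(mk["transition"], dtype=float),
        dt=float(mk.get("dt_ns", 0.1)),
        ions=dict(mk["ions"]),
        box=np.asarray(syn["scaffold"]["box"], dtype=float),
        seed=seed,
        initial_state=int(mk.get("initial_state", 0)),
        bulk_exclusion=float(mk.get("bulk_exclusion", 12.0)),
        exclusive_sites=bool(mk.get("exclusive_sites", False)),
    )


def _build_scaffold_spec(syn: dict) -> ScaffoldSpec:
    sc = syn["scaffold"]
    anchors = [
        (a["resname"], int(a["resid"]), np.asarray(a["position"], dtype=float))
        for a in sc.get("anchors", [])
    ]
    return ScaffoldSpec(
        box=np.asarray(sc["box"], dtype=float),
        cavity_radius=float(sc.get("cavity_radius", 10.0)),
        cavity_depth=float(sc.get("cavity_depth", 20.0)),
        cavity_axis=np.asarray(sc.get("cavity_axis", [0, 0, 1]), dtype=float),
        anchor_residues=anchors,
        wall_atom_spacing=float(sc.get("wall_atom_spacing", 2.0)),
    )


def simulate_from_config(config: dict, seed: int | None = None):
    """Build the synthetic system described by config['synthetic'].

    Returns (topology, trajectory, ground_truth) for the merged
    scaffold+ion system.
    """
    syn = config.get("synthetic")
    if syn is None:
        raise ConfigError("config is missing the 'synthetic' section")
    seed = config.get("seed", 0) if seed is None else seed
    scaffold_spec = _build_scaffold_spec(syn)
    scaffold_top, scaffold_xyz = build_scaffold(scaffold_spec)
    if "markov" in syn:
        ion_top, ion_traj, truth = simulate_markov_ions(
            _build_markov(syn, seed), int(syn["markov"]["n_steps"])
        )
    elif "brownian" in syn:
        br = syn["brownian"]
        spec = BrownianSpec(
            wells=[(w["center"], w["depth"], w["width"])
                   for w in br.get("wells", [])],
            diffusion_coefficient=float(br["diffusion_coefficient"]),
            kT=float(br.get("kT", 0.59616)),
            dt=float(br.get("dt_ns", 1e-3)),
            n_steps=int(br["n_steps"]),
            box=scaffold_spec.box,
            n_ions=int(br.get("n_ions", 1)),
            seed=seed,
        )
        ion_traj = simulate_brownian_ions(spec)
        from .synthetic import _ion_topology

        ion_top = _ion_topology(
            {br.get("species", "Cl-"): spec.n_ions}, scaffold_spec.box
        )
        truth = {"kind": "brownian", "seed": seed}
    else:
        raise ConfigError("synthetic section needs 'markov' or 'brownian'")
    top = scaffold_top.concat(ion_top)
    coords = np.concatenate(
        [
            np.tile(scaffold_xyz, (ion_traj.n_frames, 1, 1)),
            ion_traj.coords,
        ],
        axis=1,
    )
    traj = Trajectory(coords=coords, dt=ion_traj.dt, box=ion_traj.box)
    return top, traj, truth


def run_pipeline(config: dict, seed: int | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Run every stage and write the artifact bundle; returns the summary."""
    cfg = validate_config(config)
    if seed is not None:
        cfg["seed"] = seed
    out = Path(out_dir if out_dir is not None else (cfg["out"] or "ionsite_out"))
    out.mkdir(parents=True, exist_ok=True)
    ana = cfg["analysis"]
    summary: dict = {"version": __version__, "seed": cfg["seed"],
                     "config": _jsonable(cfg)}

    def stage(name, fn):
        t0 = _time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        log.info("stage %s done in %.2fs", name, _time.perf_counter() - t0)
        return result

    top, traj, truth = stage(
        "simulate", lambda: simulate_from_config({**config, **cfg}, cfg["seed"])
    )
    stage("write_inputs", lambda: (
        write_topology(out / "system.pdb", top, traj.coords[0]),
        write_trajectory(out / "trajectory.xyz", traj,
                         labels=[e or "X" for e in top.elements]),
        write_json(out / "ground_truth.json", truth),
    ))

    regions = stage("regions", lambda: [
        make_region(
            top, rdef["residues"], radius=float(rdef.get("radius", 6.0)),
            slab_axis=rdef.get("slab_axis"),
            slab_bounds=tuple(rdef["slab_bounds"]) if rdef.get("slab_bounds") else None,
            name=name,
        )
        for name, rdef in cfg["regions"].items()
    ])
    if not regions:
        raise StageError("stage 'regions' failed: config defines no regions")

    species = sorted(set(top.species) - {""})

    def _occupancy():
        table = occupancy_counts(traj, top, regions, species)
        table.to_frame().to_csv(out / "occupancy_per_frame.csv", index=False)
        fr = occupancy_fractions(table)
        fr.to_csv(out / "occupancy_fractions.csv", index=False)
        return table, fr

    occ_table, occ_frac = stage("occupancy", _occupancy)
    summary["occupancy_fractions"] = occ_frac.to_dict(orient="records")

    def _visits():
        import pandas as pd

        all_visits = pd.concat(
            [
                extract_visits(traj, top, region, species,
                               gap_tolerance=int(ana["gap_tolerance"]),
                               min_duration=int(ana["min_duration"]))
                for region in regions
            ],
            ignore_index=True,
        )
        all_visits.to_csv(out / "visits.csv", index=False)
        res = residence_stats(all_visits)
        res.to_csv(out / "residence_stats.csv", index=False)
        ent = count_entries(all_visits, traj.n_frames)
        ent.to_csv(out / "entries.csv", index=False)
        return res, ent

    res, ent = stage("visits", _visits)
    summary["residence_stats"] = res.to_dict(orient="records")
    summary["entries"] = ent.to_dict(orient="records")

    def _contacts():
        table = contact_frequencies(traj, top, species, cutoff=ana["cutoff"])
        table.to_csv(out / "contact_frequencies.csv", index=False)
        return table

    stage("contacts", _contacts)

    def _density():
        grid = accumulate_density(traj, top, species, spacing=ana["spacing"])
        cpf = normalize_density(grid, "counts_per_frame")
        write_grid_file(cpf, out / "density.dx")
        bulk = ana["bulk_occupancy"]
        if bulk is None:
            nz = cpf.values[cpf.values > 0]
            bulk = float(nz.mean()) if nz.size else 1.0
        gfe = gfe_from_density(cpf, bulk, temperature=ana["temperature"],
                               cap=ana["cap"])
        write_grid_file(gfe, out / "gfe.dx")
        sites = detect_sites(cpf, isovalue=ana["isovalue"],
                             min_voxels=int(ana["min_site_voxels"]))
        return cpf, gfe, sites

    _cpf, _gfe, sites = stage("density", _density)
    summary["sites"] = [
        {
            "site_id": s.site_id,
            "centroid": s.centroid.tolist(),
            "peak_value": s.peak_value,
            "integrated_density": s.integrated_density,
            "n_voxels": int(len(s.voxels)),
        }
        for s in sites
    ]
    summary["n_sites"] = len(sites)
    stage("report", lambda: write_json(out / "summary.json", summary))
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
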