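"""Declarative analysis pipeline: one config in, CSV/JSON artefacts out.

A pipeline config (YAML/JSON-compatible dict) names an input — either
structure/trajectory files or a synthetic-system spec — plus any number of
analysis blocks.  :func:`validate_config` resolves defaults and rejects
unknown keys (no silent ignore); :func:`run_pipeline` executes the stages
in dependency order, writes machine-readable outputs under the output
directory and returns a run report.  Everything stochastic (synthetic
generation, bootstrap errors) derives from the single top-level seed, so a
fixed (config, seed, inputs) triple reproduces every artefact byte for
byte.
"""

from __future__ import annotations

import copy
import json
import platform
import time as _time
import zlib
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from . import binding as _binding
from . import configsets
from . import conformation as _conf
from . import permeability as _perm
from . import saltbridge as _sb
from . import synthetic as _syn
from . import water as _water
from .md_io import Trajectory, read_structure, read_trajectory, select

__all__ = ["ConfigError", "validate_config", "run_pipeline", "load_config"]

_FLOAT_FMT = "%.8g"  # fixed CSV float format keeps outputs byte-stable


class ConfigError(ValueError):
    """Invalid pipeline configuration (unknown keys, missing values...)."""


# Allowed keys and defaults per analysis block.  None marks a required or
# context-resolved value.
_BLOCK_SCHEMAS: dict[str, dict[str, Any]] = {
    "rmsd": {"selection": "name CA", "mass_weighted": True, "reference": "first"},
    "rmsf": {"selection": "name CA", "mass_weighted": True, "reference": "mean"},
    "pca": {"selection": "name CA", "mass_weighted": True},
    "saltbridges": {"pairs": None, "pair_set": None, "threshold": _sb.DEFAULT_THRESHOLD},
    "density": {"water_selection": "water", "axis_selection": "name CA",
                "lateral_radius": 2.0, "bin_width": 0.1, "z_range": None},
    "crossings": {"water_selection": "water", "axis_selection": "name CA",
                  "z_lower": None, "z_upper": None, "lateral_radius": 2.0},
    "permeability": {"region": None, "bottom": None, "top": None,
                     "radius": _perm.DEFAULT_RADIUS, "water_selection": "water",
                     "n_subtraj": _perm.DEFAULT_N_SUBTRAJ,
                     "subtraj_len": _perm.DEFAULT_SUBTRAJ_LEN,
                     "vw": _perm.DEFAULT_WATER_VOLUME,
                     "viscosity_scale": _perm.DEFAULT_VISCOSITY_SCALE,
                     "estimator": "mean_squared"},
    "contacts": {"group_a": None, "group_b": None,
                 "cutoff": _binding.DEFAULT_CONTACT_CUTOFF,
                 "count_unique_atoms": False},
    "phosphates": {"replicas": None, "p_atoms": None, "arginines": None,
                   "analysis_window": [0.5, 1.0],
                   "bound_cutoff": _binding.DEFAULT_BOUND_CUTOFF},
}

_INPUT_KEYS = {"structure", "trajectory", "synthetic", "dt", "mass_table", "default_mass"}
_TOP_KEYS = {"seed", "output_dir", "input", "analyses"}

_SYN_KEYS = {"kind", "n_frames", "dt", "box", "pore", "waters", "saltbridge", "binding"}


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


def validate_config(config: dict) -> dict:
    """Resolve a pipeline config: fill defaults, reject unknown keys.

    Errors are aggregated and reported together.  The resolved config
    re-validates to itself (idempotent), and is embedded verbatim in the
    run report so the run can be reproduced.
    """
    errors: list[str] = []
    resolved = copy.deepcopy(config)
    unknown = set(resolved) - _TOP_KEYS
    if unknown:
        errors.append(f"unknown top-level keys: {sorted(unknown)}")
    resolved.setdefault("seed", 0)
    resolved.setdefault("output_dir", "poreflow_out")

    inp = resolved.get("input")
    if not isinstance(inp, dict):
        errors.append("config needs an 'input' mapping (files or synthetic spec)")
        inp = {}
        resolved["input"] = inp
    unknown = set(inp) - _INPUT_KEYS
    if unknown:
        errors.append(f"unknown input keys: {sorted(unknown)}")
    has_files = "structure" in inp
    has_syn = "synthetic" in inp
    if has_files == has_syn:
        errors.append("input must name either a structure (+ trajectory) or a synthetic spec")
    if has_files:
        for key in ("structure", "trajectory"):
            p = inp.get(key)
            if p is not None and not Path(p).exists():
                errors.append(f"input {key} file not found: {p}")
    if has_syn:
        syn = inp["synthetic"]
        if not isinstance(syn, dict):
            errors.append("input.synthetic must be a mapping of SyntheticSpec fields")
        else:
            unknown = set(syn) - _SYN_KEYS
            if unknown:
                errors.append(f"unknown synthetic spec keys: {sorted(unknown)}")

    analyses = resolved.get("analyses")
    if not isinstance(analyses, dict) or not analyses:
        errors.append("config needs a non-empty 'analyses' mapping")
        analyses = {}
        resolved["analyses"] = analyses
    unknown = set(analyses) - set(_BLOCK_SCHEMAS)
    if unknown:
        errors.append(f"unknown analysis blocks: {sorted(unknown)}")
    for name, block in analyses.items():
        schema = _BLOCK_SCHEMAS.get(name)
        if schema is None:
            continue
        if block is None:
            block = {}
            analyses[name] = block
        bad = set(block) - set(schema)
        if bad:
            errors.append(f"analysis {name!r}: unknown keys {sorted(bad)}")
        for key, default in schema.items():
            if key not in block and default is not None:
                block[key] = copy.deepcopy(default)
    # cross-field requirements
    if "saltbridges" in analyses and not errors:
        block = analyses["saltbridges"]
        if block.get("pair_set"):
            block["pairs"] = [list(p) for p in configsets.saltbridge_pairs(block["pair_set"])]
        if not block.get("pairs"):
            errors.append("saltbridges: need 'pairs' or a named 'pair_set'")
    if "permeability" in analyses and not errors:
        block = analyses["permeability"]
        if block.get("region"):
            cfg = configsets.pore_region_config(block["region"])
            block["bottom"], block["top"] = cfg["bottom"], cfg["top"]
            block.setdefault("radius", cfg["radius"])
        if not block.get("bottom") or not block.get("top"):
            errors.append("permeability: need ring residue lists ('bottom'/'top') or a named 'region'")
    if "crossings" in analyses and not errors:
        block = analyses["crossings"]
        if block.get("z_lower") is None or block.get("z_upper") is None:
            if not (has_syn and inp["synthetic"].get("kind", "pore") == "pore"):
                errors.append("crossings: z_lower/z_upper required for file inputs")
    if "contacts" in analyses:
        block = analyses["contacts"]
        if not block.get("group_a") or not block.get("group_b"):
            errors.append("contacts: need 'group_a' and 'group_b' selections")
    if errors:
        raise ConfigError("; ".join(errors))
    return resolved


def _load_input(resolved: dict) -> tuple[Trajectory, _syn.GroundTruth | None, dict]:
    inp = resolved["input"]
    if "synthetic" in inp:
        syn_kwargs = copy.deepcopy(inp["synthetic"])
        for key, cls in (("pore", _syn.PoreParams), ("waters", _syn.WaterParams),
                         ("saltbridge", _syn.SaltBridgeParams), ("binding", _syn.BindingParams)):
            if key in syn_kwargs and isinstance(syn_kwargs[key], dict):
                syn_kwargs[key] = cls(**syn_kwargs[key])
        if "box" in syn_kwargs:
            syn_kwargs["box"] = tuple(syn_kwargs["box"])
        spec = _syn.SyntheticSpec(seed=resolved["seed"], **syn_kwargs)
        traj, truth = _syn.generate(spec)
        return traj, truth, {"synthetic_kind": spec.kind, "n_frames": traj.n_frames}
    topo, frame = read_structure(inp["structure"],
                                 mass_table=inp.get("mass_table"),
                                 default_mass=inp.get("default_mass"))
    if inp.get("trajectory"):
        traj = read_trajectory(inp["trajectory"], topo, dt=inp.get("dt", 1.0))
    else:
        traj = Trajectory(topology=topo, frames=[frame])
    return traj, None, {"structure": str(inp["structure"]), "n_frames": traj.n_frames}


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    child = np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
    return int(child.generate_state(1)[0] % (2**31))


def run_pipeline(resolved: dict) -> dict:
    """Execute every configured stage; write artefacts; return the run report.

    A failing stage is recorded in the report and later independent stages
    still run; ``report['ok']`` is False if anything failed.
    """
    out_dir = Path(resolved["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(resolved["seed"])
    t0 = _time.time()
    traj, truth, input_info = _load_input(resolved)
    report: dict[str, Any] = {
        "config": resolved,
        "input": input_info,
        "stages": {},
        "versions": {"poreflow": _pkg_version, "numpy": np.__version__,
                     "python": platform.python_version()},
    }
    topo = traj.topology

    def run_stage(name: str, fn) -> None:
        entry: dict[str, Any] = {"status": "ok", "outputs": [], "summary": {}}
        try:
            fn(entry)
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            entry["status"] = "failed"
            entry["error"] = f"{type(exc).__name__}: {exc}"
        report["stages"][name] = entry

    analyses = resolved["analyses"]

    if "rmsd" in analyses:
        def _rmsd(entry):
            b = analyses["rmsd"]
            sel = select(topo, b["selection"])
            series = _conf.rmsd_series(traj, sel, traj.frames[0],
                                       mass_weighted=b["mass_weighted"])
            path = out_dir / "rmsd.csv"
            _write_csv(pd.DataFrame({"time_ps": series.times, "rmsd_nm": series.values}), path)
            entry["outputs"].append(str(path))
            entry["summary"] = {"mean_rmsd_nm": float(series.values.mean()),
                                "max_rmsd_nm": float(series.values.max())}
        run_stage("rmsd", _rmsd)

    if "rmsf" in analyses:
        def _rmsf(entry):
            b = analyses["rmsf"]
            sel = select(topo, b["selection"])
            prof = _conf.rmsf_profile(traj, sel, mass_weighted=b["mass_weighted"],
                                      reference=b["reference"])
            path = out_dir / "rmsf.csv"
            _write_csv(pd.DataFrame({"resid": prof.residue_ids, "rmsf_nm": prof.values}), path)
            entry["outputs"].append(str(path))
            entry["summary"] = {"mean_rmsf_nm": float(prof.values.mean())}
        run_stage("rmsf", _rmsf)

    if "pca" in analyses:
        def _pca(entry):
            b = analyses["pca"]
            sel = select(topo, b["selection"])
            res = _conf.common_pca([traj], sel, labels=["traj0"],
                                   mass_weighted=b["mass_weighted"])
            proj = res.projections["traj0"]
            p1 = out_dir / "pca_projections.csv"
            _write_csv(pd.DataFrame({"traj_label": "traj0",
                                     "frame": np.arange(len(proj)),
                                     "pc1": proj[:, 0], "pc2": proj[:, 1]}), p1)
            p2 = out_dir / "pca_eigenvalues.csv"
            _write_csv(pd.DataFrame({"mode": np.arange(len(res.eigenvalues)),
                                     "eigenvalue_nm2": res.eigenvalues}), p2)
            entry["outputs"] += [str(p1), str(p2)]
            entry["summary"] = {"pc12_span_area_nm2": _conf.pc_span_area(proj),
                                "total_variance_nm2": float(res.eigenvalues.sum())}
        run_stage("pca", _pca)

    if "saltbridges" in analyses:
        def _saltbridges(entry):
            b = analyses["saltbridges"]
            results = _sb.saltbridge_network(traj, [tuple(p) for p in b["pairs"]],
                                             threshold=b["threshold"])
            rows = [{"pair": r.pair_label, "time_ps": t, "distance_nm": d}
                    for r in results for t, d in zip(r.times, r.distances)]
            p1 = out_dir / "saltbridges.csv"
            _write_csv(pd.DataFrame(rows), p1)
            p2 = out_dir / "occupancy.csv"
            _write_csv(pd.DataFrame([{"pair": r.pair_label, "occupancy": r.occupancy,
                                      "threshold_nm": r.threshold} for r in results]), p2)
            entry["outputs"] += [str(p1), str(p2)]
            entry["summary"] = {r.pair_label: r.occupancy for r in results}
        run_stage("saltbridges", _saltbridges)

    if "density" in analyses:
        def _density(entry):
            b = analyses["density"]
            waters = select(topo, b["water_selection"])
            axis = select(topo, b["axis_selection"])
            z_range = tuple(b["z_range"]) if b.get("z_range") else None
            prof = _water.z_density_profile(traj, waters, axis,
                                            lateral_radius=b["lateral_radius"],
                                            bin_width=b["bin_width"], z_range=z_range)
            path = out_dir / "density.csv"
            _write_csv(pd.DataFrame({"z_nm": prof.z_bin_centers,
                                     "density_per_nm3": prof.density}), path)
            entry["outputs"].append(str(path))
            entry["summary"] = {"mean_waters_in_region": prof.region_integral,
                                "min_density_per_nm3": float(prof.density.min())}
        run_stage("density", _density)

    if "crossings" in analyses:
        def _crossings(entry):
            b = analyses["crossings"]
            waters = select(topo, b["water_selection"])
            axis = select(topo, b["axis_selection"])
            z_lower, z_upper = b.get("z_lower"), b.get("z_upper")
            if z_lower is None or z_upper is None:
                # synthetic pore: planes default to the ring z-levels
                half = resolved["input"]["synthetic"].get("pore", {}).get("half_length", 1.0)
                z_lower, z_upper = -half, half
            rep = _water.count_crossings(traj, waters, z_lower, z_upper,
                                         b["lateral_radius"], axis)
            path = out_dir / "crossings.csv"
            _write_csv(pd.DataFrame(
                [{"molecule": e.molecule, "time_ps": e.time, "direction": e.direction}
                 for e in rep.events],
                columns=["molecule", "time_ps", "direction"]), path)
            entry["outputs"].append(str(path))
            entry["summary"] = {"n_up": rep.n_up, "n_down": rep.n_down}
        run_stage("crossings", _crossings)

    if "permeability" in analyses:
        def _permeability(entry):
            b = analyses["permeability"]
            region = _perm.define_pore_region(topo, list(b["bottom"]), list(b["top"]),
                                              radius=b["radius"])
            waters = select(topo, b["water_selection"])
            series, fit, res = _perm.permeability_from_trajectory(
                traj, region, waters,
                n_subtraj=b["n_subtraj"], subtraj_len=b["subtraj_len"],
                vw=b["vw"], viscosity_scale=b["viscosity_scale"],
                estimator=b["estimator"], seed=_stage_seed(seed, "permeability"),
            )
            p1 = out_dir / "n_of_t.csv"
            _write_csv(pd.DataFrame({"time_ps": series.times, "n": series.n}), p1)
            p2 = out_dir / "msd.csv"
            _write_csv(pd.DataFrame({"tau_ps": fit.tau, "msd": fit.msd}), p2)
            p3 = out_dir / "permeability.json"
            payload = {"Dn_per_ps": res.Dn, "Dn_se_per_ps": res.Dn_se,
                       "vw_cm3": res.vw, "viscosity_scale": res.viscosity_scale,
                       "Pf_cm3_per_s": res.Pf, "Pf_se_cm3_per_s": res.Pf_se,
                       "n_subtraj": fit.n_subtraj, "subtraj_len_ps": fit.subtraj_len,
                       "estimator": b["estimator"]}
            if truth is not None and truth.expected_Dn is not None:
                payload["ground_truth_Dn_per_ps"] = truth.expected_Dn
            p3.write_text(json.dumps(payload, indent=2, sort_keys=True))
            entry["outputs"] += [str(p1), str(p2), str(p3)]
            entry["summary"] = {"Dn_per_ps": res.Dn, "Pf_cm3_per_s": res.Pf}
        run_stage("permeability", _permeability)

    if "contacts" in analyses:
        def _contacts(entry):
            b = analyses["contacts"]
            ga = select(topo, b["group_a"])
            gb = select(topo, b["group_b"])
            series = _binding.contact_count_series(traj, ga, gb, cutoff=b["cutoff"],
                                                   count_unique_atoms=b["count_unique_atoms"])
            path = out_dir / "contacts.csv"
            _write_csv(pd.DataFrame({"time_ps": series.times, "count": series.counts,
                                     "cutoff_nm": series.cutoff,
                                     "group_a": series.group_a,
                                     "group_b": series.group_b}), path)
            entry["outputs"].append(str(path))
            entry["summary"] = {"mean_contacts": float(series.counts.mean())}
        run_stage("contacts", _contacts)

    if "phosphates" in analyses:
        def _phosphates(entry):
            b = analyses["phosphates"]
            reps = [read_trajectory(p, topo, dt=resolved["input"].get("dt", 1.0))
                    for p in b["replicas"]]
            ens = _binding.ReplicaEnsemble(replicas=reps,
                                           analysis_window=tuple(b["analysis_window"]))
            p_atoms = {label: select(topo, expr) for label, expr in b["p_atoms"].items()}
            summary = _binding.phosphate_arginine_summary(
                ens, p_atoms, list(b["arginines"]), bound_cutoff=b["bound_cutoff"])
            path = out_dir / "phosphate_summary.csv"
            _write_csv(summary.table, path)
            entry["outputs"].append(str(path))
            entry["summary"] = {"n_bound_pairs": int(summary.table["bound"].sum())}
        run_stage("phosphates", _phosphates)

    report["ok"] = all(s["status"] == "ok" for s in report["stages"].values())
    report["wall_seconds"] = round(_time.time() - t0, 3)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
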