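"""Configuration-driven analysis workflows.

Two end-to-end pipelines tie the library stages together:

* :func:`run_stability` -- equilibration stability analysis: global and
  per-residue RMSD, dual-reference core-aligned alpha7 RMSD, zipper
  junction distances, swing-out angle, four-category state calls and the
  replicate census.
* :func:`run_lifetimes` -- forced-unbinding analysis: lifetime extraction
  per separation trace and repeat-run summaries grouped by system and
  force (never pooled across forces).

Both take a plain mapping (typically loaded from YAML), validate it as a
whole -- every problem is reported at once, not one per run -- and write
deterministic CSV outputs: same config, same inputs, byte-identical
files.  Units are fixed (A, ns, degrees, pN) and stated in the column
headers.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .lifetime import extract_lifetime, results_to_frame, summarize_lifetimes
from .observables import (
    SeparationTrace,
    junction_distances,
    separation_trace,
    swing_angle,
)
from .presets import molecule_preset
from .state_classify import (
    CATEGORY_LABELS,
    ClassifierParams,
    calls_to_frame,
    classify_replicates,
)
from .structure_io import BACKBONE_ATOMS, SelectionSpec, read_pdb, read_trajectory
from .superpose import global_rmsd, per_residue_rmsd, segment_rmsd_vs_references

__all__ = ["ConfigError", "load_config", "run_stability", "run_lifetimes"]

logger = logging.getLogger("idomain")

_CSV_FLOAT = "%.6f"


class ConfigError(ValueError):
    """Invalid workflow configuration; the message lists every problem."""


def load_config(path) -> dict:
    with open(path) as handle:
        config = yaml.safe_load(handle)
    if not isinstance(config, Mapping):
        raise ConfigError(f"{path}: config must be a mapping")
    return dict(config)


def _require(config: Mapping, key: str, errors: list[str]):
    if key not in config or config[key] in (None, [], {}):
        errors.append(f"missing required field: {key}")
        return None
    return config[key]


def _check_file(path, field_name: str, errors: list[str], base: Path) -> Path:
    resolved = (base / path).resolve() if not Path(path).is_absolute() else Path(path)
    if not resolved.exists():
        errors.append(f"{field_name}: file not found: {path}")
    return resolved


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format=_CSV_FLOAT, lineterminator="\n")


def _resolved_residue_maps(config: Mapping) -> dict:
    preset = molecule_preset(config.get("molecule", "LFA-1"))
    preset.update(config.get("residues", {}))
    return preset


def run_stability(config: Mapping, base_dir=".") -> dict:
    """Equilibration stability workflow; returns a dict of output paths."""
    base = Path(base_dir)
    errors: list[str] = []
    references_cfg = _require(config, "references", errors) or {}
    trajectories_cfg = _require(config, "trajectories", errors) or []
    output_dir = _require(config, "output_dir", errors)
    molecule = config.get("molecule", "LFA-1")
    try:
        residue_maps = _resolved_residue_maps(config)
    except KeyError as err:
        errors.append(str(err))
        residue_maps = None
    for name in ("LA", "HA"):
        if name not in references_cfg:
            errors.append(f"references: missing required reference '{name}'")
    reference_paths = {
        name: _check_file(path, f"references.{name}", errors, base)
        for name, path in references_cfg.items()
    }
    run_entries = []
    for i, entry in enumerate(trajectories_cfg):
        if not isinstance(entry, Mapping) or "path" not in entry:
            errors.append(f"trajectories[{i}]: needs at least a 'path'")
            continue
        run_entries.append(
            {
                "name": entry.get("name", f"run{i + 1}"),
                "path": _check_file(entry["path"], f"trajectories[{i}].path", errors, base),
                "topology": entry.get("topology"),
                "time_per_frame": float(entry.get("time_per_frame", 0.1)),
            }
        )
    try:
        params = ClassifierParams(**config.get("classifier", {}))
    except (TypeError, ValueError) as err:
        errors.append(f"classifier: {err}")
        params = None
    if errors:
        raise ConfigError("invalid stability config:\n  " + "\n  ".join(errors))

    out = Path(base / output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chain = residue_maps["chain"]
    core = SelectionSpec(
        chain=chain,
        resid_ranges=tuple(tuple(r) for r in
                           config.get("core", {}).get("resid_ranges",
                                                      residue_maps["core_ranges"])),
        atom_names=BACKBONE_ATOMS,
    )
    a7_lo, a7_hi = residue_maps["alpha7"]
    segment = SelectionSpec(
        chain=chain, resid_ranges=((a7_lo, a7_hi),), atom_names=BACKBONE_ATOMS
    )
    backbone_all = SelectionSpec(chain=chain, atom_names=BACKBONE_ATOMS)

    references = {}
    for name, path in reference_paths.items():
        structure = read_pdb(path, model=1)
        structure.metadata["name"] = name
        references[name] = structure
    logger.info("stability: molecule=%s, %d run(s), references=%s",
                molecule, len(run_entries), sorted(references))

    outputs: dict[str, Path] = {}
    run_inputs = []
    run_names = []
    per_residue_frames = []
    junction_frames = []
    for entry in run_entries:
        name = entry["name"]
        run_names.append(name)
        topo_path = entry["topology"]
        if topo_path is not None:
            topo_path = base / topo_path
        trajectory = read_trajectory(topo_path, entry["path"], entry["time_per_frame"])
        logger.info("run %s: %d frames x %d atoms", name,
                    trajectory.n_frames, trajectory.topology.n_atoms)

        ref_pair = {"LA": references["LA"], "HA": references["HA"]}
        series = segment_rmsd_vs_references(trajectory, ref_pair, core, segment)
        series_by_name = {s.reference_name: s for s in series}
        extra = None
        if "IA" in references:
            [extra] = segment_rmsd_vs_references(
                trajectory, {"IA": references["IA"]}, core, segment
            )
        swing = swing_angle(trajectory, (a7_hi, a7_lo), references["LA"], core, chain)
        glob = global_rmsd(trajectory, references["LA"], backbone_all, "LA")

        alpha7_frame = pd.DataFrame({"time_ns": series[0].times})
        for ref_name, s in series_by_name.items():
            alpha7_frame[f"alpha7_rmsd_A_{ref_name}"] = s.values
        if extra is not None:
            alpha7_frame["alpha7_rmsd_A_IA"] = extra.values
        alpha7_frame["swing_angle_deg"] = swing.angles_deg
        alpha7_frame["global_rmsd_A_LA"] = glob.values
        path = out / f"{name}_rmsd.csv"
        _write_csv(alpha7_frame, path)
        outputs[f"{name}_rmsd"] = path

        per_res = per_residue_rmsd(trajectory, references["LA"], backbone_all)
        frame = per_res.to_frame()
        frame.insert(0, "run", name)
        per_residue_frames.append(frame)

        junction = junction_distances(trajectory, residue_maps["zipper_pairs"], chain)
        frame = junction.to_frame()
        frame.insert(0, "run", name)
        junction_frames.append(frame)

        run = [series_by_name["LA"], series_by_name["HA"], swing]
        if extra is not None:
            run.append(extra)
        run_inputs.append(tuple(run))

    calls, census = classify_replicates(run_inputs, params)
    calls_frame = calls_to_frame(calls, run_names)
    census_frame = pd.DataFrame(
        {
            "category": list(CATEGORY_LABELS),
            "label": [CATEGORY_LABELS[c] for c in CATEGORY_LABELS],
            "count": [census[c] for c in CATEGORY_LABELS],
        }
    )
    for stem, frame in (
        ("per_residue_rmsd", pd.concat(per_residue_frames, ignore_index=True)),
        ("junction_distances", pd.concat(junction_frames, ignore_index=True)),
        ("state_calls", calls_frame),
        ("census", census_frame),
    ):
        path = out / f"{stem}.csv"
        _write_csv(frame, path)
        outputs[stem] = path

    log_path = out / "run_log.txt"
    log_path.write_text(
        yaml.safe_dump(
            {
                "workflow": "stability",
                "molecule": molecule,
                "residue_maps": {k: list(v) if isinstance(v, tuple) else v
                                 for k, v in residue_maps.items()},
                "classifier_params": vars(params),
                "runs": [entry["name"] for entry in run_entries],
                "references": {k: str(v) for k, v in reference_paths.items()},
                "census": {CATEGORY_LABELS[c]: n for c, n in census.items()},
            },
            sort_keys=True,
        )
    )
    outputs["run_log"] = log_path
    return outputs


def run_lifetimes(config: Mapping, base_dir=".") -> dict:
    """Forced-unbinding lifetime workflow; returns a dict of output paths."""
    base = Path(base_dir)
    errors: list[str] = []
    traces_cfg = config.get("traces", [])
    trajectories_cfg = config.get("trajectories", [])
    if not traces_cfg and not trajectories_cfg:
        errors.append("need at least one entry under 'traces' or 'trajectories'")
    output_dir = _require(config, "output_dir", errors)
    threshold = float(config.get("threshold", 10.0))
    dwell = int(config.get("dwell", 10))
    try:
        residue_maps = _resolved_residue_maps(config) if trajectories_cfg else None
    except KeyError as err:
        errors.append(str(err))
        residue_maps = None

    entries = []
    for i, entry in enumerate(traces_cfg):
        if not isinstance(entry, Mapping) or "path" not in entry:
            errors.append(f"traces[{i}]: needs at least a 'path'")
            continue
        entries.append(
            (
                "csv",
                {
                    "name": entry.get("name", Path(entry["path"]).stem),
                    "path": _check_file(entry["path"], f"traces[{i}].path", errors, base),
                    "system": entry.get("system", "unknown"),
                    "force_pn": entry.get("force_pn"),
                },
            )
        )
    for i, entry in enumerate(trajectories_cfg):
        if not isinstance(entry, Mapping) or "path" not in entry:
            errors.append(f"trajectories[{i}]: needs at least a 'path'")
            continue
        entries.append(
            (
                "trajectory",
                {
                    "name": entry.get("name", Path(entry["path"]).stem),
                    "path": _check_file(entry["path"], f"trajectories[{i}].path",
                                        errors, base),
                    "topology": entry.get("topology"),
                    "time_per_frame": float(entry.get("time_per_frame", 0.01)),
                    "system": entry.get("system", "unknown"),
                    "force_pn": entry.get("force_pn"),
                },
            )
        )
    if errors:
        raise ConfigError("invalid lifetimes config:\n  " + "\n  ".join(errors))

    out = Path(base / output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = []
    names = []
    groups = []
    for kind, entry in entries:
        if kind == "csv":
            trace = SeparationTrace.from_csv(
                entry["path"], force_pn=entry["force_pn"], label=entry["name"]
            )
        else:
            topo = entry["topology"]
            trajectory = read_trajectory(
                base / topo if topo else None, entry["path"], entry["time_per_frame"]
            )
            trace = separation_trace(
                trajectory,
                residue_maps["ligand_residue"],
                force_pn=entry["force_pn"],
            )
        result = extract_lifetime(trace, threshold=threshold, dwell=dwell)
        results.append(result)
        names.append(entry["name"])
        groups.append((entry["system"], entry["force_pn"]))
        logger.info("trace %s: lifetime=%s censored=%s", entry["name"],
                    result.lifetime_ns, result.censored)

    lifetimes_frame = results_to_frame(results, names)
    lifetimes_frame.insert(1, "system", [g[0] for g in groups])
    lifetimes_frame["force_pn"] = [g[1] for g in groups]

    summary_rows = []
    for key in sorted(set(groups), key=lambda g: (str(g[0]), str(g[1]))):
        members = [r for r, g in zip(results, groups) if g == key]
        row = {"system": key[0], "force_pn": key[1]}
        try:
            summary = summarize_lifetimes(members)
            row.update(
                n=summary.n, mean_ns=summary.mean_ns, sd_ns=summary.sd_ns,
                n_censored=summary.n_censored,
            )
        except ValueError:
            # all runs in the group censored: no estimate, explicit zeros
            row.update(n=0, mean_ns=None, sd_ns=None, n_censored=len(members))
        summary_rows.append(row)
    summary_frame = pd.DataFrame(summary_rows)

    outputs: dict[str, Path] = {}
    for stem, frame in (("lifetimes", lifetimes_frame), ("lifetime_summary", summary_frame)):
        path = out / f"{stem}.csv"
        _write_csv(frame, path)
        outputs[stem] = path
    log_path = out / "run_log.txt"
    log_path.write_text(
        yaml.safe_dump(
            {
                "workflow": "lifetimes",
                "threshold_A": threshold,
                "dwell_frames": dwell,
                "traces": names,
            },
            sort_keys=True,
        )
    )
    outputs["run_log"] = log_path
    return outputs
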