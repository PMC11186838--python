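"""Config-driven orchestration: one call reproduces the full analysis.

A run is described by a YAML (or JSON) config with exactly one input source
— a multi-model PDB trajectory or a named/inline synthetic condition — plus
the classification criteria and optional clustering/DCCA/occupancy
selections.  Outputs are TSV tables (percentages printed to 1 decimal) with
full-precision JSON mirrors, representative-structure PDBs and a manifest
that suffices to reproduce the run.  Logging goes to stderr; results live
only in files.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .dyncorr import dcca_matrix
from .modeclass import (CriteriaConfig, Mode, TieBreak, frames_in_mode,
                        hbond_occupancy, labels_to_dataframe, classify_frames,
                        mode_statistics)
from .presets import get_condition
from .repcluster import DPCParams, representative_frames
from .structio import SelectionSpec, read_pdb_models, write_frame_pdb
from . import synthdata

logger = logging.getLogger("halomode")

_TOP_KEYS = {
    "seed", "output_dir", "log_level", "trajectory", "synthetic", "criteria",
    "active_site", "dcca", "dcca_groups", "occupancy_residues", "substrate",
    "dpc", "max_cluster_frames",
}
_CRITERIA_KEYS = {
    "mode1_anchor", "mode2_anchor", "phosphate_acceptors", "reactive_pair_OH",
    "reactive_pair_CCl", "hbond_cutoff", "d_OH_max", "d_CCl_max", "tie_break",
}
_SYNTH_KEYS = {"preset", "n_frames", "seed"}


@dataclass
class RunConfig:
    """Validated run description; see the config schema in the docs."""

    output_dir: Path
    seed: int = 0
    log_level: str = "INFO"
    trajectory_path: Path | None = None
    synthetic: synthdata.SyntheticSpec | None = None
    criteria: CriteriaConfig | None = None  # None => template defaults (synthetic runs)
    active_site: SelectionSpec | None = None
    dcca_selection: SelectionSpec | None = None
    dcca_groups: dict[str, SelectionSpec] = field(default_factory=dict)
    occupancy_residues: list[SelectionSpec] = field(default_factory=list)
    substrate: SelectionSpec | None = None
    dpc_params: DPCParams = field(default_factory=lambda: DPCParams(n_centers=1))
    max_cluster_frames: int = 300

    def __post_init__(self) -> None:
        if (self.trajectory_path is None) == (self.synthetic is None):
            raise ConfigError(
                "Exactly one of 'trajectory' and 'synthetic' must be configured")


def _reject_unknown(d: dict, allowed: set[str], where: str) -> None:
    for key in d:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"Unknown key {key!r} in {where}{suffix}")


def _selection(d: dict | None) -> SelectionSpec | None:
    return None if d is None else SelectionSpec.from_dict(d)


def _criteria_from_dict(d: dict) -> CriteriaConfig:
    _reject_unknown(d, _CRITERIA_KEYS, "criteria")
    for key in ("mode1_anchor", "mode2_anchor", "phosphate_acceptors",
                "reactive_pair_OH", "reactive_pair_CCl"):
        if key not in d:
            raise ConfigError(f"criteria is missing required key {key!r}")
    return CriteriaConfig(
        mode1_anchor=_selection(d["mode1_anchor"]),
        mode2_anchor=_selection(d["mode2_anchor"]),
        phosphate_acceptors=_selection(d["phosphate_acceptors"]),
        reactive_pair_OH=(_selection(d["reactive_pair_OH"][0]),
                          _selection(d["reactive_pair_OH"][1])),
        reactive_pair_CCl=(_selection(d["reactive_pair_CCl"][0]),
                           _selection(d["reactive_pair_CCl"][1])),
        hbond_cutoff=float(d.get("hbond_cutoff", 3.2)),
        d_OH_max=float(d.get("d_OH_max", 3.2)),
        d_CCl_max=float(d.get("d_CCl_max", 4.5)),
        tie_break=TieBreak(d.get("tie_break", "shorter_distance")),
    )


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a run config; unknown keys are rejected with a
    spelling suggestion, and the stated cutoffs are filled as defaults."""
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"Config root must be a mapping, got {type(raw).__name__}")
    _reject_unknown(raw, _TOP_KEYS, str(path))

    synthetic = None
    if "synthetic" in raw and raw["synthetic"] is not None:
        s = raw["synthetic"]
        _reject_unknown(s, _SYNTH_KEYS, "synthetic")
        if "preset" not in s:
            raise ConfigError("synthetic requires a 'preset' name")
        synthetic = get_condition(s["preset"], n_frames=s.get("n_frames"),
                                  seed=s.get("seed", raw.get("seed")))

    criteria = None
    if "criteria" in raw and raw["criteria"] is not None:
        criteria = _criteria_from_dict(raw["criteria"])

    dcca_groups = {name: SelectionSpec.from_dict(d)
                   for name, d in (raw.get("dcca_groups") or {}).items()}
    occupancy = [SelectionSpec.from_dict(d)
                 for d in (raw.get("occupancy_residues") or [])]

    dpc_raw = raw.get("dpc") or {}
    _reject_unknown(dpc_raw, {"d_c", "kernel", "n_centers"}, "dpc")
    dpc = DPCParams(d_c=dpc_raw.get("d_c", "auto"),
                    kernel=dpc_raw.get("kernel", "gaussian"),
                    n_centers=dpc_raw.get("n_centers", 1))

    cfg = RunConfig(
        output_dir=Path(raw.get("output_dir", "halomode_out")),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
        trajectory_path=Path(raw["trajectory"]) if raw.get("trajectory") else None,
        synthetic=synthetic,
        criteria=criteria,
        active_site=_selection(raw.get("active_site")),
        dcca_selection=_selection(raw.get("dcca")),
        dcca_groups=dcca_groups,
        occupancy_residues=occupancy,
        substrate=_selection(raw.get("substrate")),
        dpc_params=dpc,
        max_cluster_frames=int(raw.get("max_cluster_frames", 300)),
    )
    logger.info("Loaded config %s (cutoffs %.1f/%.1f/%.1f Å)", path,
                (criteria or synthdata.default_criteria()).hbond_cutoff,
                (criteria or synthdata.default_criteria()).d_OH_max,
                (criteria or synthdata.default_criteria()).d_CCl_max)
    return cfg


def _write_tsv_json(df, tsv_path: Path, float_format: str | None = None) -> None:
    df.to_csv(tsv_path, sep="\t", index=False, float_format=float_format)
    records = json.loads(df.to_json(orient="records"))
    tsv_path.with_suffix(".json").write_text(json.dumps(records, indent=1) + "\n")


def _even_subsample(indices: list[int], limit: int) -> list[int]:
    if len(indices) <= limit:
        return indices
    pick = np.linspace(0, len(indices) - 1, limit).round().astype(int)
    return [indices[i] for i in sorted(set(pick.tolist()))]


@dataclass
class ReportBundle:
    """Handles to everything a run produced."""

    output_dir: Path
    labels: list
    stats: object
    representative: dict[Mode, int] = field(default_factory=dict)
    files: list[Path] = field(default_factory=list)


def run_analysis(cfg: RunConfig) -> ReportBundle:
    """Classification -> statistics -> representatives -> (occupancy, DCCA).

    Any stage error aborts the run with the stage name; outputs written so
    far are kept and flagged in ``manifest.json`` as partial.
    """
    logging.basicConfig(level=cfg.log_level)
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    manifest: dict = {
        "package": "halomode", "version": __version__,
        "numpy": np.__version__, "seed": cfg.seed, "status": "partial",
    }
    stage = "setup"
    try:
        t0 = time.perf_counter()
        if cfg.synthetic is not None:
            stage = "simulate"
            top = synthdata.build_template_topology()
            traj, truth = synthdata.sample_trajectory(cfg.synthetic)
            truth_df = pd.DataFrame({
                "frame": range(cfg.synthetic.n_frames),
                "true_mode": [m.value for m in truth.modes],
                "true_productive": list(truth.productive),
            })
            _write_tsv_json(truth_df, out / "ground_truth.tsv")
            files.append(out / "ground_truth.tsv")
            criteria = cfg.criteria or synthdata.default_criteria()
            active_site = cfg.active_site or synthdata.active_site_selection()
            substrate = cfg.substrate or synthdata.substrate_selection()
            occupancy_residues = cfg.occupancy_residues or [
                SelectionSpec.from_dict({"residues": [{"res_id": rid}]})
                for rid in (synthdata.ANCHOR_A_RES_ID, synthdata.ANCHOR_B_RES_ID,
                            synthdata.LYS_RES_ID)
            ]
        else:
            stage = "read"
            top, traj = read_pdb_models(cfg.trajectory_path)
            if cfg.criteria is None:
                raise ConfigError("criteria must be given for a trajectory input")
            criteria = cfg.criteria
            active_site = cfg.active_site
            substrate = cfg.substrate
            occupancy_residues = cfg.occupancy_residues
        logger.info("[%s] %d frames, %d atoms (%.2fs)", stage, traj.n_frames,
                    traj.n_atoms, time.perf_counter() - t0)

        stage = "classify"
        t0 = time.perf_counter()
        labels = classify_frames(traj, top, criteria)
        stats = mode_statistics(labels)
        _write_tsv_json(labels_to_dataframe(labels), out / "frame_labels.tsv")
        stats_df = stats.to_dataframe()
        tsv_df = stats_df.copy()
        for col in ("P1", "P2"):
            tsv_df[col] = tsv_df[col].map(lambda v: f"{v:.1f}")
        tsv_df.to_csv(out / "mode_stats.tsv", sep="\t", index=False,
                      float_format="%.3f")
        (out / "mode_stats.json").write_text(
            json.dumps(json.loads(stats_df.to_json(orient="records")), indent=1) + "\n")
        files += [out / "frame_labels.tsv", out / "mode_stats.tsv"]
        logger.info("[classify] P1 = %s (%.2fs)",
                    {m.value: round(stats.p1[m], 1) for m in Mode},
                    time.perf_counter() - t0)

        if occupancy_residues and substrate is not None:
            stage = "occupancy"
            t0 = time.perf_counter()
            subset = frames_in_mode(labels, Mode.MODE1) or frames_in_mode(labels, None)
            subset_name = "mode1" if frames_in_mode(labels, Mode.MODE1) else "all"
            occ = hbond_occupancy(traj, top, criteria, occupancy_residues,
                                  substrate, subset, subset_name=subset_name)
            _write_tsv_json(occ, out / "occupancy.tsv", float_format="%.1f")
            files.append(out / "occupancy.tsv")
            logger.info("[occupancy] %d residues (%.2fs)", len(occ),
                        time.perf_counter() - t0)

        rep_frames: dict[Mode, int] = {}
        if active_site is not None:
            stage = "cluster"
            t0 = time.perf_counter()
            # cap per-mode frame counts so the O(n^2) RMSD matrix stays small
            sub_labels = []
            for mode in (Mode.MODE1, Mode.MODE2):
                idx = _even_subsample(frames_in_mode(labels, mode),
                                      cfg.max_cluster_frames)
                keep = set(idx)
                sub_labels.extend(lab for lab in labels
                                  if lab.mode is mode and lab.frame in keep)
            rep = representative_frames(traj, top, sub_labels, active_site,
                                        cfg.dpc_params)
            rep_frames = rep.frames
            for mode, frame in rep.frames.items():
                path = out / f"{mode.value}_rep.pdb"
                write_frame_pdb(top, traj, frame, path)
                files.append(path)
            for mode, msg in rep.errors.items():
                logger.warning("[cluster] %s", msg)
            logger.info("[cluster] representatives %s (%.2fs)",
                        {m.value: f for m, f in rep_frames.items()},
                        time.perf_counter() - t0)

        if cfg.dcca_selection is not None:
            stage = "dcca"
            t0 = time.perf_counter()
            dcca = dcca_matrix(traj, top, cfg.dcca_selection,
                               groups=cfg.dcca_groups or None)
            df = dcca.to_dataframe()
            df.insert(0, "label", df.index)
            _write_tsv_json(df.reset_index(drop=True), out / "dcca.tsv",
                            float_format="%.4f")
            files.append(out / "dcca.tsv")
            logger.info("[dcca] %d labels (%.2fs)", len(dcca.labels),
                        time.perf_counter() - t0)

        stage = "manifest"
        manifest["status"] = "complete"
        manifest["files"] = [str(p.name) for p in files]
        manifest["config_hash"] = hashlib.sha256(
            repr(cfg).encode()).hexdigest()[:16]
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
        return ReportBundle(output_dir=out, labels=labels, stats=stats,
                            representative=rep_frames, files=files)
    except Exception as exc:
        manifest["status"] = f"failed at stage {stage}"
        manifest["error"] = str(exc)
        try:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
        except OSError:
            pass
        raise
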