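"""End-to-end analysis run: frames + topology in, report tables out.

Given a config (YAML file or dict) listing one or more datasets, the
pipeline detects hydrogen bonds per frame, writes the census / cluster /
water-partition tables, and optionally MSD-diffusion and RDF tables.
All outputs are plain delimited text with units in the header; a
manifest records the configuration, package version and seed so a rerun
is byte-identical.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamics import diffusion_coefficient, msd, rdf, select_atoms, unwrap
from .hbond import HBondParams, detect_hbonds
from .network import average_census, census, trehalose_clusters, water_partition
from .topology import Topology, infer_topology, read_topology
from .trajio import Trajectory, read_pdb, read_xyz


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


def _load_dataset(entry: dict) -> tuple[str, Trajectory, Topology]:
    label = str(entry.get("label", entry["trajectory"]))
    tpath = Path(entry["trajectory"])
    if not tpath.exists():
        raise PipelineError(f"input: trajectory file not found: {tpath}")
    if tpath.suffix.lower() == ".pdb":
        names, traj = read_pdb(tpath)
    else:
        names, traj = None, read_xyz(tpath)
    if "topology" in entry and entry["topology"]:
        top = read_topology(entry["topology"])
    elif names is not None:
        top = infer_topology(names.atom_names, names.residue_names, names.residue_ids)
    else:
        raise PipelineError(
            f"input: dataset {label!r} needs an explicit topology sidecar "
            "(XYZ carries no atom names)"
        )
    if top.n_atoms != traj.n_atoms:
        raise PipelineError(
            f"input: dataset {label!r}: topology has {top.n_atoms} atoms, "
            f"trajectory has {traj.n_atoms}"
        )
    return label, traj, top


def run_pipeline(config: dict | str | os.PathLike, outdir: str | os.PathLike) -> Path:
    """Run every configured stage; returns the output directory."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    datasets = config.get("datasets", [])
    if not datasets:
        raise PipelineError("config: no datasets listed")
    for entry in datasets:
        if not Path(entry["trajectory"]).exists():
            raise PipelineError(
                f"config: trajectory does not exist: {entry['trajectory']}"
            )

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    hb_cfg = config.get("hbond", {})
    params = HBondParams(
        d_max=float(hb_cfg.get("d_max", 3.5)),
        theta_min=float(hb_cfg.get("theta_min", 150.0)),
    )
    intermolecular = bool(hb_cfg.get("intermolecular_only", True))

    census_rows = []
    partition_rows = []
    diffusion_rows = []
    for entry in datasets:
        label, traj, top = _load_dataset(entry)
        per_frame = []
        for fi, frame in enumerate(traj):
            try:
                bonds = detect_hbonds(frame, top, params, intermolecular)
            except Exception as exc:
                raise PipelineError(f"hbonds: dataset {label!r} frame {fi}: {exc}")
            per_frame.append(bonds)
            c = census(bonds, top)
            census_rows.append({"dataset": label, "frame": fi, **c.__dict__})
            wp = water_partition(bonds, top)
            partition_rows.append({"dataset": label, "frame": fi, **wp.__dict__})
            clusters = trehalose_clusters(bonds, top)
            hist = pd.DataFrame(
                sorted(clusters.counts.items()), columns=["n", "count"]
            )
            hist.to_csv(
                out / f"clusters_{_safe(label)}_frame{fi}.tsv", sep="\t", index=False
            )

        for sel in config.get("selections", []):
            if len(traj) < 4:
                continue
            try:
                series = msd(unwrap(traj), sel, top)
                est = diffusion_coefficient(
                    series, tuple(config.get("msd", {}).get("window", (0.1, 0.5)))
                )
            except Exception as exc:
                raise PipelineError(f"msd: dataset {label!r} selection {sel!r}: {exc}")
            pd.DataFrame(
                {"lag_ps": series.lag_times, "msd_A2": series.msd}
            ).to_csv(out / f"msd_{_safe(label)}_{sel}.tsv", sep="\t", index=False)
            diffusion_rows.append(
                {
                    "dataset": label,
                    "selection": sel,
                    "D_m2_per_s": est.d,
                    "slope_A2_per_ps": est.slope,
                    "r2": est.r2,
                    "window_lo_ps": est.fit_window[0],
                    "window_hi_ps": est.fit_window[1],
                }
            )

        rdf_cfg = config.get("rdf")
        if rdf_cfg:
            try:
                ref = select_atoms(top, rdf_cfg["ref"])
                tgt = select_atoms(top, rdf_cfg["target"])
                curve = rdf(
                    traj,
                    ref,
                    tgt,
                    r_max=float(rdf_cfg.get("r_max", 8.0)),
                    bin_width=float(rdf_cfg.get("bin_width", 0.05)),
                    pair_spec=(rdf_cfg["ref"], rdf_cfg["target"]),
                )
            except Exception as exc:
                raise PipelineError(f"rdf: dataset {label!r}: {exc}")
            pd.DataFrame({"r_A": curve.r_centers, "g": curve.g}).to_csv(
                out / f"rdf_{_safe(label)}.tsv", sep="\t", index=False
            )

    pd.DataFrame(census_rows).to_csv(out / "census.tsv", sep="\t", index=False)
    pd.DataFrame(partition_rows).to_csv(
        out / "water_partition.tsv", sep="\t", index=False
    )
    if diffusion_rows:
        pd.DataFrame(diffusion_rows).to_csv(
            out / "diffusion.tsv", sep="\t", index=False
        )

    manifest = {
        "package": "sugarglass",
        "version": __version__,
        "seed": config.get("seed", 0),
        "hbond_params": {"d_max": params.d_max, "theta_min": params.theta_min,
                         "intermolecular_only": intermolecular},
        "config": _plain(config),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out


def _safe(label: str) -> str:
    return "".join(c if c.isalnum() or c in "-._" else "_" for c in str(label))


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
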