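"""Reading and writing the pipeline's delimited-text formats.

Runs are stored BIDS-derivative style: one node x volume TSV per run
(``sub-<id>_ses-<n>_cond-<name>_run-<n>_bold.tsv``, node ids in the first
column) with a companion confounds TSV carrying ``trans_x .. rot_z`` and
``framewise_displacement`` columns. Matrices (latent connectomes, ICC maps)
are TSV with node ids as header; a JSON manifest describes the cohort.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .connectivity import ParcellatedTimeseries
from .motion import MOTION_AXES, FDTrace, MotionParams

_FLOAT_FMT = "%.10g"


def run_basename(ts: ParcellatedTimeseries) -> str:
    return (
        f"sub-{ts.subject_id}_ses-{ts.session}_cond-{ts.condition}"
        f"_run-{ts.run}"
    )


def motion_params_from_fd(fd: FDTrace) -> MotionParams:
    """Six-parameter trace whose Power FD reproduces the given FD exactly.

    All displacement is placed on the anterior-posterior translation axis as a
    cumulative sum of the FD increments; rotations and the other translations
    are zero. Used to write self-consistent synthetic confounds.
    """
    vals = np.zeros((fd.n_volumes, 6))
    vals[:, MOTION_AXES.index("trans_y")] = np.cumsum(fd.values)
    return MotionParams(vals, fd.tr_seconds)


def write_run(ts: ParcellatedTimeseries, out_dir: Path) -> tuple[Path, Path]:
    """Write one run's BOLD matrix and confounds TSVs; returns both paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = run_basename(ts)
    bold_path = out_dir / f"{base}_bold.tsv"
    conf_path = out_dir / f"{base}_confounds.tsv"
    df = pd.DataFrame(
        ts.signal,
        index=list(ts.node_ids),
        columns=[f"v{i:05d}" for i in range(ts.n_volumes)],
    )
    df.to_csv(bold_path, sep="\t", float_format=_FLOAT_FMT, index_label="node")
    params = motion_params_from_fd(ts.fd)
    conf = pd.DataFrame(params.values, columns=list(MOTION_AXES))
    conf["framewise_displacement"] = ts.fd.values
    conf.to_csv(conf_path, sep="\t", float_format=_FLOAT_FMT, index=False)
    return bold_path, conf_path


def read_run(bold_path: Path, tr_seconds: float) -> ParcellatedTimeseries:
    """Read a run from its BOLD TSV plus the sibling confounds TSV."""
    bold_path = Path(bold_path)
    df = pd.read_csv(bold_path, sep="\t", index_col="node")
    conf_path = bold_path.with_name(
        bold_path.name.replace("_bold.tsv", "_confounds.tsv")
    )
    conf = pd.read_csv(conf_path, sep="\t")
    if "framewise_displacement" in conf.columns:
        fd = FDTrace(conf["framewise_displacement"].to_numpy(), tr_seconds)
    else:
        from .motion import compute_fd

        params = MotionParams(conf[list(MOTION_AXES)].to_numpy(), tr_seconds)
        fd = compute_fd(params)
    fields = dict(
        part.split("-", 1) for part in bold_path.stem.split("_") if "-" in part
    )
    return ParcellatedTimeseries(
        subject_id=fields["sub"],
        session=int(fields["ses"]),
        condition=fields["cond"],
        run=int(fields["run"]),
        signal=df.to_numpy(),
        node_ids=tuple(df.index),
        tr_seconds=tr_seconds,
        fd=fd,
    )


def write_matrix(m: np.ndarray, node_ids, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(m, index=list(node_ids), columns=list(node_ids)).to_csv(
        path, sep="\t", float_format=_FLOAT_FMT, index_label="node"
    )
    return path


def read_matrix(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="node")


def write_mask(kept: np.ndarray, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"kept": np.asarray(kept, dtype=int)}).to_csv(
        path, sep="\t", index=False
    )
    return path


def write_json(obj: Mapping, path: Path) -> Path:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def write_cohort(cohort, out_dir: Path) -> Path:
    """Write every run, the ground-truth registry, and a JSON manifest."""
    out_dir = Path(out_dir)
    runs_dir = out_dir / "runs"
    truth_dir = out_dir / "ground_truth"
    files = []
    for ts in cohort.runs:
        bold, conf = write_run(ts, runs_dir)
        files.append(bold.name)
    for sid, latent in cohort.latents.items():
        write_matrix(
            latent.matrix,
            [f"node{i:04d}" for i in range(latent.n_nodes)],
            truth_dir / f"sub-{sid}_latent.tsv",
        )
    cohort.registry.to_csv(
        out_dir / "registry.csv", index=False, float_format=_FLOAT_FMT
    )
    manifest = {
        "n_runs": len(cohort.runs),
        "n_subjects": len(cohort.latents),
        "n_nodes": cohort.config.n_nodes,
        "tr_seconds": cohort.acquisition.tr_seconds,
        "volumes_per_run": cohort.acquisition.volumes_per_run,
        "n_sessions": cohort.acquisition.n_sessions,
        "conditions": list(cohort.acquisition.conditions),
        "seed": cohort.config.seed,
        "run_files": sorted(files),
    }
    return write_json(manifest, out_dir / "manifest.json")
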