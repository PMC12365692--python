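"""End-to-end orchestration: simulate -> censor -> group -> reliability -> report.

Runs every stage in dependency order on a synthetic cohort and writes a
deterministic JSON report (plus CSV side tables). Identical config + seed
yields byte-identical outputs: all randomness flows from the single seed, and
the report contains no timestamps. Stage warnings are collected into the
report so infeasible durations, dropped networks, and tie-breaks are visible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import connectivity as conn
from . import grouping, icc, networks, trc
from .io import write_json
from .motion import censor, minutes_to_volumes, pre_censored_time_to_reach
from .synthetic import (
    AcquisitionSpec,
    MotionModel,
    SyntheticCohortConfig,
    generate_cohort,
    generate_surveys,
)

logger = logging.getLogger("fcreliab")


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the demo pipeline; every constant lives here, not in stages.

    The defaults are a desk-scale cohort (6 pairs, 60 nodes) with the full
    four-session, three-condition, two-run, 205-volume geometry, an FD
    censoring threshold of 0.15 mm, a TRC threshold of 0.8, and a 5-30 minute
    split-half duration grid.
    """

    seed: int = 0
    n_pairs: int = 6
    n_nodes: int = 60
    n_sessions: int = 4
    volumes_per_run: int = 205
    runs_per_condition_per_session: int = 2
    tr_seconds: float = 2.0
    conditions: tuple = ("narrative", "nonnarrative", "lowdemand")
    fd_threshold_mm: float = 0.15
    trc_threshold: float = 0.8
    grid_start: float = 5.0
    grid_stop: float = 30.0
    grid_step: float = 5.0
    target_postcensored_minutes: float = 30.0
    icc_durations: tuple = (5.0, 10.0, 24.0)
    consensus_thresholds: tuple = (0.66, 0.75)
    n_iterations: int = 25
    reference_minutes: float = 20.0
    min_postcensored_minutes: float | None = None
    high_motion_child_fraction: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("conditions", "icc_durations", "consensus_thresholds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def acquisition(self) -> AcquisitionSpec:
        return AcquisitionSpec(
            tr_seconds=self.tr_seconds,
            volumes_per_run=self.volumes_per_run,
            runs_per_condition_per_session=self.runs_per_condition_per_session,
            n_sessions=self.n_sessions,
            conditions=self.conditions,
        )

    def cohort_config(self) -> SyntheticCohortConfig:
        return SyntheticCohortConfig(
            n_nodes=self.n_nodes,
            n_pairs=self.n_pairs,
            high_motion_child_fraction=self.high_motion_child_fraction,
            seed=self.seed,
        )


def build_split_half_dataset(
    cohort, masks, sessions_a, sessions_b, t_minutes, groups_by_subject
):
    """Split-half Fisher-z connectomes for every subject with enough data.

    Each half is truncated to the first ``t_minutes`` of post-censored data;
    subjects that cannot supply both halves are skipped. Returns None when
    fewer than two subjects survive.
    """
    tr = cohort.acquisition.tr_seconds
    need = minutes_to_volumes(t_minutes, tr)
    ha, hb, sids, grps = [], [], [], []
    for sid in cohort.subjects:
        runs = cohort.subject_runs(sid)
        run_masks = [masks[id(r)] for r in runs]
        a = trc._half_data(runs, run_masks, frozenset(sessions_a))
        b = trc._half_data(runs, run_masks, frozenset(sessions_b))
        if a is None or b is None or a.shape[1] < need or b.shape[1] < need:
            continue
        za = conn.fc_matrix(a[:, :need]).z
        zb = conn.fc_matrix(b[:, :need]).z
        ha.append(za)
        hb.append(zb)
        sids.append(sid)
        grps.append(groups_by_subject[sid])
    if len(sids) < 2:
        return None
    node_ids = tuple(cohort.runs[0].node_ids)
    return icc.SplitHalfDataset(
        np.stack(ha),
        np.stack(hb),
        t_minutes,
        tuple(sids),
        tuple(grps),
        node_ids,
        network_labels=cohort.network_labels,
    )


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage and write ``report.json`` plus CSV tables.

    Returns the report dict. Deterministic for a fixed config.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "warnings": [],
    }

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        logger.info("stage: simulate")
        acq = config.acquisition()
        cohort = generate_cohort(config.cohort_config(), acq)
        surveys = generate_surveys(cohort, seed=config.seed + 1)
        report["cohort"] = {
            "n_subjects": len(cohort.subjects),
            "n_runs": len(cohort.runs),
            "volumes_per_condition_total": acq.volumes_per_condition_total,
            "session_minutes": acq.session_minutes,
        }

        logger.info("stage: censor")
        masks = {id(r): censor(r.fd, config.fd_threshold_mm) for r in cohort.runs}
        retention_rows = []
        for sid in cohort.subjects:
            for cond in acq.conditions:
                sel = [
                    r
                    for r in cohort.subject_runs(sid)
                    if r.condition == cond
                ]
                retained = sum(masks[id(r)].n_retained for r in sel)
                collected = sum(r.n_volumes for r in sel)
                retention_rows.append(
                    {
                        "subject_id": sid,
                        "condition": cond,
                        "collected": collected,
                        "retained": retained,
                        "percent": 100.0 * retained / collected,
                    }
                )
        retention = pd.DataFrame(retention_rows)
        retention.to_csv(out_dir / "retention.csv", index=False)

        logger.info("stage: group")
        masks_by_subject = {
            sid: [masks[id(r)] for r in cohort.subject_runs(sid)]
            for sid in cohort.subjects
        }
        counts = grouping.postcensored_counts(masks_by_subject)
        ages = dict(
            zip(cohort.registry["subject_id"], cohort.registry["age_group"])
        )
        adult_counts = [counts[s] for s, a in ages.items() if a == "adult"]
        child_counts = [counts[s] for s, a in ages.items() if a == "child"]
        try:
            threshold = grouping.pdf_intersection(
                grouping.group_pdf("adult", adult_counts),
                grouping.group_pdf("child", child_counts),
                fallback_midpoint=True,
            )
        except ValueError as err:  # degenerate counts (e.g. near-total censoring)
            warnings.warn(f"group densities degenerate ({err}); using midpoint")
            threshold = (np.mean(adult_counts) + np.mean(child_counts)) / 2.0
        assignment = grouping.classify(
            counts, threshold, ages,
            min_minutes=config.min_postcensored_minutes,
            tr_seconds=acq.tr_seconds,
        )
        assignment.to_csv(out_dir / "motion_groups.csv", index=False)
        groups_by_subject = dict(
            zip(assignment["subject_id"], assignment["group"])
        )
        report["grouping"] = {
            "threshold_volumes": float(threshold),
            "group_sizes": {
                row["group"]: int(row["n"])
                for _, row in grouping.group_summary(assignment).iterrows()
            },
        }

        logger.info("stage: trc")
        scheme = trc.default_split_scheme(acq.n_sessions)
        grid = trc.duration_grid(
            config.grid_start, config.grid_stop, config.grid_step
        )
        curve_rows, ttt_rows = [], []
        curves_by_group: dict = {}
        for sid in cohort.subjects:
            runs = cohort.subject_runs(sid)
            run_masks = [masks[id(r)] for r in runs]
            curve = trc.split_session_trc(runs, scheme, grid, masks=run_masks)
            curves_by_group.setdefault(groups_by_subject[sid], []).append(curve)
            ttt = trc.time_to_threshold(curve, config.trc_threshold)
            pre = pre_censored_time_to_reach(
                run_masks, config.target_postcensored_minutes, acq.tr_seconds
            )
            ttt_rows.append(
                {
                    "subject_id": sid,
                    "group": groups_by_subject[sid],
                    "mean_fd": float(
                        cohort.registry.set_index("subject_id").loc[sid, "mean_fd"]
                    ),
                    "time_to_threshold_min": ttt,
                    "pre_censored_min_for_target": pre,
                }
            )
            for t, v in zip(curve.grid_minutes, curve.trc):
                curve_rows.append(
                    {
                        "subject_id": sid,
                        "method": "split_session",
                        "condition_scope": "all",
                        "duration_min": t,
                        "trc": v,
                    }
                )
        pd.DataFrame(curve_rows).to_csv(out_dir / "trc_curves.csv", index=False)
        ttt_df = pd.DataFrame(ttt_rows)
        ttt_df.to_csv(out_dir / "time_to_threshold.csv", index=False)
        group_means = {
            g: [None if np.isnan(v) else round(float(v), 6)
                for v in trc.group_mean_curve(cs)]
            for g, cs in sorted(curves_by_group.items())
        }
        report["trc"] = {
            "grid_minutes": list(grid),
            "group_mean_trc": group_means,
            "mean_time_to_threshold_min": {
                g: (None if not np.isfinite(m) else round(float(m), 4))
                for g, m in ttt_df.groupby("group")["time_to_threshold_min"]
                .mean()
                .items()
            },
        }
        la, hc = "low_motion_adult", "high_motion_child"
        if la in curves_by_group and hc in curves_by_group:
            a_stack = np.vstack([c.trc for c in curves_by_group[la]])
            b_stack = np.vstack([c.trc for c in curves_by_group[hc]])
            ds = []
            for j in range(len(grid)):
                a_col = a_stack[:, j][~np.isnan(a_stack[:, j])]
                b_col = b_stack[:, j][~np.isnan(b_stack[:, j])]
                ds.append(
                    round(trc.cohens_d(a_col, b_col), 6)
                    if a_col.size >= 2 and b_col.size >= 2
                    else None
                )
            report["trc"]["cohens_d_lma_vs_hmc"] = ds

        logger.info("stage: icc")
        sessions_a, sessions_b = scheme.pairs[0]
        icc_summary = {}
        for t in config.icc_durations:
            ds = build_split_half_dataset(
                cohort, masks, sessions_a, sessions_b, t, groups_by_subject
            )
            if ds is None:
                warnings.warn(f"no split-half data at {t} min; skipped")
                continue
            edge = icc.edgewise_icc(ds)
            pre_avg = icc.network_icc_pre_average(ds)
            post_avg = icc.network_icc_post_average(
                edge, ds.node_ids, cohort.network_labels
            )
            icc_summary[str(t)] = {
                "n_subjects": ds.n_subjects,
                "mean_edge_icc": round(float(np.nanmean(edge)), 6),
                "mean_network_icc_pre": round(
                    float(np.nanmean(pre_avg.to_numpy())), 6
                ),
                "mean_network_icc_post": round(
                    float(np.nanmean(post_avg.to_numpy())), 6
                ),
            }
        report["icc"] = icc_summary

        logger.info("stage: networks")
        labels = cohort.network_labels
        templates = networks.templates_from_labels(labels)
        assignments = []
        for sid in cohort.subjects:
            runs = cohort.subject_runs(sid)
            run_masks = [masks[id(r)] for r in runs]
            data = conn.concat_censored(runs, run_masks)
            try:
                fc = conn.fc_matrix(
                    data, node_ids=runs[0].node_ids, network_labels=labels
                )
            except ValueError as err:
                warnings.warn(f"template matching skipped for {sid}: {err}")
                continue
            assignments.append(networks.template_match(fc, templates))
        if len(assignments) >= 2:
            consensus_counts = {}
            for thr in config.consensus_thresholds:
                consensus = networks.group_overlap(assignments, thr)
                kept_nodes, kept_networks, _ = (
                    networks.filter_networks_for_analysis(consensus)
                )
                consensus_counts[f"{thr:.2f}"] = {
                    "labeled_nodes": int(consensus["network"].notna().sum()),
                    "analysis_nodes": len(kept_nodes),
                    "analysis_networks": len(kept_networks),
                }
            recov = float(
                np.mean(
                    [
                        (a["network"] == pd.Series(labels)).mean()
                        for a in assignments
                    ]
                )
            )
            report["networks"] = {
                "mean_recovery_fraction": round(recov, 6),
                "consensus": consensus_counts,
            }
        else:
            warnings.warn("too few subjects with usable data for consensus maps")
            report["networks"] = {"mean_recovery_fraction": None, "consensus": {}}

        logger.info("stage: behavior")
        scored = beh.score_survey_table(surveys)
        scored.to_csv(out_dir / "behavior_scores.csv", index=False)
        report["behavior"] = {
            cond: {
                "mean_attention_pct": round(float(g["attention_pct"].mean()), 4),
                "mean_drowsiness": round(float(g["drowsiness"].mean()), 4),
            }
            for cond, g in scored.groupby("condition")
        }

        report["warnings"] = sorted({str(w.message) for w in caught})

    # JSON cannot carry inf; encode unreachable durations as null
    def _clean(o):
        if isinstance(o, dict):
            return {k: _clean(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [_clean(v) for v in o]
        if isinstance(o, (float, np.floating)):
            f = float(o)
            return None if not np.isfinite(f) else f
        if isinstance(o, (np.integer,)):
            return int(o)
        return o

    report = _clean(report)
    write_json(report, out_dir / "report.json")
    return report
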