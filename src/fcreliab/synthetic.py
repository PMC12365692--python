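"""Synthetic multi-session BOLD cohorts with known ground truth.

Emulates a dense-sampling family study: parent-child pairs scanned over
several sessions, each session comprising multiple passive-viewing conditions
with two runs each. Every subject owns a latent connectome (a correlation
matrix perturbed around an age-group template); each run is a multivariate
normal draw whose long-run empirical correlation converges to that latent
connectome, plus independent observation noise and motion-scaled contamination.
Head motion is a two-state process: a low baseline framewise displacement with
occasional bursts of lognormal magnitude, so censoring at a fixed FD threshold
removes a controllable fraction of volumes.

Because the ground truth is known, every downstream stage (censoring
accounting, reliability curves, ICC, motion grouping, template matching) has a
parameter-recovery test surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.correlation_tools import corr_clipped


def _nearest_corr(m: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to a nearby valid correlation matrix.

    Eigenvalue clipping (fast, adequate for mild perturbations) followed by
    re-symmetrization and a unit diagonal.
    """
    out = corr_clipped(m, threshold=1e-7)
    out = (out + out.T) / 2
    np.fill_diagonal(out, 1.0)
    return np.clip(out, -1.0, 1.0)

from .connectivity import ParcellatedTimeseries
from .motion import FDTrace

DEFAULT_CONDITIONS = ("narrative", "nonnarrative", "lowdemand")

#: Canonical functional network names used for labelling synthetic nodes.
CANONICAL_NETWORKS = (
    "DMN", "FP", "visual", "DAN", "VAN", "SAL", "AUD",
    "CON", "SMd", "SMl", "Tpole", "MTL", "PMN", "PON",
)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Scan-design geometry: how many volumes, runs, conditions, and sessions.

    Defaults mirror a dense-sampling design: TR = 2 s, 205 usable volumes per
    run, 2 runs per condition per session, 3 viewing conditions, 4 sessions
    (41 minutes of acquisition per session, ~2.8 hours per subject).
    """

    tr_seconds: float = 2.0
    volumes_per_run: int = 205
    runs_per_condition_per_session: int = 2
    n_sessions: int = 4
    conditions: tuple = DEFAULT_CONDITIONS

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        for name, v in [
            ("volumes_per_run", self.volumes_per_run),
            ("runs_per_condition_per_session", self.runs_per_condition_per_session),
            ("n_sessions", self.n_sessions),
        ]:
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be a positive integer")
        if len(set(self.conditions)) != len(self.conditions) or not self.conditions:
            raise ValueError("condition names must be unique and nonempty")

    @property
    def runs_per_session(self) -> int:
        return self.runs_per_condition_per_session * len(self.conditions)

    @property
    def volumes_per_session(self) -> int:
        return self.volumes_per_run * self.runs_per_session

    @property
    def session_minutes(self) -> float:
        return self.volumes_per_session * self.tr_seconds / 60.0

    @property
    def volumes_per_condition_total(self) -> int:
        """Volumes collected for one condition across all sessions."""
        return (
            self.volumes_per_run
            * self.runs_per_condition_per_session
            * self.n_sessions
        )

    @property
    def total_volumes(self) -> int:
        return self.volumes_per_session * self.n_sessions

    def runs_per_subject(self) -> int:
        return self.runs_per_session * self.n_sessions


@dataclass(frozen=True)
class MotionModel:
    """Two-state FD generator: baseline jitter plus lognormal bursts.

    Per volume, FD = |N(baseline_mm, jitter_mm)| plus, with probability
    ``burst_prob``, a lognormal burst of median exp(burst_log_mu). The burst
    indicator is u < burst_prob with u drawn once per volume, so raising
    ``burst_prob`` under the same seed strictly grows the censored set
    (common-random-number coupling). ``signal_spike_scale`` adds zero-mean
    noise to the BOLD signal with SD proportional to the volume's FD; the
    contamination carries over to the ``carryover`` volumes on either side of
    each displacement (spin-history-like persistence), so volumes adjacent to
    a censored burst survive censoring yet carry degraded signal — motion
    hurts connectivity estimates even after scrubbing, and censoring still
    has a measurable benefit.
    """

    baseline_mm: float = 0.06
    jitter_mm: float = 0.02
    burst_prob: float = 0.02
    burst_log_mu: float = math.log(0.35)
    burst_log_sigma: float = 0.8
    signal_spike_scale: float = 1.0
    carryover: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.burst_prob <= 1.0:
            raise ValueError("burst_prob must lie in [0, 1]")
        if self.baseline_mm < 0 or self.jitter_mm < 0 or self.signal_spike_scale < 0:
            raise ValueError("motion model scales must be nonnegative")
        if self.carryover < 0:
            raise ValueError("carryover must be a nonnegative integer")

    def draw_fd(self, n_volumes: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.random(n_volumes)
        base = np.abs(rng.normal(self.baseline_mm, self.jitter_mm, n_volumes))
        mags = rng.lognormal(self.burst_log_mu, self.burst_log_sigma, n_volumes)
        fd = base + np.where(u < self.burst_prob, mags, 0.0)
        fd[0] = 0.0
        return fd

    def contamination_sd(self, fd: np.ndarray) -> np.ndarray:
        """Per-volume signal-contamination SD from an FD trace.

        The local FD maximum over a +/- ``carryover`` window, scaled by
        ``signal_spike_scale``: a burst corrupts its neighbours too.
        """
        eff = fd.copy()
        for k in range(1, self.carryover + 1):
            eff[k:] = np.maximum(eff[k:], fd[:-k])
            eff[:-k] = np.maximum(eff[:-k], fd[k:])
        return self.signal_spike_scale * eff


@dataclass(frozen=True)
class LatentConnectome:
    """A subject's ground-truth FC: a symmetric PSD correlation matrix."""

    subject_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        _validate_correlation(m)
        object.__setattr__(self, "matrix", m)

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


def _validate_correlation(m: np.ndarray) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("correlation template must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("correlation template must be symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-10):
        raise ValueError("correlation template must have a unit diagonal")
    if np.max(np.abs(m)) > 1.0 + 1e-10:
        raise ValueError("correlation entries must lie in [-1, 1]")
    if np.linalg.eigvalsh(m).min() < -1e-8:
        raise ValueError("correlation template must be positive semidefinite")


def default_network_labels(
    n_nodes: int, networks: Sequence[str] = CANONICAL_NETWORKS[:12]
) -> dict:
    """Round-allocated node -> network map: contiguous, roughly equal blocks."""
    labels = {}
    n_net = len(networks)
    base, extra = divmod(n_nodes, n_net)
    i = 0
    for k, net in enumerate(networks):
        size = base + (1 if k < extra else 0)
        for _ in range(size):
            labels[f"node{i:04d}"] = net
            i += 1
    return labels


def block_template(
    network_labels: Mapping[str, str],
    within_r: float = 0.45,
    between_r: float = 0.05,
) -> np.ndarray:
    """Block-structured group correlation template from a node -> network map.

    Within-network edges get ``within_r``, between-network edges ``between_r``;
    the result is projected to the nearest correlation matrix if needed.
    """
    nets = [network_labels[k] for k in network_labels]
    n = len(nets)
    same = np.array([[a == b for b in nets] for a in nets])
    m = np.where(same, within_r, between_r).astype(float)
    np.fill_diagonal(m, 1.0)
    if np.linalg.eigvalsh(m).min() < -1e-8:
        m = _nearest_corr(m)
    return m


def generate_latent_connectome(
    template: np.ndarray,
    deviation_scale: float,
    rng: np.random.Generator | int,
    subject_id: str = "sub",
    block_deviation_scale: float = 0.0,
    network_labels: Mapping[str, str] | None = None,
) -> LatentConnectome:
    """Perturb a group template into a subject-specific correlation matrix.

    Adds symmetric Gaussian noise (SD ``deviation_scale``) to the Fisher z of
    the off-diagonal template entries, back-transforms, and projects to the
    nearest correlation matrix so the result stays PSD with entries in (-1, 1).
    ``deviation_scale = 0`` returns the template exactly.

    ``block_deviation_scale`` adds a per-network-pair shared z offset (one draw
    per block, applied to every edge in the block), giving subjects coherent
    network-level idiosyncrasies: between-subject edge "signal" is then
    correlated within blocks, the regime where averaging edges before
    reliability analysis pays off.
    """
    template = np.asarray(template, dtype=float)
    _validate_correlation(template)
    if deviation_scale < 0 or block_deviation_scale < 0:
        raise ValueError("deviation scales must be nonnegative")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    if deviation_scale == 0 and block_deviation_scale == 0:
        return LatentConnectome(subject_id, template.copy())

    n = template.shape[0]
    z = np.arctanh(np.clip(template, -1 + 1e-7, 1 - 1e-7))
    noise = rng.normal(0.0, deviation_scale, size=(n, n))
    noise = (noise + noise.T) / math.sqrt(2.0)
    z = z + noise
    if block_deviation_scale > 0:
        if network_labels is None:
            raise ValueError("block_deviation_scale requires network_labels")
        nets = list(network_labels.values())
        if len(nets) != n:
            raise ValueError("network_labels must cover every node")
        uniq = sorted(set(nets))
        idx = {name: np.array([i for i, v in enumerate(nets) if v == name])
               for name in uniq}
        for a_i, a in enumerate(uniq):
            for b in uniq[a_i:]:
                offset = rng.normal(0.0, block_deviation_scale)
                z[np.ix_(idx[a], idx[b])] += offset
                if a != b:
                    z[np.ix_(idx[b], idx[a])] += offset
    m = np.tanh(z)
    np.fill_diagonal(m, 1.0)
    if np.linalg.eigvalsh(m).min() < -1e-8:
        m = _nearest_corr(m)
    m = np.clip(m, -1.0, 1.0)
    return LatentConnectome(subject_id, m)


def generate_run(
    latent: LatentConnectome,
    acquisition: AcquisitionSpec,
    noise_scale: float,
    sd_multiplier: float,
    motion_model: MotionModel,
    rng: np.random.Generator | int,
    *,
    subject_id: str | None = None,
    session: int = 1,
    condition: str | None = None,
    run: int = 1,
    n_volumes: int | None = None,
    session_z_offset: float = 0.0,
) -> ParcellatedTimeseries:
    """Simulate one run of parcellated BOLD plus its FD trace.

    The signal is an i.i.d.-over-volumes multivariate normal draw with
    covariance ``sd_multiplier**2 * latent``; the empirical correlation of an
    arbitrarily long noise-free run therefore converges to the latent
    connectome. Independent N(0, noise_scale^2) observation noise and
    FD-proportional contamination (see :class:`MotionModel`) are added on top.
    ``session_z_offset`` shifts every latent edge by a constant on the Fisher-z
    scale before drawing, emulating day-to-day state variance.
    """
    if noise_scale < 0 or sd_multiplier <= 0:
        raise ValueError("noise_scale must be >= 0 and sd_multiplier > 0")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    n = latent.n_nodes
    V = int(n_volumes if n_volumes is not None else acquisition.volumes_per_run)
    corr = latent.matrix
    if session_z_offset != 0.0:
        z = np.arctanh(np.clip(corr, -1 + 1e-7, 1 - 1e-7)) + session_z_offset
        corr = np.tanh(z)
        np.fill_diagonal(corr, 1.0)
        if np.linalg.eigvalsh(corr).min() < -1e-8:
            corr = _nearest_corr(corr)

    fd = motion_model.draw_fd(V, rng)
    L = np.linalg.cholesky(corr + 1e-10 * np.eye(n))
    signal = sd_multiplier * (L @ rng.standard_normal((n, V)))
    if noise_scale > 0:
        signal = signal + noise_scale * rng.standard_normal((n, V))
    if motion_model.signal_spike_scale > 0:
        spikes = rng.standard_normal((n, V)) * motion_model.contamination_sd(fd)
        signal = signal + spikes
    return ParcellatedTimeseries(
        subject_id=subject_id or latent.subject_id,
        session=session,
        condition=condition or acquisition.conditions[0],
        run=run,
        signal=signal,
        node_ids=tuple(f"node{i:04d}" for i in range(n)),
        tr_seconds=acquisition.tr_seconds,
        fd=FDTrace(fd, acquisition.tr_seconds),
    )


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Everything the cohort generator needs besides the acquisition geometry.

    Defaults describe 24 parent-child pairs with low-motion adults and
    heterogeneously moving children: half the children draw a "high motion"
    burst probability, producing FD traces with frequent excursions above the
    0.15 mm censoring threshold.
    """

    n_nodes: int = 100
    n_pairs: int = 24
    networks: tuple = CANONICAL_NETWORKS[:12]
    within_network_r: float = 0.45
    between_network_r: float = 0.05
    subject_deviation_scale: float = 0.12
    block_deviation_scale: float = 0.05
    observation_noise_scale: float = 0.5
    condition_sd_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {
            "narrative": 1.0, "nonnarrative": 1.0, "lowdemand": 1.08
        }
    )
    adult_motion: MotionModel = field(default_factory=lambda: MotionModel(
        baseline_mm=0.06, jitter_mm=0.02, burst_prob=0.02))
    child_low_motion: MotionModel = field(default_factory=lambda: MotionModel(
        baseline_mm=0.08, jitter_mm=0.03, burst_prob=0.02))
    child_high_motion: MotionModel = field(default_factory=lambda: MotionModel(
        baseline_mm=0.11, jitter_mm=0.04, burst_prob=0.25))
    high_motion_child_fraction: float = 0.5
    #: Per-subject lognormal spread of the burst probability and baseline FD
    #: around the group motion model (individual motion propensity).
    subject_burst_log_sd: float = 0.4
    subject_baseline_log_sd: float = 0.15
    session_z_offset_scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2 or self.n_pairs < 1:
            raise ValueError("n_nodes >= 2 and n_pairs >= 1 required")
        if min(self.subject_deviation_scale, self.block_deviation_scale,
               self.observation_noise_scale, self.session_z_offset_scale) < 0:
            raise ValueError("scales must be nonnegative")
        if not all(v > 0 for v in self.condition_sd_multipliers.values()):
            raise ValueError("condition SD multipliers must be positive")
        if not 0.0 <= self.high_motion_child_fraction <= 1.0:
            raise ValueError("high_motion_child_fraction must lie in [0, 1]")
        if self.subject_burst_log_sd < 0 or self.subject_baseline_log_sd < 0:
            raise ValueError("subject motion spreads must be nonnegative")


@dataclass
class SyntheticCohort:
    """Generated runs plus the ground-truth registry.

    ``registry`` has one row per subject: subject_id, age_group (adult/child),
    motion profile name, and per-subject mean FD across runs. ``latents`` maps
    subject_id to its :class:`LatentConnectome`.
    """

    runs: list
    latents: dict
    registry: pd.DataFrame
    config: SyntheticCohortConfig
    acquisition: AcquisitionSpec

    def subject_runs(self, subject_id: str) -> list:
        return [r for r in self.runs if r.subject_id == subject_id]

    @property
    def subjects(self) -> list:
        return list(self.registry["subject_id"])

    @property
    def network_labels(self) -> dict:
        return default_network_labels(self.config.n_nodes, self.config.networks)


def generate_cohort(
    config: SyntheticCohortConfig,
    acquisition: AcquisitionSpec | None = None,
    seed: int | None = None,
) -> SyntheticCohort:
    """Generate the full cohort: pairs x 2 subjects x sessions x conditions x runs.

    Deterministic under a fixed config: per-subject and per-run RNG streams are
    spawned from a single seed sequence, so the output is byte-identical across
    reruns and insensitive to generation order.
    """
    acquisition = acquisition or AcquisitionSpec()
    seed = config.seed if seed is None else seed
    labels = default_network_labels(config.n_nodes, config.networks)
    template = block_template(
        labels, config.within_network_r, config.between_network_r
    )
    root = np.random.SeedSequence(seed)
    n_subjects = config.n_pairs * 2
    subject_seeds = root.spawn(n_subjects)

    runs: list = []
    latents: dict = {}
    rows = []
    n_high = int(round(config.high_motion_child_fraction * config.n_pairs))
    for pair in range(config.n_pairs):
        for role in ("adult", "child"):
            sid = f"{role}{pair + 1:03d}"
            srng = np.random.default_rng(subject_seeds[len(latents)])
            latent = generate_latent_connectome(
                template,
                config.subject_deviation_scale,
                srng,
                subject_id=sid,
                block_deviation_scale=config.block_deviation_scale,
                network_labels=labels if config.block_deviation_scale > 0 else None,
            )
            latents[sid] = latent
            if role == "adult":
                motion = config.adult_motion
                profile = "adult"
            elif pair < n_high:
                motion = config.child_high_motion
                profile = "child_high"
            else:
                motion = config.child_low_motion
                profile = "child_low"
            # individual motion propensity around the group model
            motion = replace(
                motion,
                burst_prob=min(
                    1.0,
                    motion.burst_prob
                    * srng.lognormal(0.0, config.subject_burst_log_sd),
                ),
                baseline_mm=motion.baseline_mm
                * srng.lognormal(0.0, config.subject_baseline_log_sd),
            )
            session_offsets = (
                srng.normal(0.0, config.session_z_offset_scale, acquisition.n_sessions)
                if config.session_z_offset_scale > 0
                else np.zeros(acquisition.n_sessions)
            )
            fd_sum = 0.0
            fd_count = 0
            for ses in range(1, acquisition.n_sessions + 1):
                for cond in acquisition.conditions:
                    mult = config.condition_sd_multipliers.get(cond, 1.0)
                    for rnum in range(
                        1, acquisition.runs_per_condition_per_session + 1
                    ):
                        ts = generate_run(
                            latent,
                            acquisition,
                            config.observation_noise_scale,
                            mult,
                            motion,
                            srng,
                            subject_id=sid,
                            session=ses,
                            condition=cond,
                            run=rnum,
                            session_z_offset=float(session_offsets[ses - 1]),
                        )
                        runs.append(ts)
                        fd_sum += float(ts.fd.values.sum())
                        fd_count += ts.fd.n_volumes
            rows.append(
                {
                    "subject_id": sid,
                    "age_group": role,
                    "motion_profile": profile,
                    "mean_fd": fd_sum / fd_count,
                }
            )
    registry = pd.DataFrame(rows)
    return SyntheticCohort(runs, latents, registry, config, acquisition)


def generate_surveys(
    cohort: SyntheticCohort, seed: int = 0
) -> pd.DataFrame:
    """Synthetic post-session survey responses, one row per subject/session/condition/run.

    Emulates condition-dependent engagement: the low-demand condition draws
    higher drowsiness codes and lower recall accuracy than the narrative and
    non-narrative conditions. Columns: subject_id, session, condition, run,
    correct, asked, drowsiness.
    """
    rng = np.random.default_rng(seed)
    items = ("none", "tired", "sleepy", "difficulty_staying_awake")
    rows = []
    for sid in cohort.subjects:
        for ses in range(1, cohort.acquisition.n_sessions + 1):
            for cond in cohort.acquisition.conditions:
                drowsy_p = (
                    [0.45, 0.3, 0.15, 0.1] if cond == "lowdemand"
                    else [0.75, 0.15, 0.07, 0.03]
                )
                p_correct = 0.65 if cond == "lowdemand" else 0.85
                for rnum in range(
                    1, cohort.acquisition.runs_per_condition_per_session + 1
                ):
                    asked = 6
                    rows.append(
                        {
                            "subject_id": sid,
                            "session": ses,
                            "condition": cond,
                            "run": rnum,
                            "correct": int(rng.binomial(asked, p_correct)),
                            "asked": asked,
                            "drowsiness": items[rng.choice(4, p=drowsy_p)],
                        }
                    )
    return pd.DataFrame(rows)
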