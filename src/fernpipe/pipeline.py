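"""End-to-end study orchestration: simulate cohorts, synthesize and preprocess
EEG, run the waveform statistics and the source-level group contrasts, and
assemble a reproducible report.

Per-subject random streams are derived deterministically from the master seed
and the subject identifier, so a fixed master seed reproduces the full report
(bit-identical payload, timestamps excluded) while subjects remain mutually
independent.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import Montage
from .erp_stats import (
    AnalysisConfig,
    average_condition,
    covariate_checks,
    montecarlo_bootstrap_test,
)
from .headmodel import (
    Leadfield,
    SourceSpace,
    SphereModel,
    build_source_space,
    build_spherical_leadfield,
    default_montage,
    default_sphere,
)
from .preprocessing import PreprocConfig, preprocess
from .source import (
    InverseConfig,
    baseline_noise_covariance,
    depth_weighted_min_norm,
    mannwhitney_groups,
)
from .synth import ERPTemplate, NoiseParams, synthesize_eeg
from .tasks import (
    IGTConfig,
    PDGConfig,
    filter_participants_by_omission,
    simulate_igt_session,
    simulate_pdg_session,
)

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyReport", "validate_config", "run_study", "subject_seed"]


@dataclass(frozen=True)
class StudyConfig:
    groups: dict[str, int] = field(
        default_factory=lambda: {"control": 20, "adhd": 20, "asd": 20}
    )
    tasks: tuple[str, ...] = ("igt", "pdg")
    igt: IGTConfig = field(default_factory=IGTConfig)
    pdg: PDGConfig = field(default_factory=PDGConfig)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    inverse: InverseConfig = field(default_factory=InverseConfig)
    noise: NoiseParams = field(default_factory=NoiseParams)
    base_amplitude_uv: float = -6.0
    igt_policy: str = "uniform-random"
    master_seed: int = 0
    fs: float = 1024.0
    age_range: tuple[float, float] = (8.0, 15.0)
    male_fraction: float = 0.7
    unit: str = "subjects"  # statistical units: "subjects" | "trials"


@dataclass
class StudyReport:
    config: dict
    contrasts: dict  # group -> task/contrast -> PermTestResult dict
    roi_scalars: dict  # group -> task/contrast -> list of per-subject scalars
    group_comparisons: dict  # task/contrast -> "gA_vs_gB" -> GroupComparison dict
    retention: dict  # group -> task -> {condition: [total, kept]}
    covariates: dict  # group -> task/contrast -> covariate report
    excluded_subjects: dict  # group -> list of ids excluded (omission filter)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        from .io import save_json

        save_json(self.to_dict(), path)


def subject_seed(master_seed: int, subject_id: str, stream: int = 0) -> int:
    """Deterministic per-subject seed below 2^31."""
    h = zlib.crc32(subject_id.encode())
    ss = np.random.SeedSequence([int(master_seed), int(h), int(stream)])
    return int(ss.generate_state(1)[0] % (2**31))


def validate_config(cfg: StudyConfig) -> list[str]:
    """Every sub-config invariant, violations named by path. Empty list = ok."""
    v: list[str] = []
    if not cfg.groups:
        v.append("groups: at least one group required")
    for g, n in cfg.groups.items():
        if g not in ("control", "adhd", "asd"):
            v.append(f"groups.{g}: unknown profile")
        if n <= 0:
            v.append(f"groups.{g}: subject count must be positive")
    for t in cfg.tasks:
        if t not in ("igt", "pdg"):
            v.append(f"tasks: unknown task {t!r}")
    v += [f"igt.{p}" for p in cfg.igt.validate()]
    v += [f"pdg.{p}" for p in cfg.pdg.validate()]
    v += [f"preproc.{p}" for p in cfg.preproc.validate()]
    v += [f"analysis.{p}" for p in cfg.analysis.validate()]
    v += [f"inverse.{p}" for p in cfg.inverse.validate()]
    v += [f"noise.{p}" for p in cfg.noise.validate()]
    if cfg.base_amplitude_uv > 0:
        v.append("base_amplitude_uv: must be negative or zero")
    if cfg.fs <= 0:
        v.append("fs: must be positive")
    if not 0 <= cfg.male_fraction <= 1:
        v.append("male_fraction: proportion out of range")
    if cfg.unit not in ("subjects", "trials"):
        v.append("unit: must be 'subjects' or 'trials'")
    ew = cfg.preproc.epoch_window_ms
    fw = cfg.analysis.fern_window_ms
    if fw[0] < fw[1] and not (ew[0] <= fw[0] and fw[1] <= ew[1]):
        v.append("analysis.fern_window_ms: must lie inside the epoch window")
    return v


def _igt_contrast_labels(igt: IGTConfig) -> dict[str, dict[str, list[str]]]:
    """Contrast name -> {'A': loss labels, 'B': win labels} for the
    disadvantageous-deck and high-loss-frequency option pools."""
    decks = [d for pair in igt.deck_schedules[: igt.n_versions] for d in pair]
    dd = [d.name for d in decks if not d.advantageous]
    hf = [d.name for d in decks if d.high_loss_freq]
    out = {}
    if dd:
        out["igt_dd_loss_vs_win"] = {
            "A": [f"igt/{n}/loss" for n in dd],
            "B": [f"igt/{n}/win" for n in dd],
        }
    if hf:
        out["igt_hf_loss_vs_win"] = {
            "A": [f"igt/{n}/loss" for n in hf],
            "B": [f"igt/{n}/win" for n in hf],
        }
    return out


PDG_CONTRAST = {"pdg_betray_vs_cooperate": {"A": ["pdg/betray"], "B": ["pdg/cooperate"]}}


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage


@dataclass
class _SubjectResult:
    subject_id: str
    age: float
    gender: str
    # contrast -> subject condition-average Fz waveforms and ROI scalar
    waveforms: dict
    roi: dict
    retention: dict
    trial_epochs: dict  # contrast -> (epochs_A, epochs_B) Fz arrays (trial level)


def _run_subject(
    cfg: StudyConfig,
    group: str,
    subject_id: str,
    lead: Leadfield,
    montage: Montage,
    sphere: SphereModel,
    space: SourceSpace,
) -> _SubjectResult | None:
    rng_demo = np.random.default_rng(subject_seed(cfg.master_seed, subject_id, stream=9))
    age = float(rng_demo.uniform(*cfg.age_range))
    gender = "M" if rng_demo.random() < cfg.male_fraction else "F"

    waveforms: dict = {}
    roi: dict = {}
    retention: dict = {}
    trial_epochs: dict = {}
    for task in cfg.tasks:
        if task == "igt":
            session = simulate_igt_session(
                cfg.igt,
                policy=cfg.igt_policy,
                seed=subject_seed(cfg.master_seed, subject_id, stream=0),
                participant_id=subject_id,
                group_profile=group,
            )
            contrasts = _igt_contrast_labels(cfg.igt)
        else:
            session = simulate_pdg_session(
                cfg.pdg,
                seed=subject_seed(cfg.master_seed, subject_id, stream=1),
                participant_id=subject_id,
                group_profile=group,
            )
            retained, _ = filter_participants_by_omission([session])
            if not retained:
                logger.info("subject %s excluded by omission filter", subject_id)
                return None
            contrasts = PDG_CONTRAST
        template = ERPTemplate.for_profile(group, base_amplitude_uv=cfg.base_amplitude_uv)
        raw = synthesize_eeg(
            session,
            template,
            montage,
            noise_params=cfg.noise,
            seed=subject_seed(cfg.master_seed, subject_id, stream=2 if task == "igt" else 3),
            fs=cfg.fs,
            sphere=sphere,
            source_space=space,
        )
        epochs = preprocess(raw, cfg.preproc)
        kept_labels = epochs.labels[epochs.kept]
        retention[task] = {
            cond: [int((epochs.labels == cond).sum()), int((kept_labels == cond).sum())]
            for cond in sorted(set(epochs.labels))
        }
        noise_cov = baseline_noise_covariance(
            epochs, cfg.preproc.baseline_window_ms, cfg.inverse.shrinkage
        )
        for cname, sides in contrasts.items():
            try:
                erp_a = average_condition(epochs, sides["A"])
                erp_b = average_condition(epochs, sides["B"])
            except ValueError:
                logger.info("subject %s lacks epochs for contrast %s", subject_id, cname)
                continue
            waveforms[cname] = {
                "A": erp_a.channel(cfg.analysis.electrode),
                "B": erp_b.channel(cfg.analysis.electrode),
                "times": erp_a.times,
                "n_a": erp_a.n_epochs,
                "n_b": erp_b.n_epochs,
            }
            est_a = depth_weighted_min_norm(lead, erp_a, cfg.inverse, noise_cov)
            est_b = depth_weighted_min_norm(lead, erp_b, cfg.inverse, noise_cov)
            diff = est_a.data - est_b.data
            mask = (erp_a.times >= cfg.analysis.fern_window_ms[0]) & (
                erp_a.times < cfg.analysis.fern_window_ms[1]
            )
            idx = space.roi_indices("ACC")
            roi[cname] = float(diff[np.ix_(idx, mask)].mean())
            if cfg.unit == "trials":
                sub_a = epochs.select(sides["A"])
                sub_b = epochs.select(sides["B"])
                trial_epochs[cname] = (
                    sub_a.channel(cfg.analysis.electrode),
                    sub_b.channel(cfg.analysis.electrode),
                )
    return _SubjectResult(subject_id, age, gender, waveforms, roi, retention, trial_epochs)


def run_study(cfg: StudyConfig | None = None, out_dir: str | Path | None = None) -> StudyReport:
    """Execute the full chain for every simulated subject and task.

    Produces within-group condition contrasts (loss vs win for the
    disadvantageous and high-loss-frequency option pools; betrayal vs
    cooperation) and between-group anterior-cingulate ROI contrasts.
    """
    cfg = cfg or StudyConfig()
    violations = validate_config(cfg)
    if violations:
        raise ValueError("invalid study config: " + "; ".join(violations))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    try:
        sphere = default_sphere()
        montage = default_montage(sphere)
        space = build_source_space(sphere)
        lead = build_spherical_leadfield(montage, space, sphere)
    except Exception as err:  # pragma: no cover - geometry defaults are valid
        raise StageError("forward-model", err) from err

    subjects: dict[str, list[_SubjectResult]] = {}
    excluded: dict[str, list[str]] = {}
    for group, n in cfg.groups.items():
        subjects[group] = []
        excluded[group] = []
        for i in range(n):
            sid = f"{group}-{i:02d}"
            try:
                res = _run_subject(cfg, group, sid, lead, montage, sphere, space)
            except Exception as err:
                raise StageError(f"subject:{sid}", err) from err
            if res is None:
                excluded[group].append(sid)
            else:
                subjects[group].append(res)

    contrasts_report: dict = {}
    roi_report: dict = {}
    covariates_report: dict = {}
    retention_report: dict = {}
    for group, subs in subjects.items():
        contrasts_report[group] = {}
        roi_report[group] = {}
        covariates_report[group] = {}
        retention_report[group] = {}
        if not subs:
            continue
        all_contrasts = sorted({c for s in subs for c in s.waveforms})
        for cname in all_contrasts:
            have = [s for s in subs if cname in s.waveforms]
            if cfg.unit == "subjects":
                A = np.vstack([s.waveforms[cname]["A"] for s in have])
                B = np.vstack([s.waveforms[cname]["B"] for s in have])
            else:
                A = np.vstack([s.trial_epochs[cname][0] for s in have])
                B = np.vstack([s.trial_epochs[cname][1] for s in have])
            times = have[0].waveforms[cname]["times"]
            try:
                res = montecarlo_bootstrap_test(A, B, cfg.analysis, times=times)
            except ValueError as err:
                logger.warning("contrast %s in group %s skipped: %s", cname, group, err)
                continue
            contrasts_report[group][cname] = res.to_dict()
            roi_report[group][cname] = [s.roi[cname] for s in have if cname in s.roi]
            # per-subject feedback-negativity modulation (A - B window mean)
            w0, w1 = cfg.analysis.fern_window_ms
            wmask = (times >= w0) & (times < w1)
            per_subj = (A[:, wmask] - B[:, wmask]).mean(axis=1)
            covariates_report[group][cname] = covariate_checks(
                per_subj,
                np.array([s.age for s in have]),
                np.array([s.gender for s in have]),
            )
        for task in cfg.tasks:
            agg: dict = {}
            for s in subs:
                for cond, (tot, kept) in s.retention.get(task, {}).items():
                    t0, k0 = agg.get(cond, (0, 0))
                    agg[cond] = (t0 + tot, k0 + kept)
            retention_report[group][task] = {c: list(v) for c, v in agg.items()}

    group_comparisons: dict = {}
    group_names = list(subjects)
    all_contrasts = sorted({c for g in roi_report.values() for c in g})
    for cname in all_contrasts:
        group_comparisons[cname] = {}
        for i, ga in enumerate(group_names):
            for gb in group_names[i + 1 :]:
                a = roi_report.get(ga, {}).get(cname)
                b = roi_report.get(gb, {}).get(cname)
                if not a or not b or len(a) < 2 or len(b) < 2:
                    continue
                cmpres = mannwhitney_groups(np.array(a), np.array(b))
                group_comparisons[cname][f"{ga}_vs_{gb}"] = cmpres.to_dict()

    cfg_dict = _config_to_dict(cfg)
    report = StudyReport(
        config=cfg_dict,
        contrasts=contrasts_report,
        roi_scalars=roi_report,
        group_comparisons=group_comparisons,
        retention=retention_report,
        covariates=covariates_report,
        excluded_subjects=excluded,
    )
    if out_dir is not None:
        report.save(out_dir / "study_report.json")
    return report


def _config_to_dict(cfg: StudyConfig) -> dict:
    d = dataclasses.asdict(cfg)
    pm = d["pdg"]["payoff_matrix"]
    d["pdg"]["payoff_matrix"] = {f"{a}{b}": v for (a, b), v in pm.items()}
    return json.loads(json.dumps(d, default=str))
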