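"""Condition averaging, feedback-negativity scoring and the bootstrap
Monte Carlo waveform test.

The test follows the resampling recipe standard in small-sample ERP work:
data from both conditions are pooled, resampled **with replacement** and split
into the original group sizes; a two-sample t statistic per timepoint over the
5000 resamples forms the null distribution. Pointwise two-sided Monte Carlo
p-values use the add-one convention (1 + exceedances) / (1 + B). Alongside the
raw pointwise mask (whose contiguous runs are the reported temporal extents),
a max-|t|-corrected p-value controls the familywise error over the scoring
window. A label-permutation null is available as a sensitivity variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import EpochSet, Montage

__all__ = [
    "ERP",
    "AnalysisConfig",
    "PermTestResult",
    "average_condition",
    "fern_amplitude",
    "montecarlo_bootstrap_test",
    "cohens_d",
    "difference_topography",
    "covariate_checks",
]


@dataclass
class ERP:
    """Condition-average waveform (channels x time) with provenance."""

    condition: str
    data: np.ndarray  # (n_channels, n_times) µV
    times: np.ndarray  # ms
    montage: Montage
    n_epochs: int
    options: tuple[str, ...] = ()  # task options pooled into this condition

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.montage.index(name)]


@dataclass(frozen=True)
class AnalysisConfig:
    electrode: str = "Fz"
    fern_window_ms: tuple[float, float] = (250.0, 400.0)
    n_resamples: int = 5000
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> list[str]:
        p = []
        if self.fern_window_ms[0] >= self.fern_window_ms[1]:
            p.append("window reversed")
        if self.n_resamples < 1:
            p.append("n_resamples must be >= 1")
        if not 0 < self.alpha < 1:
            p.append("alpha must be in (0, 1)")
        return p


@dataclass
class PermTestResult:
    """Pointwise curves and the summary statistics at maximal difference."""

    times: np.ndarray  # ms, timepoints inside the scoring window
    t_obs: np.ndarray  # observed two-sample t per timepoint
    p: np.ndarray  # pointwise Monte Carlo p (two-sided, add-one)
    p_corrected: np.ndarray  # max-|t|-corrected p per timepoint
    mask: np.ndarray  # p < alpha
    mask_corrected: np.ndarray
    extents_ms: list[tuple[float, float]]  # contiguous significant runs
    max_diff_time_ms: float
    t_at_max: float
    p_at_max: float
    d_at_max: float
    diff: np.ndarray  # mean(A) - mean(B) per timepoint
    n_a: int
    n_b: int
    n_resamples: int
    seed: int
    alpha: float
    null: str = "bootstrap"

    @property
    def significant(self) -> bool:
        """Familywise-calibrated decision: any corrected rejection in window."""
        return bool(self.mask_corrected.any())

    def to_dict(self) -> dict:
        return {
            "times_ms": self.times.tolist(),
            "t_obs": self.t_obs.tolist(),
            "p": self.p.tolist(),
            "p_corrected": self.p_corrected.tolist(),
            "mask": self.mask.astype(int).tolist(),
            "mask_corrected": self.mask_corrected.astype(int).tolist(),
            "extents_ms": [list(e) for e in self.extents_ms],
            "max_diff_time_ms": self.max_diff_time_ms,
            "t_at_max": self.t_at_max,
            "p_at_max": self.p_at_max,
            "d_at_max": self.d_at_max,
            "diff": self.diff.tolist(),
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_resamples": self.n_resamples,
            "seed": self.seed,
            "alpha": self.alpha,
            "null": self.null,
            "significant": self.significant,
        }


def average_condition(epochs: EpochSet, label: str | list[str]) -> ERP:
    """Pointwise mean over surviving epochs with the given label(s).

    A condition may pool several task options (e.g. the two disadvantageous
    decks of the two task versions); pass them as a list.
    """
    labels = [label] if isinstance(label, str) else list(label)
    sub = epochs.select(labels)
    if sub.n_epochs == 0:
        raise ValueError(f"no surviving epochs for condition {labels}")
    return ERP(
        condition="+".join(labels),
        data=sub.data.mean(axis=0),
        times=sub.times,
        montage=sub.montage,
        n_epochs=sub.n_epochs,
        options=tuple(labels),
    )


def fern_amplitude(erp: ERP, cfg: AnalysisConfig | None = None) -> float:
    """Mean amplitude at the scoring electrode over the feedback-negativity
    window (half-open [250, 400) ms by default)."""
    cfg = cfg or AnalysisConfig()
    w0, w1 = cfg.fern_window_ms
    mask = (erp.times >= w0) & (erp.times < w1)
    if not mask.any():
        raise ValueError("scoring window outside the epoch time axis")
    return float(erp.channel(cfg.electrode)[mask].mean())


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference with (n-1)-pooled SD; NaN if SD is zero."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 observations")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def _tstat(a_sum, a_sq, na, b_sum, b_sq, nb):
    """Pooled-variance two-sample t from sums and sums of squares.

    Degenerate (zero pooled variance) cases yield t = 0.
    """
    ma, mb = a_sum / na, b_sum / nb
    va = (a_sq - na * ma**2) / (na - 1)
    vb = (b_sq - nb * mb**2) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    sp2 = np.clip(sp2, 0.0, None)  # guard float-error negatives in degenerate resamples
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (ma - mb) / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def _runs_to_extents(mask: np.ndarray, times: np.ndarray) -> list[tuple[float, float]]:
    extents = []
    i = 0
    while i < len(mask):
        if mask[i]:
            j = i
            while j + 1 < len(mask) and mask[j + 1]:
                j += 1
            extents.append((float(times[i]), float(times[j])))
            i = j + 1
        else:
            i += 1
    return extents


def montecarlo_bootstrap_test(
    epochs_a: np.ndarray | EpochSet,
    epochs_b: np.ndarray | EpochSet,
    cfg: AnalysisConfig | None = None,
    times: np.ndarray | None = None,
    null: str = "bootstrap",
) -> PermTestResult:
    """Two-condition waveform test with a resampling null.

    Inputs are either ``EpochSet`` objects (the scoring electrode is
    extracted) or already-extracted (units x time) arrays — units may be
    trials or per-subject condition averages. With ``null="bootstrap"``
    (default) the null draws with replacement from the pooled sample; with
    ``null="permutation"`` it shuffles labels without replacement.
    """
    cfg = cfg or AnalysisConfig()
    problems = cfg.validate()
    if problems:
        raise ValueError("; ".join(problems))
    if null not in ("bootstrap", "permutation"):
        raise ValueError(f"unknown null {null!r}")
    if cfg.n_resamples < 100:
        import warnings

        warnings.warn(f"n_resamples={cfg.n_resamples} is very small", stacklevel=2)

    if isinstance(epochs_a, EpochSet):
        if times is None:
            times = epochs_a.times
        epochs_a = epochs_a.channel(cfg.electrode)[epochs_a.kept]
    if isinstance(epochs_b, EpochSet):
        epochs_b = epochs_b.channel(cfg.electrode)[epochs_b.kept]
    a = np.atleast_2d(np.asarray(epochs_a, float))
    b = np.atleast_2d(np.asarray(epochs_b, float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("conditions have different time axes")
    if times is None:
        times = np.arange(a.shape[1], dtype=float)
    times = np.asarray(times, float)
    w0, w1 = cfg.fern_window_ms
    win = (times >= w0) & (times < w1)
    if not win.any():
        raise ValueError("scoring window contains no timepoints")
    a = a[:, win]
    b = b[:, win]
    wt = times[win]
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each condition needs at least 2 units")

    t_obs = _tstat(
        a.sum(0), (a**2).sum(0), na, b.sum(0), (b**2).sum(0), nb
    )

    pooled = np.vstack([a, b])
    n = na + nb
    rng = np.random.default_rng(cfg.seed)
    B = cfg.n_resamples
    exceed = np.zeros(len(wt))
    exceed_max = np.zeros(len(wt))
    abs_t_obs = np.abs(t_obs)
    # chunked to bound memory at ~ chunk * n * n_t doubles
    chunk = max(1, int(2_000_000 / (n * len(wt))))
    done = 0
    while done < B:
        m = min(chunk, B - done)
        if null == "bootstrap":
            idx = rng.integers(0, n, size=(m, n))
        else:
            idx = np.argsort(rng.random((m, n)), axis=1)
        sample = pooled[idx]  # (m, n, n_t)
        ga, gb = sample[:, :na], sample[:, na:]
        t_null = _tstat(
            ga.sum(1), (ga**2).sum(1), na, gb.sum(1), (gb**2).sum(1), nb
        )
        abs_null = np.abs(t_null)
        exceed += (abs_null >= abs_t_obs[None, :]).sum(axis=0)
        exceed_max += (abs_null.max(axis=1)[:, None] >= abs_t_obs[None, :]).sum(axis=0)
        done += m

    p = (1.0 + exceed) / (1.0 + B)
    p_corr = (1.0 + exceed_max) / (1.0 + B)
    mask = p < cfg.alpha
    mask_corr = p_corr < cfg.alpha

    diff = a.mean(0) - b.mean(0)
    k = int(np.argmax(np.abs(diff)))
    return PermTestResult(
        times=wt,
        t_obs=t_obs,
        p=p,
        p_corrected=p_corr,
        mask=mask,
        mask_corrected=mask_corr,
        extents_ms=_runs_to_extents(mask, wt),
        max_diff_time_ms=float(wt[k]),
        t_at_max=float(t_obs[k]),
        p_at_max=float(p[k]),
        d_at_max=cohens_d(a[:, k], b[:, k]),
        diff=diff,
        n_a=na,
        n_b=nb,
        n_resamples=B,
        seed=cfg.seed,
        alpha=cfg.alpha,
        null=null,
    )


def difference_topography(erp_a: ERP, erp_b: ERP, t_ms: float) -> np.ndarray:
    """Channel-wise (A - B) map at the requested timepoint (nearest sample)."""
    if erp_a.montage is not erp_b.montage and tuple(erp_a.montage.names) != tuple(
        erp_b.montage.names
    ):
        raise ValueError("ERPs use different montages")
    if not np.array_equal(erp_a.times, erp_b.times):
        raise ValueError("ERPs use different time axes")
    if t_ms < erp_a.times[0] or t_ms > erp_a.times[-1]:
        raise ValueError(f"timepoint {t_ms} ms outside the epoch")
    k = int(np.argmin(np.abs(erp_a.times - t_ms)))
    return erp_a.data[:, k] - erp_b.data[:, k]


def covariate_checks(
    measures: np.ndarray,
    ages: np.ndarray,
    genders: np.ndarray,
) -> dict:
    """Demographic nuisance checks within one group.

    Rank (Spearman) correlation between age and the EEG measure, and a
    Mann-Whitney contrast of the measure between genders. A constant measure
    yields an 'undefined' flag instead of a correlation.
    """
    from .source import mannwhitney_groups

    measures = np.asarray(measures, float)
    ages = np.asarray(ages, float)
    genders = np.asarray(genders)
    if len(measures) != len(ages) or len(measures) != len(genders):
        raise ValueError("measures, ages and genders must have equal length")
    out: dict = {"n": len(measures)}
    if len(measures) < 3 or np.ptp(measures) == 0 or np.ptp(ages) == 0:
        out["age_correlation"] = None
        out["age_p"] = None
        out["undefined"] = True
    else:
        rho, p = stats.spearmanr(ages, measures)
        out["age_correlation"] = float(rho)
        out["age_p"] = float(p)
        out["undefined"] = False
    levels = sorted(set(genders.tolist()))
    if len(levels) == 2:
        g0 = measures[genders == levels[0]]
        g1 = measures[genders == levels[1]]
        if len(g0) >= 2 and len(g1) >= 2 and (np.ptp(measures) > 0):
            cmpres = mannwhitney_groups(g0, g1)
            out["gender_contrast"] = {
                "levels": [str(levels[0]), str(levels[1])],
                "U": cmpres.U,
                "p": cmpres.p,
                "r": cmpres.r,
            }
        else:
            out["gender_contrast"] = None
    else:
        out["gender_contrast"] = None
    return out
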