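"""Preprocessing chain: downsample, bandpass, mastoid re-reference, epoch,
baseline-correct, artifact rejection.

Defaults follow the standard feedback-ERP recipe: 1024 Hz acquisition
downsampled to 256 Hz, 0.5–20 Hz zero-phase bandpass, algebraic re-reference
to averaged mastoids, epochs of −200..800 ms around feedback onset,
baseline −200..0 ms, and threshold-based epoch rejection (peak-to-peak and
sample-to-sample gradient).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import ContinuousEEG, EpochSet

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocConfig",
    "downsample",
    "bandpass",
    "rereference_mastoids",
    "extract_epochs",
    "baseline_correct",
    "reject_artifacts",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocConfig:
    target_fs: float = 256.0
    band: tuple[float, float] = (0.5, 20.0)
    epoch_window_ms: tuple[float, float] = (-200.0, 800.0)
    baseline_window_ms: tuple[float, float] = (-200.0, 0.0)
    ptp_threshold_uv: float = 100.0
    gradient_threshold_uv: float = 50.0  # per sample

    def validate(self) -> list[str]:
        p = []
        lo, hi = self.band
        if not 0 < lo < hi:
            p.append("band must satisfy 0 < low < high")
        if hi >= self.target_fs / 2:
            p.append("band high must be below the target Nyquist frequency")
        w0, w1 = self.epoch_window_ms
        if not w0 < 0 < w1:
            p.append("epoch window must contain 0" if w0 < w1 else "window reversed")
        b0, b1 = self.baseline_window_ms
        if not (b0 < b1):
            p.append("baseline window reversed")
        elif not (w0 <= b0 and b1 <= w1):
            p.append("baseline window must lie inside the epoch window")
        if self.ptp_threshold_uv <= 0 or self.gradient_threshold_uv <= 0:
            p.append("rejection thresholds must be positive")
        return p


def downsample(raw: ContinuousEEG, target_fs: float = 256.0) -> ContinuousEEG:
    """Anti-aliased decimation to ``target_fs``; event samples are remapped.

    An 8th-order zero-phase Butterworth low-pass at 0.4 * target_fs precedes
    decimation. Non-integer ratios fall back to polyphase resampling.
    """
    if target_fs > raw.fs:
        raise ValueError(f"target_fs {target_fs} exceeds sampling rate {raw.fs}")
    if target_fs == raw.fs:
        return raw.copy()
    ratio = raw.fs / target_fs
    if abs(ratio - round(ratio)) < 1e-9:
        q = int(round(ratio))
        sos = signal.butter(8, 0.4 * target_fs, btype="low", fs=raw.fs, output="sos")
        filtered = signal.sosfiltfilt(sos, raw.data, axis=1)
        data = filtered[:, ::q]
    else:
        from fractions import Fraction

        frac = Fraction(target_fs / raw.fs).limit_denominator(1000)
        data = signal.resample_poly(raw.data, frac.numerator, frac.denominator, axis=1)
    events = raw.events.copy()
    if len(events):
        events["sample"] = np.round(
            events["sample"].to_numpy() * (target_fs / raw.fs)
        ).astype(int)
        events = events[events["sample"] < data.shape[1]]
    return ContinuousEEG(data=data, fs=target_fs, montage=raw.montage, events=events)


def bandpass(raw: ContinuousEEG, low: float = 0.5, high: float = 20.0) -> ContinuousEEG:
    """Zero-phase (forward-backward) 4th-order Butterworth bandpass."""
    if not 0 < low < high < raw.fs / 2:
        raise ValueError(f"invalid band ({low}, {high}) for fs={raw.fs}")
    sos = signal.butter(4, [low, high], btype="band", fs=raw.fs, output="sos")
    data = signal.sosfiltfilt(sos, raw.data, axis=1)
    return ContinuousEEG(data=data, fs=raw.fs, montage=raw.montage, events=raw.events.copy())


def rereference_mastoids(raw: ContinuousEEG) -> ContinuousEEG:
    """Subtract the instantaneous mean of the two mastoids from every channel."""
    i1, i2 = raw.montage.mastoid_indices
    ref = 0.5 * (raw.data[i1] + raw.data[i2])
    return ContinuousEEG(
        data=raw.data - ref[None, :], fs=raw.fs, montage=raw.montage, events=raw.events.copy()
    )


def extract_epochs(
    raw: ContinuousEEG,
    window_ms: tuple[float, float] = (-200.0, 800.0),
    usable_only: bool = True,
) -> EpochSet:
    """Cut one epoch per usable feedback event.

    The window is half-open, [start, stop): at 256 Hz a −200..800 ms window
    yields exactly 256 samples, the first at −200 ms. With ``usable_only``,
    events whose ``correct`` flag is False (wrong control-question answers)
    are dropped before epoching. Events too close to the recording edge are
    skipped with reason "boundary".
    """
    if len(raw.events) == 0:
        raise ValueError("no events to epoch")
    w0, w1 = window_ms
    if not w0 < w1:
        raise ValueError("epoch window reversed")
    events = raw.events
    if usable_only and "correct" in events.columns:
        events = events[events["correct"].astype(bool)]
    if len(events) == 0:
        raise ValueError("no usable events to epoch")
    s_pre = int(round(-w0 / 1000.0 * raw.fs))
    n_t = int(round((w1 - w0) / 1000.0 * raw.fs))
    times = (np.arange(n_t) - s_pre) / raw.fs * 1000.0

    chunks, labels = [], []
    n_skipped = 0
    for _, ev in events.iterrows():
        s0 = int(ev["sample"]) - s_pre
        if s0 < 0 or s0 + n_t > raw.n_samples:
            n_skipped += 1
            continue
        chunks.append(raw.data[:, s0 : s0 + n_t])
        labels.append(ev["condition"])
    if n_skipped:
        logger.info("skipped %d events at recording boundary", n_skipped)
    if not chunks:
        raise ValueError("all events fell outside the recording (boundary)")
    return EpochSet(
        data=np.stack(chunks),
        times=times,
        labels=np.array(labels, dtype=object),
        montage=raw.montage,
        fs=raw.fs,
    )


def baseline_correct(
    epochs: EpochSet, window_ms: tuple[float, float] = (-200.0, 0.0)
) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over the baseline window."""
    if epochs.baseline_applied:
        raise ValueError("baseline correction already applied")
    b0, b1 = window_ms
    mask = (epochs.times >= b0) & (epochs.times < b1)
    if not mask.any():
        raise ValueError("baseline window outside the epoch time axis")
    out = epochs.copy()
    out.data = out.data - out.data[:, :, mask].mean(axis=2, keepdims=True)
    out.baseline_applied = True
    return out


def reject_artifacts(
    epochs: EpochSet,
    ptp_threshold_uv: float = 100.0,
    gradient_threshold_uv: float = 50.0,
    manual_reject: list[int] | None = None,
) -> EpochSet:
    """Flag epochs exceeding peak-to-peak or gradient thresholds on any channel.

    ``manual_reject`` adds explicit epoch indices (the manual-override hook of
    the quasi-automated procedure). Retained counts per condition are logged.
    """
    if ptp_threshold_uv <= 0 or gradient_threshold_uv <= 0:
        raise ValueError("thresholds must be positive")
    out = epochs.copy()
    ptp = out.data.max(axis=2) - out.data.min(axis=2)  # (epochs, channels)
    grad = np.abs(np.diff(out.data, axis=2)).max(axis=2) if out.n_times > 1 else np.zeros_like(ptp)
    bad_ptp = (ptp > ptp_threshold_uv).any(axis=1)
    bad_grad = (grad > gradient_threshold_uv).any(axis=1)
    for i in range(out.n_epochs):
        if bad_ptp[i] or bad_grad[i]:
            out.rejected[i] = True
            out.rejection_reason[i] = "ptp" if bad_ptp[i] else "gradient"
    for i in manual_reject or []:
        out.rejected[i] = True
        out.rejection_reason[i] = "manual"
    if out.rejected.all():
        logger.warning("all epochs rejected at the given thresholds")
    kept = out.labels[out.kept]
    for cond in sorted(set(out.labels)):
        logger.info(
            "condition %s: kept %d / %d epochs",
            cond,
            int((kept == cond).sum()),
            int((out.labels == cond).sum()),
        )
    return out


def preprocess(raw: ContinuousEEG, config: PreprocConfig | None = None) -> EpochSet:
    """Full chain: downsample → bandpass → mastoid reference → epoch →
    baseline → artifact rejection."""
    config = config or PreprocConfig()
    problems = config.validate()
    if problems:
        raise ValueError("; ".join(problems))
    x = downsample(raw, config.target_fs)
    x = bandpass(x, *config.band)
    x = rereference_mastoids(x)
    ep = extract_epochs(x, config.epoch_window_ms)
    ep = baseline_correct(ep, config.baseline_window_ms)
    ep = reject_artifacts(ep, config.ptp_threshold_uv, config.gradient_threshold_uv)
    return ep
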