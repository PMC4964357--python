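"""Synthetic feedback-locked high-density EEG.

At every feedback onset of a simulated task session, a negative mediofrontal
deflection (the feedback negativity) is injected by forward-projecting a
transient dipole at an anterior-cingulate proxy location through the spherical
head model. The deflection's amplitude is scaled per trial by the outcome
condition and by the participant group profile:

* ``control`` — losses > wins and betrayal > cooperation (prosocial pattern);
* ``adhd``    — no condition modulation (and overall reduced amplitude);
* ``asd``     — losses > wins but cooperation > betrayal (self-gain pattern).

Background activity is 1/f ("pink") noise with a white floor, independently
per channel, plus optional frontally weighted blink transients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ContinuousEEG, Montage
from .headmodel import SphereModel, SourceSpace, default_sphere, dipole_potential
from .tasks import TaskSession

__all__ = [
    "ERPTemplate",
    "NoiseParams",
    "GROUP_PROFILES",
    "synthesize_eeg",
    "pink_noise",
]

#: condition gain maps implementing the three group response patterns.
#: Gains multiply the (negative) base amplitude; a larger gain means a larger
#: feedback negativity for that outcome.
GROUP_PROFILES: dict[str, dict[str, float]] = {
    "control": {"loss": 1.0, "win": 0.35, "betray": 1.0, "cooperate": 0.35},
    "adhd": {"loss": 0.55, "win": 0.55, "betray": 0.55, "cooperate": 0.55},
    "asd": {"loss": 1.0, "win": 0.35, "betray": 0.35, "cooperate": 1.0},
}


@dataclass(frozen=True)
class ERPTemplate:
    """Feedback-negativity generator description.

    ``base_amplitude_uv`` is the (negative) peak potential, in microvolts,
    that a gain-1.0 trial produces at Fz after averaged-mastoid referencing;
    the dipole moment is normalized to achieve exactly that, so condition
    contrasts are controlled on the scale they are measured.
    """

    peak_latency_ms: float = 330.0
    width_ms: float = 45.0  # Gaussian SD of the deflection
    base_amplitude_uv: float = -6.0
    condition_gain: dict[str, float] = field(
        default_factory=lambda: dict(GROUP_PROFILES["control"])
    )
    dipole_pos: np.ndarray | None = None  # ACC proxy; default from source space
    dipole_ori: np.ndarray | None = None  # unit; default radial

    def __post_init__(self) -> None:
        if not 0 < self.width_ms:
            raise ValueError("width must be positive")
        if self.base_amplitude_uv > 0:
            raise ValueError("base amplitude must be negative (a negativity) or zero")

    def gain_for(self, outcome: str) -> float:
        if outcome not in self.condition_gain:
            raise KeyError(f"no condition gain for outcome {outcome!r}")
        return self.condition_gain[outcome]

    @staticmethod
    def for_profile(profile: str, **kwargs) -> "ERPTemplate":
        if profile not in GROUP_PROFILES:
            raise KeyError(f"unknown group profile {profile!r}")
        return ERPTemplate(condition_gain=dict(GROUP_PROFILES[profile]), **kwargs)

    def waveform(self, t_s: np.ndarray) -> np.ndarray:
        """Unit-peak deflection sampled at times ``t_s`` (seconds post feedback)."""
        mu = self.peak_latency_ms / 1000.0
        sd = self.width_ms / 1000.0
        return np.exp(-0.5 * ((t_s - mu) / sd) ** 2)


@dataclass(frozen=True)
class NoiseParams:
    rms_uv: float = 10.0  # broadband RMS per channel
    slope: float = 1.0  # 1/f^slope spectral shape
    white_fraction: float = 0.2  # share of variance in the white floor
    blink_rate_hz: float = 0.03  # expected blinks per second (0 disables)
    blink_amplitude_uv: float = 120.0
    blink_width_s: float = 0.2

    def validate(self) -> list[str]:
        p = []
        if self.rms_uv < 0:
            p.append("noise RMS must be non-negative")
        if not 0 <= self.white_fraction <= 1:
            p.append("white_fraction must be in [0, 1]")
        if self.blink_rate_hz < 0:
            p.append("blink rate must be non-negative")
        return p


class DurationError(ValueError):
    pass


def pink_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    fs: float,
    rms: float,
    slope: float = 1.0,
    white_fraction: float = 0.2,
) -> np.ndarray:
    """1/f^slope noise with a white floor, unit-free RMS ``rms`` per channel."""
    if rms == 0:
        return np.zeros((n_channels, n_samples))
    from scipy import fft as sfft

    n_fft = sfft.next_fast_len(n_samples, real=True)
    freqs = np.fft.rfftfreq(n_fft, 1.0 / fs)
    # amplitude shape: 1/f^slope power component plus a white floor, each
    # normalized to unit average power so white_fraction splits the variance
    colored = np.zeros_like(freqs)
    colored[1:] = freqs[1:] ** (-slope)
    colored /= colored.mean()
    shape = np.sqrt((1.0 - white_fraction) * colored + white_fraction).astype(np.float32)
    n_f = len(freqs)
    g = rng.standard_normal((n_channels, 2 * n_f), dtype=np.float32)
    spectrum = (g[:, :n_f] + 1j * g[:, n_f:]) * shape[None, :]
    out = np.ascontiguousarray(sfft.irfft(spectrum, n=n_fft, axis=1)[:, :n_samples])
    out *= (rms / (out.std(axis=1, keepdims=True) + 1e-30)).astype(out.dtype)
    return out


def _blink_topography(montage: Montage) -> np.ndarray:
    """Frontally weighted blink projection (max near the eyes, ~0 posterior)."""
    pos = montage.positions
    r = np.linalg.norm(pos, axis=1, keepdims=True)
    d = pos / r
    eye_dir = np.array([0.0, 0.95, 0.31])  # just above the nasion
    w = np.clip(d @ eye_dir, 0.0, None) ** 3
    return w


def synthesize_eeg(
    session: TaskSession,
    template: ERPTemplate,
    montage: Montage,
    noise_params: NoiseParams | None = None,
    seed: int = 0,
    fs: float = 1024.0,
    sphere: SphereModel | None = None,
    source_space: SourceSpace | None = None,
    duration_s: float | None = None,
) -> ContinuousEEG:
    """Render a task session as continuous 130-channel EEG at ``fs`` Hz.

    Each feedback onset adds the template deflection, scaled by the trial's
    condition gain, forward-projected from the ACC-proxy dipole. The event
    table carries one marker per feedback onset with the trial's condition
    label and control-question correctness.
    """
    noise_params = noise_params or NoiseParams()
    problems = noise_params.validate()
    if problems:
        raise ValueError("; ".join(problems))
    sphere = sphere or default_sphere()
    rng = np.random.default_rng(seed)

    onsets = session.feedback_onsets()
    tail = template.peak_latency_ms / 1000.0 + 5 * template.width_ms / 1000.0 + 1.0
    needed = float(onsets[-1]) + tail
    if duration_s is None:
        duration_s = needed
    elif duration_s < needed:
        raise DurationError(
            f"session needs {needed:.1f}s of recording but only {duration_s:.1f}s requested"
        )
    n_samples = int(round(duration_s * fs))

    # dipole location/orientation: ACC-proxy centroid, radial, unless overridden
    if template.dipole_pos is None:
        space = source_space
        if space is None:
            from .headmodel import build_source_space

            space = build_source_space(sphere)
        acc = space.roi_indices("ACC")
        dip_pos = space.positions[acc].mean(axis=0)
    else:
        dip_pos = np.asarray(template.dipole_pos, float)
    if template.dipole_ori is None:
        # inward radial, matching the source-space normal convention
        dip_ori = -dip_pos / np.linalg.norm(dip_pos)
    else:
        dip_ori = np.asarray(template.dipole_ori, float)
        dip_ori = dip_ori / np.linalg.norm(dip_ori)

    # unit-moment scalp pattern, averaged-mastoid referenced, normalized so a
    # gain-1 trial peaks at base_amplitude_uv on Fz
    pattern = dipole_potential(sphere, dip_pos[None, :], dip_ori[None, :], montage.positions)
    pattern = pattern[:, 0] * 1e6  # µV per unit moment
    i1, i2 = montage.mastoid_indices
    pattern = pattern - 0.5 * (pattern[i1] + pattern[i2])
    fz_gain = pattern[montage.index("Fz")]
    if abs(fz_gain) < 1e-30:
        raise ValueError("degenerate forward pattern: zero Fz gain")
    pattern = pattern * (template.base_amplitude_uv / fz_gain)

    data = pink_noise(
        rng,
        montage.n_channels,
        n_samples,
        fs,
        noise_params.rms_uv,
        noise_params.slope,
        noise_params.white_fraction,
    )

    # one template support, added at each onset
    sup_len = int(round(tail * fs))
    t_sup = np.arange(sup_len) / fs
    wave = template.waveform(t_sup)
    rows = []
    for tr in session.trials:
        s0 = int(round(tr.feedback_onset * fs))
        seg = min(sup_len, n_samples - s0)
        if seg <= 0:
            continue
        g = template.gain_for(tr.outcome)
        data[:, s0 : s0 + seg] += g * pattern[:, None] * wave[None, :seg]
        rows.append(
            {
                "onset_s": tr.feedback_onset,
                "sample": s0,
                "trial_index": tr.index,
                "condition": tr.condition,
                "payoff": tr.payoff,
                "correct": True
                if tr.control_question_correct is None
                else bool(tr.control_question_correct),
            }
        )

    if noise_params.blink_rate_hz > 0 and noise_params.blink_amplitude_uv > 0:
        topo = _blink_topography(montage)
        n_blinks = rng.poisson(noise_params.blink_rate_hz * duration_s)
        b_len = int(round(noise_params.blink_width_s * 2 * fs))
        t_b = np.arange(b_len) / fs
        shape = np.hanning(b_len)
        for _ in range(n_blinks):
            s0 = rng.integers(0, max(1, n_samples - b_len))
            amp = noise_params.blink_amplitude_uv * rng.uniform(0.7, 1.3)
            data[:, s0 : s0 + b_len] += amp * topo[:, None] * shape[None, :]

    events = pd.DataFrame(rows)
    return ContinuousEEG(data=data, fs=fs, montage=montage, events=events)
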