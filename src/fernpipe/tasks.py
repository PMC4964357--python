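"""Simulators for the two reward paradigms.

Monetary task: a two-deck, two-version children's gambling task. Each version
pairs an advantageous deck (positive long-term profit) with a disadvantageous
one (negative long-term profit); win size and frequency are identical across
decks and versions while loss size/frequency differ, giving exactly one
high-loss-frequency deck per version. Cumulative feedback appears every 20
choices; each version ends after the 8th cumulative display (160 trials).

Social task: an observed, rigged two-player Prisoner's Dilemma. The fair
player cooperates on a fixed fraction of trials (72.5%) and the unfair player
betrays on 67.5%; the participant is rewarded with the fair player's points,
so fair-player cooperation pays less (3 points) than fair-player betrayal
(6 points). A comprehension question follows every trial; only correct-answer
trials enter the EEG analysis and participants with extreme omission error
rates (>70%) are excluded.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DeckSchedule",
    "IGTConfig",
    "PDGConfig",
    "TrialRecord",
    "TaskSession",
    "simulate_igt_session",
    "simulate_pdg_session",
    "filter_participants_by_omission",
    "default_igt_decks",
]


class ConfigurationError(ValueError):
    """Raised when a task configuration violates its invariants."""


class ParadigmError(ValueError):
    """Raised when an operation receives a session from the wrong paradigm."""


@dataclass(frozen=True)
class DeckSchedule:
    """Payoff schedule of one deck.

    Every selected card wins ``win_amount`` with probability ``win_freq`` and
    (independently) loses ``loss_amount`` with probability ``loss_freq``.
    """

    name: str
    win_amount: float
    win_freq: float
    loss_amount: float
    loss_freq: float
    advantageous: bool  # long-term profit sign: True = AD, False = DD
    high_loss_freq: bool

    @property
    def expected_payoff(self) -> float:
        return self.win_amount * self.win_freq - self.loss_amount * self.loss_freq

    def validate(self) -> list[str]:
        problems = []
        for nm, f in (("win_freq", self.win_freq), ("loss_freq", self.loss_freq)):
            if not 0.0 <= f <= 1.0:
                problems.append(f"deck {self.name}: {nm}={f} outside [0, 1]")
        if self.win_amount == 0 and self.loss_amount == 0:
            # degenerate all-zero schedule: allowed for bookkeeping tests
            return problems
        ev = self.expected_payoff
        if self.advantageous and ev <= 0:
            problems.append(f"deck {self.name}: advantageous but expected payoff {ev} <= 0")
        if not self.advantageous and ev >= 0:
            problems.append(f"deck {self.name}: disadvantageous but expected payoff {ev} >= 0")
        if self.loss_freq > 0 and self.loss_amount <= self.win_amount * self.win_freq:
            problems.append(
                f"deck {self.name}: loss amount must exceed the concurrent win "
                "so displayed losses are net losses"
            )
        return problems


def default_igt_decks() -> tuple[tuple[DeckSchedule, DeckSchedule], ...]:
    """Default deck pairs for the two task versions.

    Win size/frequency (5 units on every card) are constant everywhere; losses
    vary so each version pairs one advantageous with one disadvantageous deck
    and contains exactly one high-loss-frequency deck.
    """
    v1 = (
        DeckSchedule("v1-AD", 5.0, 1.0, 25.0, 0.1, advantageous=True, high_loss_freq=False),
        DeckSchedule("v1-DD", 5.0, 1.0, 25.0, 0.5, advantageous=False, high_loss_freq=True),
    )
    v2 = (
        DeckSchedule("v2-AD", 5.0, 1.0, 7.5, 0.5, advantageous=True, high_loss_freq=True),
        DeckSchedule("v2-DD", 5.0, 1.0, 125.0, 0.1, advantageous=False, high_loss_freq=False),
    )
    return (v1, v2)


@dataclass(frozen=True)
class IGTConfig:
    n_trials_per_version: int = 160
    block_len: int = 20
    initial_capital: float = 120.0
    deck_schedules: tuple[tuple[DeckSchedule, DeckSchedule], ...] = field(
        default_factory=default_igt_decks
    )
    n_versions: int = 2
    # screen timing (seconds); only feedback-locking depends on these
    iti_range: tuple[float, float] = (1.5, 2.5)
    cumulative_screen_s: float = 2.0

    def validate(self) -> list[str]:
        problems = []
        if self.n_trials_per_version <= 0:
            problems.append("n_trials_per_version must be positive")
        if self.block_len <= 0 or self.n_trials_per_version % self.block_len:
            problems.append("block_len must divide n_trials_per_version")
        if not 1 <= self.n_versions <= len(self.deck_schedules):
            problems.append("n_versions exceeds available deck schedules")
        win_sig = {
            (d.win_amount, d.win_freq)
            for pair in self.deck_schedules[: self.n_versions]
            for d in pair
        }
        if len(win_sig) > 1:
            problems.append("win amount/frequency must be identical across decks and versions")
        for pair in self.deck_schedules[: self.n_versions]:
            if sum(d.high_loss_freq for d in pair) != 1:
                problems.append("each version needs exactly one high-loss-frequency deck")
            for d in pair:
                problems.extend(d.validate())
        if not (0 < self.iti_range[0] <= self.iti_range[1]):
            problems.append("iti_range must be positive and ordered")
        return problems


@dataclass(frozen=True)
class PDGConfig:
    n_trials: int = 160
    cumulative_block: int = 40
    fair_coop_rate: float = 0.725
    unfair_betray_rate: float = 0.675
    #: participant points by (fair action, unfair action); C = cooperate, D = betray.
    #: The participant is paid the fair player's points, which in this rigged
    #: variant depend only on the fair player's own action: cooperation 3, betrayal 6.
    payoff_matrix: dict = field(
        default_factory=lambda: {("C", "C"): 3.0, ("C", "D"): 3.0, ("D", "C"): 6.0, ("D", "D"): 6.0}
    )
    control_question_error_rate: float = 0.0
    iti_range: tuple[float, float] = (1.5, 2.5)
    cumulative_screen_s: float = 2.0

    def validate(self) -> list[str]:
        problems = []
        if self.n_trials <= 0:
            problems.append("n_trials must be positive")
        if self.cumulative_block <= 0 or self.n_trials % self.cumulative_block:
            problems.append("cumulative_block must divide n_trials")
        for nm in ("fair_coop_rate", "unfair_betray_rate", "control_question_error_rate"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                problems.append(f"proportion out of range: {nm}={v}")
        keys = {("C", "C"), ("C", "D"), ("D", "C"), ("D", "D")}
        if set(self.payoff_matrix) != keys:
            problems.append("payoff_matrix must cover the 4 joint-action cells")
        else:
            coop = [self.payoff_matrix[("C", a)] for a in "CD"]
            betray = [self.payoff_matrix[("D", a)] for a in "CD"]
            if not min(betray) > max(coop):
                problems.append("fair-player betrayal must pay more than cooperation")
        if not (0 < self.iti_range[0] <= self.iti_range[1]):
            problems.append("iti_range must be positive and ordered")
        return problems


@dataclass(frozen=True)
class TrialRecord:
    index: int
    paradigm: str  # "IGT" | "PDG"
    choice: str  # deck name, or joint action "C/D" pair for PDG
    condition: str  # event label, e.g. "igt/v1-DD/loss" or "pdg/cooperate"
    outcome: str  # "win"/"loss" or "cooperate"/"betray"
    payoff: float
    feedback_onset: float  # seconds from recording start
    control_question_correct: bool | None = None  # PDG only


@dataclass
class TaskSession:
    participant_id: str
    paradigm: str
    group_profile: str  # "control" | "adhd" | "asd"
    config: IGTConfig | PDGConfig
    trials: list[TrialRecord]
    cumulative_feedback_times: list[float]
    seed: int
    final_capital: float | None = None  # IGT only

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def feedback_onsets(self) -> np.ndarray:
        return np.array([t.feedback_onset for t in self.trials])

    def omission_error_rate(self) -> float:
        if self.paradigm != "PDG":
            raise ParadigmError("omission errors are defined for PDG sessions only")
        wrong = sum(not t.control_question_correct for t in self.trials)
        return wrong / len(self.trials)


def _check(config) -> None:
    problems = config.validate()
    if problems:
        raise ConfigurationError("; ".join(problems))


def _draw_onsets(rng: np.random.Generator, n_trials: int, block: int, iti_range, extra: float):
    """Strictly increasing feedback onsets with jittered inter-trial intervals
    and an extra gap after every cumulative-feedback display."""
    itis = rng.uniform(iti_range[0], iti_range[1], size=n_trials)
    onsets = np.empty(n_trials)
    t = itis[0]
    cumulative_times = []
    for i in range(n_trials):
        if i:
            t += itis[i]
        onsets[i] = t
        if (i + 1) % block == 0:
            cumulative_times.append(t + 0.75)
            t += extra
    return onsets, cumulative_times


def simulate_igt_session(
    config: IGTConfig | None = None,
    policy: str = "uniform-random",
    seed: int = 0,
    participant_id: str = "sim",
    group_profile: str = "control",
) -> TaskSession:
    """Simulate one gambling-task session (all versions back to back).

    ``policy`` is either ``"uniform-random"`` (both decks equally often) or
    ``"loss-frequency-avoidant"``, the strategy children typically adopt:
    prefer the deck that is neither disadvantageous nor high-loss-frequency.
    """
    config = config or IGTConfig()
    _check(config)
    if policy not in ("uniform-random", "loss-frequency-avoidant"):
        raise ConfigurationError(f"unknown policy {policy!r}")
    rng = np.random.default_rng(seed)

    trials: list[TrialRecord] = []
    cumulative: list[float] = []
    capital = config.initial_capital
    t_offset = 0.0
    idx = 0
    for v in range(config.n_versions):
        decks = config.deck_schedules[v]
        onsets, cum = _draw_onsets(
            rng, config.n_trials_per_version, config.block_len,
            config.iti_range, config.cumulative_screen_s,
        )
        onsets = onsets + t_offset
        cumulative.extend(c + t_offset for c in cum)
        if policy == "uniform-random":
            p_pick = np.full(len(decks), 1.0 / len(decks))
        else:
            # avoid disadvantageous and high-loss-frequency options, softly
            weights = np.array(
                [0.15 if (not d.advantageous or d.high_loss_freq) else 0.7 for d in decks]
            )
            p_pick = weights / weights.sum()
        picks = rng.choice(len(decks), size=config.n_trials_per_version, p=p_pick)
        for i, k in enumerate(picks):
            deck = decks[k]
            win = rng.random() < deck.win_freq
            lose = rng.random() < deck.loss_freq
            payoff = deck.win_amount * win - deck.loss_amount * lose
            # the feedback screen shows a loss whenever a loss card is drawn
            outcome = "loss" if lose else "win"
            capital += payoff
            trials.append(
                TrialRecord(
                    index=idx,
                    paradigm="IGT",
                    choice=deck.name,
                    condition=f"igt/{deck.name}/{outcome}",
                    outcome=outcome,
                    payoff=payoff,
                    feedback_onset=onsets[i],
                )
            )
            idx += 1
        t_offset = onsets[-1] + config.cumulative_screen_s + 3.0
    return TaskSession(
        participant_id=participant_id,
        paradigm="IGT",
        group_profile=group_profile,
        config=config,
        trials=trials,
        cumulative_feedback_times=cumulative,
        seed=seed,
        final_capital=capital,
    )


def simulate_pdg_session(
    config: PDGConfig | None = None,
    seed: int = 0,
    participant_id: str = "sim",
    group_profile: str = "control",
) -> TaskSession:
    """Simulate one observed Prisoner's Dilemma session.

    Rigging is exact: the fair player cooperates on exactly
    ``round(fair_coop_rate * n_trials)`` trials and the unfair player betrays
    on exactly ``round(unfair_betray_rate * n_trials)`` trials, orders
    permuted independently by ``seed``.
    """
    config = config or PDGConfig()
    _check(config)
    rng = np.random.default_rng(seed)
    n = config.n_trials

    n_coop = round(config.fair_coop_rate * n)
    n_betray = round(config.unfair_betray_rate * n)
    fair = np.array(["C"] * n_coop + ["D"] * (n - n_coop))
    unfair = np.array(["D"] * n_betray + ["C"] * (n - n_betray))
    rng.shuffle(fair)
    rng.shuffle(unfair)
    correct = rng.random(n) >= config.control_question_error_rate

    onsets, cumulative = _draw_onsets(
        rng, n, config.cumulative_block, config.iti_range, config.cumulative_screen_s
    )
    trials = []
    for i in range(n):
        joint = (fair[i], unfair[i])
        outcome = "cooperate" if fair[i] == "C" else "betray"
        trials.append(
            TrialRecord(
                index=i,
                paradigm="PDG",
                choice=f"{fair[i]}/{unfair[i]}",
                condition=f"pdg/{outcome}",
                outcome=outcome,
                payoff=config.payoff_matrix[joint],
                feedback_onset=onsets[i],
                control_question_correct=bool(correct[i]),
            )
        )
    return TaskSession(
        participant_id=participant_id,
        paradigm="PDG",
        group_profile=group_profile,
        config=config,
        trials=trials,
        cumulative_feedback_times=cumulative,
        seed=seed,
    )


def filter_participants_by_omission(
    sessions: list[TaskSession], threshold: float = 0.70
) -> tuple[list[TaskSession], list[TaskSession]]:
    """Partition PDG sessions into (retained, excluded) by omission-error rate.

    A session is excluded when its control-question error proportion is
    *strictly greater* than ``threshold`` (default 70%). Downstream analysis
    uses only correct-response trials of retained sessions.
    """
    retained, excluded = [], []
    for s in sessions:
        if s.paradigm != "PDG":
            raise ParadigmError(f"session {s.participant_id} is not a PDG session")
        (excluded if s.omission_error_rate() > threshold else retained).append(s)
    return retained, excluded


def session_to_frame(session: TaskSession, fs: float | None = None):
    """Trial/event table (one row per trial) as a DataFrame.

    With ``fs`` given, adds the integer sample index of each feedback onset.
    """
    import pandas as pd

    rows = {
        "onset_s": [t.feedback_onset for t in session.trials],
        "trial_index": [t.index for t in session.trials],
        "condition": [t.condition for t in session.trials],
        "payoff": [t.payoff for t in session.trials],
        "correct": [
            True if t.control_question_correct is None else bool(t.control_question_correct)
            for t in session.trials
        ],
    }
    df = pd.DataFrame(rows)
    if fs is not None:
        df.insert(1, "sample", np.round(df["onset_s"].to_numpy() * fs).astype(int))
    return df


def session_metadata(session: TaskSession) -> dict:
    """JSON-serializable session metadata (configs and seeds included)."""
    cfg = dataclasses.asdict(session.config)
    if isinstance(session.config, PDGConfig):
        cfg["payoff_matrix"] = {f"{a}{b}": v for (a, b), v in cfg["payoff_matrix"].items()}
    return {
        "participant_id": session.participant_id,
        "paradigm": session.paradigm,
        "group_profile": session.group_profile,
        "seed": session.seed,
        "n_trials": session.n_trials,
        "final_capital": session.final_capital,
        "cumulative_feedback_times": list(map(float, session.cumulative_feedback_times)),
        "config": cfg,
    }
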