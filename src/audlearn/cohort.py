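"""Synthetic cohorts for an auditory category-learning experiment.

The experiment this generator emulates presents frequency-modulated tones
that vary in five dichotomous features: duration (short 400 ms / long
800 ms), direction of pitch change (up / down), loudness (76-81 dB /
86-91 dB), frequency band (five low, 500-831 Hz, or five high,
1630-2639 Hz centre frequencies) and modulation speed (0.25 / 0.5 oct/s) —
160 distinct tones in total.  Duration and direction jointly define the
target category; each participant is assigned one of four target
configurations and one response button, then works through 240 trials of
which 25% are targets, pseudo-randomised so that every 10-trial block
holds each duration x direction combination two or three times.

No generative model of participant behaviour is published for this task,
so the simulator here adopts a per-block latent Markov chain over three
performance states (low / med / high) with Bernoulli trial emissions whose
per-state hit and correct-rejection probabilities default to the state
means recovered by the mixture analysis in :mod:`audlearn.states`.  That
closes the loop: cohorts simulated at those emission means are the natural
fixture for state-recovery tests downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StimulusTone",
    "Trial",
    "ParticipantRecord",
    "LearnerProfile",
    "CohortEffects",
    "CONFIG_TARGETS",
    "STATES",
    "DEFAULT_ALLOCATION",
    "DEFAULT_EFFECTS",
    "enumerate_tones",
    "make_schedule",
    "simulate_participant",
    "generate_cohort",
    "default_learner_profile",
    "default_nonlearner_profile",
    "cohort_to_frame",
    "frame_to_records",
    "write_trial_log",
    "read_trial_log",
]

DURATIONS = ("short", "long")  # 400 ms / 800 ms
DIRECTIONS = ("up", "down")
LOUDNESS_BANDS = ("low", "high")  # 76-81 dB / 86-91 dB
SPEEDS = ("slow", "fast")  # 0.25 / 0.5 oct/s

# Five centre frequencies per band, log-spaced across the published ranges.
LOW_FREQS_HZ = (500, 569, 647, 735, 831)
HIGH_FREQS_HZ = (1630, 1839, 2074, 2340, 2639)
ALL_FREQS_HZ = LOW_FREQS_HZ + HIGH_FREQS_HZ

#: Target configuration id -> (duration, direction) defining the category.
CONFIG_TARGETS: dict[int, tuple[str, str]] = {
    1: ("short", "up"),
    2: ("short", "down"),
    3: ("long", "up"),
    4: ("long", "down"),
}

BUTTONS = ("left", "right")
LABELS = ("L", "notL")
RESPONSES = ("target_button", "nontarget_button", "none")

#: Latent performance states, in fixed index order.
STATES = ("low", "med", "high")

#: Default per-state hit probability on target trials (low, med, high).
DEFAULT_HIT_PROB = (0.358, 0.6922, 1.0)
#: Default per-state correct-rejection probability on non-target trials.
DEFAULT_CR_PROB = (0.5916, 0.8351, 1.0)

#: (config, button) -> (n_L, n_notL); reproduces the experiment's published
#: allocation of 76 participants.
DEFAULT_ALLOCATION: dict[tuple[int, str], tuple[int, int]] = {
    (1, "left"): (10, 0),
    (1, "right"): (9, 1),
    (2, "left"): (8, 0),
    (2, "right"): (6, 5),
    (3, "left"): (8, 1),
    (3, "right"): (6, 3),
    (4, "left"): (6, 2),
    (4, "right"): (9, 2),
}

TRIALS_PER_SESSION = 240
TRIALS_PER_BLOCK = 10
BLOCKS_PER_SESSION = TRIALS_PER_SESSION // TRIALS_PER_BLOCK

_PROB_ATOL = 1e-12


@dataclass(frozen=True)
class StimulusTone:
    """One frequency-modulated tone, identified by its five features."""

    duration: str
    direction: str
    loudness: str
    freq_hz: int
    speed: str

    def __post_init__(self) -> None:
        if self.duration not in DURATIONS:
            raise ValueError(f"unknown duration {self.duration!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.loudness not in LOUDNESS_BANDS:
            raise ValueError(f"unknown loudness {self.loudness!r}")
        if self.freq_hz not in ALL_FREQS_HZ:
            raise ValueError(f"unknown frequency {self.freq_hz!r}")
        if self.speed not in SPEEDS:
            raise ValueError(f"unknown speed {self.speed!r}")

    @property
    def freq_band(self) -> str:
        return "low" if self.freq_hz in LOW_FREQS_HZ else "high"


@dataclass(frozen=True)
class Trial:
    """One stimulus presentation and the participant's response to it."""

    index: int  # 1-based within the session
    tone: StimulusTone
    is_target: bool
    response: str
    correct: bool


@dataclass
class ParticipantRecord:
    """A participant's full session: metadata plus 240 ordered trials."""

    id: str
    config: int
    button: str
    label: str
    trials: list[Trial]
    latent_states: tuple[str, ...] | None = None  # per-block, simulation only

    def __post_init__(self) -> None:
        if self.config not in CONFIG_TARGETS:
            raise ValueError(f"unknown config {self.config!r}")
        if self.button not in BUTTONS:
            raise ValueError(f"unknown button {self.button!r}")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def enumerate_tones() -> list[StimulusTone]:
    """Enumerate the full stimulus space: 2x2x2x2x10 = 160 distinct tones."""
    tones = []
    for dur, dirn, loud, freq, speed in product(
        DURATIONS, DIRECTIONS, LOUDNESS_BANDS, ALL_FREQS_HZ, SPEEDS
    ):
        tones.append(StimulusTone(dur, dirn, loud, freq, speed))
    return tones


def _as_seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(int(seed))


def make_schedule(config: int, seed) -> list[tuple[StimulusTone, bool]]:
    """Build a pseudo-randomised 240-trial schedule for one participant.

    Exactly 25% of trials (60) are targets.  Each duration x direction
    combination occurs 60 times over the session and two or three times in
    every 10-trial block; this is enforced by giving each combination
    exactly five slots per 20-trial window, split 2/3 or 3/2 at random
    between the window's two blocks.  Loudness, frequency and modulation
    speed are sampled uniformly and independently.
    """
    if config not in CONFIG_TARGETS:
        raise ValueError(f"config must be one of {sorted(CONFIG_TARGETS)}, got {config!r}")
    rng = np.random.default_rng(_as_seed_sequence(seed))
    combos = list(product(DURATIONS, DIRECTIONS))
    target_combo = CONFIG_TARGETS[config]

    schedule: list[tuple[StimulusTone, bool]] = []
    for _window in range(TRIALS_PER_SESSION // (2 * TRIALS_PER_BLOCK)):
        # two of the four combos get 3 slots in the window's first block
        rich = rng.choice(4, size=2, replace=False)
        first_counts = [3 if i in rich else 2 for i in range(4)]
        for counts in (first_counts, [5 - c for c in first_counts]):
            block = [i for i, c in enumerate(counts) for _ in range(c)]
            rng.shuffle(block)
            for combo_idx in block:
                dur, dirn = combos[combo_idx]
                tone = StimulusTone(
                    duration=dur,
                    direction=dirn,
                    loudness=LOUDNESS_BANDS[rng.integers(2)],
                    freq_hz=ALL_FREQS_HZ[rng.integers(10)],
                    speed=SPEEDS[rng.integers(2)],
                )
                schedule.append((tone, (dur, dirn) == target_combo))
    return schedule


def _check_stochastic(matrix: np.ndarray, name: str) -> None:
    if matrix.shape != (3, 3):
        raise ValueError(f"{name} must be 3x3, got {matrix.shape}")
    if np.any(matrix < 0) or np.any(matrix > 1):
        raise ValueError(f"{name} entries must lie in [0, 1]")
    if not np.allclose(matrix.sum(axis=1), 1.0, atol=_PROB_ATOL):
        raise ValueError(f"{name} rows must sum to 1")


@dataclass
class LearnerProfile:
    """Behavioural profile: a 3-state block-level Markov chain with
    Bernoulli emissions.

    States are indexed (low, med, high).  ``hit_prob[s]`` is the
    probability of pressing the target button on a target trial in state
    ``s``; ``cr_prob[s]`` the probability of pressing the non-target
    button on a non-target trial.  ``config_effect`` and ``button_effect``
    are additive shifts applied to every transition probability into the
    high state (clipped, then row-renormalised) and model task-design
    influences on learning.
    """

    initial_state_distribution: np.ndarray
    transition_matrix: np.ndarray
    hit_prob: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_HIT_PROB))
    cr_prob: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_CR_PROB))
    config_effect: float = 0.0
    button_effect: float = 0.0

    def __post_init__(self) -> None:
        self.initial_state_distribution = np.asarray(
            self.initial_state_distribution, dtype=float
        )
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.hit_prob = np.asarray(self.hit_prob, dtype=float)
        self.cr_prob = np.asarray(self.cr_prob, dtype=float)
        if self.initial_state_distribution.shape != (3,):
            raise ValueError("initial_state_distribution must have length 3")
        if np.any(self.initial_state_distribution < 0) or not np.isclose(
            self.initial_state_distribution.sum(), 1.0, atol=_PROB_ATOL
        ):
            raise ValueError("initial_state_distribution must be a probability vector")
        _check_stochastic(self.transition_matrix, "transition_matrix")
        for name, p in (("hit_prob", self.hit_prob), ("cr_prob", self.cr_prob)):
            if p.shape != (3,) or np.any(p < 0) or np.any(p > 1):
                raise ValueError(f"{name} must be 3 probabilities in [0, 1]")

    def effective_transition_matrix(self) -> np.ndarray:
        """Transition matrix after applying the additive high-state shift."""
        delta = self.config_effect + self.button_effect
        t = self.transition_matrix.copy()
        t[:, 2] = np.clip(t[:, 2] + delta, 0.0, 1.0)
        return t / t.sum(axis=1, keepdims=True)

    def with_effects(self, config_effect: float, button_effect: float) -> "LearnerProfile":
        return dataclasses.replace(
            self, config_effect=config_effect, button_effect=button_effect
        )


def default_learner_profile() -> LearnerProfile:
    """Profile of a participant who discovers the rule: transitions drift
    toward the high state and stick there."""
    return LearnerProfile(
        initial_state_distribution=np.array([0.45, 0.45, 0.10]),
        transition_matrix=np.array(
            [
                [0.50, 0.40, 0.10],
                [0.05, 0.55, 0.40],
                [0.02, 0.08, 0.90],
            ]
        ),
    )


def default_nonlearner_profile() -> LearnerProfile:
    """Profile of a participant who never isolates the rule: the high
    state is rarely reached and never absorbing."""
    return LearnerProfile(
        initial_state_distribution=np.array([0.55, 0.45, 0.00]),
        transition_matrix=np.array(
            [
                [0.60, 0.38, 0.02],
                [0.30, 0.65, 0.05],
                [0.30, 0.50, 0.20],
            ]
        ),
    )


@dataclass(frozen=True)
class CohortEffects:
    """Additive high-state transition shifts by config and by button."""

    config: Mapping[int, float] = field(default_factory=dict)
    button: Mapping[str, float] = field(default_factory=dict)


#: Default design effects: the left response button and the long/up target
#: configuration modestly favour reaching the high state, mirroring the
#: direction of the effects the original analysis reported.
DEFAULT_EFFECTS = CohortEffects(config={3: 0.06}, button={"left": 0.05})


def simulate_participant(
    profile: LearnerProfile,
    config: int,
    button: str,
    seed,
    *,
    participant_id: str = "p000",
    label: str = "L",
) -> ParticipantRecord:
    """Simulate one participant's 240-trial session.

    The latent state is drawn once per 10-trial block from the profile's
    Markov chain; each response is a Bernoulli draw from the state's hit
    (target trials) or correct-rejection (non-target trials) probability.
    Correctness is recomputed from the response, never assumed.
    """
    if button not in BUTTONS:
        raise ValueError(f"unknown button {button!r}")
    ss = _as_seed_sequence(seed)
    sched_ss, resp_ss = ss.spawn(2)
    schedule = make_schedule(config, sched_ss)
    rng = np.random.default_rng(resp_ss)

    tmat = profile.effective_transition_matrix()
    states = np.empty(BLOCKS_PER_SESSION, dtype=int)
    states[0] = rng.choice(3, p=profile.initial_state_distribution)
    for b in range(1, BLOCKS_PER_SESSION):
        states[b] = rng.choice(3, p=tmat[states[b - 1]])

    trials: list[Trial] = []
    for i, (tone, is_target) in enumerate(schedule, start=1):
        s = states[(i - 1) // TRIALS_PER_BLOCK]
        if is_target:
            pressed_target = rng.random() < profile.hit_prob[s]
        else:
            pressed_target = not (rng.random() < profile.cr_prob[s])
        response = "target_button" if pressed_target else "nontarget_button"
        correct = (is_target and response == "target_button") or (
            not is_target and response == "nontarget_button"
        )
        trials.append(Trial(i, tone, is_target, response, correct))

    return ParticipantRecord(
        id=participant_id,
        config=config,
        button=button,
        label=label,
        trials=trials,
        latent_states=tuple(STATES[s] for s in states),
    )


def generate_cohort(
    allocation: Mapping[tuple[int, str], tuple[int, int]] | None = None,
    effects: CohortEffects | None = None,
    master_seed: int = 0,
    *,
    learner_profile: LearnerProfile | None = None,
    nonlearner_profile: LearnerProfile | None = None,
) -> list[ParticipantRecord]:
    """Generate a cohort under a (config, button) -> (n_L, n_notL) allocation.

    The default allocation reproduces the experiment's published table: 76
    participants, 35 left / 41 right button, 62 L / 14 notL.  Per-participant
    seeds are spawned deterministically from ``master_seed``.
    """
    if allocation is None:
        allocation = DEFAULT_ALLOCATION
    if effects is None:
        effects = DEFAULT_EFFECTS
    if learner_profile is None:
        learner_profile = default_learner_profile()
    if nonlearner_profile is None:
        nonlearner_profile = default_nonlearner_profile()
    for counts in allocation.values():
        if counts[0] < 0 or counts[1] < 0:
            raise ValueError("allocation counts must be non-negative")

    cells = sorted(allocation.items())
    n_total = sum(nl + nn for _, (nl, nn) in cells)
    seeds = _as_seed_sequence(master_seed).spawn(n_total)

    records: list[ParticipantRecord] = []
    i = 0
    for (config, button), (n_l, n_notl) in cells:
        ce = effects.config.get(config, 0.0)
        be = effects.button.get(button, 0.0)
        for label, n, base in (
            ("L", n_l, learner_profile),
            ("notL", n_notl, nonlearner_profile),
        ):
            prof = base.with_effects(ce, be)
            for _ in range(n):
                records.append(
                    simulate_participant(
                        prof,
                        config,
                        button,
                        seeds[i],
                        participant_id=f"p{i + 1:03d}",
                        label=label,
                    )
                )
                i += 1
    return records


# ---------------------------------------------------------------------------
# trial-log I/O (tidy CSV, one row per trial)

TRIAL_LOG_COLUMNS = [
    "participant_id",
    "config",
    "button",
    "label",
    "trial_index",
    "duration",
    "direction",
    "loudness_band",
    "freq_hz",
    "speed",
    "is_target",
    "response",
    "correct",
]


def cohort_to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for t in rec.trials:
            rows.append(
                (
                    rec.id,
                    rec.config,
                    rec.button,
                    rec.label,
                    t.index,
                    t.tone.duration,
                    t.tone.direction,
                    t.tone.loudness,
                    t.tone.freq_hz,
                    t.tone.speed,
                    t.is_target,
                    t.response,
                    t.correct,
                )
            )
    return pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[ParticipantRecord]:
    """Rebuild participant records from a tidy trial log; correctness is
    recomputed from response and target flag."""
    records = []
    for pid, grp in frame.groupby("participant_id", sort=False):
        grp = grp.sort_values("trial_index")
        meta = grp.iloc[0]
        trials = []
        for row in grp.itertuples(index=False):
            tone = StimulusTone(
                row.duration, row.direction, row.loudness_band, int(row.freq_hz), row.speed
            )
            is_target = bool(row.is_target)
            correct = (is_target and row.response == "target_button") or (
                not is_target and row.response == "nontarget_button"
            )
            trials.append(Trial(int(row.trial_index), tone, is_target, row.response, correct))
        records.append(
            ParticipantRecord(
                id=str(pid),
                config=int(meta.config),
                button=str(meta.button),
                label=str(meta.label),
                trials=trials,
            )
        )
    return records


def write_trial_log(records_or_frame, path) -> None:
    frame = (
        records_or_frame
        if isinstance(records_or_frame, pd.DataFrame)
        else cohort_to_frame(records_or_frame)
    )
    frame.to_csv(path, index=False)


def read_trial_log(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(TRIAL_LOG_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"trial log missing columns: {sorted(missing)}")
    return frame
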