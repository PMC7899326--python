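"""Experiment layout: participants x days x (2 sessions x 5 trials).

The layout mirrors a within-subject eye-typing fatigue study: each day one
seating of two sessions, five typing-from-memory trials per session, a 5 s
inter-trial break, and an easy/difficult sentence-set manipulation whose
order is balanced across participants and days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

EASY, DIFFICULT = "easy", "difficult"


@dataclass(frozen=True)
class TrialSlot:
    participant: str
    day: int  # 1-based
    session: int  # 1 or 2
    trial_in_session: int  # 1..trials_per_session
    trial_of_day: int  # time-on-task, 1..(sessions*trials)
    difficulty: str
    language: str


@dataclass(frozen=True)
class ExperimentDesign:
    """Static layout of one experiment.

    ``difficulty_order[(participant, day)]`` gives the per-session
    difficulty tags for that seating; orders are balanced so that over the
    participant pool easy-first and difficult-first days occur equally often.
    """

    participants: tuple[str, ...]
    days_per_participant: int
    sessions_per_day: int = 2
    trials_per_session: int = 5
    difficulty_order: dict = field(default_factory=dict)
    language: dict = field(default_factory=dict)
    inter_trial_break: float = 5.0
    sampling_rate: float = 90.0

    def __post_init__(self) -> None:
        if len(self.participants) < 1 or self.days_per_participant < 1:
            raise ValueError("participants and days must be positive")
        if self.sessions_per_day < 1 or self.trials_per_session < 1:
            raise ValueError("sessions and trials must be positive")
        if self.inter_trial_break <= 0.300:
            raise ValueError(
                "inter-trial break must exceed 0.300 s (baseline-pupil window)"
            )

    @property
    def trials_per_day(self) -> int:
        return self.sessions_per_day * self.trials_per_session

    @property
    def n_trials(self) -> int:
        return (
            len(self.participants)
            * self.days_per_participant
            * self.trials_per_day
        )

    def iter_trials(self) -> Iterator[TrialSlot]:
        for pid in self.participants:
            for day in range(1, self.days_per_participant + 1):
                order = self.difficulty_order[(pid, day)]
                tod = 0
                for sess in range(1, self.sessions_per_day + 1):
                    diff = order[(sess - 1) % len(order)]
                    for tr in range(1, self.trials_per_session + 1):
                        tod += 1
                        yield TrialSlot(
                            participant=pid,
                            day=day,
                            session=sess,
                            trial_in_session=tr,
                            trial_of_day=tod,
                            difficulty=diff,
                            language=self.language[pid],
                        )


def build_experiment_design(
    n_participants: int,
    n_days: int,
    seed: int,
    *,
    sessions_per_day: int = 2,
    trials_per_session: int = 5,
    inter_trial_break: float = 5.0,
    sampling_rate: float = 90.0,
    english_fraction: float = 10 / 18,
) -> ExperimentDesign:
    """Build a balanced experiment design.

    Difficulty order alternates with participant and day parity so
    easy-first and difficult-first seatings are balanced across the pool;
    a seeded draw assigns ``english_fraction`` of participants to English
    and the rest to Danish.  Deterministic given ``seed``.
    """
    if n_participants < 1 or n_days < 1:
        raise ValueError("n_participants and n_days must be >= 1")
    rng = np.random.default_rng(seed)
    pids = tuple(f"P{i + 1:02d}" for i in range(n_participants))

    order: dict = {}
    for i, pid in enumerate(pids):
        for day in range(1, n_days + 1):
            if (i + day) % 2 == 0:
                order[(pid, day)] = (EASY, DIFFICULT)
            else:
                order[(pid, day)] = (DIFFICULT, EASY)

    n_english = int(round(english_fraction * n_participants))
    english_ids = set(rng.choice(n_participants, size=n_english, replace=False))
    language = {
        pid: ("english" if i in english_ids else "danish")
        for i, pid in enumerate(pids)
    }

    return ExperimentDesign(
        participants=pids,
        days_per_participant=n_days,
        sessions_per_day=sessions_per_day,
        trials_per_session=trials_per_session,
        difficulty_order=order,
        language=language,
        inter_trial_break=inter_trial_break,
        sampling_rate=sampling_rate,
    )
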