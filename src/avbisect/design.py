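"""Session designs for the temporal and spatial bisection tasks.

A design fixes the conflict levels, the number of trials per interleaved
condition, the stimulus timing constants, and the adaptive-procedure
parameters used when simulating a session.  The two default designs mirror
the study layout: a temporal task with 5 conditions (vision, audition and
three audio-visual conflicts at half-conflict Δ = −50, 0, +50 ms) and a
spatial task with 7 conditions (vision, audition and five conflicts at
Δ = 0, ±4.5°, ±9° of visual-component displacement).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

TIME = "time"
SPACE = "space"
DOMAINS = (TIME, SPACE)

VISUAL = "visual"
AUDITORY = "auditory"
BIMODAL = "bimodal"
CONDITIONS = (VISUAL, AUDITORY, BIMODAL)


@dataclass(frozen=True)
class TaskDesign:
    """Layout of one bisection session.

    Parameters
    ----------
    domain:
        ``"time"`` (units ms) or ``"space"`` (units deg).
    conflicts:
        Bimodal conflict levels.  Time: half-conflict of the second
        stimulus in ms (outer stimuli carry −Δ, so the effective
        audio-visual separation of the probe is 2Δ).  Space: displacement
        of the visual component in deg (auditory at −Δ).
    trials_per_condition:
        Trials per interleaved condition (30 in the study).
    total_duration_ms:
        Duration of the three-stimulus sequence (1000 ms in both tasks).
    second_onset_ms:
        Nominal onset of the second stimulus relative to the first
        (500 ms; in the spatial task the second stimulus always occurs
        exactly there, in the temporal task it is the quantity the probe
        offset perturbs).
    quest_prior_mean, quest_prior_sd:
        Gaussian prior of each adaptive track over the bisection point.
    quest_assumed_slope:
        σ of the cumulative-Gaussian likelihood assumed by the adaptive
        procedure, of the order of child unimodal thresholds.
    jitter_sd:
        SD of the zero-mean Gaussian jitter added to every adaptive
        recommendation so that the flanks of the psychometric function
        are sampled.
    """

    domain: str
    conflicts: Tuple[float, ...]
    trials_per_condition: int = 30
    total_duration_ms: float = 1000.0
    second_onset_ms: float = 500.0
    quest_prior_mean: float = 0.0
    quest_prior_sd: float = 200.0
    quest_assumed_slope: float = 120.0
    jitter_sd: float = 100.0
    unit: str = "ms"

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.trials_per_condition <= 0:
            raise ValueError("trials_per_condition must be positive")
        if len(self.conflicts) == 0:
            raise ValueError("at least one bimodal conflict level is required")
        if self.quest_prior_sd <= 0 or self.quest_assumed_slope <= 0:
            raise ValueError("QUEST scale parameters must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be nonnegative")

    @classmethod
    def time(cls, **overrides) -> "TaskDesign":
        """Default temporal design: 5 conditions x 30 trials = 150 trials."""
        return replace(
            cls(
                domain=TIME,
                conflicts=(-50.0, 0.0, 50.0),
                quest_prior_sd=200.0,
                quest_assumed_slope=120.0,
                jitter_sd=100.0,
                unit="ms",
            ),
            **overrides,
        )

    @classmethod
    def space(cls, **overrides) -> "TaskDesign":
        """Default spatial design: 7 conditions x 30 trials = 210 trials."""
        return replace(
            cls(
                domain=SPACE,
                conflicts=(-9.0, -4.5, 0.0, 4.5, 9.0),
                quest_prior_sd=20.0,
                quest_assumed_slope=15.0,
                jitter_sd=10.0,
                unit="deg",
            ),
            **overrides,
        )

    @classmethod
    def for_domain(cls, domain: str, **overrides) -> "TaskDesign":
        if domain == TIME:
            return cls.time(**overrides)
        if domain == SPACE:
            return cls.space(**overrides)
        raise ValueError(f"unknown domain {domain!r}")

    @property
    def condition_keys(self) -> Tuple[Tuple[str, float], ...]:
        """All interleaved conditions as (condition, conflict) pairs."""
        keys = [(VISUAL, 0.0), (AUDITORY, 0.0)]
        keys.extend((BIMODAL, float(c)) for c in self.conflicts)
        return tuple(keys)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_keys)

    @property
    def n_trials(self) -> int:
        return self.n_conditions * self.trials_per_condition
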