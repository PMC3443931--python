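"""Generative observer models and session simulation for bisection tasks.

An observer sees three stimuli and reports whether the second appeared
closer to the first or to the third (response 1 = "closer to third";
positive probe offsets point toward the third stimulus — later in time, or
toward the last speaker in space).  Each modality delivers a noisy
estimate of the second stimulus's offset from that modality's own
first/third midpoint; the combination rule (optimal inverse-variance
weighting, visual or auditory capture, or fixed weights) turns the two
estimates into a decision variable whose sign determines the response.

Conflict geometry (the factor-2 bookkeeping lives here and only here):

* time — the stored conflict Δ is the *half*-conflict of the second
  stimulus: its auditory component occurs Δ ms after its visual component,
  while the first and third stimuli carry −Δ.  Relative to its own
  midpoint the visual cue sits at the probe offset x, the auditory cue at
  x + 2Δ (the outer −Δ shifts move the auditory midpoint to −Δ while the
  probe's auditory component is at x + Δ).
* space — the second stimulus's visual component is at x + Δ, its auditory
  component at x − Δ; the outer stimuli are audio-visually aligned, so
  both cues share the physical midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import ndtr

from .design import (
    AUDITORY,
    BIMODAL,
    CONDITIONS,
    DOMAINS,
    SPACE,
    TIME,
    VISUAL,
    TaskDesign,
)
from .mle import predict_bimodal_sigma, weights_from_thresholds
from .quest import QuestTrack

__all__ = [
    "RULES",
    "TrialSpec",
    "ObserverParams",
    "TrialRecord",
    "Session",
    "cue_offsets",
    "effective_weights",
    "effective_sigma",
    "response_probability",
    "simulate_trial",
    "simulate_responses",
    "simulate_training_screen",
    "simulate_session",
]

OPTIMAL = "optimal"
VISUAL_CAPTURE = "visual_capture"
AUDITORY_CAPTURE = "auditory_capture"
FIXED_WEIGHTS = "fixed_weights"
RULES = (OPTIMAL, VISUAL_CAPTURE, AUDITORY_CAPTURE, FIXED_WEIGHTS)


@dataclass(frozen=True)
class TrialSpec:
    """One bisection trial: what was presented.

    ``conflict`` is 0 for unimodal conditions by construction;
    ``probe_offset`` is the physical displacement of the second stimulus
    from the midpoint of the first and third (ms or deg).
    """

    domain: str
    condition: str
    conflict: float = 0.0
    probe_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.condition != BIMODAL and self.conflict != 0.0:
            raise ValueError("unimodal conditions must have conflict == 0")
        if not np.isfinite(self.probe_offset):
            raise ValueError("probe_offset must be finite")


@dataclass(frozen=True)
class ObserverParams:
    """Generative observer: unimodal noise and combination rule.

    ``sigma_v`` and ``sigma_a`` are the unimodal visual and auditory
    thresholds (σ of the internal noise, ms or deg).  ``lapse`` is the
    stimulus-independent guessing rate (the study's fits carry no lapse
    term, so it defaults to 0 and is bounded at 0.1 for robustness
    experiments only).
    """

    sigma_v: float
    sigma_a: float
    rule: str = OPTIMAL
    w_a_fixed: Optional[float] = None
    lapse: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sigma_v <= 0 or self.sigma_a <= 0:
            raise ValueError("unimodal sigmas must be positive")
        if self.rule not in RULES:
            raise ValueError(f"unknown combination rule {self.rule!r}")
        if self.rule == FIXED_WEIGHTS:
            if self.w_a_fixed is None or not 0.0 <= self.w_a_fixed <= 1.0:
                raise ValueError("fixed_weights requires w_a_fixed in [0, 1]")
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError("lapse must lie in [0, 0.1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class TrialRecord:
    """A trial plus the binary response (1 = second closer to third)."""

    spec: TrialSpec
    response: int

    def __post_init__(self) -> None:
        if self.response not in (0, 1):
            raise ValueError("response must be 0 or 1")


@dataclass
class Session:
    """All trials of one observer in one task, in presentation order."""

    observer_id: str
    age_group: str
    domain: str
    trials: List[TrialRecord]
    passed_training: bool = True

    def validate(self, design: Optional[TaskDesign] = None) -> None:
        if design is not None:
            if len(self.trials) != design.n_trials:
                raise ValueError(
                    f"session has {len(self.trials)} trials, design expects "
                    f"{design.n_trials}"
                )
        for t in self.trials:
            if t.spec.domain != self.domain:
                raise ValueError("trial domain does not match session domain")


def cue_offsets(spec: TrialSpec) -> Tuple[float, float]:
    """Offset of the second stimulus from each cue's *own* midpoint.

    Returns ``(offset_V, offset_A)``.  Unimodal and zero-conflict trials
    give (x, x); see the module docstring for the conflict geometry.
    """
    x, d = spec.probe_offset, spec.conflict
    if spec.condition != BIMODAL or d == 0.0:
        return (x, x)
    if spec.domain == TIME:
        return (x, x + 2.0 * d)
    return (x + d, x - d)


def effective_weights(params: ObserverParams) -> Tuple[float, float]:
    """(w_V, w_A) implied by the observer's combination rule."""
    if params.rule == OPTIMAL:
        w = weights_from_thresholds(params.sigma_v, params.sigma_a)
        return (w.w_v, w.w_a)
    if params.rule == VISUAL_CAPTURE:
        return (1.0, 0.0)
    if params.rule == AUDITORY_CAPTURE:
        return (0.0, 1.0)
    return (1.0 - params.w_a_fixed, params.w_a_fixed)


def effective_sigma(params: ObserverParams) -> float:
    """σ of the bimodal decision variable under the observer's rule."""
    if params.rule == OPTIMAL:
        return predict_bimodal_sigma(params.sigma_v, params.sigma_a)
    if params.rule == VISUAL_CAPTURE:
        return params.sigma_v
    if params.rule == AUDITORY_CAPTURE:
        return params.sigma_a
    w_v, w_a = effective_weights(params)
    return float(np.sqrt((w_v * params.sigma_v) ** 2 + (w_a * params.sigma_a) ** 2))


def response_probability(spec: TrialSpec, params: ObserverParams) -> float:
    """P(response = 1) = lapse/2 + (1 − lapse)·Φ(e/σ_eff)."""
    if spec.condition == VISUAL:
        e, s = spec.probe_offset, params.sigma_v
    elif spec.condition == AUDITORY:
        e, s = spec.probe_offset, params.sigma_a
    else:
        off_v, off_a = cue_offsets(spec)
        w_v, w_a = effective_weights(params)
        e = w_v * off_v + w_a * off_a
        s = effective_sigma(params)
    return float(params.lapse / 2.0 + (1.0 - params.lapse) * ndtr(e / s))


def simulate_trial(
    spec: TrialSpec, params: ObserverParams, rng: Optional[np.random.Generator] = None
) -> TrialRecord:
    """One Bernoulli draw from the observer model."""
    rng = params.rng() if rng is None else rng
    p = response_probability(spec, params)
    return TrialRecord(spec=spec, response=int(rng.random() < p))


def simulate_responses(
    spec: TrialSpec,
    params: ObserverParams,
    n: int,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """n i.i.d. responses at a fixed trial spec (vectorized)."""
    rng = params.rng() if rng is None else rng
    p = response_probability(spec, params)
    return (rng.random(n) < p).astype(int)


def simulate_training_screen(
    params: ObserverParams,
    domain: str = SPACE,
    n_trials: int = 10,
    pass_threshold: int = 7,
    easy_offset: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[int, bool]:
    """Simulate the training screen: n easy trials, pass at >= threshold correct.

    Each trial presents the probe at a maximal ("easy") offset whose sign
    is random; a response matching the sign is correct.  The study did not
    quantify the easy offset, so it defaults to 5·max(σ_V, σ_A), which
    makes an attentive observer's accuracy essentially 1.
    """
    if not n_trials >= pass_threshold >= 0:
        raise ValueError("need n_trials >= pass_threshold >= 0")
    rng = params.rng() if rng is None else rng
    easy = (
        5.0 * max(params.sigma_v, params.sigma_a)
        if easy_offset is None
        else float(easy_offset)
    )
    signs = np.where(rng.random(n_trials) < 0.5, -1.0, 1.0)
    p_plus = response_probability(
        TrialSpec(domain=domain, condition=BIMODAL, conflict=0.0, probe_offset=easy),
        params,
    )
    p_minus = response_probability(
        TrialSpec(domain=domain, condition=BIMODAL, conflict=0.0, probe_offset=-easy),
        params,
    )
    p1 = np.where(signs > 0, p_plus, p_minus)
    responses = (rng.random(n_trials) < p1).astype(int)
    correct = responses == (signs > 0).astype(int)
    n_correct = int(correct.sum())
    return n_correct, n_correct >= pass_threshold


def simulate_session(
    params: ObserverParams,
    design: TaskDesign,
    rng: Optional[np.random.Generator] = None,
    observer_id: str = "obs",
    age_group: str = "adult",
    run_training: bool = True,
) -> Session:
    """Simulate one full session with interleaved adaptive tracks.

    One QUEST-style track per condition (one per unisensory condition and
    one per bimodal conflict level) runs simultaneously; conditions are
    presented in a single randomized interleaving.  Each placement is the
    track's recommendation plus Gaussian jitter.  Fully reproducible given
    the generator (or ``params.seed``).
    """
    rng = params.rng() if rng is None else rng
    keys = design.condition_keys
    tracks = {
        key: QuestTrack.create(
            prior_mean=design.quest_prior_mean,
            prior_sd=design.quest_prior_sd,
            assumed_slope=design.quest_assumed_slope,
            jitter_sd=design.jitter_sd,
        )
        for key in keys
    }
    order = rng.permutation(np.repeat(np.arange(len(keys)), design.trials_per_condition))
    passed = True
    if run_training:
        _, passed = simulate_training_screen(params, domain=design.domain, rng=rng)
    trials: List[TrialRecord] = []
    for k in order:
        condition, conflict = keys[k]
        track = tracks[(condition, conflict)]
        x = track.next_placement(rng)
        spec = TrialSpec(
            domain=design.domain,
            condition=condition,
            conflict=conflict,
            probe_offset=float(x),
        )
        rec = simulate_trial(spec, params, rng)
        track.update(spec.probe_offset, rec.response)
        trials.append(rec)
    return Session(
        observer_id=observer_id,
        age_group=age_group,
        domain=design.domain,
        trials=trials,
        passed_training=passed,
    )
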