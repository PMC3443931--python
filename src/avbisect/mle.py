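"""Maximum-likelihood (MLE) cue-integration model for audio-visual bisection.

An ideal observer that fuses a visual estimate with variance σ_V² and an
auditory estimate with variance σ_A² weights them inversely to their
variances,

    w_V = σ_A² / (σ_A² + σ_V²),   w_A = σ_V² / (σ_A² + σ_V²),

so the combined estimate has variance

    σ_VA² = σ_V² σ_A² / (σ_V² + σ_A²) ≤ min(σ_V², σ_A²),

an improvement of up to √2 when the two cues are equally precise.  Under an
imposed conflict in which the visual cue is displaced by +Δ and the
auditory cue by −Δ from the neutral point, the predicted PSE is

    Ŝ(Δ) = w_V·Δ − w_A·Δ = (1 − 2 w_A)·Δ,

a line through the origin whose slope ±1 marks full visual/auditory
dominance.  Regressing measured conflict PSEs on Δ therefore yields a
second, threshold-free estimate of the auditory weight,
w_A = (1 − slope)/2.

Sign conventions (one place, used everywhere downstream)
--------------------------------------------------------
Fitted PSEs are reported against the physical probe offset (positive =
toward the third stimulus).  The symmetric ±Δ parametrization above is
reached from the bias-corrected fits by :func:`symmetrize_conflict_pses`:

* time — conflicts are stored as the half-conflict Δ of the second
  stimulus (auditory leads vision by 2Δ there, and the outer stimuli carry
  −Δ).  The fitted PSE runs from 0 (visual dominance) to −2Δ (auditory
  dominance); adding Δ recenters it on the midpoint between the two cues'
  standards, giving +Δ … −Δ.
* space — the visual standard sits at +Δ and the auditory at −Δ, and both
  move with the probe, so the fitted 50% point is the *negative* of the
  perceived shift of the standard; negating the bias-corrected PSE gives
  the perceived shift, +Δ under visual capture (the classic ventriloquist
  measure) and −Δ under auditory capture.

After this mapping both domains obey Ŝ(Δ) = (1 − 2 w_A)·Δ exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .design import SPACE, TIME
from .psychometric import ConflictPse

__all__ = [
    "WeightSet",
    "MLEPrediction",
    "SlopeEstimate",
    "predict_bimodal_sigma",
    "weights_from_thresholds",
    "predict_pse",
    "symmetrize_conflict_pses",
    "slope_from_pses",
    "weights_from_slope",
    "predict_for_observer",
]


@dataclass(frozen=True)
class WeightSet:
    """Visual and auditory cue weights.

    ``source`` records how they were obtained: ``"thresholds"`` (inverse
    variances of the unimodal fits; sums to 1 exactly, both in (0, 1)) or
    ``"pse_slope"`` (from the conflict-slope; may fall outside [0, 1] and
    is then *flagged*, never clamped — clamping would bias downstream
    weight comparisons).
    """

    w_v: float
    w_a: float
    source: str

    @property
    def in_range(self) -> bool:
        return 0.0 <= self.w_a <= 1.0 and 0.0 <= self.w_v <= 1.0


@dataclass(frozen=True)
class SlopeEstimate:
    """OLS slope of bias-corrected PSE against conflict Δ."""

    slope: float
    intercept: float
    slope_se: float
    n_points: int


@dataclass(frozen=True)
class MLEPrediction:
    """Forced-fusion predictions from a pair of unimodal thresholds."""

    sigma_va: float
    weights: WeightSet
    predicted_pse_per_conflict: Dict[float, float]


def predict_bimodal_sigma(sigma_v: float, sigma_a: float) -> float:
    """Predicted two-cue threshold σ_VA = sqrt(σ_V²σ_A²/(σ_V²+σ_A²))."""
    if sigma_v <= 0 or sigma_a <= 0:
        raise ValueError("unimodal thresholds must be positive")
    v2, a2 = sigma_v**2, sigma_a**2
    return float(np.sqrt(v2 * a2 / (v2 + a2)))


def weights_from_thresholds(sigma_v: float, sigma_a: float) -> WeightSet:
    """Inverse-variance weights; w_V + w_A = 1 exactly."""
    if sigma_v <= 0 or sigma_a <= 0:
        raise ValueError("unimodal thresholds must be positive")
    w_v = sigma_a**2 / (sigma_a**2 + sigma_v**2)
    return WeightSet(w_v=float(w_v), w_a=float(1.0 - w_v), source="thresholds")


def predict_pse(
    weights: WeightSet, conflict: float, domain: Optional[str] = None
) -> float:
    """Predicted conflict PSE Ŝ(Δ) = (w_V − w_A)·Δ in the symmetric frame.

    The formula is domain-independent once measured PSEs have been mapped
    with :func:`symmetrize_conflict_pses`; ``domain`` is accepted for API
    symmetry and documentation only.
    """
    return float((weights.w_v - weights.w_a) * conflict)


def symmetrize_conflict_pses(
    points: Sequence[ConflictPse], domain: str
) -> List[ConflictPse]:
    """Map bias-corrected fitted PSEs onto the symmetric ±Δ frame.

    See the module docstring: time adds +Δ (recentring on the inter-cue
    midpoint of the asymmetric temporal geometry); space negates (fitted
    50% point → perceived shift of the standard).
    """
    out: List[ConflictPse] = []
    for p in points:
        if domain == TIME:
            s = p.pse_corrected + p.conflict
        elif domain == SPACE:
            s = -p.pse_corrected
        else:
            raise ValueError(f"unknown domain {domain!r}")
        out.append(ConflictPse(conflict=p.conflict, pse_corrected=s, pse_se=p.pse_se))
    return out


def _as_points(points) -> Tuple[np.ndarray, np.ndarray]:
    if len(points) and isinstance(points[0], ConflictPse):
        d = np.array([p.conflict for p in points], dtype=float)
        s = np.array([p.pse_corrected for p in points], dtype=float)
    else:
        d = np.array([p[0] for p in points], dtype=float)
        s = np.array([p[1] for p in points], dtype=float)
    return d, s


def slope_from_pses(points: Sequence) -> SlopeEstimate:
    """Ordinary least-squares slope of (bias-corrected) PSE on conflict Δ.

    ``points`` is a sequence of :class:`ConflictPse` or ``(Δ, pse)``
    pairs, normally one per conflict level including Δ = 0.  The SE is the
    standard OLS slope SE (NaN with fewer than 3 points).
    """
    d, s = _as_points(points)
    if np.unique(d).size < 2:
        raise ValueError("slope requires at least 2 distinct conflict levels")
    n = d.size
    dbar, sbar = d.mean(), s.mean()
    sxx = float(((d - dbar) ** 2).sum())
    slope = float(((d - dbar) * (s - sbar)).sum() / sxx)
    intercept = float(sbar - slope * dbar)
    if n > 2:
        resid = s - (intercept + slope * d)
        se = float(np.sqrt((resid**2).sum() / (n - 2) / sxx))
    else:
        se = float("nan")
    return SlopeEstimate(slope=slope, intercept=intercept, slope_se=se, n_points=n)


def weights_from_slope(slope: float) -> WeightSet:
    """Auditory weight from the conflict slope: w_A = (1 − slope)/2.

    Values outside [0, 1] are preserved (check :attr:`WeightSet.in_range`).
    """
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    w_a = (1.0 - slope) / 2.0
    return WeightSet(w_v=float(1.0 - w_a), w_a=float(w_a), source="pse_slope")


def predict_for_observer(
    sigma_v: float, sigma_a: float, conflicts: Sequence[float]
) -> MLEPrediction:
    """Bundle all forced-fusion predictions for one observer."""
    w = weights_from_thresholds(sigma_v, sigma_a)
    return MLEPrediction(
        sigma_va=predict_bimodal_sigma(sigma_v, sigma_a),
        weights=w,
        predicted_pse_per_conflict={
            float(c): predict_pse(w, float(c)) for c in conflicts
        },
    )
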