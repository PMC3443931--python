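"""QUEST-style Bayesian adaptive placement for bisection tasks.

Each track maintains a discrete posterior over candidate bisection points
(PSEs).  The likelihood of a "closer to third" response at probe offset x
given candidate PSE m is Φ((x − m)/assumed_slope); its complement for the
other response.  The recommended placement is the posterior mean (QUEST+
convention; switchable to the mode), and every actual placement adds
zero-mean Gaussian jitter so the psychometric function is sampled on its
flanks as well as near the PSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import ndtr

_LIK_FLOOR = 1e-10


@dataclass
class QuestTrack:
    """Discrete-grid Bayesian adaptive track homing in on a bisection point."""

    grid: np.ndarray
    log_posterior: np.ndarray
    assumed_slope: float
    jitter_sd: float
    statistic: str = "mean"
    n_updates: int = 0

    @classmethod
    def create(
        cls,
        prior_mean: float,
        prior_sd: float,
        assumed_slope: float,
        jitter_sd: float,
        n_grid: int = 201,
        grid_halfwidth_sds: float = 4.0,
        statistic: str = "mean",
    ) -> "QuestTrack":
        if prior_sd <= 0:
            raise ValueError("prior_sd must be positive")
        if assumed_slope <= 0:
            raise ValueError("assumed_slope must be positive")
        if jitter_sd < 0:
            raise ValueError("jitter_sd must be nonnegative")
        if statistic not in ("mean", "mode"):
            raise ValueError("statistic must be 'mean' or 'mode'")
        # Grid must span at least ±3 assumed slopes so that data generated
        # anywhere in the plausible range keep the posterior interior.
        half = max(grid_halfwidth_sds * prior_sd, 3.0 * assumed_slope)
        grid = np.linspace(prior_mean - half, prior_mean + half, n_grid)
        log_post = -0.5 * ((grid - prior_mean) / prior_sd) ** 2
        return cls(
            grid=grid,
            log_posterior=log_post,
            assumed_slope=float(assumed_slope),
            jitter_sd=float(jitter_sd),
            statistic=statistic,
        )

    @property
    def posterior(self) -> np.ndarray:
        """Normalized posterior probabilities over the grid."""
        w = np.exp(self.log_posterior - self.log_posterior.max())
        return w / w.sum()

    @property
    def recommendation(self) -> float:
        p = self.posterior
        if self.statistic == "mode":
            return float(self.grid[int(np.argmax(p))])
        return float(np.dot(p, self.grid))

    def update(self, probe_offset: float, response: int) -> None:
        """Add the log-likelihood of one (probe, response) pair in place."""
        if response not in (0, 1):
            raise ValueError("response must be 0 or 1")
        p1 = ndtr((probe_offset - self.grid) / self.assumed_slope)
        lik = p1 if response == 1 else 1.0 - p1
        self.log_posterior = self.log_posterior + np.log(
            np.clip(lik, _LIK_FLOOR, None)
        )
        self.n_updates += 1

    def next_placement(self, rng: np.random.Generator) -> float:
        """Posterior-statistic recommendation plus Gaussian jitter."""
        jitter = rng.normal(0.0, self.jitter_sd) if self.jitter_sd > 0 else 0.0
        return self.recommendation + jitter

    def copy(self) -> "QuestTrack":
        return QuestTrack(
            grid=self.grid.copy(),
            log_posterior=self.log_posterior.copy(),
            assumed_slope=self.assumed_slope,
            jitter_sd=self.jitter_sd,
            statistic=self.statistic,
            n_updates=self.n_updates,
        )

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.tolist(),
            "log_posterior": self.log_posterior.tolist(),
            "assumed_slope": self.assumed_slope,
            "jitter_sd": self.jitter_sd,
            "statistic": self.statistic,
            "n_updates": self.n_updates,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuestTrack":
        return cls(
            grid=np.asarray(d["grid"], dtype=float),
            log_posterior=np.asarray(d["log_posterior"], dtype=float),
            assumed_slope=float(d["assumed_slope"]),
            jitter_sd=float(d["jitter_sd"]),
            statistic=d.get("statistic", "mean"),
            n_updates=int(d.get("n_updates", 0)),
        )


def track_init(
    prior_mean: float,
    prior_sd: float,
    assumed_slope: float,
    jitter_sd: float,
    n_grid: int = 201,
    statistic: str = "mean",
) -> QuestTrack:
    """Functional constructor; see :meth:`QuestTrack.create`."""
    return QuestTrack.create(
        prior_mean, prior_sd, assumed_slope, jitter_sd, n_grid=n_grid, statistic=statistic
    )


def track_update(track: QuestTrack, probe_offset: float, response: int) -> QuestTrack:
    """Return a new track with one observation incorporated."""
    out = track.copy()
    out.update(probe_offset, response)
    return out


def next_placement(track: QuestTrack, rng: np.random.Generator) -> float:
    return track.next_placement(rng)
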