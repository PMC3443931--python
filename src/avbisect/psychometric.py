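"""Cumulative-Gaussian psychometric fitting with bootstrap standard errors.

The model is P(response = 1 | x) = Φ((x − μ)/σ), fitted by maximizing the
Bernoulli likelihood of the raw trials (adaptive placement leaves the
offsets unbinned and uneven, so least squares on binned proportions would
waste information).  μ is the point of subjective equality (PSE) and σ the
threshold.  Internally the fit is a probit regression Φ(a + b·x) with
μ = −a/b, σ = 1/b, solved by iteratively reweighted least squares (IRLS)
from the canonical deterministic start; the solver is vectorized over a
leading batch axis so that bootstrap resampling refits all replicates at
once.

Standard errors are nonparametric case-resampling bootstrap SDs (100
replicates by default).  ``bias_correct`` removes the constant bisection
bias by subtracting the zero-conflict PSE, and ``pooled_bimodal_threshold``
produces the single two-cue threshold that uses all conflict conditions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = [
    "FitError",
    "PsychometricFit",
    "ConflictPse",
    "PsychometricModel",
    "fit_cumulative_gaussian",
    "bootstrap_se",
    "bootstrap_replicates",
    "bias_correct",
    "pooled_bimodal_threshold",
    "probit_nll",
    "asymptotic_se",
]

_EPS = 1e-12


class FitError(ValueError):
    """Raised when a psychometric fit cannot be carried out."""


@dataclass(frozen=True)
class PsychometricFit:
    """PSE (μ) and threshold (σ) of a cumulative-Gaussian fit.

    ``pse`` is the fitted μ of Φ((x − μ)/σ) against the physical probe
    offset; ``threshold`` the fitted σ.  SEs are bootstrap SDs (NaN when no
    bootstrap was run).
    """

    pse: float
    threshold: float
    pse_se: float = float("nan")
    threshold_se: float = float("nan")
    n_trials: int = 0
    condition: str = ""
    conflict: float = 0.0
    converged: bool = True
    n_boot: int = 0
    n_boot_failed: int = 0
    warnings: Tuple[str, ...] = ()


@dataclass(frozen=True)
class ConflictPse:
    """Bias-corrected PSE of one conflict condition (zero-conflict PSE subtracted)."""

    conflict: float
    pse_corrected: float
    pse_se: float = float("nan")


# ---------------------------------------------------------------------------
# Core batched probit IRLS
# ---------------------------------------------------------------------------

def _phi(z: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)


def _irls_probit(
    x: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit Φ(a + b x) by IRLS.  x, y: (..., n).  Returns (a, b, converged)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ybar = np.clip(y.mean(axis=-1), 1e-6, 1.0 - 1e-6)
    a = ndtri(ybar)
    b = np.zeros_like(a)
    converged = np.zeros(a.shape, dtype=bool)
    scale = np.maximum(np.ptp(x, axis=-1), _EPS)
    for _ in range(max_iter):
        eta = a[..., None] + b[..., None] * x
        eta = np.clip(eta, -7.5, 7.5)
        p = np.clip(ndtr(eta), _EPS, 1.0 - _EPS)
        ph = np.maximum(_phi(eta), _EPS)
        w = ph * ph / (p * (1.0 - p))
        z = eta + (y - p) / ph
        sw = w.sum(axis=-1)
        swx = (w * x).sum(axis=-1)
        swxx = (w * x * x).sum(axis=-1)
        swz = (w * z).sum(axis=-1)
        swxz = (w * x * z).sum(axis=-1)
        det = sw * swxx - swx * swx
        bad = ~(np.abs(det) > _EPS)
        det = np.where(bad, 1.0, det)
        a_new = (swxx * swz - swx * swxz) / det
        b_new = (sw * swxz - swx * swz) / det
        a_new = np.where(bad | converged, a, a_new)
        b_new = np.where(bad | converged, b, b_new)
        step = np.maximum(np.abs(a_new - a), np.abs(b_new - b) * scale)
        a, b = a_new, b_new
        converged = converged | (step < tol) | bad
        if converged.all():
            break
    converged = converged & np.isfinite(a) & np.isfinite(b)
    return a, b, converged


def _irls_probit_origin(
    x: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10
) -> Tuple[np.ndarray, np.ndarray]:
    """Fit Φ(b x) (PSE constrained to 0).  x, y: (..., n).  Returns (b, converged)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    b = np.zeros(x.shape[:-1], dtype=float)
    converged = np.zeros(b.shape, dtype=bool)
    scale = np.maximum(np.ptp(x, axis=-1), _EPS)
    for _ in range(max_iter):
        eta = np.clip(b[..., None] * x, -7.5, 7.5)
        p = np.clip(ndtr(eta), _EPS, 1.0 - _EPS)
        ph = np.maximum(_phi(eta), _EPS)
        w = ph * ph / (p * (1.0 - p))
        z = eta + (y - p) / ph
        swxx = (w * x * x).sum(axis=-1)
        swxz = (w * x * z).sum(axis=-1)
        bad = ~(np.abs(swxx) > _EPS)
        b_new = np.where(bad | converged, b, swxz / np.where(bad, 1.0, swxx))
        step = np.abs(b_new - b) * scale
        b = b_new
        converged = converged | (step < tol) | bad
        if converged.all():
            break
    return b, converged & np.isfinite(b)


def probit_nll(x: np.ndarray, y: np.ndarray, mu: float, sigma: float) -> float:
    """Negative Bernoulli log-likelihood of Φ((x − μ)/σ).  Oracle-friendly."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    p = np.clip(ndtr((x - mu) / sigma), _EPS, 1.0 - _EPS)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).sum())


def asymptotic_se(x: np.ndarray, mu: float, sigma: float) -> Tuple[float, float]:
    """Delta-method asymptotic SEs of (μ̂, σ̂) from the Fisher information
    at the given parameters and the actually sampled placements."""
    x = np.asarray(x, dtype=float)
    z = (x - mu) / sigma
    p = np.clip(ndtr(z), _EPS, 1.0 - _EPS)
    ph = _phi(z)
    w = ph * ph / (p * (1.0 - p))
    # Information in (a, b) of Φ(a + b x)
    info = np.array(
        [[w.sum(), (w * x).sum()], [(w * x).sum(), (w * x * x).sum()]]
    )
    cov_ab = np.linalg.inv(info)
    a = -mu / sigma
    b = 1.0 / sigma
    jac = np.array([[-1.0 / b, a / b**2], [0.0, -1.0 / b**2]])
    cov = jac @ cov_ab @ jac.T
    return float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))


# ---------------------------------------------------------------------------
# Public fitting interface
# ---------------------------------------------------------------------------

def _extract_xy(trials) -> Tuple[np.ndarray, np.ndarray, str, float]:
    """Accept a list of TrialRecord-like objects or an (x, y) pair."""
    if isinstance(trials, tuple) and len(trials) == 2:
        x = np.asarray(trials[0], dtype=float)
        y = np.asarray(trials[1], dtype=float)
        return x, y, "", 0.0
    x = np.array([t.spec.probe_offset for t in trials], dtype=float)
    y = np.array([t.response for t in trials], dtype=float)
    condition = trials[0].spec.condition if len(trials) else ""
    conflict = trials[0].spec.conflict if len(trials) else 0.0
    return x, y, condition, conflict


def fit_cumulative_gaussian(
    trials,
    *,
    condition: str = "",
    conflict: Optional[float] = None,
    n_boot: int = 0,
    rng: Optional[np.random.Generator] = None,
    min_trials: int = 20,
) -> PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit of trial data.

    Parameters
    ----------
    trials:
        Either a sequence of trial records (with ``spec.probe_offset`` and
        ``response``) or a tuple ``(x, y)`` of probe offsets and binary
        responses.
    n_boot:
        Number of case-resampling bootstrap replicates for the SEs
        (0 disables the bootstrap; the study used 100).
    min_trials:
        Minimum number of trials required to attempt a fit.

    The fit is deterministic given the data (fixed IRLS start).  Data with
    a single response class raise :class:`FitError` naming the condition;
    a threshold running into the numerical bounds is flagged, not clipped.
    """
    x, y, cond0, conf0 = _extract_xy(trials)
    condition = condition or cond0
    conflict = float(conflict if conflict is not None else conf0)
    label = condition or "<unlabelled>"
    n = x.size
    if n < min_trials:
        raise FitError(
            f"condition {label!r}: {n} trials < required minimum {min_trials}"
        )
    if y.min() == y.max():
        raise FitError(
            f"condition {label!r}: all responses are {int(y[0])}; "
            "cannot fit a psychometric function"
        )
    warnings: List[str] = []
    lo, hi = x[y == 0].max(), x[y == 1].min()
    if hi > lo:
        # Perfectly separated sample: the likelihood increases without
        # bound as sigma -> 0, so no finite threshold MLE exists.  The
        # PSE remains identifiable (any point in the separation gap
        # maximizes the limiting likelihood); report the gap midpoint so
        # bias correction and conflict-slope analyses can still use it.
        warnings.append(
            f"condition {label!r}: responses perfectly separated along the "
            "probe axis; threshold tends to zero (no finite MLE), PSE "
            "taken as the separation-gap midpoint"
        )
        return PsychometricFit(
            pse=float(0.5 * (lo + hi)), threshold=float("nan"), n_trials=n,
            condition=condition, conflict=conflict, converged=False,
            warnings=tuple(warnings),
        )
    a, b, conv = _irls_probit(x[None, :], y[None, :])
    a, b, ok = float(a[0]), float(b[0]), bool(conv[0])
    converged = ok
    if b <= 0:
        warnings.append("non-increasing response data: fitted slope <= 0")
        converged = False
        mu, sigma = float("nan"), float("nan")
    else:
        sigma = 1.0 / b
        mu = -a / b
        span = max(np.ptp(x), _EPS)
        if sigma < 1e-6 * span or sigma > 1e6 * span:
            warnings.append(
                f"threshold {sigma:.3g} at numerical bound relative to "
                f"placement span {span:.3g}"
            )
            converged = False
        elif np.count_nonzero(np.abs(x - mu) < 2.0 * sigma) < 3:
            # The entire rise of the fitted function falls between two
            # adjacent placements: the sample carries no information about
            # a slope this steep, so the estimate is flagged, not trusted.
            warnings.append(
                f"threshold {sigma:.3g} below the placement resolution "
                "(fewer than 3 trials within ±2σ of the PSE)"
            )
            converged = False
    if not ok:
        warnings.append("IRLS did not converge")
    pse_se = threshold_se = float("nan")
    n_failed = 0
    if n_boot > 0 and converged:
        pse_se, threshold_se, n_failed, boot_warn = bootstrap_se(
            (x, y), n_boot=n_boot, rng=rng
        )
        warnings.extend(boot_warn)
    return PsychometricFit(
        pse=mu,
        threshold=sigma,
        pse_se=pse_se,
        threshold_se=threshold_se,
        n_trials=n,
        condition=condition,
        conflict=conflict,
        converged=converged,
        n_boot=n_boot,
        n_boot_failed=n_failed,
        warnings=tuple(warnings),
    )


def bootstrap_replicates(
    trials,
    n_boot: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Bootstrap replicate (PSE, threshold) estimates.

    Case-resamples the trials with replacement and refits every replicate
    in one batched solve.  Returns ``(pse_reps, threshold_reps, n_failed)``
    with failed replicates (non-convergence, single response class,
    perfect separation) dropped.  The replicate values feed both the SEs
    and bootstrap bias corrections of derived quantities.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    x, y, _, _ = _extract_xy(trials)
    rng = np.random.default_rng() if rng is None else rng
    n = x.size
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, yb = x[idx], y[idx]
    one_class = yb.min(axis=1) == yb.max(axis=1)
    sep = (
        np.where(yb == 1, xb, np.inf).min(axis=1)
        > np.where(yb == 0, xb, -np.inf).max(axis=1)
    )
    a, b, conv = _irls_probit(xb, yb)
    ok = conv & (b > 0) & ~one_class & ~sep
    return -a[ok] / b[ok], 1.0 / b[ok], int(n_boot - ok.sum())


def bootstrap_se(
    trials,
    n_boot: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[float, float, int, List[str]]:
    """Case-resampling bootstrap SEs of (PSE, threshold).

    SE = SD of the replicate estimates.  Replicates that fail to converge
    are dropped and counted; more than 20% failures attaches a warning.
    ``n_boot = 1`` is degenerate (SE 0).
    """
    mu, sigma, n_failed = bootstrap_replicates(trials, n_boot=n_boot, rng=rng)
    warnings: List[str] = []
    if mu.size < 2:
        warnings.append("bootstrap degenerate: fewer than 2 converged replicates")
        return 0.0, 0.0, n_failed, warnings
    if n_failed > 0.2 * n_boot:
        warnings.append(
            f"bootstrap: {n_failed}/{n_boot} replicates failed to converge"
        )
    return (
        float(np.std(mu, ddof=1)),
        float(np.std(sigma, ddof=1)),
        n_failed,
        warnings,
    )


def bias_correct(fits: Sequence[PsychometricFit]) -> List[ConflictPse]:
    """Subtract the zero-conflict PSE from every conflict condition's PSE.

    Bisection tasks carry constant response biases that are of no interest
    here; referencing each PSE to the Δ = 0 condition removes them.  The
    Δ = 0 entry maps to exactly 0 by construction.
    """
    zero = [f for f in fits if f.conflict == 0.0]
    if not zero:
        raise FitError("bias correction requires a zero-conflict (Δ=0) fit")
    ref = zero[0]
    out = []
    for f in fits:
        if f is ref or f.conflict == 0.0:
            out.append(ConflictPse(conflict=0.0, pse_corrected=0.0, pse_se=0.0))
        else:
            se = float(np.hypot(f.pse_se, ref.pse_se))
            out.append(
                ConflictPse(
                    conflict=f.conflict,
                    pse_corrected=f.pse - ref.pse,
                    pse_se=se,
                )
            )
    return out


def pooled_bimodal_threshold(
    condition_data: Sequence[Tuple[float, np.ndarray, np.ndarray]],
    *,
    recenter: bool = True,
    n_boot: int = 0,
    rng: Optional[np.random.Generator] = None,
    min_trials: int = 20,
) -> PsychometricFit:
    """Two-cue threshold pooled over all conflict conditions.

    Parameters
    ----------
    condition_data:
        One ``(conflict, x, y)`` triple per bimodal conflict condition.
    recenter:
        If True (default), each condition's trials are recentered on that
        condition's fitted PSE before pooling, so conflict-dependent PSE
        shifts do not inflate the pooled σ; the pooled fit then constrains
        μ = 0.  If False, the raw trials are pooled and a free (μ, σ) fit
        is performed.
    """
    if len(condition_data) == 0:
        raise FitError("no bimodal conditions to pool")
    xs, ys = [], []
    for conflict, x, y in condition_data:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if recenter:
            f = fit_cumulative_gaussian(
                (x, y), condition="bimodal", conflict=conflict, min_trials=min_trials
            )
            if not f.converged:
                raise FitError(
                    f"condition 'bimodal' at conflict {conflict}: "
                    "fit did not converge; cannot recenter for pooling"
                )
            xs.append(x - f.pse)
        else:
            xs.append(x)
        ys.append(y)
    xp = np.concatenate(xs)
    yp = np.concatenate(ys)
    n = xp.size
    warnings: List[str] = []
    if recenter:
        b, conv = _irls_probit_origin(xp[None, :], yp[None, :])
        b, ok = float(b[0]), bool(conv[0])
        converged = ok and b > 0
        sigma = 1.0 / b if b > 0 else float("nan")
        mu = 0.0
    else:
        fit = fit_cumulative_gaussian((xp, yp), condition="bimodal_pooled")
        sigma, mu, converged = fit.threshold, fit.pse, fit.converged
        warnings.extend(fit.warnings)
    threshold_se = float("nan")
    n_failed = 0
    if n_boot > 0 and converged:
        threshold_se, n_failed, w = _pooled_bootstrap(
            condition_data, recenter=recenter, n_boot=n_boot, rng=rng
        )
        warnings.extend(w)
    return PsychometricFit(
        pse=mu,
        threshold=sigma,
        pse_se=0.0 if recenter else float("nan"),
        threshold_se=threshold_se,
        n_trials=n,
        condition="bimodal_pooled",
        conflict=float("nan"),
        converged=converged,
        n_boot=n_boot,
        n_boot_failed=n_failed,
        warnings=tuple(warnings),
    )


def _pooled_bootstrap(condition_data, *, recenter, n_boot, rng):
    """Bootstrap SE of the pooled σ, resampling trials within condition."""
    rng = np.random.default_rng() if rng is None else rng
    xs_b, ys_b = [], []
    failed = np.zeros(n_boot, dtype=bool)
    for conflict, x, y in condition_data:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n = x.size
        idx = rng.integers(0, n, size=(n_boot, n))
        xb, yb = x[idx], y[idx]
        if recenter:
            a, b, conv = _irls_probit(xb, yb)
            ok = conv & (b > 0)
            failed |= ~ok
            mu = np.where(ok, -a / np.where(b > 0, b, 1.0), 0.0)
            xb = xb - mu[:, None]
        xs_b.append(xb)
        ys_b.append(yb)
    xp = np.concatenate(xs_b, axis=1)
    yp = np.concatenate(ys_b, axis=1)
    if recenter:
        b, conv = _irls_probit_origin(xp, yp)
        ok = conv & (b > 0) & ~failed
        sigma = 1.0 / b[ok]
    else:
        a, b, conv = _irls_probit(xp, yp)
        ok = conv & (b > 0) & ~failed
        sigma = 1.0 / b[ok]
    n_failed = int(n_boot - ok.sum())
    warnings = []
    if ok.sum() < 2:
        return 0.0, n_failed, ["pooled bootstrap degenerate"]
    if n_failed > 0.2 * n_boot:
        warnings.append(
            f"pooled bootstrap: {n_failed}/{n_boot} replicates failed"
        )
    return float(np.std(sigma, ddof=1)), n_failed, warnings


# ---------------------------------------------------------------------------
# scikit-learn style estimator
# ---------------------------------------------------------------------------

try:  # pragma: no cover - import guard only
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    BaseEstimator = object  # type: ignore[assignment,misc]


class PsychometricModel(BaseEstimator):
    """Cumulative-Gaussian psychometric function as a scikit-learn estimator.

    A probit regression of binary responses on a single stimulus axis,
    reparametrized to the quantities psychophysics reports: the PSE
    ``pse_`` (50% point) and the threshold ``threshold_`` (σ of the
    underlying Gaussian).

    Parameters
    ----------
    n_boot:
        Bootstrap replicates for standard errors (0 = no bootstrap).
    min_trials:
        Minimum sample size accepted by :meth:`fit`.
    random_state:
        Seed for the bootstrap resampling.

    Examples
    --------
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> x = rng.normal(0, 80, 500)
    >>> y = (rng.normal(0, 50, 500) + x > 10).astype(int)
    >>> m = PsychometricModel().fit(x, y)
    >>> bool(abs(m.pse_ - 10) < 10)
    True
    """

    def __init__(self, n_boot: int = 0, min_trials: int = 20, random_state=None):
        self.n_boot = n_boot
        self.min_trials = min_trials
        self.random_state = random_state

    def fit(self, X, y):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("PsychometricModel expects a single feature")
            x = x[:, 0]
        rng = np.random.default_rng(self.random_state)
        res = fit_cumulative_gaussian(
            (x, np.asarray(y, dtype=float)),
            n_boot=self.n_boot,
            rng=rng,
            min_trials=self.min_trials,
        )
        self.pse_ = res.pse
        self.threshold_ = res.threshold
        self.pse_se_ = res.pse_se
        self.threshold_se_ = res.threshold_se
        self.converged_ = res.converged
        self.result_ = res
        self.n_features_in_ = 1
        return self

    def _check_fitted(self):
        if not hasattr(self, "pse_"):
            raise AttributeError("PsychometricModel is not fitted yet")

    def predict_proba(self, X):
        self._check_fitted()
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        p1 = ndtr((x - self.pse_) / self.threshold_)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def score(self, X, y):
        """Mean accuracy (for use with sklearn model-selection utilities)."""
        return float(np.mean(self.predict(X) == np.asarray(y)))
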