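"""Population-level statistics of segmented tracks.

Residence times of persistent / anti-persistent states are summarized by
empirical survival functions S(t) = P(T > t); heavy-tailed residence
densities psi(t) ~ t^(-mu-1) correspond to survival tails S(t) ~ t^(-mu),
so the tail exponent mu is read off a log-log line fitted to the survival
curve.  Distributions of local Hurst exponents are modeled by Gaussian
mixtures with the component count chosen by BIC, and smooth densities come
from Gaussian kernel density estimation with Scott's-rule bandwidth.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats as sp_stats
from sklearn.mixture import GaussianMixture

from .errors import DegenerateInputError, ParameterError, UndefinedFitError

__all__ = [
    "KdeConfig",
    "SurvivalCurve",
    "PowerLawFit",
    "GmmFit",
    "gaussian_kde",
    "survival_function",
    "fit_powerlaw_tail",
    "fit_gmm_bic",
    "benchmark_report",
]


@dataclass
class KdeConfig:
    """Gaussian-kernel KDE settings; bandwidth is Scott's rule
    (n^(-1/(d+4)) times the sample scale) or an explicit value."""

    bandwidth: object = "scott"  # "scott" or a positive float (absolute, 1D only)

    def __post_init__(self) -> None:
        if isinstance(self.bandwidth, str):
            if self.bandwidth != "scott":
                raise ParameterError("bandwidth must be 'scott' or a positive number")
        elif not self.bandwidth > 0:
            raise ParameterError("explicit bandwidth must be positive")


def gaussian_kde(points: np.ndarray, config: Optional[KdeConfig] = None):
    """Gaussian kernel density estimator for 1D or 2D samples.

    Returns a callable evaluating the normalized density (scipy's
    ``gaussian_kde`` under the hood).
    """
    config = config or KdeConfig()
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    elif pts.ndim == 2 and pts.shape[0] > pts.shape[1]:
        pts = pts.T  # accept (N, d) sample layout
    if pts.shape[1] < 2:
        raise ParameterError("KDE needs at least 2 samples")
    if np.any(pts.std(axis=1) == 0):
        raise DegenerateInputError("zero-variance sample: bandwidth undefined")
    if isinstance(config.bandwidth, str):
        bw = "scott"
    else:
        if pts.shape[0] != 1:
            raise ParameterError("explicit absolute bandwidth is 1D only")
        bw = float(config.bandwidth) / pts[0].std(ddof=1)
    return sp_stats.gaussian_kde(pts, bw_method=bw)


@dataclass
class SurvivalCurve:
    """Empirical survival S(t) = P(T > t) with binomial standard errors."""

    times: np.ndarray
    survival: np.ndarray
    std_errors: np.ndarray
    n_samples: int


def survival_function(durations: Sequence[float]) -> SurvivalCurve:
    """Empirical survival at the sorted unique durations (strict '>')."""
    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise ParameterError("empty duration sample")
    if np.any(d <= 0):
        raise ParameterError("durations must be positive")
    t = np.unique(d)
    n = d.size
    # P(T > t): strictly greater, so S at the largest duration is 0
    surv = 1.0 - np.searchsorted(np.sort(d), t, side="right") / n
    se = np.sqrt(surv * (1.0 - surv) / n)
    return SurvivalCurve(t, surv, se, n)


@dataclass
class PowerLawFit:
    """Least-squares power-law tail S(t) ~ t^(-mu) on a log-log line."""

    mu: float
    fit_range: tuple
    residual_rms: float
    n_points: int


def fit_powerlaw_tail(
    curve: SurvivalCurve,
    t_min: Optional[float] = None,
    upper_quantile: float = 0.99,
    t_max: Optional[float] = None,
) -> PowerLawFit:
    """Fit the survival tail exponent mu by least squares in log-log space.

    Points below ``t_min`` (default: the 20th percentile of the curve's
    support) are excluded, as are the largest durations beyond
    ``upper_quantile`` (finite tracks truncate the heaviest dwells) and any
    zero survival values.  When the truncation scale is known (e.g. the
    observation window), pass ``t_max`` explicitly and keep it a factor of
    a few below that scale: survival plunges as it approaches a hard
    truncation, which otherwise steepens the fitted tail.
    """
    t, s = curve.times, curve.survival
    if t_min is None:
        t_min = float(np.quantile(t, 0.20))
    if t_max is None:
        t_max = float(np.quantile(t, upper_quantile))
    mask = (t >= t_min) & (t <= t_max) & (s > 0)
    if mask.sum() < 5:
        raise UndefinedFitError("fewer than 5 usable points beyond t_min")
    log_t, log_s = np.log(t[mask]), np.log(s[mask])
    slope, intercept = np.polyfit(log_t, log_s, 1)
    resid = log_s - (slope * log_t + intercept)
    return PowerLawFit(
        mu=float(-slope),
        fit_range=(float(t[mask].min()), float(t[mask].max())),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_points=int(mask.sum()),
    )


@dataclass
class GmmFit:
    """Gaussian mixture fit at the BIC-minimizing component count."""

    n_components: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    bic_by_k: Dict[int, float]


def fit_gmm_bic(
    values: Sequence[float],
    k_candidates: Sequence[int] = range(1, 9),
    n_init: int = 10,
    seed: Optional[int] = None,
) -> GmmFit:
    """Fit 1D Gaussian mixtures over candidate component counts and keep
    the BIC-minimizing one (EM with ``n_init`` restarts per candidate)."""
    x = np.asarray(values, dtype=float)[:, None]
    k_candidates = list(k_candidates)
    if x.shape[0] < 10 * max(k_candidates):
        raise ParameterError("need at least 10 samples per candidate component")
    bic: Dict[int, float] = {}
    fits = {}
    for k in k_candidates:
        gm = GaussianMixture(
            n_components=k, n_init=n_init, random_state=np.random.default_rng(seed).integers(2**31),
        )
        try:
            gm.fit(x)
        except Exception:
            continue  # non-convergence: candidate skipped
        bic[k] = float(gm.bic(x))
        fits[k] = gm
    if not bic:
        raise UndefinedFitError("no mixture candidate converged")
    best_k = min(bic, key=bic.get)
    gm = fits[best_k]
    order = np.argsort(gm.means_[:, 0])
    return GmmFit(
        n_components=best_k,
        weights=gm.weights_[order],
        means=gm.means_[order, 0],
        variances=gm.covariances_[order, 0, 0],
        bic_by_k=bic,
    )


def benchmark_report(
    model_bank: Dict[int, object],
    conditions: Sequence[dict],
    n_reps: int = 1000,
    seed: Optional[int] = None,
    classical_methods: Sequence[str] = ("tamsd", "rescaled_range", "sequential_range"),
):
    """Monte-Carlo sigma_H table over a grid of benchmark conditions.

    Each condition is a dict with keys among ``n`` (track length), ``nsr``
    (noise-to-signal ratio), ``n_rand`` (random subsampling) and selects
    the matching network from ``model_bank`` (keyed by input size) plus the
    classical estimators where applicable (full consecutive tracks only).
    Returns a tidy DataFrame with one row per (condition, method).
    """
    import pandas as pd

    from . import classical, fbm
    from .evaluation import evaluate_estimates
    from .network import estimate_hurst_many
    from .trajectory import Trajectory

    rng = np.random.default_rng(seed)
    rows = []
    for cond in conditions:
        n = int(cond.get("n", 100))
        nsr = float(cond.get("nsr", 0.0))
        n_rand = cond.get("n_rand")
        h_true = rng.uniform(0.001, 0.999, size=n_reps)
        pos = fbm.simulate_fbm_ensemble(h_true, n, rng=rng)
        if nsr > 0:
            sigma = nsr * pos.std(axis=1, keepdims=True)
            pos = pos + rng.standard_normal(pos.shape) * sigma
        key = int(n_rand) if n_rand is not None else n
        if n_rand is not None:
            idx = fbm.subsample_indices(n, int(n_rand), rng, m=n_reps)
            windows = np.take_along_axis(pos, idx, axis=1)
        else:
            windows = pos
        methods = {}
        if key in model_bank:
            methods["dlfnn"] = estimate_hurst_many(model_bank[key], windows)
        else:
            methods["dlfnn"] = None
        if n_rand is None:
            for name in classical_methods:
                fn = {
                    "tamsd": classical.tamsd_hurst,
                    "rescaled_range": classical.rescaled_range_hurst,
                    "sequential_range": classical.sequential_range_hurst,
                }[name]
                ests = np.empty(n_reps)
                for i in range(n_reps):
                    try:
                        ests[i] = fn(Trajectory(i, 1.0, windows[i]))
                    except Exception:
                        ests[i] = np.nan
                methods[name] = ests
        for name, ests in methods.items():
            if ests is None or not np.isfinite(ests).any():
                rows.append(
                    dict(cond, method=name, sigma_h=np.nan, sigma_h_se=np.nan, available=False)
                )
                continue
            rep = evaluate_estimates(h_true, ests)
            abs_err = np.abs(rep.delta_h_samples)
            rows.append(
                dict(
                    cond,
                    method=name,
                    sigma_h=rep.sigma_h,
                    sigma_h_se=float(abs_err.std(ddof=1) / np.sqrt(abs_err.size)),
                    available=True,
                )
            )
    return pd.DataFrame(rows)
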