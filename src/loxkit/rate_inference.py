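"""Recombination-rate estimation by identifiability-aware model selection.

Each technical replicate contributes a time series of recombined-cell
fractions.  Two mean models are fitted with the t=0 fraction ``f0`` fixed to
its measured value:

* logistic — f(t) = fmax / (1 + (fmax/f0 - 1) exp(-k t)), free parameters
  (fmax, k), with fmax bounded between the maximum measured fraction and 1;
* exponential — f(t) = f0 exp(k t), the leading term of the expansion in
  f/fmax, with the single free parameter k.

When the fraction stays far below fmax the logistic parameters are not
identifiable (a flat series is explained equally by k = 0 at any fmax or by
fmax -> f0 at any k), so both models are fitted per replicate and the rate
estimate is taken from the model with the lower small-sample-corrected AIC
(AICc).  The exponential fit uses bounded scalar maximum likelihood; the
logistic fit uses an affine-invariant ensemble MCMC sampler under flat priors
with the maximum-likelihood sample as point estimate, so AICc compares like
with like.  The likelihood is binomial on gated counts when counts are
available, else Gaussian on fractions with per-point variance p(1-p)/n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import emcee
import numpy as np
from scipy.optimize import minimize_scalar

from .synthetic_data import (SwitchingTrajectory, eval_exponential_fraction,
                             eval_logistic_fraction)

__all__ = [
    "LogisticParams",
    "ExponentialParams",
    "FitResult",
    "ReplicateEnsemble",
    "observed_f0",
    "loglik",
    "fit_exponential",
    "fit_logistic_mcmc",
    "aicc",
    "select_model",
    "ensemble_summary",
]

K_UPPER_DEFAULT = 10.0  # per-hour; saturation within minutes at assay time scales
AICC_TIE_TOL = 1e-9
RHAT_THRESHOLD = 1.05


@dataclass
class LogisticParams:
    f0: float  # fixed from the t=0 measurement, not fitted
    fmax: float
    k: float

    def __post_init__(self) -> None:
        if not (0.0 < self.f0 <= self.fmax <= 1.0):
            raise ValueError("require 0 < f0 <= fmax <= 1")
        if self.k < 0:
            raise ValueError("k must be >= 0")


@dataclass
class ExponentialParams:
    f0: float  # fixed
    k: float

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("f0 must be > 0")
        if self.k < 0:
            raise ValueError("k must be >= 0")


@dataclass
class FitResult:
    """One model fit to one technical replicate."""

    model: str                       # "logistic" | "exponential"
    params: dict
    max_loglik: float
    n_obs: int
    n_params: int
    aicc: float
    converged: bool = True
    identifiable: bool = True
    diagnostics: dict = field(default_factory=dict)

    @property
    def k(self) -> float:
        return self.params["k"]

    def predict(self, t) -> np.ndarray:
        if self.model == "logistic":
            return eval_logistic_fraction(t, self.params["f0"],
                                          self.params["fmax"], self.params["k"])
        return eval_exponential_fraction(t, self.params["f0"], self.params["k"],
                                         warn_above_one=False)


@dataclass
class ReplicateEnsemble:
    """Selected fits across technical replicates with pointwise summaries."""

    fits: list
    t_grid: np.ndarray
    mean_curve: np.ndarray
    min_curve: np.ndarray
    max_curve: np.ndarray
    k_min: float
    k_mean: float
    k_max: float

    def __post_init__(self) -> None:
        if not (self.k_min <= self.k_mean <= self.k_max):
            raise ValueError("require k_min <= k_mean <= k_max")


def _extract(trajectory: SwitchingTrajectory):
    """(t, x, n) when counts exist, else (t, fractions, n=None)."""
    if trajectory.counts is not None:
        x, n = trajectory.counts
        return trajectory.times, x.astype(float), n.astype(float)
    return trajectory.times, trajectory.fractions, None


def observed_f0(trajectory: SwitchingTrajectory) -> float:
    """Measured t=0 fraction, Jeffreys-smoothed when the count is 0 or n.

    The logistic curve divides by f0, so an observed zero count is replaced by
    (x + 0.5)/(n + 1).
    """
    t, y, n = _extract(trajectory)
    if t[0] != 0.0:
        raise ValueError("trajectory must include a t=0 measurement")
    if n is not None:
        x0, n0 = y[0], n[0]
        if x0 == 0 or x0 == n0:
            return (x0 + 0.5) / (n0 + 1.0)
        return x0 / n0
    f0 = y[0]
    if f0 <= 0:
        raise ValueError("fraction-only trajectory has f0 = 0; supply counts "
                         "so the zero can be smoothed")
    return float(f0)


def _binomial_kernel(x: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood kernel, rows = parameter vectors.

    p of exactly 0 or 1 with discordant counts yields -inf (flagged by the
    caller), matching the degenerate-prediction contract.
    """
    p = np.atleast_2d(p)
    out = np.full(p.shape[0], -np.inf)
    ok = np.all((p > 0.0) & (p < 1.0), axis=1)
    # concordant boundary predictions contribute 0: handle p==0,x==0 / p==1,x==n
    boundary = ~ok
    if np.any(boundary):
        concordant = np.all(
            ((p > 0) | (x == 0)) & ((p < 1) | (x == n)) & (p >= 0) & (p <= 1), axis=1)
        for i in np.flatnonzero(boundary & concordant):
            pi = p[i]
            inner = (pi > 0) & (pi < 1)
            out[i] = np.sum(x[inner] * np.log(pi[inner])
                            + (n[inner] - x[inner]) * np.log1p(-pi[inner]))
    if np.any(ok):
        pok = p[ok]
        out[ok] = np.sum(x * np.log(pok) + (n - x) * np.log1p(-pok), axis=1)
    return out


def _gaussian_loglik(f_obs: np.ndarray, n_events: np.ndarray,
                     p: np.ndarray) -> np.ndarray:
    """Gaussian log-likelihood on fractions with variance p_hat(1-p_hat)/n."""
    p_hat = np.clip(f_obs, 1e-12, 1 - 1e-12)
    var = np.maximum(p_hat * (1 - p_hat) / n_events, 1e-18)
    p = np.atleast_2d(p)
    return -0.5 * np.sum((f_obs - p) ** 2 / var + np.log(2 * np.pi * var), axis=1)


def _loglik_vec(t, y, n, model: str, f0: float, theta: np.ndarray,
                n_events_fallback: np.ndarray | None) -> np.ndarray:
    """Vectorized log-likelihood for parameter matrix theta.

    theta columns: (k,) for exponential, (fmax, k) for logistic.
    """
    theta = np.atleast_2d(theta)
    if model == "exponential":
        k = theta[:, 0][:, None]
        p = f0 * np.exp(k * t[None, :])
    else:
        fmax = theta[:, 0][:, None]
        k = theta[:, 1][:, None]
        with np.errstate(over="ignore"):
            p = fmax / (1.0 + (fmax / f0 - 1.0) * np.exp(-k * t[None, :]))
    if n is not None:
        return _binomial_kernel(y, n, p)
    return _gaussian_loglik(y, n_events_fallback, p)


def loglik(trajectory: SwitchingTrajectory, model: str, params,
           n_events: float | np.ndarray | None = None) -> float:
    """Log-likelihood of a parameterized mean model for one trajectory.

    Binomial on counts when the trajectory carries them; otherwise Gaussian
    on fractions with per-point variance p_hat(1-p_hat)/n_events.
    """
    t, y, n = _extract(trajectory)
    if n is None:
        if n_events is None:
            raise ValueError("fraction-only trajectories need n_events for the "
                             "Gaussian likelihood variance")
        n_events = np.broadcast_to(np.asarray(n_events, dtype=float), t.shape)
    if model == "exponential":
        theta = np.array([[params.k if isinstance(params, ExponentialParams)
                           else params["k"]]])
        f0 = params.f0 if isinstance(params, ExponentialParams) else params["f0"]
    elif model == "logistic":
        if isinstance(params, LogisticParams):
            theta = np.array([[params.fmax, params.k]])
            f0 = params.f0
        else:
            theta = np.array([[params["fmax"], params["k"]]])
            f0 = params["f0"]
    else:
        raise ValueError("model must be 'logistic' or 'exponential'")
    return float(_loglik_vec(t, y, n, model, f0, theta, n_events)[0])


def aicc(max_loglik: float, n_params: int, n_obs: int) -> float:
    """Corrected Akaike information criterion (lower is better)."""
    if n_obs <= n_params + 1:
        raise ValueError(
            f"AICc undefined: need n_obs > n_params + 1 (got n_obs={n_obs}, "
            f"n_params={n_params})")
    return (-2.0 * max_loglik + 2.0 * n_params
            + 2.0 * n_params * (n_params + 1) / (n_obs - n_params - 1))


def _maximize_1d(fun, k_upper: float, n_grid: int = 256) -> tuple[float, float]:
    """Maximize a scalar function of k on [0, k_upper]: coarse grid + Brent."""
    grid = np.linspace(0.0, k_upper, n_grid)
    vals = fun(grid)
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    if lo == hi:
        return float(grid[i]), float(vals[i])
    def neg(k: float) -> float:
        v = fun(np.array([k]))[0]
        return -v if np.isfinite(v) else 1e300  # keep Brent away from -inf

    res = minimize_scalar(neg, bounds=(lo, hi),
                          method="bounded", options={"xatol": 1e-12})
    k_best, ll_best = float(res.x), float(-res.fun)
    if vals[i] >= ll_best:  # guard against a degenerate bracket; exact ties
        # (e.g. the k=0 boundary optimum) resolve to the grid point
        k_best, ll_best = float(grid[i]), float(vals[i])
    return k_best, ll_best


def fit_exponential(trajectory: SwitchingTrajectory, f0: float | None = None,
                    k_upper: float = K_UPPER_DEFAULT,
                    n_events: float | None = None) -> FitResult:
    """Maximum-likelihood exponential fit over k in [0, k_upper]."""
    t, y, n = _extract(trajectory)
    if t.size < 2:
        raise ValueError("need at least 2 time points")
    if f0 is None:
        f0 = observed_f0(trajectory)
    nev = None if n is not None else np.broadcast_to(
        np.asarray(n_events if n_events is not None else 1e4, dtype=float), t.shape)

    def ll(ks: np.ndarray) -> np.ndarray:
        return _loglik_vec(t, y, n, "exponential", f0, ks[:, None], nev)

    k_hat, ll_hat = _maximize_1d(ll, k_upper)
    n_obs = t.size
    result_aicc = aicc(ll_hat, 1, n_obs) if n_obs > 2 else np.nan
    return FitResult(model="exponential", params={"f0": f0, "k": k_hat},
                     max_loglik=ll_hat, n_obs=n_obs, n_params=1,
                     aicc=result_aicc, converged=bool(np.isfinite(ll_hat)),
                     diagnostics={"k_upper": k_upper})


def _split_rhat(chain: np.ndarray) -> np.ndarray:
    """Split-chain Gelman-Rubin statistic; chain shape (n_steps, n_walkers, ndim)."""
    n = chain.shape[0] // 2
    halves = np.concatenate([chain[:n], chain[n:2 * n]], axis=1)  # (n, 2*walkers, d)
    m = halves.shape[1]
    means = halves.mean(axis=0)                       # (m, d)
    variances = halves.var(axis=0, ddof=1)            # (m, d)
    W = variances.mean(axis=0)
    B = n * means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / W)
    return np.where(W > 0, rhat, 1.0)


def fit_logistic_mcmc(trajectory: SwitchingTrajectory, f0: float | None = None,
                      seed: int = 0, n_walkers: int = 32, n_steps: int = 2000,
                      n_burn: int = 500, k_upper: float = K_UPPER_DEFAULT,
                      n_events: float | None = None) -> FitResult:
    """Logistic fit by ensemble MCMC under flat priors on (fmax, k).

    The prior box is [max measured fraction, 1] x [0, k_upper]; the point
    estimate is the maximum-likelihood posterior sample so that the AICc
    comparison against the exponential fit is like-with-like.  If the fmax
    bound is empty (maximum measured fraction = 1) the fit collapses to a
    one-parameter maximization with fmax fixed at 1.

    A replicate whose fraction never rises appreciably sits on the likelihood
    ridge {k = 0} u {fmax -> f0}; such fits are flagged non-identifiable.
    """
    t, y, n = _extract(trajectory)
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if f0 is None:
        f0 = observed_f0(trajectory)
    nev = None if n is not None else np.broadcast_to(
        np.asarray(n_events if n_events is not None else 1e4, dtype=float), t.shape)

    raw_fracs = y / n if n is not None else y
    fmax_low = float(max(np.max(raw_fracs), f0))
    n_obs = t.size

    ll_k0 = float(_loglik_vec(t, y, n, "exponential", f0, np.array([[0.0]]), nev)[0])

    if fmax_low >= 1.0 - 1e-12:
        # empty fmax bound: fix fmax = 1, one free parameter
        def ll(ks: np.ndarray) -> np.ndarray:
            theta = np.column_stack([np.ones_like(ks), ks])
            return _loglik_vec(t, y, n, "logistic", f0, theta, nev)

        k_hat, ll_hat = _maximize_1d(ll, k_upper)
        return FitResult(
            model="logistic",
            params={"f0": f0, "fmax": 1.0, "k": k_hat},
            max_loglik=ll_hat, n_obs=n_obs, n_params=1,
            aicc=aicc(ll_hat, 1, n_obs) if n_obs > 2 else np.nan,
            converged=bool(np.isfinite(ll_hat)),
            identifiable=bool((ll_hat - ll_k0) > 0.5),
            diagnostics={"fmax_fixed": True})

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        inside = ((theta[:, 0] >= fmax_low) & (theta[:, 0] <= 1.0)
                  & (theta[:, 1] >= 0.0) & (theta[:, 1] <= k_upper))
        out = np.full(theta.shape[0], -np.inf)
        if np.any(inside):
            out[inside] = _loglik_vec(t, y, n, "logistic", f0, theta[inside], nev)
        return out

    rng = np.random.default_rng(seed)
    # Initialize walkers in a tight ball around a coarse-grid likelihood
    # maximum: the posterior is extremely peaked at cytometry sample sizes
    # and dispersed starts leave stray walkers stranded off the mode.
    fmax_grid = np.linspace(fmax_low, 1.0, 16)
    k_grid = np.linspace(0.0, k_upper, 64)
    mesh = np.column_stack([np.repeat(fmax_grid, k_grid.size),
                            np.tile(k_grid, fmax_grid.size)])
    theta0 = mesh[int(np.argmax(log_prob(mesh)))]
    scale = np.array([max(1e-3, 0.02 * (1.0 - fmax_low)),
                      max(1e-3, 0.02 * max(theta0[1], 0.1))])
    p0 = theta0 + scale * rng.standard_normal((n_walkers, 2))
    p0[:, 0] = np.clip(p0[:, 0], fmax_low, 1.0)
    p0[:, 1] = np.clip(p0[:, 1], 0.0, k_upper)
    sampler = emcee.EnsembleSampler(n_walkers, 2, log_prob, vectorize=True)
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False)

    chain = sampler.get_chain()           # (n_steps, n_walkers, 2)
    logp = sampler.get_log_prob()         # (n_steps, n_walkers)
    i_flat = int(np.argmax(logp))
    i_step, i_walk = np.unravel_index(i_flat, logp.shape)
    fmax_hat, k_hat = chain[i_step, i_walk]
    ll_hat = float(logp[i_step, i_walk])

    post = chain[n_burn:]
    rhat = _split_rhat(post)
    quantiles = {
        "fmax": np.quantile(post[..., 0], [0.16, 0.5, 0.84]).tolist(),
        "k": np.quantile(post[..., 1], [0.16, 0.5, 0.84]).tolist(),
    }
    return FitResult(
        model="logistic",
        params={"f0": f0, "fmax": float(fmax_hat), "k": float(k_hat)},
        max_loglik=ll_hat, n_obs=n_obs, n_params=2,
        aicc=aicc(ll_hat, 2, n_obs) if n_obs > 3 else np.nan,
        converged=bool(np.all(rhat < RHAT_THRESHOLD) and np.isfinite(ll_hat)),
        identifiable=bool((ll_hat - ll_k0) > 0.5),
        diagnostics={"rhat": rhat.tolist(),
                     "acceptance_fraction": float(np.mean(sampler.acceptance_fraction)),
                     "posterior_quantiles": quantiles,
                     "fmax_low": fmax_low})


def select_model(exp_fit: FitResult | None, logistic_fit: FitResult | None,
                 concentration: float) -> FitResult:
    """Pick the rate estimate: exponential at zero inducer, else lowest AICc.

    Replicates with no supplemented inducer get the exponential fit
    unconditionally (the logistic parameters are unidentifiable there); ties
    within 1e-9 go to the model with fewer parameters (exponential).
    """
    if concentration == 0:
        if exp_fit is None:
            raise ValueError("zero-inducer replicates require an exponential fit")
        return exp_fit
    if exp_fit is None or logistic_fit is None:
        raise ValueError("both fits are required at nonzero concentration")
    if not exp_fit.converged and not logistic_fit.converged:
        raise RuntimeError(
            "both fits flagged non-converged; diagnostics: "
            f"exp={exp_fit.diagnostics}, logistic={logistic_fit.diagnostics}")
    if not np.isfinite(exp_fit.aicc) or not np.isfinite(logistic_fit.aicc):
        raise ValueError("AICc undefined for one of the fits (too few points)")
    if abs(logistic_fit.aicc - exp_fit.aicc) < AICC_TIE_TOL:
        return exp_fit
    return logistic_fit if logistic_fit.aicc < exp_fit.aicc else exp_fit


def ensemble_summary(fits: list, t_grid) -> ReplicateEnsemble:
    """Pointwise mean and min-max envelope of selected best-fit curves."""
    if not fits:
        raise ValueError("at least one selected fit is required")
    t_grid = np.asarray(t_grid, dtype=float)
    curves = np.vstack([f.predict(t_grid) for f in fits])
    ks = np.array([f.k for f in fits])
    return ReplicateEnsemble(
        fits=list(fits), t_grid=t_grid,
        mean_curve=curves.mean(axis=0),
        min_curve=curves.min(axis=0),
        max_curve=curves.max(axis=0),
        k_min=float(ks.min()), k_mean=float(ks.mean()), k_max=float(ks.max()))
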