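"""Maximum-likelihood fits of discrete heavy-tailed distributions.

Avalanche durations and sizes are positive integers, so every model
here is discrete; continuous approximations are deliberately avoided.
Supported models:

* truncated power law  f(x) ~ x^-alpha        on [x_min, x_max],
* power law with exponential cutoff  f(x) ~ x^-alpha e^(-beta x)
  on [x_min, inf) (normalizer summed to a documented large bound),
* truncated (discrete) exponential  f(x) ~ e^(-lambda x), the standard
  alternative in loglikelihood-ratio comparisons.

Goodness of fit follows the loglikelihood-ratio convention of the
avalanche literature: R > 0 favors the first (power-law) model.

The crackling-noise scaling check compares the exponent ratio
(alpha - 1) / (tau - 1) predicted from the duration and size fits
against the exponent gamma fitted directly to the mean size per
duration curve <S>(T).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, special

__all__ = [
    "PowerLawFit",
    "ExpCutoffFit",
    "ExponentialFit",
    "BinnedDistribution",
    "fit_truncated_powerlaw",
    "fit_powerlaw_expcutoff",
    "fit_truncated_exponential",
    "loglik_ratio",
    "exponential_binning",
    "crackling_prediction",
    "mean_size_vs_duration",
    "sample_discrete_powerlaw",
    "default_fit_windows",
]

#: Minimum in-window sample count for a reported fit.
MIN_SAMPLES = 50

#: Upper summation bound of infinite-support normalizers (cutoff model
#: at very small beta); beyond it the neglected mass is irrelevant for
#: any realistic avalanche data set.
TAIL_BOUND = 1_000_000

#: Absolute exponent tolerance of the 1-D optimizations.
XTOL = 1e-6


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerLawFit:
    """Discrete truncated power-law MLE result."""

    exponent: float
    x_min: int
    x_max: Optional[int]
    n_in_window: int
    loglik: float
    degenerate: bool = False     # optimizer at a bound: no slope information
    xtol: float = XTOL

    @property
    def window(self) -> tuple[int, Optional[int]]:
        return (self.x_min, self.x_max)


@dataclass(frozen=True)
class ExpCutoffFit:
    """Power law with exponential cutoff, joint MLE over (alpha*, beta*)."""

    alpha_star: float
    beta_star: float
    x_min: int
    n_in_window: int
    loglik: float
    converged: bool = True
    message: str = ""

    @property
    def window(self) -> tuple[int, Optional[int]]:
        return (self.x_min, None)


@dataclass(frozen=True)
class ExponentialFit:
    """Discrete truncated exponential MLE result."""

    rate: float
    x_min: int
    x_max: Optional[int]
    n_in_window: int
    loglik: float

    @property
    def window(self) -> tuple[int, Optional[int]]:
        return (self.x_min, self.x_max)


@dataclass(frozen=True)
class BinnedDistribution:
    """Exponentially binned empirical density (log10 bin width b_s)."""

    bin_centers: np.ndarray
    densities: np.ndarray
    widths: np.ndarray
    b_s: float


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _window(samples: np.ndarray, x_min: int, x_max: Optional[int]) -> np.ndarray:
    x = np.asarray(samples)
    if x.size and x.min() < 0:
        raise ValueError("samples must be nonnegative integers")
    if x_min < 1:
        raise ValueError("x_min must be >= 1 for the discrete models")
    sel = x >= x_min if x_max is None else (x >= x_min) & (x <= x_max)
    return np.asarray(x[sel], dtype=np.int64)


def _log_norm_powerlaw(alpha: float, x_min: int, x_max: Optional[int]) -> float:
    """log Z with Z = sum_{k=x_min}^{x_max} k^-alpha (Hurwitz zeta tail
    for unbounded support, which requires alpha > 1)."""
    if x_max is None:
        return float(np.log(special.zeta(alpha, x_min)))
    ks = np.arange(x_min, x_max + 1, dtype=float)
    return float(special.logsumexp(-alpha * np.log(ks)))


def powerlaw_loglik(
    alpha: float, samples: np.ndarray, x_min: int, x_max: Optional[int]
) -> float:
    """Exact discrete truncated power-law loglikelihood at ``alpha``."""
    x = _window(samples, x_min, x_max)
    return float(-alpha * np.log(x).sum() - x.size * _log_norm_powerlaw(alpha, x_min, x_max))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_truncated_powerlaw(
    samples: np.ndarray,
    x_min: int,
    x_max: Optional[int],
    min_samples: int = MIN_SAMPLES,
    bounds: tuple[float, float] = (1.0 + 1e-6, 10.0),
) -> PowerLawFit:
    """MLE of the discrete power law truncated to [x_min, x_max].

    Maximizes sum log[x^-alpha / Z(alpha)] by bounded scalar
    minimization; a solution pinned at either bound (e.g. all samples
    equal to x_min) is flagged degenerate.
    """
    x = _window(samples, x_min, x_max)
    if x.size < min_samples:
        raise ValueError(
            f"only {x.size} samples inside [{x_min}, {x_max}]; "
            f"need at least {min_samples}"
        )
    slogx = float(np.log(x).sum())

    def nll(alpha: float) -> float:
        return alpha * slogx + x.size * _log_norm_powerlaw(alpha, x_min, x_max)

    res = optimize.minimize_scalar(
        nll, bounds=bounds, method="bounded", options={"xatol": XTOL}
    )
    alpha = float(res.x)
    degenerate = (alpha - bounds[0] < 10 * XTOL) or (bounds[1] - alpha < 10 * XTOL)
    return PowerLawFit(
        exponent=alpha,
        x_min=int(x_min),
        x_max=None if x_max is None else int(x_max),
        n_in_window=int(x.size),
        loglik=float(-res.fun),
        degenerate=degenerate,
    )


def _log_norm_expcutoff(alpha: float, beta: float, x_min: int) -> float:
    """log sum_{k>=x_min} k^-alpha e^-beta k, summed to TAIL_BOUND.

    For beta > 0 the sum is cut where the exponential factor is below
    1e-20 of the leading term, which leaves the result unchanged to
    double precision.
    """
    if beta > 0:
        k_hi = min(TAIL_BOUND, x_min + max(int(46.0 / beta), 10))
    else:
        k_hi = TAIL_BOUND
    ks = np.arange(x_min, k_hi + 1, dtype=float)
    return float(special.logsumexp(-alpha * np.log(ks) - beta * ks))


def fit_powerlaw_expcutoff(
    samples: np.ndarray,
    x_min: int,
    min_samples: int = MIN_SAMPLES,
) -> ExpCutoffFit:
    """Joint MLE of (alpha*, beta*) for f(x) ~ x^-alpha* e^(-beta* x)."""
    x = _window(samples, x_min, None)
    if x.size < min_samples:
        raise ValueError(
            f"only {x.size} samples >= {x_min}; need at least {min_samples}"
        )
    slogx = float(np.log(x).sum())
    sx = float(x.sum())

    def nll(p: np.ndarray) -> float:
        a, b = p
        return a * slogx + b * sx + x.size * _log_norm_expcutoff(a, b, x_min)

    res = optimize.minimize(
        nll,
        x0=np.array([1.5, 0.01]),
        method="L-BFGS-B",
        bounds=[(0.0, 10.0), (1e-9, 5.0)],
    )
    return ExpCutoffFit(
        alpha_star=float(res.x[0]),
        beta_star=float(res.x[1]),
        x_min=int(x_min),
        n_in_window=int(x.size),
        loglik=float(-res.fun),
        converged=bool(res.success),
        message=str(res.message),
    )


def fit_truncated_exponential(
    samples: np.ndarray,
    x_min: int,
    x_max: Optional[int],
    min_samples: int = MIN_SAMPLES,
) -> ExponentialFit:
    """MLE of the discrete exponential f(x) ~ e^(-lambda x) on the window."""
    x = _window(samples, x_min, x_max)
    if x.size < min_samples:
        raise ValueError(
            f"only {x.size} samples inside [{x_min}, {x_max}]; "
            f"need at least {min_samples}"
        )
    sx = float(x.sum())

    def log_norm(lam: float) -> float:
        if x_max is None:
            # geometric tail: e^-lam*x_min / (1 - e^-lam)
            return -lam * x_min - np.log1p(-np.exp(-lam))
        ks = np.arange(x_min, x_max + 1, dtype=float)
        return float(special.logsumexp(-lam * ks))

    def nll(lam: float) -> float:
        return lam * sx + x.size * log_norm(lam)

    res = optimize.minimize_scalar(
        nll, bounds=(1e-9, 10.0), method="bounded", options={"xatol": XTOL}
    )
    return ExponentialFit(
        rate=float(res.x),
        x_min=int(x_min),
        x_max=None if x_max is None else int(x_max),
        n_in_window=int(x.size),
        loglik=float(-res.fun),
    )


def loglik_ratio(model_a, model_b) -> float:
    """Signed goodness-of-fit comparison R = loglik_a - loglik_b.

    Both models must have been fitted to the same windowed sample set;
    by convention the power-law model goes first, so R > 0 means the
    data favor the power law.
    """
    if model_a.window != model_b.window or model_a.n_in_window != model_b.n_in_window:
        raise ValueError(
            "models were fitted on different sample windows: "
            f"{model_a.window} (n={model_a.n_in_window}) vs "
            f"{model_b.window} (n={model_b.n_in_window})"
        )
    return float(model_a.loglik - model_b.loglik)


# ---------------------------------------------------------------------------
# binning, scaling relation
# ---------------------------------------------------------------------------

def exponential_binning(samples: np.ndarray, b_s: float = 0.1) -> BinnedDistribution:
    """Histogram with edges at 10^(k b_s) normalized to a density.

    Bin centers are geometric means of the edges; leading empty bins
    are dropped (which is why unit-mass left cutoffs are invisible in
    binned plots).
    """
    if b_s <= 0:
        raise ValueError("b_s must be > 0")
    x = np.asarray(samples, dtype=float)
    if x.size == 0 or x.min() < 1:
        raise ValueError("samples must be >= 1 and nonempty")
    k_hi = int(np.ceil(np.log10(x.max()) / b_s)) + 1
    edges = 10.0 ** (b_s * np.arange(0, k_hi + 1))
    counts, _ = np.histogram(x, bins=edges)
    widths = np.diff(edges)
    densities = counts / (widths * x.size)
    centers = np.sqrt(edges[:-1] * edges[1:])
    first = int(np.argmax(counts > 0))
    return BinnedDistribution(
        bin_centers=centers[first:],
        densities=densities[first:],
        widths=widths[first:],
        b_s=float(b_s),
    )


def crackling_prediction(alpha: float, tau: float) -> float:
    """Crackling-noise exponent ratio gamma = (alpha - 1) / (tau - 1)."""
    if tau <= 1:
        raise ValueError("tau must exceed 1")
    return (alpha - 1.0) / (tau - 1.0)


def mean_size_vs_duration(
    avalanches, fit_window: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Mean avalanche size per duration and its log-log slope gamma.

    Groups avalanches by duration, averages S within each group, and
    fits a least-squares line to log10<S> vs log10 T over durations in
    ``fit_window``.  Returns (durations, mean sizes, gamma).
    """
    t = np.asarray(avalanches.durations)
    s = np.asarray(avalanches.sizes, dtype=float)
    lo, hi = fit_window
    lo = max(lo, 1)                      # zero durations carry no slope
    ts = np.unique(t[t >= 1])
    means = np.array([s[t == ti].mean() for ti in ts])
    in_win = (ts >= lo) & (ts <= hi)
    if in_win.sum() < 2:
        raise ValueError("need at least 2 distinct durations inside the fit window")
    gamma = float(
        np.polyfit(np.log10(ts[in_win]), np.log10(means[in_win]), 1)[0]
    )
    return ts, means, gamma


# ---------------------------------------------------------------------------
# synthetic sampler (fixture generator and round-trip oracle input)
# ---------------------------------------------------------------------------

def sample_discrete_powerlaw(
    exponent: float,
    x_min: int,
    x_max: Optional[int],
    n: int,
    rng,
) -> np.ndarray:
    """I.i.d. draws from the discrete (truncated) power law.

    Inverse-CDF sampling on the exactly normalized mass function; an
    unbounded upper tail is truncated at TAIL_BOUND (requires
    exponent > 1 so the neglected mass is tiny).
    """
    if exponent <= 1 and x_max is None:
        raise ValueError("unbounded support requires exponent > 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    hi = TAIL_BOUND if x_max is None else x_max
    ks = np.arange(x_min, hi + 1, dtype=float)
    pmf = ks ** (-float(exponent))
    cdf = np.cumsum(pmf)
    cdf /= cdf[-1]
    u = rng.random(n)
    return (x_min + np.searchsorted(cdf, u, side="left")).astype(np.int64)


def default_fit_windows(n_e: int = 200) -> dict[str, tuple[int, int]]:
    """Duration/size fit windows, scaled from the N_E=200 reference.

    At the reference size the windows are T in [6, 60] and S in
    [10, 1500].  For larger networks the upper cutoffs grow with the
    accessible avalanche scale: S_max proportionally to N_E and T_max
    with sqrt(N_E/200).
    """
    scale = n_e / 200.0
    return {
        "duration": (6, int(round(60 * np.sqrt(scale)))),
        "size": (10, int(round(1500 * scale))),
    }
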