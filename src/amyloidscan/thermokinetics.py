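"""Critical-concentration and aggregation-kinetics fitting.

Two in vitro observables complement the selection screen:

* the critical concentration ``C_crit`` — the monomer concentration at
  which fibril growth and dissociation balance — obtained by linear
  extrapolation of the endpoint fibril yield (ThioT fluorescence) versus
  the initial monomer concentration to its x-intercept, and
* the macroscopic rate constants ``lambda`` (primary-pathway composite,
  lambda = sqrt(2 k+ kn m0^nc)) and ``kappa`` (secondary-pathway
  composite, kappa = sqrt(2 k+ k2 m0^(n2+1))) obtained by fitting the
  closed-form integrated rate law for nucleated polymerisation with
  secondary nucleation to a normalised aggregation trace.

The integrated rate law is the standard fixed-point solution of the
moment equations

    dP/dt = kn m(t)^nc + k2 m(t)^n2 M(t)
    dM/dt = 2 k+ m(t) P(t),    m(t) = m_tot - M(t),

expressed entirely in terms of (lambda, kappa) and the reaction orders
(nc, n2); its accuracy is pinned against direct numerical integration of
these equations in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats


# ----------------------------------------------------------------------
# containers

@dataclass
class CcritSeries:
    """Endpoint signal versus initial monomer concentration for one variant."""

    m0: np.ndarray              # initial monomer concentrations (uM)
    signal: np.ndarray          # endpoint fluorescence (a.u.)
    label: str = ""

    def __post_init__(self) -> None:
        self.m0 = np.asarray(self.m0, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.m0.shape != self.signal.shape:
            raise ValueError("m0 and signal must have equal length")
        if np.any(self.m0 <= 0):
            raise ValueError("initial monomer concentrations must be positive")


@dataclass
class KineticTrace:
    """Time-resolved aggregate-mass signal (plateau-normalised)."""

    t: np.ndarray               # time (h), strictly increasing
    y: np.ndarray               # normalised mass signal
    m0: float | None = None     # initial monomer concentration (uM)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape:
            raise ValueError("t and y must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")


@dataclass
class CcritFit:
    c_crit: float
    slope: float
    intercept: float
    ci: tuple[float, float]
    n_points: int


@dataclass
class KineticFit:
    lambda_rate: float
    kappa_rate: float
    nc: float
    n2: float
    rss: float
    success: bool
    message: str = ""


@dataclass
class CorrelationResult:
    spearman_rho: float
    spearman_p: float
    pearson_r: float
    pearson_p: float
    n: int


# ----------------------------------------------------------------------
# critical concentration

def fit_ccrit(
    series: CcritSeries,
    detection_floor: float = 0.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> CcritFit:
    """Linear extrapolation of endpoint yield to its x-intercept (C_crit).

    Points with signal above ``detection_floor`` enter an ordinary
    least-squares fit ``signal = slope * (m0 - c_crit)``; the critical
    concentration is the x-intercept ``-intercept/slope``.  A bootstrap
    over points (``n_boot`` resamples, percentile 95% interval) quantifies
    its uncertainty.

    Raises
    ------
    ValueError : fewer than 3 points above the floor, or slope <= 0
        (no positive-yield regime to extrapolate).
    """
    mask = series.signal > detection_floor
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 points above the detection floor, got {int(mask.sum())}"
        )
    x, y = series.m0[mask], series.signal[mask]
    res = stats.linregress(x, y)
    if res.slope <= 0:
        raise ValueError("non-positive slope: no positive-yield regime")
    c_crit = -res.intercept / res.slope

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(x), len(x))
        if len(np.unique(x[idx])) < 2:
            continue
        b = stats.linregress(x[idx], y[idx])
        if b.slope > 0:
            boots.append(-b.intercept / b.slope)
    if boots:
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    else:
        ci = (float("nan"), float("nan"))
    return CcritFit(float(c_crit), float(res.slope), float(res.intercept),
                    ci, int(mask.sum()))


# ----------------------------------------------------------------------
# integrated rate law

def _log_b_plus_cexp(b: float, c_plus: float, e: np.ndarray) -> np.ndarray:
    """log(b + c_plus * exp(e)), stable for large e.

    Both arguments of the log are provably positive for valid parameters
    (b + c_plus >= 0 and c_plus * exp(e) grows), so no complex branch is
    needed.
    """
    out = np.empty_like(e)
    small = e < 30.0
    out[small] = np.log(b + c_plus * np.exp(e[small]))
    big = ~small
    if np.any(big):
        out[big] = e[big] + np.log(c_plus) + np.log1p(
            b * np.exp(-e[big]) / c_plus
        )
    return out


def model_mass(
    t: np.ndarray,
    lambda_rate: float,
    kappa_rate: float,
    nc: float = 2.0,
    n2: float = 2.0,
) -> np.ndarray:
    """Normalised aggregate mass M(t)/M_inf of the integrated rate law.

    Parameters
    ----------
    t : time grid (same units as 1/lambda_rate).
    lambda_rate : composite primary-pathway rate constant (> 0).
    kappa_rate : composite secondary-pathway rate constant (>= 0).
    nc, n2 : primary and secondary nucleation reaction orders.

    With ``kappa_rate`` ~ 0 the solution degenerates to the
    primary-nucleation (Oosawa) closed form
    ``1 - sech(sqrt(nc/2) lambda t)^(2/nc)``, used below a relative
    threshold of 1e-6 to avoid catastrophic cancellation.
    """
    t = np.asarray(t, dtype=float)
    lam = float(lambda_rate)
    kap = float(kappa_rate)
    if lam <= 0:
        raise ValueError("lambda_rate must be positive")
    if kap < 0:
        raise ValueError("kappa_rate must be non-negative")

    if kap <= 1e-6 * lam:
        z = np.sqrt(nc / 2.0) * lam * t
        return 1.0 - np.cosh(z) ** (-2.0 / nc)

    c_plus = lam**2 / (2.0 * kap**2)
    k_inf = np.sqrt(2.0 * kap**2 / (n2 * (n2 + 1.0)) + 2.0 * lam**2 / nc)
    k_bar = np.sqrt(k_inf**2 + 4.0 * c_plus**2 * kap**2)
    b_plus = (k_inf + k_bar) / (2.0 * kap)
    b_minus = (k_inf - k_bar) / (2.0 * kap)

    e = kap * t
    log_bracket = (
        np.log(b_plus + c_plus)
        - _log_b_plus_cexp(b_plus, c_plus, e)
        + _log_b_plus_cexp(b_minus, c_plus, e)
        - np.log(b_minus + c_plus)
    )
    exponent = k_inf**2 / (kap * k_bar)
    return 1.0 - np.exp(exponent * log_bracket - k_inf * t)


def half_time(
    lambda_rate: float, kappa_rate: float, nc: float = 2.0, n2: float = 2.0
) -> float:
    """Time at which the normalised mass reaches one half."""
    f = lambda t: model_mass(np.array([t]), lambda_rate, kappa_rate, nc, n2)[0] - 0.5
    hi = 1.0 / max(lambda_rate, kappa_rate)
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("half-time search did not bracket")
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-12))


# ----------------------------------------------------------------------
# kinetic fitting

def normalize_trace(
    trace: KineticTrace, n_baseline: int = 3, n_plateau: int = 5
) -> KineticTrace:
    """Rescale a raw trace to [0, 1] using baseline and plateau averages.

    Baseline = mean of the first ``n_baseline`` points, plateau = mean of
    the last ``n_plateau`` points.
    """
    base = float(np.mean(trace.y[:n_baseline]))
    top = float(np.mean(trace.y[-n_plateau:]))
    if top <= base:
        raise ValueError("plateau does not exceed baseline; cannot normalise")
    return KineticTrace(trace.t, (trace.y - base) / (top - base), trace.m0)


def fit_kinetics(
    trace: KineticTrace,
    nc: float = 2.0,
    n2: float = 2.0,
    bounds: tuple[float, float] = (1e-3, 1e3),
    grid_size: int = 5,
    normalize: bool = False,
) -> KineticFit:
    """Fit (lambda, kappa) of :func:`model_mass` to a normalised trace.

    Nonlinear least squares in log-parameter space from a deterministic
    ``grid_size x grid_size`` log-spaced multi-start grid spanning
    ``bounds`` (the same bounds apply to both rates).  The best
    (lowest-RSS) converged fit is returned; if no start converges the fit
    is flagged as failed rather than silently defaulted.
    """
    if normalize:
        trace = normalize_trace(trace)
    t, y = trace.t, trace.y
    lo, hi = np.log(bounds[0]), np.log(bounds[1])

    def residuals(logp: np.ndarray) -> np.ndarray:
        lam, kap = np.exp(logp)
        return model_mass(t, lam, kap, nc, n2) - y

    starts = np.linspace(lo, hi, grid_size)
    best: KineticFit | None = None
    for la in starts:
        for ka in starts:
            try:
                sol = optimize.least_squares(
                    residuals, x0=[la, ka], bounds=([lo, lo], [hi, hi]),
                    method="trf",
                )
            except Exception:
                continue
            if not sol.success:
                continue
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best.rss:
                lam, kap = np.exp(sol.x)
                best = KineticFit(float(lam), float(kap), nc, n2, rss, True)
    if best is None:
        return KineticFit(float("nan"), float("nan"), nc, n2, float("inf"),
                          False, "no start converged")
    return best


# ----------------------------------------------------------------------
# correlation of in vitro observables with fitness

def rank_correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman and Pearson correlation with two-sided p-values.

    Used e.g. for variant fitness versus log2(C_crit variant / C_crit WT),
    versus lambda, and versus kappa across a panel of purified variants.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    sp = stats.spearmanr(x, y)
    pe = stats.pearsonr(x, y)
    return CorrelationResult(
        float(sp.statistic), float(sp.pvalue),
        float(pe.statistic), float(pe.pvalue), len(x),
    )
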