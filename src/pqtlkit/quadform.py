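"""P-values for quadratic forms in standard normal variables.

The null distribution of variance-component score statistics (SKAT-type
tests) is a positively weighted sum of independent one-degree-of-freedom
chi-square variables, ``Q ~ sum_i lambda_i * chi2_1``.  Tail probabilities
are computed by numerical inversion of the characteristic function
(Imhof's method) with a moment-matching noncentral-chi-square
approximation (Liu's method, with Lee's kurtosis modification) as a
fallback and as the cheap vectorised route used in bulk simulations.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, stats

__all__ = ["imhof_sf", "liu_params", "liu_sf", "liu_ppf", "quadform_sf"]


def imhof_sf(q: float, lam: np.ndarray, *, limit: int = 200, epsabs: float = 1e-10) -> tuple[float, bool]:
    """Upper-tail probability P(Q > q) by Imhof's integral.

    Returns ``(p, converged)``.  ``lam`` are the (positive) weights of the
    chi-square mixture; zero weights are dropped.
    """
    lam = np.asarray(lam, dtype=float)
    lam = lam[np.abs(lam) > 1e-12 * max(1.0, np.max(np.abs(lam)) if lam.size else 1.0)]
    if lam.size == 0:
        return 1.0, True

    def theta(u):
        return 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u

    def rho(u):
        return np.prod((1.0 + (lam * u) ** 2) ** 0.25)

    def integrand(u):
        if u == 0.0:
            return 0.5 * (np.sum(lam) - q)
        return np.sin(theta(u)) / (u * rho(u))

    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            val, err = integrate.quad(integrand, 0.0, np.inf, limit=limit, epsabs=epsabs)
    except Exception:  # pragma: no cover - scipy integration failure
        return np.nan, False
    p = 0.5 + val / np.pi
    converged = np.isfinite(p) and err < 1e-4
    return float(min(max(p, 0.0), 1.0)), bool(converged)


def liu_params(lam: np.ndarray) -> dict:
    """Moment-matching parameters for the Liu (Lee-modified) approximation."""
    lam = np.asarray(lam, dtype=float)
    c1 = lam.sum()
    c2 = (lam**2).sum()
    c3 = (lam**3).sum()
    c4 = (lam**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2.0 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
    mu_q = c1
    sigma_q = np.sqrt(2.0 * c2)
    mu_x = df + delta
    sigma_x = np.sqrt(2.0 * (df + 2.0 * delta))
    return {"df": df, "delta": delta, "mu_q": mu_q, "sigma_q": sigma_q, "mu_x": mu_x, "sigma_x": sigma_x}

def liu_sf(q, lam=None, *, params: dict | None = None):
    """Upper-tail probability by noncentral-chi-square moment matching.

    Vectorised over ``q``; pass ``params`` from :func:`liu_params` to reuse
    the mixture moments across many statistics.
    """
    if params is None:
        params = liu_params(lam)
    q = np.asarray(q, dtype=float)
    z = (q - params["mu_q"]) / params["sigma_q"]
    x = z * params["sigma_x"] + params["mu_x"]
    return stats.ncx2.sf(x, params["df"], params["delta"])


def liu_ppf(alpha, lam=None, *, params: dict | None = None):
    """Quantile q with P(Q > q) = alpha under the Liu approximation."""
    if params is None:
        params = liu_params(lam)
    x = stats.ncx2.isf(alpha, params["df"], params["delta"])
    z = (x - params["mu_x"]) / params["sigma_x"]
    return z * params["sigma_q"] + params["mu_q"]


def quadform_sf(q: float, lam: np.ndarray, method: str = "auto") -> tuple[float, str]:
    """P(Q > q) for Q = sum lambda_i chi2_1.

    ``method='auto'`` tries characteristic-function inversion first and
    falls back to moment matching when the integral does not converge or
    returns a degenerate value.  Returns ``(p, method_used)``.
    """
    lam = np.asarray(lam, dtype=float)
    if method not in {"auto", "imhof", "liu"}:
        raise ValueError(f"unknown method {method!r}")
    if method in {"auto", "imhof"}:
        p, ok = imhof_sf(q, lam)
        if ok and 0.0 < p <= 1.0:
            return p, "imhof"
        if method == "imhof":
            return p, "imhof"
    p = float(liu_sf(q, lam))
    return min(max(p, 0.0), 1.0), "liu"
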