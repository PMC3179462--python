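"""Degree-distribution characterization: CCDF and broad-scale fits.

Small-world networks fall into three classes by degree distribution:
scale-free (pure power law), broad-scale (power law with an exponential
cutoff), and single-scale (fast-decaying tail).  We work on the
complementary cumulative distribution P(K >= k) to reduce noise, test
straight-line decay in a double-logarithmic plot by its coefficient of
determination, and fit the truncated power-law form
P(K >= k) = c * k^(alpha-1) * exp(-k / k_c), whose good fit (R^2 close
to 1) is the signature of a broad-scale network: hubs exist, extreme
hubs do not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .graph import BackboneGraph

#: Upper bound on the cutoff scale; estimates at or near this bound mean
#: "no visible cutoff" (the data are consistent with a pure power law).
K_CUTOFF_MAX = 1e6


def degree_ccdf(g: BackboneGraph | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Complementary cumulative degree distribution.

    Accepts a graph or a raw degree sequence.  Returns integer degrees k
    from min(degree) to max(degree)+1 and P(K >= k); the first entry is 1
    and the last 0, and the sequence is nonincreasing.
    """
    deg = g.degree if isinstance(g, BackboneGraph) else np.asarray(g)
    deg = np.sort(deg)
    k = np.arange(deg[0], deg[-1] + 2)
    p = 1.0 - np.searchsorted(deg, k, side="left") / deg.size
    return k, p


@dataclass
class LogLogFit:
    slope: float
    intercept: float
    r2: float
    gradient_magnitude: float
    fit_range: tuple[int, int]
    degenerate: bool = False


def fit_loglog_line(
    k: np.ndarray,
    p: np.ndarray,
    fit_range: tuple[float, float] | None = None,
) -> LogLogFit:
    """Least-squares straight line on (log k, log P).

    Only points with k > 0 and P > 0 (within ``fit_range``, inclusive)
    enter the fit; at least 3 are required.  ``gradient_magnitude`` is
    |slope|.  A constant P is degenerate: slope 0 with R^2 = 1 by the
    zero-variance convention, flagged.
    """
    k = np.asarray(k, dtype=float)
    p = np.asarray(p, dtype=float)
    keep = (k > 0) & (p > 0)
    if fit_range is not None:
        keep &= (k >= fit_range[0]) & (k <= fit_range[1])
    if keep.sum() < 3:
        raise ValueError("log-log fit needs >= 3 positive points in range")
    lk, lp = np.log(k[keep]), np.log(p[keep])
    used = (int(k[keep].min()), int(k[keep].max()))
    if np.allclose(lp, lp[0]):
        return LogLogFit(0.0, float(lp[0]), 1.0, 0.0, used, degenerate=True)
    res = stats.linregress(lk, lp)
    return LogLogFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        gradient_magnitude=abs(float(res.slope)),
        fit_range=used,
    )


@dataclass
class DegreeFit:
    """Truncated power-law fit of a degree CCDF."""

    alpha: float
    k_cutoff: float
    c: float
    r2_truncated: float
    r2_loglog: float
    loglog: LogLogFit
    fit_range: tuple[int, int]

    def predict(self, k: np.ndarray) -> np.ndarray:
        k = np.asarray(k, dtype=float)
        return self.c * k ** (self.alpha - 1.0) * np.exp(-k / self.k_cutoff)


def _truncated_log_model(log_k, log_c, alpha, k_cutoff):
    return log_c + (alpha - 1.0) * log_k - np.exp(log_k) / k_cutoff


def fit_truncated_powerlaw(
    k: np.ndarray,
    p: np.ndarray,
    loglog_range: tuple[float, float] | None = None,
) -> DegreeFit:
    """Fit P(K >= k) = c * k^(alpha-1) * exp(-k/k_c) in log space.

    Nonlinear least squares on log P with multi-start initialization
    (several alpha and cutoff starting points); also reports the
    straight-line log-log fit.  When ``loglog_range`` is not given, the
    line is fitted to the power-law regime k <= k_c ("linear decay before
    the sharp cutoff"), falling back to all positive points if that
    leaves fewer than 3.  For data with no cutoff, k_c runs to the
    ``K_CUTOFF_MAX`` bound (i.e. beyond any observed degree).
    """
    k = np.asarray(k, dtype=float)
    p = np.asarray(p, dtype=float)
    keep = (k > 0) & (p > 0)
    if keep.sum() < 4:
        raise ValueError("truncated power-law fit needs >= 4 positive points")
    lk, lp = np.log(k[keep]), np.log(p[keep])
    k_max = k[keep].max()

    best = None
    for alpha0 in (1.5, 2.5, 3.5):
        for kc0 in (k_max / 4, k_max, 4 * k_max):
            try:
                popt, _ = optimize.curve_fit(
                    _truncated_log_model,
                    lk,
                    lp,
                    p0=(0.0, alpha0, kc0),
                    bounds=([-np.inf, -10.0, 1e-6], [np.inf, 10.0, K_CUTOFF_MAX]),
                    maxfev=20000,
                )
            except RuntimeError:
                continue
            resid = lp - _truncated_log_model(lk, *popt)
            sse = float(resid @ resid)
            if best is None or sse < best[0]:
                best = (sse, popt)
    if best is None:
        raise RuntimeError(
            "truncated power-law fit did not converge from any start "
            f"(n={keep.sum()}, k range {k[keep].min()}..{k_max})"
        )
    sse, (log_c, alpha, k_cutoff) = best
    ss_tot = float(((lp - lp.mean()) ** 2).sum())
    r2_trunc = 1.0 if ss_tot == 0 else 1.0 - sse / ss_tot

    if loglog_range is None:
        rng = (k[keep].min(), min(k_cutoff, k_max))
        in_rng = (k[keep] >= rng[0]) & (k[keep] <= rng[1])
        if in_rng.sum() < 3:
            rng = (k[keep].min(), k_max)
    else:
        rng = loglog_range
    line = fit_loglog_line(k, p, rng)

    return DegreeFit(
        alpha=float(alpha),
        k_cutoff=float(k_cutoff),
        c=float(np.exp(log_c)),
        r2_truncated=float(r2_trunc),
        r2_loglog=line.r2,
        loglog=line,
        fit_range=(int(k[keep].min()), int(k_max)),
    )


def degree_fit(g: BackboneGraph, **kwargs) -> DegreeFit:
    """Convenience: CCDF of a graph's degrees plus the truncated fit."""
    k, p = degree_ccdf(g)
    return fit_truncated_powerlaw(k, p, **kwargs)
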