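"""Mendelian randomisation: single-instrument two-stage least squares.

Uses the SNP genotype ``G`` as an instrumental variable for the putative
exposure ``X`` to test the causal effect X -> Y.  With one instrument the
2SLS estimate coincides algebraically with the Wald ratio
``cov(G, Y) / cov(G, X)``.  The standard error is the textbook
homoskedastic second-stage one (structural residuals ``y - a - b x``
evaluated with the *observed* exposure) and the p-value is a
normal-approximation Wald test of the fitted-exposure coefficient.
A detection is declared when p < threshold (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from ._exceptions import DegenerateDataError
from ._validation import unpack_triplet


@dataclass
class MrResult:
    """Outcome of one MR test.

    ``weak_instrument`` is set when the instrument-exposure covariance is
    numerically zero (including the monomorphic-genotype case); such
    results always count as non-detections.
    """

    beta_iv: float
    se: float
    p_value: float
    detected: bool
    threshold: float = 0.05
    weak_instrument: bool = False
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "beta_iv": self.beta_iv, "se": self.se, "p_value": self.p_value,
            "detected": self.detected, "threshold": self.threshold,
            "weak_instrument": self.weak_instrument, "degenerate": self.degenerate,
        }


class MendelianRandomization(BaseEstimator):
    """Single-instrument 2SLS estimator of the X -> Y causal effect.

    Parameters
    ----------
    threshold : float, default=0.05
        Significance level below which ``detected_`` is set.

    Attributes
    ----------
    beta_iv_ : float
        Instrumental-variable (Wald-ratio) estimate of the causal effect.
    se_ : float
        Homoskedastic second-stage standard error.
    p_value_ : float
        Two-sided normal-approximation Wald p-value.
    detected_ : bool
        ``p_value_ < threshold`` (always False for flagged results).
    weak_instrument_, degenerate_ : bool
        Data-quality flags; see :class:`MrResult`.
    """

    def __init__(self, threshold: float = 0.05):
        self.threshold = threshold

    def fit(self, X, y=None):
        """Fit on an ``(n, 3)`` array (or DataFrame) with columns ``g, x, y``."""
        g, x, yv = unpack_triplet(X)
        res = mr_test(g, x, yv, threshold=self.threshold)
        self.result_ = res
        self.beta_iv_ = res.beta_iv
        self.se_ = res.se
        self.p_value_ = res.p_value
        self.detected_ = res.detected
        self.weak_instrument_ = res.weak_instrument
        self.degenerate_ = res.degenerate
        return self


def mr_test(g, x, y, threshold: float = 0.05) -> MrResult:
    """Run the single-instrument 2SLS (Wald-ratio) test of X -> Y.

    Returns a flagged, non-detected result instead of raising when the
    genotype is monomorphic or the instrument-exposure covariance is
    numerically zero, so replicated benchmarks can count such replicates
    as non-detections rather than aborting.
    """
    g = np.asarray(g, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(g)
    if not (len(x) == len(y) == n):
        raise ValueError("g, x, y must have equal length")
    if n < 3:
        raise ValueError("need at least 3 observations")

    gc = g - g.mean()
    xc = x - x.mean()
    yc = y - y.mean()
    s_gg = gc @ gc
    s_xx = xc @ xc
    if s_gg == 0.0:
        return MrResult(np.nan, np.nan, np.nan, False, threshold,
                        weak_instrument=True, degenerate=True)
    s_gx = gc @ xc
    s_gy = gc @ yc
    # instrument relevance: |corr(g, x)| numerically zero
    weak = s_xx == 0.0 or abs(s_gx) < 1e-12 * np.sqrt(s_gg * s_xx)
    if weak:
        return MrResult(np.nan, np.nan, np.nan, False, threshold,
                        weak_instrument=True)

    beta = s_gy / s_gx  # 2SLS == Wald ratio for a single instrument
    resid = yc - beta * xc  # structural residuals use the observed exposure
    sigma2 = (resid @ resid) / (n - 2)
    # var(beta) = sigma2 / sum((xhat - xbar)^2), with xhat the first-stage fit
    var_beta = sigma2 * s_gg / (s_gx * s_gx)
    se = float(np.sqrt(var_beta))
    if se == 0.0:
        p = 0.0 if beta != 0.0 else 1.0
    else:
        p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return MrResult(float(beta), se, p, bool(p < threshold), threshold)
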