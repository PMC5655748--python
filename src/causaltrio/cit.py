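"""Causal inference test (CIT) for complete mediation G -> X -> Y.

The test declares that X mediates, and is the only causal link between,
the genotype G and the outcome Y.  It is an intersection-union test over
four component conditions, each giving a p-value:

1. ``p1``: G is associated with Y            (F test of G in Y ~ G)
2. ``p2``: G is associated with X given Y    (partial F of G in X ~ Y + G)
3. ``p3``: X is associated with Y given G    (partial F of X in Y ~ G + X)
4. ``p4``: Y is independent of G given X     (permutation equivalence test)

The omnibus p-value is the maximum of the four; significance therefore
requires every condition to hold jointly.  Condition 4 is an
*equivalence* test — small ``p4`` supports conditional independence — and
is built by permutation: the observed statistic is the partial F for G in
``Y ~ X + G``; each null replicate permutes the residuals of X given G
(keeping the fitted G-component in place), which preserves both the X-G
association and G's marginal effect on Y while destroying the part of the
mediation adjustment that is not due to G, and recomputes the partial F.
``p4`` is the add-one permutation proportion of null statistics *at or
below* the observed one, so it lies in ``[1/(B+1), 1]`` and never
reaches zero.  Under a true chain the observed residual G effect sits far
below the no-mediation reference (small p4); when the adjustment owes
nothing to X beyond its G-component — e.g. when a latent confounder,
not X itself, carries the X-Y link — observed and reference statistics
are exchangeable and p4 is diffuse, blocking detection.

The genotype enters all regressions as a numeric 0/1/2 covariate by
default, consistent with the additive generative model; a 2-df factor
coding is available via ``coding="factor"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from ._validation import unpack_triplet


@dataclass
class CitResult:
    p1: float
    p2: float
    p3: float
    p4: float
    p_omnibus: float
    detected: bool
    b_perm: int
    threshold: float = 0.05
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "p1": self.p1, "p2": self.p2, "p3": self.p3, "p4": self.p4,
            "p_omnibus": self.p_omnibus, "detected": self.detected,
            "b_perm": self.b_perm, "threshold": self.threshold,
            "degenerate": self.degenerate,
        }


class CausalInferenceTest(BaseEstimator):
    """Four-component mediation test with a permutation equivalence test.

    Parameters
    ----------
    b_perm : int, default=1000
        Number of permutations for the conditional-independence component
        (must be >= 100).
    threshold : float, default=0.05
        Detection level for the omnibus p-value.
    coding : {"additive", "factor"}, default="additive"
        How the genotype enters the component regressions.
    random_state : int, Generator or None
        Seeds the permutation stream.

    Attributes
    ----------
    p1_, p2_, p3_, p4_ : float
        Component p-values.
    p_omnibus_ : float
        ``max(p1_, p2_, p3_, p4_)`` — the intersection-union p-value.
    detected_ : bool
    """

    def __init__(self, b_perm: int = 1000, threshold: float = 0.05,
                 coding: str = "additive", random_state=None):
        self.b_perm = b_perm
        self.threshold = threshold
        self.coding = coding
        self.random_state = random_state

    def fit(self, X, y=None):
        g, x, yv = unpack_triplet(X)
        rng = np.random.default_rng(self.random_state)
        res = cit_test(g, x, yv, b_perm=self.b_perm, threshold=self.threshold,
                       coding=self.coding, rng=rng)
        self.result_ = res
        self.p1_, self.p2_, self.p3_, self.p4_ = res.p1, res.p2, res.p3, res.p4
        self.p_omnibus_ = res.p_omnibus
        self.detected_ = res.detected
        return self


def _genotype_columns(g: np.ndarray, coding: str) -> np.ndarray:
    if coding == "additive":
        return g[:, None]
    if coding == "factor":
        levels = np.unique(g)[1:]  # reference = lowest level present
        return (g[:, None] == levels[None, :]).astype(float)
    raise ValueError(f"unknown genotype coding {coding!r}")


def _ols_f_added(resp: np.ndarray, base_cols: list[np.ndarray],
                 added: np.ndarray) -> float:
    """p-value for adding `added` columns to an intercept + base regression."""
    if np.ptp(resp) == 0.0:
        return 1.0
    n = len(resp)
    x0 = np.column_stack([np.ones(n)] + base_cols) if base_cols else np.ones((n, 1))
    x1 = np.column_stack([x0, added])
    fit1 = sm.OLS(resp, x1).fit()
    fit0 = sm.OLS(resp, x0).fit()
    _, p, _ = fit1.compare_f_test(fit0)
    return 1.0 if np.isnan(p) else float(p)


def _partial_f_g_additive(yc, xc, gc, s_yy, s_gg, s_gy, n):
    """Partial F for centred g in y ~ x + g, closed form (1 df)."""
    s_xx = xc @ xc
    s_xy = xc @ yc
    s_xg = xc @ gc
    det = s_xx * s_gg - s_xg * s_xg
    with np.errstate(divide="ignore", invalid="ignore"):
        rss_full = s_yy - (s_gg * s_xy**2 - 2 * s_xg * s_xy * s_gy + s_xx * s_gy**2) / det
        rss_red = s_yy - s_xy**2 / s_xx
        f = (rss_red - rss_full) / (rss_full / (n - 3))
    return f


def _partial_f_g_lstsq(y, x, gcols):
    n = len(y)
    x0 = np.column_stack([np.ones(n), x])
    x1 = np.column_stack([x0, gcols])
    rss0 = np.linalg.lstsq(x0, y, rcond=None)[1]
    rss1 = np.linalg.lstsq(x1, y, rcond=None)[1]
    rss0 = float(rss0[0]) if len(rss0) else 0.0
    rss1 = float(rss1[0]) if len(rss1) else 0.0
    k = gcols.shape[1]
    if rss1 <= 0:
        return np.inf
    return (rss0 - rss1) / k / (rss1 / (n - x1.shape[1]))


def cit_test(g, x, y, b_perm: int = 1000, threshold: float = 0.05,
             coding: str = "additive", rng=None) -> CitResult:
    """Run the four-component causal inference test of G -> X -> Y.

    See the module docstring for the construction of each component.
    A zero-variance genotype makes every component return p = 1 and flags
    the result as degenerate.
    """
    g = np.asarray(g, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(g)
    if not (len(x) == len(y) == n):
        raise ValueError("g, x, y must have equal length")
    if b_perm < 100:
        raise ValueError(f"b_perm must be >= 100, got {b_perm}")
    rng = np.random.default_rng(rng)

    if np.ptp(g) == 0.0:
        return CitResult(1.0, 1.0, 1.0, 1.0, 1.0, False, b_perm, threshold,
                         degenerate=True)

    gcols = _genotype_columns(g, coding)
    p1 = _ols_f_added(y, [], gcols)
    p2 = _ols_f_added(x, [y], gcols)
    p3 = _ols_f_added(y, [gcols], x[:, None])
    p4 = _permutation_equivalence_p(g, x, y, gcols, b_perm, coding, rng)

    p_omni = max(p1, p2, p3, p4)
    return CitResult(p1, p2, p3, p4, p_omni, bool(p_omni < threshold),
                     b_perm, threshold)


def _permutation_equivalence_p(g, x, y, gcols, b_perm, coding, rng) -> float:
    """Permutation p-value for the condition Y independent of G given X."""
    n = len(y)
    if np.ptp(y) == 0.0:
        return 1.0
    if coding == "additive":
        yc = y - y.mean()
        gc = g - g.mean()
        xc = x - x.mean()
        s_yy = yc @ yc
        s_gg = gc @ gc
        s_gy = gc @ yc
        f_obs = _partial_f_g_additive(yc, xc, gc, s_yy, s_gg, s_gy, n)
        # null draws keep each individual's fitted G-component of X and
        # permute only the X residuals: the X-G association and the
        # marginal G-Y association survive, the residual X-Y link dies
        bhat = (gc @ xc) / s_gg if s_gg > 0 else 0.0
        x_fit = bhat * gc
        x_res = xc - x_fit
        perm_idx = rng.permuted(np.broadcast_to(np.arange(n), (b_perm, n)), axis=1)
        xp = x_fit[None, :] + x_res[perm_idx]  # (B, n), centred
        s_xx = np.einsum("bi,bi->b", xp, xp)
        s_xy = xp @ yc
        s_xg = xp @ gc
        det = s_xx * s_gg - s_xg**2
        with np.errstate(divide="ignore", invalid="ignore"):
            rss_full = s_yy - (s_gg * s_xy**2 - 2 * s_xg * s_xy * s_gy
                               + s_xx * s_gy**2) / det
            rss_red = s_yy - s_xy**2 / s_xx
            f_null = (rss_red - rss_full) / (rss_full / (n - 3))
        f_null = np.where(np.isfinite(f_null), f_null, np.inf)
    else:
        f_obs = _partial_f_g_lstsq(y, x, gcols)
        design = np.column_stack([np.ones(n), gcols])
        coef, _, _, _ = np.linalg.lstsq(design, x, rcond=None)
        x_fit = design @ coef
        x_res = x - x_fit
        f_null = np.empty(b_perm)
        for b in range(b_perm):
            f_null[b] = _partial_f_g_lstsq(y, x_fit + rng.permutation(x_res),
                                           gcols)
    # add-one estimator: small p4 means the observed conditional G effect is
    # far below the no-mediation null, i.e. supports Y _||_ G | X
    return float((1 + np.sum(f_null <= f_obs)) / (b_perm + 1))
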