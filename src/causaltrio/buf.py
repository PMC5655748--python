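"""Bayesian partition framework: classify each trait as U, D or I.

Each of the two traits is assigned one of three association classes with
respect to the genotype G: ``U`` (unassociated), ``D`` (directly
associated) or ``I`` (indirectly associated, i.e. associated only through
the other trait).  The nine ``(x_class, y_class)`` partitions are scored
by a Bayes factor against the all-unassociated reference ``(U, U)``.

Five partitions coincide with lettered causal models:

    (D, D) = a    (D, I) = b    (I, D) = c    (D, U) = m    (U, D) = n

Under the partition likelihood the joint density factorises as
``p(U vars) * p(D vars | U vars, G) * p(I vars | D vars, U vars)``; the
I-factor does not involve G, so against (U, U) everything cancels except
one conjugate Bayesian regression Bayes factor ("G in" vs "G out") per
D-classified trait, with any U-trait as a covariate:

    BF(D,U) = BF1(x | cov y)      BF(U,D) = BF1(y | cov x)
    BF(D,I) = BF1(x)              BF(I,D) = BF1(y)
    BF(D,D) = BF1(x) * BF1(y | cov x)
    no D trait                ->  BF = 1

``BF1`` places a zero-centred normal prior with scale ``sigma_a`` on the
genotype effect (on the response standardised to unit variance), a flat
prior on intercept/covariate coefficients and a scale-invariant prior on
the residual variance, and averages the resulting closed-form Bayes
factor uniformly over a grid of prior scales.  The default grid
(0.05, 0.1, 0.2, 0.4) is the published default of the conjugate
genotype-regression framework this score follows.  Reported values are
log10 Bayes factors; the highest-scoring partition is selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from ._exceptions import DegenerateDataError
from ._validation import unpack_triplet

#: The nine (x_class, y_class) partitions, row-major over {U, D, I}.
PARTITIONS: tuple[tuple[str, str], ...] = tuple(
    (cx, cy) for cx in ("U", "D", "I") for cy in ("U", "D", "I")
)

#: Partitions that coincide with lettered causal models.
PARTITION_ALIASES: dict[tuple[str, str], str] = {
    ("D", "D"): "a", ("D", "I"): "b", ("I", "D"): "c",
    ("D", "U"): "m", ("U", "D"): "n",
}
ALIAS_TO_PARTITION = {v: k for k, v in PARTITION_ALIASES.items()}

DEFAULT_SIGMA_A_GRID: tuple[float, ...] = (0.05, 0.1, 0.2, 0.4)

_TIE_TOL = 1e-12


@dataclass
class BufResult:
    log10_bf: dict
    selected: tuple
    tie_flag: bool
    sigma_a_grid: tuple

    @property
    def selected_alias(self) -> str | None:
        return PARTITION_ALIASES.get(self.selected)

    def to_dict(self) -> dict:
        table = {}
        for part, val in self.log10_bf.items():
            key = "".join(part)
            table[key] = {"log10_bf": val,
                          "alias": PARTITION_ALIASES.get(part)}
        return {"log10_bf": table,
                "selected": "".join(self.selected),
                "selected_alias": self.selected_alias,
                "tie_flag": self.tie_flag,
                "sigma_a_grid": list(self.sigma_a_grid)}


def log10_bf1(response, g, covariate=None,
              sigma_a_grid: Sequence[float] = DEFAULT_SIGMA_A_GRID) -> float:
    """log10 Bayes factor for including G in one Gaussian regression.

    The response is standardised to unit sample variance (the prior on the
    genotype effect is expressed on that scale); the covariate, if any,
    enters with a flat prior so its scaling is irrelevant.
    """
    w = np.asarray(response, dtype=float)
    g = np.asarray(g, dtype=float)
    n = len(w)
    sd = w.std(ddof=1)
    if not sd > 0:
        raise DegenerateDataError("response has zero variance")
    w = (w - w.mean()) / sd

    cols = [np.ones(n)]
    if covariate is not None:
        cols.append(np.asarray(covariate, dtype=float))
    C = np.column_stack(cols)
    k = C.shape[1]
    # project the nuisance columns out of both response and genotype
    beta_w, _, _, _ = np.linalg.lstsq(C, w, rcond=None)
    beta_g, _, _, _ = np.linalg.lstsq(C, g, rcond=None)
    wr = w - C @ beta_w
    gr = g - C @ beta_g
    rss0 = float(wr @ wr)
    s_gg = float(gr @ gr)
    s_gw = float(gr @ wr)
    if rss0 <= 0:
        raise DegenerateDataError("response fully explained by nuisance terms")
    if s_gg <= 0:
        # monomorphic genotype carries no evidence either way
        return 0.0

    grid = np.asarray(sigma_a_grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("sigma_a_grid must be nonempty with positive entries")
    log_bfs = np.empty(grid.size)
    for i, sa in enumerate(grid):
        shrink = rss0 - s_gw**2 / (s_gg + sa**-2)
        log_bfs[i] = (-0.5 * np.log1p(sa**2 * s_gg)
                      - 0.5 * (n - k) * (np.log(shrink) - np.log(rss0)))
    # uniform average over the prior-scale grid, in Bayes-factor space
    return float((logsumexp(log_bfs) - np.log(grid.size)) / np.log(10.0))


def buf_bf(g, x, y, sigma_a_grid: Sequence[float] = DEFAULT_SIGMA_A_GRID) -> BufResult:
    """Score all nine partitions by log10 Bayes factor against (U, U)."""
    g = np.asarray(g, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = tuple(float(s) for s in sigma_a_grid)
    if len(grid) == 0 or any(s <= 0 for s in grid):
        raise ValueError("sigma_a_grid must be nonempty with positive entries")

    bf_x = log10_bf1(x, g, sigma_a_grid=grid)
    bf_y = log10_bf1(y, g, sigma_a_grid=grid)
    bf_x_given_y = log10_bf1(x, g, covariate=y, sigma_a_grid=grid)
    bf_y_given_x = log10_bf1(y, g, covariate=x, sigma_a_grid=grid)

    table: dict[tuple[str, str], float] = {}
    for part in PARTITIONS:
        cx, cy = part
        if cx == "D" and cy == "D":
            val = bf_x + bf_y_given_x
        elif cx == "D":
            val = bf_x_given_y if cy == "U" else bf_x
        elif cy == "D":
            val = bf_y_given_x if cx == "U" else bf_y
        else:
            val = 0.0  # no directly associated trait: all factors cancel
        table[part] = float(val)

    best = max(table.values())
    top = [p for p in PARTITIONS if table[p] >= best - _TIE_TOL]
    selected = top[0]
    return BufResult(table, selected, len(top) > 1, grid)


def buf_select(result: BufResult, correct) -> bool:
    """True iff the unique argmax partition equals ``correct``.

    ``correct`` may be a partition tuple or a lettered alias.  Ties count
    as incorrect (and are flagged on the result).
    """
    if isinstance(correct, str):
        correct = ALIAS_TO_PARTITION[correct]
    if result.tie_flag:
        return False
    return result.selected == tuple(correct)


class BayesFactorPartition(BaseEstimator):
    """Highest-Bayes-factor selection among the nine U/D/I partitions.

    Attributes
    ----------
    log10_bf_ : dict of (str, str) -> float
    selected_ : tuple of (str, str)
    selected_alias_ : str or None
        Lettered model name of the selected partition, when one exists.
    tie_flag_ : bool
    """

    def __init__(self, sigma_a_grid: Sequence[float] = DEFAULT_SIGMA_A_GRID):
        self.sigma_a_grid = sigma_a_grid

    def fit(self, X, y=None):
        g, x, yv = unpack_triplet(X)
        res = buf_bf(g, x, yv, sigma_a_grid=self.sigma_a_grid)
        self.result_ = res
        self.log10_bf_ = res.log10_bf
        self.selected_ = res.selected
        self.selected_alias_ = res.selected_alias
        self.tie_flag_ = res.tie_flag
        return self
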