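"""Structural equation models: Gaussian path analysis over (G, X, Y).

Only five of the twelve admissible causal structures leave a degree of
freedom for a covariance-structure test; these are the testable set

    a: G -> X, G -> Y          b: G -> X, X -> Y      c: G -> Y, Y -> X
    f: G -> X, Y -> X          g: G -> Y, X -> Y

Each is a recursive linear-Gaussian path model with uncorrelated errors,
for which per-equation least squares is the exact maximum-likelihood fit.
With S the unbiased sample covariance of (G, X, Y) and Sigma(theta) the
model-implied covariance, the ML discrepancy is

    F_ML = ln|Sigma| - ln|S| + tr(S Sigma^-1) - 3,

the test statistic is chi2 = (n - 1) * F_ML on df = 1 (six distinct
second moments, five free parameters), and models are compared by

    BIC = chi2 - df * ln(n)        (lower is better).

Means are saturated (the chi-square is covariance-only), so a correctly
specified model has E[chi2] ~= 1 and an average BIC of about
1 - ln(1000) ~= -5.9 at the benchmark's sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from ._exceptions import DegenerateDataError
from ._validation import unpack_triplet

#: Equations of each testable model: (response, parents) in causal order
#: over the variable indices g=0, x=1, y=2.
SEM_MODELS: dict[str, tuple[tuple[str, tuple[str, ...]], ...]] = {
    "a": (("x", ("g",)), ("y", ("g",))),
    "b": (("x", ("g",)), ("y", ("x",))),
    "c": (("y", ("g",)), ("x", ("y",))),
    "f": (("y", ()), ("x", ("g", "y"))),
    "g": (("x", ()), ("y", ("g", "x"))),
}

SEM_MODEL_IDS: tuple[str, ...] = tuple(SEM_MODELS)

_IDX = {"g": 0, "x": 1, "y": 2}

#: Tie tolerance on BIC differences.
TIE_TOL = 1e-6


@dataclass
class SemFit:
    model_id: str
    theta: dict
    chi_square: float
    df: int
    bic: float
    loglik: float
    n: int

    def to_dict(self) -> dict:
        return {"model_id": self.model_id, "theta": self.theta,
                "chi_square": self.chi_square, "df": self.df,
                "bic": self.bic, "loglik": self.loglik, "n": self.n}


@dataclass
class SemSelection:
    fits: dict
    selected: str
    tie_flag: bool
    failed: tuple = ()

    @property
    def bic_table(self) -> dict:
        return {m: f.bic for m, f in self.fits.items()}

    def to_dict(self) -> dict:
        return {"bic": self.bic_table, "selected": self.selected,
                "tie_flag": self.tie_flag, "failed": list(self.failed)}


def implied_sigma(model_id: str, theta: dict) -> np.ndarray:
    """Model-implied covariance of (G, X, Y) from structural parameters.

    ``theta`` holds ``var_g``, one coefficient ``b_<resp>_<parent>`` per
    path, and residual (or exogenous) variances ``psi_x``, ``psi_y``.
    The implied covariance follows the reduced form
    ``Sigma = (I - B)^-1 Psi (I - B)^-T``.
    """
    B = np.zeros((3, 3))
    psi = np.zeros(3)
    psi[0] = theta["var_g"]
    for resp, parents in SEM_MODELS[model_id]:
        psi[_IDX[resp]] = theta[f"psi_{resp}"]
        for p in parents:
            B[_IDX[resp], _IDX[p]] = theta[f"b_{resp}_{p}"]
    inv = np.linalg.inv(np.eye(3) - B)
    return inv @ np.diag(psi) @ inv.T


def _ml_theta(model_id: str, S: np.ndarray) -> dict:
    """Exact ML parameters by per-equation least squares on S."""
    theta = {"var_g": float(S[0, 0])}
    for resp, parents in SEM_MODELS[model_id]:
        r = _IDX[resp]
        if parents:
            p = [_IDX[v] for v in parents]
            coef = np.linalg.solve(S[np.ix_(p, p)], S[p, r])
            for v, b in zip(parents, coef):
                theta[f"b_{resp}_{v}"] = float(b)
            theta[f"psi_{resp}"] = float(S[r, r] - S[r, p] @ coef)
        else:
            theta[f"psi_{resp}"] = float(S[r, r])
    return theta


def discrepancy(S: np.ndarray, sigma: np.ndarray) -> float:
    """ML fit function F_ML(S, Sigma) for 3 observed variables."""
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    if sign_s <= 0 or sign_m <= 0:
        raise DegenerateDataError("singular covariance matrix in SEM fit")
    return float(logdet_m - logdet_s + np.trace(S @ np.linalg.inv(sigma)) - 3.0)


def loglik_from_sigma(S: np.ndarray, sigma: np.ndarray, n: int) -> float:
    """Gaussian covariance-structure log-likelihood (means saturated).

    Uses the (n - 1) weighting consistent with the chi-square convention,
    so that per-equation OLS maximises it exactly.
    """
    _, logdet_m = np.linalg.slogdet(sigma)
    return float(-0.5 * (n - 1) * (logdet_m + np.trace(S @ np.linalg.inv(sigma))
                                   + 3.0 * np.log(2.0 * np.pi)))


def _sample_cov(g, x, y) -> tuple[np.ndarray, int]:
    data = np.column_stack([np.asarray(g, float), np.asarray(x, float),
                            np.asarray(y, float)])
    n = data.shape[0]
    if n < 4:
        raise ValueError("need at least 4 observations for a df=1 test")
    S = np.cov(data, rowvar=False, ddof=1)
    return S, n


def sem_fit_model(model_id: str, g, x, y) -> SemFit:
    """Fit one testable path model by maximum likelihood.

    Raises :class:`DegenerateDataError` when the sample covariance is
    singular (e.g. a monomorphic genotype or an exactly collinear trait).
    """
    if model_id not in SEM_MODELS:
        raise ValueError(f"model {model_id!r} is not in the testable set "
                         f"{SEM_MODEL_IDS}")
    S, n = _sample_cov(g, x, y)
    return _fit_from_cov(model_id, S, n)


def _fit_from_cov(model_id: str, S: np.ndarray, n: int) -> SemFit:
    sign, _ = np.linalg.slogdet(S)
    if sign <= 0:
        raise DegenerateDataError("singular sample covariance matrix")
    theta = _ml_theta(model_id, S)
    sigma = implied_sigma(model_id, theta)
    f_ml = discrepancy(S, sigma)
    chi2 = max((n - 1) * f_ml, 0.0)
    df = 1
    bic = chi2 - df * np.log(n)
    ll = loglik_from_sigma(S, sigma, n)
    return SemFit(model_id, theta, float(chi2), df, float(bic), ll, n)


def sem_select(g, x, y) -> SemSelection:
    """Fit all five testable models and select the lowest BIC.

    If an individual model fails to fit, selection proceeds over the
    remainder and the failure is recorded.  Ties (BICs within 1e-6) are
    flagged, not broken.
    """
    S, n = _sample_cov(g, x, y)
    fits: dict[str, SemFit] = {}
    failed = []
    for m in SEM_MODEL_IDS:
        try:
            fits[m] = _fit_from_cov(m, S, n)
        except (DegenerateDataError, np.linalg.LinAlgError):
            failed.append(m)
    if not fits:
        raise DegenerateDataError("no SEM model could be fitted")
    bics = {m: f.bic for m, f in fits.items()}
    selected = min(bics, key=bics.get)
    ordered = sorted(bics.values())
    tie = len(ordered) > 1 and (ordered[1] - ordered[0]) < TIE_TOL
    return SemSelection(fits, selected, tie, tuple(failed))


class PathModelSelector(BaseEstimator):
    """Lowest-BIC selection among the five testable path models.

    Attributes
    ----------
    fits_ : dict of str -> SemFit
    bic_table_ : dict of str -> float
    selected_ : str
        Model id with the lowest BIC.
    tie_flag_ : bool
    """

    def fit(self, X, y=None):
        g, x, yv = unpack_triplet(X)
        sel = sem_select(g, x, yv)
        self.selection_ = sel
        self.fits_ = sel.fits
        self.bic_table_ = sel.bic_table
        self.selected_ = sel.selected
        self.tie_flag_ = sel.tie_flag
        return self
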