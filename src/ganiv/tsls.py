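"""Linear first-stage baselines: OLS first stage and the TSLS estimator.

The same linear fit serves two roles: the classic two-stage least squares
first stage, and the parametric first stage of the DeLIVR-style baseline
(whose second stage is a shallow neural network, see :mod:`ganiv.stage2`).
Under the Gaussian assumption the fit also yields an explicit conditional
density N(alpha0 + alpha1'z, sigma2_G) used by the distribution criteria.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "FirstStageOlsFit",
    "CollinearityError",
    "WeakInstrumentError",
    "fit_first_stage_ols",
    "tsls_estimate",
    "ols_conditional_logdensity",
]


class CollinearityError(ValueError):
    """Design matrix is rank deficient."""


class WeakInstrumentError(ValueError):
    """Instrument essentially uncorrelated with the exposure."""


@dataclass(frozen=True)
class FirstStageOlsFit:
    """Least-squares fit of exposure on instruments."""

    alpha0: float
    alpha1: np.ndarray
    sigma2_G: float
    n_fit: int

    def predict(self, Z) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return self.alpha0 + Z @ self.alpha1

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha0": self.alpha0,
                "alpha1": np.asarray(self.alpha1).tolist(),
                "sigma2_G": self.sigma2_G,
                "n_fit": self.n_fit,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FirstStageOlsFit":
        d = json.loads(text)
        return cls(d["alpha0"], np.asarray(d["alpha1"]), d["sigma2_G"], d["n_fit"])


def fit_first_stage_ols(Z, G) -> FirstStageOlsFit:
    """OLS of G on Z with intercept; residual variance uses n - p - 1."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    G = np.asarray(G, dtype=float).ravel()
    n, p = Z.shape
    if n <= p + 1:
        raise ValueError("need more samples than instruments plus intercept")
    X = np.column_stack([np.ones(n), Z])
    rank = np.linalg.matrix_rank(X)
    if rank < p + 1:
        bad = _collinear_columns(X)
        raise CollinearityError(
            f"rank-deficient instrument design (offending columns: {bad})"
        )
    coef, *_ = np.linalg.lstsq(X, G, rcond=None)
    resid = G - X @ coef
    sigma2 = float(resid @ resid / (n - p - 1))
    return FirstStageOlsFit(float(coef[0]), coef[1:], sigma2, n)


def _collinear_columns(X: np.ndarray) -> list[int]:
    """Identify columns (0-based, excluding intercept) in the null space."""
    bad = []
    for j in range(1, X.shape[1]):
        others = np.delete(X, j, axis=1)
        proj, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        if np.allclose(others @ proj, X[:, j], atol=1e-10):
            bad.append(j - 1)
    return bad


def tsls_estimate(Z, G, Y, corr_tol: float = 1e-6) -> tuple[float, float]:
    """Two-stage least squares estimate (beta1, beta0).

    A single instrument uses the closed-form covariance ratio
    beta1 = Cov(Z, Y) / Cov(Z, G); multiple instruments use the two-stage
    plug-in (regress G on Z, then Y on the fitted exposure).  Both routes
    agree in the single-instrument case.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] == 1 and Z.shape[1] > 1:
        Z = Z.T
    G = np.asarray(G, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float).ravel()
    if Z.shape[1] == 1:
        z = Z[:, 0]
        sz, sg = z.std(), G.std()
        if sz == 0 or sg == 0 or abs(np.corrcoef(z, G)[0, 1]) < corr_tol:
            raise WeakInstrumentError(
                "instrument is (numerically) uncorrelated with the exposure"
            )
        cov_zy = np.cov(z, Y, ddof=1)[0, 1]
        cov_zg = np.cov(z, G, ddof=1)[0, 1]
        beta1 = cov_zy / cov_zg
        beta0 = Y.mean() - beta1 * G.mean()
        return float(beta1), float(beta0)
    fit = fit_first_stage_ols(Z, G)
    g_hat = fit.predict(Z)
    if g_hat.std() < corr_tol:
        raise WeakInstrumentError("fitted exposure has no variation")
    X = np.column_stack([np.ones(len(Y)), g_hat])
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return float(coef[1]), float(coef[0])


def ols_conditional_logdensity(fit: FirstStageOlsFit, z, g) -> np.ndarray:
    """Gaussian log density of g given z implied by the linear first stage."""
    if fit.sigma2_G <= 0:
        raise ValueError("degenerate fitted density: sigma2_G must be > 0")
    mean = fit.predict(z)
    return stats.norm.logpdf(
        np.asarray(g, dtype=float), loc=mean, scale=np.sqrt(fit.sigma2_G)
    )
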