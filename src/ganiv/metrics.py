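"""Evaluation statistics for both estimation stages.

Stage 1 (conditional exposure distribution): mean-absolute exposure bias
against the true conditional mean h(z), a Monte-Carlo Kullback-Leibler
estimator, and a min-max-scaled squared maximum mean discrepancy (MMD).
Stage 2 (causal-effect fit): outcome bias against the noiseless outcome,
MSE against observations, and the RV coefficient (which for vectors is the
squared uncentered correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from scipy.spatial.distance import cdist

__all__ = [
    "MetricsRecord",
    "DensityEstimate",
    "exposure_bias",
    "kde_logdensity",
    "kl_estimate",
    "mmd_squared",
    "outcome_metrics",
]

_LOGP_FLOOR = -700.0  # clamp before exponentiation


@dataclass
class MetricsRecord:
    """Per-replicate metric bundle, one entry per method."""

    replicate: int = 0
    stage1: dict = field(default_factory=dict)  # method -> {bias, kl, mmd2}
    stage2: dict = field(default_factory=dict)  # method -> {split -> {bias, mse, rv}}
    config_fingerprint: str = ""

    def rows(self):
        """Tidy rows: (replicate, method, stage, split, metric, value)."""
        out = []
        for method, d in self.stage1.items():
            for metric, value in d.items():
                out.append((self.replicate, method, "stage1", "", metric, value))
        for method, splits in self.stage2.items():
            for split, d in splits.items():
                for metric, value in d.items():
                    out.append((self.replicate, method, "stage2", split, metric, value))
        return out


@dataclass
class DensityEstimate:
    """Gaussian KDE wrapper retaining its support and bandwidth."""

    samples: np.ndarray
    bandwidth: float
    kernel: str = "gaussian"

    def logpdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float).ravel()
        d = x[:, None] - self.samples[None, :]
        logk = -0.5 * (d / self.bandwidth) ** 2 - 0.5 * np.log(
            2 * np.pi * self.bandwidth**2
        )
        return np.logaddexp.reduce(logk, axis=1) - np.log(len(self.samples))


def exposure_bias(g_hat, h_vals) -> float:
    """Mean absolute deviation of estimated conditional means from h(z)."""
    g_hat = np.asarray(g_hat, dtype=float).ravel()
    h_vals = np.asarray(h_vals, dtype=float).ravel()
    if g_hat.shape != h_vals.shape:
        raise ValueError("g_hat and h_vals must have equal lengths")
    return float(np.mean(np.abs(g_hat - h_vals)))


def kde_logdensity(samples, eval_points, bandwidth_rule: str = "scott"):
    """Gaussian-kernel KDE log density, bandwidth by Scott's rule of thumb.

    Returns ``(log_densities, DensityEstimate)``.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if len(samples) < 2 or samples.std() == 0:
        raise ValueError("KDE needs >= 2 samples with nonzero spread")
    if bandwidth_rule == "scott":
        bw = samples.std(ddof=1) * len(samples) ** (-1.0 / 5.0)
    elif bandwidth_rule == "silverman":
        bw = 1.06 * samples.std(ddof=1) * len(samples) ** (-1.0 / 5.0)
    else:
        bw = float(bandwidth_rule)
        if bw <= 0:
            raise ValueError("bandwidth must be positive")
    est = DensityEstimate(samples=samples, bandwidth=bw)
    return est.logpdf(eval_points), est


def kl_estimate(x_samples, logp, logp_hat) -> float:
    """Monte-Carlo KL(p || p_hat) from draws of the true density p.

    With r = log p_hat(x) - log p(x), the estimator averages
    exp(r) - 1 - r; its expectation is >= 0 for any proper p_hat and 0 iff
    the densities agree on the support of p.
    """
    logp = np.asarray(logp, dtype=float).ravel()
    logp_hat = np.asarray(logp_hat, dtype=float).ravel()
    x = np.asarray(x_samples, dtype=float).ravel()
    if not (len(x) == len(logp) == len(logp_hat)):
        raise ValueError("x_samples, logp, logp_hat must have equal lengths")
    if not (np.all(np.isfinite(logp)) and np.all(np.isfinite(logp_hat))):
        raise ValueError("log densities must be finite")
    r = np.clip(logp_hat, _LOGP_FLOOR, None) - np.clip(logp, _LOGP_FLOOR, None)
    return float(np.mean(np.exp(r) - 1.0 - r))


def mmd_squared(
    gen_samples, true_samples, bandwidth: float | None = None,
    scaling: str = "stacked",
) -> float:
    """Min-max-scaled squared MMD between generated and true sample sets.

    One Gaussian-RBF Gram matrix is built over the stacked 2M points, passed
    through the min-max scaler phi(x) = (x - min)/(max - min) (global over
    the stacked matrix by default, per-block optionally), then partitioned
    into the three M x M blocks; the statistic is
    mean(phi(K_gen,gen)) - 2 mean(phi(K_gen,true)) + mean(phi(K_true,true)),
    diagonals included (the biased V-statistic form).  The kernel bandwidth
    defaults to the median heuristic on the stacked set.
    """
    a = np.asarray(gen_samples, dtype=float).reshape(len(gen_samples), -1)
    b = np.asarray(true_samples, dtype=float).reshape(len(true_samples), -1)
    if a.shape[0] != b.shape[0]:
        raise ValueError("both sample sets must have the same size M")
    if a.shape[0] < 2:
        raise ValueError("need M >= 2 samples per set")
    stacked = np.vstack([a, b])
    d2 = cdist(stacked, stacked, "sqeuclidean")
    if bandwidth is None:
        med = np.median(d2[np.triu_indices_from(d2, k=1)])
        bandwidth = np.sqrt(med / 2.0) if med > 0 else 1.0
    K = np.exp(-d2 / (2.0 * bandwidth**2))
    M = a.shape[0]
    if scaling == "stacked":
        kmin, kmax = K.min(), K.max()
        P = (K - kmin) / (kmax - kmin) if kmax > kmin else np.zeros_like(K)
        paa, pab, pbb = P[:M, :M], P[:M, M:], P[M:, M:]
    elif scaling == "per_block":
        def scale(block):
            lo, hi = block.min(), block.max()
            return (block - lo) / (hi - lo) if hi > lo else np.zeros_like(block)
        paa, pab, pbb = scale(K[:M, :M]), scale(K[:M, M:]), scale(K[M:, M:])
    else:
        raise ValueError("scaling must be 'stacked' or 'per_block'")
    return float(paa.mean() - 2.0 * pab.mean() + pbb.mean())


def outcome_metrics(y_hat, y, y0) -> dict:
    """Stage-2 criteria: bias vs the noiseless outcome, MSE, RV coefficient."""
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    y0 = np.asarray(y0, dtype=float).ravel()
    if not (len(y_hat) == len(y) == len(y0)):
        raise ValueError("y_hat, y, y0 must have equal lengths")
    bias = float(np.mean(np.abs(y_hat - y0)))
    mse = float(np.mean((y_hat - y) ** 2))
    ny, nh = np.linalg.norm(y), np.linalg.norm(y_hat)
    if ny == 0 or nh == 0:
        raise ValueError("RV undefined for an identically-zero vector")
    rv = float((y @ y_hat) ** 2 / (ny**2 * nh**2))
    return {"bias": bias, "mse": mse, "rv": rv}
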