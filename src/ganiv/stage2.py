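"""Second-stage exposure-to-outcome regressors.

Four model kinds operate on the stage-1 fitted exposure:

* ``dfnn``   -- deep functional neural network: each input block is expanded
  on a B-spline basis (a scalar fitted exposure is expanded in its value
  domain; an ordered vector block is smoothed along its position index),
  then fed to a two-hidden-layer ReLU network.
* ``mfdl``   -- multimodal variant: separate basis expansion per modality
  (e.g. fitted exposure and tag-SNP dosages) fused by the same network.
* ``shallow_nn`` -- one-hidden-layer network on the raw inputs (the
  DeLIVR-style second stage).
* ``linear`` -- ordinary least squares (the TSLS second stage).

Network fits use Adam with L2 regularization and early stopping; learning
rate and L2 weight are selected by grid search under k-fold cross
validation (default 3 folds) minimizing validation MSE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass


import numpy as np
from scipy.interpolate import BSpline
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
import warnings

__all__ = [
    "DfnnConfig",
    "MfdlConfig",
    "SecondStageModel",
    "bspline_design",
    "fit_second_stage",
    "predict",
]


@dataclass(frozen=True)
class DfnnConfig:
    """Hyperparameters for the functional second-stage network."""

    n_basis: int = 10
    spline_order: int = 3
    hidden_layers: tuple[int, ...] = (32, 16)
    activation: str = "relu"
    l2_grid: tuple[float, ...] = (1e-2, 1e-3, 1e-4)
    lr_grid: tuple[float, ...] = (1e-2, 1e-3, 1e-4)
    cv_folds: int = 3
    max_epochs: int = 2000
    patience: int = 20
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_basis < self.spline_order + 1:
            raise ValueError("n_basis must be >= spline_order + 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass(frozen=True)
class MfdlConfig(DfnnConfig):
    """Multimodal settings: per-block basis sizes (None -> shared default)."""

    block_n_basis: tuple[int, ...] | None = None


class SecondStageModel:
    """A fitted exposure-to-outcome regressor with a ``predict`` contract."""

    def __init__(self, kind, config, block_domains, estimator, history,
                 selected, coef=None):
        self.kind = kind
        self.config = config
        self.block_domains = block_domains  # per block: (lo, hi) or None
        self.estimator = estimator  # MLPRegressor or None for linear
        self.history = history  # best-validation loss per epoch (running min)
        self.selected = selected  # chosen (learning rate, l2) or {}
        self.coef = coef  # linear kind: (intercept, coefs)

    def predict(self, X_blocks) -> np.ndarray:
        blocks = _as_blocks(X_blocks)
        X = _featurize(blocks, self.kind, self.config, self.block_domains)
        if self.kind == "linear":
            b0, b = self.coef
            out = b0 + X @ b
        else:
            out = self.estimator.predict(X)
        if (
            self.kind in ("dfnn", "mfdl")
            and len(blocks) == 1
            and blocks[0].shape[1] == 1
        ):
            out = self._extrapolate_scalar(blocks[0][:, 0], out)
        return out

    def _extrapolate_scalar(self, x, out):
        """Boundary-linear extrapolation beyond the training value domain.

        Inside the domain the spline features are used as-is; outside, the
        fitted curve is continued linearly with the one-sided slope at the
        nearer boundary (first-order Taylor), which behaves far better on
        tail values than clamping to the boundary level.
        """
        lo, hi = self.block_domains[0]
        eps = 1e-4 * (hi - lo)
        out = out.copy()
        for bound, sign, mask in (
            (lo, -1.0, x < lo),
            (hi, 1.0, x > hi),
        ):
            if not mask.any():
                continue
            pts = np.array([bound, bound - sign * eps])
            feats = _featurize([pts[:, None]], self.kind, self.config,
                               self.block_domains)
            fb, fb_in = self.estimator.predict(feats)
            slope = sign * (fb - fb_in) / eps
            out[mask] = fb + slope * (x[mask] - bound)
        return out

    def save(self, path):
        if self.kind != "linear":
            raise NotImplementedError("only linear models serialize to text")
        with open(path, "w") as fh:
            json.dump({"kind": self.kind, "intercept": self.coef[0],
                       "coef": np.asarray(self.coef[1]).tolist()}, fh)


def bspline_design(x, n_basis: int, order: int,
                   domain: tuple[float, float] | None = None) -> np.ndarray:
    """B-spline basis evaluations on an open-uniform knot vector.

    Returns a (len(x), n_basis) matrix; rows sum to 1 on the domain
    interior (partition of unity).  Points outside the domain are clamped
    to its boundary (extrapolation by clamping).
    """
    if n_basis < order + 1:
        raise ValueError("n_basis must be >= order + 1")
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 1:
        raise ValueError("need at least one evaluation position")
    lo, hi = domain if domain is not None else (x.min(), x.max())
    if hi <= lo:
        hi = lo + 1.0
    xc = np.clip(x, lo, hi)
    n_interior = n_basis - order - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    t = np.r_[[lo] * (order + 1), interior, [hi] * (order + 1)]
    # evaluate just inside the right edge so the last basis is included
    xc = np.minimum(xc, hi - 1e-12 * max(abs(hi), 1.0))
    return BSpline.design_matrix(xc, t, order).toarray()


def _as_blocks(X_blocks) -> list[np.ndarray]:
    if isinstance(X_blocks, (list, tuple)):
        blocks = [np.asarray(b, dtype=float) for b in X_blocks]
    else:
        blocks = [np.asarray(X_blocks, dtype=float)]
    out = []
    n = None
    for b in blocks:
        if b.ndim == 1:
            b = b[:, None]
        if n is None:
            n = b.shape[0]
        elif b.shape[0] != n:
            raise ValueError("input blocks disagree on sample count")
        out.append(b)
    return out


def _block_domain(block: np.ndarray) -> tuple[float, float]:
    if block.shape[1] == 1:
        return float(block.min()), float(block.max())
    return 0.0, float(block.shape[1] - 1)


def _featurize(blocks, kind, config, domains) -> np.ndarray:
    """Basis-expand blocks for dfnn/mfdl; concatenate raw otherwise."""
    if kind in ("shallow_nn", "linear"):
        return np.column_stack(blocks)
    feats = []
    per_block = getattr(config, "block_n_basis", None)
    for i, b in enumerate(blocks):
        nb = per_block[i] if per_block else config.n_basis
        dom = domains[i]
        if b.shape[1] == 1:
            # scalar exposure: basis functions act on the value domain
            feats.append(bspline_design(b[:, 0], nb, config.spline_order, dom))
        else:
            # ordered sequence: functional smoothing along positions
            pos = np.arange(b.shape[1], dtype=float)
            design = bspline_design(pos, nb, config.spline_order, dom)
            feats.append(b @ design / b.shape[1])
    return np.column_stack(feats)


def fit_second_stage(X_blocks, Y, config=None, kind: str = "dfnn") -> SecondStageModel:
    """Fit a second-stage regressor of the requested kind.

    dfnn/mfdl/shallow_nn: grid search over (learning rate, L2 weight) by
    k-fold cross validation on mean validation MSE, then a refit on the full
    training data with early stopping on a held-out validation fraction.
    linear: OLS with intercept.
    """
    if kind not in ("dfnn", "mfdl", "shallow_nn", "linear"):
        raise ValueError(f"unknown model kind {kind!r}")
    if config is None:
        config = MfdlConfig() if kind == "mfdl" else DfnnConfig()
    blocks = _as_blocks(X_blocks)
    if kind == "mfdl" and len(blocks) < 2:
        raise ValueError("mfdl expects at least two input blocks")
    Y = np.asarray(Y, dtype=float).ravel()
    if len(Y) != blocks[0].shape[0]:
        raise ValueError("Y length must match the input blocks")
    if Y.std() == 0:
        raise ValueError("degenerate target: Y has zero variance")

    domains = [_block_domain(b) for b in blocks]
    X = _featurize(blocks, kind, config, domains)

    if kind == "linear":
        A = np.column_stack([np.ones(len(Y)), X])
        coef, *_ = np.linalg.lstsq(A, Y, rcond=None)
        resid_hist = [float(np.mean((Y - A @ coef) ** 2))]
        return SecondStageModel(kind, config, domains, None, resid_hist, {},
                                coef=(float(coef[0]), coef[1:]))

    # shallow kind keeps a single hidden layer (default width 16)
    hidden = config.hidden_layers if kind != "shallow_nn" else config.hidden_layers[-1:]

    def make(lr, l2, seed):
        return MLPRegressor(
            hidden_layer_sizes=tuple(hidden), activation=config.activation,
            solver="adam", alpha=l2, learning_rate_init=lr,
            max_iter=config.max_epochs, early_stopping=True,
            validation_fraction=config.validation_fraction,
            n_iter_no_change=config.patience, random_state=seed,
        )

    best = None
    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    splits = list(kf.split(X))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for lr in config.lr_grid:
            for l2 in config.l2_grid:
                losses = []
                for tr, va in splits:
                    m = make(lr, l2, config.seed)
                    try:
                        m.fit(X[tr], Y[tr])
                        mse = float(np.mean((m.predict(X[va]) - Y[va]) ** 2))
                    except Exception:
                        mse = np.inf
                    losses.append(mse)
                mean_loss = float(np.mean(losses))
                if np.isfinite(mean_loss) and (best is None or mean_loss < best[0]):
                    best = (mean_loss, lr, l2)
        if best is None:
            raise RuntimeError("grid search failed: all candidate fits diverged")
        _, lr, l2 = best
        final = make(lr, l2, config.seed)
        final.fit(X, Y)

    # running best-validation loss (1 - R^2-score converted is not needed;
    # sklearn tracks validation R^2, monotone best == running max score)
    scores = np.asarray(final.validation_scores_, dtype=float)
    history = list(np.minimum.accumulate(1.0 - scores))
    return SecondStageModel(kind, config, domains, final, history,
                            {"learning_rate": lr, "l2": l2})


def predict(model: SecondStageModel, X_blocks) -> np.ndarray:
    """Deterministic forward evaluation of a fitted second-stage model."""
    out = model.predict(X_blocks)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite predictions")
    return out
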