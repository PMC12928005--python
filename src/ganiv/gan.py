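"""Conditional GAN estimation of the exposure distribution given instruments.

The generator maps (instrument dosages z, noise s) to exposure draws; the
discriminator scores (exposure, instruments) pairs as real versus
generated.  Training minimizes the non-saturating generator loss and the
binary-cross-entropy discriminator loss with an R1 gradient penalty on real
inputs.  At the optimum the generated conditional law matches the data law:
the analytic optimal discriminator is p_data/(p_data + p_G), where the
minimax objective equals -log 4, and a balanced discriminator accuracy near
0.5 (with generator and discriminator losses close) is the practical
convergence signal.

The trained sampler supports conditional draws and the Monte-Carlo
conditional-mean estimator E(G|Z=z) ~ mean of M draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._autodiff import (
    Tensor, clip, concat_cols, grad, slice_rows, tlog, tmean, tsum,
)
from ._nn import MLP, Adam

__all__ = [
    "GanConfig",
    "ConditionalSampler",
    "TrainDiagnostics",
    "TrainingFailureError",
    "generator_loss",
    "discriminator_loss",
    "optimal_discriminator",
    "train_conditional_gan",
    "sample_conditional",
    "conditional_mean",
    "discriminator_balanced_accuracy",
]

_EPS = 1e-7


class TrainingFailureError(RuntimeError):
    """Raised when training produces a non-finite loss; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class GanConfig:
    """Hyperparameters for conditional-GAN training.

    ``epochs`` counts full passes over the training split (default 50 000,
    the long-run profile); ``desk()`` returns a scaled-down profile for
    interactive use.  ``m_samples`` is the Monte-Carlo draw count for
    conditional means.
    """

    gen_hidden: tuple[int, int, int] = (64, 64, 64)
    disc_hidden: tuple[int, int, int] = (64, 64, 64)
    noise_dim: int = 5
    lambda_r1: float = 1.0
    epochs: int = 50_000
    batch_size: int = 64
    lr_gen: float = 1e-4
    lr_disc: float = 1e-4
    adam_betas: tuple[float, float] = (0.5, 0.999)
    d_steps_per_g_step: int = 1
    m_samples: int = 1000
    seed: int = 0
    log_every: int = 100
    acc_tol: float = 0.1
    patience: int = 10
    stop_on_convergence: bool = True
    ema_decay: float | None = 0.999
    lr_schedule: str | None = "cosine"  # anneal lr to lr/20 over the run

    def __post_init__(self):
        if len(self.gen_hidden) != 3 or len(self.disc_hidden) != 3:
            raise ValueError("exactly three hidden-layer widths per network")
        if self.lambda_r1 < 0:
            raise ValueError("lambda_r1 must be >= 0")
        if self.epochs < 1 or self.m_samples < 1:
            raise ValueError("epochs and m_samples must be >= 1")

    @classmethod
    def desk(cls, **overrides) -> "GanConfig":
        """Scaled-down profile for tests and worked examples."""
        base = dict(epochs=3000, gen_hidden=(64, 64, 64), disc_hidden=(64, 64, 64))
        base.update(overrides)
        return cls(**base)


@dataclass
class TrainDiagnostics:
    """Logged losses/accuracies per logging step plus the convergence flag."""

    steps: list = field(default_factory=list)
    loss_g: list = field(default_factory=list)
    loss_d: list = field(default_factory=list)
    loss_d_real: list = field(default_factory=list)
    loss_d_fake: list = field(default_factory=list)
    loss_d_r1: list = field(default_factory=list)
    accuracy: list = field(default_factory=list)
    converged: bool = False
    converged_step: int | None = None

    def log(self, step, lg, ld, lreal, lfake, lr1, acc):
        self.steps.append(step)
        self.loss_g.append(lg)
        self.loss_d.append(ld)
        self.loss_d_real.append(lreal)
        self.loss_d_fake.append(lfake)
        self.loss_d_r1.append(lr1)
        self.accuracy.append(acc)

    def to_csv(self, path):
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["step", "loss_g", "loss_d", "loss_d_real", "loss_d_fake",
                 "loss_d_r1", "accuracy"]
            )
            for row in zip(self.steps, self.loss_g, self.loss_d,
                           self.loss_d_real, self.loss_d_fake,
                           self.loss_d_r1, self.accuracy):
                w.writerow(row)


# -- loss functions (also the unit-testable reference forms) ------------

def generator_loss(d_probs_fake) -> float:
    """Non-saturating loss: mean of -log D(fake)."""
    d = np.asarray(d_probs_fake, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("empty batch")
    d = np.clip(d, _EPS, 1 - _EPS)
    return float(np.mean(-np.log(d)))


def discriminator_loss(d_real, d_fake, grad_sq_norms, lambda_r1) -> dict:
    """BCE discriminator loss with R1 penalty; returns total and components.

    total = 1/2 (L_real + L_fake) + (lambda/2) mean ||grad_g D(g,z)||^2.
    """
    if lambda_r1 < 0:
        raise ValueError("lambda_r1 must be >= 0")
    d_real = np.clip(np.asarray(d_real, dtype=float).ravel(), _EPS, 1 - _EPS)
    d_fake = np.clip(np.asarray(d_fake, dtype=float).ravel(), _EPS, 1 - _EPS)
    gsq = np.asarray(grad_sq_norms, dtype=float).ravel()
    l_real = float(np.mean(-np.log(d_real)))
    l_fake = float(np.mean(-np.log(1.0 - d_fake)))
    l_r1 = float(0.5 * lambda_r1 * np.mean(gsq)) if gsq.size else 0.0
    total = 0.5 * (l_real + l_fake) + l_r1
    return {"total": total, "real": l_real, "fake": l_fake, "r1": l_r1}


def optimal_discriminator(p_data, p_g) -> np.ndarray:
    """Analytic optimum D*(g,z) = p_data / (p_data + p_g) (test oracle)."""
    p_data = np.asarray(p_data, dtype=float)
    p_g = np.asarray(p_g, dtype=float)
    denom = p_data + p_g
    if np.any(denom == 0):
        raise ValueError("optimal discriminator undefined where both densities vanish")
    return p_data / denom


# -- sampler ------------------------------------------------------------

@dataclass
class ConditionalSampler:
    """Trained conditional generator with its standardization constants."""

    generator: MLP
    noise_dim: int
    z_mean: np.ndarray
    z_std: np.ndarray
    g_mean: float
    g_std: float
    config: GanConfig | None = None
    discriminator: MLP | None = None

    @property
    def n_instruments(self) -> int:
        return len(np.atleast_1d(self.z_mean))

    def _standardize_z(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if z.ndim == 0:
            z = z.reshape(1, 1)
        elif z.ndim == 1:
            # for a single instrument, a 1-D array means several
            # conditioning values; otherwise it is one instrument vector
            z = z.reshape(-1, 1) if self.n_instruments == 1 else z.reshape(1, -1)
        return (z - self.z_mean) / self.z_std

    def sample(self, z, M: int, seed: int = 0) -> np.ndarray:
        """M exposure draws per conditioning row; shape (M,) or (n_z, M)."""
        if M < 1:
            raise ValueError("M must be >= 1")
        za = np.asarray(z)
        single = za.ndim == 0 or (
            za.ndim == 1
            and (self.n_instruments > 1 or za.size == 1)
        )
        zs = self._standardize_z(z)
        m = zs.shape[0]
        rng = np.random.default_rng(seed)
        s = rng.standard_normal((m * M, self.noise_dim))
        zt = np.repeat(zs, M, axis=0)
        out = self.generator.forward_numpy(np.column_stack([zt, s])).ravel()
        out = out * self.g_std + self.g_mean
        out = out.reshape(m, M)
        return out[0] if single else out

    def conditional_mean(self, z, M: int | None = None, seed: int = 0):
        """Monte-Carlo estimate of E(G|Z=z): the mean of ``sample``."""
        if M is None:
            M = self.config.m_samples if self.config else 1000
        draws = self.sample(z, M, seed)
        return float(draws.mean()) if draws.ndim == 1 else draws.mean(axis=1)

    # -- serialization --------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "generator": self.generator.state(),
            "noise_dim": self.noise_dim,
            "z_mean": np.asarray(self.z_mean).tolist(),
            "z_std": np.asarray(self.z_std).tolist(),
            "g_mean": self.g_mean,
            "g_std": self.g_std,
            "config": asdict(self.config) if self.config else None,
            "discriminator": self.discriminator.state()
            if self.discriminator
            else None,
        }
        return json.dumps(payload)

    def save(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "ConditionalSampler":
        d = json.loads(text)
        cfg = d["config"]
        if cfg is not None:
            for key in ("gen_hidden", "disc_hidden", "adam_betas"):
                cfg[key] = tuple(cfg[key])
            cfg = GanConfig(**cfg)
        return cls(
            generator=MLP.from_state(d["generator"]),
            noise_dim=d["noise_dim"],
            z_mean=np.asarray(d["z_mean"]),
            z_std=np.asarray(d["z_std"]),
            g_mean=d["g_mean"],
            g_std=d["g_std"],
            config=cfg,
            discriminator=MLP.from_state(d["discriminator"])
            if d["discriminator"]
            else None,
        )

    @classmethod
    def load(cls, path) -> "ConditionalSampler":
        with open(path) as fh:
            return cls.from_json(fh.read())


def sample_conditional(sampler: ConditionalSampler, z, M: int, seed: int = 0):
    return sampler.sample(z, M, seed)


def conditional_mean(sampler: ConditionalSampler, z, M: int, seed: int = 0):
    return sampler.conditional_mean(z, M, seed)


# -- training -----------------------------------------------------------

def _balanced_accuracy(disc: MLP, g_real_std, z_std, g_fake_std) -> float:
    """Accuracy on an equal count of real and generated samples, cutoff 0.5."""
    d_real = disc.forward_numpy(np.column_stack([g_real_std, z_std])).ravel()
    d_fake = disc.forward_numpy(np.column_stack([g_fake_std, z_std])).ravel()
    return float(0.5 * (np.mean(d_real > 0.5) + np.mean(d_fake <= 0.5)))


def discriminator_balanced_accuracy(
    sampler: ConditionalSampler, Z, G, seed: int = 0
) -> float:
    """Balanced real-vs-generated accuracy of the stored discriminator."""
    if sampler.discriminator is None:
        raise ValueError("sampler carries no discriminator")
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    G = np.asarray(G, dtype=float).ravel()
    zs = (Z - sampler.z_mean) / sampler.z_std
    gs = (G - sampler.g_mean) / sampler.g_std
    fake = sampler.sample(Z, M=1, seed=seed).ravel()
    fs = (fake - sampler.g_mean) / sampler.g_std
    return _balanced_accuracy(sampler.discriminator, gs[:, None], zs, fs[:, None])


def train_conditional_gan(Z, G, config: GanConfig | None = None):
    """Adversarial training of the conditional exposure sampler.

    Alternates ``d_steps_per_g_step`` discriminator updates (BCE + R1
    penalty) with one non-saturating generator update per minibatch.
    Inputs are standardized to zero mean / unit variance before training and
    the returned sampler de-standardizes its outputs.  When ``ema_decay`` is
    set, the sampler uses an exponential moving average of the generator
    weights, which damps the oscillation inherent to adversarial updates.
    Returns ``(ConditionalSampler, TrainDiagnostics)``.
    """
    config = config or GanConfig()
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] == 1 and np.asarray(G).size > 1:
        Z = Z.T
    G = np.asarray(G, dtype=float).ravel()
    n, p = Z.shape
    if n != len(G):
        raise ValueError("Z and G must have the same sample count")
    if n < config.batch_size:
        raise ValueError("sample count must be >= batch_size")

    z_mean, z_std = Z.mean(axis=0), Z.std(axis=0)
    z_std = np.where(z_std > 0, z_std, 1.0)
    g_mean, g_std = G.mean(), G.std()
    if g_std == 0:
        g_std = 1.0
    Zs = (Z - z_mean) / z_std
    Gs = (G - g_mean) / g_std

    rng = np.random.default_rng(config.seed)
    gen = MLP(p + config.noise_dim, config.gen_hidden, 1, "tanh", "linear", rng)
    disc = MLP(p + 1, config.disc_hidden, 1, "elu", "sigmoid", rng)
    opt_g = Adam(gen.params, lr=config.lr_gen, betas=config.adam_betas)
    opt_d = Adam(disc.params, lr=config.lr_disc, betas=config.adam_betas)

    diag = TrainDiagnostics()
    B = config.batch_size
    g_step = 0
    lam = config.lambda_r1
    recent_ok = 0
    ema = (
        [p.data.copy() for p in gen.params]
        if config.ema_decay is not None
        else None
    )

    for epoch in range(config.epochs):
        if config.lr_schedule == "cosine":
            frac = epoch / max(config.epochs - 1, 1)
            scale = 0.05 + 0.95 * 0.5 * (1 + np.cos(np.pi * frac))
            opt_g.lr = config.lr_gen * scale
            opt_d.lr = config.lr_disc * scale
        order = rng.permutation(n)
        for start in range(0, n - B + 1, B):
            idx = order[start : start + B]
            zb, gb = Zs[idx], Gs[idx][:, None]

            for _ in range(config.d_steps_per_g_step):
                s = rng.standard_normal((B, config.noise_dim))
                fake = gen.forward_numpy(np.column_stack([zb, s]))
                # one fused pass: real rows first, generated rows after
                g_col = Tensor(np.vstack([gb, fake]), requires_grad=True)
                zt = Tensor(np.vstack([zb, zb]))
                d_all = disc(concat_cols([g_col, zt]))
                d_real = slice_rows(d_all, 0, B)
                d_fake = slice_rows(d_all, B, 2 * B)
                l_real = tmean(-tlog(clip(d_real, _EPS, 1 - _EPS)))
                l_fake = tmean(-tlog(clip(1.0 - d_fake, _EPS, 1 - _EPS)))
                if lam > 0:
                    gx_all = grad(tsum(d_all), g_col)
                    gx = slice_rows(gx_all, 0, B)  # penalty on real inputs
                    r1 = 0.5 * lam * tmean(gx * gx)
                else:
                    r1 = Tensor(0.0)
                loss_d = 0.5 * (l_real + l_fake) + r1
                if not np.isfinite(loss_d.data):
                    raise TrainingFailureError(
                        "non-finite discriminator loss", diag
                    )
                opt_d.step(grad(loss_d, disc.params))

            s = rng.standard_normal((B, config.noise_dim))
            gen_in = concat_cols([Tensor(zb), Tensor(s)])
            fake_t = gen(gen_in)
            d_on_fake = disc(concat_cols([fake_t, Tensor(zb)]))
            loss_g = tmean(-tlog(clip(d_on_fake, _EPS, 1 - _EPS)))
            if not np.isfinite(loss_g.data):
                raise TrainingFailureError("non-finite generator loss", diag)
            opt_g.step(grad(loss_g, gen.params))
            g_step += 1
            if ema is not None:
                # warmup-corrected decay so short runs track the live weights
                d = min(config.ema_decay, (1 + g_step) / (10 + g_step))
                for e, p in zip(ema, gen.params):
                    e *= d
                    e += (1 - d) * p.data

            if g_step % config.log_every == 0:
                comp = discriminator_loss(
                    d_real.data.ravel(), d_fake.data.ravel(),
                    (gx.data.ravel() ** 2) if lam > 0 else np.zeros(B), lam,
                )
                s2 = rng.standard_normal((B, config.noise_dim))
                fake2 = gen.forward_numpy(np.column_stack([zb, s2]))
                acc = _balanced_accuracy(disc, gb, zb, fake2)
                diag.log(
                    g_step, float(loss_g.data), comp["total"], comp["real"],
                    comp["fake"], comp["r1"], acc,
                )
                recent_ok = recent_ok + 1 if abs(acc - 0.5) <= config.acc_tol else 0
                if recent_ok >= config.patience and not diag.converged:
                    diag.converged = True
                    diag.converged_step = g_step
                    if config.stop_on_convergence:
                        break
        if diag.converged and config.stop_on_convergence:
            break

    if ema is not None:
        for e, p in zip(ema, gen.params):
            p.data[...] = e
    sampler = ConditionalSampler(
        generator=gen, noise_dim=config.noise_dim, z_mean=z_mean, z_std=z_std,
        g_mean=float(g_mean), g_std=float(g_std), config=config,
        discriminator=disc,
    )
    return sampler, diag
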