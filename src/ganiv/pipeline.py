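"""End-to-end orchestration: splits, preprocessing, IV selection, runs.

The canonical experiment layout follows the two-stage protocol: 20% of
samples train the stage-1 conditional-distribution estimator; the fitted
conditional-mean exposure is computed on the remaining 80%, which is split
4:1 into second-stage training and testing sets.  Replicate experiments
draw independent seeds from one master seed and produce tidy per-replicate
CSVs plus median/IQR summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import synthetic
from .gan import GanConfig, train_conditional_gan
from .metrics import (
    MetricsRecord,
    exposure_bias,
    kde_logdensity,
    kl_estimate,
    mmd_squared,
    outcome_metrics,
)
from .stage2 import DfnnConfig, MfdlConfig, fit_second_stage
from .tsls import fit_first_stage_ols, ols_conditional_logdensity

logger = logging.getLogger("ganiv")

__all__ = [
    "SplitSpec",
    "IVSet",
    "NoValidIVs",
    "RunConfig",
    "split_dataset",
    "preprocess_genotypes",
    "adjust_covariates",
    "select_ivs_backward_aic",
    "run_experiment",
    "run_replicates",
]


@dataclass(frozen=True)
class SplitSpec:
    """Sample-splitting proportions for the two-stage protocol."""

    stage1_fraction: float = 0.2
    train_test_ratio: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.stage1_fraction < 1:
            raise ValueError("stage1_fraction must lie in (0, 1)")
        if self.train_test_ratio <= 0:
            raise ValueError("train_test_ratio must be positive")


@dataclass
class IVSet:
    """Instruments selected by backward-AIC with the final-model F statistic."""

    columns: list
    f_statistic: float
    coefficients: np.ndarray
    aic: float


@dataclass
class NoValidIVs:
    """Signal (not an exception): no instrument set met the F threshold."""

    f_statistic: float
    reason: str


@dataclass
class RunConfig:
    """Configuration of one experiment (scenario x methods x settings)."""

    scenario: dict = field(default_factory=lambda: {"kind": "simulation1"})
    methods: tuple = ("ganiv", "tsls")
    gan: GanConfig = field(default_factory=GanConfig)
    dfnn: DfnnConfig = field(default_factory=DfnnConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    replicates: int = 100
    output_dir: str | None = None
    seed: int = 0
    # stage-1 criteria settings: Monte-Carlo draws per instrument value and
    # number of evaluation samples for the density criteria
    m_samples: int = 1000
    n_density_eval: int = 50
    stage1_metrics: tuple = ("bias", "kl", "mmd2")

    def __post_init__(self):
        if not self.methods:
            raise ValueError("at least one method required")
        for m in self.methods:
            if m not in ("ganiv", "tsls", "delivr"):
                raise ValueError(f"unknown method {m!r}")

    def fingerprint(self) -> str:
        payload = json.dumps(
            {
                "scenario": self.scenario,
                "methods": list(self.methods),
                "gan": dataclasses.asdict(self.gan),
                "dfnn": dataclasses.asdict(self.dfnn),
                "split": dataclasses.asdict(self.split),
                "seed": self.seed,
                "m_samples": self.m_samples,
            },
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def split_dataset(n: int, spec: SplitSpec):
    """Disjoint, exhaustive (stage1, train, test) index sets.

    Sizes: floor(stage1_fraction*n) for stage 1; the rest is split so that
    test gets floor(rest/(ratio+1)) and train the remainder.
    """
    n1 = int(np.floor(spec.stage1_fraction * n))
    rest = n - n1
    n_test = int(np.floor(rest / (spec.train_test_ratio + 1)))
    n_train = rest - n_test
    if min(n1, n_train, n_test) < 1:
        raise ValueError(f"n={n} too small for the requested split")
    perm = np.random.default_rng(spec.seed).permutation(n)
    return perm[:n1], perm[n1 : n1 + n_train], perm[n1 + n_train :]


def preprocess_genotypes(
    dosages, maf_min: float = 0.05, ld_r2_max: float = 0.9, window: int = 50
):
    """MAF filter then windowed greedy LD pruning (keep the earlier SNP).

    Missing dosages (NaN) are imputed to the column mean first.  Returns
    ``(filtered_matrix, kept_indices, report)`` where the report lists each
    removal with its reason.
    """
    X = np.array(dosages, dtype=float)
    report = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.isnan(col).any():
            col[np.isnan(col)] = np.nanmean(col) if not np.isnan(col).all() else 0.0
    freq = X.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    keep = []
    for j in range(X.shape[1]):
        if maf[j] < maf_min:
            report.append((j, f"MAF {maf[j]:.4f} < {maf_min}"))
        else:
            keep.append(j)
    pruned: list[int] = []
    for j in keep:
        removed = False
        for k in pruned[-(window - 1):] if window > 1 else []:
            sx, sy = X[:, j].std(), X[:, k].std()
            if sx == 0 or sy == 0:
                continue
            r2 = np.corrcoef(X[:, j], X[:, k])[0, 1] ** 2
            if r2 > ld_r2_max:
                report.append((j, f"LD r2 {r2:.3f} with SNP {k} > {ld_r2_max}"))
                removed = True
                break
        if not removed:
            pruned.append(j)
    if not pruned:
        raise ValueError("all SNPs removed by filtering")
    return X[:, pruned], np.asarray(pruned), report


def adjust_covariates(y, covariates=None) -> np.ndarray:
    """Standardized residuals of y regressed on covariates (plus intercept)."""
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if covariates is None or np.size(covariates) == 0:
        resid = y - y.mean()
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        if n <= C.shape[1] + 1:
            raise ValueError("need more samples than covariates plus intercept")
        X = np.column_stack([np.ones(n), C])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("collinear covariates")
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
    sd = resid.std()
    if sd <= 1e-10 * max(1.0, float(np.abs(y).max())):
        raise ValueError("degenerate zero-residual outcome")
    return resid / sd


def select_ivs_backward_aic(
    snps, expression, f_min: float = 10.0, columns=None, max_candidates=None
):
    """Backward model selection by AIC, then an instrument-strength gate.

    Starting from all candidates (pre-screened to at most n/2 by marginal
    correlation when necessary), repeatedly drop the predictor whose removal
    most improves AIC; stop when no removal improves it.  Returns an
    :class:`IVSet` when the final model's overall F statistic reaches
    ``f_min``, else a :class:`NoValidIVs` signal.
    """
    X = np.atleast_2d(np.asarray(snps, dtype=float))
    y = np.asarray(expression, dtype=float).ravel()
    n, p = X.shape
    cols = list(columns) if columns is not None else list(range(p))
    limit = max_candidates if max_candidates is not None else n // 2
    if p > limit:
        corr = np.array(
            [abs(np.corrcoef(X[:, j], y)[0, 1]) if X[:, j].std() > 0 else 0.0
             for j in range(p)]
        )
        order = np.argsort(-corr)[:limit]
        X, cols = X[:, order], [cols[j] for j in order]

    active = list(range(X.shape[1]))

    def fit(idx):
        return sm.OLS(y, sm.add_constant(X[:, idx])).fit()

    current = fit(active)
    while len(active) > 1:
        best_aic, best_drop = current.aic, None
        for j in active:
            cand = [k for k in active if k != j]
            res = fit(cand)
            if res.aic < best_aic:
                best_aic, best_drop = res.aic, j
        if best_drop is None:
            break
        active = [k for k in active if k != best_drop]
        current = fit(active)
    f_stat = float(current.fvalue)
    if not np.isfinite(f_stat) or f_stat < f_min:
        return NoValidIVs(f_stat, f"final-model F {f_stat:.2f} < {f_min}")
    return IVSet(
        columns=[cols[j] for j in active],
        f_statistic=f_stat,
        coefficients=np.asarray(current.params[1:]),
        aic=float(current.aic),
    )


# -- experiment orchestration -------------------------------------------

def _make_dataset(scenario: dict, seed: int):
    kind = scenario.get("kind", "simulation1")
    kwargs = {k: v for k, v in scenario.items() if k != "kind"}
    if kind == "simulation1":
        return synthetic.make_simulation1_dataset(seed=seed, **kwargs)
    if kind == "simulation2":
        return synthetic.make_simulation2_dataset(seed=seed, **kwargs)
    if kind == "pleiotropy":
        return synthetic.make_pleiotropy_dataset(seed=seed, **kwargs)
    raise ValueError(f"unknown scenario kind {kind!r}")


def _stage1_density_metrics(
    ds, idx_eval, method, predictor, rng, m_samples, which
):
    """KL and min-max-MMD averaged over evaluated instrument values."""
    kls, mmds = [], []
    for i in idx_eval:
        z = ds.Z[i]
        h_i = ds.h_vals[i]
        # draws from the true conditional density
        eps = synthetic.draw_noise(
            ds.noise_spec, m_samples, int(rng.integers(2**31))
        )
        x_true = h_i + eps
        if "kl" in which:
            logp = ds.true_logdensity(x_true, z).ravel()
            logp_hat = predictor["logdensity"](z, x_true)
            kls.append(kl_estimate(x_true, logp, logp_hat))
        if "mmd2" in which:
            x_gen = predictor["sample"](z, m_samples)
            mmds.append(mmd_squared(x_gen, x_true))
    out = {}
    if kls:
        out["kl"] = float(np.mean(kls))
    if mmds:
        out["mmd2"] = float(np.mean(mmds))
    return out


def run_experiment(config: RunConfig, replicate: int = 0, seed: int | None = None):
    """One full two-stage run of every configured method.

    Returns a :class:`MetricsRecord` carrying stage-1 criteria (simulation
    scenarios only, where ground-truth oracles exist) and stage-2 criteria
    on the train and test splits.  Method-level failures are logged and
    recorded as missing entries without aborting the other methods.
    """
    seed = config.seed if seed is None else seed
    ds = _make_dataset(config.scenario, seed)
    record = MetricsRecord(replicate=replicate,
                           config_fingerprint=config.fingerprint())
    if isinstance(ds, synthetic.PleiotropyDataset):
        _run_pleiotropy(config, ds, record, seed)
    else:
        _run_two_stage(config, ds, record, seed)
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = pd.DataFrame(
            record.rows(),
            columns=["replicate", "method", "stage", "split", "metric", "value"],
        )
        rows.to_csv(outdir / f"metrics_rep{replicate:04d}.csv", index=False)
    return record


def _fit_stage1(config, Z1, G1, seed):
    """Fit both first stages; returns {method_key: predictor dict}."""
    preds = {}
    need_gan = "ganiv" in config.methods
    need_ols = any(m in config.methods for m in ("tsls", "delivr"))
    if need_ols:
        fit = fit_first_stage_ols(Z1, G1)
        ols_rng = np.random.default_rng(seed + 7)
        preds["ols"] = {
            "conditional_mean": lambda Z: fit.predict(Z),
            "logdensity": lambda z, g: ols_conditional_logdensity(fit, z, g).ravel(),
            "sample": lambda z, M: ols_rng.normal(
                float(np.asarray(fit.predict(z)).ravel()[0]),
                np.sqrt(fit.sigma2_G), size=M,
            ),
            "fit": fit,
        }
    if need_gan:
        gan_cfg = dataclasses.replace(
            config.gan,
            seed=seed,
            batch_size=min(config.gan.batch_size, len(G1)),
        )
        sampler, diag = train_conditional_gan(Z1, G1, gan_cfg)

        counter = {"k": 0}

        def _next_seed():
            counter["k"] += 1
            return (seed + 31 * counter["k"]) % (2**31)

        def gan_logdensity(z, g, _s=sampler):
            draws = _s.sample(z, config.m_samples, seed=_next_seed())
            logd, _ = kde_logdensity(draws, g)
            return logd

        preds["gan"] = {
            "conditional_mean": lambda Z: sampler.conditional_mean(
                Z, config.m_samples, seed=seed + 13
            ),
            "logdensity": gan_logdensity,
            "sample": lambda z, M: sampler.sample(z, M, seed=_next_seed()),
            "sampler": sampler,
            "diagnostics": diag,
        }
    return preds


_METHOD_STAGE1 = {"ganiv": "gan", "tsls": "ols", "delivr": "ols"}
_METHOD_STAGE2 = {"ganiv": "dfnn", "tsls": "linear", "delivr": "shallow_nn"}


def _run_two_stage(config, ds, record, seed):
    idx1, idx_tr, idx_te = split_dataset(
        ds.n, dataclasses.replace(config.split, seed=seed)
    )
    preds = _fit_stage1(config, ds.Z[idx1], ds.G[idx1], seed)
    rng = np.random.default_rng(seed + 23)
    rest = np.concatenate([idx_tr, idx_te])
    n_eval = min(config.n_density_eval, len(rest))
    idx_eval = rng.choice(rest, size=n_eval, replace=False)

    ghat = {}
    for key, pred in preds.items():
        ghat[key] = np.asarray(pred["conditional_mean"](ds.Z[rest])).ravel()

    for method in config.methods:
        key = _METHOD_STAGE1[method]
        if key not in preds:
            continue
        try:
            s1 = {}
            if "bias" in config.stage1_metrics:
                s1["bias"] = exposure_bias(ghat[key], ds.h_vals[rest])
            s1.update(
                _stage1_density_metrics(
                    ds, idx_eval, method, preds[key], rng,
                    min(config.m_samples, 500),
                    [m for m in config.stage1_metrics if m != "bias"],
                )
            )
            record.stage1[method] = s1
        except Exception:
            logger.exception("stage-1 metrics failed for %s", method)

    pos = {i: k for k, i in enumerate(rest)}
    tr_loc = np.array([pos[i] for i in idx_tr])
    te_loc = np.array([pos[i] for i in idx_te])
    for method in config.methods:
        key = _METHOD_STAGE1[method]
        if key not in preds:
            continue
        try:
            g_all = ghat[key]
            kind = _METHOD_STAGE2[method]
            cfg = config.dfnn
            model = fit_second_stage(g_all[tr_loc], ds.Y[idx_tr], cfg, kind=kind)
            record.stage2[method] = {}
            for split, loc, idx in (
                ("train", tr_loc, idx_tr), ("test", te_loc, idx_te)
            ):
                y_hat = model.predict(g_all[loc])
                record.stage2[method][split] = outcome_metrics(
                    y_hat, ds.Y[idx], ds.y0[idx]
                )
        except Exception:
            logger.exception("stage-2 failed for %s", method)


def _run_pleiotropy(config, ds, record, seed):
    """Pleiotropy protocol: stage 1 on the exposure cohort, stage 2 on the
    outcome cohort (4:1 train/test), tag-SNPs as a second modality."""
    exp_idx = ds.indices("exposure")
    out_idx = ds.indices("outcome")
    tags_cols = np.flatnonzero(ds.ld_pairs)
    preds = _fit_stage1(config, ds.Z_E[exp_idx], ds.G_E[exp_idx], seed)

    rng = np.random.default_rng(seed + 29)
    perm = rng.permutation(len(out_idx))
    n_test = int(np.floor(len(out_idx) / (config.split.train_test_ratio + 1)))
    te, tr = out_idx[perm[:n_test]], out_idx[perm[n_test:]]

    for method in config.methods:
        key = _METHOD_STAGE1[method]
        if key not in preds:
            continue
        try:
            if ds.h_E is not None:
                gh = np.asarray(preds[key]["conditional_mean"](ds.Z_E[out_idx])).ravel()
                record.stage1[method] = {
                    "bias": exposure_bias(gh, ds.h_E[out_idx])
                }
            ghat_tr = np.asarray(preds[key]["conditional_mean"](ds.Z_E[tr])).ravel()
            ghat_te = np.asarray(preds[key]["conditional_mean"](ds.Z_E[te])).ravel()
            tags_tr = ds.Z_U[np.ix_(tr, tags_cols)]
            tags_te = ds.Z_U[np.ix_(te, tags_cols)]
            kind = {"ganiv": "mfdl", "tsls": "linear", "delivr": "shallow_nn"}[method]
            cfg = (
                MfdlConfig(**dataclasses.asdict(config.dfnn))
                if kind == "mfdl"
                else config.dfnn
            )
            model = fit_second_stage([ghat_tr, tags_tr], ds.Y[tr], cfg, kind=kind)
            record.stage2[method] = {}
            for split, gh_s, tg_s, idx in (
                ("train", ghat_tr, tags_tr, tr), ("test", ghat_te, tags_te, te)
            ):
                y_hat = model.predict([gh_s, tg_s])
                record.stage2[method][split] = outcome_metrics(
                    y_hat, ds.Y[idx], ds.y0[idx]
                )
        except Exception:
            logger.exception("pleiotropy run failed for %s", method)


def run_replicates(config: RunConfig):
    """Replicate experiments with independent seeds; tidy CSV + summary.

    Completed replicates found in the output directory are skipped on
    rerun (resumability).  Returns ``(per_replicate_df, summary_df)``.
    """
    if config.replicates < 1:
        raise ValueError("replicate count must be >= 1")
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.replicates)]
    outdir = Path(config.output_dir) if config.output_dir else None
    frames = []
    for r, s in enumerate(seeds):
        if outdir is not None:
            f = outdir / f"metrics_rep{r:04d}.csv"
            if f.exists():
                df = pd.read_csv(f)
                df["split"] = df["split"].fillna("")
                frames.append(df)
                logger.info("replicate %d already complete; skipping", r)
                continue
        try:
            rec = run_experiment(config, replicate=r, seed=s)
        except Exception:
            logger.exception("replicate %d failed", r)
            continue
        frames.append(
            pd.DataFrame(
                rec.rows(),
                columns=["replicate", "method", "stage", "split", "metric", "value"],
            )
        )
    per_rep = pd.concat(frames, ignore_index=True)
    grouped = per_rep.groupby(["method", "stage", "split", "metric"], dropna=False)
    summary = grouped["value"].agg(
        median="median",
        q1=lambda v: v.quantile(0.25),
        q3=lambda v: v.quantile(0.75),
        n="count",
    ).reset_index()
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        per_rep.to_csv(outdir / "per_replicate.csv", index=False)
        summary.to_csv(outdir / "summary.csv", index=False)
    return per_rep, summary
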