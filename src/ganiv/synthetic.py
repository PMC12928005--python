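"""Simulation designs for two-stage instrumental-variable experiments.

Generates genotype instruments under Hardy-Weinberg equilibrium, exposures
with configurable noise families (Normal, Laplace, Gamma, mixture of
Normals), confounded outcomes under several nonlinear causal forms, and
LD-block cohorts driving an unobserved pleiotropic pathway.  Every dataset
carries its ground-truth oracles -- the noiseless instrument-to-exposure map
h(z), the true conditional log-density log p(g|z) and the noiseless outcome
f(G) -- so that estimators can be scored without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "NoiseSpec",
    "CausalFunctionSpec",
    "SimulatedDataset",
    "PleiotropyDataset",
    "simulate_genotypes",
    "simulate_ld_block",
    "draw_noise",
    "make_linear_exposure",
    "causal_effect",
    "make_outcome",
    "make_simulation1_dataset",
    "make_simulation2_dataset",
    "make_pleiotropy_dataset",
]

NOISE_FAMILIES = ("normal", "laplace", "gamma", "mixture_normal")
CAUSAL_FORMS = ("linear", "cos", "poly", "two_way_thres", "three_way_thres")


@dataclass(frozen=True)
class NoiseSpec:
    """A univariate noise family for exposure / outcome disturbances.

    params by family:
      normal:         mean, sd
      laplace:        loc, scale
      gamma:          shape, scale
      mixture_normal: means (tuple), sds (tuple), weights (tuple)
    ``center`` shifts draws by the analytic mean so the population mean is 0.
    """

    family: str = "normal"
    params: dict = field(default_factory=dict)
    center: bool = False

    def __post_init__(self):
        if self.family not in NOISE_FAMILIES:
            raise ValueError(
                f"unknown noise family {self.family!r}; expected one of {NOISE_FAMILIES}"
            )
        p = self._full_params()
        for key in ("sd", "scale"):
            if key in p and np.any(np.asarray(p[key]) <= 0):
                raise ValueError(f"{key} must be strictly positive")
        if "sds" in p and np.any(np.asarray(p["sds"]) <= 0):
            raise ValueError("sds must be strictly positive")

    def _full_params(self) -> dict:
        defaults = {
            "normal": {"mean": 0.0, "sd": 1.0},
            "laplace": {"loc": 0.0, "scale": 1.0},
            "gamma": {"shape": 2.0, "scale": 1.0},
            "mixture_normal": {
                "means": (-2.0, 2.0),
                "sds": (1.0, 1.0),
                "weights": (0.5, 0.5),
            },
        }[self.family]
        return {**defaults, **self.params}

    @property
    def mean(self) -> float:
        """Analytic mean of the (uncentered) distribution."""
        p = self._full_params()
        if self.family == "normal":
            return p["mean"]
        if self.family == "laplace":
            return p["loc"]
        if self.family == "gamma":
            return p["shape"] * p["scale"]
        w = np.asarray(p["weights"], dtype=float)
        return float(np.dot(w / w.sum(), p["means"]))

    @property
    def variance(self) -> float:
        p = self._full_params()
        if self.family == "normal":
            return p["sd"] ** 2
        if self.family == "laplace":
            return 2.0 * p["scale"] ** 2
        if self.family == "gamma":
            return p["shape"] * p["scale"] ** 2
        w = np.asarray(p["weights"], dtype=float)
        w = w / w.sum()
        m = np.asarray(p["means"], dtype=float)
        s = np.asarray(p["sds"], dtype=float)
        mu = float(np.dot(w, m))
        return float(np.dot(w, s**2 + m**2) - mu**2)

    def scaled_to_unit_variance(self) -> "NoiseSpec":
        """Return a spec of the same family rescaled to variance 1."""
        c = 1.0 / np.sqrt(self.variance)
        p = self._full_params()
        if self.family == "normal":
            new = {"mean": p["mean"] * c, "sd": p["sd"] * c}
        elif self.family == "laplace":
            new = {"loc": p["loc"] * c, "scale": p["scale"] * c}
        elif self.family == "gamma":
            new = {"shape": p["shape"], "scale": p["scale"] * c}
        else:
            new = {
                "means": tuple(float(m * c) for m in p["means"]),
                "sds": tuple(float(s * c) for s in p["sds"]),
                "weights": tuple(p["weights"]),
            }
        return NoiseSpec(self.family, new, center=self.center)

    def logpdf(self, x) -> np.ndarray:
        """Log density of the noise (after centering, if requested)."""
        x = np.asarray(x, dtype=float)
        if self.center:
            x = x + self.mean
        p = self._full_params()
        if self.family == "normal":
            return stats.norm.logpdf(x, loc=p["mean"], scale=p["sd"])
        if self.family == "laplace":
            return stats.laplace.logpdf(x, loc=p["loc"], scale=p["scale"])
        if self.family == "gamma":
            return stats.gamma.logpdf(x, a=p["shape"], scale=p["scale"])
        w = np.asarray(p["weights"], dtype=float)
        w = w / w.sum()
        comps = [
            np.log(wk) + stats.norm.logpdf(x, loc=mk, scale=sk)
            for wk, mk, sk in zip(w, p["means"], p["sds"])
        ]
        return np.logaddexp.reduce(comps, axis=0)


@dataclass(frozen=True)
class CausalFunctionSpec:
    """A named exposure-to-outcome causal form f(g).

    Shipped forms (coefficients listed in order):
      linear:          b0 + b1*g                       (default 0, 1)
      cos:             a*cos(b*g)                      (default a=2, b=1)
      poly:            c2*g^2 + c1*g                   (default 0.5, 1)
      two_way_thres:   g + g' + min(g*g', tau)   with g' = g shifted by 1
      three_way_thres: g + g' + g'' + min(g*g'*g'', tau)
    The threshold forms emulate interaction terms truncated at ``threshold``
    (default tau=2); for a scalar exposure the interacting copies are
    deterministic shifts of g so the form stays a function of g alone.
    """

    name: str = "linear"
    coefficients: tuple = ()
    threshold: float = 2.0

    def __post_init__(self):
        if self.name not in CAUSAL_FORMS:
            raise ValueError(
                f"unknown causal form {self.name!r}; expected one of {CAUSAL_FORMS}"
            )

    def _coef(self, defaults):
        c = list(self.coefficients) + list(defaults[len(self.coefficients):])
        return c

    def __call__(self, g) -> np.ndarray:
        g = np.asarray(g, dtype=float)
        if self.name == "linear":
            b0, b1 = self._coef((0.0, 1.0))
            return b0 + b1 * g
        if self.name == "cos":
            a, b = self._coef((2.0, 1.0))
            return a * np.cos(b * g)
        if self.name == "poly":
            c2, c1 = self._coef((0.5, 1.0))
            return c2 * g**2 + c1 * g
        if self.name == "two_way_thres":
            g2 = g + 1.0
            return g + g2 + np.minimum(g * g2, self.threshold)
        g2, g3 = g + 1.0, g - 1.0
        return g + g2 + g3 + np.minimum(g * g2 * g3, self.threshold)


def causal_effect(spec: CausalFunctionSpec, g) -> np.ndarray:
    """Evaluate the causal form elementwise (deterministic)."""
    return spec(np.asarray(g, dtype=float))


@dataclass
class SimulatedDataset:
    """One simulated replicate with its ground-truth oracles."""

    Z: np.ndarray
    G: np.ndarray
    Y: np.ndarray
    U: np.ndarray
    h_vals: np.ndarray
    true_logdensity: Callable[[np.ndarray, np.ndarray], np.ndarray]
    y0: np.ndarray
    seed: int
    noise_spec: NoiseSpec | None = None
    causal_spec: CausalFunctionSpec | None = None
    alpha0: float = 0.0
    alpha1: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.G)
        for name in ("Y", "U", "h_vals", "y0"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from G")
        if self.Z.shape[0] != n:
            raise ValueError("Z row count differs from G")

    @property
    def n(self) -> int:
        return len(self.G)

    def h_of(self, Z: np.ndarray) -> np.ndarray:
        """Noiseless conditional-mean exposure at new instrument values."""
        if self.alpha1 is None:
            raise ValueError("dataset has no stored linear exposure map")
        return self.alpha0 + np.atleast_2d(Z) @ np.asarray(self.alpha1)


@dataclass
class PleiotropyDataset:
    """LD-block cohort where instruments tag an unobserved second pathway."""

    Z_E: np.ndarray
    Z_U: np.ndarray
    G_E: np.ndarray
    G_U: np.ndarray
    Y: np.ndarray
    cohort: np.ndarray
    pleiotropic_proportion: float
    ld_pairs: np.ndarray  # boolean: which Z_E columns have an in-LD partner
    y0: np.ndarray
    seed: int
    h_E: np.ndarray | None = None  # true conditional mean of G_E given Z_E
    h_U: np.ndarray | None = None

    def indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.cohort == label)


# -- generators ---------------------------------------------------------

def simulate_genotypes(n_samples: int, n_snps: int, maf: float, seed: int) -> np.ndarray:
    """Draw dosages {0,1,2} i.i.d. under Hardy-Weinberg proportions."""
    if not 0 < maf < 1:
        raise ValueError("maf must lie strictly inside (0, 1)")
    if n_samples < 1 or n_snps < 1:
        raise ValueError("n_samples and n_snps must be >= 1")
    rng = np.random.default_rng(seed)
    probs = [(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2]
    return rng.choice(3, size=(n_samples, n_snps), p=probs).astype(float)


def _dosage_from_latent(latent: np.ndarray, maf: float) -> np.ndarray:
    """Threshold standard-normal latents into HWE dosage classes."""
    q0 = stats.norm.ppf((1 - maf) ** 2)
    q1 = stats.norm.ppf((1 - maf) ** 2 + 2 * maf * (1 - maf))
    return (latent > q0).astype(float) + (latent > q1).astype(float)


def simulate_ld_block(
    n_samples: int,
    n_causal: int,
    r_target: float,
    pleiotropic_proportion: float,
    maf: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Causal dosages Z_E plus a partner set Z_U in pairwise LD.

    A fraction ``pleiotropic_proportion`` of Z_U columns is generated from a
    latent bivariate normal (thresholded to HWE genotype classes) whose
    latent correlation is searched so the *dosage* correlation is close to
    ``r_target``; the remaining columns are independent.  Returns
    ``(Z_E, Z_U, ld_pairs)`` where ``ld_pairs`` flags partnered columns.
    """
    if n_causal < 1:
        raise ValueError("n_causal must be >= 1")
    if not 0 < r_target <= 1:
        raise ValueError("r_target must lie in (0, 1]")
    if not 0 <= pleiotropic_proportion <= 1:
        raise ValueError("pleiotropic_proportion must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    latent_rho = 1.0 if r_target == 1.0 else _latent_rho_for(r_target, maf)
    n_pairs = int(round(pleiotropic_proportion * n_causal))
    pair_idx = rng.choice(n_causal, size=n_pairs, replace=False)
    ld_pairs = np.zeros(n_causal, dtype=bool)
    ld_pairs[pair_idx] = True

    lat_E = rng.standard_normal((n_samples, n_causal))
    Z_E = _dosage_from_latent(lat_E, maf)
    Z_U = np.empty_like(Z_E)
    for j in range(n_causal):
        if ld_pairs[j]:
            if latent_rho >= 1.0:
                Z_U[:, j] = Z_E[:, j]
                continue
            lat = latent_rho * lat_E[:, j] + np.sqrt(
                1 - latent_rho**2
            ) * rng.standard_normal(n_samples)
        else:
            lat = rng.standard_normal(n_samples)
        Z_U[:, j] = _dosage_from_latent(lat, maf)
    return Z_E, Z_U, ld_pairs


def _latent_rho_for(r_target: float, maf: float, n_mc: int = 200_000) -> float:
    """Monotone bisection for the latent correlation giving dosage corr ~ r."""
    rng = np.random.default_rng(12345)
    a = rng.standard_normal(n_mc)
    b = rng.standard_normal(n_mc)
    da = _dosage_from_latent(a, maf)

    def dosage_corr(rho):
        lat = rho * a + np.sqrt(1 - rho**2) * b
        db = _dosage_from_latent(lat, maf)
        return np.corrcoef(da, db)[0, 1]

    lo, hi = 0.0, 1.0 - 1e-9
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if dosage_corr(mid) < r_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def draw_noise(spec: NoiseSpec, n: int, seed: int) -> np.ndarray:
    """n i.i.d. draws from the noise family, mean-centered when requested."""
    rng = np.random.default_rng(seed)
    p = spec._full_params()
    if spec.family == "normal":
        x = rng.normal(p["mean"], p["sd"], size=n)
    elif spec.family == "laplace":
        x = rng.laplace(p["loc"], p["scale"], size=n)
    elif spec.family == "gamma":
        x = rng.gamma(p["shape"], p["scale"], size=n)
    else:
        w = np.asarray(p["weights"], dtype=float)
        w = w / w.sum()
        comp = rng.choice(len(w), size=n, p=w)
        x = rng.normal(
            np.asarray(p["means"], dtype=float)[comp],
            np.asarray(p["sds"], dtype=float)[comp],
        )
    if spec.center:
        x = x - spec.mean
    return x


def make_linear_exposure(
    Z: np.ndarray, alpha0: float, alpha1: Sequence[float], noise: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """G = alpha0 + Z @ alpha1 + noise, plus the noiseless map h(z)."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    alpha1 = np.asarray(alpha1, dtype=float).ravel()
    noise = np.asarray(noise, dtype=float).ravel()
    if Z.shape[1] != alpha1.size:
        raise ValueError("alpha1 length must equal the number of instruments")
    if Z.shape[0] != noise.size:
        raise ValueError("noise length must equal the number of samples")
    h_vals = alpha0 + Z @ alpha1
    return h_vals + noise, h_vals


def make_outcome(
    G: np.ndarray,
    spec: CausalFunctionSpec,
    confounder_rho: float,
    noise_G: np.ndarray,
    eps_Y: np.ndarray,
    seed: int,
    gamma: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Confounded outcome Y = f(G) + gamma*U + eps_Y.

    The confounder is a shared latent Gaussian,
    U = rho * standardize(noise_G) + sqrt(1 - rho^2) * eta, so that
    corr(U, noise_G) = rho exactly in population.
    """
    if not abs(confounder_rho) < 1:
        raise ValueError("|confounder_rho| must be < 1")
    G = np.asarray(G, dtype=float).ravel()
    noise_G = np.asarray(noise_G, dtype=float).ravel()
    eps_Y = np.asarray(eps_Y, dtype=float).ravel()
    if not (len(G) == len(noise_G) == len(eps_Y)):
        raise ValueError("G, noise_G and eps_Y must have equal lengths")
    rng = np.random.default_rng(seed)
    sd = noise_G.std()
    z_eps = (noise_G - noise_G.mean()) / sd if sd > 0 else np.zeros_like(noise_G)
    eta = rng.standard_normal(len(G))
    U = confounder_rho * z_eps + np.sqrt(1 - confounder_rho**2) * eta
    y0 = causal_effect(spec, G)
    Y = y0 + gamma * U + eps_Y
    return Y, U, y0


# -- study-condition scenario builders ----------------------------------

def make_simulation1_dataset(
    n: int = 1000,
    n_snps: int = 3,
    maf: float = 0.2,
    noise_family: str = "normal",
    alpha0: float = 0.0,
    alpha1: float | Sequence[float] = 1.0,
    confounder_rho: float = 0.5,
    gamma: float = 1.0,
    eps_y_sd: float = 1.0,
    seed: int = 0,
) -> SimulatedDataset:
    """Exposure-distribution study: linear IV map, one of four noise families.

    Every family is rescaled to unit variance (variance-matched) and
    mean-centered so families differ only in distributional shape.  The
    outcome is linear in G with a confounder correlated with the exposure
    noise.
    """
    ss = np.random.SeedSequence(seed)
    s_geno, s_noise, s_conf, s_epsy = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    ]
    Z = simulate_genotypes(n, n_snps, maf, s_geno)
    spec = NoiseSpec(noise_family, center=True).scaled_to_unit_variance()
    eps_G = draw_noise(spec, n, s_noise)
    a1 = np.full(n_snps, alpha1) if np.isscalar(alpha1) else np.asarray(alpha1)
    G, h_vals = make_linear_exposure(Z, alpha0, a1, eps_G)
    causal = CausalFunctionSpec("linear", (0.0, 1.0))
    eps_Y = np.random.default_rng(s_epsy).normal(0.0, eps_y_sd, size=n)
    Y, U, y0 = make_outcome(G, causal, confounder_rho, eps_G, eps_Y, s_conf, gamma)

    def true_logdensity(g, z):
        z = np.atleast_2d(np.asarray(z, dtype=float))
        h = alpha0 + z @ a1
        return spec.logpdf(np.asarray(g, dtype=float) - h)

    return SimulatedDataset(
        Z=Z, G=G, Y=Y, U=U, h_vals=h_vals, true_logdensity=true_logdensity,
        y0=y0, seed=seed, noise_spec=spec, causal_spec=causal,
        alpha0=alpha0, alpha1=a1,
    )


def make_simulation2_dataset(
    n: int = 1000,
    n_snps: int = 3,
    maf: float = 0.2,
    causal_form: str = "cos",
    confounder_rho: float = 0.5,
    gamma: float = 1.0,
    eps_y_sd: float = 1.0,
    seed: int = 0,
) -> SimulatedDataset:
    """Nonlinear causal-effect study: Gaussian exposure, nonlinear f(G).

    The exposure is mean-centered (intercept -2*maf*n_snps), emulating
    normalized expression data; without centering, dosage-sum exposures sit
    on a one-sided range where the shipped nonlinear forms degenerate to
    near-linear maps.
    """
    ds = make_simulation1_dataset(
        n=n, n_snps=n_snps, maf=maf, noise_family="normal",
        alpha0=-2.0 * maf * n_snps,
        confounder_rho=confounder_rho, gamma=gamma, eps_y_sd=eps_y_sd, seed=seed,
    )
    causal = CausalFunctionSpec(causal_form)
    s_conf = int(np.random.SeedSequence(seed).spawn(5)[4].generate_state(1)[0] % (2**31))
    eps_G = ds.G - ds.h_vals
    eps_Y = np.random.default_rng(s_conf + 1).normal(0.0, eps_y_sd, size=n)
    Y, U, y0 = make_outcome(ds.G, causal, confounder_rho, eps_G, eps_Y, s_conf, gamma)
    ds.Y, ds.U, ds.y0, ds.causal_spec = Y, U, y0, causal
    return ds


def make_pleiotropy_dataset(
    n_total: int = 1500,
    cohort_sizes: tuple[int, int, int] = (500, 500, 500),
    pleiotropic_proportion: float = 1.0,
    linear: bool = True,
    n_causal: int = 10,
    r_target: float = 0.8,
    maf: float = 0.2,
    beta_E: float = 1.0,
    beta_U: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> PleiotropyDataset:
    """Pleiotropy-through-LD cohort with an unobserved second exposure.

    The observed exposure G_E and unobserved exposure G_U are linear in
    their causal SNP sets (Z_E, Z_U) plus independent noise; Z_U columns are
    in LD with a configurable fraction of Z_E.  The linear scenario has
    Y = beta_E*G_E + beta_U*G_U + eps; the nonlinear scenario adds quadratic
    and trigonometric terms of G_E.  Samples are labeled into disjoint
    exposure / reference / outcome cohorts.
    """
    if sum(cohort_sizes) != n_total:
        raise ValueError("cohort sizes must sum to n_total")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    Z_E, Z_U, ld_pairs = simulate_ld_block(
        n_total, n_causal, r_target, pleiotropic_proportion, maf, seeds[0]
    )
    rng = np.random.default_rng(seeds[1])
    # weights scaled so the genetic signal in each exposure has ~unit
    # variance (n_causal * E[w^2] * var(dosage) ~ 1), matching the
    # exposure-noise scale used across the simulation designs
    w_scale = 1.0 / np.sqrt(n_causal * 2 * maf * (1 - maf))
    w_E = rng.normal(w_scale, w_scale / 3, size=n_causal)
    w_U = rng.normal(w_scale, w_scale / 3, size=n_causal)
    # dosages are centered at their HWE expectation (2*maf) so both
    # exposures are mean-zero, as normalized expression data would be
    Zc_E, Zc_U = Z_E - 2 * maf, Z_U - 2 * maf
    h_E = Zc_E @ w_E
    h_U = Zc_U @ w_U
    G_E = h_E + noise_sd * rng.standard_normal(n_total)
    G_U = h_U + noise_sd * rng.standard_normal(n_total)
    eps = noise_sd * np.random.default_rng(seeds[2]).standard_normal(n_total)
    if linear:
        y0 = beta_E * G_E
    else:
        y0 = beta_E * G_E + 0.5 * G_E**2 + np.sin(G_E)
    Y = y0 + beta_U * G_U + eps
    cohort = np.repeat(
        np.array(["exposure", "reference", "outcome"]), cohort_sizes
    )
    perm = np.random.default_rng(seeds[3]).permutation(n_total)
    cohort = cohort[perm]
    return PleiotropyDataset(
        Z_E=Z_E, Z_U=Z_U, G_E=G_E, G_U=G_U, Y=Y, cohort=cohort,
        pleiotropic_proportion=pleiotropic_proportion, ld_pairs=ld_pairs,
        y0=y0, seed=seed, h_E=h_E, h_U=h_U,
    )
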