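"""Synthetic count datasets with the structure the analysis assumes.

The generator mirrors the study's sampling design: ~245 grid cells, two
noninvasive detection methods ("hair_trap", 4 occasions; "bear_rub", 5
occasions), low per-occasion detection (median p around 0.06-0.13),
correlated site-level landscape covariates, and an optional fraction of
sites with no effort for the second method.  A heterogeneity block splits
the population into two latent subgroups with their own abundance
coefficients and per-method susceptibility, so "a segment of the population
invisible to one method" is expressible exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
import math

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from . import model_core as mc

_STAGE_COV, _STAGE_POP, _STAGE_CNT, _STAGE_MASK = 11, 12, 13, 14


@dataclass
class ScenarioConfig:
    """Full generative description of one synthetic scenario."""

    n_sites: int = 245
    occasions: tuple = (4, 5)
    method_names: tuple = ("hair_trap", "bear_rub")
    n_abundance_covariates: int = 15
    covariate_rho: float = 0.3          # exchangeable pairwise correlation
    beta0: float = math.log(3.0)        # log mean abundance per cell
    beta: tuple = ()                    # sparse true slopes; () = all zero
    detection_p: tuple = (0.07, 0.13)   # target median per-occasion p
    det_slopes: tuple = ((0.3, 0.2), (0.3, 0.2))  # (time, effort) per method
    frac_missing_method2: float = 0.31  # share of sites with no method-2 effort
    # --- heterogeneity block ------------------------------------------
    mixing_fraction: float = 0.0        # share of expected abundance in group B
    beta_b: tuple | None = None         # group-B slopes (defaults to beta)
    susceptibility: tuple = ((1.0, 1.0), (1.0, 1.0))  # [group][method]
    seed: int = 20040615

    def __post_init__(self) -> None:
        self.beta = tuple(self.beta) + (0.0,) * (
            self.n_abundance_covariates - len(self.beta)
        )
        if len(self.beta) != self.n_abundance_covariates:
            raise ValueError("beta longer than n_abundance_covariates")
        if self.beta_b is not None:
            self.beta_b = tuple(self.beta_b) + (0.0,) * (
                self.n_abundance_covariates - len(self.beta_b)
            )
            if len(self.beta_b) != self.n_abundance_covariates:
                raise ValueError("beta_b longer than n_abundance_covariates")
        if not 0.0 <= self.mixing_fraction <= 1.0:
            raise ValueError("mixing_fraction must lie in [0, 1]")
        if not 0.0 <= self.frac_missing_method2 <= 1.0:
            raise ValueError("frac_missing_method2 must lie in [0, 1]")
        for row in self.susceptibility:
            for s in row:
                if not 0.0 <= s <= 1.0:
                    raise ValueError("susceptibilities must lie in [0, 1]")

    # -- (de)serialization, used by the config file round-trip ----------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["occasions"] = list(d["occasions"])
        d["method_names"] = list(d["method_names"])
        d["beta"] = list(d["beta"])
        d["beta_b"] = None if d["beta_b"] is None else list(d["beta_b"])
        d["detection_p"] = list(d["detection_p"])
        d["det_slopes"] = [list(r) for r in d["det_slopes"]]
        d["susceptibility"] = [list(r) for r in d["susceptibility"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key in ("occasions", "method_names", "beta", "detection_p"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        for key in ("det_slopes", "susceptibility"):
            if key in d and d[key] is not None:
                d[key] = tuple(tuple(r) for r in d[key])
        if d.get("beta_b") is not None:
            d["beta_b"] = tuple(d["beta_b"])
        return cls(**d)


@dataclass
class Population:
    """Latent abundance split by subgroup; N = N_a + N_b per site."""

    N: np.ndarray
    subgroup_N: np.ndarray      # (n_sites, 2)

    def latent(self) -> mc.LatentAbundance:
        return mc.LatentAbundance(self.N)


def _rng(config_seed, explicit_seed, stage) -> np.random.Generator:
    seed = config_seed if explicit_seed is None else explicit_seed
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def generate_covariates(config: ScenarioConfig, seed=None):
    """Correlated site covariates plus per-method detection covariates.

    Abundance covariates are multivariate normal with exchangeable pairwise
    correlation ``covariate_rho`` and are standardized.  Each detection
    component gets a per-occasion time covariate (a Julian-day analogue) and
    a site-level effort covariate, both standardized.
    """
    rng = _rng(config.seed, seed, _STAGE_COV)
    J = config.n_abundance_covariates
    R = np.full((J, J), config.covariate_rho)
    np.fill_diagonal(R, 1.0)
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as e:
        raise ValueError(
            f"covariate correlation rho={config.covariate_rho} does not give "
            "a positive-definite correlation matrix"
        ) from e
    z = rng.standard_normal((config.n_sites, J))
    x = z @ L.T
    abund = mc.AbundanceDesign(
        x, [f"x{j + 1}" for j in range(J)]
    ).standardized()

    v, names = {}, {}
    for m_i, m in enumerate(config.method_names):
        T = config.occasions[m_i]
        # Julian-day analogue: occasion-driven, with small site-level jitter
        time = np.tile(np.arange(T, dtype=float), (config.n_sites, 1))
        time += 0.25 * rng.standard_normal((config.n_sites, T))
        # sampling effort: site-level, right-skewed like trap counts/rub days
        effort = np.exp(rng.normal(0.0, 0.5, config.n_sites))
        effort = np.tile(effort[:, None], (1, T))
        arr = np.stack([time, effort], axis=2)
        v[m] = arr
        names[m] = ["time", "effort"]
    det = mc.DetectionDesign(v, names).standardized()
    return abund, det


def simulate_population(config: ScenarioConfig, abund_design: mc.AbundanceDesign,
                        seed=None) -> Population:
    """Draw latent abundance; two thinned-Poisson subgroups when mixing > 0."""
    rng = _rng(config.seed, seed, _STAGE_POP)
    beta_a = np.asarray(config.beta, dtype=float)
    beta_b = np.asarray(
        config.beta if config.beta_b is None else config.beta_b, dtype=float
    )
    f = config.mixing_fraction
    lam_a = (1.0 - f) * np.exp(config.beta0 + abund_design.x @ beta_a)
    lam_b = f * np.exp(config.beta0 + abund_design.x @ beta_b)
    for lam in (lam_a, lam_b):
        if np.any(lam > 1e6):
            raise ValueError(
                "expected abundance exceeds 1e6; use a smaller beta0 or slopes"
            )
    n_a = rng.poisson(lam_a)
    n_b = rng.poisson(lam_b) if f > 0 else np.zeros_like(n_a)
    return Population(
        N=(n_a + n_b).astype(np.int64),
        subgroup_N=np.stack([n_a, n_b], axis=1).astype(np.int64),
    )


def detection_intercepts(config: ScenarioConfig,
                         det_design: mc.DetectionDesign) -> dict:
    """Solve each method's logit intercept so the median per-occasion
    detection probability hits its configured target."""
    out = {}
    for m_i, m in enumerate(config.method_names):
        slopes = np.asarray(config.det_slopes[m_i], dtype=float)
        eta = det_design.v[m] @ slopes
        target = config.detection_p[m_i]

        def gap(a0, eta=eta, target=target):
            return float(np.median(expit(a0 + eta))) - target

        out[m] = float(brentq(gap, -15.0, 10.0, xtol=1e-10))
    return out


def true_params(config: ScenarioConfig,
                det_design: mc.DetectionDesign) -> mc.ModelParams:
    """The generating parameters in model form (group-A slopes when mixed)."""
    beta = np.asarray(config.beta, dtype=float)
    a0 = detection_intercepts(config, det_design)
    return mc.ModelParams(
        beta0=config.beta0, beta=beta, w=(beta != 0).astype(np.int64),
        alpha0=a0,
        alpha={m: np.asarray(config.det_slopes[m_i], dtype=float)
               for m_i, m in enumerate(config.method_names)},
    )


def simulate_counts(config: ScenarioConfig, population: Population,
                    det_design: mc.DetectionDesign, seed=None) -> mc.CountData:
    """Binomial counts given latent abundance, with subgroup-by-method
    susceptibility thinning and the method-2 effort mask applied."""
    rng = _rng(config.seed, seed, _STAGE_CNT)
    n = population.N.shape[0]
    a0 = detection_intercepts(config, det_design)
    blocks = []
    for m_i, m in enumerate(config.method_names):
        slopes = np.asarray(config.det_slopes[m_i], dtype=float)
        p = expit(a0[m] + det_design.v[m] @ slopes)   # (n, T_m)
        counts = np.zeros_like(p, dtype=np.int64)
        for g in (0, 1):
            s = config.susceptibility[g][m_i]
            if s == 0.0:
                continue
            Ng = population.subgroup_N[:, g]
            if Ng.sum() == 0:
                continue
            counts += rng.binomial(Ng[:, None], s * p)
        blocks.append(counts)
    counts = np.concatenate(blocks, axis=1)
    mask = np.ones_like(counts, dtype=bool)

    n_missing = int(round(config.frac_missing_method2 * n))
    if n_missing > 0 and len(config.method_names) > 1:
        mask_rng = _rng(config.seed, seed, _STAGE_MASK)
        missing = mask_rng.choice(n, size=n_missing, replace=False)
        T1 = config.occasions[0]
        mask[missing, T1:] = False
    return mc.CountData(
        counts, mask,
        site_ids=[f"cell{i + 1}" for i in range(n)],
        method_names=list(config.method_names),
        occasions_per_method=list(config.occasions),
    )


@dataclass
class SimulatedDataset:
    """A complete scenario realization plus the generating truth."""

    config: ScenarioConfig
    counts: mc.CountData
    abund_design: mc.AbundanceDesign
    det_design: mc.DetectionDesign
    population: Population
    truth: mc.ModelParams


def make_dataset(config: ScenarioConfig, seed=None) -> SimulatedDataset:
    """Covariates -> population -> counts, all from one master seed."""
    abund, det = generate_covariates(config, seed)
    pop = simulate_population(config, abund, seed)
    counts = simulate_counts(config, pop, det, seed)
    return SimulatedDataset(
        config=config, counts=counts, abund_design=abund, det_design=det,
        population=pop, truth=true_params(config, det),
    )


def scenario_presets() -> dict:
    """Named, fully specified scenario configurations.

    ``shared_population``: both methods sample the same homogeneous
    population; 2 of 15 candidate covariates truly act on abundance
    (standardized effects +0.75 and -0.75); every site has effort for both
    methods, matching an analysis restricted to dually sampled cells.

    ``heterogeneous_subpopulations``: half the expected abundance sits in a
    subgroup that is invisible to the first method and responds to a
    different covariate, the mechanism by which two methods can sample
    different segments of a population.
    """
    shared = ScenarioConfig(
        beta=(0.75, -0.75),
        frac_missing_method2=0.0,
    )
    hetero = ScenarioConfig(
        beta=(0.75,),
        beta_b=(0.0, 0.75),
        mixing_fraction=0.5,
        susceptibility=((1.0, 1.0), (0.0, 1.0)),
        frac_missing_method2=0.0,
    )
    return {"shared_population": shared, "heterogeneous_subpopulations": hetero}


def get_preset(name: str) -> ScenarioConfig:
    presets = scenario_presets()
    if name not in presets:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        )
    return replace(presets[name])
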