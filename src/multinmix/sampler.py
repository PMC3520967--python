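"""Metropolis-within-Gibbs MCMC for the two-method N-mixture model.

``run_mcmc`` drives the JIT-compiled per-chain kernel in :mod:`._kernels`,
handles multi-chain bookkeeping (burn-in, thinning, per-chain seeding,
overdispersed initialization) and returns a :class:`PosteriorSamples`
container.  ``update_latent_abundance`` / ``update_coefficients`` /
``update_indicators`` expose one sweep of each kernel family individually for
oracle-level testing.  ``bgr_statistic`` implements the Brooks-Gelman-Rubin
interval-based potential scale reduction diagnostic.

Priors (proper but vague, on standardized covariates): Normal(0, 3.16) on
every coefficient, Bernoulli(0.5) on every inclusion indicator; both are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import model_core as mc
from ._kernels import chain_kernel

_LGAM_SIZE = 100_000


@dataclass
class SamplerConfig:
    """MCMC run protocol: chain lengths mirror the study's run settings."""

    n_iter: int = 190_000
    burn_in: int = 10_000
    thin: int = 20
    n_chains: int = 3
    seed: int = 0
    proposal_scale: float = 0.5     # initial random-walk sd, adapted in burn-in
    latent_step: int = 5            # latent-N proposal is +/- U{1..latent_step}
    prior_sd: float = 3.16          # Normal prior sd for all coefficients
    prior_inclusion: float = 0.5    # Bernoulli prior on each indicator
    adapt_window: int = 100
    save_latent: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1 or self.n_chains < 1 or self.latent_step < 1:
            raise ValueError("thin, n_chains and latent_step must be >= 1")
        if not 0.0 < self.prior_inclusion < 1.0:
            raise ValueError("prior_inclusion must lie in (0, 1)")

    @property
    def n_saved(self) -> int:
        """Saved draws per chain: floor((n_iter - burn_in) / thin)."""
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws across chains.

    Coefficient arrays have shape ``(n_chains, n_saved, ...)``; ``alpha`` maps
    each method name to its slope draws.  ``N`` holds latent abundance draws
    when the run saved them.
    """

    beta0: np.ndarray
    beta: np.ndarray
    w: np.ndarray
    alpha0: np.ndarray
    alpha: dict
    N: np.ndarray | None
    covariate_names: list
    method_names: list
    det_cov_names: dict
    site_ids: list
    acceptance: pd.DataFrame
    attempts: pd.DataFrame
    chain_seeds: list
    config: SamplerConfig

    @property
    def n_chains(self) -> int:
        return self.beta0.shape[0]

    @property
    def n_saved(self) -> int:
        return self.beta0.shape[1]

    def pooled_beta(self) -> np.ndarray:
        return self.beta.reshape(-1, self.beta.shape[2])

    def pooled_w(self) -> np.ndarray:
        return self.w.reshape(-1, self.w.shape[2])

    def pooled_N(self) -> np.ndarray:
        if self.N is None:
            raise ValueError("latent draws were not saved")
        return self.N.reshape(-1, self.N.shape[2])

    def monitored(self) -> tuple[np.ndarray, list]:
        """Continuous monitored parameters as (chain, draw, param) + names."""
        blocks = [self.beta0[:, :, None], self.beta]
        names = ["beta0"] + [f"beta_{n}" for n in self.covariate_names]
        blocks.append(self.alpha0)
        names += [f"alpha0_{m}" for m in self.method_names]
        for m in self.method_names:
            blocks.append(self.alpha[m])
            names += [f"alpha_{m}_{n}" for n in self.det_cov_names[m]]
        return np.concatenate(blocks, axis=2), names

    def rhat(self) -> pd.Series:
        """Brooks-Gelman-Rubin statistic per monitored parameter."""
        mat, names = self.monitored()
        return pd.Series(
            [bgr_statistic(mat[:, :, k]) for k in range(mat.shape[2])],
            index=names, name="bgr",
        )

    def to_dataframe(self, include_latent: bool = False) -> pd.DataFrame:
        """One row per saved draw; chain-labeled rectangular export."""
        C, S = self.n_chains, self.n_saved
        cols = {
            "chain": np.repeat(np.arange(C), S),
            "draw": np.tile(np.arange(S), C),
            "beta0": self.beta0.reshape(-1),
        }
        for j, nme in enumerate(self.covariate_names):
            cols[f"beta_{nme}"] = self.beta[:, :, j].reshape(-1)
        for j, nme in enumerate(self.covariate_names):
            cols[f"w_{nme}"] = self.w[:, :, j].reshape(-1)
        for m_i, m in enumerate(self.method_names):
            cols[f"alpha0_{m}"] = self.alpha0[:, :, m_i].reshape(-1)
            for k, nme in enumerate(self.det_cov_names[m]):
                cols[f"alpha_{m}_{nme}"] = self.alpha[m][:, :, k].reshape(-1)
        if include_latent and self.N is not None:
            for i, sid in enumerate(self.site_ids):
                cols[f"N_{sid}"] = self.N[:, :, i].reshape(-1)
        return pd.DataFrame(cols)


def _pack_arrays(data: mc.CountData, abund: mc.AbundanceDesign,
                 det: mc.DetectionDesign):
    """Flatten the ragged per-method structure into padded kernel arrays."""
    if abund.x.shape[0] != data.n_sites:
        raise ValueError("abundance design rows do not match sites")
    K_det = np.array(
        [len(det.covariate_names[m]) for m in data.method_names], dtype=np.int64
    )
    Kmax = max(1, int(K_det.max()) if len(K_det) else 1)
    V = np.zeros((data.n_sites, data.total_occasions, Kmax))
    for m, sl in data.method_slices.items():
        arr = det.v[m]
        if arr.shape[0] != data.n_sites or arr.shape[1] != sl.stop - sl.start:
            raise ValueError(f"detection design shape mismatch for {m!r}")
        V[:, sl, : arr.shape[2]] = arr
    return (
        np.ascontiguousarray(data.counts, dtype=np.int64),
        np.ascontiguousarray(data.observed_mask),
        data.method_of_col,
        np.ascontiguousarray(abund.x, dtype=float),
        V, K_det, Kmax,
    )


_lgam_table = gammaln(np.arange(_LGAM_SIZE, dtype=float) + 1.0)


def _initial_params(rng, J, method_names, det_cov_names, config,
                    update_w) -> mc.ModelParams:
    """Overdispersed per-chain start: Normal(0, 2 x proposal scale)."""
    sd = 2.0 * config.proposal_scale
    return mc.ModelParams(
        beta0=float(rng.normal(0.0, sd)),
        beta=rng.normal(0.0, sd, J),
        w=np.ones(J, dtype=np.int64),
        alpha0={m: float(rng.normal(0.0, sd)) for m in method_names},
        alpha={m: rng.normal(0.0, sd, len(det_cov_names[m]))
               for m in method_names},
    )


def run_mcmc(
    data: mc.CountData,
    abund_design: mc.AbundanceDesign,
    det_designs: mc.DetectionDesign,
    config: SamplerConfig,
    update_w: bool = True,
) -> PosteriorSamples:
    """Run the full Metropolis-within-Gibbs sampler; reproducible given config.

    With ``update_w=False`` all indicators stay fixed at 1 (used for refits
    with a chosen covariate set).
    """
    y, mask, moc, X, V, K_det, Kmax = _pack_arrays(data, abund_design, det_designs)
    J = X.shape[1]
    M = len(data.method_names)
    lower = data.min_abundance()

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_chains)

    C, S = config.n_chains, config.n_saved
    out_beta0 = np.empty((C, S))
    out_beta = np.empty((C, S, J))
    out_w = np.empty((C, S, J), np.int8)
    out_alpha0 = np.empty((C, S, M))
    out_alpha_pad = np.empty((C, S, M, Kmax))
    out_N = np.empty((C, S, data.n_sites), np.int64) if config.save_latent else None
    acc_rows = []
    att_rows = []
    chain_seeds = []

    for c in range(C):
        k_ss, i_ss = children[c].spawn(2)
        kernel_seed = int(k_ss.generate_state(1)[0] % (2**31))
        chain_seeds.append(kernel_seed)
        rng = np.random.default_rng(i_ss)
        params = _initial_params(rng, J, data.method_names,
                                 det_designs.covariate_names, config, update_w)
        N0 = lower + 1
        _check_finite_start(data, N0, params, abund_design, det_designs)

        alpha_pad = np.zeros((M, Kmax))
        for m_i, m in enumerate(data.method_names):
            alpha_pad[m_i, : K_det[m_i]] = params.alpha[m]
        alpha0_arr = np.array(
            [params.alpha0[m] for m in data.method_names], dtype=float
        )
        res = chain_kernel(
            kernel_seed, config.n_iter, config.burn_in, config.thin,
            y, mask, moc, X, V, K_det,
            float(params.beta0), params.beta.astype(float),
            params.w.astype(np.int64), alpha0_arr, alpha_pad,
            N0.astype(np.int64).copy(),
            True, True, bool(update_w),
            float(config.prior_sd), float(config.prior_inclusion),
            float(config.proposal_scale), int(config.latent_step),
            int(config.adapt_window),
            lower.astype(np.int64), bool(config.save_latent), _lgam_table,
        )
        (s_beta0, s_beta, s_w, s_alpha0, s_alpha, s_N,
         acc_post, att_post, scales, _) = res
        out_beta0[c] = s_beta0
        out_beta[c] = s_beta
        out_w[c] = s_w
        out_alpha0[c] = s_alpha0
        out_alpha_pad[c] = s_alpha
        if out_N is not None:
            out_N[c] = s_N
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = np.where(att_post > 0, acc_post / np.maximum(att_post, 1), np.nan)
        acc_rows.append(rates)
        att_rows.append(att_post)

    block_names = (["beta0"] + [f"beta_{n}" for n in abund_design.covariate_names]
                   + [f"alpha_block_{m}" for m in data.method_names])
    acceptance = pd.DataFrame(acc_rows, columns=block_names)
    acceptance.index.name = "chain"
    attempts = pd.DataFrame(att_rows, columns=block_names)
    attempts.index.name = "chain"

    alpha = {
        m: out_alpha_pad[:, :, m_i, : K_det[m_i]]
        for m_i, m in enumerate(data.method_names)
    }
    return PosteriorSamples(
        beta0=out_beta0, beta=out_beta, w=out_w, alpha0=out_alpha0,
        alpha=alpha, N=out_N,
        covariate_names=list(abund_design.covariate_names),
        method_names=list(data.method_names),
        det_cov_names={m: list(det_designs.covariate_names[m])
                       for m in data.method_names},
        site_ids=list(data.site_ids),
        acceptance=acceptance, attempts=attempts, chain_seeds=chain_seeds,
        config=config,
    )


def _check_finite_start(data, N0, params, abund_design, det_designs) -> None:
    for i in range(data.n_sites):
        ll = mc.site_joint_loglik(data, int(N0[i]), params, abund_design,
                                  det_designs, i)
        if not np.isfinite(ll):
            raise ValueError(
                f"non-finite log posterior at initialization for site "
                f"{data.site_ids[i]!r}"
            )


# ---------------------------------------------------------------------------
# single-sweep kernels (shared code path with run_mcmc, for oracle testing)
# ---------------------------------------------------------------------------

def _single_sweep(data, abund_design, det_designs, params, N, rng, config,
                  upd_latent, upd_coef, upd_w, n_iter=1):
    y, mask, moc, X, V, K_det, Kmax = _pack_arrays(data, abund_design, det_designs)
    alpha_pad = np.zeros((len(data.method_names), Kmax))
    for m_i, m in enumerate(data.method_names):
        alpha_pad[m_i, : K_det[m_i]] = params.alpha[m]
    alpha0_arr = np.array([params.alpha0[m] for m in data.method_names], float)
    beta = params.beta.astype(float).copy()
    w = params.w.astype(np.int64).copy()
    N = np.asarray(N, dtype=np.int64).copy()
    seed = int(rng.integers(2**31))
    res = chain_kernel(
        seed, n_iter, 0, 1, y, mask, moc, X, V, K_det,
        float(params.beta0), beta, w, alpha0_arr, alpha_pad, N,
        upd_latent, upd_coef, upd_w,
        float(config.prior_sd), float(config.prior_inclusion),
        float(config.proposal_scale), int(config.latent_step), 0,
        data.min_abundance().astype(np.int64), True, _lgam_table,
    )
    (s_beta0, s_beta, s_w, s_alpha0, s_alpha, s_N, *_rest, beta0_out) = res
    new_params = mc.ModelParams(
        beta0=float(beta0_out), beta=beta, w=w,
        alpha0={m: float(alpha0_arr[m_i])
                for m_i, m in enumerate(data.method_names)},
        alpha={m: alpha_pad[m_i, : K_det[m_i]].copy()
               for m_i, m in enumerate(data.method_names)},
    )
    return new_params, N, (s_beta0, s_beta, s_w, s_alpha0, s_alpha, s_N)


def update_latent_abundance(data, params, abund_design, det_designs, N, rng,
                            config=None):
    """One symmetric random-walk sweep over all sites' latent abundances."""
    config = config or SamplerConfig(n_iter=2, burn_in=0, thin=1)
    _, N_new, _ = _single_sweep(data, abund_design, det_designs, params, N,
                                rng, config, True, False, False)
    return N_new


def update_coefficients(data, params, abund_design, det_designs, N, rng,
                        config=None):
    """One random-walk MH sweep over all coefficient blocks."""
    config = config or SamplerConfig(n_iter=2, burn_in=0, thin=1)
    new_params, _, _ = _single_sweep(data, abund_design, det_designs, params,
                                     N, rng, config, False, True, False)
    return new_params


def update_indicators(data, params, abund_design, det_designs, N, rng,
                      config=None):
    """One Gibbs sweep over all inclusion indicators (Kuo-Mallick step)."""
    config = config or SamplerConfig(n_iter=2, burn_in=0, thin=1)
    new_params, _, _ = _single_sweep(data, abund_design, det_designs, params,
                                     N, rng, config, False, False, True)
    return new_params


# ---------------------------------------------------------------------------
# convergence diagnostic
# ---------------------------------------------------------------------------

def bgr_statistic(draws, prob: float = 0.8) -> float:
    """Brooks-Gelman-Rubin interval-based potential scale reduction factor.

    Ratio of the width of the pooled empirical ``prob``-interval to the mean
    width of the within-chain intervals.  Values near 1 indicate the chains
    agree; the study's convergence rule is BGR <= 1.01.  Quantiles use the
    inverted-CDF definition so exact chain copies give exactly 1.

    Parameters
    ----------
    draws : array-like, shape (n_chains, n_draws)
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2:
        raise ValueError("draws must be (n_chains, n_draws)")
    m, n = draws.shape
    if m < 2:
        raise ValueError("the BGR statistic needs at least 2 chains")
    if n < 10:
        raise ValueError("the BGR statistic needs at least 10 draws per chain")
    lo, hi = (1.0 - prob) / 2.0, 1.0 - (1.0 - prob) / 2.0
    q = np.quantile(draws, [lo, hi], axis=1, method="inverted_cdf")
    within = float(np.mean(q[1] - q[0]))
    qp = np.quantile(draws.reshape(-1), [lo, hi], method="inverted_cdf")
    pooled = float(qp[1] - qp[0])
    if within == 0.0:
        return 1.0 if pooled == 0.0 else float("inf")
    return pooled / within
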