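"""Independent oracles used by the test suite.

These deliberately avoid the package's sampler code path: posterior
quantities on tiny problems are computed by dense grid integration /
exhaustive enumeration so the MCMC output can be checked against exact
(to quadrature accuracy) answers.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import expit


def latent_posterior_pmf(y_obs, p_obs, lam, K):
    """Exact posterior pmf of one site's latent N given fixed parameters.

    ``y_obs`` and ``p_obs`` are the observed counts and their detection
    probabilities; the posterior is proportional to
    Poisson(N; lam) * prod Binom(y | N, p) on N = 0..K.
    """
    grid = np.arange(K + 1)
    logw = stats.poisson.logpmf(grid, lam).astype(float)
    for y, p in zip(y_obs, p_obs):
        logw += stats.binom.logpmf(y, grid, p)
    logw -= logw.max()
    w = np.exp(logw)
    return grid, w / w.sum()


def _binom_table(y_block, p_grid, K):
    """prod_t Binom(y_t | N, p) for N = 0..K over a grid of p values."""
    out = np.ones((K + 1, p_grid.size))
    grid = np.arange(K + 1)
    for y in y_block:
        out *= stats.binom.pmf(y, grid[:, None], p_grid[None, :])
    return out


def _slice_integral(y1, y2, x, b0g, b1g, a1g, a2g, prior_sd, K,
                    include_slope):
    """Integral (and moment accumulators) of one indicator slice.

    ``include_slope=False`` drops the slope dimension entirely: on that slice
    the slope's prior integrates out to exactly 1.
    """
    n = x.size
    grid = np.arange(K + 1, dtype=float)
    p1 = expit(a1g)
    p2 = expit(a2g)
    if include_slope:
        b1_axis = b1g
        slope_prior = stats.norm.pdf(b1g, 0, prior_sd)
    else:
        b1_axis = np.zeros(1)
        slope_prior = np.ones(1)

    def trap(g):
        if g.size == 1:
            return np.ones(1)
        w = np.full(g.size, g[1] - g[0])
        w[0] = w[-1] = 0.5 * (g[1] - g[0])
        return w

    weight = (
        (stats.norm.pdf(b0g, 0, prior_sd) * trap(b0g))[:, None, None, None]
        * (slope_prior * (trap(b1g) if include_slope else np.ones(1)))[None, :, None, None]
        * (stats.norm.pdf(a1g, 0, prior_sd) * trap(a1g))[None, None, :, None]
        * (stats.norm.pdf(a2g, 0, prior_sd) * trap(a2g))[None, None, None, :]
    )
    F, G = [], []
    for i in range(n):
        coef = b1_axis if include_slope else np.zeros(1)
        lam = np.exp(b0g[:, None] + coef[None, :] * x[i])
        P = stats.poisson.pmf(grid[:, None, None], lam[None])
        B1 = _binom_table(y1[i], p1, K)
        B2 = _binom_table(y2[i], p2, K)
        F.append(np.einsum("nxy,na,nb->xyab", P, B1, B2, optimize=True))
        G.append(np.einsum("nxy,na,nb->xyab", grid[:, None, None] * P,
                           B1, B2, optimize=True))
    post = weight.copy()
    for Fi in F:
        post = post * Fi
    Z = post.sum()
    axes = {"b0": (1, 2, 3), "b1": (0, 2, 3), "a1": (0, 1, 3),
            "a2": (0, 1, 2)}
    out = {"Z": Z}
    for name, ax, g in (("b0", axes["b0"], b0g), ("a1", axes["a1"], a1g),
                        ("a2", axes["a2"], a2g)):
        marg = post.sum(axis=ax)
        out[f"E_{name}"] = float((marg @ g) / Z)
        mu = (marg @ g) / marg.sum()
        out[f"sd_{name}"] = float(np.sqrt((marg @ (g - mu) ** 2) / marg.sum()))
    if include_slope:
        marg = post.sum(axis=axes["b1"])
        out["E_b1"] = float((marg @ b1g) / Z)
        mu = (marg @ b1g) / marg.sum()
        out["sd_b1"] = float(np.sqrt((marg @ (b1g - mu) ** 2) / marg.sum()))
    out["E_N"] = np.array([
        float(np.where(Fi > 0, post / np.where(Fi > 0, Fi, 1.0) * Gi,
                       0.0).sum() / Z)
        for Fi, Gi in zip(F, G)
    ])
    return out


def _toy_moments(y1, y2, x, b0g, b1g, a1g, a2g, prior_sd, prior_pi, K):
    """Posterior moments mixing the two indicator slices exactly."""
    s1 = _slice_integral(y1, y2, x, b0g, b1g, a1g, a2g, prior_sd, K, True)
    s0 = _slice_integral(y1, y2, x, b0g, b1g, a1g, a2g, prior_sd, K, False)
    z1 = prior_pi * s1["Z"]
    z0 = (1.0 - prior_pi) * s0["Z"]
    pw1 = z1 / (z1 + z0)
    mix = lambda key: pw1 * s1[key] + (1.0 - pw1) * s0[key]
    out = {
        "P_w1": float(pw1),
        "E_beta0": float(mix("E_b0")),
        "E_alpha1": float(mix("E_a1")),
        "E_alpha2": float(mix("E_a2")),
        "E_N": mix("E_N"),
        "E_beta1_given_w1": s1["E_b1"],
        # the w = 0 slice contributes the prior mean 0 for the slope
        "E_beta1": float(pw1 * s1["E_b1"]),
        "sd_beta0": float(max(s1["sd_b0"], s0["sd_b0"])),
        "sd_alpha1": float(max(s1["sd_a1"], s0["sd_a1"])),
        "sd_alpha2": float(max(s1["sd_a2"], s0["sd_a2"])),
        "sd_beta1_given_w1": s1["sd_b1"],
    }
    return out


def toy_posterior_quadrature(counts, mask_split, x, prior_sd, prior_pi,
                             K=20, coarse=21, fine=41):
    """Two-pass dense-grid posterior for the 3-site, 2-method toy.

    Unknowns: abundance intercept and one slope with its inclusion
    indicator, one detection intercept per method, latent N per site.
    The indicator's two slices are integrated separately (the excluded
    slope integrates out against its prior exactly).
    """
    y1 = counts[:, :mask_split]
    y2 = counts[:, mask_split:]
    wide = dict(
        b0g=np.linspace(-3.0, 3.5, coarse),
        b1g=np.linspace(-3.0, 3.0, coarse),
        a1g=np.linspace(-6.0, 4.0, coarse),
        a2g=np.linspace(-6.0, 4.0, coarse),
    )
    m0 = _toy_moments(y1, y2, x, prior_sd=prior_sd, prior_pi=prior_pi,
                      K=K, **wide)

    def refine(center, sd, lo, hi):
        a = max(lo, center - 7 * sd)
        b = min(hi, center + 7 * sd)
        return np.linspace(a, b, fine)

    fine_grids = dict(
        b0g=refine(m0["E_beta0"], m0["sd_beta0"], -4, 4),
        b1g=refine(m0["E_beta1_given_w1"], m0["sd_beta1_given_w1"], -4, 4),
        a1g=refine(m0["E_alpha1"], m0["sd_alpha1"], -8, 5),
        a2g=refine(m0["E_alpha2"], m0["sd_alpha2"], -8, 5),
    )
    return _toy_moments(y1, y2, x, prior_sd=prior_sd, prior_pi=prior_pi,
                        K=K, **fine_grids)


def inverted_cdf_quantile(values, q):
    """Independent transcription: smallest value with empirical CDF >= q."""
    srt = np.sort(np.asarray(values, dtype=float))
    n = srt.size
    k = int(np.ceil(q * n)) - 1
    return srt[max(k, 0)]
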