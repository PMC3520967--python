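"""Data containers and exact likelihood terms for the two-method N-mixture model.

The hierarchical model: latent site abundance ``N_i ~ Poisson(lambda_i)`` with
``log lambda_i = beta0 + sum_j w_j * beta_j * x_ij``, and observed counts
``y[i, t, m] ~ Binomial(N_i, p_m(i, t))`` with a separate logit-linear detection
component per sampling method ``m``.  Binary indicators ``w_j`` switch abundance
covariates in and out of the model (Kuo–Mallick variable selection).

Counts from methods with unequal numbers of occasions are stored as one
rectangular ``(site, occasion)`` array whose columns are the concatenated
per-method occasion blocks, together with a boolean effort mask; a masked entry
means the method was not run at that site/occasion and contributes nothing to
the likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit, logsumexp

#: large negative sentinel used instead of -inf inside accept/reject arithmetic
NEG_INF = -1.0e300

_P_LO = 1.0e-300
_P_HI = np.nextafter(1.0, 0.0)


@dataclass
class CountData:
    """Observed counts per (site, occasion, method) with an effort mask.

    ``counts`` and ``observed_mask`` have shape ``(n_sites, total_occasions)``
    where the columns are the occasions of ``method_names[0]`` followed by the
    occasions of ``method_names[1]``, etc.
    """

    counts: np.ndarray
    observed_mask: np.ndarray
    site_ids: list
    method_names: list
    occasions_per_method: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a (site, occasion) matrix")
        if self.counts.shape != self.observed_mask.shape:
            raise ValueError("counts and observed_mask shapes differ")
        if len(self.site_ids) != self.counts.shape[0]:
            raise ValueError("site_ids length does not match counts")
        if len(self.method_names) != len(self.occasions_per_method):
            raise ValueError("method_names / occasions_per_method mismatch")
        if sum(self.occasions_per_method) != self.counts.shape[1]:
            raise ValueError(
                "occasion columns do not add up to sum(occasions_per_method)"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            flo = np.asarray(self.counts, dtype=float)
            if np.any(self.observed_mask & (flo != np.floor(flo))):
                raise ValueError("observed counts must be integers")
            self.counts = np.where(self.observed_mask, flo, 0.0).astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts[self.observed_mask] < 0):
            raise ValueError("observed counts must be non-negative")
        # zero out masked cells so downstream code can ignore the mask safely
        self.counts = np.where(self.observed_mask, self.counts, 0)

    # -- structure helpers -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def n_methods(self) -> int:
        return len(self.method_names)

    @property
    def total_occasions(self) -> int:
        return self.counts.shape[1]

    @property
    def method_slices(self) -> dict:
        out, start = {}, 0
        for name, T in zip(self.method_names, self.occasions_per_method):
            out[name] = slice(start, start + T)
            start += T
        return out

    @property
    def method_of_col(self) -> np.ndarray:
        return np.repeat(
            np.arange(self.n_methods), self.occasions_per_method
        ).astype(np.int64)

    def min_abundance(self) -> np.ndarray:
        """Per-site lower bound for latent N: the max observed count."""
        masked = np.where(self.observed_mask, self.counts, 0)
        return masked.max(axis=1).astype(np.int64)

    def validate(self) -> None:
        """Strict check used by file readers and fitting entry points."""
        per_site = self.observed_mask.sum(axis=1)
        if np.any(per_site == 0):
            bad = [self.site_ids[i] for i in np.nonzero(per_site == 0)[0]]
            raise ValueError(f"sites with no observed effort at all: {bad[:10]}")

    def mask_method(self, method: str) -> "CountData":
        """Copy of the data with one method's occasions fully masked out."""
        if method not in self.method_names:
            raise KeyError(f"unknown method {method!r}; have {self.method_names}")
        mask = self.observed_mask.copy()
        mask[:, self.method_slices[method]] = False
        return CountData(
            self.counts.copy(), mask, list(self.site_ids),
            list(self.method_names), list(self.occasions_per_method),
        )

    def subset_sites(self, idx) -> "CountData":
        idx = np.asarray(idx)
        return CountData(
            self.counts[idx], self.observed_mask[idx],
            [self.site_ids[i] for i in idx],
            list(self.method_names), list(self.occasions_per_method),
        )


@dataclass
class AbundanceDesign:
    """Site-level abundance covariates (constant over occasions)."""

    x: np.ndarray                       # (n_sites, J)
    covariate_names: list
    center: np.ndarray | None = None    # standardization record
    scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        if self.x.shape[1] != len(self.covariate_names):
            raise ValueError("covariate_names length does not match x columns")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("abundance covariates must be finite")

    @property
    def n_covariates(self) -> int:
        return self.x.shape[1]

    def standardized(self) -> "AbundanceDesign":
        """Center/scale every column; the transform is stored for prediction."""
        center = self.x.mean(axis=0)
        scale = self.x.std(axis=0, ddof=0)
        scale = np.where(scale == 0, 1.0, scale)
        return AbundanceDesign(
            (self.x - center) / scale, list(self.covariate_names), center, scale
        )

    def subset(self, names) -> "AbundanceDesign":
        names = list(names)
        idx = [self.covariate_names.index(n) for n in names]
        return AbundanceDesign(
            self.x[:, idx], names,
            None if self.center is None else self.center[idx],
            None if self.scale is None else self.scale[idx],
        )


@dataclass
class DetectionDesign:
    """Per-method detection covariates, possibly varying by occasion.

    ``v[method]`` has shape ``(n_sites, T_method, K_method)``.
    """

    v: dict
    covariate_names: dict

    def __post_init__(self) -> None:
        for m, arr in self.v.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 3:
                raise ValueError(f"detection covariates for {m!r} must be 3-d")
            if arr.shape[2] != len(self.covariate_names[m]):
                raise ValueError(f"covariate_names mismatch for method {m!r}")
            self.v[m] = arr

    def standardized(self) -> "DetectionDesign":
        out = {}
        for m, arr in self.v.items():
            center = arr.mean(axis=(0, 1))
            scale = arr.std(axis=(0, 1), ddof=0)
            scale = np.where(scale == 0, 1.0, scale)
            out[m] = (arr - center) / scale
        return DetectionDesign(out, {m: list(n) for m, n in self.covariate_names.items()})


@dataclass
class ModelParams:
    """Abundance coefficients + indicators and per-method detection coefficients."""

    beta0: float
    beta: np.ndarray                # (J,)
    w: np.ndarray                   # (J,) binary inclusion indicators
    alpha0: dict                    # method -> float, logit-scale intercept
    alpha: dict                     # method -> (K_m,) slopes

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.w = np.atleast_1d(np.asarray(self.w, dtype=np.int64))
        if self.beta.shape != self.w.shape:
            raise ValueError("beta and w must have the same length")
        if not np.all(np.isin(self.w, (0, 1))):
            raise ValueError("indicators w must be 0/1")
        if not (np.isfinite(self.beta0) and np.all(np.isfinite(self.beta))):
            raise ValueError("coefficients must be finite")
        self.alpha = {m: np.atleast_1d(np.asarray(a, dtype=float))
                      for m, a in self.alpha.items()}


@dataclass
class LatentAbundance:
    """Integer latent abundance per site."""

    N: np.ndarray

    def __post_init__(self) -> None:
        self.N = np.atleast_1d(np.asarray(self.N))
        if np.any(self.N < 0) or not np.issubdtype(self.N.dtype, np.integer):
            raise ValueError("latent abundance must be non-negative integers")

    def check_bounds(self, data: CountData) -> None:
        lb = data.min_abundance()
        if np.any(self.N < lb):
            bad = np.nonzero(self.N < lb)[0]
            raise ValueError(
                f"latent N below max observed count at sites {bad[:10].tolist()}"
            )


# ---------------------------------------------------------------------------
# likelihood terms
# ---------------------------------------------------------------------------

def expected_abundance(params: ModelParams, design: AbundanceDesign) -> np.ndarray:
    """Per-site Poisson mean ``lambda_i = exp(beta0 + sum_j w_j beta_j x_ij)``.

    Covariates whose indicator is 0 contribute nothing.
    """
    if design.n_covariates != params.beta.shape[0]:
        raise ValueError(
            f"design has {design.n_covariates} covariates but beta has "
            f"{params.beta.shape[0]} entries"
        )
    eta = params.beta0 + design.x @ (params.w * params.beta)
    return np.exp(eta)


def detection_probability(
    params: ModelParams, design: DetectionDesign, method: str,
    site: int, occasion: int,
) -> float:
    """Per-occasion detection probability on the logit scale, strictly in (0, 1)."""
    if method not in params.alpha0:
        raise KeyError(
            f"no detection component for method {method!r}; "
            f"have {sorted(params.alpha0)}"
        )
    v = design.v[method][site, occasion, :]
    eta = params.alpha0[method] + float(v @ params.alpha[method])
    return float(np.clip(expit(eta), _P_LO, _P_HI))


def detection_prob_matrix(
    params: ModelParams, design: DetectionDesign, data: CountData
) -> np.ndarray:
    """Detection probabilities as an (n_sites, total_occasions) matrix."""
    cols = []
    for m in data.method_names:
        eta = params.alpha0[m] + np.einsum("itk,k->it", design.v[m], params.alpha[m])
        cols.append(expit(eta))
    return np.clip(np.concatenate(cols, axis=1), _P_LO, _P_HI)


def count_loglik(y: int, N: int, p: float) -> float:
    """log Binomial(N, p) pmf at y; -inf when the count exceeds abundance."""
    if y < 0 or N < 0:
        raise ValueError("y and N must be non-negative")
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly inside (0, 1)")
    if y > N:
        return -math.inf
    return float(stats.binom.logpmf(y, N, p))


def site_joint_loglik(
    data: CountData, N_i: int, params: ModelParams,
    abund_design: AbundanceDesign, det_designs: DetectionDesign, site: int,
) -> float:
    """Poisson(lambda_i) log pmf at N_i plus all observed binomial terms.

    Masked (no-effort) entries contribute exactly 0.
    """
    lam = expected_abundance(params, abund_design)[site]
    total = float(stats.poisson.logpmf(N_i, lam))
    p = detection_prob_matrix(params, det_designs, data)[site]
    for t in range(data.total_occasions):
        if data.observed_mask[site, t]:
            total += count_loglik(int(data.counts[site, t]), int(N_i), float(p[t]))
    return total


def marginal_site_loglik(
    data: CountData, params: ModelParams, abund_design: AbundanceDesign,
    det_designs: DetectionDesign, site: int, truncation: int,
) -> float:
    """Exact single-site marginal log-likelihood with latent N summed out.

    Sums ``Poisson(N; lambda_i) * prod Binomial(y | N, p)`` over
    ``N = maxcount .. truncation``.  Deterministic; used as an exact-inference
    oracle for the sampler.  Raises if the Poisson tail above the truncation
    point still carries mass > 1e-8.
    """
    lb = int(data.min_abundance()[site])
    if truncation < lb:
        raise ValueError("truncation K must be >= max observed count at the site")
    lam = float(expected_abundance(params, abund_design)[site])
    tail = float(stats.poisson.sf(truncation, lam))
    if tail >= 1e-8:
        raise ValueError(
            f"Poisson tail mass above K={truncation} is {tail:.3g} >= 1e-8; "
            "increase K"
        )
    grid = np.arange(lb, truncation + 1)
    terms = stats.poisson.logpmf(grid, lam).astype(float)
    p = detection_prob_matrix(params, det_designs, data)[site]
    y = data.counts[site]
    for t in range(data.total_occasions):
        if data.observed_mask[site, t]:
            terms = terms + stats.binom.logpmf(y[t], grid, p[t])
    return float(logsumexp(terms))


def full_data_loglik(
    data: CountData, latent: LatentAbundance, params: ModelParams,
    abund_design: AbundanceDesign, det_designs: DetectionDesign,
) -> float:
    """Joint log density over independent sites (sum of site_joint_loglik)."""
    return float(
        sum(
            site_joint_loglik(data, int(latent.N[i]), params, abund_design,
                              det_designs, i)
            for i in range(data.n_sites)
        )
    )
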