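"""JIT-compiled Metropolis-within-Gibbs kernel for the two-method N-mixture model.

One call runs one chain.  The kernel works on plain arrays:

* ``y, mask``           -- counts and effort mask, shape (n_sites, T_total)
* ``method_of_col``     -- method index of each occasion column
* ``X``                 -- abundance design (n_sites, J)
* ``V, K_det``          -- detection design padded to (n_sites, T_total, Kmax);
                           column t uses covariates 0..K_det[method_of_col[t]]-1
* ``lgam``              -- lookup table lgam[k] = lgamma(k + 1)

Per iteration it sweeps three update families, each of which can be switched
off so single kernels can be exercised in isolation:

1. latent abundance: symmetric integer random walk per site, rejected
   automatically below the max-observed-count support bound;
2. coefficients: scalar Gaussian random-walk MH for the abundance intercept
   and each included slope (slopes with indicator 0 are redrawn from their
   prior, the standard Kuo-Mallick move), plus a joint random-walk block per
   detection component;
3. indicators: exact Bernoulli full-conditional (Gibbs) per covariate with
   the slope held fixed.

Proposal scales adapt toward a 20-50% acceptance rate during burn-in only.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _logsig(x):
    # log(logistic(x)), stable for both tails
    if x >= 0.0:
        return -math.log1p(math.exp(-x))
    return x - math.log1p(math.exp(x))


@njit(cache=True)
def chain_kernel(
    seed,
    n_iter, burn_in, thin,
    y, mask, method_of_col,
    X, V, K_det,
    beta0, beta, w, alpha0, alpha, N,
    upd_latent, upd_coef, upd_w,
    prior_sd, prior_pi, init_scale, n_step, adapt_window,
    lower, save_latent, lgam,
):
    np.random.seed(seed)
    n, T = y.shape
    J = X.shape[1]
    M = K_det.shape[0]
    Kmax = alpha.shape[1]
    Ltab = lgam.shape[0]

    inv2v = 0.5 / (prior_sd * prior_sd)
    logit_pi = math.log(prior_pi) - math.log(1.0 - prior_pi)

    # abundance linear predictor and mean
    eta = np.empty(n)
    lam = np.empty(n)
    for i in range(n):
        s = beta0
        for j in range(J):
            if w[j] == 1:
                s += beta[j] * X[i, j]
        eta[i] = s
        lam[i] = math.exp(s)

    # detection logits and log-probabilities
    xb = np.empty((n, T))
    lp = np.empty((n, T))
    l1p = np.empty((n, T))
    for i in range(n):
        for t in range(T):
            m = method_of_col[t]
            s = alpha0[m]
            for k in range(K_det[m]):
                s += alpha[m, k] * V[i, t, k]
            xb[i, t] = s
            lp[i, t] = _logsig(s)
            l1p[i, t] = _logsig(-s)

    # adaptation blocks: beta0 | beta_1..beta_J | one block per method
    P = 1 + J + M
    scales = np.full(P, init_scale)
    acc = np.zeros(P)
    att = np.zeros(P)
    acc_post = np.zeros(P)
    att_post = np.zeros(P)
    deltas = np.empty(Kmax + 1)

    n_save = (n_iter - burn_in) // thin
    if n_save < 0:
        n_save = 0
    s_beta0 = np.empty(n_save)
    s_beta = np.empty((n_save, J))
    s_w = np.empty((n_save, J), np.int8)
    s_alpha0 = np.empty((n_save, M))
    s_alpha = np.empty((n_save, M, Kmax))
    ncol = n if save_latent else 1
    s_N = np.zeros((n_save, ncol), np.int64)

    isave = 0
    for it in range(n_iter):
        adapting = it < burn_in

        # ---- latent abundance ------------------------------------------
        if upd_latent:
            for i in range(n):
                step = 1 + np.random.randint(n_step)
                if np.random.random() < 0.5:
                    step = -step
                Np = N[i] + step
                if Np < lower[i] or Np + 1 >= Ltab:
                    continue
                dN = Np - N[i]
                d = dN * eta[i] - (lgam[Np] - lgam[N[i]])
                for t in range(T):
                    if mask[i, t]:
                        yy = y[i, t]
                        d += (lgam[Np] - lgam[Np - yy]) \
                            - (lgam[N[i]] - lgam[N[i] - yy]) \
                            + dN * l1p[i, t]
                if math.log(np.random.random()) < d:
                    N[i] = Np
            # Metropolized independence proposal from Poisson(lambda_i):
            # the Poisson factors cancel, leaving the binomial ratio only.
            # This cuts through the abundance/latent-N funnel that a short
            # random walk cannot cross when lambda is large.
            for i in range(n):
                Np = np.random.poisson(lam[i])
                if Np < lower[i] or Np + 1 >= Ltab:
                    continue
                dN = Np - N[i]
                if dN == 0:
                    continue
                d = 0.0
                for t in range(T):
                    if mask[i, t]:
                        yy = y[i, t]
                        d += (lgam[Np] - lgam[Np - yy]) \
                            - (lgam[N[i]] - lgam[N[i] - yy]) \
                            + dN * l1p[i, t]
                if d >= 0.0 or math.log(np.random.random()) < d:
                    N[i] = Np

        if upd_coef:
            # ---- abundance intercept -----------------------------------
            att[0] += 1.0
            if not adapting:
                att_post[0] += 1.0
            delta = np.random.normal() * scales[0]
            b0p = beta0 + delta
            sumN = 0.0
            sumlam = 0.0
            for i in range(n):
                sumN += N[i]
                sumlam += lam[i]
            d = delta * sumN - (math.exp(delta) - 1.0) * sumlam
            d -= (b0p * b0p - beta0 * beta0) * inv2v
            if math.log(np.random.random()) < d:
                beta0 = b0p
                ed = math.exp(delta)
                for i in range(n):
                    eta[i] += delta
                    lam[i] *= ed
                acc[0] += 1.0
                if not adapting:
                    acc_post[0] += 1.0

            # ---- abundance slopes --------------------------------------
            for j in range(J):
                pidx = 1 + j
                if upd_w and w[j] == 0:
                    # Kuo-Mallick: excluded slope moves under its prior
                    beta[j] = np.random.normal() * prior_sd
                    continue
                att[pidx] += 1.0
                if not adapting:
                    att_post[pidx] += 1.0
                delta = np.random.normal() * scales[pidx]
                bp = beta[j] + delta
                d = -(bp * bp - beta[j] * beta[j]) * inv2v
                if w[j] == 1:
                    for i in range(n):
                        e = delta * X[i, j]
                        d += N[i] * e - lam[i] * (math.exp(e) - 1.0)
                if math.log(np.random.random()) < d:
                    beta[j] = bp
                    if w[j] == 1:
                        for i in range(n):
                            eta[i] += delta * X[i, j]
                            lam[i] = math.exp(eta[i])
                    acc[pidx] += 1.0
                    if not adapting:
                        acc_post[pidx] += 1.0

        # ---- inclusion indicators (Gibbs full conditional) -------------
        if upd_w:
            for j in range(J):
                d10 = 0.0  # loglik(w_j = 1) - loglik(w_j = 0), slope fixed
                if w[j] == 1:
                    for i in range(n):
                        e0 = eta[i] - beta[j] * X[i, j]
                        d10 += N[i] * beta[j] * X[i, j] - (lam[i] - math.exp(e0))
                else:
                    for i in range(n):
                        e1 = eta[i] + beta[j] * X[i, j]
                        d10 += N[i] * beta[j] * X[i, j] - (math.exp(e1) - lam[i])
                z = logit_pi + d10
                if z > 700.0:
                    p1 = 1.0
                elif z < -700.0:
                    p1 = 0.0
                else:
                    p1 = 1.0 / (1.0 + math.exp(-z))
                wn = 1 if np.random.random() < p1 else 0
                if wn != w[j]:
                    if wn == 1:
                        for i in range(n):
                            eta[i] += beta[j] * X[i, j]
                            lam[i] = math.exp(eta[i])
                    else:
                        for i in range(n):
                            eta[i] -= beta[j] * X[i, j]
                            lam[i] = math.exp(eta[i])
                    w[j] = wn

        # ---- detection coefficients, one joint block per method --------
        if upd_coef:
            for m in range(M):
                pidx = 1 + J + m
                att[pidx] += 1.0
                if not adapting:
                    att_post[pidx] += 1.0
                Km = K_det[m]
                for k in range(Km + 1):
                    deltas[k] = np.random.normal() * scales[pidx]
                a0p = alpha0[m] + deltas[0]
                d = -(a0p * a0p - alpha0[m] * alpha0[m]) * inv2v
                for k in range(Km):
                    ap = alpha[m, k] + deltas[k + 1]
                    d -= (ap * ap - alpha[m, k] * alpha[m, k]) * inv2v
                for i in range(n):
                    for t in range(T):
                        if method_of_col[t] != m or not mask[i, t]:
                            continue
                        s = xb[i, t] + deltas[0]
                        for k in range(Km):
                            s += deltas[k + 1] * V[i, t, k]
                        d += y[i, t] * (_logsig(s) - lp[i, t]) \
                            + (N[i] - y[i, t]) * (_logsig(-s) - l1p[i, t])
                if math.log(np.random.random()) < d:
                    alpha0[m] += deltas[0]
                    for k in range(Km):
                        alpha[m, k] += deltas[k + 1]
                    for i in range(n):
                        for t in range(T):
                            if method_of_col[t] != m:
                                continue
                            s = xb[i, t] + deltas[0]
                            for k in range(Km):
                                s += deltas[k + 1] * V[i, t, k]
                            xb[i, t] = s
                            lp[i, t] = _logsig(s)
                            l1p[i, t] = _logsig(-s)
                    acc[pidx] += 1.0
                    if not adapting:
                        acc_post[pidx] += 1.0

        # ---- proposal-scale adaptation (burn-in only) ------------------
        if adapting and adapt_window > 0 and (it + 1) % adapt_window == 0:
            for pp in range(P):
                if att[pp] > 0.0:
                    r = acc[pp] / att[pp]
                    if r > 0.45:
                        scales[pp] *= 1.3
                    elif r < 0.25:
                        scales[pp] /= 1.3
                att[pp] = 0.0
                acc[pp] = 0.0

        # ---- save ------------------------------------------------------
        if it >= burn_in and (it - burn_in) % thin == 0 and isave < n_save:
            s_beta0[isave] = beta0
            for j in range(J):
                s_beta[isave, j] = beta[j]
                s_w[isave, j] = w[j]
            for m in range(M):
                s_alpha0[isave, m] = alpha0[m]
                for k in range(Kmax):
                    s_alpha[isave, m, k] = alpha[m, k]
            if save_latent:
                for i in range(n):
                    s_N[isave, i] = N[i]
            isave += 1

    return (s_beta0, s_beta, s_w, s_alpha0, s_alpha, s_N,
            acc_post, att_post, scales, beta0)
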