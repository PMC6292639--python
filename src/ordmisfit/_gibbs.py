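"""Numba Gibbs kernel for the liability threshold model with miscoding.

One compiled function executes the whole per-iteration scan in fixed order:

1. switching indicators / true classes ``r`` (if the misclassification layer
   is enabled), tallying the switch-count matrix ``gamma``;
2. liabilities from truncated normals on the current class intervals;
3. fixed-effect levels, single-site, normal full conditionals truncated to
   the uniform-prior bounds;
4. breeding values, single-site, with ``A^{-1}/sigma_u^2`` in the precision;
5. the genetic variance from its scaled inverse chi-squared conditional;
6. the free thresholds, uniform between the bracketing order statistics;
7. the misclassification columns ``pi_{.k}`` from Dirichlet conjugacy.

The residual variance is fixed at 1 and ``t_0`` at 0 throughout; neither is
represented as a parameter anywhere in the state, which enforces the
identifiability restrictions by construction.

State arrays are updated in place so a caller can warm-start the kernel
(n_iter=1 calls are how the joint-distribution correctness test drives it).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SQRT2 = math.sqrt(2.0)


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * math.erfc(-x / _SQRT2)


@njit(cache=True)
def _ndtri(p):
    """Inverse standard normal CDF (Wichura's AS 241, double precision)."""
    q = p - 0.5
    if abs(q) <= 0.425:
        r = 0.180625 - q * q
        num = (((((((2.5090809287301226727e3 * r + 3.3430575583588128105e4) * r
                    + 6.7265770927008700853e4) * r + 4.5921953931549871457e4) * r
                  + 1.3731693765509461125e4) * r + 1.9715909503065514427e3) * r
                + 1.3314166789178437745e2) * r + 3.3871328727963666080e0)
        den = (((((((5.2264952788528545610e3 * r + 2.8729085735721942674e4) * r
                    + 3.9307895800092710610e4) * r + 2.1213794301586595867e4) * r
                  + 5.3941960214247511077e3) * r + 6.8718700749205790830e2) * r
                + 4.2313330701600911252e1) * r + 1.0)
        return q * num / den
    if q < 0.0:
        r = p
    else:
        r = 1.0 - p
    if r <= 0.0:
        r = 5e-324
    r = math.sqrt(-math.log(r))
    if r <= 5.0:
        r = r - 1.6
        num = (((((((7.74545014278341407640e-4 * r + 2.27238449892691845833e-2) * r
                    + 2.41780725177450611770e-1) * r + 1.27045825245236838258e0) * r
                  + 3.64784832476320460504e0) * r + 5.76949722146069140550e0) * r
                + 4.63033784615654529590e0) * r + 1.42343711074968357734e0)
        den = (((((((1.05075007164441684324e-9 * r + 5.47593808499534494600e-4) * r
                    + 1.51986665636164571966e-2) * r + 1.48103976427480074590e-1) * r
                  + 6.89767334985100004550e-1) * r + 1.67638483018380384940e0) * r
                + 2.05319162663775882187e0) * r + 1.0)
    else:
        r = r - 5.0
        num = (((((((2.01033439929228813265e-7 * r + 2.71155556874348757815e-5) * r
                    + 1.24266094738807843860e-3) * r + 2.65321895265761230930e-2) * r
                  + 2.96560571828504891230e-1) * r + 1.78482653991729133580e0) * r
                + 5.46378491116411436990e0) * r + 6.65790464350110377720e0)
        den = (((((((2.04426310338993978564e-15 * r + 1.42151175831644588870e-7) * r
                    + 1.84631831751005468180e-5) * r + 7.86869131145613259100e-4) * r
                  + 1.48753612908506148525e-2) * r + 1.36929880922735805310e-1) * r
                + 5.99832206555887937690e-1) * r + 1.0)
    x = num / den
    if q < 0.0:
        return -x
    return x


@njit(cache=True)
def _truncnorm(mu, sd, lo, hi):
    """Draw from N(mu, sd^2) restricted to (lo, hi); bounds may be +-inf."""
    if lo == -np.inf:
        pa = 0.0
    else:
        pa = _norm_cdf((lo - mu) / sd)
    if hi == np.inf:
        pb = 1.0
    else:
        pb = _norm_cdf((hi - mu) / sd)
    u = pa + np.random.random() * (pb - pa)
    if u < 1e-16:
        u = 1e-16
    if u > 1.0 - 1e-16:
        u = 1.0 - 1e-16
    x = mu + sd * _ndtri(u)
    # numerical safety at extreme truncation
    if lo != -np.inf and x < lo:
        x = lo + 1e-12 * (1.0 + abs(lo))
    if hi != np.inf and x > hi:
        x = hi
    return x


@njit(cache=True)
def truncnorm_draws(seed, mu, sd, lo, hi, n):
    """Seeded batch of kernel truncated-normal draws (test harness)."""
    np.random.seed(seed)
    out = np.empty(n)
    for i in range(n):
        out[i] = _truncnorm(mu, sd, lo, hi)
    return out


@njit(cache=True)
def run_chain(
    seed,
    n_iter,
    burnin,
    thin,
    # data
    y,          # int64[n] observed classes 0..C-1
    eff_idx,    # int64[n, n_eff] global fixed-effect column per record
    animal,     # int64[n] 0-based pedigree index per record
    n_levels_total,
    level_ptr, level_rows,   # CSR of records per global fixed-effect level
    arec_ptr, arec_rows,     # CSR of records per pedigree animal
    ai_indptr, ai_indices, ai_data,  # A^{-1} CSR
    # priors / settings
    beta_min, beta_max, nu, s2,
    tau,        # float64[C, C] Dirichlet concentrations (column k = obs class)
    C,
    misclass_enabled,
    estimate_pi,
    warmup,     # iterations with the layer inert while location params adapt
    t_upper,
    # state, updated in place
    l, r, beta, u, sigma_u2_box, thr, pi,
    # accumulators, filled in place
    sigma_u2_samples, t1_samples,
    u_sum, beta_sum, pi_sum, gamma_sum, mis_count, r_tally,
):
    np.random.seed(seed)
    n = y.shape[0]
    q = u.shape[0]
    n_eff = eff_idx.shape[1]
    eta = np.empty(n)
    theta = np.empty(C)
    w = np.empty(C)
    gamma = np.zeros((C, C), dtype=np.int64)
    keep = 0

    for it in range(n_iter):
        # linear predictors at current (beta, u)
        for i in range(n):
            e = u[animal[i]]
            for f in range(n_eff):
                e += beta[eff_idx[i, f]]
            eta[i] = e

        # -- 1. switching indicators / true classes ------------------------
        layer_on = misclass_enabled and it >= warmup
        if layer_on:
            for j in range(C):
                for k in range(C):
                    gamma[j, k] = 0
            for i in range(n):
                # model-implied class probabilities theta_ij
                prev = 0.0
                for j in range(C):
                    if j < C - 1:
                        cur = _norm_cdf(thr[j] - eta[i])
                    else:
                        cur = 1.0
                    theta[j] = cur - prev
                    prev = cur
                tot = 0.0
                k = y[i]
                for j in range(C):
                    w[j] = pi[j, k] * theta[j]
                    tot += w[j]
                if tot <= 0.0:
                    r[i] = k
                else:
                    v = np.random.random() * tot
                    acc = 0.0
                    rj = C - 1
                    for j in range(C):
                        acc += w[j]
                        if v <= acc:
                            rj = j
                            break
                    r[i] = rj
                gamma[r[i], k] += 1

        # -- 2. liabilities -------------------------------------------------
        for i in range(n):
            ri = r[i]
            lo = -np.inf if ri == 0 else thr[ri - 1]
            hi = np.inf if ri == C - 1 else thr[ri]
            l[i] = _truncnorm(eta[i], 1.0, lo, hi)

        # -- 3. fixed-effect levels (single site) ---------------------------
        for c in range(n_levels_total):
            n_c = level_ptr[c + 1] - level_ptr[c]
            if n_c == 0:
                continue
            ssum = 0.0
            for idx in range(level_ptr[c], level_ptr[c + 1]):
                i = level_rows[idx]
                ssum += l[i] - (eta[i] - beta[c])
            mean = ssum / n_c
            sd = 1.0 / math.sqrt(n_c)
            newb = _truncnorm(mean, sd, beta_min, beta_max)
            delta = newb - beta[c]
            beta[c] = newb
            for idx in range(level_ptr[c], level_ptr[c + 1]):
                eta[level_rows[idx]] += delta

        # -- 4. breeding values (single site) -------------------------------
        lam = 1.0 / sigma_u2_box[0]
        for a in range(q):
            num = 0.0
            n_a = arec_ptr[a + 1] - arec_ptr[a]
            for idx in range(arec_ptr[a], arec_ptr[a + 1]):
                i = arec_rows[idx]
                num += l[i] - (eta[i] - u[a])
            diag = 0.0
            off = 0.0
            for idx in range(ai_indptr[a], ai_indptr[a + 1]):
                k = ai_indices[idx]
                if k == a:
                    diag = ai_data[idx]
                else:
                    off += ai_data[idx] * u[k]
            prec = n_a + lam * diag
            mean = (num - lam * off) / prec
            newu = mean + np.random.normal(0.0, 1.0) / math.sqrt(prec)
            delta = newu - u[a]
            u[a] = newu
            for idx in range(arec_ptr[a], arec_ptr[a + 1]):
                eta[arec_rows[idx]] += delta

        # -- 5. genetic variance -------------------------------------------
        ss = 0.0
        for a in range(q):
            for idx in range(ai_indptr[a], ai_indptr[a + 1]):
                ss += u[a] * ai_data[idx] * u[ai_indices[idx]]
        sigma_u2_box[0] = (ss + nu * s2) / np.random.chisquare(q + nu)

        # -- 6. free thresholds ---------------------------------------------
        for m in range(1, C - 1):
            lo = thr[m - 1]
            hi = t_upper if m == C - 2 else thr[m + 1]
            for i in range(n):
                if r[i] == m:
                    if l[i] > lo:
                        lo = l[i]
                elif r[i] == m + 1:
                    if l[i] < hi:
                        hi = l[i]
            if hi <= lo:
                hi = lo + 1e-12
            thr[m] = lo + np.random.random() * (hi - lo)

        # -- 7. misclassification rows --------------------------------------
        # pi[j, k] = P(recorded k | true j); each true class's row is a
        # simplex, conjugately updated from its switch counts gamma[j, .]
        if layer_on and estimate_pi:
            for j in range(C):
                tot = 0.0
                for k in range(C):
                    g = np.random.gamma(tau[j, k] + gamma[j, k], 1.0)
                    pi[j, k] = g
                    tot += g
                for k in range(C):
                    pi[j, k] /= tot

        # -- accumulate ------------------------------------------------------
        if it >= burnin and (it - burnin) % thin == 0:
            sigma_u2_samples[keep] = sigma_u2_box[0]
            t1_samples[keep] = thr[1] if C >= 3 else thr[0]
            for a in range(q):
                u_sum[a] += u[a]
            for c in range(n_levels_total):
                beta_sum[c] += beta[c]
            for j in range(C):
                for k in range(C):
                    pi_sum[j, k] += pi[j, k]
                    gamma_sum[j, k] += gamma[j, k]
            for i in range(n):
                if r[i] != y[i]:
                    mis_count[i] += 1
                r_tally[i, r[i]] += 1
            keep += 1
    return keep
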