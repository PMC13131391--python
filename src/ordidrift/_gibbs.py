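"""Numba kernel for the single-site Gibbs sweep of the animal model.

Model: y_i = mu + u_i + e_i for phenotyped animals, u ~ N(0, A sigma_u^2)
over all pedigree members, e ~ N(0, I sigma_e^2), flat prior on mu and
scaled inverse chi-squared priors on both variances.  The u-update visits
animals one at a time using the sparse rows of A^-1 (CSR arrays), which is
the only part of the sampler that cannot be vectorized; everything else is
cheap.  The kernel owns its RNG stream (numba's, seeded once per chain).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _inv_chi2(df: float, scale_sum: float) -> float:
    """Draw from the scaled inverse chi-squared full conditional:
    scale_sum / ChiSquare(df), with ChiSquare via Gamma(df/2, 2)."""
    return scale_sum / (2.0 * np.random.gamma(0.5 * df, 1.0))


@njit(cache=True)
def gibbs_chain(indptr, indices, data, diag,            # A^-1 in CSR + diagonal
                y, is_phen,                              # responses, mask
                n_iter, burn_in, thin,
                nu_u, s2_u, nu_e, s2_e,
                sigma_u2_0, sigma_e2_0, seed):
    """Run one chain; return thinned draws and the running mean of u.

    Returns (sigma_u2_draws, sigma_e2_draws, mu_draws, u_mean, n_saved).
    """
    np.random.seed(seed)
    n = len(diag)
    n_rec = 0
    ysum = 0.0
    for i in range(n):
        if is_phen[i]:
            n_rec += 1
            ysum += y[i]

    mu = ysum / n_rec
    u = np.zeros(n)
    sigma_u2 = sigma_u2_0
    sigma_e2 = sigma_e2_0

    n_save = (n_iter - burn_in + thin - 1) // thin
    su2_draws = np.empty(n_save)
    se2_draws = np.empty(n_save)
    mu_draws = np.empty(n_save)
    u_mean = np.zeros(n)
    saved = 0

    for it in range(n_iter):
        inv_su2 = 1.0 / sigma_u2
        inv_se2 = 1.0 / sigma_e2

        # ---- u, single site ------------------------------------------
        for i in range(n):
            off = 0.0  # sum_j != i  A^-1_ij u_j
            for p in range(indptr[i], indptr[i + 1]):
                j = indices[p]
                if j != i:
                    off += data[p] * u[j]
            prec = diag[i] * inv_su2
            rhs = -off * inv_su2
            if is_phen[i]:
                prec += inv_se2
                rhs += (y[i] - mu) * inv_se2
            sd = 1.0 / np.sqrt(prec)
            u[i] = rhs / prec + sd * np.random.standard_normal()

        # ---- mu (flat prior) -----------------------------------------
        acc = 0.0
        for i in range(n):
            if is_phen[i]:
                acc += y[i] - u[i]
        mu = acc / n_rec + np.sqrt(sigma_e2 / n_rec) * np.random.standard_normal()

        # ---- variances -----------------------------------------------
        uAu = 0.0
        for i in range(n):
            row = 0.0
            for p in range(indptr[i], indptr[i + 1]):
                row += data[p] * u[indices[p]]
            uAu += u[i] * row
        sigma_u2 = _inv_chi2(nu_u + n, uAu + nu_u * s2_u)

        sse = 0.0
        for i in range(n):
            if is_phen[i]:
                r = y[i] - mu - u[i]
                sse += r * r
        sigma_e2 = _inv_chi2(nu_e + n_rec, sse + nu_e * s2_e)

        if it >= burn_in and (it - burn_in) % thin == 0:
            su2_draws[saved] = sigma_u2
            se2_draws[saved] = sigma_e2
            mu_draws[saved] = mu
            for i in range(n):
                u_mean[i] += u[i]
            saved += 1

    for i in range(n):
        u_mean[i] /= saved
    return su2_draws, se2_draws, mu_draws, u_mean, saved
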