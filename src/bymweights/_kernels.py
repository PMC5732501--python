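"""Numba-compiled Metropolis-within-Gibbs kernel for the BYM Poisson model.

One call runs one chain.  Site-wise random-walk Metropolis updates for the
structured (γ) and unstructured (ε) effects, random-walk updates for α, β and
the two scale parameters (on the log scale), with proposal scales adapted
towards standard acceptance rates during burn-in only.  The γ conditional
combines the exact ICAR full conditional (weighted neighbour mean, variance
σγ²/row-sum) with the Poisson likelihood; γ is recentred to sum to zero over
non-island areas after every sweep.  Setting ``likelihood_on=0`` turns the
sampler into a prior sampler, used by the calibration tests.
"""

import numpy as np
from numba import njit

# adaptation targets: 0.44 for scalar/site-wise moves (Roberts & Rosenthal)
_TARGET = 0.44
_ADAPT_WINDOW = 50


@njit(cache=True)
def _site_loglik(y_i, e_i, eta_i, likelihood_on):
    if not likelihood_on:
        return 0.0
    m = eta_i
    if m > 500.0:  # exp would overflow; the -E*exp term dominates anyway
        return y_i * m - 1e300
    return y_i * m - e_i * np.exp(m)


@njit(cache=True)
def run_chain(y, e, x, w, rowsum, include_structured, likelihood_on,
              n_burn, n_keep, thin, seed,
              var_alpha, var_beta, se_scale2, sg_shape, sg_rate,
              alpha0, beta0, gamma0, eps0, sg2_0, se_0):
    """Run one MCMC chain; returns stored draws after burn-in, thinned.

    Returns (alpha, beta, sigma_gamma2, sigma_eps, gamma, eps, accept_rates).
    """
    np.random.seed(seed)
    n = y.shape[0]
    n_store = n_keep // thin

    alpha = alpha0
    beta = beta0
    gamma = gamma0.copy()
    eps = eps0.copy()
    sg2 = sg2_0
    se = se_0

    island = rowsum <= 0.0
    n_free = 0
    for i in range(n):
        if not island[i]:
            n_free += 1
    if include_structured:
        for i in range(n):
            if island[i]:
                gamma[i] = 0.0

    # linear predictor pieces kept incrementally
    eta = np.empty(n)
    for i in range(n):
        eta[i] = alpha + beta * x[i] + gamma[i] + eps[i]

    s_gamma = 0.5
    s_eps = 0.5
    s_alpha = 0.1
    s_beta = 0.1
    s_lsg = 0.5
    s_lse = 0.5

    acc_gamma = 0.0
    acc_eps = 0.0
    acc_alpha = 0.0
    acc_beta = 0.0
    acc_lsg = 0.0
    acc_lse = 0.0
    n_win = 0

    out_alpha = np.empty(n_store)
    out_beta = np.empty(n_store)
    out_sg2 = np.empty(n_store)
    out_se = np.empty(n_store)
    out_gamma = np.empty((n_store, n))
    out_eps = np.empty((n_store, n))

    total = n_burn + n_keep
    stored = 0

    for it in range(total):
        # --- structured effects γ: site-wise RW Metropolis against the ICAR
        # full conditional times the Poisson likelihood
        if include_structured:
            for i in range(n):
                if island[i]:
                    continue
                m_i = 0.0
                for j in range(n):
                    m_i += w[i, j] * gamma[j]
                m_i /= rowsum[i]
                v_i = sg2 / rowsum[i]
                g_old = gamma[i]
                g_new = g_old + s_gamma * np.random.normal()
                eta_new = eta[i] + (g_new - g_old)
                d = _site_loglik(y[i], e[i], eta_new, likelihood_on) \
                    - _site_loglik(y[i], e[i], eta[i], likelihood_on) \
                    - 0.5 * ((g_new - m_i) ** 2 - (g_old - m_i) ** 2) / v_i
                if d >= 0.0 or np.random.random() < np.exp(d):
                    gamma[i] = g_new
                    eta[i] = eta_new
                    acc_gamma += 1.0 / n
            # sum-to-zero constraint over non-island areas; the removed mean
            # is absorbed by α so η is unchanged
            gbar = 0.0
            for i in range(n):
                if not island[i]:
                    gbar += gamma[i]
            gbar /= n_free
            for i in range(n):
                if not island[i]:
                    gamma[i] -= gbar
            alpha += gbar
            # eta unchanged: alpha absorbs the shift

        # --- unstructured effects ε: site-wise RW Metropolis, N(0, σε²) prior
        for i in range(n):
            e_old = eps[i]
            e_new = e_old + s_eps * np.random.normal()
            eta_new = eta[i] + (e_new - e_old)
            d = _site_loglik(y[i], e[i], eta_new, likelihood_on) \
                - _site_loglik(y[i], e[i], eta[i], likelihood_on) \
                - 0.5 * (e_new * e_new - e_old * e_old) / (se * se)
            if d >= 0.0 or np.random.random() < np.exp(d):
                eps[i] = e_new
                eta[i] = eta_new
                acc_eps += 1.0 / n

        # --- α: RW Metropolis, N(0, var_alpha) prior, full likelihood
        a_new = alpha + s_alpha * np.random.normal()
        d = -0.5 * (a_new * a_new - alpha * alpha) / var_alpha
        if likelihood_on:
            for i in range(n):
                d += _site_loglik(y[i], e[i], eta[i] + (a_new - alpha), True) \
                    - _site_loglik(y[i], e[i], eta[i], True)
        if d >= 0.0 or np.random.random() < np.exp(d):
            for i in range(n):
                eta[i] += a_new - alpha
            alpha = a_new
            acc_alpha += 1.0

        # --- β: RW Metropolis, N(0, var_beta) prior
        b_new = beta + s_beta * np.random.normal()
        d = -0.5 * (b_new * b_new - beta * beta) / var_beta
        if likelihood_on:
            for i in range(n):
                d += _site_loglik(y[i], e[i], eta[i] + (b_new - beta) * x[i], True) \
                    - _site_loglik(y[i], e[i], eta[i], True)
        if d >= 0.0 or np.random.random() < np.exp(d):
            for i in range(n):
                eta[i] += (b_new - beta) * x[i]
            beta = b_new
            acc_beta += 1.0

        # --- σγ²: RW on log scale; Gamma(shape, rate) prior on the variance,
        # ICAR pseudo-likelihood (σγ²)^{-(n_free-1)/2} exp(-SS/(2σγ²))
        if include_structured:
            ss = 0.0
            for i in range(n):
                if island[i]:
                    continue
                wg = 0.0
                for j in range(n):
                    wg += w[i, j] * gamma[j]
                ss += rowsum[i] * gamma[i] * gamma[i] - gamma[i] * wg
            l_old = np.log(sg2)
            l_new = l_old + s_lsg * np.random.normal()
            sg2_new = np.exp(l_new)
            # log target + log Jacobian (logpost in terms of l = log σγ²)
            lp_old = sg_shape * l_old - sg_rate * sg2 \
                - 0.5 * (n_free - 1) * l_old - 0.5 * ss / sg2
            lp_new = sg_shape * l_new - sg_rate * sg2_new \
                - 0.5 * (n_free - 1) * l_new - 0.5 * ss / sg2_new
            d = lp_new - lp_old
            if d >= 0.0 or np.random.random() < np.exp(d):
                sg2 = sg2_new
                acc_lsg += 1.0

        # --- σε: RW on log scale; half-normal prior with scale² = se_scale2
        sum_e2 = 0.0
        for i in range(n):
            sum_e2 += eps[i] * eps[i]
        l_old = np.log(se)
        l_new = l_old + s_lse * np.random.normal()
        se_new = np.exp(l_new)
        lp_old = -0.5 * se * se / se_scale2 - (n - 1.0) * l_old \
            - 0.5 * sum_e2 / (se * se)
        lp_new = -0.5 * se_new * se_new / se_scale2 - (n - 1.0) * l_new \
            - 0.5 * sum_e2 / (se_new * se_new)
        d = lp_new - lp_old
        if d >= 0.0 or np.random.random() < np.exp(d):
            se = se_new
            acc_lse += 1.0

        # --- adapt proposal scales during burn-in only
        n_win += 1
        if it < n_burn and n_win == _ADAPT_WINDOW:
            f = np.exp(0.1)
            s_gamma *= f if acc_gamma / n_win > _TARGET else 1.0 / f
            s_eps *= f if acc_eps / n_win > _TARGET else 1.0 / f
            s_alpha *= f if acc_alpha / n_win > _TARGET else 1.0 / f
            s_beta *= f if acc_beta / n_win > _TARGET else 1.0 / f
            s_lsg *= f if acc_lsg / n_win > _TARGET else 1.0 / f
            s_lse *= f if acc_lse / n_win > _TARGET else 1.0 / f
            acc_gamma = acc_eps = acc_alpha = acc_beta = acc_lsg = acc_lse = 0.0
            n_win = 0
        elif it == n_burn - 1:
            acc_gamma = acc_eps = acc_alpha = acc_beta = acc_lsg = acc_lse = 0.0
            n_win = 0

        # --- store
        if it >= n_burn:
            k = it - n_burn
            if (k + 1) % thin == 0:
                out_alpha[stored] = alpha
                out_beta[stored] = beta
                out_sg2[stored] = sg2
                out_se[stored] = se
                for i in range(n):
                    out_gamma[stored, i] = gamma[i]
                    out_eps[stored, i] = eps[i]
                stored += 1

    rates = np.empty(6)
    denom = n_win if n_win > 0 else 1
    rates[0] = acc_gamma / denom
    rates[1] = acc_eps / denom
    rates[2] = acc_alpha / denom
    rates[3] = acc_beta / denom
    rates[4] = acc_lsg / denom
    rates[5] = acc_lse / denom
    return out_alpha, out_beta, out_sg2, out_se, out_gamma, out_eps, rates
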