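"""Model fit and adequacy measures: DIC3, Moran's I, Gelman–Rubin.

DIC3 (Celeux et al.'s third variant) replaces the plug-in density of the
classic DIC with the posterior mean of the likelihood, which keeps it
positive and well behaved for mixture-like posteriors:

    DIC3 = −4·(1/M) Σ_m Σ_i log f(y_i|θ⁽ᵐ⁾) + 2·Σ_i log[(1/M) Σ_m f(y_i|θ⁽ᵐ⁾)].

Moran's I measures global spatial autocorrelation of a per-area vector z
against a weights matrix; significance is assessed by a two-sided permutation
test around its null expectation E[I] = −1/(N−1).  Residual adequacy is
Moran's I on the posterior-mean unstructured effects ε, always with the
binary first-order (A1) weights, whatever weights the model was fitted with.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .model import PosteriorSample, AreaDataset
from .weights import WeightsMatrix, row_standardise

__all__ = [
    "FitEvaluation",
    "dic3",
    "morans_i",
    "morans_p",
    "residual_autocorrelation",
    "gelman_rubin",
    "compare_models",
]


@dataclass
class FitEvaluation:
    """Evaluation record for one fitted model on one data set."""

    spec_label: str
    dataset_label: str
    dic3: float
    mean_deviance: float
    morans_I: float
    morans_p: float
    gelman_rubin: dict | None = None


def _pointwise_loglik(y, E, posterior: PosteriorSample) -> np.ndarray:
    """log f(y_i | θ⁽ᵐ⁾) for every pooled draw m and area i, shape (M, N)."""
    y = np.asarray(y, dtype=float)
    E = np.asarray(E, dtype=float)
    eta = posterior.eta().reshape(-1, posterior.n_areas)
    log_mu = np.log(E)[None, :] + eta
    return y[None, :] * log_mu - np.exp(log_mu) - gammaln(y + 1)[None, :]


def dic3(y, E, posterior: PosteriorSample) -> tuple[float, float]:
    """DIC3 and the posterior mean deviance, chains pooled.

    Per-area density averages are taken in log space with log-sum-exp, so
    small densities at large counts cannot underflow.
    """
    if np.any(np.asarray(E) <= 0):
        raise ValueError("expected counts must be positive")
    ll = _pointwise_loglik(y, E, posterior)      # (M, N)
    m = ll.shape[0]
    mean_dev = float(-2.0 * ll.sum(axis=1).mean())
    log_fhat = logsumexp(ll, axis=0) - np.log(m)  # (N,)
    if np.any(~np.isfinite(log_fhat)):
        bad = np.flatnonzero(~np.isfinite(log_fhat)).tolist()
        raise FloatingPointError(f"posterior mean density is zero for areas {bad}")
    return float(2.0 * mean_dev + 2.0 * log_fhat.sum()), mean_dev


def _standardised(wm: WeightsMatrix) -> np.ndarray:
    return wm.w if wm.standardised else row_standardise(wm).w


def morans_i(z, wm: WeightsMatrix, standardise: bool = True) -> float:
    """Moran's I = (N/S₀)·Σ_ij w_ij (z_i−z̄)(z_j−z̄) / Σ_i (z_i−z̄)².

    Computed on the row-standardised weights by default (set
    ``standardise=False`` for the raw matrix).
    """
    z = np.asarray(z, dtype=float)
    w = _standardised(wm) if standardise else wm.w
    if w.sum() == 0:
        raise ValueError("weights matrix has no positive entries")
    zc = z - z.mean()
    denom = zc @ zc
    if denom == 0:
        raise ValueError("Moran's I is undefined for a constant vector")
    s0 = w.sum()
    return float(len(z) / s0 * (zc @ w @ zc) / denom)


def morans_p(z, wm: WeightsMatrix, n_perm: int = 9_999, seed: int = 0,
             standardise: bool = True) -> float:
    """Two-sided permutation p-value for Moran's I (add-one rule).

    p = (1 + #{ |I* − E[I]| ≥ |I_obs − E[I]| }) / (n_perm + 1) with
    E[I] = −1/(N−1); deterministic given ``seed``.
    """
    z = np.asarray(z, dtype=float)
    n = len(z)
    w = _standardised(wm) if standardise else wm.w
    if w.sum() == 0:
        raise ValueError("weights matrix has no positive entries")
    zc = z - z.mean()
    denom = zc @ zc
    if denom == 0:
        raise ValueError("Moran's I is undefined for a constant vector")
    s0 = w.sum()
    scale = n / s0 / denom
    i_obs = scale * (zc @ w @ zc)
    e_i = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = 2_000
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        zp = rng.permuted(np.broadcast_to(zc, (b, n)), axis=1).T
        quad = np.einsum("ib,ib->b", zp, w @ zp)
        i_perm = scale * quad
        exceed += int(np.sum(np.abs(i_perm - e_i) >= np.abs(i_obs - e_i) - 1e-15))
        done += b
    return (1 + exceed) / (n_perm + 1)


def residual_autocorrelation(posterior: PosteriorSample, a1: WeightsMatrix,
                             n_perm: int = 9_999, seed: int = 0
                             ) -> tuple[float, float]:
    """Moran's I and permutation p on the posterior-mean residuals ε.

    Always uses the binary first-order (A1) weights regardless of which
    weights the model was fitted with.
    """
    eps_mean = posterior.eps.mean(axis=(0, 1))
    return (morans_i(eps_mean, a1),
            morans_p(eps_mean, a1, n_perm=n_perm, seed=seed))


def gelman_rubin(chains: np.ndarray) -> float:
    """Classic potential scale reduction factor R̂ for one parameter.

    ``chains`` has shape (C, M), C ≥ 2 chains of M draws; no rank
    normalisation or chain splitting.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least two chains of draws")
    c, m = chains.shape
    if m < 10:
        raise ValueError("need at least 10 draws per chain")
    within = chains.var(axis=1, ddof=1).mean()
    between = m * chains.mean(axis=1).var(ddof=1)
    var_hat = (m - 1) / m * within + between / m
    if within == 0:
        return 1.0
    return float(np.sqrt(var_hat / within))


def posterior_rhats(posterior: PosteriorSample) -> dict:
    """R̂ for the scalar parameters (and the γ/ε grand means per draw)."""
    out = {
        "alpha": gelman_rubin(posterior.alpha),
        "beta": gelman_rubin(posterior.beta),
        "sigma_eps": gelman_rubin(posterior.sigma_eps),
    }
    if posterior.include_structured:
        out["sigma_gamma2"] = gelman_rubin(posterior.sigma_gamma2)
    return out


def compare_models(evaluations: list[FitEvaluation]):
    """Comparison table: models sorted by DIC3 with ΔDIC and a similar-fit flag.

    Models within 2 DIC units of the best are flagged as having a similar fit.
    """
    import pandas as pd

    if not evaluations:
        raise ValueError("need at least one evaluation")
    labels = {e.dataset_label for e in evaluations}
    if len(labels) != 1:
        raise ValueError(f"evaluations mix datasets: {sorted(labels)}")
    df = pd.DataFrame({
        "model": [e.spec_label for e in evaluations],
        "dataset": [e.dataset_label for e in evaluations],
        "dic3": [e.dic3 for e in evaluations],
        "mean_deviance": [e.mean_deviance for e in evaluations],
        "morans_I": [e.morans_I for e in evaluations],
        "morans_p": [e.morans_p for e in evaluations],
    })
    df = df.sort_values("dic3", kind="mergesort").reset_index(drop=True)
    df["delta_dic"] = df["dic3"] - df["dic3"].iloc[0]
    df["similar_fit"] = df["delta_dic"] <= 2.0
    return df
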