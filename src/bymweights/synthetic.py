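"""Synthetic areal count data on a rectangular lattice.

Three regimes of the underlying spatial random field (USRF) on a 12×12 grid:

``noise``
    independent Gaussian noise — no spatial autocorrelation;
``smooth``
    a single strongly autocorrelated Gaussian Markov random field draw;
``clusters``
    a convolution of two GMRF draws — a smooth large-scale field thresholded
    into high/low regions, multiplied by a correlated positive field and added
    to small-scale noise — giving around four contiguous patches of elevated
    values on a noisy background.

Observed counts decompose additively on the log scale:
log μ_i = log E_i + β_gen·x̃_i + usrf_i + noise_i, with the covariate x
generated as a scaled copy of the USRF plus noise (so the two are moderately
correlated), log-expected counts from a Gaussian/Gamma mixture concentrated
near 2, and y_i ~ Poisson(μ_i).  Every output is a pure function of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import label as _ndimage_label

from .geometry import ArealGeometry, contiguity, grid_lattice
from .model import AreaDataset

__all__ = [
    "GeneratorConfig",
    "SyntheticComponents",
    "sample_gmrf",
    "make_usrf",
    "make_covariate",
    "make_expected",
    "make_observed",
    "generate_dataset",
    "sample_icar",
    "count_high_patches",
]

REGIMES = ("noise", "smooth", "clusters")


@dataclass
class GeneratorConfig:
    """Tunable parameters of the synthetic-data generator.

    Defaults state the generating world once: a 12×12 lattice, a structured
    field with standard deviation 0.5 on the log-relative-risk scale (the
    order of magnitude of published lip-cancer BYM fits), a covariate carrying
    a stronger effect than either random effect, and log-expected counts
    concentrated near 2 with a few modestly larger values.
    """

    rows: int = 12
    cols: int = 12
    #: proper-CAR autocorrelation for the smooth regime (close to 1 stands in
    #: for the intrinsic field's "strong positive spatial autocorrelation")
    rho: float = 0.99
    #: marginal sd of the USRF (log-relative-risk scale)
    usrf_scale: float = 0.7
    #: neighbourhood-averaging convolution passes applied to the smooth-regime
    #: field; the raw proper-CAR draw is not smooth enough on a 12×12 grid to
    #: reproduce a "smooth surface with a strong degree of autocorrelation"
    smooth_passes: int = 4
    # clusters regime: large-scale field autocorrelation, its high-region
    # quantile, the positive modulating field's log-sd, patch height, and
    # background noise sd
    cluster_rho: float = 0.9
    #: convolution passes on the large-scale clusters field; with the default
    #: autocorrelation this puts the high region into ≈4 contiguous patches
    cluster_passes: int = 3
    cluster_threshold_q: float = 0.75
    cluster_positive_sd: float = 0.2
    cluster_height: float = 1.1
    cluster_background_sd: float = 0.08
    #: covariate loading on the USRF and its noise sd — defaults give a
    #: moderate Pearson correlation (about 0.6) with the USRF
    cov_loading: float = 0.5
    cov_noise_sd: float = 0.3
    # log-expected-count mixture: Gaussian(2, 0.15²) w.p. 0.9, else 2 + Gamma(2, 4)
    # — most logE near 2, a few modestly larger
    loge_mean: float = 2.0
    loge_sd: float = 0.15
    gamma_shape: float = 2.0
    gamma_rate: float = 4.0
    mixture_p: float = 0.9
    #: generating covariate effect — stronger than either spatial random effect
    beta_gen: float = 1.0
    #: sd of the additional log-scale observation noise
    obs_noise_sd: float = 0.1
    #: "poisson" samples y ~ Po(μ); "round" rounds μ to integers instead
    discretise: str = "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.rho < 1 or not 0 < self.cluster_rho < 1:
            raise ValueError("autocorrelation parameters must lie in (0, 1)")
        if not 0 <= self.mixture_p <= 1:
            raise ValueError("mixture probability must lie in [0, 1]")
        for name in ("usrf_scale", "cov_noise_sd", "obs_noise_sd",
                     "cluster_positive_sd", "cluster_background_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class SyntheticComponents:
    """Ground-truth additive components behind one synthetic data set."""

    usrf: np.ndarray
    x: np.ndarray
    logE: np.ndarray
    noise: np.ndarray
    y: np.ndarray
    regime: str
    seed: int

    def log_mu(self, beta_gen: float) -> np.ndarray:
        """Exact additive identity: log μ = logE + β_gen·x̃ + usrf + noise."""
        xc = self.x - self.x.mean()
        return self.logE + beta_gen * xc + self.usrf + self.noise


def _subseed(seed: int, k: int) -> int:
    return (seed * 1000003 + k) % (2 ** 31)


def sample_gmrf(geom: ArealGeometry, rho: float, marginal_sd: float,
                seed: int) -> np.ndarray:
    """One draw from a proper conditional-autoregressive Gaussian field.

    Precision ∝ (D − ρA) with A the binary first-order (queen) adjacency
    matrix and D its row-sum diagonal; the draw is rescaled so its empirical
    standard deviation equals ``marginal_sd``.
    """
    if not 0 < rho < 1:
        raise ValueError("rho must lie in (0, 1)")
    if marginal_sd < 0:
        raise ValueError("marginal_sd must be nonnegative")
    n = geom.n_areas
    if marginal_sd == 0:
        return np.zeros(n)
    a = contiguity(geom, include_vertex=True).adjacency_matrix()
    q = np.diag(a.sum(axis=1)) - rho * a
    try:
        chol = np.linalg.cholesky(q)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "CAR precision is not positive definite (disconnected graph with "
            "rho near 1?)") from err
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    draw = np.linalg.solve(chol.T, z)  # cov = Q^{-1}
    draw = draw - draw.mean()
    sd = draw.std()
    if sd == 0:
        return np.zeros(n)
    return draw * (marginal_sd / sd)


def make_usrf(regime: str, geom: ArealGeometry, config: GeneratorConfig,
              seed: int | None = None) -> np.ndarray:
    """Generate the underlying spatial random field for one regime."""
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; choose one of {REGIMES}")
    seed = config.seed if seed is None else seed
    n = geom.n_areas
    if regime == "noise":
        rng = np.random.default_rng(_subseed(seed, 1))
        return rng.normal(0.0, config.usrf_scale, n)
    if regime == "smooth":
        field_ = sample_gmrf(geom, config.rho, 1.0, _subseed(seed, 1))
        field_ = _convolve(field_, geom, config.smooth_passes)
        return _rescale(field_, config.usrf_scale)
    # clusters: threshold a large-scale field, modulate by a positive
    # correlated field, add small-scale noise
    large = _convolve(sample_gmrf(geom, config.cluster_rho, 1.0, _subseed(seed, 1)),
                      geom, config.cluster_passes)
    high = large > np.quantile(large, config.cluster_threshold_q)
    positive = np.exp(sample_gmrf(geom, config.rho, config.cluster_positive_sd,
                                  _subseed(seed, 2)))
    rng = np.random.default_rng(_subseed(seed, 3))
    background = rng.normal(0.0, config.cluster_background_sd, n)
    return high * config.cluster_height * positive + background


def _convolve(field_: np.ndarray, geom: ArealGeometry, passes: int) -> np.ndarray:
    """Average each area with its queen neighbours ``passes`` times.

    A linear convolution of a Gaussian Markov random field, used to lengthen
    the correlation range beyond what the first-order proper CAR achieves.
    """
    if passes <= 0:
        return field_
    a = contiguity(geom, include_vertex=True).adjacency_matrix()
    rs = a.sum(axis=1)
    rs[rs == 0] = 1.0
    smooth_op = 0.5 * (np.eye(geom.n_areas) + a / rs[:, None])
    out = field_.copy()
    for _ in range(passes):
        out = smooth_op @ out
    return out


def _rescale(field_: np.ndarray, sd: float) -> np.ndarray:
    out = field_ - field_.mean()
    s = out.std()
    if s == 0 or sd == 0:
        return np.zeros_like(out)
    return out * (sd / s)


def make_covariate(usrf: np.ndarray, a: float, sd: float, seed: int) -> np.ndarray:
    """Covariate as a scaled USRF plus Gaussian noise: x = a·usrf + N(0, sd²)."""
    rng = np.random.default_rng(seed)
    return a * np.asarray(usrf, dtype=float) + rng.normal(0.0, sd, len(usrf))


def make_expected(n: int, config: GeneratorConfig, seed: int) -> np.ndarray:
    """Log-expected counts from a Gaussian/Gamma mixture concentrated near 2.

    With probability ``mixture_p`` (default 0.9) logE ~ N(2, 0.15²); otherwise
    logE = 2 + Gamma(2, 1), giving a right tail of a few larger values.
    """
    if n < 1:
        raise ValueError("need at least one area")
    rng = np.random.default_rng(seed)
    gauss = rng.normal(config.loge_mean, config.loge_sd, n)
    tail = config.loge_mean + rng.gamma(config.gamma_shape,
                                        1.0 / config.gamma_rate, n)
    pick_gauss = rng.random(n) < config.mixture_p
    return np.where(pick_gauss, gauss, tail)


def make_observed(usrf: np.ndarray, x: np.ndarray, logE: np.ndarray,
                  config: GeneratorConfig, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Counts from the additive log-scale decomposition.

    μ_i = exp(logE_i + β_gen·x̃_i + usrf_i + noise_i) with x̃ the centred
    covariate; y ~ Poisson(μ) (or round(μ) when ``discretise="round"``).
    Returns ``(y, noise)``.
    """
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, config.obs_noise_sd, len(usrf))
    xc = np.asarray(x) - np.mean(x)
    mu = np.exp(np.asarray(logE) + config.beta_gen * xc + np.asarray(usrf) + noise)
    if config.discretise == "round":
        y = np.round(mu).astype(np.int64)
    else:
        y = rng.poisson(mu).astype(np.int64)
    return y, noise


def generate_dataset(regime: str, config: GeneratorConfig | None = None
                     ) -> tuple[AreaDataset, SyntheticComponents, ArealGeometry]:
    """Assemble one synthetic data set plus its ground-truth components."""
    config = config or GeneratorConfig()
    geom = grid_lattice(config.rows, config.cols)
    seed = config.seed
    usrf = make_usrf(regime, geom, config, seed)
    x = make_covariate(usrf, config.cov_loading, config.cov_noise_sd,
                       _subseed(seed, 4))
    logE = make_expected(geom.n_areas, config, _subseed(seed, 5))
    y, noise = make_observed(usrf, x, logE, config, _subseed(seed, 6))
    data = AreaDataset(area_ids=list(geom.area_ids), y=y, E=np.exp(logE), x=x)
    comps = SyntheticComponents(usrf=usrf, x=x, logE=logE, noise=noise, y=y,
                                regime=regime, seed=seed)
    return data, comps, geom


def sample_icar(w: np.ndarray, sigma_gamma2: float, seed: int) -> np.ndarray:
    """Exact draw from the intrinsic CAR prior under the sum-to-zero constraint.

    The improper joint density ∝ exp(−γᵀ(D−W)γ / 2σγ²) is proper on the
    subspace orthogonal to the constant vector (for a connected graph); the
    draw uses the spectral decomposition of D−W restricted to its positive
    eigenvalues.  Intended for simulating data from the fitted model itself.
    """
    w = np.asarray(w, dtype=float)
    q = np.diag(w.sum(axis=1)) - w
    evals, evecs = np.linalg.eigh(q)
    pos = evals > 1e-10 * evals.max()
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(pos.sum())
    gamma = evecs[:, pos] @ (z / np.sqrt(evals[pos])) * np.sqrt(sigma_gamma2)
    return gamma - gamma.mean()


def count_high_patches(values: np.ndarray, rows: int, cols: int,
                       q: float = 0.75) -> int:
    """Number of queen-contiguous patches of cells above the q-quantile."""
    grid = np.asarray(values).reshape(rows, cols)
    high = grid > np.quantile(grid, q)
    structure = np.ones((3, 3), dtype=int)  # 8-connectivity, matching queen
    _, n = _ndimage_label(high, structure=structure)
    return int(n)
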