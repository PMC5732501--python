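"""Spatial weights matrices for ICAR smoothing.

Seventeen specifications in four families, each producing a symmetric,
nonnegative, zero-diagonal matrix ``W``:

==========  ==================================================================
label       construction
==========  ==================================================================
A1          binary first-order adjacency (queen by default)
A2          third-order adjacency, order weights ω = (e⁰, e^−0.5, e^−1)
D1, D2, D3  inverse geographic distance to the power k = 1, 2, 5
D4          exponential decay exp(−λ d) with λ = 10 / mean(d)
D5          Gaussian decay exp(−d²/(2b²)) with b = 1/λ
C1–C5       same kernels on covariate distances δ_ij = |x_i − x_j|
H1–H5       same kernels on hybrid distances d_ij · δ_ij
==========  ==================================================================

For the C and H families the decay and bandwidth parameters are recomputed
from the covariate (resp. hybrid) distances.  Inverse-power kernels can hit
zero distances (coincident centroids, tied covariates); non-finite entries
are replaced per row by the row's maximum finite value, after which the lower
triangle is overwritten by the transpose of the upper triangle to restore
symmetry.  Row standardisation is a separate, final step (the fitted model
standardises internally).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import ArealGeometry, ContiguityGraph, UNREACHABLE, adjacency_order, contiguity, pairwise_centroid_distance

__all__ = [
    "SPEC_LABELS",
    "WeightsSpec",
    "WeightsMatrix",
    "adjacency_weights",
    "inverse_power_weights",
    "decay_scale",
    "exponential_decay_weights",
    "gaussian_decay_weights",
    "covariate_distances",
    "hybrid_distances",
    "sanitise_symmetrise",
    "row_standardise",
    "build_weights",
    "neighbour_profile",
]

logger = logging.getLogger(__name__)

SPEC_LABELS = ("A1", "A2", "D1", "D2", "D3", "D4", "D5",
               "C1", "C2", "C3", "C4", "C5", "H1", "H2", "H3", "H4", "H5")

#: order weights for the third-order adjacency model A2
A2_ORDER_WEIGHTS = (np.exp(0.0), np.exp(-0.5), np.exp(-1.0))

#: numerator of the decay-scale rule λ = decay_numerator / mean(distance)
DECAY_NUMERATOR = 10.0

_FAMILY = {"A": "adjacency", "D": "geographic", "C": "covariate", "H": "hybrid"}
_KERNEL_BY_DIGIT = {"1": ("inverse-power", 1), "2": ("inverse-power", 2),
                    "3": ("inverse-power", 5), "4": ("exponential-decay", None),
                    "5": ("gaussian-decay", None)}


@dataclass
class WeightsSpec:
    """Label and construction parameters of one weights specification."""

    label: str
    family: str
    kernel: str
    exponent: int | None = None
    order_weights: tuple | None = None
    decay: float | None = None       # λ, for exponential decay
    bandwidth: float | None = None   # b, for Gaussian decay


@dataclass
class WeightsMatrix:
    """A spatial weights matrix with its provenance.

    ``w`` is N×N, nonnegative, finite and zero-diagonal; symmetric unless
    ``standardised`` (row standardisation breaks symmetry in general).
    """

    w: np.ndarray
    spec: WeightsSpec
    standardised: bool = False

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        n = self.w.shape[0]
        if self.w.shape != (n, n):
            raise ValueError("weights matrix must be square")
        if not np.all(np.isfinite(self.w)):
            raise ValueError("weights matrix contains non-finite entries")
        if np.any(self.w < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(np.diag(self.w) != 0):
            raise ValueError("weights diagonal must be zero")
        if not self.standardised and not np.allclose(self.w, self.w.T, rtol=0, atol=1e-12):
            raise ValueError("unstandardised weights must be symmetric")

    @property
    def n_areas(self) -> int:
        return self.w.shape[0]


def adjacency_weights(graph: ContiguityGraph, n: int = 1,
                      order_weights=(1.0,)) -> WeightsMatrix:
    """nth-order adjacency weights: w_ij = ω_k for kth-order neighbours, k ≤ n.

    ``n=1, ω=(1,)`` gives the binary first-order matrix (A1).
    """
    omega = np.asarray(order_weights, dtype=float)
    if omega.shape != (n,):
        raise ValueError(f"order_weights must have length n={n}")
    if np.any(omega <= 0):
        raise ValueError("order weights must be positive")
    order = adjacency_order(graph, max_order=n)
    w = np.zeros_like(order, dtype=float)
    for k in range(1, n + 1):
        w[order == k] = omega[k - 1]
    if n == 1 and omega[0] == 1.0:
        label = "A1"
    elif n == 3:
        label = "A2"
    else:
        label = f"A(n={n})"
    spec = WeightsSpec(label=label, family="adjacency", kernel="binary-order",
                       order_weights=tuple(omega))
    return WeightsMatrix(w, spec)


def inverse_power_weights(dist: np.ndarray, k: int) -> np.ndarray:
    """Raw inverse-distance-power kernel (1/d)^k; zero distances yield inf.

    Returns a raw matrix — non-finite entries are expected and must pass
    through :func:`sanitise_symmetrise` before use.
    """
    if k < 1:
        raise ValueError("exponent k must be a positive integer")
    d = np.asarray(dist, dtype=float)
    with np.errstate(divide="ignore"):
        w = (1.0 / d) ** k
    np.fill_diagonal(w, 0.0)
    return w


def decay_scale(dist: np.ndarray) -> tuple[float, float]:
    """Decay rate λ = 10 / mean off-diagonal distance, and bandwidth b = 1/λ.

    The mean is over all ordered pairs i ≠ j (identical to the unordered-pair
    mean).  This makes the decay kernels invariant to rescaling the distance
    units.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("decay scale needs at least two areas")
    mean_d = (d.sum() - np.trace(d)) / (n * (n - 1))
    lam = DECAY_NUMERATOR / mean_d
    return lam, 1.0 / lam


def exponential_decay_weights(dist: np.ndarray, lam: float) -> np.ndarray:
    """Raw exponential-decay kernel exp(−λ d); diagonal forced to zero."""
    if lam <= 0:
        raise ValueError("decay rate λ must be positive")
    w = np.exp(-lam * np.asarray(dist, dtype=float))
    np.fill_diagonal(w, 0.0)
    return w


def gaussian_decay_weights(dist: np.ndarray, b: float) -> np.ndarray:
    """Raw Gaussian-decay kernel exp(−d²/(2b²)); diagonal forced to zero."""
    if b <= 0:
        raise ValueError("bandwidth b must be positive")
    d = np.asarray(dist, dtype=float)
    w = np.exp(-(d ** 2) / (2.0 * b * b))
    np.fill_diagonal(w, 0.0)
    return w


def covariate_distances(x) -> np.ndarray:
    """δ_ij = |x_i − x_j|, the covariate analogue of geographic distance."""
    x = np.asarray(x, dtype=float)
    return np.abs(x[:, None] - x[None, :])


def hybrid_distances(d: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Elementwise product d_ij · δ_ij of geographic and covariate distances."""
    d = np.asarray(d, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if d.shape != delta.shape:
        raise ValueError("distance matrices must have the same shape")
    return d * delta


def sanitise_symmetrise(raw: np.ndarray, spec: WeightsSpec | None = None) -> WeightsMatrix:
    """Replace non-finite entries by the row maximum, then force symmetry.

    Per row, every non-finite weight is replaced by the maximum finite value in
    that row; the lower triangle is then overwritten by the transpose of the
    upper triangle.  A row with no finite off-diagonal entry is unrecoverable.
    """
    w = np.array(raw, dtype=float)
    n = w.shape[0]
    if w.shape != (n, n):
        raise ValueError("raw weights must be square")
    off_diag = ~np.eye(n, dtype=bool)
    for i in range(n):
        row = w[i]
        bad = ~np.isfinite(row)
        if bad.any():
            finite_off = row[off_diag[i] & np.isfinite(row)]
            if finite_off.size == 0:
                raise ValueError(f"row {i} has no finite off-diagonal weight to substitute")
            row[bad] = finite_off.max()
    iu = np.triu_indices(n, k=1)
    w[(iu[1], iu[0])] = w[iu]
    np.fill_diagonal(w, 0.0)
    if spec is None:
        spec = WeightsSpec(label="custom", family="custom", kernel="custom")
    return WeightsMatrix(w, spec)


def row_standardise(wm: WeightsMatrix) -> WeightsMatrix:
    """Divide each row by its sum so nonzero rows sum to one.

    All-zero rows (islands) are left unchanged with a logged warning; the
    model pins the structured effect of an island to zero.
    """
    w = wm.w.copy()
    sums = w.sum(axis=1)
    islands = np.flatnonzero(sums == 0)
    if islands.size:
        logger.warning("row standardisation: %d island row(s) left as zeros: %s",
                       islands.size, islands.tolist())
    nz = sums > 0
    w[nz] = w[nz] / sums[nz, None]
    return WeightsMatrix(w, wm.spec, standardised=True)


def build_weights(spec_label: str, geom: ArealGeometry, x=None, *,
                  include_vertex: bool = True,
                  decay_numerator: float = DECAY_NUMERATOR) -> WeightsMatrix:
    """Build any of the 17 weights specifications from geometry (+ covariate).

    The covariate ``x`` is required for the C and H families; geometry shapes
    are required for the A family.  The returned matrix is unstandardised and
    symmetric; apply :func:`row_standardise` before computing Moran's I or a
    neighbour profile.
    """
    label = spec_label.upper()
    if label not in SPEC_LABELS:
        raise ValueError(f"unknown weights spec {spec_label!r}; choose one of {SPEC_LABELS}")
    family = _FAMILY[label[0]]
    if family == "adjacency":
        graph = contiguity(geom, include_vertex=include_vertex)
        if label == "A1":
            return adjacency_weights(graph, n=1, order_weights=(1.0,))
        return adjacency_weights(graph, n=3, order_weights=A2_ORDER_WEIGHTS)

    if family in ("covariate", "hybrid") and x is None:
        raise ValueError(f"spec {label} requires a covariate")
    if family == "geographic":
        dist = pairwise_centroid_distance(geom)
    elif family == "covariate":
        dist = covariate_distances(x)
    else:
        dist = hybrid_distances(pairwise_centroid_distance(geom), covariate_distances(x))

    kernel, k = _KERNEL_BY_DIGIT[label[1]]
    spec = WeightsSpec(label=label, family=family, kernel=kernel, exponent=k)
    if kernel == "inverse-power":
        raw = inverse_power_weights(dist, k)
        return sanitise_symmetrise(raw, spec)
    n = dist.shape[0]
    if n < 2:
        raise ValueError("decay kernels need at least two areas")
    mean_d = (dist.sum() - np.trace(dist)) / (n * (n - 1))
    lam = decay_numerator / mean_d
    b = 1.0 / lam
    if kernel == "exponential-decay":
        spec.decay = lam
        raw = exponential_decay_weights(dist, lam)
    else:
        spec.bandwidth = b
        raw = gaussian_decay_weights(dist, b)
    return sanitise_symmetrise(raw, spec)


def neighbour_profile(wm: WeightsMatrix, thresholds) -> np.ndarray:
    """Mean number of non-negligible neighbours at each weight threshold.

    For each threshold ``t``, counts per row the off-diagonal entries with
    normalised weight ≥ t and averages over rows ("excluding areas with
    normalised weights less than the threshold"); non-increasing in ``t``.
    """
    if not wm.standardised:
        raise ValueError("neighbour_profile expects a row-standardised matrix")
    thresholds = np.asarray(thresholds, dtype=float)
    w = wm.w.copy()
    np.fill_diagonal(w, -np.inf)  # never count self
    out = np.empty(len(thresholds))
    for t_idx, t in enumerate(thresholds):
        if t <= 0:
            counts = (w > 0).sum(axis=1)
        else:
            counts = (w >= t).sum(axis=1)
        out[t_idx] = counts.mean()
    return out
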