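"""Distributed inverse solutions: wMNE, dSPM, sLORETA.

All three share the regularized minimum-norm backbone

    G = C_s L' (L C_s L' + alpha C_n)^-1,

where C_s is the source prior covariance (identity for plain MNE; the
depth-weighting prior for wMNE) and C_n the sensor noise covariance.
dSPM rescales the rows of a (w)MNE operator by the estimated noise standard
deviation at each source point (a diagonal normalization, so row shapes are
preserved); sLORETA standardizes by the inverse matrix square roots of the
3x3 diagonal blocks of the resolution matrix A = G L, which mixes only the
three components of one source point.

The regularization parameter alpha is chosen by generalized cross-validation
on the whitened, prior-weighted system, with the fixed fallback alpha = 1/3
whenever the GCV minimizer drops below 0.01.

A scikit-learn style estimator (:class:`InverseSolver`) wraps the whole
fit-then-apply chain; the module-level functions are the individual steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .forward import LeadField

__all__ = [
    "NoiseCovariance",
    "DepthWeights",
    "InverseOperator",
    "SourceEstimate",
    "estimate_noise_covariance",
    "depth_weights",
    "wmne_operator",
    "mne_operator",
    "gcv_alpha",
    "dspm_operator",
    "sloreta_operator",
    "resolution_matrix",
    "apply_inverse",
    "InverseSolver",
    "DEFAULT_ALPHA_GRID",
]

DEFAULT_ALPHA_GRID = np.logspace(-6, 2, 40)
_EIG_FLOOR = 1e-12


@dataclass
class NoiseCovariance:
    """Sensor noise covariance with scale-aware Tikhonov loading.

    ``matrix`` already contains the loading term eps*(tr(C)/N_e)*I.
    """

    matrix: np.ndarray
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("noise covariance must be symmetric")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    def inv_sqrt(self) -> np.ndarray:
        """Whitener C^(-1/2) via symmetric eigendecomposition."""
        vals, vecs = np.linalg.eigh(self.matrix)
        floor = _EIG_FLOOR * vals.max()
        vals = np.maximum(vals, floor)
        return (vecs / np.sqrt(vals)) @ vecs.T


@dataclass
class DepthWeights:
    """Per-source depth-compensation weights w_p (capped dynamic range)."""

    values: np.ndarray
    gamma: float = 0.5
    limit: float = 10.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values <= 0):
            raise ValueError("depth weights must be positive")


@dataclass
class InverseOperator:
    """Linear map from sensor data to source components, s_hat = G d."""

    matrix: np.ndarray
    method: str
    alpha: float
    base: str | None = None
    normalization: str = "none"  # none | diagonal | block
    channel_names: list[str] | None = None
    average_reference: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] % 3:
            raise ValueError("operator must have 3 rows per source point")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[0] // 3

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[1]


@dataclass
class SourceEstimate:
    """Estimated source components (N_s, 3, T) and per-vertex amplitude norms."""

    components: np.ndarray
    norms: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if self.components.ndim == 2:
            self.components = self.components[:, :, None]
        self.norms = np.linalg.norm(self.components, axis=1)

    @property
    def n_sources(self) -> int:
        return self.components.shape[0]


def estimate_noise_covariance(
    segments: np.ndarray | list[np.ndarray], epsilon: float = 0.1
) -> NoiseCovariance:
    """Sample covariance of concatenated resting data plus Tikhonov loading.

    ``segments`` is one (n_channels, n_times) array or a list of them; they
    are concatenated along time.  C <- C + eps * (tr(C)/N_e) * I.
    """
    if isinstance(segments, np.ndarray):
        segments = [segments]
    data = np.concatenate([np.asarray(s, dtype=float) for s in segments], axis=1)
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite values in noise segments")
    n_ch, n_t = data.shape
    if n_t < n_ch + 1:
        raise ValueError(f"need at least {n_ch + 1} samples, got {n_t}")
    c = np.cov(data, bias=True)  # population normalization (1/n)
    c = c + epsilon * (np.trace(c) / n_ch) * np.eye(n_ch)
    return NoiseCovariance(c, epsilon)


def depth_weights(lead_field: LeadField, gamma: float = 0.5, limit: float = 10.0) -> DepthWeights:
    """w_p = (sum of squared column norms of source p)^(-gamma), capped.

    Deep sources have weak columns and therefore get large weights; weights
    exceeding ``limit * min(w)`` are clipped so max(w)/min(w) <= limit.
    """
    L = lead_field.matrix
    sq = (L**2).reshape(L.shape[0], -1, 3).sum(axis=(0, 2))  # per-point sum over I_p
    if np.any(sq == 0):
        bad = np.flatnonzero(sq == 0)
        raise ValueError(f"all-zero lead-field columns at vertices {bad[:10].tolist()}")
    w = sq ** (-gamma)
    w = np.minimum(w, limit * w.min())
    return DepthWeights(w, gamma, limit)


def _solve_mn(L: np.ndarray, c_n: np.ndarray, prior: np.ndarray, alpha: float) -> np.ndarray:
    """C_s L' (L C_s L' + alpha C_n)^-1 with a symmetric-eig pseudo-inverse."""
    csl = prior[:, None] * L.T  # C_s L'
    inner = L @ csl + alpha * c_n
    vals, vecs = np.linalg.eigh(inner)
    top = vals.max()
    if top <= 0:
        raise np.linalg.LinAlgError("inner matrix not positive; increase alpha")
    keep = vals > _EIG_FLOOR * top
    if not keep.all():
        vals = np.where(keep, vals, np.inf)
    return csl @ ((vecs / vals) @ vecs.T)


def wmne_operator(
    lead_field: LeadField,
    noise_cov: NoiseCovariance,
    weights: DepthWeights | None,
    alpha: float,
) -> InverseOperator:
    """Weighted minimum-norm operator (plain MNE when ``weights`` is None).

    The depth weights act as the source prior covariance: C_s has the three
    diagonal entries w_p for the component triple of source point p, so the
    penalty on s_hat is sum_p |s_p|^2 / w_p.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    n_s = lead_field.n_sources
    prior = np.ones(3 * n_s) if weights is None else np.repeat(weights.values, 3)
    g = _solve_mn(lead_field.matrix, noise_cov.matrix, prior, alpha)
    return InverseOperator(
        g,
        "wmne" if weights is not None else "mne",
        alpha,
        channel_names=lead_field.electrode_names,
        average_reference=lead_field.average_reference,
    )


def mne_operator(lead_field: LeadField, noise_cov: NoiseCovariance, alpha: float) -> InverseOperator:
    """Unweighted minimum-norm operator (the usual sLORETA base)."""
    return wmne_operator(lead_field, noise_cov, None, alpha)


def gcv_alpha(
    lead_field: LeadField,
    data: np.ndarray,
    noise_cov: NoiseCovariance,
    weights: DepthWeights | None = None,
    grid: np.ndarray = DEFAULT_ALPHA_GRID,
    fallback_below: float = 0.01,
    fallback: float = 1.0 / 3.0,
) -> float:
    """Regularization parameter by generalized cross-validation.

    GCV(alpha) = ||(I-H) d~||_F^2 / tr(I-H)^2 on the whitened system
    d~ = C_n^(-1/2) d, H = K K'(K K' + alpha I)^-1, K = C_n^(-1/2) L C_s^(1/2);
    the trace is exact via SVD.  If the grid minimizer is below
    ``fallback_below`` the fixed default ``fallback`` (1/3) is returned.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty alpha grid")
    d = np.atleast_2d(np.asarray(data, dtype=float))
    if d.shape[0] != lead_field.n_electrodes:
        d = d.T
    if not np.any(d):
        raise ValueError("all-zero data; cannot run GCV")
    white = noise_cov.inv_sqrt()
    prior = (
        np.ones(3 * lead_field.n_sources)
        if weights is None
        else np.repeat(weights.values, 3)
    )
    k = white @ (lead_field.matrix * np.sqrt(prior)[None, :])
    dt = white @ d
    u, sv, _ = np.linalg.svd(k, full_matrices=False)
    proj = u.T @ dt
    resid_perp = (dt**2).sum() - (proj**2).sum()  # component outside span(U)
    n_e = k.shape[0]
    lam = sv**2
    scores = np.empty_like(grid)
    for i, a in enumerate(grid):
        shrink = a / (lam + a)  # diagonal of (I - H) within span(U)
        resid = resid_perp + ((shrink[:, None] * proj) ** 2).sum()
        denom = (n_e - len(lam)) + shrink.sum()
        scores[i] = resid / denom**2
    best = float(grid[int(np.argmin(scores))])
    return fallback if best < fallback_below else best


def dspm_operator(base: InverseOperator, noise_cov: NoiseCovariance) -> InverseOperator:
    """Noise-normalize a (w)MNE operator row-wise (dSPM).

    Each source point's three rows are divided by the estimated noise
    standard deviation s_p^(-1) where
    s_p = (sum over the point's rows g of g C_n g')^(-1/2).
    """
    g = base.matrix
    gc = g @ noise_cov.matrix
    var = (gc * g).sum(axis=1).reshape(-1, 3).sum(axis=1)
    if np.any(var <= 0):
        bad = np.flatnonzero(var <= 0)
        raise ValueError(f"zero noise-variance estimate at vertices {bad[:10].tolist()}")
    scale = np.repeat(var ** (-0.5), 3)
    return InverseOperator(
        scale[:, None] * g,
        "dspm",
        base.alpha,
        base=base.method,
        normalization="diagonal",
        channel_names=base.channel_names,
        average_reference=base.average_reference,
    )


def _inv_sqrt_3x3(block: np.ndarray, tol_scale: float) -> np.ndarray:
    sym = 0.5 * (block + block.T)
    vals, vecs = np.linalg.eigh(sym)
    if np.any(vals < _EIG_FLOOR * max(np.trace(sym), tol_scale)):
        raise np.linalg.LinAlgError
    return (vecs / np.sqrt(vals)) @ vecs.T


def sloreta_operator(base: InverseOperator, lead_field: LeadField) -> InverseOperator:
    """Standardize an MNE operator by the resolution-matrix diagonal blocks.

    S_p = (A_[pp])^(-1/2) with A = G L; each 3x3 block is symmetrized and
    inverted through its eigendecomposition.  Mixing happens only within a
    source point's component triple.
    """
    g = base.matrix
    n_s = base.n_sources
    n_e = g.shape[1]
    # diagonal 3x3 blocks of A = G L, one per source point
    blocks = np.einsum(
        "pie,epj->pij",
        g.reshape(n_s, 3, n_e),
        lead_field.matrix.reshape(n_e, n_s, 3),
    )
    out = np.empty_like(g)
    scale = float(np.abs(np.trace(blocks, axis1=1, axis2=2)).mean())
    for p in range(n_s):
        block = blocks[p]
        try:
            s = _inv_sqrt_3x3(block, scale)
        except np.linalg.LinAlgError:
            raise ValueError(f"non-positive resolution block at vertex {p}") from None
        out[3 * p : 3 * p + 3] = s @ g[3 * p : 3 * p + 3]
    return InverseOperator(
        out,
        "sloreta",
        base.alpha,
        base=base.method,
        normalization="block",
        channel_names=base.channel_names,
        average_reference=base.average_reference,
    )


def resolution_matrix(op: InverseOperator, lead_field: LeadField) -> np.ndarray:
    """A = G L: maps true source components to estimated ones."""
    return op.matrix @ lead_field.matrix


def apply_inverse(op: InverseOperator, data: np.ndarray) -> SourceEstimate:
    """s_hat = G d per time sample; returns components and amplitude norms.

    ``data`` is (n_channels, n_times) or (n_channels,).  If the operator was
    built from an average-referenced lead field, the average reference is
    applied to the data first.
    """
    d = np.asarray(data, dtype=float)
    if d.ndim == 1:
        d = d[:, None]
    if d.shape[0] != op.n_channels:
        raise ValueError(
            f"channel mismatch: operator expects {op.n_channels} channels, "
            f"data has {d.shape[0]}"
        )
    if op.average_reference:
        d = d - d.mean(axis=0, keepdims=True)
    s = op.matrix @ d
    return SourceEstimate(s.reshape(op.n_sources, 3, -1))


class InverseSolver(BaseEstimator, TransformerMixin):
    """scikit-learn style wrapper around one source localization method.

    Parameters
    ----------
    lead_field : LeadField
    method : {"wmne", "dspm", "sloreta", "mne"}
        wMNE and dSPM use the depth-weighted prior; sLORETA standardizes the
        unweighted MNE operator.
    alpha : float or "gcv"
        Fixed regularization parameter, or GCV selection on the data passed
        to :meth:`fit` as ``gcv_data``.
    epsilon, gamma, depth_limit : noise-covariance loading fraction and
        depth-weighting order/cap.

    ``fit(X)`` expects resting-state noise samples with shape
    (n_samples, n_channels); ``transform(X)`` maps sensor samples of the same
    shape to flattened source components (n_samples, 3*N_s).
    """

    def __init__(
        self,
        lead_field: LeadField,
        method: str = "wmne",
        alpha: float | str = "gcv",
        epsilon: float = 0.1,
        gamma: float = 0.5,
        depth_limit: float = 10.0,
        alpha_grid: np.ndarray = DEFAULT_ALPHA_GRID,
    ) -> None:
        self.lead_field = lead_field
        self.method = method
        self.alpha = alpha
        self.epsilon = epsilon
        self.gamma = gamma
        self.depth_limit = depth_limit
        self.alpha_grid = alpha_grid

    def fit(self, X: np.ndarray, y=None, gcv_data: np.ndarray | None = None) -> "InverseSolver":
        if self.method not in ("wmne", "dspm", "sloreta", "mne"):
            raise ValueError(f"unknown method {self.method!r}")
        noise = np.asarray(X, dtype=float).T  # (channels, samples)
        self.noise_cov_ = estimate_noise_covariance(noise, self.epsilon)
        weighted = self.method in ("wmne", "dspm")
        self.weights_ = (
            depth_weights(self.lead_field, self.gamma, self.depth_limit) if weighted else None
        )
        if self.alpha == "gcv":
            if gcv_data is None:
                raise ValueError("alpha='gcv' requires gcv_data")
            self.alpha_ = gcv_alpha(
                self.lead_field,
                np.asarray(gcv_data, dtype=float).T,
                self.noise_cov_,
                self.weights_,
                np.asarray(self.alpha_grid, dtype=float),
            )
        else:
            self.alpha_ = float(self.alpha)
        base = wmne_operator(self.lead_field, self.noise_cov_, self.weights_, self.alpha_)
        if self.method == "dspm":
            self.operator_ = dspm_operator(base, self.noise_cov_)
        elif self.method == "sloreta":
            self.operator_ = sloreta_operator(base, self.lead_field)
        else:
            self.operator_ = base
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        est = apply_inverse(self.operator_, np.asarray(X, dtype=float).T)
        n = est.components.shape[2]
        return est.components.reshape(-1, n).T

    def estimate(self, data: np.ndarray) -> SourceEstimate:
        """Apply the fitted operator to (n_channels, n_times) data."""
        return apply_inverse(self.operator_, data)
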