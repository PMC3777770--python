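"""Parametric tissue segmentation: EM with a hidden Markov random field.

Model.  In-brain voxel intensities y_i (channel vector, lesions already
removed) follow per-class multivariate Gaussians N(mu_k, Sigma_k); the label
field carries a Potts prior over the 6-neighbourhood with coupling beta and
an external field given by the class proportions pi_k.  The per-voxel,
per-class energy is

    U_ik = -log pi_k + 1/2 log|Sigma_k| + 1/2 (y_i - mu_k)' Sigma_k^-1 (y_i - mu_k)
           + beta * #{6-neighbours j in mask : x_j != k}

MAP labels are found by ICM; EM alternates ICM, posterior computation with
the MRF prior frozen at the current labels' neighbour counts, posterior-
weighted M-step updates of (pi, mu, Sigma), and an optional multiplicative
bias-field update (log-domain polynomial fit of the intensity residuals).
With beta = 0 and bias off the procedure reduces exactly to a plain
Gaussian-mixture EM (the -log pi external field makes the reduction exact).

ICM is run as checkerboard (red-black) sweeps: under the 6-neighbourhood the
two parities do not interact, so each half-sweep is exact coordinate descent
and the total energy never increases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .core import CSF, GM, WM, BinaryMask, LabelMap, MultichannelVolume

__all__ = [
    "GaussianClassParams", "HMRFConfig", "BiasField", "EMResult",
    "initialize_from_seeds", "icm_update", "em_hmrf_segment",
    "segment_cerebellum", "total_energy",
]

log = logging.getLogger(__name__)

_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


@dataclass
class GaussianClassParams:
    classes: np.ndarray          # label codes, ascending
    means: np.ndarray            # (K, C)
    covs: np.ndarray             # (K, C, C)
    priors: np.ndarray           # (K,), sums to 1

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        self.means = np.asarray(self.means, dtype=float)
        self.covs = np.asarray(self.covs, dtype=float)
        self.priors = np.asarray(self.priors, dtype=float)
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("class priors must sum to 1")
        for k, cov in enumerate(self.covs):
            if not np.allclose(cov, cov.T):
                raise ValueError(f"covariance of class {self.classes[k]} not symmetric")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ValueError(f"covariance of class {self.classes[k]} not PD")


@dataclass
class HMRFConfig:
    beta: float = 0.5
    em_max_iter: int = 20
    icm_max_iter: int = 5
    tol: float = 1e-4
    bias_order: int | None = 3    # None disables bias estimation
    seed: int = 0                 # reserved for stochastic options; ICM is deterministic

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.em_max_iter < 1 or self.icm_max_iter < 1:
            raise ValueError("iteration counts must be >= 1")


@dataclass
class BiasField:
    """Per-channel multiplicative field exp(polynomial in normalized coords)."""
    order: int
    log_coeffs: Dict[str, np.ndarray]
    fields: Dict[str, np.ndarray]        # full-grid fields, 1 outside the mask


@dataclass
class EMResult:
    labels: LabelMap
    params: GaussianClassParams
    bias: BiasField | None
    posteriors: np.ndarray               # (N_mask, K)
    mask: BinaryMask
    converged: bool
    n_iter: int
    ll_history: List[float]
    flags: List[str] = field(default_factory=list)


def _regularize(cov: np.ndarray, eps_scale: float = 1e-6) -> np.ndarray:
    eps = eps_scale * max(np.trace(cov) / cov.shape[0], 1e-12)
    if np.linalg.eigvalsh(cov).min() < eps:
        cov = cov + eps * np.eye(cov.shape[0])
    return cov


def initialize_from_seeds(volume: MultichannelVolume, seeds: LabelMap,
                          classes: Sequence[int],
                          channels: Sequence[str] = ("t1", "t2"),
                          ) -> GaussianClassParams:
    """Sample mean/covariance/fraction of the seed voxels of each class."""
    y = volume.stack(channels)
    C = y.shape[-1]
    means, covs, counts = [], [], []
    for k in classes:
        pts = y[seeds.labels == k]
        if len(pts) < C + 1:
            raise ValueError(f"class {k}: {len(pts)} seed voxels, need >= {C + 1}")
        means.append(pts.mean(axis=0))
        covs.append(_regularize(np.atleast_2d(np.cov(pts, rowvar=False))))
        counts.append(len(pts))
    counts = np.asarray(counts, dtype=float)
    return GaussianClassParams(np.asarray(list(classes)), np.asarray(means),
                               np.asarray(covs), counts / counts.sum())


def _unary_energies(y: np.ndarray, params: GaussianClassParams) -> np.ndarray:
    """(N, K) array of -log pi + 1/2 log|Sigma| + 1/2 Mahalanobis^2."""
    N = y.shape[0]
    K = len(params.classes)
    U = np.empty((N, K))
    for k in range(K):
        cov = params.covs[k]
        L = np.linalg.cholesky(cov)
        z = np.linalg.solve(L, (y - params.means[k]).T)
        maha = (z ** 2).sum(axis=0)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        U[:, k] = 0.5 * maha + 0.5 * logdet - np.log(max(params.priors[k], 1e-300))
    return U


def _neighbor_same_counts(lab_idx: np.ndarray, inmask: np.ndarray, K: int) -> np.ndarray:
    """For each class k, count in-mask 6-neighbours currently labelled k."""
    same = np.zeros((K,) + lab_idx.shape, dtype=np.int16)
    for k in range(K):
        onehot = ((lab_idx == k) & inmask).astype(np.int16)
        for off in _OFFSETS:
            shifted = np.zeros_like(onehot)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            for a, o in enumerate(off):
                if o == 1:
                    src[a], dst[a] = slice(1, None), slice(0, -1)
                elif o == -1:
                    src[a], dst[a] = slice(0, -1), slice(1, None)
            shifted[tuple(dst)] = onehot[tuple(src)]
            same[k] += shifted
    return same


def _neighbor_counts(inmask: np.ndarray) -> np.ndarray:
    return _neighbor_same_counts(np.zeros(inmask.shape, dtype=np.int8), inmask, 1)[0]


def total_energy(lab_idx: np.ndarray, inmask: np.ndarray, U_grid: np.ndarray,
                 beta: float) -> float:
    """Potts + unary energy; each differing neighbour pair counted once."""
    e = float(U_grid[inmask, lab_idx[inmask]].sum())
    pairs = 0
    for a in range(3):
        hi = [slice(None)] * 3
        lo = [slice(None)] * 3
        hi[a], lo[a] = slice(1, None), slice(0, -1)
        both = inmask[tuple(hi)] & inmask[tuple(lo)]
        pairs += int((both & (lab_idx[tuple(hi)] != lab_idx[tuple(lo)])).sum())
    return e + beta * pairs


def icm_update(lab_idx: np.ndarray, inmask: np.ndarray, U_grid: np.ndarray,
               beta: float, max_sweeps: int = 5) -> np.ndarray:
    """Checkerboard ICM sweeps; stops when a full sweep changes nothing."""
    K = U_grid.shape[-1]
    idx = np.indices(lab_idx.shape).sum(axis=0)
    parities = [(idx % 2 == 0) & inmask, (idx % 2 == 1) & inmask]
    lab = lab_idx.copy()
    nnb = _neighbor_counts(inmask)
    for _ in range(max_sweeps):
        changed = 0
        for par in parities:
            same = _neighbor_same_counts(lab, inmask, K)
            E = U_grid.copy()
            for k in range(K):
                E[..., k] += beta * (nnb - same[k])
            new = np.argmin(E[par], axis=-1)
            changed += int((new != lab[par]).sum())
            lab[par] = new
        if changed == 0:
            break
    return lab


def _poly_design(shape: Tuple[int, int, int], inmask: np.ndarray, order: int) -> np.ndarray:
    idx = np.indices(shape, dtype=np.float64)
    u = [2.0 * idx[a][inmask] / max(shape[a] - 1, 1) - 1.0 for a in range(3)]
    cols = [np.ones(inmask.sum())]
    for deg in range(1, order + 1):
        for combo in combinations_with_replacement(range(3), deg):
            col = np.ones_like(cols[0])
            for a in combo:
                col = col * u[a]
            cols.append(col)
    return np.stack(cols, axis=1)


def _fit_bias(y_raw: np.ndarray, labels_k: np.ndarray, params: GaussianClassParams,
              design: np.ndarray, channels: Sequence[str],
              ) -> tuple[Dict[str, np.ndarray], np.ndarray]:
    """Least-squares log-domain polynomial fit of per-channel residuals.

    Voxels whose intensity or class mean sits near zero carry no usable
    ratio information (log residuals explode), so the fit uses only voxels
    where both exceed a small fraction of the channel's intensity scale; the
    smooth polynomial extrapolates the field everywhere else.  The fitted
    log-field is zero-mean over the mask and capped at |log 3|.
    """
    coeffs: Dict[str, np.ndarray] = {}
    logb = np.zeros_like(y_raw)
    for c, ch in enumerate(channels):
        mu_c = params.means[labels_k, c]
        floor = 0.05 * max(float(np.abs(params.means[:, c]).max()), 1e-12)
        valid = (y_raw[:, c] > floor) & (mu_c > floor)
        if valid.sum() < design.shape[1] * 3:
            coeffs[ch] = np.zeros(design.shape[1])
            logb[:, c] = 0.0
            continue
        resid = np.log(y_raw[valid, c]) - np.log(mu_c[valid])
        coef, *_ = np.linalg.lstsq(design[valid], resid, rcond=None)
        fit = design @ coef
        fit -= fit.mean()                       # mean log-field 0 over the mask
        fit = np.clip(fit, -np.log(3.0), np.log(3.0))
        coeffs[ch] = coef
        logb[:, c] = fit
    return coeffs, logb


def _m_step(y: np.ndarray, post: np.ndarray, params: GaussianClassParams,
            init: GaussianClassParams, flags: List[str]) -> GaussianClassParams:
    K, C = params.means.shape
    nk = post.sum(axis=0)
    means = params.means.copy()
    covs = params.covs.copy()
    priors = nk / nk.sum()
    for k in range(K):
        if nk[k] < max(C + 1, 1e-6 * len(y)):
            # collapsed class: freeze at initialization
            means[k] = init.means[k]
            covs[k] = init.covs[k]
            priors[k] = max(priors[k], 1e-12)
            msg = f"class {params.classes[k]} collapsed; parameters frozen"
            if msg not in flags:
                flags.append(msg)
            continue
        w = post[:, k]
        mu = (w[:, None] * y).sum(axis=0) / nk[k]
        d = y - mu
        cov = (w[:, None, None] * (d[:, :, None] * d[:, None, :])).sum(axis=0) / nk[k]
        means[k] = mu
        covs[k] = _regularize(cov)
    priors = priors / priors.sum()
    return GaussianClassParams(params.classes, means, covs, priors)


def em_hmrf_segment(volume: MultichannelVolume, mask: BinaryMask, seeds: LabelMap,
                    config: HMRFConfig | None = None,
                    channels: Sequence[str] = ("t1", "t2"),
                    classes: Sequence[int] = (CSF, GM, WM),
                    ) -> EMResult:
    """EM-HMRF segmentation of the in-mask voxels into ``classes``.

    ``seeds`` initialize the Gaussian parameters; unseeded voxels start at
    their maximum-likelihood class.  Returns MAP labels, the fitted class
    parameters, the estimated bias field (if enabled) and the final
    posteriors (rows follow ``np.argwhere(mask.mask)`` order).
    """
    config = config or HMRFConfig()
    classes = np.asarray(sorted(classes))
    inmask = mask.mask
    if not inmask.any():
        raise ValueError("empty mask")
    y_raw = volume.stack(channels)[inmask]

    init = initialize_from_seeds(volume, seeds, classes, channels)
    params = init
    flags: List[str] = []

    design = (_poly_design(volume.shape, inmask, config.bias_order)
              if config.bias_order is not None else None)
    logb = np.zeros_like(y_raw)

    # initial label indices: seeds where given, ML elsewhere
    code_to_k = {int(c): k for k, c in enumerate(classes)}
    lab_idx = np.zeros(volume.shape, dtype=np.int8)
    y_corr = y_raw * np.exp(-logb)
    U = _unary_energies(y_corr, params)
    ml = np.argmin(U, axis=1).astype(np.int8)
    lab_idx[inmask] = ml
    seed_flat = seeds.labels[inmask]
    for code, k in code_to_k.items():
        sel = seed_flat == code
        lab_flat = lab_idx[inmask]
        lab_flat[sel] = k
        lab_idx[inmask] = lab_flat

    nnb = _neighbor_counts(inmask)
    ll_hist: List[float] = []
    post = None
    converged = False
    it = 0
    for it in range(1, config.em_max_iter + 1):
        y_corr = y_raw * np.exp(-logb)
        U = _unary_energies(y_corr, params)
        U_grid = np.full(volume.shape + (len(classes),), 0.0)
        U_grid[inmask] = U

        lab_idx = icm_update(lab_idx, inmask, U_grid, config.beta,
                             max_sweeps=config.icm_max_iter)

        # posteriors with the MRF prior frozen at current neighbour counts
        same = _neighbor_same_counts(lab_idx, inmask, len(classes))
        E = U.copy()
        for k in range(len(classes)):
            E[:, k] += config.beta * (nnb[inmask] - same[k][inmask])
        m = E.min(axis=1, keepdims=True)
        P = np.exp(-(E - m))
        Z = P.sum(axis=1, keepdims=True)
        post = P / Z
        ll = float((np.log(Z) - m).sum())
        ll_hist.append(ll)

        params = _m_step(y_corr, post, params, init, flags)

        if design is not None:
            _, logb = _fit_bias(y_raw, lab_idx[inmask], params, design, channels)

        if len(ll_hist) >= 2:
            denom = max(abs(ll_hist[-2]), 1e-12)
            if abs(ll_hist[-1] - ll_hist[-2]) / denom < config.tol:
                converged = True
                break
        log.info("EM iter %d: pseudo-LL %.4f", it, ll)

    if not converged:
        flags.append(f"EM did not converge in {config.em_max_iter} iterations")

    # final MAP labels with the final parameters
    y_corr = y_raw * np.exp(-logb)
    U = _unary_energies(y_corr, params)
    U_grid = np.full(volume.shape + (len(classes),), 0.0)
    U_grid[inmask] = U
    lab_idx = icm_update(lab_idx, inmask, U_grid, config.beta,
                         max_sweeps=config.icm_max_iter)

    labels = np.zeros(volume.shape, dtype=np.int32)
    labels[inmask] = classes[lab_idx[inmask]]

    bias = None
    if design is not None:
        fields = {}
        for c, ch in enumerate(channels):
            f = np.ones(volume.shape)
            f[inmask] = np.exp(logb[:, c])
            fields[ch] = f
        coeffs, _ = _fit_bias(y_raw, lab_idx[inmask], params, design, channels)
        bias = BiasField(config.bias_order, coeffs, fields)

    return EMResult(LabelMap(labels, volume.spacing), params, bias, post,
                    mask, converged, it, ll_hist, flags)


def segment_cerebellum(volume: MultichannelVolume, cerebellum_mask: BinaryMask,
                       seeds: LabelMap, config: HMRFConfig | None = None,
                       channels: Sequence[str] = ("t1", "t2")) -> EMResult:
    """Two-class (GM/WM) EM-HMRF restricted to the cerebellum mask.

    The cerebellum gets its own parameter estimates because its GM/WM
    intensity profiles differ from the rest of the brain.
    """
    if not cerebellum_mask.mask.any():
        raise ValueError("empty cerebellum mask")
    restricted = LabelMap(np.where(cerebellum_mask.mask, seeds.labels, 0),
                          seeds.spacing)
    return em_hmrf_segment(volume, cerebellum_mask, restricted, config,
                           channels=channels, classes=(GM, WM))
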