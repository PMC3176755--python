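"""Probe-level to probeset-level expression: RMA and a model-based index.

RMA = per-array convolution background correction (observed = exponential
signal + Gaussian optical background), quantile normalization across
arrays, log2 transform, then per-probeset median polish; the reported
expression is overall + array effect.

The model-based expression index (MBEI) fits the multiplicative model
PM_ja ≈ φ_j·θ_a per probeset by alternating least squares under the
identifiability constraint Σφ_j² = J, down-weights outlier probes once, and
reports log2 θ_a. It operates on quantile-normalized linear-scale
intensities (no background subtraction), matching a PM-only fit.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import stats

from .annotate import ProbesetAnnotation
from .containers import ExpressionMatrix, IntensityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "estimate_background_params",
    "normexp_signal",
    "background_correct",
    "quantile_normalize",
    "median_polish",
    "median_polish_blocks",
    "rma",
    "mbei",
]


def estimate_background_params(x: np.ndarray) -> tuple[float, float, float]:
    """(mu, sigma, alpha) of the Normal+Exponential convolution for one array.

    mu: kernel-density maximizer over the lower half of the data (background
    mode); sigma: RMS deviation of points below the mode; alpha: reciprocal
    mean exceedance above the mode. A documented heuristic — the parameters
    are injectable wherever they matter.
    """
    x = np.asarray(x, dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate array: constant intensities")
    lower = np.sort(x)[: max(2, x.size // 2)]
    kde = stats.gaussian_kde(lower)
    grid = np.linspace(lower.min(), lower.max(), 512)
    mu = float(grid[np.argmax(kde(grid))])
    below = x[x < mu]
    if below.size < 2:
        below = x[x <= np.quantile(x, 0.25)]
    sigma = float(np.sqrt(np.mean((below - mu) ** 2)))
    above = x[x > mu]
    mean_exceed = float(np.mean(above - mu)) if above.size else 1.0
    alpha = 1.0 / max(mean_exceed, 1e-12)
    return mu, max(sigma, 1e-12), alpha


def normexp_signal(x: np.ndarray, mu: float, sigma: float, alpha: float) -> np.ndarray:
    """E[S | O = x] under O = S + B, S ~ Exp(alpha) on [0, ∞), B ~ N(mu, sigma²).

    Conditionally, S | O=x ~ N(a, sigma²) truncated to s ≥ 0 with
    a = x − mu − sigma²·alpha, whose mean is a + sigma·φ(a/σ)/Φ(a/σ).
    Computed in log space for numerical stability far in the left tail.
    """
    x = np.asarray(x, dtype=float)
    a = x - mu - sigma * sigma * alpha
    z = a / sigma
    # phi(z)/Phi(z) via logs; for z << 0 this is the inverse Mills ratio
    log_ratio = stats.norm.logpdf(z) - stats.norm.logcdf(z)
    out = a + sigma * np.exp(log_ratio)
    return np.maximum(out, np.finfo(float).tiny)


def background_correct(
    matrix: IntensityMatrix,
    params: dict[str, tuple[float, float, float]] | None = None,
) -> IntensityMatrix:
    """Per-array convolution background correction; strictly positive,
    strictly increasing in the input. ``params`` may inject per-array
    (mu, sigma, alpha) tuples, bypassing estimation."""
    corrected = np.empty_like(matrix.values)
    for a, aid in enumerate(matrix.array_ids):
        col = matrix.values[:, a]
        if params is not None and aid in params:
            mu, sigma, alpha = params[aid]
        else:
            mu, sigma, alpha = estimate_background_params(col)
            logger.info("array %s: mu=%.3f sigma=%.3f alpha=%.4f", aid, mu, sigma, alpha)
        corrected[:, a] = normexp_signal(col, mu, sigma, alpha)
    return IntensityMatrix(
        values=corrected,
        probe_ids=list(matrix.probe_ids),
        array_ids=list(matrix.array_ids),
        array_meta=dict(matrix.array_meta),
    )


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Force every column to the across-column mean of sorted values.

    Ties within a column receive the mean of the reference values at the
    tied ranks. Idempotent; a single column passes through unchanged.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    n, m = values.shape
    if m == 1:
        return values.copy()
    order = np.argsort(values, axis=0, kind="stable")
    ref = np.mean(np.take_along_axis(values, order, axis=0), axis=1)
    out = np.empty_like(values)
    for j in range(m):
        col = values[:, j]
        normed = np.empty(n)
        normed[order[:, j]] = ref
        # average reference values over tied input ranks
        _, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        if np.any(counts > 1):
            sums = np.bincount(inv, weights=normed)
            normed = (sums / counts)[inv]
        out[:, j] = normed
    return out


def median_polish(
    block: np.ndarray, tol: float = 0.01, max_iter: int = 10
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish of one probes × arrays block (log2 scale).

    Alternating row/column median sweeps, rows first, until the largest
    absolute sweep median drops below ``tol`` or ``max_iter`` full passes.
    Returns ``(overall, probe_effects, array_effects, residuals)``; the
    probeset expression per array is ``overall + array_effects``.
    """
    block = np.asarray(block, dtype=float)
    if not np.all(np.isfinite(block)):
        raise ValueError("median polish requires finite input")
    if block.ndim != 2 or block.size == 0:
        raise ValueError("expected a non-empty 2-D block")
    resid = block.copy()
    overall = 0.0
    row_eff = np.zeros(block.shape[0])
    col_eff = np.zeros(block.shape[1])
    for _ in range(max_iter):
        rmed = np.median(resid, axis=1)
        resid -= rmed[:, None]
        row_eff += rmed
        cmed_of_rows = np.median(row_eff)
        row_eff -= cmed_of_rows
        overall += cmed_of_rows

        cmed = np.median(resid, axis=0)
        resid -= cmed[None, :]
        col_eff += cmed
        rmed_of_cols = np.median(col_eff)
        col_eff -= rmed_of_cols
        overall += rmed_of_cols

        if max(np.abs(rmed).max(), np.abs(cmed).max()) < tol:
            break
    return overall, row_eff, col_eff, resid


def median_polish_blocks(
    blocks: np.ndarray, tol: float = 0.01, max_iter: int = 10
) -> np.ndarray:
    """Vectorized median polish over a stack of equally sized blocks.

    ``blocks`` has shape (n_sets, probes, arrays); returns the per-set
    expression (overall + array effect) of shape (n_sets, arrays). Same
    sweep schedule as :func:`median_polish`, run in lockstep across sets.
    """
    resid = np.asarray(blocks, dtype=float).copy()
    if resid.ndim != 3:
        raise ValueError("expected (n_sets, probes, arrays)")
    n_sets = resid.shape[0]
    overall = np.zeros(n_sets)
    row_eff = np.zeros(resid.shape[:2])
    col_eff = np.zeros((n_sets, resid.shape[2]))
    active = np.ones(n_sets, dtype=bool)  # converged blocks stop sweeping
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        rmed = np.median(resid[idx], axis=2)
        resid[idx] -= rmed[:, :, None]
        row_eff[idx] += rmed
        shift = np.median(row_eff[idx], axis=1)
        row_eff[idx] -= shift[:, None]
        overall[idx] += shift

        cmed = np.median(resid[idx], axis=1)
        resid[idx] -= cmed[:, None, :]
        col_eff[idx] += cmed
        shift = np.median(col_eff[idx], axis=1)
        col_eff[idx] -= shift[:, None]
        overall[idx] += shift

        sweep_max = np.maximum(np.abs(rmed).max(axis=1), np.abs(cmed).max(axis=1))
        active[idx] = sweep_max >= tol
    return overall[:, None] + col_eff


def _preprocessed_log2(matrix: IntensityMatrix, params=None) -> np.ndarray:
    bc = background_correct(matrix, params=params)
    return np.log2(quantile_normalize(bc.values))


def rma(
    matrix: IntensityMatrix,
    annotation: ProbesetAnnotation,
    background_params: dict | None = None,
    tol: float = 0.01,
    max_iter: int = 10,
) -> ExpressionMatrix:
    """Full RMA: background correct → quantile normalize → log2 → median polish."""
    missing = sorted(annotation.used_probes - set(matrix.probe_ids))
    if missing:
        raise ValueError(f"annotation references probes absent from matrix: {missing[:10]}")
    log2 = _preprocessed_log2(matrix, params=background_params)
    index = {p: i for i, p in enumerate(matrix.probe_ids)}
    probesets = sorted(annotation.probeset_to_probes)
    values = np.empty((len(probesets), len(matrix.array_ids)))
    for i, ps in enumerate(probesets):
        rows = [index[p] for p in sorted(annotation.probeset_to_probes[ps])]
        overall, _pe, col_eff, _res = median_polish(log2[rows, :], tol=tol, max_iter=max_iter)
        values[i, :] = overall + col_eff
    return ExpressionMatrix(
        values=values,
        probeset_ids=probesets,
        array_ids=list(matrix.array_ids),
        method="rma",
        array_meta=dict(matrix.array_meta),
    )


def _fit_mbei_block(
    block: np.ndarray, max_iter: int = 200, tol: float = 1e-10
) -> np.ndarray:
    """Alternating LS for PM_ja ≈ φ_j θ_a with Σφ² = J; one outlier pass."""
    J, A = block.shape
    weights = np.ones((J, 1))

    def fit(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        phi = np.sqrt(np.maximum(block.mean(axis=1), 1e-12))
        phi *= np.sqrt(J / np.sum(phi**2))
        theta = np.zeros(A)
        for _ in range(max_iter):
            theta_new = (w * phi[:, None] * block).sum(axis=0) / np.maximum(
                (w * phi[:, None] ** 2).sum(), 1e-300
            )
            phi_new = (w * theta_new[None, :] * block).sum(axis=1) / np.maximum(
                (w[:, 0] * (theta_new**2).sum()), 1e-300
            )
            norm = np.sqrt(np.sum(phi_new**2) / J)
            if norm <= 0:
                break
            phi_new /= norm
            theta_new *= norm
            scale = max(np.max(np.abs(theta_new)), 1.0)
            if (
                np.max(np.abs(phi_new - phi)) < tol
                and np.max(np.abs(theta_new - theta)) / scale < tol
            ):
                phi, theta = phi_new, theta_new
                return phi, theta
            phi, theta = phi_new, theta_new
        warnings.warn("MBEI alternating fit did not converge; returning last iterate")
        return phi, theta

    phi, theta = fit(weights)
    if J > 1:
        resid = block - phi[:, None] * theta[None, :]
        s = resid.std()
        if s > 0:
            out_rows = np.any(np.abs(resid) / s > 3, axis=1)
            if out_rows.any() and not out_rows.all():
                weights = np.where(out_rows[:, None], 0.01, 1.0)
                phi, theta = fit(weights)
    return np.maximum(theta, np.finfo(float).tiny)


def mbei(
    matrix: IntensityMatrix,
    annotation: ProbesetAnnotation,
    max_iter: int = 100,
) -> ExpressionMatrix:
    """Model-based expression index on quantile-normalized intensities."""
    if len(matrix.array_ids) < 2:
        raise ValueError("MBEI needs at least two arrays")
    missing = sorted(annotation.used_probes - set(matrix.probe_ids))
    if missing:
        raise ValueError(f"annotation references probes absent from matrix: {missing[:10]}")
    normed = quantile_normalize(matrix.values)
    index = {p: i for i, p in enumerate(matrix.probe_ids)}
    probesets = sorted(annotation.probeset_to_probes)
    values = np.empty((len(probesets), len(matrix.array_ids)))
    for i, ps in enumerate(probesets):
        rows = [index[p] for p in sorted(annotation.probeset_to_probes[ps])]
        theta = _fit_mbei_block(normed[rows, :], max_iter=max_iter)
        values[i, :] = np.log2(theta)
    return ExpressionMatrix(
        values=values,
        probeset_ids=probesets,
        array_ids=list(matrix.array_ids),
        method="mbei",
        array_meta=dict(matrix.array_meta),
    )
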