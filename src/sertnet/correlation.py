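"""Rank-based (partial) correlation and the Fisher transformation.

Partial Spearman correlation is computed by the residualization convention:
rank-transform the two variables and every covariate (average ranks for
ties), residualize the ranks of each variable on an intercept plus the
covariate ranks by least squares, and return the Pearson correlation of the
two residual vectors. For one covariate without ties this coincides with the
classical recursion rho_xy.c = (rho_xy - rho_xc rho_yc) /
sqrt((1-rho_xc^2)(1-rho_yc^2)); with several covariates it is the usual
"nonparametric partial correlation" and handles a binary covariate such as
gender cleanly (two tied groups of ranks, equivalent to 0/1 dummy coding).

Correlation-matrix construction has a batched fast path used by the
permutation engine: all regions are ranked at once and residualized with a
single projection, so thousands of permuted matrices cost a few matrix
products.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats

from .errors import SertnetError, UndefinedCorrelationError
from .types import CohortTable, CorrelationMatrix

#: |rho| is clamped to this before arctanh so Fisher z stays finite. The
#: clamp only guards against infinities: inference comes from the
#: permutation null, never from the analytic variance of z, and at n <= 38
#: attainable rho resolution is orders of magnitude coarser than 1e-7.
FISHER_CLAMP = 1e-7


def rank_transform(x: np.ndarray) -> np.ndarray:
    """Ascending ranks 1..n, ties receiving the average of the ranks spanned.

    The rank sum is n(n+1)/2 regardless of ties.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise SertnetError("rank_transform requires a 1-D vector of length >= 2")
    if not np.all(np.isfinite(x)):
        raise SertnetError("rank_transform requires finite values")
    return stats.rankdata(x, method="average")


def _residualize(ranks: np.ndarray, cov_ranks: np.ndarray) -> np.ndarray:
    """Residuals of each column of ``ranks`` on [1, cov_ranks] by least squares."""
    n = ranks.shape[0]
    design = np.column_stack([np.ones(n), cov_ranks])
    coef, *_ = np.linalg.lstsq(design, ranks, rcond=None)
    return ranks - design @ coef


def partial_spearman(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> float:
    """Partial Spearman rank correlation of x and y given covariate columns.

    With no covariates this equals classical Spearman rho (Pearson
    correlation of average-tie ranks). The result is clipped to [-1, 1]
    against floating-point overshoot.

    Raises
    ------
    UndefinedCorrelationError
        If x or y is constant after ranking, or n < m + 4 where m is the
        number of covariate columns.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise SertnetError("x and y must be 1-D vectors of equal length")
    n = x.size
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise SertnetError("covariate rows must match x length")
    m = cov.shape[1]
    if n < m + 4:
        raise UndefinedCorrelationError(
            f"n={n} too small for {m} covariates (need n >= {m + 4})"
        )
    rx = rank_transform(x)
    ry = rank_transform(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedCorrelationError("constant input after ranking")
    if m:
        cov_ranks = np.column_stack([rank_transform(c) for c in cov.T])
        rx, ry = _residualize(np.column_stack([rx, ry]), cov_ranks).T
        if np.linalg.norm(rx) < 1e-12 * n or np.linalg.norm(ry) < 1e-12 * n:
            raise UndefinedCorrelationError(
                "zero residual variance after covariate adjustment"
            )
    else:
        rx = rx - rx.mean()
        ry = ry - ry.mean()
    r = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    return float(np.clip(r, -1.0, 1.0))


def correlation_matrix(
    cohort: CohortTable,
    covariate_names: Sequence[str] = (),
) -> CorrelationMatrix:
    """Partial-Spearman matrix over all region pairs of one cohort.

    Entry (i, j) is ``partial_spearman`` of regions i and j given the named
    covariates; each unordered pair is computed once, the diagonal is 1.
    """
    cohort.require_min_n(len(covariate_names))
    k = len(cohort.region_set)
    cov = cohort.covariate_matrix(covariate_names)
    bp = cohort.bp_matrix
    rho = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            try:
                r = partial_spearman(bp[:, i], bp[:, j], cov if cov.size else None)
            except UndefinedCorrelationError as exc:
                names = cohort.region_set.names
                raise UndefinedCorrelationError(
                    f"pair ({names[i]}, {names[j]}): {exc}"
                ) from exc
            rho[i, j] = rho[j, i] = r
    return CorrelationMatrix(
        region_set=cohort.region_set,
        rho=rho,
        n=cohort.n,
        covariate_names=tuple(covariate_names),
    )


def fisher_z(rho: np.ndarray | float) -> np.ndarray | float:
    """Fisher r-to-z transform, arctanh(rho), kept finite by clamping |rho|.

    Odd and strictly increasing; |rho| is clamped to 1 - 1e-7 so endpoints
    map to about +-8.4 instead of infinity. Values outside [-1, 1] beyond
    numerical tolerance are a domain error.
    """
    arr = np.asarray(rho, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = np.abs(arr) > 1.0 + 1e-12
    if np.any(bad & np.isfinite(arr)):
        raise SertnetError(f"correlation outside [-1, 1]: {arr[bad]}")
    clipped = np.clip(arr, -(1.0 - FISHER_CLAMP), 1.0 - FISHER_CLAMP)
    out = np.arctanh(clipped)
    out = np.where(np.isnan(arr), np.nan, out)
    if np.isscalar(rho) or np.ndim(rho) == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# batched fast path


def rank_columns(data: np.ndarray) -> np.ndarray:
    """Average-tie ranks along axis -2 (within each column of each slice)."""
    return stats.rankdata(data, method="average", axis=-2)


def batch_partial_spearman_matrices(
    bp: np.ndarray,
    cov: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Partial-Spearman matrices for a stack of cohorts at once.

    Parameters
    ----------
    bp : (..., n, k) array
        Stack of subjects-by-regions matrices.
    cov : (n, m) or (..., n, m) array or None
        Covariates; a 2-D array is shared across the stack (paired designs,
        where relabelling never changes the covariate rows).

    Returns
    -------
    rho : (..., k, k) array
        Correlation matrices; unit diagonal.
    degenerate : (...,) boolean array
        True where any region had zero (residual) rank variance; those
        slices contain NaN off-diagonals and must be discarded by the caller.
    """
    bp = np.asarray(bp, dtype=float)
    n = bp.shape[-2]
    ranks = rank_columns(bp)
    if cov is not None and cov.size:
        cov = np.asarray(cov, dtype=float)
        cov_ranks = rank_columns(cov)
        ones = np.broadcast_to(
            np.ones(n)[:, None], cov_ranks.shape[:-1] + (1,)
        )
        design = np.concatenate([ones, cov_ranks], axis=-1)
        q, _ = np.linalg.qr(design)
        resid = ranks - q @ (np.swapaxes(q, -1, -2) @ ranks)
    else:
        resid = ranks - ranks.mean(axis=-2, keepdims=True)
    norms = np.linalg.norm(resid, axis=-2)
    degenerate = np.any(norms < 1e-9 * n, axis=-1)
    safe = np.where(norms < 1e-9 * n, np.nan, norms)
    unit = resid / safe[..., None, :]
    rho = np.swapaxes(unit, -1, -2) @ unit
    rho = np.clip(rho, -1.0, 1.0)
    k = bp.shape[-1]
    rho[..., np.arange(k), np.arange(k)] = 1.0
    return rho, np.asarray(degenerate, dtype=bool)
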