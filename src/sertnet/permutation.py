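"""Permutation null distributions for interregional correlation differences.

Two exchangeability schemes are supported, matching the two study designs:

* ``unpaired_groups`` — the group labels of the pooled subjects are permuted
  with group sizes held fixed (e.g. 19 healthy controls vs 19 patients at
  baseline). Covariates are subject attributes and travel with their rows;
  only the group assignment is exchanged.
* ``paired_conditions`` — for a longitudinal within-subject comparison the
  two condition labels are swapped independently per subject, so every
  permuted dataset still assigns each subject exactly once to each
  condition. This is the constraint that makes the relabelling a valid null
  for repeated measurements.

The test statistic is the entrywise difference of Fisher-z-transformed
partial Spearman matrices; two-sided p-values rank |delta z| with ties
counted toward the null (>= comparison) and the add-one rule
(b+1)/(B+1) for sampled permutations. When the number of distinct
relabellings (2^n paired, C(nA+nB, nA) unpaired) is small the null is
enumerated exhaustively and the exact fraction reported instead.

Benjamini-Hochberg FDR is applied over the k(k-1)/2 upper-triangle
p-values of each contrast separately ("based on the number of
correlations": 36 tests for the default nine-region set).
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np

from .correlation import batch_partial_spearman_matrices, fisher_z, rank_columns
from .errors import ConfigurationError, DesignError, SertnetError
from .types import CohortTable, ContrastResult, PermutationScheme

_CHUNK = 2048  # draws per vectorized block; bounds memory at ~tens of MB


def _check_compatible(
    cohort_a: CohortTable, cohort_b: CohortTable, paired: bool
) -> None:
    if cohort_a.region_set != cohort_b.region_set:
        raise ConfigurationError("cohorts have different region sets")
    if paired:
        if set(cohort_a.subject_ids) != set(cohort_b.subject_ids):
            raise DesignError(
                "paired contrast requires identical subject sets; "
                f"got {sorted(set(cohort_a.subject_ids) ^ set(cohort_b.subject_ids))} "
                "unmatched"
            )


def _single_matrix(bp: np.ndarray, cov: np.ndarray | None) -> np.ndarray:
    rho, degenerate = batch_partial_spearman_matrices(bp[None], cov)
    if degenerate[0]:
        raise SertnetError("undefined correlation in observed data")
    return rho[0]


def observed_stat(
    cohort_a: CohortTable,
    cohort_b: CohortTable,
    covariate_names: Sequence[str] = (),
) -> tuple[np.ndarray, np.ndarray]:
    """Observed (delta_rho, delta_z), cohortB minus cohortA, NaN diagonal."""
    _check_compatible(cohort_a, cohort_b, paired=False)
    cohort_a.require_min_n(len(covariate_names))
    cohort_b.require_min_n(len(covariate_names))
    rho_a = _single_matrix(
        cohort_a.bp_matrix, cohort_a.covariate_matrix(covariate_names)
    )
    rho_b = _single_matrix(
        cohort_b.bp_matrix, cohort_b.covariate_matrix(covariate_names)
    )
    delta_rho = rho_b - rho_a
    delta_z = fisher_z(rho_b) - fisher_z(rho_a)
    k = len(cohort_a.region_set)
    np.fill_diagonal(delta_rho, np.nan)
    np.fill_diagonal(delta_z, np.nan)
    return delta_rho, delta_z


def _exceed_counts(
    delta_z: np.ndarray, obs: np.ndarray, alternative: str
) -> np.ndarray:
    """Per-pair counts of permuted statistics at least as extreme as observed."""
    if alternative == "two_sided":
        hits = np.abs(delta_z) >= np.abs(obs) - 1e-12
    elif alternative == "greater":
        hits = delta_z >= obs - 1e-12
    else:
        hits = delta_z <= obs + 1e-12
    return hits.sum(axis=0)


def paired_relabel(
    bp_a: np.ndarray, bp_b: np.ndarray, swaps: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Apply per-subject condition swaps: rows with swap=1 change condition.

    Every subject contributes exactly one row to each relabelled condition,
    the longitudinal exchangeability constraint.
    """
    mask = swaps[:, :, None].astype(bool)
    perm_a = np.where(mask, bp_b[None], bp_a[None])
    perm_b = np.where(mask, bp_a[None], bp_b[None])
    return perm_a, perm_b


def _paired_delta_z(
    bp_a: np.ndarray,
    bp_b: np.ndarray,
    cov: np.ndarray | None,
    swaps: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """delta_z stacks for paired swap patterns (B, n) -> (B, k, k)."""
    perm_a, perm_b = paired_relabel(bp_a, bp_b, swaps)
    rho_a, deg_a = batch_partial_spearman_matrices(perm_a, cov)
    rho_b, deg_b = batch_partial_spearman_matrices(perm_b, cov)
    return fisher_z(rho_b) - fisher_z(rho_a), deg_a | deg_b


def _unpaired_delta_z(
    pooled_bp: np.ndarray,
    pooled_cov: np.ndarray | None,
    assignments: np.ndarray,
    n_a: int,
) -> tuple[np.ndarray, np.ndarray]:
    """delta_z stacks for pooled-index assignments (B, nA+nB) -> (B, k, k)."""
    idx_a = assignments[:, :n_a]
    idx_b = assignments[:, n_a:]
    bp_a = pooled_bp[idx_a]
    bp_b = pooled_bp[idx_b]
    if pooled_cov is not None and pooled_cov.size:
        cov_a = pooled_cov[idx_a]
        cov_b = pooled_cov[idx_b]
    else:
        cov_a = cov_b = None
    rho_a, deg_a = batch_partial_spearman_matrices(bp_a, cov_a)
    rho_b, deg_b = batch_partial_spearman_matrices(bp_b, cov_b)
    return fisher_z(rho_b) - fisher_z(rho_a), deg_a | deg_b


def n_distinct_relabellings(scheme_mode: str, n_a: int, n_b: int) -> int:
    if scheme_mode == "paired_conditions":
        return 2 ** n_a
    return math.comb(n_a + n_b, n_a)


def permutation_test(
    cohort_a: CohortTable,
    cohort_b: CohortTable,
    scheme: PermutationScheme,
    covariate_names: Sequence[str] = (),
    seed: int | None = None,
) -> ContrastResult:
    """Permutation p-values for every region pair; q_fdr left unfilled (NaN).

    The seed fully determines the sampled draws; identical inputs and seed
    give bit-identical p matrices. Draws in which any region has zero
    residual rank variance are discarded and counted in
    ``n_rejected_draws``.
    """
    paired = scheme.mode == "paired_conditions"
    _check_compatible(cohort_a, cohort_b, paired)
    cohort_a.require_min_n(len(covariate_names))
    cohort_b.require_min_n(len(covariate_names))
    if paired:
        cohort_b = cohort_b.reordered(cohort_a.subject_ids)
        cov_b = cohort_b.covariate_matrix(covariate_names)
        cov_a = cohort_a.covariate_matrix(covariate_names)
        if cov_a.size and not np.allclose(cov_a, cov_b):
            raise DesignError(
                "paired cohorts disagree on subject covariates"
            )

    k = len(cohort_a.region_set)
    rho_a = _single_matrix(
        cohort_a.bp_matrix, cohort_a.covariate_matrix(covariate_names)
    )
    rho_b = _single_matrix(
        cohort_b.bp_matrix, cohort_b.covariate_matrix(covariate_names)
    )
    delta_rho = rho_b - rho_a
    obs_z = fisher_z(rho_b) - fisher_z(rho_a)

    n_a, n_b = cohort_a.n, cohort_b.n
    total = n_distinct_relabellings(scheme.mode, n_a, n_b)
    exact = 0 < total <= scheme.exact_threshold

    bp_a = cohort_a.bp_matrix
    bp_b = cohort_b.bp_matrix
    prerank = scheme.rank_within_cohort
    if prerank is None:
        prerank = paired
    if prerank:
        # Spearman statistics are unchanged, but permuted cohorts now mix
        # comparable rank scales instead of raw per-condition scales
        bp_a = rank_columns(bp_a)
        bp_b = rank_columns(bp_b)
    cov_shared = cohort_a.covariate_matrix(covariate_names)
    if not cov_shared.size:
        cov_shared = None

    counts = np.zeros((k, k))
    n_valid = 0
    n_rejected = 0
    rng = np.random.default_rng(seed)

    def accumulate(delta_z: np.ndarray, degenerate: np.ndarray) -> None:
        nonlocal n_valid, n_rejected
        ok = ~degenerate
        n_rejected += int(degenerate.sum())
        n_valid += int(ok.sum())
        if ok.any():
            counts_local = _exceed_counts(
                delta_z[ok], obs_z[None], scheme.alternative
            )
            counts[:] += counts_local

    if paired:
        if exact:
            patterns = np.array(
                list(itertools.product((0, 1), repeat=n_a)), dtype=np.int8
            )
            for start in range(0, len(patterns), _CHUNK):
                dz, deg = _paired_delta_z(
                    bp_a, bp_b, cov_shared, patterns[start : start + _CHUNK]
                )
                accumulate(dz, deg)
        else:
            remaining = scheme.n_permutations
            while remaining > 0:
                b = min(remaining, _CHUNK)
                swaps = rng.integers(0, 2, size=(b, n_a), dtype=np.int8)
                dz, deg = _paired_delta_z(bp_a, bp_b, cov_shared, swaps)
                accumulate(dz, deg)
                remaining -= b
    else:
        pooled_bp = np.vstack([bp_a, bp_b])
        ca = cohort_a.covariate_matrix(covariate_names)
        cb = cohort_b.covariate_matrix(covariate_names)
        pooled_cov = np.vstack([ca, cb]) if ca.size else None
        n_total = n_a + n_b
        if exact:
            combos = itertools.combinations(range(n_total), n_a)
            all_idx = np.arange(n_total)
            assignments = []
            for combo in combos:
                sel = np.zeros(n_total, dtype=bool)
                sel[list(combo)] = True
                assignments.append(
                    np.concatenate([all_idx[sel], all_idx[~sel]])
                )
            assignments = np.asarray(assignments)
            for start in range(0, len(assignments), _CHUNK):
                dz, deg = _unpaired_delta_z(
                    pooled_bp,
                    pooled_cov,
                    assignments[start : start + _CHUNK],
                    n_a,
                )
                accumulate(dz, deg)
        else:
            remaining = scheme.n_permutations
            while remaining > 0:
                b = min(remaining, _CHUNK)
                perms = np.argsort(rng.random((b, n_total)), axis=1)
                dz, deg = _unpaired_delta_z(pooled_bp, pooled_cov, perms, n_a)
                accumulate(dz, deg)
                remaining -= b

    if n_valid == 0:
        raise SertnetError("all permutation draws were degenerate")

    if exact:
        p = counts / n_valid
    else:
        p = (counts + 1.0) / (n_valid + 1.0)
    np.fill_diagonal(p, np.nan)
    np.fill_diagonal(delta_rho, np.nan)
    dz = obs_z.copy()
    np.fill_diagonal(dz, np.nan)

    nanmat = np.full((k, k), np.nan)
    falsemat = np.zeros((k, k), dtype=bool)
    return ContrastResult(
        region_set=cohort_a.region_set,
        scheme=scheme,
        rho_a=rho_a,
        rho_b=rho_b,
        delta_rho=delta_rho,
        delta_z=dz,
        p_perm=p,
        q_fdr=nanmat,
        sig_uncorrected=falsemat.copy(),
        sig_fdr=falsemat.copy(),
        n_permutations=n_valid if exact else scheme.n_permutations,
        seed=seed,
        exact=exact,
        n_rejected_draws=n_rejected,
        label_a=f"{cohort_a.group}:{cohort_a.condition}",
        label_b=f"{cohort_b.group}:{cohort_b.condition}",
        covariate_names=tuple(covariate_names),
    )


def bh_fdr(
    p: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over a vector of p-values.

    Returns (q, reject): q[i] = min_{j >= i} m * p_(j) / j (capped at 1)
    mapped back to input order; reject where q <= alpha, equivalently all
    p up to the largest i with p_(i) <= i * alpha / m.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise SertnetError("bh_fdr requires a non-empty 1-D vector")
    if np.any(p <= 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise SertnetError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(p)
    q[order] = q_sorted
    return q, q <= alpha


def run_contrast(
    cohort_a: CohortTable,
    cohort_b: CohortTable,
    scheme: PermutationScheme,
    covariate_names: Sequence[str] = (),
    alpha: float = 0.05,
    seed: int | None = None,
) -> ContrastResult:
    """Full contrast: permutation p-values plus BH-FDR over region pairs."""
    result = permutation_test(cohort_a, cohort_b, scheme, covariate_names, seed)
    result.alpha = alpha
    pairs = result.region_set.pairs()
    pvec = np.array([result.p_perm[i, j] for i, j in pairs])
    q, reject = bh_fdr(pvec, alpha)
    k = len(result.region_set)
    qmat = np.full((k, k), np.nan)
    sig_unc = np.zeros((k, k), dtype=bool)
    sig_fdr = np.zeros((k, k), dtype=bool)
    for (i, j), pv, qv, rej in zip(pairs, pvec, q, reject):
        qmat[i, j] = qmat[j, i] = qv
        sig_unc[i, j] = sig_unc[j, i] = pv <= alpha
        sig_fdr[i, j] = sig_fdr[j, i] = rej
    result.q_fdr = qmat
    result.sig_uncorrected = sig_unc
    result.sig_fdr = sig_fdr
    result.validate()
    return result
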