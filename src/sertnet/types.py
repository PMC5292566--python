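"""Core domain types for interregional molecular-correlation analysis.

The unit of analysis is a *cohort*: all subjects of one group measured under
one condition, each contributing a vector of regional PET binding potentials
(BP_ND, unitless) plus the covariates age and gender. Downstream modules
compute covariate-adjusted Spearman correlation matrices per cohort and
permutation contrasts between cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .errors import ConfigurationError, DesignError, IntegrityError

#: ROI set used throughout: subcortical serotonin-transporter-rich regions
#: plus the two cortical regions with adequate signal for SERT quantification,
#: each averaged over both hemispheres.
DEFAULT_REGION_NAMES = (
    "thalamus",
    "putamen",
    "caudate",
    "pallidum",
    "midbrain",
    "hippocampus",
    "amygdala",
    "ACC",
    "insula",
)

#: Default covariates partialled out of every correlation.
DEFAULT_COVARIATES = ("age", "gender")


@dataclass(frozen=True)
class RegionSet:
    """Ordered, immutable set of ROI names.

    Order is fixed at construction and preserved through the pipeline; all
    matrices are indexed in this order. Name lookup is case-insensitive and
    whitespace-trimmed, since region labels carry no semantic case.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        names = tuple(str(n).strip() for n in self.names)
        if len(names) == 0:
            raise ConfigurationError("RegionSet requires at least one region")
        if any(not n for n in names):
            raise ConfigurationError("region names must be non-empty")
        lowered = [n.lower() for n in names]
        if len(set(lowered)) != len(lowered):
            raise ConfigurationError(f"duplicate region names in {names!r}")
        object.__setattr__(self, "names", names)

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[str]:
        return iter(self.names)

    @property
    def n_pairs(self) -> int:
        """Number of unordered region pairs, k(k-1)/2."""
        k = len(self.names)
        return k * (k - 1) // 2

    def index(self, name: str) -> int:
        target = str(name).strip().lower()
        for i, n in enumerate(self.names):
            if n.lower() == target:
                return i
        raise KeyError(f"unknown region {name!r}; have {self.names}")

    def pairs(self) -> list[tuple[int, int]]:
        """Upper-triangle (i, j) index pairs with i < j, row-major order."""
        k = len(self.names)
        return [(i, j) for i in range(k) for j in range(i + 1, k)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return tuple(n.lower() for n in self.names) == tuple(
            n.lower() for n in other.names
        )

    def __hash__(self) -> int:
        return hash(tuple(n.lower() for n in self.names))


def default_region_set() -> RegionSet:
    return RegionSet(DEFAULT_REGION_NAMES)


@dataclass
class SubjectRecord:
    """One subject-scan: regional BP_ND values plus subject attributes.

    ``gender`` is a binary code (default coding: female=1, male=0); the
    coding convention is fixed at read time and does not affect rank-based
    partial correlations, which absorb any affine recoding.
    """

    subject_id: str
    group: str
    condition: str
    age: float
    gender: int
    bp: np.ndarray

    def __post_init__(self) -> None:
        self.bp = np.asarray(self.bp, dtype=float)
        if self.bp.ndim != 1:
            raise IntegrityError(
                f"subject {self.subject_id}: bp must be a 1-D vector"
            )
        if not np.all(np.isfinite(self.bp)):
            raise IntegrityError(
                f"subject {self.subject_id}: non-finite BP_ND value"
            )
        if not np.isfinite(self.age) or self.age <= 0:
            raise IntegrityError(
                f"subject {self.subject_id}: age must be positive, got {self.age}"
            )


@dataclass
class CohortTable:
    """All subjects of one (group, condition) cell: the unit of analysis."""

    region_set: RegionSet
    records: list[SubjectRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise IntegrityError("CohortTable requires at least one record")
        k = len(self.region_set)
        groups = {r.group for r in self.records}
        conditions = {r.condition for r in self.records}
        if len(groups) != 1 or len(conditions) != 1:
            raise IntegrityError(
                f"cohort mixes groups {groups} / conditions {conditions}"
            )
        seen: set[str] = set()
        for r in self.records:
            if len(r.bp) != k:
                raise IntegrityError(
                    f"subject {r.subject_id}: {len(r.bp)} BP values for "
                    f"{k} regions"
                )
            if r.subject_id in seen:
                raise IntegrityError(
                    f"duplicate subject {r.subject_id!r} in cohort "
                    f"({r.group}, {r.condition})"
                )
            seen.add(r.subject_id)

    @property
    def group(self) -> str:
        return self.records[0].group

    @property
    def condition(self) -> str:
        return self.records[0].condition

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    @property
    def bp_matrix(self) -> np.ndarray:
        """Subjects x regions BP_ND matrix (row order = record order)."""
        return np.vstack([r.bp for r in self.records])

    def covariate_matrix(self, names: Sequence[str]) -> np.ndarray:
        """Subjects x covariates matrix for the named subject attributes."""
        cols = []
        for name in names:
            key = name.strip().lower()
            if key == "age":
                cols.append([r.age for r in self.records])
            elif key == "gender":
                cols.append([float(r.gender) for r in self.records])
            else:
                raise ConfigurationError(f"unknown covariate {name!r}")
        if not cols:
            return np.empty((self.n, 0))
        return np.column_stack(cols)

    def require_min_n(self, n_covariates: int) -> None:
        """Partial rank correlation needs residual degrees of freedom."""
        needed = n_covariates + 4
        if self.n < needed:
            raise DesignError(
                f"cohort ({self.group}, {self.condition}) has n={self.n}; "
                f"need at least {needed} subjects for {n_covariates} covariates"
            )

    def reordered(self, subject_order: Sequence[str]) -> "CohortTable":
        """Same cohort with records re-ordered to the given subject IDs."""
        by_id = {r.subject_id: r for r in self.records}
        missing = [s for s in subject_order if s not in by_id]
        if missing or len(subject_order) != len(self.records):
            raise DesignError(
                f"cannot reorder cohort ({self.group}, {self.condition}): "
                f"subject sets differ (missing {missing})"
            )
        return CohortTable(self.region_set, [by_id[s] for s in subject_order])


@dataclass
class CorrelationMatrix:
    """Symmetric ROI x ROI matrix of (partial) Spearman rho for one cohort."""

    region_set: RegionSet
    rho: np.ndarray
    n: int
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        k = len(self.region_set)
        if self.rho.shape != (k, k):
            raise ConfigurationError(
                f"rho shape {self.rho.shape} != ({k}, {k})"
            )
        self.covariate_names = tuple(self.covariate_names)

    def validate(self) -> None:
        rho = self.rho
        if not np.allclose(rho, rho.T, atol=1e-12):
            raise ConfigurationError("correlation matrix not symmetric")
        if not np.allclose(np.diag(rho), 1.0, atol=1e-12):
            raise ConfigurationError("correlation matrix diagonal != 1")
        off = rho[~np.eye(len(rho), dtype=bool)]
        if off.size and (off.min() < -1 - 1e-12 or off.max() > 1 + 1e-12):
            raise ConfigurationError("off-diagonal correlation outside [-1, 1]")


@dataclass
class PermutationScheme:
    """Declaration of the permutation null.

    mode
        ``unpaired_groups``: exchange group labels over the pooled subjects,
        preserving group sizes — the null for a between-group contrast.
        ``paired_conditions``: swap the two condition labels independently
        within each subject, so every permuted dataset still assigns each
        subject exactly once to each condition — the null for a longitudinal
        within-subject contrast.
    n_permutations
        Monte-Carlo sample size B when sampling is used.
    alternative
        ``two_sided`` ranks |delta z|; ``greater`` / ``less`` rank signed
        delta z.
    exact_threshold
        When the number of distinct relabellings (2^n paired, C(nA+nB, nA)
        unpaired) is at most this, the null is enumerated exhaustively and
        the exact p reported; set 0 to force sampling.
    rank_within_cohort
        Reduce each cohort to within-cohort column ranks before permuting.
        Leaves the observed Spearman statistic untouched (ranks of ranks
        are ranks) but makes the relabelling distribution-preserving when
        the conditions live on different scales — e.g. drug occupancy
        shrinking one condition's values several-fold, which would
        otherwise stamp a common condition factor onto every permuted
        cohort. None (default) resolves to True for paired_conditions and
        False for unpaired_groups (where both cohorts share a scale).
    """

    mode: str
    n_permutations: int = 10_000
    alternative: str = "two_sided"
    exact_threshold: int = 1024
    rank_within_cohort: bool | None = None

    MODES = ("unpaired_groups", "paired_conditions")
    ALTERNATIVES = ("two_sided", "greater", "less")

    def __post_init__(self) -> None:
        if self.mode not in self.MODES:
            raise ConfigurationError(
                f"mode must be one of {self.MODES}, got {self.mode!r}"
            )
        if self.alternative not in self.ALTERNATIVES:
            raise ConfigurationError(
                f"alternative must be one of {self.ALTERNATIVES}, "
                f"got {self.alternative!r}"
            )
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")
        if self.exact_threshold < 0:
            raise ConfigurationError("exact_threshold must be >= 0")


@dataclass
class ContrastResult:
    """Per-region-pair results of one two-cohort contrast.

    All matrices are symmetric with NaN on the diagonal (the diagonal is not
    a tested hypothesis). ``delta_*`` are cohortB minus cohortA.
    """

    region_set: RegionSet
    scheme: PermutationScheme
    rho_a: np.ndarray
    rho_b: np.ndarray
    delta_rho: np.ndarray
    delta_z: np.ndarray
    p_perm: np.ndarray
    q_fdr: np.ndarray
    sig_uncorrected: np.ndarray
    sig_fdr: np.ndarray
    n_permutations: int
    seed: int | None
    alpha: float = 0.05
    exact: bool = False
    n_rejected_draws: int = 0
    label_a: str = "A"
    label_b: str = "B"
    covariate_names: tuple[str, ...] = field(default_factory=tuple)

    def validate(self) -> None:
        k = len(self.region_set)
        offmask = ~np.eye(k, dtype=bool)
        for name in ("delta_rho", "delta_z", "p_perm", "q_fdr"):
            m = getattr(self, name)
            if m.shape != (k, k):
                raise ConfigurationError(f"{name} shape {m.shape} != ({k},{k})")
            if not np.allclose(m[offmask], m.T[offmask], equal_nan=True):
                raise ConfigurationError(f"{name} not symmetric")
        p = self.p_perm[offmask]
        if np.any(p <= 0) or np.any(p > 1):
            raise ConfigurationError("p_perm outside (0, 1]")
        if np.any(self.q_fdr[offmask] + 1e-12 < p):
            raise ConfigurationError("BH-adjusted q below raw p")
        if np.any(self.sig_fdr & ~self.sig_uncorrected):
            raise ConfigurationError(
                "pair significant after FDR but not before correction"
            )
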