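"""Synthetic longitudinal PET cohorts with controllable correlation structure.

The study data this pipeline targets (regional serotonin-transporter BP_ND
in patients scanned at baseline, after a first SSRI dose and after three
weeks of treatment, plus once-scanned healthy controls) are not publicly
deposited, so a generator stands in as the test bed. It emulates the
features the statistics depend on:

* a latent Gaussian copula whose Pearson matrix is calibrated entrywise by
  r = 2 sin(pi * rho_s / 6) so that generated data hit a *Spearman* target
  exactly in population — the pipeline's statistic is Spearman, so targets
  live on the Spearman scale;
* per-condition multiplicative occupancy: SSRI binding reduces BP_ND by a
  fraction per region, a monotone per-region rescaling that leaves rank
  correlations untouched (detected correlation changes therefore reflect
  structure change, not mean change);
* linear age and gender effects shared across regions, the confounding the
  covariate adjustment exists to remove;
* additive measurement noise and a zero floor (BP_ND is non-negative by
  definition); floor events are counted, not hidden.

Subjects (IDs, age, gender) are shared across conditions, matching the
longitudinal design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigurationError, SertnetError
from .types import CohortTable, RegionSet, SubjectRecord, default_region_set

#: Eigenvalue floor used when repairing an indefinite converted matrix.
_PSD_EPS = 1e-8

#: Hard error if a PSD repair moves any non-designated entry by more than
#: this (on the Pearson correlation scale); smaller repairs are applied and
#: reported on the config.
DEFAULT_PSD_TOLERANCE = 0.1


def spearman_to_pearson(rho_s: float | np.ndarray) -> float | np.ndarray:
    """Pearson correlation of a bivariate normal with given Spearman rho.

    r = 2 sin(pi * rho_s / 6): the exact Gaussian-copula relation, so a
    latent multivariate normal with Pearson r yields Spearman rho_s.
    """
    arr = np.asarray(rho_s, dtype=float)
    if np.any(np.abs(arr) > 1 + 1e-12):
        raise SertnetError(f"Spearman rho outside [-1, 1]: {arr}")
    out = 2.0 * np.sin(np.pi * np.clip(arr, -1, 1) / 6.0)
    if np.ndim(rho_s) == 0:
        return float(out)
    return out


def nearest_psd(
    matrix: np.ndarray,
    fixed: np.ndarray | None = None,
    max_iter: int = 5000,
    tol: float = 1e-12,
) -> tuple[np.ndarray, float]:
    """Nearest positive-semidefinite correlation matrix by alternating
    projections (eigenvalue clipping against the PSD cone, entry reset
    against the affine constraints), with Dykstra's correction.

    By default only the unit diagonal is enforced, giving the
    minimum-Frobenius-distance correlation matrix. ``fixed`` may mark
    additional entries to hold exactly — used when a scenario's injected
    correlations are the quantity under study and only the unspecified
    pairs may absorb an inconsistency.

    Returns the repaired matrix and its Frobenius distance to the input
    (0.0 when the input is already PSD).
    """
    m = np.asarray(matrix, dtype=float)
    m = (m + m.T) / 2.0
    vals = np.linalg.eigvalsh(m)
    if vals.min() >= 0:
        return m, 0.0
    hold = np.eye(len(m), dtype=bool)
    if fixed is not None:
        hold = hold | np.asarray(fixed, dtype=bool)
    x = m.copy()
    correction = np.zeros_like(m)
    for _ in range(max_iter):
        r = x - correction
        vals, vecs = np.linalg.eigh(r)
        y = (vecs * np.maximum(vals, _PSD_EPS)) @ vecs.T
        correction = y - r
        x_new = y.copy()
        x_new[hold] = m[hold]
        if np.linalg.norm(x_new - x) < tol:
            x = x_new
            break
        x = x_new
    if np.linalg.eigvalsh(x).min() < -1e-6:
        raise ConfigurationError(
            "PSD repair did not converge: the fixed correlations admit no "
            "positive-semidefinite completion"
        )
    return x, float(np.linalg.norm(x - m))


@dataclass
class SyntheticConfig:
    """Full generative recipe for a longitudinal synthetic cohort.

    R_target maps condition label -> k x k target *Spearman* matrix; the
    first key is the baseline condition and must have zero occupancy.
    Occupancy maps condition -> per-region occupied fraction in [0, 1);
    scalars are broadcast over regions. beta_age is in BP_ND units per year
    (applied to age minus the midrange), beta_gender an additive offset for
    gender code 1.
    """

    n_subjects: int
    region_set: RegionSet
    mu: np.ndarray
    sigma: np.ndarray
    R_target: dict[str, np.ndarray]
    occupancy: dict[str, np.ndarray]
    age_range: tuple[float, float] = (27.0, 54.0)
    beta_age: np.ndarray | float = 0.0
    p_female: float = 0.5
    beta_gender: np.ndarray | float = 0.0
    noise_sd: np.ndarray | float = 0.0
    seed: int = 0
    group: str = "MDD"
    #: reuse one underlying standard-normal draw across conditions (each
    #: condition's correlation structure applied to the same draw): perfect
    #: within-subject stability, the regime where occupancy rescaling is the
    #: only between-condition difference.
    share_latents: bool = False
    psd_tolerance: float = DEFAULT_PSD_TOLERANCE
    #: condition -> boolean mask of R_target entries that a PSD repair must
    #: hold exactly (scenario-injected correlations); remaining pairs are
    #: free to absorb an indefiniteness.
    repair_fixed: dict[str, np.ndarray] = field(default_factory=dict)
    #: filled by validation: condition -> Frobenius distance of PSD repair
    psd_repairs: dict[str, float] = field(default_factory=dict)
    #: condition -> largest drift of a free entry under repair (Pearson scale)
    psd_repair_drift: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = len(self.region_set)
        self.mu = np.broadcast_to(np.asarray(self.mu, float), (k,)).copy()
        self.sigma = np.broadcast_to(np.asarray(self.sigma, float), (k,)).copy()
        self.beta_age = np.broadcast_to(np.asarray(self.beta_age, float), (k,)).copy()
        self.beta_gender = np.broadcast_to(
            np.asarray(self.beta_gender, float), (k,)
        ).copy()
        self.noise_sd = np.broadcast_to(np.asarray(self.noise_sd, float), (k,)).copy()
        if self.n_subjects < 2:
            raise ConfigurationError("need at least 2 subjects")
        if np.any(self.mu <= 0):
            raise ConfigurationError("baseline means must be positive")
        if not self.R_target:
            raise ConfigurationError("R_target must name at least one condition")
        for cond, mat in self.R_target.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (k, k):
                raise ConfigurationError(
                    f"R_target[{cond}] shape {mat.shape} != ({k}, {k})"
                )
            if not np.allclose(mat, mat.T) or not np.allclose(np.diag(mat), 1.0):
                raise ConfigurationError(
                    f"R_target[{cond}] must be symmetric with unit diagonal"
                )
            self.R_target[cond] = mat
        occ = {}
        for cond in self.R_target:
            val = self.occupancy.get(cond, 0.0)
            val = np.broadcast_to(np.asarray(val, float), (k,)).copy()
            if np.any(val < 0) or np.any(val >= 1):
                raise ConfigurationError(
                    f"occupancy[{cond}] must lie in [0, 1)"
                )
            occ[cond] = val
        self.occupancy = occ
        baseline = self.conditions[0]
        if np.any(self.occupancy[baseline] != 0):
            raise ConfigurationError(
                f"baseline condition {baseline!r} must have zero occupancy"
            )
        if not (0 <= self.p_female <= 1):
            raise ConfigurationError("p_female must be a probability")
        lo, hi = self.age_range
        if not (0 < lo < hi):
            raise ConfigurationError("age_range must satisfy 0 < min < max")
        self._validate_psd()

    @property
    def conditions(self) -> list[str]:
        return list(self.R_target)

    def _validate_psd(self) -> None:
        """Convert each target to the Pearson scale and repair if indefinite.

        Without a ``repair_fixed`` mask, no entry may move by more than
        ``psd_tolerance``; with a mask, the designated entries are held
        exactly and the free pairs absorb the repair (their largest drift
        is recorded, not bounded — they are declared adjustable).
        """
        self._pearson: dict[str, np.ndarray] = {}
        for cond, mat in self.R_target.items():
            pearson = spearman_to_pearson(mat)
            np.fill_diagonal(pearson, 1.0)
            fixed = self.repair_fixed.get(cond)
            repaired, dist = nearest_psd(pearson, fixed=fixed)
            drift = float(np.abs(repaired - pearson).max())
            if fixed is None and drift > self.psd_tolerance:
                raise ConfigurationError(
                    f"R_target[{cond}] is too far from positive semidefinite "
                    f"(max entry change {drift:.3f} > {self.psd_tolerance}); "
                    "either adjust the targets or mark adjustable entries "
                    "via repair_fixed"
                )
            if dist > 0:
                self.psd_repairs[cond] = dist
                self.psd_repair_drift[cond] = drift
            self._pearson[cond] = repaired

    def pearson_latent(self, condition: str) -> np.ndarray:
        """Latent Pearson matrix actually used for the given condition."""
        return self._pearson[condition]

    def realized_spearman(self, condition: str) -> np.ndarray:
        """Population Spearman structure actually generated (post-repair).

        Inverse copula relation rho_s = (6 / pi) asin(r / 2); equals
        R_target when no repair was needed, and still equals it on every
        ``repair_fixed`` entry otherwise.
        """
        r = self._pearson[condition]
        out = 6.0 / np.pi * np.arcsin(np.clip(r, -1, 1) / 2.0)
        np.fill_diagonal(out, 1.0)
        return out


def generate_cohorts(config: SyntheticConfig) -> list[CohortTable]:
    """Generate one CohortTable per condition with shared subjects.

    Per subject: age ~ Uniform(age_range), gender ~ Bernoulli(p_female).
    Per condition, a latent standard-normal vector with the calibrated
    Pearson structure is drawn (independently across conditions), and

        BP = (mu + beta_age*(age - midrange) + beta_gender*gender
              + sigma*latent) * (1 - occupancy) + noise

    Negative values are floored at zero; the count of floor events is
    stored as ``cohort.n_floored`` on each returned table. The seed
    determines everything.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    k = len(config.region_set)
    ages = rng.uniform(*config.age_range, size=n)
    genders = (rng.random(n) < config.p_female).astype(int)
    midrange = (config.age_range[0] + config.age_range[1]) / 2.0
    subject_ids = [f"{config.group}{idx + 1:03d}" for idx in range(n)]

    systematic = (
        config.mu[None, :]
        + config.beta_age[None, :] * (ages - midrange)[:, None]
        + config.beta_gender[None, :] * genders[:, None]
    )

    cohorts = []
    shared_z = rng.standard_normal((n, k)) if config.share_latents else None
    for cond in config.conditions:
        pearson = config.pearson_latent(cond)
        chol = np.linalg.cholesky(pearson + _PSD_EPS * np.eye(k))
        z = shared_z if shared_z is not None else rng.standard_normal((n, k))
        latent = z @ chol.T
        noise = rng.standard_normal((n, k)) * config.noise_sd[None, :]
        bp = (systematic + config.sigma[None, :] * latent) * (
            1.0 - config.occupancy[cond][None, :]
        ) + noise
        n_floored = int(np.sum(bp < 0))
        bp = np.maximum(bp, 0.0)
        records = [
            SubjectRecord(
                subject_id=subject_ids[i],
                group=config.group,
                condition=cond,
                age=float(ages[i]),
                gender=int(genders[i]),
                bp=bp[i],
            )
            for i in range(n)
        ]
        cohort = CohortTable(config.region_set, records)
        cohort.n_floored = n_floored  # type: ignore[attr-defined]
        cohorts.append(cohort)
    return cohorts


# ---------------------------------------------------------------------------
# default scenario


def _table_pairs() -> dict[str, list[tuple[str, str, float]]]:
    """Correlation increases injected per follow-up condition.

    PET2 carries the seven pairs reported as uncorrected increases after a
    single dose; PET3 the ten ACC/insula pairs reported as FDR-significant
    after three weeks plus the three additional uncorrected pairs.
    """
    pet2 = [
        ("ACC", "midbrain", 0.45),
        ("ACC", "pallidum", 0.61),
        ("ACC", "putamen", 0.34),
        ("hippocampus", "amygdala", 0.20),
        ("hippocampus", "insula", 0.37),
        ("hippocampus", "pallidum", 0.47),
        ("insula", "pallidum", 0.56),
    ]
    pet3 = [
        ("ACC", "amygdala", 0.49),
        ("ACC", "hippocampus", 0.24),
        ("ACC", "midbrain", 0.67),
        ("ACC", "pallidum", 0.71),
        ("ACC", "putamen", 0.49),
        ("insula", "amygdala", 0.47),
        ("insula", "hippocampus", 0.43),
        ("insula", "midbrain", 0.51),
        ("insula", "pallidum", 0.61),
        ("insula", "putamen", 0.36),
    ]
    return {"PET2": pet2, "PET3": pet3}


#: The ten ACC/insula pair increases of the three-week contrast, the
#: injected effects the default scenario is built around.
THREE_WEEK_PAIR_EFFECTS = tuple(_table_pairs()["PET3"])


def ssri_study_scenario(
    n_subjects: int = 19,
    baseline_rho: float = 0.2,
    seed: int = 0,
) -> SyntheticConfig:
    """Default longitudinal scenario mirroring the study conditions.

    19 patients, the nine-region ROI set, three conditions (PET1 baseline,
    PET2 six hours after a first SSRI dose, PET3 after three weeks of daily
    intake). Region means follow the [11C]DASB binding gradient (midbrain
    and thalamus high, ACC and insula low); occupancy is 0.70 at PET2 and
    0.75 at PET3, uniform over regions. Starting from a uniform moderate
    baseline correlation, the reported pair-level increases are injected
    into the follow-up target matrices (ten ACC/insula pairs by +0.24 to
    +0.71 at PET3); all other pairs keep the baseline value.
    """
    regions = default_region_set()
    k = len(regions)
    # order: thalamus, putamen, caudate, pallidum, midbrain, hippocampus,
    #        amygdala, ACC, insula — typical DASB BP_ND magnitudes
    mu = np.array([1.8, 1.5, 1.3, 1.1, 2.0, 0.9, 1.1, 0.45, 0.55])
    sigma = 0.18 * mu
    # measurement noise is added after occupancy scaling, so it is sized
    # against the smallest signal in the design (25% of baseline at PET3):
    # 1% of the baseline mean keeps rank-correlation attenuation below ~5%
    # in every condition, consistent with ROI-averaged BP_ND estimates whose
    # variability is dominated by between-subject differences
    noise_sd = 0.01 * mu
    beta_age = -0.008 * mu  # gradual decline in availability with age
    beta_gender = 0.04 * mu

    base = np.full((k, k), baseline_rho)
    np.fill_diagonal(base, 1.0)
    targets = {"PET1": base.copy()}
    repair_fixed = {}
    for cond, pairs in _table_pairs().items():
        mat = base.copy()
        fixed = np.zeros((k, k), dtype=bool)
        for a, b, delta in pairs:
            i, j = regions.index(a), regions.index(b)
            mat[i, j] = mat[j, i] = min(baseline_rho + delta, 0.97)
            fixed[i, j] = fixed[j, i] = True
        targets[cond] = mat
        # the injected increases are the quantity under study: a PSD repair
        # must hold them exactly and shift only the unreported pairs
        repair_fixed[cond] = fixed

    return SyntheticConfig(
        n_subjects=n_subjects,
        region_set=regions,
        mu=mu,
        sigma=sigma,
        R_target=targets,
        occupancy={"PET1": 0.0, "PET2": 0.70, "PET3": 0.75},
        age_range=(27.0, 54.0),
        beta_age=beta_age,
        p_female=13.0 / 19.0,
        beta_gender=beta_gender,
        noise_sd=noise_sd,
        seed=seed,
        group="MDD",
        repair_fixed=repair_fixed,
    )


def healthy_control_scenario(
    n_subjects: int = 19,
    baseline_rho: float = 0.2,
    seed: int = 1,
) -> SyntheticConfig:
    """Once-scanned control cohort: baseline structure only, no occupancy."""
    base = ssri_study_scenario(n_subjects=n_subjects, baseline_rho=baseline_rho)
    return SyntheticConfig(
        n_subjects=n_subjects,
        region_set=base.region_set,
        mu=base.mu,
        sigma=base.sigma,
        R_target={"PET1": base.R_target["PET1"].copy()},
        occupancy={"PET1": 0.0},
        age_range=base.age_range,
        beta_age=base.beta_age,
        p_female=6.0 / 19.0,
        beta_gender=base.beta_gender,
        noise_sd=base.noise_sd,
        seed=seed,
        group="HC",
    )


# ---------------------------------------------------------------------------
# config (de)serialization


def config_to_dict(config: SyntheticConfig) -> dict:
    return {
        "n_subjects": config.n_subjects,
        "regions": list(config.region_set.names),
        "mu": config.mu.tolist(),
        "sigma": config.sigma.tolist(),
        "R_target": {c: m.tolist() for c, m in config.R_target.items()},
        "occupancy": {c: v.tolist() for c, v in config.occupancy.items()},
        "age_range": list(config.age_range),
        "beta_age": config.beta_age.tolist(),
        "p_female": config.p_female,
        "beta_gender": config.beta_gender.tolist(),
        "noise_sd": config.noise_sd.tolist(),
        "seed": config.seed,
        "group": config.group,
        "share_latents": config.share_latents,
        "repair_fixed": {
            c: np.asarray(m).astype(int).tolist()
            for c, m in config.repair_fixed.items()
        },
    }


def config_from_dict(data: Mapping) -> SyntheticConfig:
    return SyntheticConfig(
        n_subjects=int(data["n_subjects"]),
        region_set=RegionSet(tuple(data["regions"])),
        mu=np.asarray(data["mu"], float),
        sigma=np.asarray(data["sigma"], float),
        R_target={c: np.asarray(m, float) for c, m in data["R_target"].items()},
        occupancy={c: np.asarray(v, float) for c, v in data["occupancy"].items()},
        age_range=tuple(data.get("age_range", (27.0, 54.0))),
        beta_age=np.asarray(data.get("beta_age", 0.0), float),
        p_female=float(data.get("p_female", 0.5)),
        beta_gender=np.asarray(data.get("beta_gender", 0.0), float),
        noise_sd=np.asarray(data.get("noise_sd", 0.0), float),
        seed=int(data.get("seed", 0)),
        group=str(data.get("group", "MDD")),
        share_latents=bool(data.get("share_latents", False)),
        repair_fixed={
            c: np.asarray(m, dtype=bool)
            for c, m in data.get("repair_fixed", {}).items()
        },
    )


def save_config(config: SyntheticConfig, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path) -> SyntheticConfig:
    import yaml

    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
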