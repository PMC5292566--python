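"""Whole-study orchestration: the default three contrasts over four cohorts.

The study design this mirrors: patients scanned at baseline (PET1), six
hours after a first SSRI dose (PET2) and after at least three weeks of daily
intake (PET3); controls scanned once at baseline. The default contrasts are

* HC(PET1) vs MDD(PET1) — unpaired group-label permutation,
* MDD PET1 vs PET2 and MDD PET1 vs PET3 — paired within-subject
  condition swaps.

PET2 vs PET3 is expressible in a custom config but not run by default.
Each contrast gets its own BH-FDR over the region pairs. A run is a pure
function of (input, config, seed): identical seeds give identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .correlation import correlation_matrix
from .errors import ConfigurationError, DesignError
from .io import (
    export_network,
    write_contrast_report,
    write_correlation_matrix,
)
from .permutation import run_contrast
from .synthetic import generate_cohorts, healthy_control_scenario, ssri_study_scenario
from .types import CohortTable, PermutationScheme


@dataclass
class ContrastSpec:
    """Selector pair plus permutation mode for one contrast."""

    cohort_a: tuple[str, str]  # (group, condition)
    cohort_b: tuple[str, str]
    mode: str  # unpaired_groups | paired_conditions

    @property
    def name(self) -> str:
        return (
            f"{self.cohort_a[0]}-{self.cohort_a[1]}_vs_"
            f"{self.cohort_b[0]}-{self.cohort_b[1]}"
        )


DEFAULT_CONTRASTS = (
    ContrastSpec(("HC", "PET1"), ("MDD", "PET1"), "unpaired_groups"),
    ContrastSpec(("MDD", "PET1"), ("MDD", "PET2"), "paired_conditions"),
    ContrastSpec(("MDD", "PET1"), ("MDD", "PET3"), "paired_conditions"),
)


@dataclass
class StudyConfig:
    """Configuration of a full study run."""

    cohorts: list[CohortTable]
    covariate_names: tuple[str, ...] = ("age", "gender")
    contrasts: Sequence[ContrastSpec] = DEFAULT_CONTRASTS
    alpha: float = 0.05
    n_permutations: int = 10_000
    alternative: str = "two_sided"
    exact_threshold: int = 1024
    seed: int = 0
    output_dir: Path = Path("study_output")

    def cohort(self, group: str, condition: str) -> CohortTable:
        for c in self.cohorts:
            if c.group == group and c.condition == condition:
                return c
        available = [(c.group, c.condition) for c in self.cohorts]
        raise ConfigurationError(
            f"no cohort ({group}, {condition}); available: {available}"
        )

    def validate(self) -> None:
        for spec in self.contrasts:
            a = self.cohort(*spec.cohort_a)
            b = self.cohort(*spec.cohort_b)
            if spec.mode == "paired_conditions":
                if set(a.subject_ids) != set(b.subject_ids):
                    raise DesignError(
                        f"paired contrast {spec.name} requires matched subjects"
                    )
            PermutationScheme(mode=spec.mode)  # mode validity


def synthetic_study_cohorts(seed: int = 0, n_subjects: int = 19) -> list[CohortTable]:
    """The four cells of the default synthetic study (HC x1, MDD x3)."""
    patients = generate_cohorts(
        ssri_study_scenario(n_subjects=n_subjects, seed=seed)
    )
    controls = generate_cohorts(
        healthy_control_scenario(n_subjects=n_subjects, seed=seed + 1)
    )
    return controls + patients


def run_study(config: StudyConfig) -> dict:
    """Execute every contrast, writing the full report bundle.

    Per cohort: a correlation-matrix CSV. Per contrast: the pair-level
    report, both correlation matrices, a significance-masked delta matrix,
    and node/edge network files. A JSON run log records seed, permutation
    counts, alpha, version and discarded-draw counts. Returns the log dict.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    log: dict = {
        "version": __version__,
        "seed": config.seed,
        "n_permutations": config.n_permutations,
        "alpha": config.alpha,
        "covariates": list(config.covariate_names),
        "cohorts": [],
        "contrasts": [],
    }

    matrices = {}
    for cohort in config.cohorts:
        cm = correlation_matrix(cohort, config.covariate_names)
        matrices[(cohort.group, cohort.condition)] = cm
        name = f"correlation_{cohort.group}_{cohort.condition}.csv"
        write_correlation_matrix(cm, out / name)
        log["cohorts"].append(
            {"group": cohort.group, "condition": cohort.condition, "n": cohort.n}
        )

    for offset, spec in enumerate(config.contrasts):
        a = config.cohort(*spec.cohort_a)
        b = config.cohort(*spec.cohort_b)
        scheme = PermutationScheme(
            mode=spec.mode,
            n_permutations=config.n_permutations,
            alternative=config.alternative,
            exact_threshold=config.exact_threshold,
        )
        result = run_contrast(
            a,
            b,
            scheme,
            config.covariate_names,
            alpha=config.alpha,
            seed=config.seed + offset,
        )
        stem = spec.name
        write_contrast_report(result, out / f"contrast_{stem}.csv")
        masked = np.where(result.sig_fdr, result.delta_rho, 0.0)
        np.savetxt(
            out / f"delta_rho_fdr_masked_{stem}.csv",
            np.nan_to_num(masked),
            delimiter=",",
            fmt="%.6f",
        )
        export_network(
            result,
            out / f"network_{stem}.node",
            out / f"network_{stem}.edge",
            edge_field="delta_rho",
            mask="sig_fdr",
        )
        log["contrasts"].append(
            {
                "name": stem,
                "mode": spec.mode,
                "seed": result.seed,
                "exact": result.exact,
                "n_permutations": result.n_permutations,
                "n_rejected_draws": result.n_rejected_draws,
                "n_sig_uncorrected": int(result.sig_uncorrected.sum() // 2),
                "n_sig_fdr": int(result.sig_fdr.sum() // 2),
            }
        )

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return log
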