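"""Shared fixtures: small deterministic cohorts and tables on disk."""

from __future__ import annotations

import numpy as np
import pytest

from sertnet.types import CohortTable, RegionSet, SubjectRecord


@pytest.fixture
def small_regions() -> RegionSet:
    return RegionSet(("r1", "r2", "r3", "r4"))


def make_cohort(
    regions: RegionSet,
    n: int,
    group: str = "G",
    condition: str = "C1",
    seed: int = 0,
    subject_prefix: str = "s",
    ages=None,
    genders=None,
) -> CohortTable:
    rng = np.random.default_rng(seed)
    ages = rng.uniform(28, 55, n) if ages is None else np.asarray(ages)
    genders = (
        (rng.random(n) < 0.5).astype(int) if genders is None else np.asarray(genders)
    )
    records = [
        SubjectRecord(
            subject_id=f"{subject_prefix}{i:02d}",
            group=group,
            condition=condition,
            age=float(ages[i]),
            gender=int(genders[i]),
            bp=rng.uniform(0.2, 2.5, len(regions)),
        )
        for i in range(n)
    ]
    return CohortTable(regions, records)


def make_paired_cohorts(
    regions: RegionSet, n: int, seed: int = 0
) -> tuple[CohortTable, CohortTable]:
    """Two conditions over the same subjects (covariates shared)."""
    rng = np.random.default_rng(seed)
    ages = rng.uniform(28, 55, n)
    genders = (rng.random(n) < 0.5).astype(int)
    a = make_cohort(
        regions, n, condition="C1", seed=seed + 1, ages=ages, genders=genders
    )
    b = make_cohort(
        regions, n, condition="C2", seed=seed + 2, ages=ages, genders=genders
    )
    return a, b


@pytest.fixture
def paired_cohorts(small_regions):
    return make_paired_cohorts(small_regions, n=8, seed=3)


@pytest.fixture
def cohort_csv(tmp_path):
    """38-row four-cell study file: HC baseline plus MDD x three conditions."""
    path = tmp_path / "cohorts.csv"
    rng = np.random.default_rng(11)
    rows = ["subject_id,group,condition,age,gender,thalamus,putamen,ACC"]
    for i in range(19):
        rows.append(
            f"hc{i:02d},HC,PET1,{rng.uniform(28, 54):.2f},"
            f"{int(rng.random() < 0.3)},"
            + ",".join(f"{v:.4f}" for v in rng.uniform(0.3, 2.2, 3))
        )
    for i in range(19):
        age = rng.uniform(28, 54)
        g = int(rng.random() < 0.7)
        for cond in ("PET1", "PET2", "PET3"):
            rows.append(
                f"md{i:02d},MDD,{cond},{age:.2f},{g},"
                + ",".join(f"{v:.4f}" for v in rng.uniform(0.1, 2.2, 3))
            )
    path.write_text("\n".join(rows) + "\n")
    return path
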