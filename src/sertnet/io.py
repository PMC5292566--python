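"""Tabular readers/writers and network-file export.

Input is a delimited text file (comma or tab, auto-detected) in long format:
one row per subject-scan with subject ID, group, condition, age, gender and
one column per ROI holding BP_ND. Rows are partitioned into one
:class:`~sertnet.types.CohortTable` per (group, condition) cell — a
bijection: every row lands in exactly one cohort.

Outputs are a long-format contrast report (one row per region pair) and the
plain-text node/edge files consumed by brain-network viewers (node: ``x y z
color size label`` per region; edge: a k x k matrix with non-significant
entries zeroed).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, IntegrityError, ParseError, SchemaError
from .types import CohortTable, ContrastResult, RegionSet, SubjectRecord


@dataclass
class ColumnSchema:
    """Mapping from required fields to column names in the input table.

    ROI columns default to every column not claimed by a required field,
    in file order. Gender strings are mapped through ``gender_labels``
    (case-insensitive; default coding female=1, male=0); numeric 0/1 cells
    are accepted as-is.
    """

    subject_id: str = "subject_id"
    group: str = "group"
    condition: str = "condition"
    age: str = "age"
    gender: str = "gender"
    roi_columns: tuple[str, ...] | None = None
    gender_labels: Mapping[str, int] = field(
        default_factory=lambda: {"female": 1, "f": 1, "male": 0, "m": 0}
    )

    @property
    def required(self) -> tuple[str, ...]:
        return (self.subject_id, self.group, self.condition, self.age, self.gender)


def _detect_delimiter(path: Path) -> str:
    if path.suffix.lower() in (".tsv", ".tab"):
        return "\t"
    if path.suffix.lower() == ".csv":
        return ","
    header = path.read_text().splitlines()[0] if path.read_text() else ""
    return "\t" if header.count("\t") >= header.count(",") else ","


def _parse_gender(value, schema: ColumnSchema, row: int) -> int:
    text = str(value).strip().lower()
    if text in ("0", "1"):
        return int(text)
    if text in schema.gender_labels:
        return int(schema.gender_labels[text])
    raise ParseError(
        f"row {row}: cannot interpret gender value {value!r} "
        f"(known labels: {sorted(schema.gender_labels)})"
    )


def read_cohort_table(
    path,
    schema: ColumnSchema | None = None,
    delimiter: str | None = None,
) -> list[CohortTable]:
    """Read a long-format subject-scan table into cohorts.

    Returns one CohortTable per (group, condition), ordered by first
    appearance in the file; row order is preserved within each cohort.
    """
    path = Path(path)
    schema = schema or ColumnSchema()
    sep = delimiter or _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]

    colmap = {c.lower(): c for c in df.columns}
    resolved = {}
    for attr in ("subject_id", "group", "condition", "age", "gender"):
        wanted = getattr(schema, attr)
        actual = colmap.get(wanted.lower())
        if actual is None:
            raise SchemaError(f"missing required column {wanted!r}")
        resolved[attr] = actual

    if schema.roi_columns is not None:
        roi_cols = []
        for name in schema.roi_columns:
            actual = colmap.get(name.strip().lower())
            if actual is None:
                raise SchemaError(f"missing ROI column {name!r}")
            roi_cols.append(actual)
    else:
        claimed = set(resolved.values())
        roi_cols = [c for c in df.columns if c not in claimed]
    if len(roi_cols) < 2:
        raise SchemaError(
            f"need at least 2 ROI columns, found {len(roi_cols)}: {roi_cols}"
        )
    region_set = RegionSet(tuple(roi_cols))

    def parse_float(value, row: int, col: str) -> float:
        try:
            out = float(value)
        except (TypeError, ValueError):
            raise ParseError(
                f"row {row}, column {col!r}: non-numeric value {value!r}"
            ) from None
        if not np.isfinite(out):
            raise ParseError(f"row {row}, column {col!r}: non-finite value")
        return out

    cohorts: dict[tuple[str, str], list[SubjectRecord]] = {}
    seen: set[tuple[str, str]] = set()
    for idx, row in df.iterrows():
        rowno = int(idx) + 2  # header is line 1
        sid = str(row[resolved["subject_id"]]).strip()
        group = str(row[resolved["group"]]).strip()
        cond = str(row[resolved["condition"]]).strip()
        key = (sid, cond)
        if key in seen:
            raise IntegrityError(
                f"row {rowno}: duplicate (subject, condition) = {key}"
            )
        seen.add(key)
        record = SubjectRecord(
            subject_id=sid,
            group=group,
            condition=cond,
            age=parse_float(row[resolved["age"]], rowno, resolved["age"]),
            gender=_parse_gender(row[resolved["gender"]], schema, rowno),
            bp=np.array(
                [parse_float(row[c], rowno, c) for c in roi_cols]
            ),
        )
        cohorts.setdefault((group, cond), []).append(record)
    return [CohortTable(region_set, recs) for recs in cohorts.values()]


def write_cohort_tables(
    cohorts: Sequence[CohortTable],
    path,
    delimiter: str = ",",
    float_fmt: str = "%.6f",
) -> None:
    """Write cohorts back to one long-format delimited file."""
    path = Path(path)
    if not cohorts:
        raise ConfigurationError("no cohorts to write")
    region_set = cohorts[0].region_set
    rows = []
    for cohort in cohorts:
        if cohort.region_set != region_set:
            raise ConfigurationError("cohorts disagree on region sets")
        for r in cohort.records:
            row = {
                "subject_id": r.subject_id,
                "group": r.group,
                "condition": r.condition,
                "age": float_fmt % r.age,
                "gender": r.gender,
            }
            row.update(
                {name: float_fmt % v for name, v in zip(region_set.names, r.bp)}
            )
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def write_contrast_report(result: ContrastResult, path, delimiter: str = ",") -> None:
    """Long-format report: one row per region pair, sorted by q then p.

    Columns: region_a, region_b, rho_a, rho_b, delta_rho, delta_z, p_perm,
    q_fdr, sig_uncorrected, sig_fdr. Floats carry 6 decimals.
    """
    names = result.region_set.names
    rows = []
    for i, j in result.region_set.pairs():
        rows.append(
            {
                "region_a": names[i],
                "region_b": names[j],
                "rho_a": result.rho_a[i, j],
                "rho_b": result.rho_b[i, j],
                "delta_rho": result.delta_rho[i, j],
                "delta_z": result.delta_z[i, j],
                "p_perm": result.p_perm[i, j],
                "q_fdr": result.q_fdr[i, j],
                "sig_uncorrected": bool(result.sig_uncorrected[i, j]),
                "sig_fdr": bool(result.sig_fdr[i, j]),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["q_fdr", "p_perm"], kind="stable"
    )
    df.to_csv(path, sep=delimiter, index=False, float_format="%.6f")


def read_contrast_report(path, delimiter: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=delimiter)


def write_correlation_matrix(matrix, path, delimiter: str = ",") -> None:
    """Square CSV of the correlation matrix with region names as labels."""
    names = list(matrix.region_set.names)
    pd.DataFrame(matrix.rho, index=names, columns=names).to_csv(
        path, sep=delimiter, float_format="%.6f"
    )


#: Approximate MNI centroids (mm) of the bilaterally averaged ROIs; x is the
#: across-hemisphere mean (midline for paired structures). Used for network
#: export when the caller supplies no coordinates.
DEFAULT_COORDS: dict[str, tuple[float, float, float]] = {
    "thalamus": (0.0, -18.0, 8.0),
    "putamen": (0.0, 2.0, 0.0),
    "caudate": (0.0, 10.0, 10.0),
    "pallidum": (0.0, -4.0, -1.0),
    "midbrain": (0.0, -28.0, -12.0),
    "hippocampus": (0.0, -22.0, -14.0),
    "amygdala": (0.0, -2.0, -20.0),
    "ACC": (0.0, 36.0, 16.0),
    "insula": (0.0, 4.0, 2.0),
}


def export_network(
    result: ContrastResult,
    node_path,
    edge_path,
    node_coords: Mapping[str, tuple[float, float, float]] | None = None,
    edge_field: str = "delta_rho",
    mask: str = "sig_fdr",
) -> None:
    """Write plain-text .node/.edge files for brain-network viewers.

    Node file: one row per region, ``x y z color size label``; color is 1,
    size the number of surviving edges at that region. Edge file: the chosen
    matrix (``delta_rho``, ``delta_z``, ...) with masked-out entries set to
    zero, space-delimited, k rows of k numbers.
    """
    names = result.region_set.names
    coords = dict(DEFAULT_COORDS) if node_coords is None else dict(node_coords)
    lookup = {k.strip().lower(): v for k, v in coords.items()}
    missing = [n for n in names if n.lower() not in lookup]
    if missing:
        raise ConfigurationError(f"missing coordinates for regions: {missing}")

    values = np.array(getattr(result, edge_field), dtype=float)
    if mask not in ("sig_fdr", "sig_uncorrected", "none"):
        raise ConfigurationError(f"unknown mask {mask!r}")
    if mask == "none":
        keep = ~np.eye(len(names), dtype=bool)
    else:
        keep = np.array(getattr(result, mask), dtype=bool)
    edges = np.where(keep, values, 0.0)
    edges = np.nan_to_num(edges, nan=0.0)

    degree = (edges != 0).sum(axis=1)
    with open(node_path, "w") as fh:
        for i, name in enumerate(names):
            x, y, z = lookup[name.lower()]
            fh.write(f"{x:.1f} {y:.1f} {z:.1f} 1 {int(degree[i])} {name}\n")
    with open(edge_path, "w") as fh:
        for row in edges:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
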