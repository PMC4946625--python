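"""CSV/JSON readers and writers for contrast data and partitions.

CSV dialect (UTF-8, comma, dot decimal).  Main file, one row per contrast:

    study,design,baseline,treatment,estimate,variance

Multi-arm within-study covariances live in a sidecar file named
``<stem>.cov.csv`` next to the main file:

    study,t1,t2,cov

Off-diagonal entries absent from the sidecar default to zero.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import ParseError
from .inference import ContrastDataset, StudyRecord
from .partitions import ConsistencyPartition, Design

__all__ = [
    "read_contrast_csv",
    "write_contrast_csv",
    "report_partition",
    "partition_from_dict",
    "cov_sidecar_path",
]

_MAIN_COLUMNS = ["study", "design", "baseline", "treatment", "estimate", "variance"]
_COV_COLUMNS = ["study", "t1", "t2", "cov"]


def cov_sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".cov.csv")


def _check_header(actual: list[str] | None, expected: list[str], path: Path) -> None:
    if actual != expected:
        raise ParseError(
            f"{path}: expected header {','.join(expected)}, got "
            f"{','.join(actual) if actual else '<empty file>'}"
        )


def read_contrast_csv(
    path: str | Path, cov_path: str | Path | None = None
) -> ContrastDataset:
    """Read and validate a contrast dataset.

    Designs are inferred from each study's treatment set and must agree with
    the ``design`` column.  The covariance sidecar is auto-detected when
    ``cov_path`` is not given.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    rows_by_study: dict[str, list[dict]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, _MAIN_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            try:
                estimate = float(row["estimate"])
                variance = float(row["variance"])
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}:{lineno}: non-numeric estimate or variance"
                ) from None
            if variance <= 0:
                raise ParseError(f"{path}:{lineno}: variance must be positive")
            if row["treatment"] == row["baseline"]:
                raise ParseError(
                    f"{path}:{lineno}: treatment equals baseline "
                    f"({row['baseline']}); a design needs at least 2 treatments"
                )
            row = dict(row, estimate=estimate, variance=variance, lineno=lineno)
            rows_by_study.setdefault(row["study"], []).append(row)

    if not rows_by_study:
        raise ParseError(f"{path}: no data rows")

    cov_entries: dict[tuple[str, str, str], float] = {}
    sidecar = Path(cov_path) if cov_path is not None else cov_sidecar_path(path)
    if sidecar.exists():
        with sidecar.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            _check_header(reader.fieldnames, _COV_COLUMNS, sidecar)
            for lineno, row in enumerate(reader, start=2):
                try:
                    value = float(row["cov"])
                except (TypeError, ValueError):
                    raise ParseError(
                        f"{sidecar}:{lineno}: non-numeric covariance"
                    ) from None
                key = (row["study"], *sorted((row["t1"], row["t2"])))
                cov_entries[key] = value

    records = []
    for study, rows in rows_by_study.items():
        baselines = {r["baseline"] for r in rows}
        if len(baselines) != 1:
            raise ParseError(
                f"{path}: study {study} lists multiple baselines {sorted(baselines)}"
            )
        baseline = baselines.pop()
        treatments = tuple(sorted(r["treatment"] for r in rows))
        if len(set(treatments)) != len(treatments):
            raise ParseError(f"{path}: study {study} repeats a treatment row")
        design = Design({baseline, *treatments})
        declared = {r["design"] for r in rows}
        if declared != {design.label}:
            raise ParseError(
                f"{path}: study {study} design column {sorted(declared)} does "
                f"not match its arms ({design.label})"
            )
        by_treatment = {r["treatment"]: r for r in rows}
        k = len(treatments)
        cov = np.zeros((k, k))
        for i, t in enumerate(treatments):
            cov[i, i] = by_treatment[t]["variance"]
            for j in range(i + 1, k):
                cov[i, j] = cov[j, i] = cov_entries.get(
                    (study, *sorted((t, treatments[j]))), 0.0
                )
        try:
            record = StudyRecord(
                study=study,
                design=design,
                baseline=baseline,
                treatments=treatments,
                estimates=np.array([by_treatment[t]["estimate"] for t in treatments]),
                covariance=cov,
            )
        except Exception as exc:
            lineno = rows[0]["lineno"]
            raise ParseError(f"{path}:{lineno}: study {study}: {exc}") from None
        records.append(record)
    return ContrastDataset(records)


def write_contrast_csv(dataset: ContrastDataset, path: str | Path) -> Path:
    """Write a dataset in the canonical dialect; returns the main file path.

    A covariance sidecar is written whenever any study has more than one
    contrast.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MAIN_COLUMNS)
        for r in dataset.records:
            for i, t in enumerate(r.treatments):
                writer.writerow(
                    [
                        r.study,
                        r.design.label,
                        r.baseline,
                        t,
                        repr(float(r.estimates[i])),
                        repr(float(r.covariance[i, i])),
                    ]
                )
    if any(r.n_contrasts > 1 for r in dataset.records):
        with cov_sidecar_path(path).open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(_COV_COLUMNS)
            for r in dataset.records:
                for i in range(r.n_contrasts):
                    for j in range(i + 1, r.n_contrasts):
                        writer.writerow(
                            [
                                r.study,
                                r.treatments[i],
                                r.treatments[j],
                                repr(float(r.covariance[i, j])),
                            ]
                        )
    return path


def report_partition(p: ConsistencyPartition, format: str = "text") -> str:
    """Deterministic rendering of a partition as text or JSON."""
    if format == "json":
        treatments = sorted(frozenset().union(*(d.members for d in p.designs)))
        return json.dumps(
            {
                "treatments": treatments,
                "groups": p.group_labels(),
                "source": p.source,
            },
            indent=2,
        )
    if format == "text":
        lines = []
        if p.source:
            lines.append(f"# source: {p.source}")
        for i, group in enumerate(p.groups, start=1):
            lines.append(f"group {i}: " + ", ".join(d.label for d in group))
        return "\n".join(lines)
    raise ValueError(f"unknown format {format!r}")


def partition_from_dict(payload: Mapping) -> ConsistencyPartition:
    """Inverse of the JSON form produced by :func:`report_partition`."""
    groups = [
        [Design.parse(label) for label in group] for group in payload["groups"]
    ]
    return ConsistencyPartition(groups, source=payload.get("source"))
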