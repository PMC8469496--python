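"""Cohorts of per-sample CPD measurements: record types and tabular I/O.

A cohort file is one row per blood sample.  Columns whose headers parse as
CPD parameter names (``SD-V-NE``, ``mn_umals_ly``, ...) become measurement
values; everything else is routed to per-record metadata.  Missing cells
stay missing — a record is only "scoreable" for a rule if every parameter
the rule needs is present.

Diagnosis groups are free strings matched case-insensitively against a
label scheme that maps each fine group to a coarse screening class
(neoplastic / non-neoplastic).  The shipped default scheme places normal
and reactive samples in the non-neoplastic class and the leukaemia /
lymphoma / MDS groups in the neoplastic class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .parameters import CPDParameter, is_parameter_name, parse_parameter

NON_NEOPLASTIC = "non-neoplastic"
NEOPLASTIC = "neoplastic"

#: Default fine-group -> coarse-class scheme. "APML" is accepted as a
#: synonym of APL, as both spellings occur in the CPD literature.
DEFAULT_LABEL_SCHEME: dict[str, str] = {
    "normal": NON_NEOPLASTIC,
    "reactive": NON_NEOPLASTIC,
    "aml": NEOPLASTIC,
    "apl": NEOPLASTIC,
    "apml": NEOPLASTIC,
    "all": NEOPLASTIC,
    "lymphoma": NEOPLASTIC,
    "cll": NEOPLASTIC,
    "cml": NEOPLASTIC,
    "mds": NEOPLASTIC,
}


class CohortError(ValueError):
    """Raised for malformed cohort files or inconsistent cohorts."""


@dataclass
class CPDRecord:
    """One sample's CPD measurements plus metadata.

    ``values`` maps :class:`CPDParameter` to a finite, non-negative float
    (instrument channel units).  Absent parameters are simply not in the
    map.
    """

    sample_id: str
    values: dict[CPDParameter, float]
    group: str | None = None
    metadata: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for param, value in self.values.items():
            if not math.isfinite(value) or value < 0:
                raise CohortError(
                    f"sample {self.sample_id!r}: {param} value {value!r} "
                    "must be finite and >= 0"
                )

    def get(self, parameter: CPDParameter) -> float | None:
        return self.values.get(parameter)

    def is_scoreable(self, parameters: Iterable[CPDParameter]) -> bool:
        """True if every listed parameter is present on this record."""
        return all(p in self.values for p in parameters)


@dataclass
class Cohort:
    """Ordered collection of records with a coarse-class label scheme."""

    records: list[CPDRecord]
    label_scheme: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_SCHEME)
    )

    def __post_init__(self) -> None:
        self.label_scheme = {k.lower(): v for k, v in self.label_scheme.items()}
        seen: set[str] = set()
        for rec in self.records:
            if rec.sample_id in seen:
                raise CohortError(f"duplicate sample_id {rec.sample_id!r}")
            seen.add(rec.sample_id)
        for rec in self.records:
            if rec.group is not None and rec.group.lower() not in self.label_scheme:
                raise CohortError(
                    f"sample {rec.sample_id!r}: group {rec.group!r} not covered "
                    "by the label scheme"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CPDRecord]:
        return iter(self.records)

    def coarse_class(self, record: CPDRecord) -> str | None:
        """Coarse screening class of a record (None if unlabelled)."""
        if record.group is None:
            return None
        return self.label_scheme[record.group.lower()]

    def parameters(self) -> list[CPDParameter]:
        """Parameters present on at least one record, sorted."""
        seen: set[CPDParameter] = set()
        for rec in self.records:
            seen.update(rec.values)
        return sorted(seen)

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: one row per sample, parameter columns by name.

        Absent values appear as NaN.  ``sample_id`` and ``group`` come
        first, then metadata columns, then parameters in sorted order.
        """
        params = self.parameters()
        rows = []
        for rec in self.records:
            row: dict[str, object] = {"sample_id": rec.sample_id, "group": rec.group}
            row.update(rec.metadata)
            for p in params:
                row[str(p)] = rec.values.get(p, float("nan"))
            rows.append(row)
        return pd.DataFrame(rows)


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if header_line.count("\t") > header_line.count(",") else ","


def read_cohort(
    path: str | Path,
    label_scheme: Mapping[str, str] | None = None,
    extra_cell_types: Iterable[str] = (),
) -> Cohort:
    """Read a cohort from a CSV or TSV file.

    The delimiter is sniffed from the header row.  Columns named
    ``sample_id`` and ``group`` (case-insensitive) are routed to the
    corresponding record fields; other non-parameter columns become
    metadata.  Empty cells become absent values, never zeros.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise CohortError(f"{path}: empty file")
    sep = _sniff_delimiter(header)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    param_cols: dict[str, CPDParameter] = {}
    meta_cols: list[str] = []
    id_col = group_col = None
    for col in df.columns:
        low = col.strip().lower()
        if low == "sample_id":
            id_col = col
        elif low == "group":
            group_col = col
        elif is_parameter_name(col, extra_cell_types):
            param_cols[col] = parse_parameter(col, extra_cell_types)
        else:
            meta_cols.append(col)
    if not param_cols:
        raise CohortError(f"{path}: no column parses as a CPD parameter name")

    records: list[CPDRecord] = []
    for i, row in df.iterrows():
        sample_id = row[id_col] if id_col is not None else f"sample-{i + 1}"
        group = row[group_col] if group_col is not None else None
        if group is not None and group.strip() == "":
            group = None
        values: dict[CPDParameter, float] = {}
        for col, param in param_cols.items():
            cell = row[col].strip()
            if cell == "":
                continue
            try:
                values[param] = float(cell)
            except ValueError:
                raise CohortError(
                    f"{path}: sample {sample_id!r}, column {col!r}: "
                    f"cannot parse value {cell!r}"
                ) from None
        metadata = {c: row[c] for c in meta_cols}
        records.append(CPDRecord(str(sample_id), values, group, metadata))

    scheme = dict(label_scheme) if label_scheme is not None else dict(DEFAULT_LABEL_SCHEME)
    return Cohort(records, scheme)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as CSV with full decimal precision.

    ``read_cohort(write_cohort(c))`` reproduces values bit-exactly (floats
    are written with ``repr`` round-trip precision), preserves record
    order, and keeps absent cells absent.
    """
    path = Path(path)
    params = cohort.parameters()
    meta_keys: list[str] = []
    for rec in cohort.records:
        for k in rec.metadata:
            if k not in meta_keys:
                meta_keys.append(k)
    header = ["sample_id", "group", *meta_keys, *(str(p) for p in params)]
    lines = [",".join(header)]
    for rec in cohort.records:
        cells = [rec.sample_id, rec.group or ""]
        cells += [str(rec.metadata.get(k, "")) for k in meta_keys]
        for p in params:
            v = rec.values.get(p)
            cells.append("" if v is None else repr(float(v)))
        lines.append(",".join(cells))
    path.write_text("\n".join(lines) + "\n")
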