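"""Reading and writing expression matrices, sample sheets, annotations and call tables.

All on-disk formats are tab-separated text.  Expression matrices additionally
support the GEO series-matrix dialect, in which lines beginning with ``!`` are
metadata and the data table is delimited by ``!series_matrix_table_begin`` /
``!series_matrix_table_end`` markers.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from dyndiff.errors import ParseError, ValidationError

logger = logging.getLogger("dyndiff")

#: An expression matrix is a probes-x-samples DataFrame of non-negative reals
#: with unique string row (probe) and column (sample) identifiers.
ExpressionMatrix = pd.DataFrame

PARENTAL = "parental"
ONCOGENE = "oncogene"
_LINE_LABELS = (PARENTAL, ONCOGENE)


@dataclass(frozen=True)
class SampleSheet:
    """Maps sample ids to cell line and hours since inhibitor addition."""

    table: pd.DataFrame  # columns: sample_id, cell_line, time_hours

    def __post_init__(self) -> None:
        t = self.table
        required = {"sample_id", "cell_line", "time_hours"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
        if t["sample_id"].duplicated().any():
            dupes = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids in sheet: {dupes}")
        bad = set(t["cell_line"]) - set(_LINE_LABELS)
        if bad:
            raise ValidationError(
                f"unknown cell line labels {sorted(bad)}; expected one of {_LINE_LABELS}"
            )
        pairs = t[["cell_line", "time_hours"]].apply(tuple, axis=1)
        if pairs.duplicated().any():
            raise ValidationError(
                "duplicate (cell line, time) pairs: "
                f"{sorted(set(pairs[pairs.duplicated()]))}"
            )

    def samples_for(self, line: str) -> pd.DataFrame:
        sub = self.table[self.table["cell_line"] == line]
        return sub.sort_values("time_hours")


@dataclass
class TimeSeriesExperiment:
    """Matched intensity matrices for two cell lines on one shared time grid.

    ``parental`` and ``oncogene`` are features-x-timepoints DataFrames whose
    columns are the time grid in hours (floats, strictly increasing, first
    element 0).  ``annotation`` optionally maps probe ids to gene symbols.
    """

    times: np.ndarray
    parental: pd.DataFrame
    oncogene: pd.DataFrame
    annotation: pd.Series | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValidationError("time grid must be 1-D with at least two points")
        if not np.all(np.diff(self.times) > 0):
            raise ValidationError("time grid must be strictly increasing")
        if self.times[0] != 0.0:
            raise ValidationError(
                "time grid must include t=0: normalization to the zero "
                "time point is undefined without it"
            )
        for name, m in (("parental", self.parental), ("oncogene", self.oncogene)):
            if list(m.columns) != list(self.times):
                raise ValidationError(f"{name} matrix columns do not match the time grid")
        if not self.parental.index.equals(self.oncogene.index):
            raise ValidationError("parental and oncogene matrices differ in probe universe")

    @property
    def feature_ids(self) -> pd.Index:
        return self.parental.index

    def line(self, label: str) -> pd.DataFrame:
        if label == PARENTAL:
            return self.parental
        if label == ONCOGENE:
            return self.oncogene
        raise KeyError(label)

    def with_matrices(
        self, parental: pd.DataFrame, oncogene: pd.DataFrame
    ) -> "TimeSeriesExperiment":
        return TimeSeriesExperiment(
            times=self.times, parental=parental, oncogene=oncogene,
            annotation=self.annotation,
        )


# ---------------------------------------------------------------------------
# expression-matrix readers / writers
# ---------------------------------------------------------------------------

def _geo_table_lines(lines: Iterable[str]) -> list[str]:
    """Extract the data-table lines from a GEO series-matrix file.

    If begin/end markers are present the table is taken between them;
    otherwise every non-metadata (non-``!``) line is used.
    """
    out: list[str] = []
    in_table = False
    saw_marker = False
    for ln in lines:
        stripped = ln.strip("\n")
        if stripped.startswith("!series_matrix_table_begin"):
            in_table, saw_marker = True, True
            continue
        if stripped.startswith("!series_matrix_table_end"):
            in_table = False
            continue
        if saw_marker:
            if in_table and stripped:
                out.append(stripped)
        elif not stripped.startswith("!") and stripped:
            out.append(stripped)
    return out


def read_expression_matrix(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a probes-x-samples intensity matrix from tab-separated text.

    Parameters
    ----------
    path:
        File with a header row of sample ids and probe ids in the first column.
    dialect:
        ``"tsv"`` for a plain table, ``"geo"`` for the GEO series-matrix
        dialect (``!``-prefixed metadata lines are skipped, quoted identifiers
        unquoted).

    Raises
    ------
    ParseError
        On ragged rows, duplicate probe ids or non-numeric cells, naming the
        offending row/column.
    """
    path = Path(path)
    if dialect not in ("tsv", "geo"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, newline="") as fh:
        if dialect == "geo":
            rows = [r for r in csv.reader(_geo_table_lines(fh), delimiter="\t")]
        else:
            rows = [r for r in csv.reader(fh, delimiter="\t") if r]
    if not rows:
        raise ParseError(f"{path}: empty file")

    def unquote(s: str) -> str:
        s = s.strip()
        if len(s) >= 2 and s[0] == '"' and s[-1] == '"':
            return s[1:-1]
        return s

    header = [unquote(c) for c in rows[0]]
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise ParseError(f"{path}: duplicate sample ids {dupes}")
    n_cols = len(header)
    probe_ids: list[str] = []
    values = np.empty((len(rows) - 1, n_cols - 1), dtype=float)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != n_cols:
            raise ParseError(
                f"{path}: row {i} has {len(row)} fields, expected {n_cols} (ragged row)"
            )
        probe_ids.append(unquote(row[0]))
        for j, cell in enumerate(row[1:]):
            try:
                values[i - 2, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell at row {i}, column "
                    f"{samples[j]!r}: {cell!r}"
                ) from None
    if len(set(probe_ids)) != len(probe_ids):
        seen: set[str] = set()
        dupes = sorted({p for p in probe_ids if p in seen or seen.add(p)})  # type: ignore[func-returns-value]
        raise ParseError(f"{path}: duplicate probe ids {dupes}")
    matrix = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"), columns=samples)
    if matrix.isna().any().any():
        raise ParseError(f"{path}: missing values are not supported")
    return matrix


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a tab-separated sample sheet (sample_id, cell_line, time_hours)."""
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cell_line": str})
    try:
        table["time_hours"] = table["time_hours"].astype(float)
    except (KeyError, ValueError) as exc:
        raise ParseError(f"{path}: bad sample sheet: {exc}") from exc
    return SampleSheet(table)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.Series:
    """Read a two-column probe-to-gene table; returns a probe-indexed Series."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise ParseError(f"{path}: annotation needs two columns (probe, gene)")
    probes, genes = table.columns[0], table.columns[1]
    if table[probes].duplicated().any():
        dupes = table.loc[table[probes].duplicated(), probes].tolist()
        raise ParseError(f"{path}: duplicate probe ids in annotation: {dupes}")
    return pd.Series(table[genes].values, index=table[probes].values, name="gene")


def write_annotation(annotation: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"probe_id": annotation.index, "gene": annotation.values}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# experiment assembly
# ---------------------------------------------------------------------------

def assemble_experiment(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    annotation: pd.Series | None = None,
) -> TimeSeriesExperiment:
    """Partition a sample matrix into per-line time series on a shared grid.

    Every matrix sample must appear in the sheet (and vice versa); both lines
    must be present, share an identical strictly-increasing time grid and
    include t=0.
    """
    sheet_ids = set(sheet.table["sample_id"])
    matrix_ids = set(matrix.columns)
    missing = sorted(matrix_ids - sheet_ids)
    if missing:
        raise ValidationError(f"samples absent from sample sheet: {missing}")
    extra = sorted(sheet_ids - matrix_ids)
    if extra:
        raise ValidationError(f"sheet samples absent from matrix: {extra}")

    per_line: dict[str, pd.DataFrame] = {}
    grids: dict[str, np.ndarray] = {}
    for line in _LINE_LABELS:
        sub = sheet.samples_for(line)
        if sub.empty:
            raise ValidationError(f"no samples for cell line {line!r}")
        times = sub["time_hours"].to_numpy(dtype=float)
        if 0.0 not in times:
            raise ValidationError(
                f"{line} series lacks t=0: normalization to the zero time "
                "point is undefined"
            )
        m = matrix[sub["sample_id"].tolist()].copy()
        m.columns = times
        per_line[line] = m
        grids[line] = times
    if not np.array_equal(grids[PARENTAL], grids[ONCOGENE]):
        raise ValidationError(
            "time grids differ between lines: "
            f"parental={grids[PARENTAL].tolist()} oncogene={grids[ONCOGENE].tolist()}"
        )
    return TimeSeriesExperiment(
        times=grids[PARENTAL],
        parental=per_line[PARENTAL],
        oncogene=per_line[ONCOGENE],
        annotation=annotation,
    )


# ---------------------------------------------------------------------------
# gene-call table writer / reader
# ---------------------------------------------------------------------------

CALL_COLUMNS = ["gene", "class", "max_abs_r", "time_of_extreme", "direction", "passed_prefilter"]


def write_gene_calls(calls, path: str | Path) -> None:
    """Write a call set as a tab-separated table.

    Rows are ordered by descending ``max_abs_r`` with ties broken
    lexicographically by gene id; an empty call set yields a header-only file.
    """
    frame = calls.to_frame()
    frame = frame.sort_values(
        ["max_abs_r", "gene"], ascending=[False, True], kind="mergesort"
    )
    frame.to_csv(path, sep="\t", index=False, columns=CALL_COLUMNS)


def read_gene_calls(path: str | Path):
    """Read a call table written by :func:`write_gene_calls`."""
    from dyndiff.dynamics import GeneCall, GeneCallSet

    table = pd.read_csv(path, sep="\t", dtype={"gene": str})
    calls = [
        GeneCall(
            gene=row["gene"],
            klass=row["class"],
            max_abs_r=float(row["max_abs_r"]),
            time_of_extreme=float(row["time_of_extreme"]),
            direction=row["direction"],
            passed_prefilter=bool(row["passed_prefilter"]),
        )
        for _, row in table.iterrows()
    ]
    return GeneCallSet(calls)
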