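"""Text-format I/O for expression matrices, sample sheets, truth tables and screen results.

All formats are plain tab-separated text with a header row, chosen to
mirror the layout of a GEO series-matrix export split into a value matrix
and a companion sample sheet:

* matrix TSV      — first column ``gene_id``, one column per sample,
  linear-scale abundances;
* sample sheet    — columns ``sample_id``, ``condition``, ``timepoint_h``,
  ``replicate``;
* truth TSV       — columns ``gene_id``, ``class_label``, ``peak_fold``
  (planted simulation ground truth);
* results TSV     — one row per gene with its temporal class label and
  per-timepoint fold changes / p-values.

Floats are serialized with ``repr`` (shortest round-trip representation,
>= 9 significant digits), so write -> read is lossless and the byte stream
is deterministic for a fixed input.
"""

from __future__ import annotations

import math
import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionIOError",
    "DuplicateIdentifierError",
    "MetadataMismatchError",
    "MatrixParseError",
    "ExpressionMatrix",
    "read_matrix",
    "write_matrix",
    "read_truth",
    "write_truth",
    "read_results_table",
    "write_results",
    "results_frame",
]

SAMPLE_SHEET_COLUMNS = ("sample_id", "condition", "timepoint_h", "replicate")

CONTROL_CONDITION = "control"


class ExpressionIOError(Exception):
    """Base class for matrix/sample-sheet format errors."""


class DuplicateIdentifierError(ExpressionIOError):
    """A gene or sample identifier occurs more than once."""


class MetadataMismatchError(ExpressionIOError):
    """A sample present in the matrix has no row in the sample sheet."""


class MatrixParseError(ExpressionIOError):
    """A cell could not be parsed as a number; names the row and column."""


def _fmt(value: float) -> str:
    """repr-faithful float formatting; integers stay readable."""
    f = float(value)
    if f.is_integer() and abs(f) < 1e15:
        return str(int(f))
    return repr(f)


@dataclass
class ExpressionMatrix:
    """A genes x samples abundance table with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene_id with one column per sample_id;
        linear-scale, non-negative abundances.
    samples
        DataFrame indexed by sample_id with columns ``condition``
        (``"control"`` or the injured/treated arm label), ``timepoint_h``
        (hours post injury, float) and ``replicate`` (int).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    floored_cells: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DuplicateIdentifierError(f"duplicate gene_id(s): {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise DuplicateIdentifierError(f"duplicate sample_id(s): {dups}")
        missing = [s for s in self.values.columns if s not in self.samples.index]
        if missing:
            raise MetadataMismatchError(
                f"sample(s) in matrix missing from sample sheet: {missing}"
            )
        self.samples = self.samples.loc[list(self.values.columns)].copy()
        self.samples["timepoint_h"] = self.samples["timepoint_h"].astype(float)
        self.samples["replicate"] = self.samples["replicate"].astype(int)
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise MatrixParseError("matrix contains non-finite values")
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise MatrixParseError("matrix contains negative abundances")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def timepoints_h(self) -> list[float]:
        return sorted(self.samples["timepoint_h"].unique().tolist())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.samples["condition"].unique().tolist())

    def select_samples(self, condition: str | None = None,
                       timepoint_h: float | None = None) -> list[str]:
        """Sample ids matching the given condition and/or exact timepoint."""
        mask = pd.Series(True, index=self.samples.index)
        if condition is not None:
            mask &= self.samples["condition"] == condition
        if timepoint_h is not None:
            mask &= self.samples["timepoint_h"] == float(timepoint_h)
        return list(self.samples.index[mask])

    def floored(self, floor: float | None = None) -> "ExpressionMatrix":
        """Return a copy with non-positive cells raised to the positivity floor.

        The floor defaults to half the smallest strictly positive value in
        the matrix; the number of raised cells is recorded in
        ``floored_cells``.  Background-subtracted array matrices
        occasionally contain zeros or small negatives, which would break
        the log transform downstream.
        """
        arr = self.values.to_numpy(dtype=float)
        nonpos = arr <= 0
        n_flagged = int(nonpos.sum())
        if n_flagged == 0:
            return ExpressionMatrix(self.values.copy(), self.samples.copy(), 0)
        if floor is None:
            positives = arr[arr > 0]
            if positives.size == 0:
                raise MatrixParseError("matrix has no positive values to derive a floor")
            floor = float(positives.min()) / 2.0
        fixed = arr.copy()
        fixed[nonpos] = floor
        out = pd.DataFrame(fixed, index=self.values.index, columns=self.values.columns)
        return ExpressionMatrix(out, self.samples.copy(), n_flagged)


def _atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write text to ``path`` atomically (temp file + rename)."""
    directory = os.path.dirname(os.fspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="\n") as handle:
            handle.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_matrix(matrix: ExpressionMatrix, matrix_path, sample_sheet_path) -> None:
    """Write the matrix TSV and its companion sample sheet."""
    lines = ["\t".join(["gene_id", *matrix.sample_ids])]
    arr = matrix.values.to_numpy(dtype=float)
    for gene, row in zip(matrix.gene_ids, arr):
        lines.append("\t".join([str(gene), *[_fmt(v) for v in row]]))
    _atomic_write_text(matrix_path, "\n".join(lines) + "\n")

    sheet = ["\t".join(SAMPLE_SHEET_COLUMNS)]
    for sid, meta in matrix.samples.iterrows():
        sheet.append("\t".join([
            str(sid), str(meta["condition"]),
            _fmt(meta["timepoint_h"]), str(int(meta["replicate"])),
        ]))
    _atomic_write_text(sample_sheet_path, "\n".join(sheet) + "\n")


def read_matrix(matrix_path, sample_sheet_path) -> ExpressionMatrix:
    """Read a matrix TSV and sample sheet; validates identifiers and cells.

    Round-trips with :func:`write_matrix` (content identity, sample order
    preserved).
    """
    raw = pd.read_csv(matrix_path, sep="\t", dtype=str)
    if raw.columns[0] != "gene_id":
        raise MatrixParseError(
            f"{matrix_path}: first column must be 'gene_id', got {raw.columns[0]!r}"
        )
    gene_ids = raw["gene_id"].astype(str)
    if gene_ids.duplicated().any():
        dups = gene_ids[gene_ids.duplicated()].unique().tolist()
        raise DuplicateIdentifierError(f"{matrix_path}: duplicate gene row(s) {dups}")
    body = raw.drop(columns=["gene_id"])
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & body.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise MatrixParseError(
            f"{matrix_path}: non-numeric cell at gene {gene_ids.iloc[r]!r}, "
            f"sample {body.columns[c]!r}: {body.iat[r, c]!r}"
        )
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise MatrixParseError(
            f"{matrix_path}: empty cell at gene {gene_ids.iloc[r]!r}, "
            f"sample {body.columns[c]!r}"
        )
    # numpy's str->float conversion is correctly rounded; pandas' default
    # converter can be off in the last bit, breaking lossless round-trips
    values = pd.DataFrame(body.to_numpy(dtype=str).astype(np.float64),
                          index=pd.Index(gene_ids, name="gene_id"),
                          columns=body.columns)

    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype=str)
    missing_cols = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing_cols:
        raise MatrixParseError(
            f"{sample_sheet_path}: missing column(s) {missing_cols}"
        )
    if sheet["sample_id"].duplicated().any():
        dups = sheet["sample_id"][sheet["sample_id"].duplicated()].unique().tolist()
        raise DuplicateIdentifierError(f"{sample_sheet_path}: duplicate sample(s) {dups}")
    samples = sheet.set_index("sample_id")
    absent = [s for s in values.columns if s not in samples.index]
    if absent:
        raise MetadataMismatchError(
            f"sample(s) {absent} present in {matrix_path} but missing from "
            f"{sample_sheet_path}"
        )
    try:
        samples["timepoint_h"] = samples["timepoint_h"].astype(float)
        samples["replicate"] = samples["replicate"].astype(int)
    except ValueError as exc:
        raise MatrixParseError(f"{sample_sheet_path}: {exc}") from exc
    return ExpressionMatrix(values, samples)


# ---------------------------------------------------------------------------
# truth tables


def write_truth(truth: dict[str, tuple[str, float]], path) -> None:
    """Write planted ground truth as TSV (gene_id, class_label, peak_fold)."""
    lines = ["gene_id\tclass_label\tpeak_fold"]
    for gene, (label, peak) in truth.items():
        lines.append(f"{gene}\t{label}\t{_fmt(peak)}")
    _atomic_write_text(path, "\n".join(lines) + "\n")


def read_truth(path) -> dict[str, tuple[str, float]]:
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "class_label": str})
    return {
        row.gene_id: (row.class_label, float(row.peak_fold))
        for row in frame.itertuples()
    }


# ---------------------------------------------------------------------------
# screen results

def results_frame(result) -> pd.DataFrame:
    """Flatten a ScreenResult into the ranked results table.

    Rows are sorted by (class_label, descending max fold change, gene_id)
    so the candidate list is stable and human-scannable.
    """
    timepoints = result.timepoints
    rows = []
    for gene in result.labels:
        profile = result.profiles[gene]
        max_fc = max((profile.fold_change[t] for t in timepoints if t > 0),
                     default=1.0)
        row: dict[str, object] = {
            "gene_id": gene,
            "class_label": result.labels[gene],
            "max_fold_change": max_fc,
        }
        for t in timepoints:
            row[f"fc_{_fmt(t)}h"] = profile.fold_change[t]
            p = profile.p_value.get(t, math.nan)
            row[f"p_{_fmt(t)}h"] = p
        rows.append(row)
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values(
            by=["class_label", "max_fold_change", "gene_id"],
            ascending=[True, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
    return frame


def write_results(result, path) -> None:
    """Write a ScreenResult as a deterministic ranked TSV."""
    frame = results_frame(result)
    if frame.empty:
        timepoints = getattr(result, "timepoints", [])
        header = ["gene_id", "class_label", "max_fold_change"]
        for t in timepoints:
            header += [f"fc_{_fmt(t)}h", f"p_{_fmt(t)}h"]
        _atomic_write_text(path, "\t".join(header) + "\n")
        return
    lines = ["\t".join(frame.columns)]
    for _, row in frame.iterrows():
        cells = []
        for col, value in row.items():
            if col in ("gene_id", "class_label"):
                cells.append(str(value))
            elif isinstance(value, float) and math.isnan(value):
                cells.append("NA")
            else:
                cells.append(_fmt(float(value)))
        lines.append("\t".join(cells))
    _atomic_write_text(path, "\n".join(lines) + "\n")


def read_results_table(path) -> pd.DataFrame:
    """Read a results TSV back as a DataFrame (labels as strings, NA -> NaN)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"],
                       dtype={"gene_id": str, "class_label": str})
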