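"""Readers and writers for the file formats handled by the pipeline.

Supported formats: GEO-style series matrix (``!Sample_*`` metadata lines
plus a ``!series_matrix_table_begin`` ... ``end`` block), MAGE-TAB (SDRF
sample table + tab-delimited data matrix), Affymetrix-style platform
annotation tables, and the TSV/CSV export dialect used for all outputs.

Export dialect conventions (fixed here, not by any upstream format):

* matrix files: line 1 is an empty leading field followed by the sample
  names, so every line has the same field count; each following line is a
  probe id and its values with at least 10 significant digits;
* metadata files: header ``sample_id`` + attribute names, one row per
  sample;
* TSV never quotes fields (a delimiter inside an id is an error); CSV uses
  RFC-style minimal quoting and accepts a custom single-char delimiter;
* UTF-8 encoding, LF written, LF/CRLF accepted on read.
"""

from __future__ import annotations

import csv
import io
import logging
from pathlib import Path

import numpy as np

from tacitus.types import ExpressionMatrix, FormatError, PlatformAnnotation, SampleMetadata

logger = logging.getLogger(__name__)

#: Annotation cell contents treated as "no identifier".
NULL_TOKENS = ("", "---", "NA")

#: Separator for multi-valued annotation cells; only the first token is kept.
MULTI_VALUE_SEP = " /// "

# 17 significant digits round-trips IEEE doubles exactly
_FLOAT_FMT = "{:.17g}"


# ---------------------------------------------------------------------------
# helpers


def _open_read(path: str | Path) -> io.TextIOWrapper:
    return open(path, "r", encoding="utf-8", newline="")


def _resolve_delimiter(dialect: str, delimiter: str | None) -> str:
    if dialect == "tsv":
        if delimiter not in (None, "\t"):
            raise FormatError("tsv dialect uses a tab delimiter; do not override it")
        return "\t"
    if dialect == "csv":
        delim = delimiter if delimiter is not None else ","
        if len(delim) != 1:
            raise FormatError(f"delimiter must be a single character, got {delim!r}")
        return delim
    raise FormatError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")


def _parse_float(cell: str, line_no: int, col: int, path: str | Path) -> float:
    try:
        return float(cell)
    except ValueError:
        raise FormatError(
            f"{path}: non-numeric value {cell!r} at line {line_no}, column {col + 1}"
        ) from None


def _impute_missing(values: np.ndarray, probe_ids: list[str], source: str) -> np.ndarray:
    """Replace NaN entries with the row mean (rows must not be all-NaN)."""
    n_missing = int(np.isnan(values).sum())
    if n_missing == 0:
        return values
    for r in range(values.shape[0]):
        row = values[r]
        mask = np.isnan(row)
        if not mask.any():
            continue
        if mask.all():
            raise FormatError(f"{source}: probe {probe_ids[r]!r} has no numeric values")
        row[mask] = row[~mask].mean()
    logger.warning("%s: imputed %d missing values with row means", source, n_missing)
    return values


_MISSING_CELLS = {"", "null", "NULL", "NA", "NaN", "nan"}


def _cell_to_float(cell: str, line_no: int, col: int, path: str | Path) -> float:
    if cell in _MISSING_CELLS:
        return float("nan")
    return _parse_float(cell, line_no, col, path)


# ---------------------------------------------------------------------------
# GEO series matrix


def read_series_matrix(path: str | Path) -> tuple[ExpressionMatrix, SampleMetadata]:
    """Parse a GEO-style series matrix file.

    Returns the expression matrix (columns ordered as the table header) and
    the per-sample metadata assembled from the ``!Sample_*`` lines.
    """
    attr_lines: list[tuple[str, list[str]]] = []
    table_rows: list[tuple[int, list[str]]] = []
    in_table = False
    table_seen = False
    with _open_read(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                table_seen = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                if line:
                    table_rows.append((line_no, line.split("\t")))
                continue
            if line.startswith("!Sample_"):
                key, _, rest = line.partition("\t")
                name = key[len("!Sample_") :]
                values = [_unquote(v) for v in rest.split("\t")] if rest else []
                attr_lines.append((name, values))
    if not table_seen:
        raise FormatError(f"{path}: missing !series_matrix_table_begin block")
    if not table_rows:
        raise FormatError(f"{path}: series matrix table block has no header row")

    header_no, header = table_rows[0]
    sample_ids = [_unquote(c) for c in header[1:]]
    n_samples = len(sample_ids)

    probe_ids: list[str] = []
    seen: set[str] = set()
    data = np.empty((len(table_rows) - 1, n_samples), dtype=float)
    for r, (line_no, row) in enumerate(table_rows[1:]):
        if len(row) != n_samples + 1:
            raise FormatError(
                f"{path}: ragged table row at line {line_no} "
                f"({len(row)} fields, expected {n_samples + 1})"
            )
        probe = _unquote(row[0])
        if probe in seen:
            raise FormatError(f"{path}: duplicated probe id {probe!r} at line {line_no}")
        seen.add(probe)
        probe_ids.append(probe)
        for c, cell in enumerate(row[1:]):
            data[r, c] = _cell_to_float(cell, line_no, c + 1, path)
    data = _impute_missing(data, probe_ids, str(path))

    # Duplicate !Sample_* names (common for characteristics lines) get a
    # numeric suffix so each becomes a distinct attribute.
    attributes: list[str] = []
    table: dict[str, dict[str, str]] = {s: {} for s in sample_ids}
    counts: dict[str, int] = {}
    for name, values in attr_lines:
        k = counts.get(name, 0)
        counts[name] = k + 1
        attr = name if k == 0 else f"{name}.{k}"
        attributes.append(attr)
        for i, sid in enumerate(sample_ids):
            table[sid][attr] = values[i] if i < len(values) else ""

    matrix = ExpressionMatrix(probe_ids, sample_ids, data)
    metadata = SampleMetadata(sample_ids, attributes, table)
    return matrix, metadata


def _unquote(value: str) -> str:
    if len(value) >= 2 and value[0] == '"' and value[-1] == '"':
        return value[1:-1]
    return value


def write_series_matrix(
    matrix: ExpressionMatrix, metadata: SampleMetadata, path: str | Path
) -> None:
    """Emit ``matrix``/``metadata`` as a toy series matrix file (fixture writer)."""
    if matrix.sample_ids != metadata.sample_ids:
        raise FormatError("matrix and metadata sample ids differ")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for attr in metadata.attributes:
            cells = "\t".join(f'"{metadata.value(s, attr)}"' for s in matrix.sample_ids)
            fh.write(f"!Sample_{attr}\t{cells}\n")
        fh.write("!series_matrix_table_begin\n")
        fh.write("\t".join(['"ID_REF"'] + [f'"{s}"' for s in matrix.sample_ids]) + "\n")
        for r, probe in enumerate(matrix.probe_ids):
            vals = "\t".join(_FLOAT_FMT.format(v) for v in matrix.values[r])
            fh.write(f'"{probe}"\t{vals}\n' if vals else f'"{probe}"\n')
        fh.write("!series_matrix_table_end\n")


# ---------------------------------------------------------------------------
# MAGE-TAB


def read_magetab(
    sdrf_path: str | Path, matrix_path: str | Path
) -> tuple[ExpressionMatrix, SampleMetadata]:
    """Parse a MAGE-TAB SDRF table plus its tab-delimited data matrix.

    Sample ids come from the first SDRF column and are matched by exact
    string against the matrix column headers; SDRF rows without a matrix
    column (and matrix columns without an SDRF row) are dropped with a
    warning.
    """
    with _open_read(sdrf_path) as fh:
        sdrf_rows = [line.rstrip("\r\n").split("\t") for line in fh if line.strip()]
    if len(sdrf_rows) < 1:
        raise FormatError(f"{sdrf_path}: empty SDRF")
    sdrf_header = sdrf_rows[0]
    attributes = sdrf_header[1:]
    sdrf_table: dict[str, dict[str, str]] = {}
    sdrf_order: list[str] = []
    for row in sdrf_rows[1:]:
        row = row + [""] * (len(sdrf_header) - len(row))
        sid = row[0]
        sdrf_order.append(sid)
        sdrf_table[sid] = dict(zip(attributes, row[1:]))

    with _open_read(matrix_path) as fh:
        lines = [line.rstrip("\r\n") for line in fh]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise FormatError(f"{matrix_path}: empty data matrix")
    mat_header = lines[0].split("\t")
    mat_samples = mat_header[1:]

    shared = [s for s in mat_samples if s in sdrf_table]
    if not shared:
        raise FormatError(
            f"no overlapping sample names between {sdrf_path} and {matrix_path}"
        )
    dropped_sdrf = [s for s in sdrf_order if s not in set(mat_samples)]
    if dropped_sdrf:
        logger.warning(
            "%s: %d SDRF samples absent from data matrix, dropped: %s",
            sdrf_path,
            len(dropped_sdrf),
            dropped_sdrf,
        )
    dropped_mat = [s for s in mat_samples if s not in sdrf_table]
    if dropped_mat:
        logger.warning(
            "%s: %d matrix columns absent from SDRF, dropped: %s",
            matrix_path,
            len(dropped_mat),
            dropped_mat,
        )

    keep_cols = [i for i, s in enumerate(mat_samples) if s in sdrf_table]
    probe_ids: list[str] = []
    data = np.empty((len(lines) - 1, len(keep_cols)), dtype=float)
    for r, line in enumerate(lines[1:]):
        row = line.split("\t")
        if len(row) != len(mat_header):
            raise FormatError(
                f"{matrix_path}: ragged row at line {r + 2} "
                f"({len(row)} fields, expected {len(mat_header)})"
            )
        probe_ids.append(row[0])
        for c, col in enumerate(keep_cols):
            data[r, c] = _cell_to_float(row[col + 1], r + 2, col + 1, matrix_path)
    data = _impute_missing(data, probe_ids, str(matrix_path))

    matrix = ExpressionMatrix(probe_ids, shared, data)
    metadata = SampleMetadata(
        shared, attributes, {s: dict(sdrf_table[s]) for s in shared}
    )
    return matrix, metadata


def write_magetab(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    sdrf_path: str | Path,
    matrix_path: str | Path,
) -> None:
    """Emit ``matrix``/``metadata`` as a toy SDRF + data matrix pair (fixture writer)."""
    if matrix.sample_ids != metadata.sample_ids:
        raise FormatError("matrix and metadata sample ids differ")
    with open(sdrf_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(["Source Name"] + metadata.attributes) + "\n")
        for sid in metadata.sample_ids:
            fh.write(
                "\t".join([sid] + [metadata.value(sid, a) for a in metadata.attributes])
                + "\n"
            )
    with open(matrix_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(["ID_REF"] + matrix.sample_ids) + "\n")
        for r, probe in enumerate(matrix.probe_ids):
            vals = [probe] + [_FLOAT_FMT.format(v) for v in matrix.values[r]]
            fh.write("\t".join(vals) + "\n")


# ---------------------------------------------------------------------------
# platform annotation tables


def read_platform_annotation(
    path: str | Path,
    probe_column: str,
    id_columns: dict[str, str],
    platform_id: str = "",
) -> PlatformAnnotation:
    """Parse a tab-delimited annotation table into a :class:`PlatformAnnotation`.

    ``id_columns`` maps table column names to identifier namespaces. Empty,
    ``---`` and ``NA`` cells become null identifiers; multi-valued cells
    keep the first ``" /// "``-separated token.
    """
    with _open_read(path) as fh:
        rows = [
            line.rstrip("\r\n").split("\t")
            for line in fh
            if line.strip() and not line.startswith(("#", "!"))
        ]
    if not rows:
        raise FormatError(f"{path}: no header row found")
    header = rows[0]
    col_index = {name: i for i, name in enumerate(header)}
    if probe_column not in col_index:
        raise FormatError(
            f"{path}: probe column {probe_column!r} not found; available: {header}"
        )
    missing = [c for c in id_columns if c not in col_index]
    if missing:
        raise FormatError(
            f"{path}: id columns {missing} not found; available: {header}"
        )

    probe_idx = col_index[probe_column]
    probe_ids: list[str] = []
    mapping: dict[str, dict[str, str | None]] = {}
    for row in rows[1:]:
        row = row + [""] * (len(header) - len(row))
        probe = row[probe_idx]
        entry: dict[str, str | None] = {}
        for col, namespace in id_columns.items():
            cell = row[col_index[col]].strip()
            if cell in NULL_TOKENS:
                entry[namespace] = None
            else:
                entry[namespace] = cell.split(MULTI_VALUE_SEP)[0].strip()
        probe_ids.append(probe)
        mapping[probe] = entry
    return PlatformAnnotation(
        platform_id=platform_id or str(path),
        probe_ids=probe_ids,
        namespaces=list(id_columns.values()),
        mapping=mapping,
    )


# ---------------------------------------------------------------------------
# TSV/CSV export dialect


def _check_bare_field(field: str, delimiter: str, what: str) -> None:
    if delimiter in field:
        raise FormatError(f"{what} {field!r} contains the delimiter {delimiter!r}")
    if "\n" in field or "\r" in field:
        raise FormatError(f"{what} {field!r} contains a newline")


def write_table(
    matrix: ExpressionMatrix,
    path: str | Path,
    dialect: str = "tsv",
    delimiter: str | None = None,
) -> None:
    """Write an expression matrix in the export dialect.

    Line 1 holds an empty leading field then the sample names; each further
    line holds a probe id and the row's values.
    """
    delim = _resolve_delimiter(dialect, delimiter)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if dialect == "csv":
            writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
            writer.writerow([""] + matrix.sample_ids)
            for r, probe in enumerate(matrix.probe_ids):
                writer.writerow([probe] + [_FLOAT_FMT.format(v) for v in matrix.values[r]])
        else:
            for sid in matrix.sample_ids:
                _check_bare_field(sid, delim, "sample id")
            fh.write(delim + delim.join(matrix.sample_ids) + "\n")
            for r, probe in enumerate(matrix.probe_ids):
                _check_bare_field(probe, delim, "probe id")
                cells = [probe] + [_FLOAT_FMT.format(v) for v in matrix.values[r]]
                fh.write(delim.join(cells) + "\n")


def read_table(
    path: str | Path,
    dialect: str = "tsv",
    delimiter: str | None = None,
    scale: str = "log2_intensity",
) -> ExpressionMatrix:
    """Read a matrix written by :func:`write_table`."""
    delim = _resolve_delimiter(dialect, delimiter)
    with _open_read(path) as fh:
        if dialect == "csv":
            rows = [row for row in csv.reader(fh, delimiter=delim) if row]
        else:
            rows = [
                line.rstrip("\r\n").split(delim)
                for line in fh
                if line.rstrip("\r\n") != ""
            ]
    if not rows:
        raise FormatError(f"{path}: empty matrix file")
    header = rows[0]
    sample_ids = header[1:]  # leading field (usually empty) is ignored
    probe_ids: list[str] = []
    data = np.empty((len(rows) - 1, len(sample_ids)), dtype=float)
    for r, row in enumerate(rows[1:]):
        if len(row) != len(sample_ids) + 1:
            raise FormatError(
                f"{path}: ragged row at line {r + 2} "
                f"({len(row)} fields, expected {len(sample_ids) + 1})"
            )
        probe_ids.append(row[0])
        for c, cell in enumerate(row[1:]):
            data[r, c] = _parse_float(cell, r + 2, c + 1, path)
    return ExpressionMatrix(probe_ids, sample_ids, data, scale=scale)


def write_metadata(
    metadata: SampleMetadata,
    path: str | Path,
    dialect: str = "tsv",
    delimiter: str | None = None,
) -> None:
    """Write sample metadata: header ``sample_id`` + attributes, one row per sample."""
    delim = _resolve_delimiter(dialect, delimiter)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if dialect == "csv":
            writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
            writer.writerow(["sample_id"] + metadata.attributes)
            for sid in metadata.sample_ids:
                writer.writerow([sid] + [metadata.value(sid, a) for a in metadata.attributes])
        else:
            for name in ["sample_id"] + metadata.attributes:
                _check_bare_field(name, delim, "attribute name")
            fh.write(delim.join(["sample_id"] + metadata.attributes) + "\n")
            for sid in metadata.sample_ids:
                cells = [sid] + [metadata.value(sid, a) for a in metadata.attributes]
                for cell in cells:
                    _check_bare_field(cell, delim, "metadata value")
                fh.write(delim.join(cells) + "\n")


def read_metadata(
    path: str | Path, dialect: str = "tsv", delimiter: str | None = None
) -> SampleMetadata:
    """Read metadata written by :func:`write_metadata`."""
    delim = _resolve_delimiter(dialect, delimiter)
    with _open_read(path) as fh:
        if dialect == "csv":
            rows = [row for row in csv.reader(fh, delimiter=delim) if row]
        else:
            rows = [
                line.rstrip("\r\n").split(delim)
                for line in fh
                if line.rstrip("\r\n") != ""
            ]
    if not rows:
        raise FormatError(f"{path}: empty metadata file")
    header = rows[0]
    if not header or header[0] != "sample_id":
        raise FormatError(f"{path}: metadata header must start with 'sample_id'")
    attributes = header[1:]
    sample_ids: list[str] = []
    table: dict[str, dict[str, str]] = {}
    for r, row in enumerate(rows[1:]):
        if len(row) != len(header):
            raise FormatError(
                f"{path}: ragged row at line {r + 2} "
                f"({len(row)} fields, expected {len(header)})"
            )
        sid = row[0]
        sample_ids.append(sid)
        table[sid] = dict(zip(attributes, row[1:]))
    return SampleMetadata(sample_ids, attributes, table)
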