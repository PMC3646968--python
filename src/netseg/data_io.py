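"""Reading, filtering and writing of expression-like time-course matrices.

The central container is :class:`ExpressionMatrix`: rows are biological
entities (genes, proteins, metabolites), columns are ordered time points.
Filtering follows the standard pre-processing for network reconstruction
from expression time courses: drop profiles with missing values, profiles
without functional annotation (optional, user-supplied flags) and profiles
whose coefficient of variation falls below a floor.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from netseg.multseg import SegmentationResult

#: Tokens parsed as missing values (case-insensitive).
MISSING_TOKENS = frozenset({"", "na", "nan", "null"})


class MatrixParseError(ValueError):
    """Raised when a matrix file is malformed (names the offending line)."""


class FilterError(ValueError):
    """Raised when filtering removes every profile."""


@dataclass
class ExpressionMatrix:
    """n entities x T time points of real values.

    Parameters
    ----------
    entity_ids : sequence of str
        Unique row identifiers.
    time_labels : sequence of str
        Column labels; their order *is* the time order.
    values : ndarray of shape (n, T)
        Measurements; NaN marks a missing value (allowed only before
        filtering).
    """

    entity_ids: list[str]
    time_labels: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.entity_ids = [str(e) for e in self.entity_ids]
        self.time_labels = [str(t) for t in self.time_labels]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, T = self.values.shape
        if len(self.entity_ids) != n:
            raise ValueError(
                f"{len(self.entity_ids)} entity ids for {n} rows of values"
            )
        if len(self.time_labels) != T:
            raise ValueError(
                f"{len(self.time_labels)} time labels for {T} columns of values"
            )
        if T < 2:
            raise ValueError("at least 2 time points are required")
        if len(set(self.entity_ids)) != n:
            raise ValueError("entity ids must be unique")

    @property
    def n_entities(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.entity_ids, columns=self.time_labels
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            entity_ids=[str(i) for i in frame.index],
            time_labels=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
        )


#: entity_id -> has_annotation flag; entities absent from the map are
#: treated as unannotated.
AnnotationMap = Mapping[str, bool]


def _parse_cell(token: str, line_no: int, path: str) -> float:
    token = token.strip()
    if token.lower() in MISSING_TOKENS:
        return math.nan
    try:
        return float(token)
    except ValueError:
        raise MatrixParseError(
            f"{path}, line {line_no}: non-numeric value {token!r}"
        ) from None


def read_matrix(path: str | Path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a delimited entities-by-time matrix.

    The first row holds the time labels, the first column the entity ids.
    Empty cells and the tokens NA/NaN/null (any case) are read as missing.

    Raises
    ------
    MatrixParseError
        On ragged rows or non-numeric cells, naming the offending line.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        rows = [row for row in reader]
    rows = [row for row in rows if any(cell.strip() for cell in row)]
    if len(rows) < 2:
        raise MatrixParseError(f"{path}: expected a header row and data rows")
    header = rows[0]
    # Header may or may not carry a leading corner label for the id column:
    # data rows are either as wide as the header (corner present) or one
    # field wider (corner absent).
    h = len(header)
    if len(rows[1]) == h:
        time_labels = [lbl.strip() for lbl in header[1:]]
        data_width = h
    elif len(rows[1]) == h + 1:
        time_labels = [lbl.strip() for lbl in header]
        data_width = h + 1
    else:
        raise MatrixParseError(
            f"{path}, line 2: expected {h} or {h + 1} fields to match the "
            f"header, found {len(rows[1])}"
        )
    entity_ids: list[str] = []
    values: list[list[float]] = []
    for line_no, row in enumerate(rows[1:], start=2):
        if len(row) != data_width:
            raise MatrixParseError(
                f"{path}, line {line_no}: expected {data_width} fields, "
                f"found {len(row)}"
            )
        entity_ids.append(row[0].strip())
        values.append([_parse_cell(c, line_no, str(path)) for c in row[1:]])
    return ExpressionMatrix(entity_ids, time_labels, np.array(values))


def write_matrix(
    matrix: ExpressionMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write a matrix in the format :func:`read_matrix` reads.

    Values are written with shortest round-trip float formatting so a
    read-back reproduces them bit-identically.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["entity_id", *matrix.time_labels])
        for eid, row in zip(matrix.entity_ids, matrix.values):
            writer.writerow(
                [eid, *(repr(float(v)) if not math.isnan(v) else "NA" for v in row)]
            )


def read_annotations(path: str | Path, delimiter: str = "\t") -> dict[str, bool]:
    """Read a two-column (entity_id, 0/1) annotation flag file."""
    out: dict[str, bool] = {}
    with Path(path).open(newline="") as fh:
        for line_no, row in enumerate(csv.reader(fh, delimiter=delimiter), 1):
            if not row or not any(c.strip() for c in row):
                continue
            if len(row) < 2:
                raise MatrixParseError(
                    f"{path}, line {line_no}: expected (entity_id, flag)"
                )
            out[row[0].strip()] = row[1].strip() not in {"0", "false", "False"}
    return out


def coefficient_of_variation(row: np.ndarray) -> float:
    """Sample standard deviation over absolute mean; +inf for a near-zero mean."""
    sd = float(np.std(row, ddof=1))
    mean = abs(float(np.mean(row)))
    if mean < np.finfo(float).eps:
        return math.inf
    return sd / mean


def filter_matrix(
    matrix: ExpressionMatrix,
    annotations: AnnotationMap | None = None,
    cv_min: float = 1.0,
    log_scale: bool = False,
) -> ExpressionMatrix:
    """Apply the entity filters used before network reconstruction.

    Removes profiles that (a) contain any missing value, (b) are unannotated
    when an annotation map is supplied (entities absent from the map count as
    unannotated), or (c) have a coefficient of variation below ``cv_min``
    (default 1). Row order of survivors is preserved; the operation is
    idempotent.

    Parameters
    ----------
    log_scale : bool
        Compute the CV on log2-transformed values (requires positive data);
        default is the raw scale.
    """
    if cv_min < 0:
        raise ValueError("cv_min must be non-negative")
    keep: list[int] = []
    for idx, eid in enumerate(matrix.entity_ids):
        row = matrix.values[idx]
        if np.isnan(row).any():
            continue
        if annotations is not None and not annotations.get(eid, False):
            continue
        cv_row = row
        if log_scale:
            if np.any(row <= 0):
                raise ValueError(
                    f"log-scale CV requires positive values (entity {eid!r})"
                )
            cv_row = np.log2(row)
        if coefficient_of_variation(cv_row) < cv_min:
            continue
        keep.append(idx)
    if not keep:
        raise FilterError(
            "filtering removed every profile; relax cv_min or review the "
            "annotation map"
        )
    return ExpressionMatrix(
        [matrix.entity_ids[i] for i in keep],
        list(matrix.time_labels),
        matrix.values[keep].copy(),
    )


def segments_from_breakpoints(
    breakpoints: Sequence[int], T: int
) -> list[tuple[int, int]]:
    """Expand segment-final breakpoints into 1-based inclusive (start, end)."""
    bps = list(breakpoints)
    if not bps:
        raise ValueError(
            "a segmentation needs at least one breakpoint (k >= 2 segments)"
        )
    if sorted(set(bps)) != bps:
        raise ValueError("breakpoints must be strictly increasing")
    if bps[0] < 1 or bps[-1] >= T:
        raise ValueError(f"breakpoints must lie within [1, {T - 1}]")
    edges = [0, *bps, T]
    return [(edges[j] + 1, edges[j + 1]) for j in range(len(edges) - 1)]


def write_results(result: "SegmentationResult", path: str | Path) -> None:
    """Write a segmentation result as JSON plus a per-segment TSV table.

    ``path`` is the JSON file; a table with columns (segment, start, end,
    length), 1-based inclusive, is written next to it with the suffix
    ``.segments.tsv``.
    """
    path = Path(path)
    segments = segments_from_breakpoints(result.breakpoints, result.T)
    payload = result.to_dict()
    payload["segments"] = [
        {"segment": j + 1, "start": s, "end": e, "length": e - s + 1}
        for j, (s, e) in enumerate(segments)
    ]
    path.write_text(json.dumps(payload, indent=2) + "\n")
    table = path.with_suffix(".segments.tsv")
    with table.open("w") as fh:
        fh.write("segment\tstart\tend\tlength\n")
        for j, (s, e) in enumerate(segments, start=1):
            fh.write(f"{j}\t{s}\t{e}\t{e - s + 1}\n")
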