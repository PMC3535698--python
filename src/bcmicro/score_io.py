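"""Tabular I/O for score tables, fold-change tables and expression records.

All tables are plain TSV.  A score table has the layout::

    mirna<TAB>gene<TAB><tool1>...<toolK>[<TAB>label]

Missing scores are written as ``NaN`` and parsed from a configurable token
set; internally a missing score is IEEE NaN, so the per-tool presence
indicator ``s_i`` is simply "score i is not NaN".  Identifiers are opaque,
case-sensitive strings and every (miRNA, gene) pair occurs at most once.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DuplicateKeyError, ParseError

#: Canonical ordering of the six upstream prediction tools.  Serialized
#: models and generated tables always use this order so that a model file
#: is unambiguous about which column is which.
TOOL_ORDER: tuple[str, ...] = (
    "TargetScan",
    "miRanda",
    "PicTar",
    "mirTarget",
    "PITA",
    "Diana-microT",
)

DEFAULT_MISSING_TOKENS: frozenset[str] = frozenset({"NA", "NaN", ""})



@dataclass
class ScoreRecord:
    """One (miRNA, gene) pair with a score vector over K tools.

    ``scores`` holds one float per tool; NaN marks a tool that reported no
    score.  ``label`` is 1 (known target), 0 (known non-target) or None.
    """

    mirna_id: str
    gene_id: str
    scores: np.ndarray
    label: int | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise ValueError("scores must be a 1-D vector")
        if np.isinf(self.scores).any():
            raise ValueError(
                f"infinite score for ({self.mirna_id}, {self.gene_id})"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0/1/None, got {self.label!r}")

    @property
    def present(self) -> np.ndarray:
        """Boolean presence indicators s_i (True where a score exists)."""
        return ~np.isnan(self.scores)


@dataclass
class ScoreTable:
    """A collection of :class:`ScoreRecord` sharing one tool ordering."""

    tool_names: list[str]
    records: list[ScoreRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tool_names = list(self.tool_names)
        k = len(self.tool_names)
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            if len(rec.scores) != k:
                raise ValueError(
                    f"record ({rec.mirna_id}, {rec.gene_id}) has "
                    f"{len(rec.scores)} scores, expected {k}"
                )
            key = (rec.mirna_id, rec.gene_id)
            if key in seen:
                raise DuplicateKeyError(f"duplicate pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def score_matrix(self) -> np.ndarray:
        """(n, K) float matrix with NaN for missing scores."""
        if not self.records:
            return np.empty((0, len(self.tool_names)))
        return np.vstack([r.scores for r in self.records])

    @property
    def labels(self) -> np.ndarray:
        """Float label vector; NaN where the class is unknown."""
        return np.array(
            [math.nan if r.label is None else float(r.label) for r in self.records]
        )

    def subset(self, indices) -> "ScoreTable":
        return ScoreTable(self.tool_names, [self.records[i] for i in indices])


@dataclass
class FoldChangeTable:
    """gene -> protein fold change (log scale, as provided upstream)."""

    entries: dict[str, float]

    def __post_init__(self) -> None:
        for gene, fc in self.entries.items():
            if not math.isfinite(fc):
                raise ValueError(f"non-finite fold change for {gene}")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ExpressionRecord:
    """One differential-expression result used for negative-set filtering."""

    gene_id: str
    p_value: float
    fold_change: float  # linear scale, > 0
    direction: str  # "up" or "down"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if not self.fold_change > 0:
            raise ValueError(f"fold_change must be positive, got {self.fold_change}")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up'/'down', got {self.direction!r}")


def _parse_cell(cell: str, missing_tokens: frozenset[str], where: str) -> float:
    if cell in missing_tokens:
        return math.nan
    try:
        value = float(cell)
    except ValueError as exc:
        raise ParseError(f"non-numeric cell {cell!r} at {where}") from exc
    if math.isinf(value):
        raise ParseError(f"infinite value at {where}")
    return value


def read_score_table(
    path,
    tool_names: list[str] | None = None,
    missing_tokens=DEFAULT_MISSING_TOKENS,
) -> ScoreTable:
    """Read a TSV score table.

    The header must start with ``mirna`` and ``gene``; the remaining
    columns are tool names, optionally followed by a trailing ``label``
    column with values in {1, 0} (or a missing token for unknown).  When
    *tool_names* is given the header's tool columns must match it exactly.
    """
    missing_tokens = frozenset(missing_tokens)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, header required") from None
        if len(header) < 3 or header[0] != "mirna" or header[1] != "gene":
            raise ParseError(
                f"{path}: header must be 'mirna<TAB>gene<TAB><tools...>'"
            )
        has_label = header[-1] == "label"
        file_tools = header[2 : len(header) - 1 if has_label else len(header)]
        if tool_names is not None and list(tool_names) != file_tools:
            raise ParseError(
                f"{path}: tool columns {file_tools} do not match expected "
                f"{list(tool_names)}"
            )
        k = len(file_tools)
        n_cols = len(header)
        records: list[ScoreRecord] = []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != n_cols:
                raise ParseError(
                    f"{path}: line {lineno}: expected {n_cols} columns, "
                    f"got {len(row)}"
                )
            scores = np.array(
                [
                    _parse_cell(row[2 + i], missing_tokens, f"{path}:{lineno}")
                    for i in range(k)
                ]
            )
            label: int | None = None
            if has_label:
                cell = row[-1]
                if cell not in missing_tokens:
                    if cell not in ("0", "1"):
                        raise ParseError(
                            f"{path}: line {lineno}: label must be 0 or 1, "
                            f"got {cell!r}"
                        )
                    label = int(cell)
            records.append(ScoreRecord(row[0], row[1], scores, label))
    return ScoreTable(file_tools, records)


def _fmt(value: float) -> str:
    # repr gives the shortest decimal that round-trips the float exactly
    return "NaN" if math.isnan(value) else repr(float(value))


def write_score_table(table: ScoreTable, path) -> None:
    """Write a score table (with a label column iff any record is labeled)."""
    has_label = any(r.label is not None for r in table.records)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        header = ["mirna", "gene", *table.tool_names]
        if has_label:
            header.append("label")
        writer.writerow(header)
        for rec in table.records:
            row = [rec.mirna_id, rec.gene_id, *(_fmt(v) for v in rec.scores)]
            if has_label:
                row.append("" if rec.label is None else str(rec.label))
            writer.writerow(row)


def write_predictions(table: ScoreTable, posteriors, path) -> None:
    """Write the table plus an appended ``posterior`` column."""
    posteriors = np.asarray(posteriors, dtype=float)
    if len(posteriors) != len(table.records):
        raise ValueError(
            f"{len(posteriors)} posteriors for {len(table.records)} records"
        )
    if len(posteriors) and (
        np.nanmin(posteriors) < 0 or np.nanmax(posteriors) > 1
    ):
        raise ValueError("posteriors must lie in [0, 1]")
    has_label = any(r.label is not None for r in table.records)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        header = ["mirna", "gene", *table.tool_names]
        if has_label:
            header.append("label")
        header.append("posterior")
        writer.writerow(header)
        for rec, post in zip(table.records, posteriors):
            row = [rec.mirna_id, rec.gene_id, *(_fmt(v) for v in rec.scores)]
            if has_label:
                row.append("" if rec.label is None else str(rec.label))
            row.append("{:.8g}".format(post))
            writer.writerow(row)


def read_fold_change_table(path) -> FoldChangeTable:
    """Read a two-column ``gene<TAB>fold_change`` TSV (header required)."""
    entries: dict[str, float] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, header required") from None
        if len(header) != 2:
            raise ParseError(f"{path}: expected 2 columns, got {len(header)}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(row)}"
                )
            gene, cell = row
            if gene in entries:
                raise DuplicateKeyError(f"{path}: line {lineno}: duplicate gene {gene}")
            try:
                value = float(cell)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric fold change {cell!r}"
                ) from exc
            if not math.isfinite(value):
                raise ParseError(f"{path}: line {lineno}: non-finite fold change")
            entries[gene] = value
    return FoldChangeTable(entries)
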