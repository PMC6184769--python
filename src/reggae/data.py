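"""Core data containers and text-format readers/writers.

Expression data travels as a tab-separated matrix (genes in rows, samples in
columns) plus a two-column sample/group file; regulator-target interaction
(RTI) collections travel either as GMT gene sets (one regulator per line) or
as a two-column edge list.  All identifier matching is exact, case-sensitive
string equality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "ExpressionMatrix",
    "RTICollection",
    "ResultTable",
    "RESULT_COLUMNS",
    "read_expression",
    "read_rti",
    "write_results",
    "read_results",
]


class DataError(ValueError):
    """Raised when an input file or container violates its invariants."""


# ---------------------------------------------------------------------------
# Expression data
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A normalized genes x samples expression matrix with two sample groups.

    Parameters
    ----------
    gene_ids : list of str
        Unique row identifiers, in row order.
    sample_ids : list of str
        Unique column identifiers, in column order.
    values : ndarray, shape (n_genes, n_samples)
        Normalized expression values; must be finite.
    groups : dict
        Mapping ``sample_id -> group label``; exactly two distinct labels,
        both non-empty.
    case_group : str
        The label designated as the "case" group (scores are signed so that
        positive means higher in this group).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    groups: dict[str, str]
    case_group: str
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise DataError(f"duplicate gene identifier: {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise DataError(f"duplicate sample identifier: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression matrix contains non-finite values")
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise DataError(f"samples without group label: {missing}")
        labels = sorted({self.groups[s] for s in self.sample_ids})
        if len(labels) != 2:
            raise DataError(
                f"exactly two groups required, found {len(labels)}: {labels}"
            )
        if self.case_group not in labels:
            raise DataError(
                f"case group {self.case_group!r} not among group labels {labels}"
            )
        for lab in labels:
            n = sum(1 for s in self.sample_ids if self.groups[s] == lab)
            if n < 2:
                raise DataError(f"group {lab!r} has {n} sample(s); at least 2 required")
        if len(self.sample_ids) < 10:
            warnings.warn(
                f"only {len(self.sample_ids)} samples; correlation estimates are "
                "unstable below 10 samples",
                stacklevel=2,
            )
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    # -- convenience accessors ------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def control_group(self) -> str:
        labels = {self.groups[s] for s in self.sample_ids}
        return next(iter(labels - {self.case_group}))

    @property
    def case_indices(self) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.groups[s] == self.case_group]
        )

    @property
    def control_indices(self) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.groups[s] != self.case_group]
        )

    def has_gene(self, gene_id: str) -> bool:
        return gene_id in self._index

    def row_index(self, gene_id: str) -> int:
        return self._index[gene_id]

    def rows(self, gene_ids: Sequence[str]) -> np.ndarray:
        return self.values[[self._index[g] for g in gene_ids], :]

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        groups: dict[str, str],
        case_group: str | None = None,
    ) -> "ExpressionMatrix":
        """Build from a DataFrame (index = gene ids, columns = sample ids)."""
        sample_ids = [str(c) for c in frame.columns]
        if case_group is None:
            case_group = groups[sample_ids[0]] if sample_ids else ""
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=sample_ids,
            values=frame.to_numpy(dtype=float),
            groups=dict(groups),
            case_group=case_group,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def _first_duplicate(items: Iterable[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


def read_expression(
    matrix_path: str | Path,
    groups_path: str | Path,
    case_group: str | None = None,
) -> ExpressionMatrix:
    """Read an expression TSV (first column gene id, header = sample ids) and a
    two-column (sample, group) file into a validated :class:`ExpressionMatrix`.

    ``case_group`` designates which of the two labels is the case group; if
    omitted the group of the first sample column is used.
    """
    try:
        frame = pd.read_csv(matrix_path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise DataError(f"malformed expression matrix {matrix_path}: {exc}") from exc
    if frame.shape[1] == 0:
        raise DataError(f"expression matrix {matrix_path} has no sample columns")
    try:
        frame = frame.astype(float)
    except (TypeError, ValueError) as exc:
        raise DataError(f"non-numeric cell in expression matrix: {exc}") from exc

    glab = pd.read_csv(groups_path, sep="\t", header=None, dtype=str)
    if glab.shape[1] != 2:
        raise DataError(
            f"groups file {groups_path} must have exactly two columns, found {glab.shape[1]}"
        )
    groups = dict(zip(glab.iloc[:, 0], glab.iloc[:, 1]))
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise DataError(f"exactly two groups required, found {len(labels)}: {labels}")
    extra = [s for s in groups if s not in set(map(str, frame.columns))]
    if extra:
        warnings.warn(f"ignoring {len(extra)} labelled sample(s) absent from the matrix")
        groups = {s: g for s, g in groups.items() if s not in set(extra)}
    return ExpressionMatrix.from_dataframe(frame, groups, case_group=case_group)


# ---------------------------------------------------------------------------
# Regulator-target interactions
# ---------------------------------------------------------------------------


@dataclass
class RTICollection:
    """A collection of regulator -> target-gene interactions.

    ``forward`` maps each regulator to its targets (insertion-ordered,
    duplicates collapsed); ``reverse`` maps each target gene to the ordered
    list of regulators that target it.  The two maps are exact transposes.
    """

    forward: dict[str, list[str]]
    reverse: dict[str, list[str]] = field(init=False)

    def __post_init__(self) -> None:
        for reg, targets in self.forward.items():
            if not targets:
                raise DataError(f"regulator {reg!r} has an empty target set")
            if len(set(targets)) != len(targets):
                self.forward[reg] = list(dict.fromkeys(targets))
        rev: dict[str, list[str]] = {}
        for reg, targets in self.forward.items():
            for g in targets:
                rev.setdefault(g, []).append(reg)
        self.reverse = rev

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "RTICollection":
        """Build from (regulator, target) pairs; duplicates collapse to one RTI."""
        forward: dict[str, dict[str, None]] = {}
        for reg, target in pairs:
            forward.setdefault(reg, {})[target] = None
        if not forward:
            raise DataError("no regulator-target pairs")
        return cls(forward={r: list(t) for r, t in forward.items()})

    @property
    def regulators(self) -> list[str]:
        return list(self.forward)

    @property
    def n_pairs(self) -> int:
        return sum(len(t) for t in self.forward.values())

    def targets_of(self, regulator: str) -> list[str]:
        return self.forward.get(regulator, [])

    def regulators_of(self, gene: str) -> list[str]:
        return self.reverse.get(gene, [])


def read_rti(path: str | Path, format: str = "gmt") -> RTICollection:
    """Parse an RTI collection from a GMT gene-set file or a two-column
    (regulator, target) edge list.  Duplicate pairs are collapsed."""
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise DataError(f"empty RTI file: {path}")
    pairs: list[tuple[str, str]] = []
    if format == "gmt":
        for i, ln in enumerate(lines, 1):
            fields = ln.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}:{i}: GMT line needs >=3 fields, found {len(fields)}")
            reg = fields[0]
            pairs.extend((reg, g) for g in fields[2:] if g)
    elif format == "edges":
        for i, ln in enumerate(lines, 1):
            fields = ln.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise DataError(f"{path}:{i}: edge line needs exactly 2 fields, found {len(fields)}")
            pairs.append((fields[0], fields[1]))
    else:
        raise DataError(f"unknown RTI format {format!r} (expected 'gmt' or 'edges')")
    return RTICollection.from_pairs(pairs)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "rank",
    "regulator",
    "n_occurrences",
    "statistic",
    "p_raw",
    "p_adjusted",
    "p_median",
    "p_sd",
    "p_mad",
    "ci_low",
    "ci_high",
    "mean_signed_correlation",
    "direction",
]


@dataclass
class ResultTable:
    """A ranked per-regulator result table plus the run parameters."""

    table: pd.DataFrame
    metadata: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in RESULT_COLUMNS if c not in self.table.columns]
        if missing:
            raise DataError(f"result table missing columns: {missing}")
        self.table = self.table.loc[:, RESULT_COLUMNS].reset_index(drop=True)
        n = len(self.table)
        if n and not np.array_equal(self.table["rank"].to_numpy(), np.arange(1, n + 1)):
            raise DataError("ranks must be 1-based and consecutive")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def regulators(self) -> list[str]:
        return list(self.table["regulator"])

    def rank_of(self, regulator: str) -> int | None:
        hit = self.table.index[self.table["regulator"] == regulator]
        return int(self.table.loc[hit[0], "rank"]) if len(hit) else None


def write_results(table: ResultTable, path: str | Path) -> None:
    """Write a :class:`ResultTable` as TSV with ``#``-prefixed metadata lines.

    Floats carry 8 significant digits so that re-reading reproduces ranks.
    """
    path = Path(path)
    with path.open("w") as fh:
        for key in sorted(table.metadata):
            fh.write(f"# {key}: {table.metadata[key]}\n")
        table.table.to_csv(fh, sep="\t", index=False, float_format="%.8g")


def read_results(path: str | Path) -> ResultTable:
    """Re-read a table written by :func:`write_results`."""
    metadata: dict[str, object] = {}
    with Path(path).open() as fh:
        lines = fh.readlines()
    for ln in lines:
        if ln.startswith("#"):
            body = ln[1:].strip()
            if ": " in body:
                key, val = body.split(": ", 1)
                metadata[key] = val
        else:
            break
    frame = pd.read_csv(path, sep="\t", comment="#")
    if frame.empty:
        frame = pd.DataFrame(columns=RESULT_COLUMNS)
    return ResultTable(table=frame, metadata=metadata)
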