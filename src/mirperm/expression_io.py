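"""Reading, writing and validation of the pipeline's on-disk formats.

All tabular formats are UTF-8 TSV with the identifier in the first column;
lines starting with ``#`` are comments and are ignored on read.  Writers emit
a single provenance comment line (tool version plus an optional note) so that
every output can be traced back to the run that produced it.  Gene sets use
the conventional GMT layout (set name, description, member genes, one set per
line).  A minimal GEO series-matrix reader is provided for loading deposited
expression tables; group labels for series-matrix samples must be supplied by
the caller because GEO characteristics parsing is not reliable enough to
guess treatment arms from.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__

logger = logging.getLogger(__name__)

GROUPS = ("treated", "control")

#: significant digits used by all numeric writers; round-tripping through
#: text is identity at this precision for float64 payloads
PRINT_PRECISION = 12


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


def _provenance_line(note: str | None = None) -> str:
    tail = f" | {note}" if note else ""
    return f"# mirperm v{__version__}{tail}\n"


@dataclass
class ExpressionMatrix:
    """Probe- or miRNA-level intensities with sample group labels.

    ``values`` is indexed by feature identifier with one column per sample
    (column order is meaningful and preserved); ``groups`` maps every sample
    to ``"treated"`` or ``"control"``.
    """

    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate probe ids: {list(dups)[:5]}")
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate sample ids in matrix header")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise FormatError(f"samples without group assignment: {missing}")
        bad = {s: g for s, g in self.groups.items() if g not in GROUPS}
        if bad:
            raise FormatError(f"unknown group labels: {bad}")
        self.groups = {s: self.groups[s] for s in self.values.columns}
        for g in GROUPS:
            if g not in self.groups.values():
                raise FormatError(f"group '{g}' has no samples")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"non-finite intensity at probe {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative intensity at probe {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    @property
    def n_probes(self) -> int:
        return len(self.values)

    def subset(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        unknown = [p for p in probe_ids if p not in self.values.index]
        if unknown:
            raise KeyError(f"unknown probe ids: {unknown[:5]}")
        return ExpressionMatrix(self.values.loc[list(probe_ids)], dict(self.groups))

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.groups == other.groups
            and self.values.index.equals(other.values.index)
            and self.values.columns.equals(other.values.columns)
            and np.allclose(self.values.to_numpy(), other.values.to_numpy(),
                            rtol=10 ** -(PRINT_PRECISION - 1), atol=0)
        )


@dataclass
class ProbeAnnotation:
    """Many-to-one probe → miRNA map."""

    mirna_of: dict[str, str]

    def __getitem__(self, probe_id: str) -> str:
        return self.mirna_of[probe_id]

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.mirna_of

    @property
    def mirna_ids(self) -> list[str]:
        # insertion-ordered unique miRNA ids
        return list(dict.fromkeys(self.mirna_of.values()))


@dataclass
class GeneSetCollection:
    """Named gene sets over a fixed gene universe."""

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            stray = members - self.universe
            if stray:
                raise FormatError(
                    f"gene set {name!r} has genes outside the universe: "
                    f"{sorted(stray)[:5]}"
                )

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    @property
    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class AssaySeries:
    """Replicate scalar measurements for one exposure condition."""

    condition: str
    values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.condition not in GROUPS:
            raise FormatError(f"unknown condition {self.condition!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise FormatError("assay values must be one-dimensional")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# TSV expression matrix + sample sheet


def read_expression(matrix_path: str | Path, sample_sheet_path: str | Path) -> ExpressionMatrix:
    """Load a probe×sample TSV and its sample sheet into a validated matrix."""
    try:
        values = pd.read_csv(matrix_path, sep="\t", comment="#", index_col=0)
    except ValueError as exc:
        raise FormatError(f"{matrix_path}: {exc}") from exc
    for col in values.columns:
        coerced = pd.to_numeric(values[col], errors="coerce")
        if coerced.isna().any() and not values[col].isna().any():
            bad = values.index[coerced.isna()][0]
            raise FormatError(
                f"{matrix_path}: non-numeric value at probe {bad!r}, sample {col!r}"
            )
        values[col] = coerced
    if values.isna().any().any():
        r = values.index[values.isna().any(axis=1)][0]
        raise FormatError(f"{matrix_path}: missing value in probe {r!r}")

    sheet = pd.read_csv(sample_sheet_path, sep="\t", comment="#")
    required = {"sample_id", "group"}
    if not required.issubset(sheet.columns):
        raise FormatError(
            f"{sample_sheet_path}: sample sheet needs columns {sorted(required)}"
        )
    groups = dict(zip(sheet["sample_id"].astype(str), sheet["group"].astype(str)))
    missing = [s for s in values.columns if s not in groups]
    if missing:
        raise FormatError(
            f"{sample_sheet_path}: no group for matrix column(s) {missing}"
        )
    return ExpressionMatrix(values, {s: groups[s] for s in values.columns})


def write_expression(matrix: ExpressionMatrix, matrix_path: str | Path,
                     sample_sheet_path: str | Path | None = None,
                     note: str | None = None) -> None:
    with open(matrix_path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_line(note))
        matrix.values.to_csv(fh, sep="\t", index_label="probe_id",
                             float_format=f"%.{PRINT_PRECISION}g")
    if sample_sheet_path is not None:
        with open(sample_sheet_path, "w", encoding="utf-8") as fh:
            fh.write(_provenance_line(note))
            fh.write("sample_id\tgroup\n")
            for s, g in matrix.groups.items():
                fh.write(f"{s}\t{g}\n")


# ---------------------------------------------------------------------------
# probe annotation


def read_annotation(path: str | Path) -> ProbeAnnotation:
    table = pd.read_csv(path, sep="\t", comment="#")
    if not {"probe_id", "mirna_id"}.issubset(table.columns):
        raise FormatError(f"{path}: annotation needs columns probe_id, mirna_id")
    if table["probe_id"].duplicated().any():
        dup = table.loc[table["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise FormatError(f"{path}: probe {dup!r} annotated more than once")
    return ProbeAnnotation(dict(zip(table["probe_id"].astype(str),
                                    table["mirna_id"].astype(str))))


def write_annotation(annotation: ProbeAnnotation, path: str | Path,
                     note: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_line(note))
        fh.write("probe_id\tmirna_id\n")
        for probe, mirna in annotation.mirna_of.items():
            fh.write(f"{probe}\t{mirna}\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gene_sets(gmt_path: str | Path, universe: Iterable[str]) -> GeneSetCollection:
    """Read a GMT file, restricting every set to ``universe``.

    Genes outside the universe are dropped (count logged); sets empty after
    filtering are dropped; a duplicated set name keeps the last definition.
    """
    universe = frozenset(universe)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    n_dropped_genes = 0
    with open(gmt_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{gmt_path}:{lineno}: GMT line needs >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, description, *genes = fields
            members = frozenset(g for g in genes if g)
            kept = members & universe
            n_dropped_genes += len(members - universe)
            if name in sets:
                logger.warning("duplicate gene set %r at %s:%d; last wins",
                               name, gmt_path, lineno)
            if not kept:
                logger.info("gene set %r empty after universe filter; dropped", name)
                if name in sets:
                    del sets[name]
                continue
            sets[name] = (description, kept)
    if n_dropped_genes:
        logger.info("dropped %d gene(s) outside the universe while reading %s",
                    n_dropped_genes, gmt_path)
    return GeneSetCollection(sets, universe)


def write_gene_sets(collection: GeneSetCollection, gmt_path: str | Path) -> None:
    with open(gmt_path, "w", encoding="utf-8") as fh:
        for name, (description, members) in collection.sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# target-score table


def read_target_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", comment="#")
    needed = {"mirna_id", "gene_id", "score"}
    if not needed.issubset(table.columns):
        raise FormatError(f"{path}: target table needs columns {sorted(needed)}")
    if table.duplicated(subset=["mirna_id", "gene_id"]).any():
        raise FormatError(f"{path}: duplicate (mirna_id, gene_id) pair")
    scores = table["score"].to_numpy(dtype=float)
    if ((scores < 0) | (scores > 100)).any():
        raise FormatError(f"{path}: target scores must lie in [0, 100]")
    return table


def write_target_table(table: pd.DataFrame, path: str | Path,
                       note: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_line(note))
        table.to_csv(fh, sep="\t", index=False,
                     float_format=f"%.{PRINT_PRECISION}g")


# ---------------------------------------------------------------------------
# assay replicates


def read_assay_series(path: str | Path) -> dict[str, AssaySeries]:
    table = pd.read_csv(path, sep="\t", comment="#")
    needed = {"condition", "replicate_id", "value"}
    if not needed.issubset(table.columns):
        raise FormatError(f"{path}: assay table needs columns {sorted(needed)}")
    out: dict[str, AssaySeries] = {}
    for condition, chunk in table.groupby("condition", sort=False):
        out[str(condition)] = AssaySeries(str(condition),
                                          chunk["value"].to_numpy(dtype=float))
    return out


def write_assay_series(series: Iterable[AssaySeries], path: str | Path,
                       note: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_line(note))
        fh.write("condition\treplicate_id\tvalue\n")
        for s in series:
            for i, v in enumerate(s.values):
                fh.write(f"{s.condition}\t{i}\t{v:.{PRINT_PRECISION}g}\n")


# ---------------------------------------------------------------------------
# GEO series-matrix (read-only)

_TABLE_BEGIN = "!series_matrix_table_begin"
_TABLE_END = "!series_matrix_table_end"


def read_series_matrix(path: str | Path, groups: Mapping[str, str]) -> ExpressionMatrix:
    """Parse a GEO series-matrix text file.

    Only the expression table between the begin/end markers is used; sample
    group labels come from ``groups`` (GEO characteristics lines are not
    interpreted).  Quoted identifiers and values are unquoted before parsing.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    try:
        start = next(i for i, l in enumerate(lines)
                     if l.strip().lower().startswith(_TABLE_BEGIN))
    except StopIteration:
        raise FormatError(f"{path}: missing {_TABLE_BEGIN} marker") from None
    try:
        end = next(i for i, l in enumerate(lines[start + 1:], start + 1)
                   if l.strip().lower().startswith(_TABLE_END))
    except StopIteration:
        raise FormatError(f"{path}: missing {_TABLE_END} marker") from None
    block = "\n".join(lines[start + 1:end])
    values = pd.read_csv(io.StringIO(block), sep="\t", index_col=0)
    values.index = [str(i).strip('"') for i in values.index]
    values.columns = [str(c).strip('"') for c in values.columns]
    for col in values.columns:
        if values[col].dtype == object:
            values[col] = pd.to_numeric(values[col].str.strip('"'))
    return ExpressionMatrix(values, {c: groups[c] for c in values.columns})
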