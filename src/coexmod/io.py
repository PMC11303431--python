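"""Readers and writers for the tabular formats the pipeline touches.

Expression matrices and trait tables travel as :class:`pandas.DataFrame`
objects with samples on the rows (index) and features / traits on the
columns.  All on-disk tables are delimited text with a header row and an
ID column; TSV is the default, CSV is auto-detected from the ``.csv``
extension.  Gene-set annotations use the GMT dialect (one set per line:
name, description, then members).
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("coexmod")

#: tokens treated as missing on input (compared case-insensitively)
MISSING_TOKENS = {"", "na", "nan"}


class ParseError(ValueError):
    """Raised when a delimited table violates the format contract."""


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited table: header row, ID column, numeric-or-missing cells."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sep_for(path)
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split(sep)[1:]
    seen: set[str] = set()
    for name in header:
        if name in seen:  # pandas would silently mangle these
            raise ParseError(f"{path}: duplicated column ID {name!r}")
        seen.add(name)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                      keep_default_na=False)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ParseError(f"{path}: duplicated row ID {dup!r}")
    if raw.columns.duplicated().any():
        dup = raw.columns[raw.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicated column ID {dup!r}")

    def _cell(value: str, row: str, col: str) -> float:
        if value.strip().lower() in MISSING_TOKENS:
            return np.nan
        try:
            return float(value)
        except ValueError:
            raise ParseError(
                f"{path}: non-numeric cell {value!r} at row {row!r}, column {col!r}"
            ) from None

    values = np.empty(raw.shape, dtype=float)
    cols = list(raw.columns)
    for i, (row_id, row) in enumerate(raw.iterrows()):
        for j, value in enumerate(row):
            values[i, j] = _cell(value, str(row_id), str(cols[j]))
    out = pd.DataFrame(values, index=raw.index.astype(str), columns=[str(c) for c in cols])
    out.index.name = raw.index.name
    return out


def read_expression_matrix(path: str | Path,
                           orientation: str = "rows-are-samples") -> pd.DataFrame:
    """Read an expression matrix, returning it oriented samples x features.

    Parameters
    ----------
    path:
        Delimited text file with a header row and an ID column.
    orientation:
        ``"rows-are-samples"`` (default) or ``"rows-are-features"``; the
        latter is transposed on read so the in-memory layout is always
        samples x features.
    """
    if orientation not in ("rows-are-samples", "rows-are-features"):
        raise ValueError(f"unknown orientation {orientation!r}")
    table = _read_table(path)
    if orientation == "rows-are-features":
        table = table.T
    table.index.name = "sample_id"
    table.columns.name = "feature_id"
    return table


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a samples x traits table; blank / NA cells become missing."""
    table = _read_table(path)
    table.index.name = "sample_id"
    table.columns.name = "trait"
    for trait in table.columns:
        if table[trait].isna().all():
            logger.warning("trait %r has no observed values; retained", trait)
    return table


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a table as delimited text at full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep=_sep_for(path), float_format="%.17g")


# -- gene sets ---------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named sets of feature identifiers, e.g. 'hemorrhage-related proteins'."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB member...`` per line.

    Lines with fewer than three fields are skipped with a warning; a
    repeated set name overrides the earlier definition (last wins).
    """
    collection = GeneSetCollection()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            logger.warning("%s:%d: fewer than 3 fields, skipped", path, lineno)
            continue
        name, description = parts[0], parts[1]
        members = {m for m in parts[2:] if m}
        if name in collection.sets:
            logger.warning("%s:%d: duplicate gene set %r, last definition wins",
                           path, lineno, name)
        collection.sets[name] = members
        collection.descriptions[name] = description
    return collection


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list, one identifier per line."""
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


# -- run configuration -------------------------------------------------------

DEFAULT_POWER_GRID = tuple(range(1, 11)) + (12, 14, 16, 18, 20)


@dataclass
class RunConfig:
    """All tunables of the pipeline stages, with their defaults.

    Loaded from a flat TOML file; unknown keys are rejected.
    """

    # preprocessing
    collapse_probes: str = "none"          # "none" | "max-variance"
    filter_top_n: int | None = 10_000      # None disables the variance filter
    # network
    power_grid: tuple[float, ...] = DEFAULT_POWER_GRID
    r2_cut: float = 0.8
    signed: bool = False
    # module detection
    cut_height: float = 0.98
    min_module_size: int = 30
    merge_dissimilarity: float = 0.2
    # trait association
    correlation_method: str = "pearson"    # "pearson" | "spearman" | "auto"
    bh_correction: bool = False
    # candidate ranking
    centrality: str = "kIM"                # "kIM" | "kME"
    top_k: int = 100
    mic_alpha: float = 0.6
    mic_c: float = 15.0
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.collapse_probes not in ("none", "max-variance"):
            raise ValueError(f"collapse_probes: {self.collapse_probes!r}")
        if self.filter_top_n is not None and self.filter_top_n < 1:
            raise ValueError("filter_top_n must be >= 1 or None")
        self.power_grid = tuple(float(p) for p in self.power_grid)
        if not self.power_grid or min(self.power_grid) < 1:
            raise ValueError("power_grid must be nonempty with powers >= 1")
        if not 0 <= self.r2_cut <= 1:
            raise ValueError("r2_cut must be in [0, 1]")
        if not 0 < self.cut_height < 1:
            raise ValueError("cut_height must be in (0, 1)")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")
        if not 0 <= self.merge_dissimilarity <= 1:
            raise ValueError("merge_dissimilarity must be in [0, 1]")
        if self.correlation_method not in ("pearson", "spearman", "auto"):
            raise ValueError(f"correlation_method: {self.correlation_method!r}")
        if self.centrality not in ("kIM", "kME"):
            raise ValueError(f"centrality: {self.centrality!r}")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not 0 < self.mic_alpha <= 1:
            raise ValueError("mic_alpha must be in (0, 1]")
        if self.mic_c < 1:
            raise ValueError("mic_c must be >= 1")

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            value = getattr(self, f.name)
            out[f.name] = list(value) if isinstance(value, tuple) else value
        return out


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional TOML file plus keyword overrides.

    Unknown keys (in the file or the overrides) raise, so typos never
    silently fall back to a default.
    """
    values: dict = {}
    if path is not None:
        with open(path, "rb") as handle:
            values.update(tomllib.load(handle))
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(RunConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**values)
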