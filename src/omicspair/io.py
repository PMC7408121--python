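"""Core data containers and TSV/GMT readers and writers.

The on-disk dialect is deliberately small: UTF-8, tab-separated, no
quoting, first column header ``feature_id`` for matrices, ``NA`` for
missing values.  Matrices must be complete — missing values are rejected
at read time because every downstream model assumes complete cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError, UsageError

logger = logging.getLogger(__name__)

#: Recognized matrix layers, in rough pipeline order.
LAYERS = ("counts", "normalized", "adjusted", "raw_abundance", "log_abundance")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} ID: {x!r}")
        seen.add(x)


@dataclass
class OmicsMatrix:
    """A features x samples numeric matrix with a layer tag.

    Parameters
    ----------
    feature_ids : list of str
        Unique row identifiers (genes or metabolites).
    sample_ids : list of str
        Unique column identifiers.
    values : ndarray of shape (n_features, n_samples)
        Dense float matrix; must be finite (no NaN/inf).
    layer : str
        One of :data:`LAYERS`.  ``counts`` additionally requires all
        values to be non-negative.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    layer: str

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.layer not in LAYERS:
            raise UsageError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.values.ndim != 2:
            raise FormatError("matrix values must be two-dimensional")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise FormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if self.values.size == 0:
            raise FormatError("empty matrix")
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if self.layer == "counts" and np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise FormatError(
                f"negative count at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)
        df.index.name = "feature_id"
        return df

    def select_features(self, keep: Sequence[str], layer: str | None = None) -> "OmicsMatrix":
        """Return a sub-matrix containing ``keep`` features, in current order."""
        keep_set = set(keep)
        idx = [i for i, f in enumerate(self.feature_ids) if f in keep_set]
        return OmicsMatrix(
            [self.feature_ids[i] for i in idx],
            list(self.sample_ids),
            self.values[idx, :],
            layer or self.layer,
        )

    def with_layer(self, layer: str) -> "OmicsMatrix":
        return OmicsMatrix(list(self.feature_ids), list(self.sample_ids), self.values.copy(), layer)


@dataclass
class SampleTable:
    """Per-sample phenotype labels and nuisance covariates.

    Wraps a DataFrame indexed by ``sample_id``.  Column names are free,
    but the stock designs use ``breed``, ``fe_group``, ``pen``,
    ``batch``, ``rin``, ``slaughter_age_days``, ``sampling_age_days``
    and optionally ``fcr``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.index.name != "sample_id":
            if "sample_id" in self.frame.columns:
                self.frame = self.frame.set_index("sample_id")
            else:
                raise FormatError("sample table needs a 'sample_id' column or index")
        self.frame.index = self.frame.index.map(str)
        if self.frame.index.has_duplicates:
            dup = self.frame.index[self.frame.index.duplicated()][0]
            raise FormatError(f"duplicate sample ID: {dup!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def column(self, name: str) -> pd.Series:
        if name not in self.frame.columns:
            raise UsageError(f"metadata column {name!r} not found "
                             f"(have: {', '.join(self.frame.columns)})")
        return self.frame[name]

    def subset(self, sample_ids: Sequence[str]) -> "SampleTable":
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise UsageError(f"samples absent from metadata: {missing}")
        return SampleTable(self.frame.loc[list(sample_ids)].copy())


@dataclass
class PathwayLibrary:
    """Named feature sets, optionally with a per-set edge list."""

    sets: dict[str, list[str]]
    graphs: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"pathway set {name!r} is empty")
            if len(set(members)) != len(members):
                raise FormatError(f"pathway set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# matrix TSV


def read_matrix(path: str | Path, layer: str) -> OmicsMatrix:
    """Read a features x samples TSV into an :class:`OmicsMatrix`.

    The first row holds sample IDs, the first column feature IDs.
    ``NA`` cells and non-numeric cells are format errors reported with
    their coordinates.
    """
    path = Path(path)
    try:
        # round_trip parsing: the decimal text maps back to the exact double
        df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False,
                         na_values=[], float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty matrix file") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: empty matrix")
    body = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        series = df[col]
        if series.dtype.kind in "fiu":
            body[:, j] = series.to_numpy(dtype=float)
            continue
        for i, cell in enumerate(series):
            try:
                body[i, j] = float(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-numeric or missing cell at feature "
                    f"{df.index[i]!r}, sample {col!r}: {cell!r}"
                ) from None
    return OmicsMatrix(list(df.index.map(str)), list(map(str, df.columns)), body, layer)


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    """Write a matrix TSV that :func:`read_matrix` round-trips exactly.

    Floats are serialized with ``repr`` so the decimal text parses back
    to the identical binary value.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for fid, row in zip(matrix.feature_ids, matrix.values):
            fh.write(fid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str},
                     keep_default_na=False, na_values=["NA"])
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing 'sample_id' column")
    return SampleTable(df)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> PathwayLibrary:
    """Parse a GMT file (set name, description, members; tab-separated).

    Duplicate members within one line are dropped with a warning.  An
    empty file yields an empty library (with a warning).
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields "
                    f"(name, description, members); got {len(fields)}"
                )
            name = fields[0]
            members: list[str] = []
            seen: set[str] = set()
            dropped = 0
            for m in fields[2:]:
                if not m:
                    continue
                if m in seen:
                    dropped += 1
                    continue
                seen.add(m)
                members.append(m)
            if dropped:
                logger.warning("GMT set %r: dropped %d duplicate member(s)", name, dropped)
            sets[name] = members
    if not sets:
        logger.warning("GMT file %s contains no sets", path)
    return PathwayLibrary(sets)


def write_gmt(library: PathwayLibrary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in library.sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


# ---------------------------------------------------------------------------
# config


def load_config(path: str | Path) -> dict:
    """Load a flat YAML mapping of pipeline settings."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, Mapping):
        raise ConfigError(f"{path}: config must be a key/value mapping")
    return dict(cfg)
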