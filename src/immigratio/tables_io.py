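"""Reading, validating and writing the tabular artifacts of the pipeline.

The raw input is an OTU count table (OTUs in rows, samples in columns, one
trailing taxonomy column) plus a sample metadata table.  Orientation is fixed:
a transposed count table fails schema checks rather than being silently
auto-detected, because sample ids and OTU ids are not reliably
distinguishable.  Taxonomy travels as a single semicolon-separated lineage
string here and is parsed only by :mod:`immigratio.taxonomy`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvariantError, ParseError, SchemaError

logger = logging.getLogger("immigratio")

SAMPLE_TYPES = ("primary", "surplus", "digester")
PROCESS_TYPES = ("mesophilic", "thermophilic", "thp", "na")
INFLUENT_TYPES = ("primary", "surplus")

#: Required metadata columns (``reactor`` and ``date`` are optional).
METADATA_COLUMNS = ("sample_id", "plant", "sample_type", "process_type")

_TAXONOMY_COLUMN = {"ampvis_tsv": "Taxonomy", "biom_tsv": "#taxonomy"}


@dataclass
class CountTable:
    """Integer OTU x sample read-count matrix with aligned taxonomy strings.

    Attributes
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix, index = OTU ids, columns = sample ids.
    taxonomy : pandas.Series
        Semicolon-separated lineage string per OTU, aligned with ``counts``.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise InvariantError(f"duplicate OTU ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise InvariantError(f"duplicate sample ids: {dups}")
        if not set(self.taxonomy.index) == set(c.index):
            missing = sorted(set(c.index) - set(self.taxonomy.index))
            extra = sorted(set(self.taxonomy.index) - set(c.index))
            raise InvariantError(
                f"taxonomy/count OTU mismatch: missing={missing[:5]} extra={extra[:5]}"
            )
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise InvariantError("counts must have an integer dtype")
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise InvariantError(
                f"negative count at OTU {c.index[bad[0]]!r}, sample {c.columns[bad[1]]!r}"
            )
        # keep taxonomy in count order
        self.taxonomy = self.taxonomy.reindex(c.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def select_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.counts.loc[:, list(sample_ids)], self.taxonomy)

    def select_otus(self, otu_ids) -> "CountTable":
        ids = list(otu_ids)
        return CountTable(self.counts.loc[ids], self.taxonomy.loc[ids])


@dataclass
class ValidatedDataset:
    """A count table joined with metadata covering exactly its samples."""

    counts: CountTable
    samples: pd.DataFrame = field(repr=False)


def _coerce_int_matrix(df: pd.DataFrame, path: str) -> pd.DataFrame:
    """Convert a string-valued frame to integers, reporting the first bad cell."""
    num = df.apply(pd.to_numeric, errors="coerce")
    if num.isna().any().any():
        r, c = np.argwhere(num.isna().to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric count {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    arr = num.to_numpy()
    if (arr < 0).any():
        r, c = np.argwhere(arr < 0)[0]
        raise ParseError(
            f"{path}: negative count at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if not np.allclose(arr, np.round(arr)):
        r, c = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
        raise ParseError(
            f"{path}: non-integer count {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    return num.round().astype(np.int64)


def read_count_table(path, dialect: str = "ampvis_tsv") -> CountTable:
    """Read a TSV OTU table (first column OTU ids, last column taxonomy).

    Parameters
    ----------
    path : str or Path
        Tab-separated file; rows are OTUs, columns are samples, the final
        column holds the lineage string.
    dialect : {"ampvis_tsv", "biom_tsv"}
        Name of the taxonomy column: ``Taxonomy`` or ``#taxonomy``.
    """
    if dialect not in _TAXONOMY_COLUMN:
        raise SchemaError(f"unknown dialect {dialect!r}; use one of {sorted(_TAXONOMY_COLUMN)}")
    tax_col = _TAXONOMY_COLUMN[dialect]
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None  # written back as "OTU" regardless of source header
    if df.columns.size == 0 or df.columns[-1] != tax_col:
        raise SchemaError(
            f"{path}: last column must be {tax_col!r} for dialect {dialect!r}; "
            f"found {list(df.columns[-1:])}"
        )
    taxonomy = df[tax_col].fillna("")
    counts = _coerce_int_matrix(df.drop(columns=[tax_col]), str(path))
    return CountTable(counts, taxonomy)


def write_count_table(ct: CountTable, path, dialect: str = "ampvis_tsv") -> None:
    """Write a count table in the same TSV layout ``read_count_table`` expects."""
    tax_col = _TAXONOMY_COLUMN[dialect]
    out = ct.counts.copy()
    out[tax_col] = ct.taxonomy
    out.index.name = "OTU"
    out.to_csv(path, sep="\t")


def _normalize_enum(value, allowed, column: str, default: str | None = None):
    v = ("" if value is None or (isinstance(value, float) and np.isnan(value)) else str(value)).strip().lower()
    if v == "" and default is not None:
        return default
    if v not in allowed:
        raise InvariantError(
            f"{column}={value!r} not recognised; allowed values: {sorted(allowed)}"
        )
    return v


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata table (CSV or TSV, sniffed by pandas).

    Returns a frame with columns sample_id, plant, reactor, sample_type,
    process_type, date.  Enums are normalized case-insensitively; the
    invariants (digester samples carry a process type, influent samples carry
    ``na``) are enforced here.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: metadata missing required columns {missing}")
    for opt in ("reactor", "date"):
        if opt not in df.columns:
            df[opt] = ""
    df = df[["sample_id", "plant", "reactor", "sample_type", "process_type", "date"]].copy()
    df["sample_id"] = df["sample_id"].astype(str).str.strip()
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise InvariantError(f"{path}: duplicate sample_id {dups}")
    df["sample_type"] = [
        _normalize_enum(v, SAMPLE_TYPES, "sample_type") for v in df["sample_type"]
    ]
    df["process_type"] = [
        _normalize_enum(v, PROCESS_TYPES, "process_type", default="na")
        for v in df["process_type"]
    ]
    df["reactor"] = df["reactor"].fillna("").astype(str)
    df["date"] = df["date"].fillna("").astype(str)
    validate_metadata(df)
    return df.reset_index(drop=True)


def validate_metadata(samples: pd.DataFrame) -> None:
    """Enforce the sample_type/process_type pairing rules."""
    bad_dig = samples[(samples.sample_type == "digester") & (samples.process_type == "na")]
    if len(bad_dig):
        raise InvariantError(
            f"digester samples must carry a process type: {bad_dig.sample_id.tolist()}"
        )
    bad_inf = samples[
        samples.sample_type.isin(INFLUENT_TYPES) & (samples.process_type != "na")
    ]
    if len(bad_inf):
        raise InvariantError(
            "influent (primary/surplus) samples must have process_type=na: "
            f"{bad_inf.sample_id.tolist()}"
        )


def validate_dataset(counts: CountTable, samples: pd.DataFrame) -> ValidatedDataset:
    """Reconcile count columns with metadata rows; align order by sample_id.

    Raises :class:`InvariantError` enumerating the differences when the two
    sample sets are not identical, and logs the per (sample_type,
    process_type) group sizes on success.
    """
    validate_metadata(samples)
    count_ids = set(counts.sample_ids)
    meta_ids = set(samples.sample_id)
    if count_ids != meta_ids:
        only_counts = sorted(count_ids - meta_ids)
        only_meta = sorted(meta_ids - count_ids)
        raise InvariantError(
            "count columns and metadata rows differ: "
            f"only in counts={only_counts}, only in metadata={only_meta}"
        )
    if not count_ids:
        raise InvariantError("empty sample set")
    samples = samples.set_index("sample_id").loc[counts.sample_ids].reset_index()
    groups = (
        samples.groupby(["sample_type", "process_type"], observed=True)
        .size()
        .sort_index()
    )
    summary = ", ".join(f"{st}/{pt}: {n}" for (st, pt), n in groups.items())
    logger.info("validated dataset: %s", summary)
    return ValidatedDataset(counts=counts, samples=samples)


def write_table(obj, path) -> None:
    """Write a result table as TSV with floats at 6 significant digits.

    Accepts any of the result dataclasses defined in later modules (they all
    expose ``to_frame()``) or a plain DataFrame.  Row order is the type's
    documented deterministic order.
    """
    frame = obj.to_frame() if hasattr(obj, "to_frame") else obj
    if not isinstance(frame, pd.DataFrame):
        from .exceptions import ArgumentError

        raise ArgumentError(f"cannot write object of type {type(obj).__name__}")
    frame.to_csv(path, sep="\t", float_format="%.6g")
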