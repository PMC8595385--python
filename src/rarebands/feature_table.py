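"""Feature (ASV/OTU) count tables: reading, validation, filtering, writing.

An amplicon feature table is an integer matrix of read counts with features
(amplicon sequence variants or OTUs) as rows and samples as columns, optionally
annotated with a semicolon-delimited taxonomic lineage per feature. All
downstream analyses in this package start from such a table; proportions and
transformed values are produced downstream only, never ingested.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "LibrarySizeSummary",
    "FeatureTableValidationError",
    "read_feature_table",
    "write_feature_table",
    "filter_by_taxonomy",
    "filter_min_count",
    "library_sizes",
]

#: header cells accepted for the feature-ID column of a TSV table
_ID_HEADERS = ("#OTU ID", "feature_id")
_TAXONOMY_COLUMN = "taxonomy"

DEFAULT_EXCLUDE_TERMS = ("mitochondria", "chloroplast")


class FeatureTableValidationError(ValueError):
    """Raised when a count table violates the FeatureTable contract."""


@dataclass(frozen=True)
class FeatureTable:
    """An integer count matrix of shape (n_features, n_samples).

    Parameters
    ----------
    feature_ids : list of str
        Unique feature (ASV/OTU) identifiers, one per row of ``counts``.
    sample_ids : list of str
        Unique sample identifiers, one per column of ``counts``.
    counts : ndarray of int
        Non-negative read counts, shape ``(len(feature_ids), len(sample_ids))``.
    taxonomy : dict, optional
        Map feature_id -> semicolon-delimited lineage string. Keys must be a
        subset of ``feature_ids``; features may lack taxonomy.
    """

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray
    taxonomy: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise FeatureTableValidationError(
                f"counts must be 2-dimensional, got shape {counts.shape}"
            )
        if counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise FeatureTableValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            # reject fractional values rather than silently rounding
            rounded = np.rint(counts)
            bad = np.nonzero(~np.isclose(counts, rounded, rtol=0, atol=0))
            if bad[0].size:
                i, j = bad[0][0], bad[1][0]
                raise FeatureTableValidationError(
                    f"non-integer count {counts[i, j]!r} at feature "
                    f"{self.feature_ids[i]!r}, sample {self.sample_ids[j]!r}"
                )
            counts = rounded.astype(np.int64)
        counts = counts.astype(np.int64, copy=False)
        if counts.size and counts.min() < 0:
            i, j = np.argwhere(counts < 0)[0]
            raise FeatureTableValidationError(
                f"negative count {counts[i, j]} at feature "
                f"{self.feature_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

        for kind, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))
                raise FeatureTableValidationError(f"duplicate {kind} ID {dup!r}")
        if self.taxonomy is not None:
            extra = set(self.taxonomy) - set(self.feature_ids)
            if extra:
                raise FeatureTableValidationError(
                    f"taxonomy keys not in feature_ids: {sorted(extra)[:5]}"
                )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        """Counts as a features x samples DataFrame."""
        return pd.DataFrame(
            np.asarray(self.counts),
            index=list(self.feature_ids),
            columns=list(self.sample_ids),
        )

    def sample_counts(self, sample_id: str) -> np.ndarray:
        """The count vector for one sample."""
        return np.asarray(self.counts)[:, self.sample_ids.index(sample_id)]

    def select_features(self, keep: np.ndarray) -> "FeatureTable":
        """New table restricted to the boolean/index mask ``keep`` over features."""
        keep = np.asarray(keep)
        ids = tuple(np.asarray(self.feature_ids, dtype=object)[keep])
        tax = None
        if self.taxonomy is not None:
            tax = {f: self.taxonomy[f] for f in ids if f in self.taxonomy}
        return FeatureTable(ids, self.sample_ids, np.asarray(self.counts)[keep], tax)


@dataclass(frozen=True)
class LibrarySizeSummary:
    """Per-sample library sizes (column sums) with the minimum flagged."""

    per_sample: dict[str, int]
    minimum: int
    minimum_sample: str


def library_sizes(table: FeatureTable) -> LibrarySizeSummary:
    """Summarize library sizes; minimum ties break to the first sample."""
    sums = np.asarray(table.counts).sum(axis=0) if table.n_features else np.zeros(
        table.n_samples, dtype=np.int64
    )
    per_sample = {s: int(v) for s, v in zip(table.sample_ids, sums)}
    if not per_sample:
        raise FeatureTableValidationError("table has no samples")
    idx = int(np.argmin(sums))  # argmin returns the first minimal index
    return LibrarySizeSummary(per_sample, int(sums[idx]), table.sample_ids[idx])


def filter_by_taxonomy(
    table: FeatureTable,
    exclude_terms: list[str] | tuple[str, ...] = DEFAULT_EXCLUDE_TERMS,
    case_sensitive: bool = False,
) -> FeatureTable:
    """Remove features whose lineage contains any exclusion term.

    The canonical use is stripping organelle (mitochondria / chloroplast) 16S
    sequences. Matching is substring on the full lineage string,
    case-insensitive by default because rank prefixes vary across reference
    databases. Features lacking a taxonomy annotation are retained: absence of
    annotation is not evidence of organelle origin.
    """
    if not exclude_terms or table.taxonomy is None:
        if exclude_terms and table.taxonomy is None:
            raise FeatureTableValidationError(
                "cannot filter by taxonomy: table has no taxonomy annotations"
            )
        return table
    terms = [t if case_sensitive else t.lower() for t in exclude_terms]

    def hit(fid: str) -> bool:
        lineage = table.taxonomy.get(fid)
        if lineage is None:
            return False
        hay = lineage if case_sensitive else lineage.lower()
        return any(t in hay for t in terms)

    keep = np.array([not hit(f) for f in table.feature_ids], dtype=bool)
    return table.select_features(keep)


def filter_min_count(table: FeatureTable, min_total: int) -> FeatureTable:
    """Keep features whose total count across samples is >= ``min_total``."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    if table.n_features == 0:
        return table
    totals = np.asarray(table.counts).sum(axis=1)
    return table.select_features(totals >= min_total)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def _detect_format(path: str) -> str:
    lower = str(path).lower()
    return "biom" if lower.endswith(".biom") else "tsv"


def read_feature_table(
    path: str, format: str | None = None, orientation: str = "features_as_rows"
) -> FeatureTable:
    """Read a feature table from TSV or BIOM (JSON 1.0 / HDF5 2.1).

    TSV dialect: first column holds feature IDs (header ``#OTU ID`` or
    ``feature_id``), remaining columns are samples; an optional final
    ``taxonomy`` column holds semicolon-delimited lineages. ``orientation``
    may be set to ``"samples_as_rows"`` for transposed TSV input.
    """
    if format is None:
        format = _detect_format(path)
    if format == "tsv":
        return _read_tsv(path, orientation)
    if format == "biom":
        return _read_biom(path)
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'biom'")


def write_feature_table(table: FeatureTable, path: str, format: str | None = None) -> str:
    """Write a feature table; ``read_feature_table`` round-trips it exactly."""
    if format is None:
        format = _detect_format(path)
    if format == "tsv":
        _write_tsv(table, path)
    elif format == "biom":
        _write_biom(table, path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'biom'")
    return path


def _read_tsv(path: str, orientation: str) -> FeatureTable:
    with open(path, "r", encoding="utf-8") as fh:
        # tolerate a leading "# Constructed from ..." comment line as written
        # by classic QIIME exports
        pos = fh.tell()
        first = fh.readline()
        if first.startswith("#") and not any(first.startswith(h) for h in _ID_HEADERS):
            pos = fh.tell()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", dtype=str, index_col=0)
    taxonomy = None
    if _TAXONOMY_COLUMN in df.columns:
        tax_col = df.pop(_TAXONOMY_COLUMN)
        taxonomy = {
            str(f): str(t) for f, t in tax_col.items() if pd.notna(t) and str(t) != ""
        }
    if orientation == "samples_as_rows":
        df = df.T
    elif orientation != "features_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    feature_ids = [str(i) for i in df.index]
    sample_ids = [str(c) for c in df.columns]
    counts = np.zeros(df.shape, dtype=np.int64)
    values = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = values[i, j]
            try:
                as_float = float(cell)
            except (TypeError, ValueError):
                raise FeatureTableValidationError(
                    f"non-numeric cell {cell!r} at feature {feature_ids[i]!r}, "
                    f"sample {sample_ids[j]!r}"
                ) from None
            if not float(as_float).is_integer():
                raise FeatureTableValidationError(
                    f"non-integer cell {cell!r} at feature {feature_ids[i]!r}, "
                    f"sample {sample_ids[j]!r}"
                )
            counts[i, j] = int(as_float)
    return FeatureTable(tuple(feature_ids), tuple(sample_ids), counts, taxonomy)


def _write_tsv(table: FeatureTable, path: str) -> None:
    df = table.to_dataframe()
    df.index.name = "#OTU ID"
    if table.taxonomy is not None:
        df[_TAXONOMY_COLUMN] = [table.taxonomy.get(f, "") for f in table.feature_ids]
    df.to_csv(path, sep="\t")


def _read_biom(path: str) -> FeatureTable:
    from skbio.table import Table

    with open(path, "rb") as fh:
        magic = fh.read(8)
    if magic.startswith(b"\x89HDF"):
        import h5py

        with h5py.File(path, "r") as fh:
            biom = Table.from_hdf5(fh)
    else:
        with open(path, "r", encoding="utf-8") as fh:
            biom = Table.from_json(__import__("json").load(fh))
    counts = np.asarray(biom.matrix_data.todense())
    feature_ids = tuple(str(i) for i in biom.ids(axis="observation"))
    sample_ids = tuple(str(i) for i in biom.ids(axis="sample"))
    taxonomy = None
    md = biom.metadata(axis="observation")
    if md is not None:
        taxonomy = {}
        for fid, m in zip(feature_ids, md):
            if m and m.get("taxonomy"):
                lineage = m["taxonomy"]
                if not isinstance(lineage, str):
                    lineage = ";".join(str(r) for r in lineage)
                taxonomy[fid] = lineage
        taxonomy = taxonomy or None
    if counts.size and np.any(counts != np.rint(counts)):
        raise FeatureTableValidationError(f"BIOM table {path!r} holds non-integer counts")
    return FeatureTable(feature_ids, sample_ids, counts.astype(np.int64), taxonomy)


def _write_biom(table: FeatureTable, path: str) -> None:
    from skbio.table import Table

    obs_md = None
    if table.taxonomy is not None:
        obs_md = [
            {"taxonomy": table.taxonomy.get(f, "").split(";") if f in table.taxonomy else []}
            for f in table.feature_ids
        ]
    biom = Table(
        np.asarray(table.counts, dtype=float),
        observation_ids=list(table.feature_ids),
        sample_ids=list(table.sample_ids),
        observation_metadata=obs_md,
    )
    if str(path).lower().endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as fh:
            biom.to_hdf5(fh, generated_by="rarebands")
    else:
        with open(path, "w", encoding="utf-8") as fh:
            biom.to_json(generated_by="rarebands", direct_io=fh)
    if not os.path.exists(path):  # pragma: no cover - defensive
        raise IOError(f"failed to write {path!r}")
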