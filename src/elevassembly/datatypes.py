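"""Core data containers for elevation-gradient community analysis.

The package works with four objects throughout:

* :class:`OtuTable` — a samples × OTUs abundance matrix (raw integer counts
  or normalized real abundances), stored as a :class:`pandas.DataFrame`.
* sample metadata — a :class:`pandas.DataFrame` indexed by sample id with an
  ``elevation`` column (meters) and optional ``pH``, ``temperature``,
  ``SOM``, ``group``, ``latitude``, ``longitude``, ``site`` columns.
* a rooted phylogeny — a :class:`skbio.TreeNode` whose tips are OTU ids.
* distance matrices — :class:`skbio.DistanceMatrix` (symmetric, hollow).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "OtuTable",
    "ValidatedDataset",
    "ValidationError",
    "validate_metadata",
    "validate_dataset",
    "as_distance_matrix",
]

#: columns recognised in sample metadata beyond the mandatory two
OPTIONAL_METADATA_COLUMNS = (
    "pH",
    "temperature",
    "SOM",
    "group",
    "latitude",
    "longitude",
    "site",
)


class ValidationError(ValueError):
    """Raised when a table, metadata frame or tree violates its contract."""


@dataclass
class OtuTable:
    """Samples × OTUs abundance matrix.

    Parameters
    ----------
    counts
        Non-negative matrix with sample ids as the index and OTU ids as the
        columns. Raw tables hold integer counts; normalized tables hold real
        abundances.
    normalized
        Whether the values have been normalized. Richness and the
        Raup–Crick null model require raw counts and refuse normalized
        tables.
    norm_method
        ``"css"`` or ``"tss"`` for normalized tables, ``None`` for raw.
    """

    counts: pd.DataFrame
    normalized: bool = False
    norm_method: str | None = None
    norm_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.counts
        if not isinstance(df, pd.DataFrame):
            df = pd.DataFrame(df)
            self.counts = df
        if df.shape[0] == 0:
            raise ValidationError("no samples in OTU table")
        if df.shape[1] == 0:
            raise ValidationError("no OTUs in OTU table")
        dup_s = df.index[df.index.duplicated()].unique().tolist()
        if dup_s:
            raise ValidationError(f"duplicate sample ids: {dup_s}")
        dup_o = df.columns[df.columns.duplicated()].unique().tolist()
        if dup_o:
            raise ValidationError(f"duplicate OTU ids: {dup_o}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = np.argwhere(~np.vectorize(np.isreal)(values))
            raise ValidationError(f"non-numeric cells at {bad[:5].tolist()}")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))
            raise ValidationError(f"non-finite cells at {bad[:5].tolist()}")
        if (values < 0).any():
            bad = np.argwhere(values < 0)
            coords = [
                (df.index[i], df.columns[j]) for i, j in bad[:5]
            ]
            raise ValidationError(f"negative abundances at {coords}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)

    @property
    def library_sizes(self) -> pd.Series:
        """Per-sample total abundance (reads for raw tables)."""
        return self.counts.sum(axis=1)

    def require_raw(self, operation: str) -> None:
        if self.normalized:
            raise ValidationError(
                f"{operation} requires raw counts, got a table normalized "
                f"with {self.norm_method!r}"
            )

    def presence(self) -> pd.DataFrame:
        """Boolean presence/absence view (abundance > 0)."""
        return self.counts > 0

    def subset_samples(self, sample_ids) -> "OtuTable":
        return OtuTable(
            self.counts.loc[list(sample_ids)],
            normalized=self.normalized,
            norm_method=self.norm_method,
            norm_params=dict(self.norm_params),
        )

    def subset_otus(self, otu_ids) -> "OtuTable":
        return OtuTable(
            self.counts[list(otu_ids)],
            normalized=self.normalized,
            norm_method=self.norm_method,
            norm_params=dict(self.norm_params),
        )


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata frame (index = sample id).

    Requires a finite ``elevation`` column; pH values, where present, must
    lie strictly inside (0, 14). Returns the frame unchanged on success.
    """
    if "elevation" not in metadata.columns:
        raise ValidationError("metadata is missing the 'elevation' column")
    dup = metadata.index[metadata.index.duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"duplicate sample ids in metadata: {dup}")
    elev = pd.to_numeric(metadata["elevation"], errors="coerce")
    if elev.isna().any() or not np.isfinite(elev.to_numpy()).all():
        bad = metadata.index[~np.isfinite(
            pd.to_numeric(metadata["elevation"], errors="coerce").fillna(np.inf)
        )].tolist()
        raise ValidationError(f"non-finite elevation for samples: {bad}")
    if "pH" in metadata.columns:
        ph = pd.to_numeric(metadata["pH"], errors="coerce").dropna()
        bad = ph[(ph <= 0) | (ph >= 14)]
        if len(bad):
            raise ValidationError(
                f"pH outside (0, 14) for samples: {bad.index.tolist()}"
            )
    return metadata


@dataclass
class ValidatedDataset:
    """An OTU table, metadata frame and tree with mutually consistent ids.

    ``metadata`` is reindexed to the table's samples; the tree covers at
    least the table's OTUs (optionally sheared down to exactly them).
    """

    table: OtuTable
    metadata: pd.DataFrame
    tree: TreeNode


def validate_dataset(
    table: OtuTable,
    metadata: pd.DataFrame,
    tree: TreeNode | None = None,
    on_unmatched_otus: str = "error",
    shear_tree: bool = True,
) -> ValidatedDataset:
    """Cross-validate a table, metadata and (optional) tree.

    Every table sample must appear in the metadata; every table OTU must be
    a tree tip. ``on_unmatched_otus="prune"`` drops table OTUs missing from
    the tree with a warning instead of raising.
    """
    validate_metadata(metadata)
    missing_samples = [s for s in table.sample_ids if s not in metadata.index]
    if missing_samples:
        raise ValidationError(
            f"samples absent from metadata: {missing_samples}"
        )
    meta = metadata.loc[table.sample_ids].copy()

    if tree is not None:
        tips = {t.name for t in tree.tips()}
        unmatched = [o for o in table.otu_ids if o not in tips]
        if unmatched:
            if on_unmatched_otus == "prune":
                warnings.warn(
                    f"dropping {len(unmatched)} OTUs absent from tree: "
                    f"{unmatched[:5]}..."
                )
                keep = [o for o in table.otu_ids if o in tips]
                if not keep:
                    raise ValidationError("no table OTUs found in tree")
                table = table.subset_otus(keep)
            else:
                raise ValidationError(
                    f"OTUs absent from tree: {unmatched}"
                )
        if shear_tree and tips - set(table.otu_ids):
            tree = tree.shear(table.otu_ids)
            tree.prune()
    return ValidatedDataset(table=table, metadata=meta, tree=tree)


def as_distance_matrix(values: np.ndarray, ids, metric_name: str = "") -> DistanceMatrix:
    """Build a :class:`skbio.DistanceMatrix`, symmetrising tiny float noise.

    Values must be symmetric within 1e-10 with an (enforced) zero diagonal.
    """
    values = np.asarray(values, dtype=float)
    if not np.allclose(values, values.T, atol=1e-10):
        raise ValidationError(f"{metric_name or 'distance'} matrix not symmetric")
    sym = (values + values.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    return DistanceMatrix(sym, ids=list(ids))
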