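"""Shared community-data container.

A :class:`CountTable` holds a samples-by-ASV matrix of non-negative integer
read counts together with optional per-sample metadata (location within the
reactor — anode, cathode or suspension — and reactor id).  It is the object
that flows through filtering, phylogenetic merging, diversity and network
stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LOCATIONS = ("anode", "cathode", "suspension")


@dataclass
class CountTable:
    """Samples x ASVs read-count matrix with optional sample metadata.

    Parameters
    ----------
    counts
        DataFrame with samples as rows and ASV ids as columns; values must be
        non-negative integers.
    sample_meta
        Optional DataFrame indexed like ``counts`` with columns such as
        ``location`` and ``reactor``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate ASV ids: {dups}")
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if values.size and (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.sample_meta is not None:
            missing = self.counts.index.difference(self.sample_meta.index)
            if len(missing):
                raise ValueError(f"sample_meta missing samples: {missing.tolist()}")

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[1]

    def relative_abundances(self) -> pd.DataFrame:
        """Per-sample proportions (each row sums to 1; empty rows stay 0)."""
        totals = self.counts.sum(axis=1)
        rel = self.counts.div(totals.replace(0, np.nan), axis=0)
        return rel.fillna(0.0)

    def subset_samples(self, sample_ids) -> "CountTable":
        meta = None
        if self.sample_meta is not None:
            meta = self.sample_meta.loc[list(sample_ids)]
        return CountTable(self.counts.loc[list(sample_ids)].copy(), meta)

    def copy(self) -> "CountTable":
        meta = None if self.sample_meta is None else self.sample_meta.copy()
        return CountTable(self.counts.copy(), meta)
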