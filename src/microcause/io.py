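"""Tabular and tree I/O plus the core count-matrix container.

All on-disk formats are plain text: TSV for matrices and metadata,
Newick for trees, JSON for configuration and truth ledgers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "read_counts_tsv",
    "read_metadata_tsv",
    "read_taxonomy_tsv",
    "read_newick",
    "write_newick",
]

#: Taxonomic ranks recognized in taxonomy tables, coarsest first.
RANKS = ("Phylum", "Class", "Order", "Family", "Genus")


@dataclass
class CountMatrix:
    """Samples x taxa table of non-negative integer counts.

    Parameters
    ----------
    counts : ndarray of shape (n_samples, n_taxa)
        Non-negative counts; every sample must have at least one
        positive cell.
    sample_ids, taxon_ids : sequences of str
        Row and column labels.
    taxonomy : DataFrame, optional
        Indexed by taxon id with rank columns (``Phylum`` ... ``Genus``).
    """

    counts: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    taxonomy: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional")
        n, a = self.counts.shape
        if n != len(self.sample_ids) or a != len(self.taxon_ids):
            raise ValueError("counts shape does not match id lists")
        if (self.counts < 0).any():
            raise ValueError("negative counts are not allowed")
        if (self.counts.sum(axis=1) <= 0).any():
            bad = [self.sample_ids[i] for i in
                   np.where(self.counts.sum(axis=1) <= 0)[0]]
            raise ValueError(f"samples with all-zero counts: {bad}")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.taxon_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       taxonomy: pd.DataFrame | None = None) -> "CountMatrix":
        return cls(df.to_numpy(), list(df.index.astype(str)),
                   list(df.columns.astype(str)), taxonomy)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        """Return a new matrix restricted to ``sample_ids``, in that order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        idx = [pos[s] for s in sample_ids]
        return CountMatrix(self.counts[idx], list(sample_ids),
                           list(self.taxon_ids), self.taxonomy)

    def subset_taxa(self, taxon_ids: Sequence[str]) -> "CountMatrix":
        pos = {t: i for i, t in enumerate(self.taxon_ids)}
        missing = [t for t in taxon_ids if t not in pos]
        if missing:
            raise KeyError(f"unknown taxon ids: {missing}")
        idx = [pos[t] for t in taxon_ids]
        tax = None
        if self.taxonomy is not None:
            tax = self.taxonomy.loc[[t for t in taxon_ids]]
        return CountMatrix(self.counts[:, idx], list(self.sample_ids),
                           list(taxon_ids), tax)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path,
                    taxonomy: pd.DataFrame | None = None) -> CountMatrix:
    """Read a counts TSV (first column sample_id, remaining columns taxa)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix.from_dataframe(df, taxonomy)


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    """Read a per-sample metadata TSV (covariates plus ``exposure``)."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    df.index = df.index.astype(str)
    return df


def read_taxonomy_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="taxon_id")
    df.index = df.index.astype(str)
    return df


def read_newick(path: str | Path) -> str:
    """Read a Newick file and return the (stripped) newick string."""
    text = Path(path).read_text().strip()
    if not text.endswith(";"):
        raise ValueError(f"{path} does not look like a Newick file")
    return text


def write_newick(newick: str, path: str | Path) -> None:
    newick = newick.strip()
    if not newick.endswith(";"):
        newick += ";"
    Path(path).write_text(newick + "\n")


def write_json(obj, path: str | Path) -> None:
    """Serialize ``obj`` deterministically (sorted keys, no timestamps)."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"cannot serialize {type(o)!r}")
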