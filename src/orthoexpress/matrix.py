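"""Count-matrix container shared by every stage of the pipeline.

A :class:`CountMatrix` couples a loci x samples table of non-negative
integer read counts with a sample sheet that maps each sample to a taxon
label and a replicate index.  The four default taxa are the two parental
species (``bro`` = *Argyranthemum broussonetii*, ``fru`` =
*A. frutescens*) and the two homoploid hybrid species (``sun`` =
*A. sundingii*, ``lem`` = *A. lemsii*).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "read_counts", "write_counts"]

SAMPLE_SHEET_COLUMNS = ("sample", "taxon", "replicate")


@dataclass
class CountMatrix:
    """Loci x samples integer counts plus per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by locus id with one column per sample id.
        Values must be non-negative integers.
    samples
        DataFrame indexed by sample id with columns ``taxon`` and
        ``replicate``.  Its index must match ``counts.columns``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate locus ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("sample sheet does not match count matrix columns")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.round().astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if "taxon" not in self.samples.columns:
            raise ValueError("sample sheet needs a 'taxon' column")

    # -- convenience accessors -------------------------------------------

    @property
    def locus_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def taxa(self) -> list[str]:
        return list(dict.fromkeys(self.samples["taxon"]))

    def lib_sizes(self) -> pd.Series:
        """Raw library sizes (column sums)."""
        return self.counts.sum(axis=0)

    def samples_of(self, taxon: str) -> list[str]:
        hit = self.samples.index[self.samples["taxon"] == taxon]
        if len(hit) == 0:
            raise KeyError(f"unknown taxon label: {taxon!r}")
        return list(hit)

    def group_indices(self) -> dict[str, np.ndarray]:
        """Column indices of each taxon, in sample-sheet order."""
        cols = {s: i for i, s in enumerate(self.counts.columns)}
        return {
            t: np.array([cols[s] for s in self.samples_of(t)], dtype=int)
            for t in self.taxa
        }

    def subset_loci(self, loci) -> "CountMatrix":
        return CountMatrix(self.counts.loc[loci], self.samples.copy())


def read_counts(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    """Read a count TSV (first column locus id) and a sample sheet TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    try:
        samples = pd.read_csv(samples_path, sep="\t", dtype={"sample": str})
    except Exception as exc:  # pragma: no cover - passthrough context
        raise ValueError(f"could not parse sample sheet {samples_path}: {exc}") from exc
    missing = [c for c in SAMPLE_SHEET_COLUMNS[:2] if c not in samples.columns]
    if missing:
        raise ValueError(
            f"sample sheet {samples_path} lacks required column(s) {missing}"
        )
    samples = samples.set_index("sample")
    # order samples to the count-matrix columns
    absent = [s for s in counts.columns if s not in samples.index]
    if absent:
        raise ValueError(f"sample sheet {samples_path} missing samples {absent}")
    samples = samples.loc[list(counts.columns)]
    return CountMatrix(counts, samples)


def write_counts(cm: CountMatrix, counts_path: str | Path, samples_path: str | Path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="locus")
    cm.samples.to_csv(samples_path, sep="\t", index_label="sample")
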