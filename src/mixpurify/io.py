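"""Expression-matrix I/O and TPM computation.

Matrices are gene x sample tables of non-negative values, tagged with a
unit: raw read ``counts`` or ``tpm`` (transcripts per million, every column
summing to one million).  Files are plain tab-separated text with a
``gene_id`` first column and one header row of sample ids; gene-length
tables are two-column TSV (``gene_id``, ``length_bp`` of merged exons).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TPM_SUM = 1e6
_FLOAT_FMT = "%.10g"  # 10 significant digits on disk


@dataclass
class ExpressionMatrix:
    """A gene x sample expression table with a unit tag.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes on the index, samples on the columns, non-negative entries.
    unit : {"counts", "tpm"}
        If ``tpm``, every column must sum to 1e6 (relative tolerance 1e-6).
    """

    values: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "tpm"):
            raise ValueError(f"unknown unit {self.unit!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy(dtype=float)
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative value at gene {idx[g]!r}, sample {cols[s]!r}"
            )
        if self.unit == "tpm":
            sums = arr.sum(axis=0)
            bad = ~np.isclose(sums, TPM_SUM, rtol=1e-6)
            if bad.any():
                raise ValueError(
                    f"TPM columns must sum to 1e6; offending samples: "
                    f"{list(cols[bad])}"
                )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def sample(self, sample_id: str) -> pd.Series:
        """Return one sample's expression vector."""
        if sample_id not in self.values.columns:
            raise KeyError(f"sample {sample_id!r} not in matrix")
        return self.values[sample_id]


@dataclass
class GeneLengthTable:
    """Merged-exon lengths (bp) per gene, used for TPM computation."""

    lengths: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))

    def __post_init__(self) -> None:
        if self.lengths.index.has_duplicates:
            dups = self.lengths.index[self.lengths.index.duplicated()]
            raise ValueError(f"duplicate gene ids in length table: {list(dups.unique())}")
        if (self.lengths <= 0).any():
            bad = self.lengths.index[self.lengths <= 0].tolist()
            raise ValueError(f"non-positive gene lengths: {bad}")


def compute_tpm(counts: ExpressionMatrix, lengths: GeneLengthTable) -> ExpressionMatrix:
    """Convert read counts to transcripts per million.

    Per sample, each gene's count is divided by its merged-exon length to
    give a transcript rate; rates are normalised to sum to one million.
    Genes present in the length table but absent from the counts matrix are
    ignored: the counts matrix defines the gene universe.

    Raises
    ------
    ValueError
        If a gene is missing from the length table (named in the message),
        or a sample has zero total counts.
    """
    if counts.unit != "counts":
        raise ValueError("compute_tpm expects a counts matrix")
    missing = counts.gene_ids.difference(lengths.lengths.index)
    if len(missing) > 0:
        raise ValueError(f"no length for gene(s): {list(missing)}")
    length_vec = lengths.lengths.reindex(counts.gene_ids).to_numpy(dtype=float)
    arr = counts.values.to_numpy(dtype=float)
    rates = arr / length_vec[:, None]
    totals = rates.sum(axis=0)
    zero = totals == 0
    if zero.any():
        raise ValueError(
            f"all-zero counts in sample(s): {list(counts.sample_ids[zero])}"
        )
    tpm = rates / totals[None, :] * TPM_SUM
    return ExpressionMatrix(
        pd.DataFrame(tpm, index=counts.gene_ids, columns=counts.sample_ids),
        unit="tpm",
    )


def read_matrix(path: str | Path, unit: str) -> ExpressionMatrix:
    """Read a gene x sample TSV (first column gene id, header of sample ids)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise ValueError(f"duplicate sample ids in {path}: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = samples  # keep verbatim header (pandas mangles duplicates)
    return ExpressionMatrix(df, unit=unit)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with 10 significant digits."""
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_gene_lengths(path: str | Path) -> GeneLengthTable:
    """Read a two-column gene-length TSV (gene_id, length_bp)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GeneLengthTable(df.iloc[:, 0].astype(int))
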