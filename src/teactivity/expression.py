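"""Expression preparation: count filtering, log2-TPM, double centering, deltas.

The response of the activity model is the stacked vector of per-pair
treatment-minus-control differences of the doubly centered log2-TPM matrix.
Double centering removes gene-specific basal levels and sample-specific
offsets (library depth, batch); pairing removes everything shared between a
treatment sample and its control, leaving the treatment-induced shift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "ExpressionMatrix",
    "PairDesign",
    "DeltaExpression",
    "filter_genes",
    "normalize_log_tpm",
    "double_center",
    "build_delta",
    "read_counts_tsv",
    "read_pairs_tsv",
]


@dataclass
class CountTable:
    """Raw RNA-seq counts (genes × samples) with per-gene lengths in bp."""

    counts: pd.DataFrame
    gene_lengths: pd.Series

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            missing = list(self.counts.index[self.gene_lengths.isna()])[:5]
            raise ValueError(f"missing gene lengths for {missing}")
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class ExpressionMatrix:
    """Log2-TPM expression values with a record of the centering applied."""

    values: pd.DataFrame
    centering_state: str = "raw"  # raw | column_centered | doubly_centered


@dataclass
class PairDesign:
    """Ordered treatment/control sample pairs; a sample may repeat."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("at least one pair is required")

    @property
    def labels(self) -> list[str]:
        return [f"{t}-{c}" for t, c in self.pairs]


@dataclass
class DeltaExpression:
    """Stacked per-pair, per-gene expression differences (the response)."""

    values: np.ndarray
    gene_index: np.ndarray  # gene id per stacked row
    pair_index: np.ndarray  # pair label per stacked row

    def __post_init__(self) -> None:
        if not (len(self.values) == len(self.gene_index) == len(self.pair_index)):
            raise ValueError("values, gene_index and pair_index lengths differ")

    @property
    def genes(self) -> list[str]:
        """Unique gene ids in stacking order of the first pair."""
        first = self.pair_index == self.pair_index[0]
        return list(self.gene_index[first])

    @property
    def n_pairs(self) -> int:
        return len(dict.fromkeys(self.pair_index))


def filter_genes(
    ct: CountTable,
    min_count: int = 10,
    perturbed: Iterable[str] = (),
) -> CountTable:
    """Keep genes reaching ``min_count`` in at least one sample.

    Experimentally perturbed genes (e.g. an overexpressed transgene) are
    removed regardless of counts so their direct response is not mistaken
    for a cis-regulatory signal.
    """
    perturbed = set(perturbed)
    keep = (ct.counts.max(axis=1) >= min_count) & ~ct.counts.index.isin(perturbed)
    if not keep.any():
        raise ValueError("no genes pass the count filter")
    return CountTable(ct.counts.loc[keep], ct.gene_lengths.loc[keep])


def normalize_log_tpm(
    ct: CountTable, pseudocount_percentile: float = 5.0
) -> ExpressionMatrix:
    """Pseudocounted log2-TPM normalization.

    Per sample: the pseudocount is the 5th percentile of that column's
    non-zero raw counts (linear interpolation between order statistics);
    counts plus pseudocount are divided by gene length, scaled to sum to 1e6
    (TPM) and log2-transformed.
    """
    counts = ct.counts.to_numpy(dtype=float)
    lengths = ct.gene_lengths.to_numpy(dtype=float)
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        col = counts[:, j]
        nonzero = col[col > 0]
        if nonzero.size == 0:
            raise ValueError(
                f"sample {ct.sample_ids[j]!r} has all-zero counts; "
                "pseudocount percentile undefined"
            )
        pseudo = np.percentile(nonzero, pseudocount_percentile)
        rate = (col + pseudo) / lengths
        tpm = rate / rate.sum() * 1e6
        out[:, j] = np.log2(tpm)
    values = pd.DataFrame(out, index=ct.counts.index, columns=ct.counts.columns)
    return ExpressionMatrix(values=values, centering_state="raw")


def double_center(E: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract column means, then row means.

    Removes the sample offsets d_s and gene basal levels c_p of the additive
    expression model; the result has all row and column means equal to zero.
    Idempotent.
    """
    if E.centering_state == "doubly_centered":
        return ExpressionMatrix(E.values.copy(), "doubly_centered")
    values = E.values
    if values.shape[1] == 1:
        warnings.warn("single-sample matrix: column centering yields all zeros")
    centered = values - values.mean(axis=0)
    centered = centered.sub(centered.mean(axis=1), axis=0)
    return ExpressionMatrix(values=centered, centering_state="doubly_centered")


def build_delta(E: ExpressionMatrix, design: PairDesign) -> DeltaExpression:
    """Stack treatment-minus-control difference vectors in design order."""
    if E.centering_state != "doubly_centered":
        raise ValueError("expression matrix must be doubly centered")
    samples = set(E.values.columns)
    for t, c in design.pairs:
        if t not in samples or c not in samples:
            missing = t if t not in samples else c
            raise ValueError(f"pair sample {missing!r} not in expression matrix")
    blocks, gene_idx, pair_idx = [], [], []
    genes = np.asarray(E.values.index, dtype=object)
    for (t, c), label in zip(design.pairs, design.labels):
        blocks.append(E.values[t].to_numpy() - E.values[c].to_numpy())
        gene_idx.append(genes)
        pair_idx.append(np.full(len(genes), label, dtype=object))
    return DeltaExpression(
        values=np.concatenate(blocks),
        gene_index=np.concatenate(gene_idx),
        pair_index=np.concatenate(pair_idx),
    )


# ---------------------------------------------------------------------------
# readers


def read_counts_tsv(
    path: str | Path, lengths_path: str | Path | None = None
) -> CountTable:
    """Read a counts TSV (first column gene_id, header of sample ids).

    Gene lengths come either from a ``length`` column in the counts file or
    from a separate two-column TSV (gene_id, length).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "length" in df.columns:
        lengths = df.pop("length")
    elif lengths_path is not None:
        lt = pd.read_csv(lengths_path, sep="\t", index_col=0)
        lengths = lt.iloc[:, 0]
    else:
        raise ValueError("gene lengths required: 'length' column or lengths file")
    return CountTable(counts=df, gene_lengths=lengths)


def read_pairs_tsv(path: str | Path) -> PairDesign:
    """Read a two-column TSV of (treatment, control) sample ids."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (treatment, control)")
    first = tuple(df.iloc[0])
    if first[:2] == ("treatment", "control"):
        df = df.iloc[1:]
    return PairDesign(pairs=[(t, c) for t, c in zip(df[0], df[1])])
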