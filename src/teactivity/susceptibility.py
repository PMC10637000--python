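"""Gene × TE-subfamily regulatory-susceptibility matrices.

The susceptibility ``N[p, m]`` measures how exposed gene ``p`` is to
subfamily ``m``: in *hard* mode the number of merged integrants overlapping
the gene's cis-regulatory windows, in *weighted* mode a sum of Gaussian
kernel weights of TE-promoter center distances. In both modes, integrants
overlapping the gene's promoters or exons are excluded — per gene, so a TE
inside gene A's exon may still count for a neighbouring gene B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomicInterval, TEIntegrant, build_windows

logger = logging.getLogger(__name__)

__all__ = [
    "SusceptibilityMatrix",
    "FunctionalSplit",
    "kernel_weight",
    "gene_susceptibility_hard",
    "gene_susceptibility_weighted",
    "assemble_matrix",
    "filter_subfamilies",
    "split_functional",
    "FUNCTIONAL_SUFFIX",
    "NONFUNCTIONAL_SUFFIX",
]

FUNCTIONAL_SUFFIX = ".functional"
NONFUNCTIONAL_SUFFIX = ".nonfunctional"


def kernel_weight(d, L: float):
    """Gaussian distance weight ``exp(-d^2 / (2 L^2))``.

    ``d`` is the base-pair distance between a TE center and the closest
    promoter center; ``L`` is the kernel bandwidth (standard deviation) in
    base pairs. Accepts scalars or arrays; equals 1 at d = 0 and decays
    strictly with distance.
    """
    if L <= 0:
        raise ValueError(f"bandwidth L must be positive, got {L}")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    w = np.exp(-(d**2) / (2.0 * float(L) ** 2))
    return w if w.ndim else float(w)


@dataclass
class SusceptibilityMatrix:
    """Genes × subfamilies matrix with its build metadata.

    ``values`` is a DataFrame with gene_ids as the index and subfamily labels
    as columns; hard-mode entries are integer counts.
    """

    values: pd.DataFrame
    mode: str  # "hard" | "weighted"
    flank: int | None = None
    bandwidth_L: float | None = None
    tad_restricted: bool = False

    def __post_init__(self) -> None:
        if self.mode not in {"hard", "weighted"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate subfamily columns")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene_ids")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("susceptibilities must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def subfamilies(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# mode: {self.mode}\n")
            if self.mode == "hard":
                fh.write(f"# flank: {self.flank}\n")
            else:
                fh.write(f"# bandwidth_L: {self.bandwidth_L}\n")
            fh.write(f"# tad_restricted: {self.tad_restricted}\n")
            self.values.to_csv(fh, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SusceptibilityMatrix":
        meta: dict[str, str] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].strip().partition(":")
                meta[key.strip()] = val.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            values = pd.read_csv(fh, sep="\t", index_col="gene_id")
        mode = meta.get("mode", "hard")
        flank = int(meta["flank"]) if meta.get("flank", "None") != "None" else None
        L = (
            float(meta["bandwidth_L"])
            if meta.get("bandwidth_L", "None") != "None"
            else None
        )
        return cls(
            values=values,
            mode=mode,
            flank=flank,
            bandwidth_L=L,
            tad_restricted=meta.get("tad_restricted", "False") == "True",
        )

    def to_mtx(self, prefix: str | Path) -> None:
        """Write sparse MTX plus row/column label files (``<prefix>.mtx`` …)."""
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        prefix = str(prefix)
        mmwrite(prefix + ".mtx", csr_matrix(self.values.to_numpy()))
        Path(prefix + ".genes.txt").write_text(
            "\n".join(self.gene_ids) + "\n"
        )
        Path(prefix + ".subfamilies.txt").write_text(
            "\n".join(self.subfamilies) + "\n"
        )


@dataclass
class FunctionalSplit:
    """Configuration for splitting subfamilies by overlap with functional ranges."""

    functional_ranges: list[GenomicInterval]
    protected_subfamilies: set[str] = field(default_factory=set)
    min_fraction_total: float = 100.0

    def __post_init__(self) -> None:
        if not self.functional_ranges:
            raise ValueError("functional_ranges must be non-empty")


# ---------------------------------------------------------------------------
# vectorized per-chromosome TE arrays


class _ChromTEs:
    """Sorted per-chromosome arrays of merged integrants for vector ops."""

    def __init__(self, tes: Sequence[TEIntegrant]):
        self.start = np.array([t.interval.start for t in tes], dtype=np.int64)
        self.end = np.array([t.interval.end for t in tes], dtype=np.int64)
        self.center = (self.start + self.end) // 2
        self.subfamily = np.array([t.subfamily for t in tes], dtype=object)

    def __len__(self) -> int:
        return len(self.start)

    def overlap_mask(self, intervals: Sequence[GenomicInterval]) -> np.ndarray:
        mask = np.zeros(len(self), dtype=bool)
        for iv in intervals:
            mask |= (self.start < iv.end) & (self.end > iv.start)
        return mask


def _group_by_chrom(tes: Iterable[TEIntegrant]) -> dict[str, _ChromTEs]:
    by_chrom: dict[str, list[TEIntegrant]] = {}
    for te in tes:
        by_chrom.setdefault(te.interval.chrom, []).append(te)
    return {c: _ChromTEs(members) for c, members in by_chrom.items()}


def _tad_index(centers: np.ndarray, tads: Sequence[GenomicInterval]) -> np.ndarray:
    """TAD id per center under half-open membership; -1 when in no TAD."""
    idx = np.full(centers.shape, -1, dtype=np.int64)
    for i, tad in enumerate(tads):
        idx[(centers >= tad.start) & (centers < tad.end)] = i
    return idx


def _retained_mask(gene: GeneModel, chrom_tes: _ChromTEs) -> np.ndarray:
    """True for integrants not overlapping the gene's promoters or exons."""
    excluded = chrom_tes.overlap_mask(gene.promoters) | chrom_tes.overlap_mask(
        gene.exon_union
    )
    return ~excluded


def _sum_by_subfamily(
    subfamilies: np.ndarray, weights: np.ndarray
) -> dict[str, float]:
    out: dict[str, float] = {}
    for sf, w in zip(subfamilies, weights):
        if w != 0:
            out[sf] = out.get(sf, 0.0) + float(w)
    return out


def gene_susceptibility_hard(
    gene: GeneModel, tes: Sequence[TEIntegrant], flank: int = 50_000
) -> dict[str, int]:
    """Per-subfamily counts of merged integrants in the gene's windows.

    ``tes`` must be merged integrants on the gene's chromosome. Integrants
    overlapping the gene's promoters or exon union are excluded.
    """
    chrom_tes = tes if isinstance(tes, _ChromTEs) else _ChromTEs(list(tes))
    windows = build_windows(gene.promoters, flank)
    mask = chrom_tes.overlap_mask(windows) & _retained_mask(gene, chrom_tes)
    counts = _sum_by_subfamily(chrom_tes.subfamily[mask], mask[mask].astype(int))
    return {sf: int(v) for sf, v in counts.items()}


def gene_susceptibility_weighted(
    gene: GeneModel,
    tes: Sequence[TEIntegrant],
    L: float,
    tads: Sequence[GenomicInterval] | None = None,
) -> dict[str, float]:
    """Per-subfamily sums of Gaussian weights over same-chromosome integrants.

    Each retained integrant contributes ``kernel_weight(d, L)`` where ``d``
    is the distance between its center and the center of the gene's closest
    promoter. With ``tads``, the weight is zeroed whenever the TE center and
    that closest promoter center fall in different TADs or either falls in
    no TAD.
    """
    chrom_tes = tes if isinstance(tes, _ChromTEs) else _ChromTEs(list(tes))
    mask = _retained_mask(gene, chrom_tes)
    if not mask.any():
        return {}
    centers = chrom_tes.center[mask]
    prom_centers = np.array([p.center for p in gene.promoters], dtype=np.int64)
    dists = np.abs(centers[:, None] - prom_centers[None, :])
    nearest = np.argmin(dists, axis=1)
    d = dists[np.arange(len(centers)), nearest]
    w = kernel_weight(d, L)
    if tads is not None:
        te_tad = _tad_index(centers, tads)
        prom_tad = _tad_index(prom_centers, tads)[nearest]
        w = np.where((te_tad >= 0) & (te_tad == prom_tad), w, 0.0)
    return _sum_by_subfamily(chrom_tes.subfamily[mask], w)


def assemble_matrix(
    genes: Sequence[GeneModel],
    tes: Sequence[TEIntegrant],
    mode: str = "hard",
    flank: int = 50_000,
    L: float | None = None,
    tads: Sequence[GenomicInterval] | None = None,
) -> SusceptibilityMatrix:
    """Assemble the full susceptibility matrix over ``genes`` × subfamilies.

    ``tes`` should be post-merge integrants. Rows follow the given gene
    order; columns are sorted by subfamily label; all-zero rows are kept
    (filtering is a separate step).
    """
    gene_ids = [g.gene_id for g in genes]
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise ValueError(f"duplicate gene_ids: {dupes[:5]}")
    if mode == "weighted" and (L is None or L <= 0):
        raise ValueError("weighted mode requires a positive bandwidth L")

    by_chrom = _group_by_chrom(tes)
    tads_by_chrom: dict[str, list[GenomicInterval]] = {}
    if tads is not None:
        for tad in tads:
            tads_by_chrom.setdefault(tad.chrom, []).append(tad)

    subfamilies = sorted({t.subfamily for t in tes})
    col_of = {sf: j for j, sf in enumerate(subfamilies)}
    mat = np.zeros((len(genes), len(subfamilies)))
    for i, gene in enumerate(genes):
        chrom_tes = by_chrom.get(gene.chrom)
        if chrom_tes is None:
            continue
        if mode == "hard":
            row = gene_susceptibility_hard(gene, chrom_tes, flank)
        else:
            gene_tads = tads_by_chrom.get(gene.chrom, []) if tads is not None else None
            row = gene_susceptibility_weighted(gene, chrom_tes, L, gene_tads)
        for sf, v in row.items():
            mat[i, col_of[sf]] = v

    values = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"),
                          columns=subfamilies)
    if mode == "hard":
        values = values.astype(int)
    return SusceptibilityMatrix(
        values=values,
        mode=mode,
        flank=flank if mode == "hard" else None,
        bandwidth_L=L if mode == "weighted" else None,
        tad_restricted=tads is not None,
    )


def filter_subfamilies(
    N: SusceptibilityMatrix, min_total: float = 150.0
) -> SusceptibilityMatrix:
    """Drop subfamily columns whose susceptibility sum is < ``min_total``."""
    sums = N.values.sum(axis=0)
    keep = sums >= min_total
    dropped = list(sums.index[~keep])
    if dropped:
        logger.info("dropping %d subfamilies below %s: %s",
                    len(dropped), min_total, dropped)
    if not keep.any():
        raise ValueError("all subfamily columns fall below the threshold")
    return SusceptibilityMatrix(
        values=N.values.loc[:, keep],
        mode=N.mode,
        flank=N.flank,
        bandwidth_L=N.bandwidth_L,
        tad_restricted=N.tad_restricted,
    )


def split_functional(
    genes: Sequence[GeneModel],
    tes: Sequence[TEIntegrant],
    split: FunctionalSplit,
    reference_N: SusceptibilityMatrix,
    tads: Sequence[GenomicInterval] | None = None,
) -> SusceptibilityMatrix:
    """Split each subfamily into functional / non-functional fraction columns.

    An integrant is functional when it overlaps (≥ 1 bp) any functional
    range. The matrix is rebuilt with the reference's mode and parameters,
    restricted to subfamilies retained in ``reference_N``; fraction column
    sums always add up to the unsplit column. When either fraction of a
    non-protected subfamily sums below ``min_fraction_total``, both fractions
    are collapsed back to the unsplit reference column.
    """
    ranges_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in split.functional_ranges:
        ranges_by_chrom.setdefault(iv.chrom, []).append(iv)

    kept = set(reference_N.subfamilies)
    relabeled: list[TEIntegrant] = []
    for te in tes:
        if te.subfamily not in kept:
            continue
        chrom_ranges = ranges_by_chrom.get(te.interval.chrom, [])
        functional = any(te.interval.overlaps(r) for r in chrom_ranges)
        suffix = FUNCTIONAL_SUFFIX if functional else NONFUNCTIONAL_SUFFIX
        relabeled.append(
            TEIntegrant(te.interval, te.subfamily + suffix, te.instance_id)
        )

    split_N = assemble_matrix(
        genes,
        relabeled,
        mode=reference_N.mode,
        flank=reference_N.flank or 50_000,
        L=reference_N.bandwidth_L,
        tads=tads,
    )
    values = split_N.values.reindex(index=reference_N.values.index)

    columns: dict[str, pd.Series] = {}
    zeros = pd.Series(0.0, index=reference_N.values.index)
    for sf in reference_N.subfamilies:
        func = values.get(sf + FUNCTIONAL_SUFFIX, zeros)
        nonfunc = values.get(sf + NONFUNCTIONAL_SUFFIX, zeros)
        protected = sf in split.protected_subfamilies
        if not protected and (
            func.sum() < split.min_fraction_total
            or nonfunc.sum() < split.min_fraction_total
        ):
            logger.info("collapsing %s (fraction sums %.1f / %.1f)",
                        sf, func.sum(), nonfunc.sum())
            columns[sf] = reference_N.values[sf].astype(float)
        else:
            columns[sf + FUNCTIONAL_SUFFIX] = func
            columns[sf + NONFUNCTIONAL_SUFFIX] = nonfunc

    out = pd.DataFrame({k: columns[k] for k in sorted(columns)})
    if reference_N.mode == "hard":
        out = out.astype(int)
    return SusceptibilityMatrix(
        values=out,
        mode=reference_N.mode,
        flank=reference_N.flank,
        bandwidth_L=reference_N.bandwidth_L,
        tad_restricted=reference_N.tad_restricted,
    )
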