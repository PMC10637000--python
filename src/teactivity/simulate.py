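"""Synthetic genomes, annotations and count tables with known activities.

The generator emulates the structure the pipeline consumes in the field:
RepeatMasker-style TE integrants (some fragmented into pieces separated by
< 100 bp), multi-TSS gene models, and raw count tables produced by
inverting the log2-TPM normalization from a generative additive model

    E_ps = c_p + d_s + sum_m N_pm A_ms + eps

with gene basal levels c_p, sample offsets d_s, Gaussian noise eps, and
condition-specific activities A encoding the treatment-minus-control
differences. Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    GeneModel,
    GenomicInterval,
    TEIntegrant,
    build_promoters,
    merge_fragments,
    union_intervals,
    write_gene_table,
    write_te_bed,
)
from .expression import CountTable, PairDesign
from .susceptibility import SusceptibilityMatrix, assemble_matrix

__all__ = [
    "SimulationParams",
    "SimulatedAnnotation",
    "SimulationTruth",
    "SimulatedExperiment",
    "simulate_annotation",
    "simulate_counts",
    "delta_from_matrix",
]


def _default_activities() -> dict[str, float]:
    return {"SF04": -0.15, "SF08": 0.10, "SF13": 0.20}


@dataclass
class SimulationParams:
    """Study conditions for the synthetic fixture.

    Defaults describe a gene-dense toy genome: two 25 Mb chromosomes with
    500 genes (~100 kb apart, so 50 kb-flank windows tile the sequence) and
    20 subfamilies of 250 integrants each — enough incidences per subfamily
    to clear the susceptibility-sum filter, as retained subfamilies do on
    real annotations. Activities are log2 units per integrant; noise_sd is
    the s.d. of the per-entry Gaussian noise on log2 expression.
    """

    n_chroms: int = 2
    chrom_length: int = 25_000_000
    n_genes: int = 500
    n_subfamilies: int = 20
    integrants_per_subfamily: int = 250
    te_length_range: tuple[int, int] = (300, 3000)
    fragmentation_rate: float = 0.1
    true_activities: dict[str, float] = field(default_factory=_default_activities)
    active_fraction: dict[str, float] = field(default_factory=dict)
    baseline_mean: float = 5.0
    baseline_sd: float = 1.5
    sample_offset_sd: float = 0.3
    noise_sd: float = 0.5
    n_pairs: int = 2
    mode: str = "hard"
    flank: int = 50_000
    generating_L: float | None = None
    library_size: float = 3e6
    depth_range: tuple[float, float] = (1.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.fragmentation_rate <= 1:
            raise ValueError("fragmentation_rate must lie in [0, 1]")
        for sf, frac in self.active_fraction.items():
            if not 0 < frac <= 1:
                raise ValueError(f"active_fraction[{sf}] must lie in (0, 1]")
        if self.mode == "weighted" and not self.generating_L:
            raise ValueError("weighted generating mode requires generating_L")

    @property
    def subfamily_names(self) -> list[str]:
        return [f"SF{i + 1:02d}" for i in range(self.n_subfamilies)]


@dataclass
class SimulatedAnnotation:
    """Gene models plus TE integrants, pre- and post-fragmentation."""

    genes: list[GeneModel]
    tes: list[TEIntegrant]  # as written to BED; some parents split in two
    parents: list[TEIntegrant]  # unfragmented truth; merge_fragments target

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_te_bed(self.tes, outdir / "te.bed")
        write_gene_table(self.genes, outdir / "genes.tsv")


@dataclass
class SimulationTruth:
    """Generative ground truth for one simulated experiment."""

    activities: dict[str, float]
    N_effect: SusceptibilityMatrix  # susceptibilities that actually acted
    N_all: SusceptibilityMatrix  # susceptibilities of all integrants
    expected_delta: pd.Series  # per-gene expected treatment-minus-control
    active_ranges: list[GenomicInterval]  # truly active integrant intervals


@dataclass
class SimulatedExperiment:
    counts: CountTable
    design: PairDesign
    truth: SimulationTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df = self.counts.counts.copy()
        df.insert(0, "length", self.counts.gene_lengths)
        df.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene_id")
        with open(outdir / "pairs.tsv", "w") as fh:
            fh.write("treatment\tcontrol\n")
            for t, c in self.design.pairs:
                fh.write(f"{t}\t{c}\n")
        truth = pd.Series(self.truth.activities, name="delta_activity")
        truth.to_csv(outdir / "truth.tsv", sep="\t", index_label="subfamily")


def simulate_annotation(params: SimulationParams) -> SimulatedAnnotation:
    """Place gene models and TE integrants on the toy genome.

    Genes carry 1-3 TSS (some spaced < 1 kb to exercise promoter
    clustering, some in a second cluster) and a few exons. Integrants of
    the same subfamily and strand are kept >= 150 bp apart so that fragment
    merging exactly restores the parent set; a ``fragmentation_rate``
    fraction of parents is emitted as two fragments with a gap < 100 bp.
    """
    rng = np.random.default_rng(params.seed)
    chroms = [f"chr{i + 1}" for i in range(params.n_chroms)]

    genes: list[GeneModel] = []
    per_chrom = np.array_split(np.arange(params.n_genes), params.n_chroms)
    for chrom, idx in zip(chroms, per_chrom):
        n = len(idx)
        spacing = params.chrom_length // (n + 1)
        if spacing < 20_000:
            raise ValueError("chromosome too short for the requested gene count")
        for j, g in enumerate(idx):
            anchor = (j + 1) * spacing + int(rng.integers(-spacing // 10, spacing // 10))
            strand = "+" if rng.random() < 0.5 else "-"
            tss = [anchor]
            n_tss = int(rng.integers(1, 4))
            if n_tss >= 2:
                tss.append(anchor + int(rng.integers(50, 900)))
            if n_tss == 3:  # second promoter cluster, > 1 kb away
                tss.append(anchor + int(rng.integers(1600, 4000)))
            exons = []
            pos = anchor + 800
            for _ in range(3):
                length = int(rng.integers(300, 1200))
                exons.append(GenomicInterval(chrom, pos, pos + length))
                pos += length + int(rng.integers(500, 2000))
            genes.append(
                GeneModel(
                    gene_id=f"G{g + 1:04d}",
                    chrom=chrom,
                    strand=strand,
                    tss=sorted(tss),
                    promoters=build_promoters(sorted(tss), chrom),
                    exon_union=union_intervals(exons),
                )
            )

    parents: list[TEIntegrant] = []
    tes: list[TEIntegrant] = []
    occupied: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    lo, hi = params.te_length_range
    for sf in params.subfamily_names:
        for k in range(params.integrants_per_subfamily):
            placed = False
            for _ in range(100):
                chrom = chroms[int(rng.integers(params.n_chroms))]
                length = int(rng.integers(lo, hi + 1))
                start = int(rng.integers(0, params.chrom_length - length))
                strand = "+" if rng.random() < 0.5 else "-"
                key = (chrom, strand, sf)
                taken = occupied.setdefault(key, [])
                if all(start >= e + 150 or start + length <= s - 150
                       for s, e in taken):
                    taken.append((start, start + length))
                    placed = True
                    break
            if not placed:
                raise ValueError(f"could not place integrant {sf}#{k}")
            instance = f"{sf}.{k:04d}"
            parent = TEIntegrant(
                GenomicInterval(chrom, start, start + length, strand), sf, instance
            )
            parents.append(parent)
            if params.fragmentation_rate > 0 and length >= 600 and (
                rng.random() < params.fragmentation_rate
            ):
                gap = int(rng.integers(1, 100))
                cut = int(rng.integers(150, length - 150 - gap))
                tes.append(TEIntegrant(
                    GenomicInterval(chrom, start, start + cut, strand),
                    sf, instance + "/a"))
                tes.append(TEIntegrant(
                    GenomicInterval(chrom, start + cut + gap, start + length, strand),
                    sf, instance + "/b"))
            else:
                tes.append(parent)

    order = lambda t: (t.interval.chrom, t.interval.start, t.interval.end)
    return SimulatedAnnotation(
        genes=genes, tes=sorted(tes, key=order), parents=sorted(parents, key=order)
    )


def simulate_counts(
    annotation: SimulatedAnnotation,
    params: SimulationParams,
    seed: int | None = None,
) -> SimulatedExperiment:
    """Draw a count table from the generative model on a fixed annotation.

    ``seed`` (default ``params.seed + 1``) controls only the stochastic
    expression layer, so replicate studies can reuse one annotation. Counts
    are produced by inverting the pseudocounted log2-TPM transform: the
    per-sample pseudocount is solved by fixed-point iteration so the
    pipeline's normalization recovers the generated expression up to
    rounding.
    """
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    genes = annotation.genes
    merged = merge_fragments(annotation.tes)

    N_all = assemble_matrix(
        genes, merged, mode=params.mode,
        flank=params.flank, L=params.generating_L,
    )

    active_ranges: list[GenomicInterval] = []
    if params.active_fraction:
        effect_tes = []
        by_sf: dict[str, list[TEIntegrant]] = {}
        for te in merged:
            by_sf.setdefault(te.subfamily, []).append(te)
        for sf, members in by_sf.items():
            frac = params.active_fraction.get(sf)
            if frac is None:
                effect_tes.extend(members)
            else:
                n_active = max(1, int(round(frac * len(members))))
                pick = rng.choice(len(members), size=n_active, replace=False)
                chosen = [members[i] for i in sorted(pick)]
                effect_tes.extend(chosen)
                if sf in params.true_activities:
                    active_ranges.extend(t.interval for t in chosen)
        N_effect = assemble_matrix(
            genes, effect_tes, mode=params.mode,
            flank=params.flank, L=params.generating_L,
        ).values.reindex(columns=N_all.subfamilies).fillna(0)
        N_effect = SusceptibilityMatrix(
            values=N_effect, mode=params.mode,
            flank=N_all.flank, bandwidth_L=N_all.bandwidth_L,
        )
    else:
        N_effect = N_all

    activities = dict(params.true_activities)
    unknown = set(activities) - set(N_all.subfamilies)
    if unknown:
        raise ValueError(f"active subfamilies missing from annotation: {unknown}")
    a = pd.Series(0.0, index=N_effect.subfamilies)
    for sf, da in activities.items():
        a[sf] = da
    expected_delta = pd.Series(
        N_effect.values.to_numpy() @ a.to_numpy(),
        index=N_effect.values.index, name="expected_delta",
    )

    gene_ids = [g.gene_id for g in genes]
    lengths = pd.Series(
        [max(g.exon_length, 1) for g in genes], index=gene_ids, name="length"
    )
    c_p = rng.normal(params.baseline_mean, params.baseline_sd, size=len(genes))

    sample_names = [f"T{j + 1}" for j in range(params.n_pairs)] + [
        f"C{j + 1}" for j in range(params.n_pairs)
    ]
    counts = {}
    for s in sample_names:
        treated = s.startswith("T")
        d_s = rng.normal(0.0, params.sample_offset_sd)
        eps = rng.normal(0.0, params.noise_sd, size=len(genes))
        mu = c_p + d_s + (expected_delta.to_numpy() if treated else 0.0) + eps
        depth = rng.uniform(*params.depth_range)
        x = (2.0**mu) * lengths.to_numpy()
        x *= params.library_size * depth / x.sum()
        counts[s] = _invert_pseudocount(x)

    count_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"))
    if (count_df.to_numpy() > 2**53).any():
        raise ValueError("activities or depths too large: counts overflow")
    design = PairDesign(pairs=[(f"T{j + 1}", f"C{j + 1}")
                               for j in range(params.n_pairs)])
    truth = SimulationTruth(
        activities=activities,
        N_effect=N_effect,
        N_all=N_all,
        expected_delta=expected_delta,
        active_ranges=active_ranges,
    )
    return SimulatedExperiment(
        counts=CountTable(counts=count_df, gene_lengths=lengths),
        design=design,
        truth=truth,
    )


def _invert_pseudocount(x: np.ndarray, percentile: float = 5.0) -> np.ndarray:
    """Solve counts = round(x - pi) with pi the percentile of nonzero counts."""
    pi = 0.0
    counts = np.maximum(np.rint(x), 0.0)
    for _ in range(50):
        counts = np.maximum(np.rint(x - pi), 0.0)
        nonzero = counts[counts > 0]
        if nonzero.size == 0:
            raise ValueError("expression too low to invert the pseudocount")
        pi_new = float(np.percentile(nonzero, percentile))
        if abs(pi_new - pi) < 1e-9:
            break
        pi = 0.5 * pi + 0.5 * pi_new  # damped to avoid rounding-induced cycles
    return counts.astype(np.int64)


def delta_from_matrix(
    N: SusceptibilityMatrix,
    activities: Mapping[str, float],
    n_pairs: int = 1,
    noise_sd: float = 0.0,
    intercept: float = 0.0,
    seed: int = 0,
):
    """Build a stacked delta-expression response directly from a matrix.

    Bypasses the count layer: the response is ``intercept + N a`` per pair
    plus Gaussian noise. Used to study the regression and bandwidth-CV
    machinery under exactly known geometry.
    """
    from .expression import DeltaExpression

    rng = np.random.default_rng(seed)
    a = np.array([activities.get(sf, 0.0) for sf in N.subfamilies])
    base = intercept + N.values.to_numpy() @ a
    genes = np.asarray(N.values.index, dtype=object)
    blocks, gene_idx, pair_idx = [], [], []
    for j in range(n_pairs):
        noise = rng.normal(0.0, noise_sd, size=len(base)) if noise_sd else 0.0
        blocks.append(base + noise)
        gene_idx.append(genes)
        pair_idx.append(np.full(len(genes), f"pair{j + 1}", dtype=object))
    return DeltaExpression(
        values=np.concatenate(blocks),
        gene_index=np.concatenate(gene_idx),
        pair_index=np.concatenate(pair_idx),
    )
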