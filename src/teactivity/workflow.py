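"""End-to-end convenience: counts + design + susceptibility → activities."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .expression import (
    CountTable,
    DeltaExpression,
    PairDesign,
    build_delta,
    double_center,
    filter_genes,
    normalize_log_tpm,
)
from .model import ActivityTable, fit_activities
from .susceptibility import SusceptibilityMatrix, filter_subfamilies

__all__ = ["PreparedData", "prepare_inputs", "estimate_activities"]


@dataclass
class PreparedData:
    """Filtered, aligned model inputs ready for fitting."""

    delta: DeltaExpression
    N: SusceptibilityMatrix


def prepare_inputs(
    counts: CountTable,
    design: PairDesign,
    N: SusceptibilityMatrix,
    min_count: int = 10,
    min_subfamily_total: float = 150.0,
    perturbed: Iterable[str] = (),
) -> PreparedData:
    """Run the filtering and normalization chain and align N to the genes kept.

    Genes failing the count filter, experimentally perturbed genes, and
    genes absent from the susceptibility matrix are dropped; the subfamily
    sum filter is applied on the retained gene set.
    """
    ct = filter_genes(counts, min_count=min_count, perturbed=perturbed)
    in_N = set(N.values.index)
    keep = [g for g in ct.gene_ids if g in in_N]
    if not keep:
        raise ValueError("no genes shared between counts and susceptibility matrix")
    ct = CountTable(ct.counts.loc[keep], ct.gene_lengths.loc[keep])

    E = double_center(normalize_log_tpm(ct))
    delta = build_delta(E, design)

    N_sub = SusceptibilityMatrix(
        values=N.values.loc[keep],
        mode=N.mode,
        flank=N.flank,
        bandwidth_L=N.bandwidth_L,
        tad_restricted=N.tad_restricted,
    )
    N_sub = filter_subfamilies(N_sub, min_total=min_subfamily_total)
    return PreparedData(delta=delta, N=N_sub)


def estimate_activities(
    counts: CountTable,
    design: PairDesign,
    N: SusceptibilityMatrix,
    min_count: int = 10,
    min_subfamily_total: float = 150.0,
    perturbed: Iterable[str] = (),
) -> ActivityTable:
    """Full pipeline: filter, normalize, center, difference, fit by OLS."""
    prepared = prepare_inputs(
        counts, design, N,
        min_count=min_count,
        min_subfamily_total=min_subfamily_total,
        perturbed=perturbed,
    )
    return fit_activities(prepared.delta, prepared.N)
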