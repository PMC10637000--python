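"""Hypergeometric DE-enrichment baseline and the AUC comparison utility.

The baseline detector asks, per subfamily and per direction of change,
whether more differentially expressed genes lie within cis-regulatory
distance of the subfamily's integrants than expected by chance, using the
hypergeometric distribution. Up- and down-regulated results are gathered
into one table and BH-adjusted together. Unlike the regression model, the
baseline discards effect magnitudes, which is what the AUC comparison
against a known set of causal subfamilies probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .expression import DeltaExpression
from .model import benjamini_hochberg
from .susceptibility import SusceptibilityMatrix

__all__ = [
    "DEGeneSet",
    "GroundTruth",
    "hypergeom_enrichment",
    "classification_auc",
    "de_from_observed_deltas",
    "read_de_tsv",
]


@dataclass
class DEGeneSet:
    """Universe of tested genes with up- and down-regulated subsets."""

    universe: set[str]
    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (self.up | self.down) <= self.universe:
            raise ValueError("DE genes must be contained in the universe")
        if self.up & self.down:
            raise ValueError("a gene cannot be both up- and down-regulated")


@dataclass
class GroundTruth:
    """Known causal subfamilies and per-subfamily classification scores.

    Scores follow the 1 − (BH-adjusted p) convention: higher means more
    confidently called cis-regulatory.
    """

    positives: set[str]
    scored: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.positives <= set(self.scored):
            raise ValueError("positives must be among the scored subfamilies")


def hypergeom_enrichment(
    de: DEGeneSet, N: SusceptibilityMatrix
) -> pd.DataFrame:
    """Per-subfamily, per-direction hypergeometric enrichment of DE genes.

    A gene counts as "near" subfamily m when ``N[p, m] >= 1`` in the
    hard-threshold matrix. For each direction, with universe size U, K DE
    genes, n near genes of which k are DE, the p-value is P(X >= k) for
    X ~ Hypergeometric(U, K, n) (survival function at k − 1; exact). BH
    runs once over the concatenated up+down table.
    """
    if N.mode != "hard":
        raise ValueError("enrichment uses the hard-threshold matrix")
    gene_ids = np.asarray(N.values.index, dtype=object)
    in_universe = np.isin(gene_ids, list(de.universe))
    U = int(in_universe.sum())
    if U == 0:
        raise ValueError("no universe genes found in the susceptibility matrix")

    rows = []
    for sf in N.subfamilies:
        near = (N.values[sf].to_numpy() >= 1) & in_universe
        near_genes = set(gene_ids[near])
        n = len(near_genes)
        for direction, de_set in (("up", de.up), ("down", de.down)):
            K = len(de_set)
            if K == 0:
                p = 1.0
            else:
                k = len(near_genes & de_set)
                p = float(stats.hypergeom.sf(k - 1, U, K, n))
            rows.append({"subfamily": sf, "direction": direction, "p": p})

    table = pd.DataFrame(rows)
    table["adj_p"] = benjamini_hochberg(table["p"].to_numpy())
    return table


def classification_auc(truth: GroundTruth) -> float:
    """Mann-Whitney AUC of the scores against the positive/negative labels.

    Equals P(score_pos > score_neg) + 0.5 P(tie) over all positive/negative
    subfamily pairs.
    """
    labels = np.array([sf in truth.positives for sf in truth.scored], dtype=int)
    scores = np.array([truth.scored[sf] for sf in truth.scored], dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("ground truth must contain both classes")
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(labels, scores))


def de_from_observed_deltas(
    delta: DeltaExpression, threshold: float
) -> DEGeneSet:
    """Lenient empirical DE call from observed per-gene mean deltas.

    Averages each gene's stacked delta over replicate pairs and labels genes
    beyond ``±threshold`` (log2 units) as up/down. A stand-in for an
    external count-based DE caller, suitable for simulations where the
    baseline detector needs DE labels derived, like real DE calls, from the
    noisy data rather than from the generative truth.
    """
    s = pd.Series(delta.values, index=delta.gene_index)
    mean = s.groupby(level=0, sort=False).mean()
    universe = set(mean.index)
    up = set(mean.index[mean >= threshold])
    down = set(mean.index[mean <= -threshold])
    return DEGeneSet(universe=universe, up=up, down=down)


def read_de_tsv(path: str | Path, universe: set[str]) -> DEGeneSet:
    """Read a two-column TSV (gene_id, direction in {up, down})."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (gene_id, direction)")
    if tuple(df.iloc[0])[:2] == ("gene_id", "direction"):
        df = df.iloc[1:]
    up = set(df[0][df[1] == "up"])
    down = set(df[0][df[1] == "down"])
    bad = set(df[1]) - {"up", "down"}
    if bad:
        raise ValueError(f"{path}: unknown directions {sorted(bad)}")
    return DEGeneSet(universe=universe, up=up, down=down)
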