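"""Ordinary-least-squares fit of the delta-expression activity model.

The model regresses the stacked per-pair differences in doubly centered
log2 expression on the susceptibility matrix:

    dE'_p = dA_0 + sum_m N_pm * dA_m + eps

Each coefficient dA_m is the log2 fold-change in a gene's expression
attributable to one integrant of subfamily m within cis-regulatory reach;
a t-test against zero with Benjamini-Hochberg adjustment across subfamilies
flags differentially cis-regulatory subfamilies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .expression import DeltaExpression
from .susceptibility import SusceptibilityMatrix

__all__ = [
    "ActivityTable",
    "fit_activities",
    "stack_design",
    "benjamini_hochberg",
    "fold_change_interval",
]


@dataclass
class ActivityTable:
    """Per-subfamily activity estimates with uncertainty and fit summaries."""

    table: pd.DataFrame  # index subfamily; estimate, std_error, t_value, p_value, adj_p_value
    intercept: float
    intercept_se: float
    overall_f_p: float
    adj_r_squared: float
    residual_df: int
    n_obs: int

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        """Subfamilies with BH-adjusted p ≤ ``alpha``, strongest first."""
        hits = self.table[self.table["adj_p_value"] <= alpha]
        return hits.sort_values("adj_p_value")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# intercept: {self.intercept:.10g}\n")
            fh.write(f"# intercept_se: {self.intercept_se:.10g}\n")
            fh.write(f"# overall_f_p: {self.overall_f_p:.6g}\n")
            fh.write(f"# adj_r_squared: {self.adj_r_squared:.6g}\n")
            fh.write(f"# n_obs: {self.n_obs}\n")
            fh.write(f"# residual_df: {self.residual_df}\n")
            self.table.to_csv(fh, sep="\t", index_label="subfamily")


def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def fold_change_interval(
    estimate: float, se: float, level: float = 0.95
) -> tuple[float, float]:
    """Fold-change confidence interval implied by a log2 activity estimate.

    Returns ``(2^(est - z*se), 2^(est + z*se))`` with z the standard-normal
    quantile for the level (1.96 at 95%).
    """
    if se < 0:
        raise ValueError("standard error must be non-negative")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (2.0 ** (estimate - z * se), 2.0 ** (estimate + z * se))


def stack_design(
    N: SusceptibilityMatrix, delta: DeltaExpression
) -> pd.DataFrame:
    """Row-expand N to match the stacked delta vector.

    Every stacked row of the response is matched with its gene's
    susceptibility row; genes missing from N raise an error.
    """
    missing = set(delta.gene_index) - set(N.values.index)
    if missing:
        raise ValueError(
            f"genes absent from susceptibility matrix: {sorted(missing)[:5]}"
        )
    return N.values.loc[delta.gene_index]


def fit_activities(
    delta: DeltaExpression, N: SusceptibilityMatrix | pd.DataFrame
) -> ActivityTable:
    """Fit the activity model by OLS with an intercept.

    ``N`` may be a susceptibility matrix over the delta's genes (it is then
    row-expanded internally) or an already stacked design frame. Standard
    errors come from sigma^2 (X'X)^-1 with sigma^2 = RSS / residual_df;
    BH adjustment runs across the subfamily coefficients only.
    """
    if isinstance(N, SusceptibilityMatrix):
        X = stack_design(N, delta)
    else:
        X = N
    y = np.asarray(delta.values, dtype=float)
    if len(X) != len(y):
        raise ValueError(f"design has {len(X)} rows but response has {len(y)}")
    n_obs, n_cols = X.shape
    if n_obs <= n_cols + 1:
        raise ValueError(
            f"{n_obs} observations cannot identify {n_cols} activities + intercept"
        )

    Xmat = np.column_stack([np.ones(n_obs), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(Xmat)
    if rank < Xmat.shape[1]:
        raise ValueError(
            "rank-deficient design; collinear columns: "
            f"{_collinear_columns(Xmat, list(X.columns))}"
        )

    fit = sm.OLS(y, Xmat).fit()
    p_sub = fit.pvalues[1:]
    table = pd.DataFrame(
        {
            "estimate": fit.params[1:],
            "std_error": fit.bse[1:],
            "t_value": fit.tvalues[1:],
            "p_value": p_sub,
            "adj_p_value": benjamini_hochberg(p_sub),
        },
        index=pd.Index(X.columns, name="subfamily"),
    )
    return ActivityTable(
        table=table,
        intercept=float(fit.params[0]),
        intercept_se=float(fit.bse[0]),
        overall_f_p=float(fit.f_pvalue),
        adj_r_squared=float(fit.rsquared_adj),
        residual_df=int(fit.df_resid),
        n_obs=int(n_obs),
    )


def _collinear_columns(Xmat: np.ndarray, names: list[str]) -> list[str]:
    """Name design columns implicated in a rank deficiency (QR pivot check)."""
    from scipy.linalg import qr

    _, R, piv = qr(Xmat, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xmat.shape) * np.finfo(float).eps
    bad = [piv[i] for i in range(len(diag)) if diag[i] <= tol]
    labels = ["<intercept>"] + names
    return [labels[i] for i in sorted(bad)]
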