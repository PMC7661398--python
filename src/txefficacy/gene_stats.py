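"""Per-gene two-sample t statistics — the atomic quantity behind every index.

All comparisons use Student's pooled-variance two-sample t with
df = n_a + n_b - 2 and a two-sided p value from the central t distribution.
The pooled (rather than Welch) form is deliberate: the degrees of freedom of
every downstream test (nu = 4 for a 3-vs-3 comparison, df = n1 + n2 - 2 for
the subset-vs-background comparison of |t| lists) only arise under pooling.

Statistics are computed on CPM-normalized values directly, without a log
transformation, and no multiple-testing correction feeds the indices; an
optional Benjamini-Hochberg column can be added to output tables for
inspection only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix, GroupDesign

__all__ = [
    "GeneStat",
    "pooled_t",
    "t_from_summary",
    "per_gene_stats",
    "rank_genes_by_abs_t",
    "add_bh_fdr",
]

#: Columns of the per-gene statistics table.
STAT_COLUMNS = [
    "gene_id",
    "mean_a",
    "mean_b",
    "se_diff",
    "t",
    "abs_t",
    "df",
    "p",
    "degenerate",
]


@dataclass(frozen=True)
class GeneStat:
    """Pooled two-sample t statistic for one gene.

    ``degenerate`` marks the pathological case of zero pooled variance with
    unequal means (t undefined); degenerate genes are excluded from every
    downstream index sum *and* denominator.
    """

    gene_id: str
    mean_a: float
    mean_b: float
    se_diff: float
    t: float
    abs_t: float
    df: int
    p: float
    degenerate: bool


def t_from_summary(mean_diff: float, se: float) -> float:
    """|t| from a printed |mean difference| and its standard error."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    return abs(mean_diff) / se


def pooled_t(values_a, values_b, gene_id: str = "") -> GeneStat:
    """Student's pooled-variance two-sample t for one gene.

    t = (mean_a - mean_b) / sqrt(s_p^2 (1/n_a + 1/n_b)) with the pooled
    variance s_p^2 = ((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2),
    df = n_a + n_b - 2, two-sided p.  Zero pooled variance with equal means
    gives t = 0, p = 1; with unequal means the gene is flagged degenerate.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("values_a and values_b must be 1-D")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values for a variance estimate")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite expression value")
    rec = _vectorized_stats(a[None, :], b[None, :], [gene_id]).iloc[0]
    return GeneStat(
        gene_id=gene_id,
        mean_a=float(rec["mean_a"]),
        mean_b=float(rec["mean_b"]),
        se_diff=float(rec["se_diff"]),
        t=float(rec["t"]),
        abs_t=float(rec["abs_t"]),
        df=int(rec["df"]),
        p=float(rec["p"]),
        degenerate=bool(rec["degenerate"]),
    )


def _vectorized_stats(A: np.ndarray, B: np.ndarray, gene_ids) -> pd.DataFrame:
    """Pooled t per row of the (genes x n_a) and (genes x n_b) arrays."""
    na, nb = A.shape[1], B.shape[1]
    df = na + nb - 2
    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    var_a = A.var(axis=1, ddof=1)
    var_b = B.var(axis=1, ddof=1)
    sp2 = ((na - 1) * var_a + (nb - 1) * var_b) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = mean_a - mean_b
    zero_var = sp2 == 0.0
    degenerate = zero_var & (diff != 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    t = np.where(zero_var & ~degenerate, 0.0, t)
    t = np.where(degenerate, np.nan, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero_var & ~degenerate, 1.0, p)
    p = np.where(degenerate, np.nan, p)
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "mean_a": mean_a,
            "mean_b": mean_b,
            "se_diff": se,
            "t": t,
            "abs_t": np.abs(t),
            "df": df,
            "p": p,
            "degenerate": degenerate,
        }
    )


def per_gene_stats(
    m: ExpressionMatrix,
    design: GroupDesign,
    role_a: str,
    role_b: str,
) -> pd.DataFrame:
    """Pooled t statistics for every gene of ``m`` between two sample roles.

    Returns one row per gene, in the matrix's gene order, with columns
    ``gene_id, mean_a, mean_b, se_diff, t, abs_t, df, p, degenerate``.
    ``t`` is signed (mean_a - mean_b); every index downstream consumes
    ``abs_t``.
    """
    design.validate_for(m, [role_a, role_b], min_per_role=2)
    A = m.subset_samples(design.samples(role_a))
    B = m.subset_samples(design.samples(role_b))
    return _vectorized_stats(A, B, m.gene_ids)


def rank_genes_by_abs_t(records: pd.DataFrame) -> pd.DataFrame:
    """Sort a per-gene statistics table by |t| descending.

    Ties break by gene identifier ascending so the output is deterministic.
    Degenerate genes (|t| undefined) sort last.
    """
    if records.empty:
        raise ValueError("no gene records to rank")
    out = records.sort_values(
        by=["abs_t", "gene_id"],
        ascending=[False, True],
        na_position="last",
        kind="mergesort",
    )
    return out.reset_index(drop=True)


def add_bh_fdr(records: pd.DataFrame) -> pd.DataFrame:
    """Append a Benjamini-Hochberg adjusted-p column (display only: the
    desirability and disruption indices never consume it)."""
    from statsmodels.stats.multitest import multipletests

    out = records.copy()
    ok = out["p"].notna()
    adj = np.full(len(out), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["p_bh"] = adj
    return out
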