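"""Restorative-drug desirability: per-gene delta-t and the I_DD = E + T indices.

A restorative drug should move a patient's transcriptome back toward that of
healthy controls.  For each gene, deviation from the healthy group is scored
by the absolute pooled t statistic of healthy (H) versus patients before
treatment (Pb), and again versus the same patients after treatment (Pa):

    delta_t = |t|_{H~Pb} - |t|_{H~Pa}

Positive delta_t means the gene's expression moved closer to healthy after
the drug.  Aggregating over the N analyzed genes:

    I_DD = mean(delta_t)                       (index of drug desirability)
    E    = sum(delta_t for delta_t > 0) / N    (transcriptomic efficacy)
    T    = sum(delta_t for delta_t < 0) / N    (transcriptomic toxicity)

so that I_DD = E + T holds exactly: a drug becomes more desirable either by
raising E or by shrinking |T|.  Significance of I_DD is a one-sample t test
of the delta_t values against 0 (df = N - 1) and a matching t-based
confidence interval.  Genes with delta_t exactly 0 count in N but in neither
sum, preserving the identity.

The distance-based analogue delta_d = |MeanH - MeanPb| - |MeanH - MeanPa| is
carried alongside for interpretation; the indices use delta_t because the t
statistic scales each mean difference by its standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix, GroupDesign
from . import gene_stats

__all__ = [
    "DesirabilityReport",
    "DesirabilityComparison",
    "delta_t_per_gene",
    "desirability_summary",
    "rank_genes_by_delta_t",
    "compare_desirability",
    "RestorativeModel",
    "RestorativeResults",
]


@dataclass(frozen=True)
class DesirabilityReport:
    """Aggregate desirability indices over a set of per-gene delta_t values."""

    n_genes: int
    n_positive: int
    n_negative: int
    n_zero: int
    n_degenerate: int
    i_dd: float
    e_index: float
    t_index: float
    se: float
    ci_low: float
    ci_high: float
    t_stat: float
    df: int
    p: float
    alpha: float

    def to_dict(self) -> dict:
        return asdict(self)

    def summary(self) -> str:
        lines = [
            "Restorative drug desirability",
            "-----------------------------",
            f"genes analyzed        {self.n_genes}"
            + (f"  (+{self.n_degenerate} degenerate excluded)" if self.n_degenerate else ""),
            f"delta_t > 0 / < 0 / = 0   {self.n_positive} / {self.n_negative} / {self.n_zero}",
            f"I_DD (mean delta_t)   {self.i_dd:.5f}",
            f"E  (efficacy)         {self.e_index:.5f}",
            f"T  (toxicity)         {self.t_index:.5f}",
            f"SE of delta_t mean    {self.se:.5f}",
            f"{100 * (1 - self.alpha):.0f}% CI               ({self.ci_low:.5f}, {self.ci_high:.5f})",
            f"H0 I_DD = 0:          t = {self.t_stat:.4f}, df = {self.df}, p = {self.p:.4g}",
        ]
        return "\n".join(lines)


def delta_t_per_gene(stats_HPb: pd.DataFrame, stats_HPa: pd.DataFrame) -> pd.DataFrame:
    """Combine the H~Pb and H~Pa per-gene tables into delta records.

    Both tables must cover the same genes in the same order (they come from
    the same matrix) and share the healthy-group means.  Output columns:
    ``gene_id, mean_h, mean_pb, mean_pa, t_b, t_a, delta_t, delta_d,
    degenerate`` where ``t_b``/``t_a`` are the absolute t statistics and
    ``degenerate`` is true if either underlying comparison was degenerate.
    """
    gb = list(stats_HPb["gene_id"])
    ga = list(stats_HPa["gene_id"])
    if gb != ga:
        raise ValueError("the two statistics tables cover different genes (or a different order)")
    mean_h = stats_HPb["mean_a"].to_numpy(dtype=float)
    mean_h_check = stats_HPa["mean_a"].to_numpy(dtype=float)
    if not np.allclose(mean_h, mean_h_check, rtol=1e-12, atol=0):
        raise ValueError("healthy-group means disagree between the two tables")
    mean_pb = stats_HPb["mean_b"].to_numpy(dtype=float)
    mean_pa = stats_HPa["mean_b"].to_numpy(dtype=float)
    t_b = stats_HPb["abs_t"].to_numpy(dtype=float)
    t_a = stats_HPa["abs_t"].to_numpy(dtype=float)
    degenerate = (
        stats_HPb["degenerate"].to_numpy(dtype=bool)
        | stats_HPa["degenerate"].to_numpy(dtype=bool)
    )
    return pd.DataFrame(
        {
            "gene_id": gb,
            "mean_h": mean_h,
            "mean_pb": mean_pb,
            "mean_pa": mean_pa,
            "t_b": t_b,
            "t_a": t_a,
            "delta_t": t_b - t_a,
            "delta_d": np.abs(mean_h - mean_pb) - np.abs(mean_h - mean_pa),
            "degenerate": degenerate,
        }
    )


def desirability_summary(deltas: pd.DataFrame, alpha: float = 0.05) -> DesirabilityReport:
    """Aggregate per-gene delta_t values into the desirability report.

    Degenerate genes are dropped from both the sums and the denominator.
    The one-sample test and CI use the t distribution with df = N - 1.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    degenerate = deltas["degenerate"].to_numpy(dtype=bool) if "degenerate" in deltas else None
    dt = deltas["delta_t"].to_numpy(dtype=float)
    if degenerate is not None:
        dt = dt[~degenerate]
        n_degenerate = int(degenerate.sum())
    else:
        n_degenerate = 0
    n = len(dt)
    if n < 2:
        raise ValueError("need >= 2 non-degenerate genes to summarize")
    i_dd = float(dt.mean())
    e_index = float(dt[dt > 0].sum() / n)
    t_index = float(dt[dt < 0].sum() / n)
    sd = float(dt.std(ddof=1))
    se = sd / np.sqrt(n)
    df = n - 1
    if se > 0:
        t_stat = i_dd / se
        p = float(2.0 * stats.t.sf(abs(t_stat), df))
    else:  # all delta_t identical
        t_stat = 0.0 if i_dd == 0 else np.inf * np.sign(i_dd)
        p = 1.0 if i_dd == 0 else 0.0
    tcrit = float(stats.t.ppf(1 - alpha / 2, df))
    return DesirabilityReport(
        n_genes=n,
        n_positive=int((dt > 0).sum()),
        n_negative=int((dt < 0).sum()),
        n_zero=int((dt == 0).sum()),
        n_degenerate=n_degenerate,
        i_dd=i_dd,
        e_index=e_index,
        t_index=t_index,
        se=float(se),
        ci_low=float(i_dd - tcrit * se),
        ci_high=float(i_dd + tcrit * se),
        t_stat=float(t_stat),
        df=df,
        p=p,
        alpha=alpha,
    )


def rank_genes_by_delta_t(deltas: pd.DataFrame, direction: str = "worst") -> pd.DataFrame:
    """Rank genes by delta_t.

    ``direction='worst'`` sorts ascending (most negative first: genes whose
    expression drifted further from healthy under the drug — side effects);
    ``direction='best'`` sorts descending.  Ties break by gene id.
    """
    if deltas.empty:
        raise ValueError("no delta records to rank")
    if direction not in ("worst", "best"):
        raise ValueError("direction must be 'worst' or 'best'")
    out = deltas.sort_values(
        by=["delta_t", "gene_id"],
        ascending=[direction == "worst", True],
        na_position="last",
        kind="mergesort",
    )
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class DesirabilityComparison:
    """Verdict from comparing two desirability reports on CI overlap."""

    verdict: str  # "1 more desirable" | "2 more desirable" | "indistinguishable"
    delta_i_dd: float
    delta_e: float
    delta_t_index: float
    universes_differ: bool

    def summary(self) -> str:
        s = (
            f"verdict: {self.verdict}\n"
            f"I_DD difference (2 - 1): {self.delta_i_dd:.5f} "
            f"(E: {self.delta_e:+.5f}, T: {self.delta_t_index:+.5f})"
        )
        if self.universes_differ:
            s += "\nwarning: reports cover different gene universes; comparison is indicative only"
        return s


def compare_desirability(
    report_1: DesirabilityReport, report_2: DesirabilityReport
) -> DesirabilityComparison:
    """Decide which of two experiments is the more desirable drug/dose.

    Experiment 2 wins when its CI lower bound exceeds experiment 1's point
    I_DD, or its point I_DD exceeds experiment 1's CI upper bound (and
    symmetrically for experiment 1); otherwise the two are indistinguishable.
    The I_DD difference is decomposed into the E and T contributions.
    """
    universes_differ = report_1.n_genes != report_2.n_genes
    two_wins = report_2.ci_low > report_1.i_dd or report_2.i_dd > report_1.ci_high
    one_wins = report_1.ci_low > report_2.i_dd or report_1.i_dd > report_2.ci_high
    if two_wins and not one_wins:
        verdict = "2 more desirable"
    elif one_wins and not two_wins:
        verdict = "1 more desirable"
    elif two_wins and one_wins:
        # CIs mutually exclusive; the larger point estimate wins
        verdict = "2 more desirable" if report_2.i_dd > report_1.i_dd else "1 more desirable"
    else:
        verdict = "indistinguishable"
    return DesirabilityComparison(
        verdict=verdict,
        delta_i_dd=report_2.i_dd - report_1.i_dd,
        delta_e=report_2.e_index - report_1.e_index,
        delta_t_index=report_2.t_index - report_1.t_index,
        universes_differ=universes_differ,
    )


class RestorativeModel:
    """Desirability analysis of a restorative drug.

    Parameters
    ----------
    matrix : ExpressionMatrix
        CPM-normalized (and typically low-expression-filtered) matrix.
    design : GroupDesign
        Must assign >= 2 samples to each of the three roles.
    role_healthy, role_before, role_after : str
        Role tokens for healthy controls and patients before/after treatment.
    geneset : iterable of str, optional
        Restrict the analysis to an a-priori candidate gene set (applied via
        the matrix's gene selection; unmatched identifiers are recorded on
        the results object).
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        design: GroupDesign,
        role_healthy: str = "H",
        role_before: str = "Pb",
        role_after: str = "Pa",
        geneset: Optional[Iterable[str]] = None,
    ):
        if not matrix.normalized:
            raise ValueError("matrix must be CPM-normalized before analysis")
        self.unmatched_geneset: list[str] = []
        if geneset is not None:
            matrix, self.unmatched_geneset = matrix.select_genes(geneset)
        design.validate_for(matrix, [role_healthy, role_before, role_after])
        self.matrix = matrix
        self.design = design
        self.roles = (role_healthy, role_before, role_after)

    def fit(self, alpha: float = 0.05) -> "RestorativeResults":
        h, pb, pa = self.roles
        stats_b = gene_stats.per_gene_stats(self.matrix, self.design, h, pb)
        stats_a = gene_stats.per_gene_stats(self.matrix, self.design, h, pa)
        deltas = delta_t_per_gene(stats_b, stats_a)
        report = desirability_summary(deltas, alpha=alpha)
        return RestorativeResults(self, stats_b, stats_a, deltas, report)


class RestorativeResults:
    """Fitted desirability indices with per-gene tables.

    Attributes: ``stats_before`` / ``stats_after`` (per-gene H~Pb and H~Pa
    tables), ``deltas`` (delta_t/delta_d table), ``report``
    (:class:`DesirabilityReport`).
    """

    def __init__(self, model, stats_before, stats_after, deltas, report):
        self.model = model
        self.stats_before = stats_before
        self.stats_after = stats_after
        self.deltas = deltas
        self.report = report

    @property
    def i_dd(self) -> float:
        return self.report.i_dd

    @property
    def e_index(self) -> float:
        return self.report.e_index

    @property
    def t_index(self) -> float:
        return self.report.t_index

    def rank(self, direction: str = "worst") -> pd.DataFrame:
        return rank_genes_by_delta_t(self.deltas, direction)

    def rank_divergent_genes(self) -> pd.DataFrame:
        """Genes most different between healthy and untreated patients."""
        return gene_stats.rank_genes_by_abs_t(self.stats_before)

    def compare(self, other: "RestorativeResults") -> DesirabilityComparison:
        return compare_desirability(self.report, other.report)

    def summary(self) -> str:
        return self.report.summary()

    def to_dict(self) -> dict:
        return {
            "analysis": "restorative",
            "roles": list(self.model.roles),
            "unmatched_geneset": self.model.unmatched_geneset,
            **self.report.to_dict(),
        }
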