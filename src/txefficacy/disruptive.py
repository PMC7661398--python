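"""Disruptive-drug indices: mean |t| disruption, its analytic null, and toxicity.

A disruptive drug (an anti-cancer or anti-pathogen agent) should perturb the
malignant transcriptome as much as possible.  With GE_mb / GE_ma the
malignant expression before/after treatment, the transcriptomic efficacy over
M genes is the mean absolute pooled t statistic

    E = sum_i |t_i(GE_ma ~ GE_mb)| / M.

Under the null of no drug effect each |t_i| follows the folded central t
distribution with nu = n_before + n_after - 2 degrees of freedom, whose mean
has the closed form

    E(|t| | nu) = 2 sqrt(nu) Gamma((nu+1)/2) / (sqrt(pi) (nu-1) Gamma(nu/2)),

equal to exactly 1 at nu = 4 (a 3-vs-3 comparison).  Significance of E is a
one-sample t test of the M per-gene |t| values against this expectation,
with SE = sd(|t|)/sqrt(M) and df = M - 1.

Transcriptomic toxicity applies the same machinery to *normal* tissue before
and after exposure (roles NB/NA).  The toxicity aggregate is reported both as
a mean (comparable across gene universes, and to E) and as the literal sum of
the |t| values; the two differ only by the factor M and the report carries
both rather than silently preferring one.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.special import gammaln

from .matrix import ExpressionMatrix, GroupDesign
from . import gene_stats

__all__ = [
    "expected_abs_t",
    "expected_abs_t_quadrature",
    "DisruptionReport",
    "disruption_index",
    "geneset_disruption",
    "toxicity_index",
    "compare_geneset_vs_all",
    "DisruptionModel",
    "DisruptionResults",
]


def expected_abs_t(nu: float) -> float:
    """Mean of |t| for a central t distribution with ``nu`` degrees of freedom.

    Closed form 2*sqrt(nu)*Gamma((nu+1)/2) / (sqrt(pi)*(nu-1)*Gamma(nu/2)),
    evaluated through log-gamma for stability at large nu.  The mean only
    exists for nu > 1.
    """
    if nu <= 1:
        raise ValueError("E(|t|) does not exist for nu <= 1 (the mean diverges)")
    lg = gammaln((nu + 1) / 2.0) - gammaln(nu / 2.0)
    return float(2.0 * np.sqrt(nu) / (np.sqrt(np.pi) * (nu - 1.0)) * np.exp(lg))


def expected_abs_t_quadrature(nu: float) -> float:
    """E(|t|) by numerical quadrature of t*f(t|nu) over (0, inf), normalized
    by the upper-half mass 1/2.  Verification path for :func:`expected_abs_t`."""
    if nu <= 1:
        raise ValueError("E(|t|) does not exist for nu <= 1 (the mean diverges)")
    num, _ = integrate.quad(lambda t: t * stats.t.pdf(t, nu), 0, np.inf)
    den, _ = integrate.quad(lambda t: stats.t.pdf(t, nu), 0, np.inf)
    return float(num / den)


@dataclass(frozen=True)
class DisruptionReport:
    """Mean-|t| disruption index with its analytic-null significance test."""

    mode: str  # "efficacy" (malignant before/after) or "toxicity" (normal)
    aggregate: str  # "mean" or "sum" (which aggregate e_index reports)
    n_genes: int
    n_degenerate: int
    e_index: float  # the requested aggregate of |t|
    mean_abs_t: float
    sum_abs_t: float
    null_expectation: float  # E(|t| | nu) for the per-gene test df
    nu: int  # per-gene t df = n_before + n_after - 2
    se: float  # SE of the per-gene |t| values
    t_stat: float
    df: int  # n_genes - 1
    p: float

    def to_dict(self) -> dict:
        return asdict(self)

    def summary(self) -> str:
        label = "Transcriptomic toxicity" if self.mode == "toxicity" else "Transcriptomic disruption efficacy"
        lines = [
            label,
            "-" * len(label),
            f"genes analyzed        {self.n_genes}"
            + (f"  (+{self.n_degenerate} degenerate excluded)" if self.n_degenerate else ""),
            f"mean |t|              {self.mean_abs_t:.5f}",
            f"sum |t|               {self.sum_abs_t:.5f}",
            f"null E(|t| | nu={self.nu})   {self.null_expectation:.5f}",
            f"SE of |t| values      {self.se:.5f}",
            f"H0 mean|t| = E(|t|):  t = {self.t_stat:.5f}, df = {self.df}, p = {self.p:.4g}",
        ]
        return "\n".join(lines)


def _report_from_abs_t(
    abs_t: np.ndarray, nu: int, n_degenerate: int, mode: str, aggregate: str
) -> DisruptionReport:
    m = len(abs_t)
    if m < 2:
        raise ValueError("need >= 2 non-degenerate genes")
    if aggregate not in ("mean", "sum"):
        raise ValueError("aggregate must be 'mean' or 'sum'")
    mean_abs = float(abs_t.mean())
    sum_abs = float(abs_t.sum())
    null = expected_abs_t(nu)
    se = float(abs_t.std(ddof=1) / np.sqrt(m))
    if se > 0:
        t_stat = (mean_abs - null) / se
        p = float(2.0 * stats.t.sf(abs(t_stat), m - 1))
    else:
        t_stat = 0.0 if mean_abs == null else np.inf * np.sign(mean_abs - null)
        p = 1.0 if mean_abs == null else 0.0
    return DisruptionReport(
        mode=mode,
        aggregate=aggregate,
        n_genes=m,
        n_degenerate=n_degenerate,
        e_index=mean_abs if aggregate == "mean" else sum_abs,
        mean_abs_t=mean_abs,
        sum_abs_t=sum_abs,
        null_expectation=null,
        nu=nu,
        se=se,
        t_stat=float(t_stat),
        df=m - 1,
        p=p,
    )


def disruption_index(
    m: ExpressionMatrix,
    design: GroupDesign,
    role_before: str = "CTRL",
    role_after: str = "TREAT",
    aggregate: str = "mean",
    mode: str = "efficacy",
) -> "DisruptionResults":
    """Mean-|t| disruption index between two sample roles (convenience form
    of :class:`DisruptionModel`)."""
    return DisruptionModel(
        m, design, role_before=role_before, role_after=role_after, mode=mode
    ).fit(aggregate=aggregate)


def geneset_disruption(
    m: ExpressionMatrix,
    design: GroupDesign,
    gene_list: Iterable[str],
    role_before: str = "CTRL",
    role_after: str = "TREAT",
    aggregate: str = "mean",
) -> "DisruptionResults":
    """Disruption index restricted to an a-priori gene set (e.g. apoptosis
    genes for a drug meant to kill tumor cells)."""
    return DisruptionModel(
        m, design, role_before=role_before, role_after=role_after, geneset=gene_list
    ).fit(aggregate=aggregate)


def toxicity_index(
    m: ExpressionMatrix,
    design: GroupDesign,
    role_before: str = "NB",
    role_after: str = "NA",
    aggregate: str = "mean",
) -> "DisruptionResults":
    """Transcriptomic toxicity: the disruption machinery applied to normal
    tissue before (NB) and after (NA) drug exposure.  The results object
    carries both the mean and the literal sum aggregate."""
    return DisruptionModel(
        m, design, role_before=role_before, role_after=role_after, mode="toxicity"
    ).fit(aggregate=aggregate)


def compare_geneset_vs_all(abs_t_geneset, abs_t_all) -> gene_stats.GeneStat:
    """Pooled two-sample t between a gene set's |t| values and the full
    gene universe's |t| values.

    The subset is compared against the *full* list with the overlap retained
    (so df = n_subset + n_all - 2); pass a disjoint background explicitly if
    an exclusion variant is wanted.  A positive t means the gene set is more
    disrupted than the average gene.
    """
    return gene_stats.pooled_t(abs_t_geneset, abs_t_all, gene_id="geneset_vs_all")


class DisruptionModel:
    """Disruption analysis of a disruptive drug between two sample roles.

    ``mode`` is a label distinguishing efficacy (malignant cells before vs
    after treatment) from toxicity (normal cells); the arithmetic is shared.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        design: GroupDesign,
        role_before: str = "CTRL",
        role_after: str = "TREAT",
        geneset: Optional[Iterable[str]] = None,
        mode: str = "efficacy",
    ):
        if not matrix.normalized:
            raise ValueError("matrix must be CPM-normalized before analysis")
        if mode not in ("efficacy", "toxicity"):
            raise ValueError("mode must be 'efficacy' or 'toxicity'")
        self.unmatched_geneset: list[str] = []
        if geneset is not None:
            matrix, self.unmatched_geneset = matrix.select_genes(geneset)
        design.validate_for(matrix, [role_before, role_after])
        self.matrix = matrix
        self.design = design
        self.role_before = role_before
        self.role_after = role_after
        self.mode = mode

    def fit(self, aggregate: str = "mean") -> "DisruptionResults":
        # per-gene t of after vs before; only |t| feeds the index
        table = gene_stats.per_gene_stats(
            self.matrix, self.design, self.role_after, self.role_before
        )
        ok = ~table["degenerate"].to_numpy(dtype=bool)
        if not ok.any():
            raise ValueError("all genes are degenerate; no |t| values to aggregate")
        abs_t = table.loc[ok, "abs_t"].to_numpy(dtype=float)
        nu = int(table["df"].iloc[0])
        report = _report_from_abs_t(
            abs_t, nu, n_degenerate=int((~ok).sum()), mode=self.mode, aggregate=aggregate
        )
        return DisruptionResults(self, table, report)


class DisruptionResults:
    """Fitted disruption/toxicity index with the per-gene |t| table."""

    def __init__(self, model: DisruptionModel, stats_table: pd.DataFrame, report: DisruptionReport):
        self.model = model
        self.stats = stats_table
        self.report = report

    @property
    def e_index(self) -> float:
        return self.report.e_index

    @property
    def abs_t(self) -> np.ndarray:
        ok = ~self.stats["degenerate"].to_numpy(dtype=bool)
        return self.stats.loc[ok, "abs_t"].to_numpy(dtype=float)

    def rank(self) -> pd.DataFrame:
        return gene_stats.rank_genes_by_abs_t(self.stats)

    def compare_geneset(self, gene_list: Iterable[str]) -> tuple["DisruptionResults", gene_stats.GeneStat]:
        """Disruption of an a-priori gene set plus the subset-vs-all test."""
        sub = DisruptionModel(
            self.model.matrix,
            self.model.design,
            role_before=self.model.role_before,
            role_after=self.model.role_after,
            geneset=gene_list,
            mode=self.model.mode,
        ).fit(aggregate=self.report.aggregate)
        test = compare_geneset_vs_all(sub.abs_t, self.abs_t)
        return sub, test

    def summary(self) -> str:
        return self.report.summary()

    def to_dict(self) -> dict:
        return {
            "analysis": "disruptive",
            "roles": [self.model.role_before, self.model.role_after],
            "unmatched_geneset": self.model.unmatched_geneset,
            **self.report.to_dict(),
        }
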