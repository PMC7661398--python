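"""Seedable generators emulating the three experimental designs.

Counts are drawn from a negative-binomial (gamma-Poisson) model, the standard
overdispersed description of RNA-seq counts: a gene with mean mu and size
(dispersion) parameter r has variance mu + mu^2/r.  Effects are
multiplicative fold changes on the mean.

* Restorative design (whole-blood cohort): healthy controls H, patients
  before treatment Pb with a disease fold change on an affected gene subset,
  and the same patients after treatment Pa where a restoration fraction
  rho in [0, 1] removes the disease effect on the log scale
  (mean = baseline * effect^(1 - rho)), so rho = 1 restores the healthy mean
  exactly and rho = 0 leaves Pa distributed like Pb.
* Disruptive design (treated cell line): CTRL vs TREAT with a perturbed gene
  subset, plus an optional designated gene set whose log-fold changes are
  boosted by a multiplier (drugs targeting e.g. apoptosis genes).
* Dose-mortality design: dead-cell counts n_dead ~ Binomial(n_cell,
  inverse-logit(a + b*dose)) per dose, optionally with two expression
  covariates mirroring a mechanistic gene (monotone in dose) and a noise gene.

Every generator takes an integer seed, is byte-deterministic given it, and
returns a truth table alongside the data so recovery tests never re-derive
the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, GroupDesign

__all__ = [
    "RestorativeSimSpec",
    "DisruptiveSimSpec",
    "simulate_restorative",
    "simulate_disruptive",
    "simulate_dose_mortality",
]


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Negative-binomial draws with the (mean, size) parameterization."""
    mean = np.asarray(mean, dtype=float)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


@dataclass(frozen=True)
class RestorativeSimSpec:
    """Conditions for a simulated restorative-drug cohort.

    Defaults mirror the whole-blood cohort design the indices were built
    around: 20 samples per role over ~15.6k genes, baseline means log-uniform
    across four orders of magnitude, moderate overdispersion, a 20% affected
    gene fraction with log2 fold changes of sd 1, and a half-restoring drug.
    """

    n_genes: int = 15570
    n_healthy: int = 20
    n_before: int = 20
    n_after: int = 20
    baseline_range: tuple[float, float] = (1.0, 1e4)
    dispersion: float = 10.0
    affected_fraction: float = 0.2
    effect_lfc_sd: float = 1.0
    restoration_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.affected_fraction <= 1:
            raise ValueError("affected_fraction must be in [0, 1]")
        if not 0 <= self.restoration_fraction <= 1:
            raise ValueError("restoration_fraction must be in [0, 1]")
        if min(self.n_genes, self.n_healthy, self.n_before, self.n_after) < 1:
            raise ValueError("counts must be positive integers")
        if self.dispersion <= 0 or self.baseline_range[0] <= 0:
            raise ValueError("dispersion and baseline means must be positive")


@dataclass(frozen=True)
class DisruptiveSimSpec:
    """Conditions for a simulated disruptive-drug experiment (3 vs 3 cell
    line design by default, with a strongly perturbed 30% of genes)."""

    n_genes: int = 10000
    n_ctrl: int = 3
    n_treat: int = 3
    baseline_range: tuple[float, float] = (1.0, 1e4)
    dispersion: float = 10.0
    perturbed_fraction: float = 0.3
    effect_lfc_sd: float = 2.0
    geneset_size: int = 0
    geneset_boost: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.perturbed_fraction <= 1:
            raise ValueError("perturbed_fraction must be in [0, 1]")
        if min(self.n_genes, self.n_ctrl, self.n_treat) < 1:
            raise ValueError("counts must be positive integers")
        if self.geneset_size < 0 or self.geneset_size > self.n_genes:
            raise ValueError("geneset_size must be in [0, n_genes]")
        if self.dispersion <= 0 or self.baseline_range[0] <= 0:
            raise ValueError("dispersion and baseline means must be positive")


def _baselines(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))


def simulate_restorative(
    spec: RestorativeSimSpec,
) -> tuple[ExpressionMatrix, GroupDesign, pd.DataFrame]:
    """Simulate (matrix, design, truth) for the restorative design.

    Truth columns: ``gene_id, affected, fold_change, mean_h, mean_pb,
    mean_pa``.  Unaffected genes have fold_change 1.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    base = _baselines(rng, spec.n_genes, *spec.baseline_range)
    affected = rng.random(spec.n_genes) < spec.affected_fraction
    lfc = np.where(affected, rng.normal(0.0, spec.effect_lfc_sd, spec.n_genes), 0.0)
    fold = np.exp2(lfc)
    mean_h = base
    mean_pb = base * fold
    mean_pa = base * fold ** (1.0 - spec.restoration_fraction)

    blocks, samples, roles = [], [], []
    for role, n, mu in (
        ("H", spec.n_healthy, mean_h),
        ("Pb", spec.n_before, mean_pb),
        ("Pa", spec.n_after, mean_pa),
    ):
        blocks.append(_nb_counts(rng, np.repeat(mu[:, None], n, axis=1), spec.dispersion))
        samples += [f"{role}{i + 1:02d}" for i in range(n)]
        roles += [role] * n
    values = pd.DataFrame(np.hstack(blocks), index=gene_ids, columns=samples, dtype=float)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "affected": affected,
            "fold_change": fold,
            "mean_h": mean_h,
            "mean_pb": mean_pb,
            "mean_pa": mean_pa,
        }
    )
    return (
        ExpressionMatrix(values, normalized=False),
        GroupDesign(dict(zip(samples, roles))),
        truth,
    )


def simulate_disruptive(
    spec: DisruptiveSimSpec,
) -> tuple[ExpressionMatrix, GroupDesign, pd.DataFrame]:
    """Simulate (matrix, design, truth) for the disruptive CTRL/TREAT design.

    The designated gene set is the first ``geneset_size`` genes; their
    (treatment) log fold changes are multiplied by ``geneset_boost``.  Truth
    columns: ``gene_id, perturbed, in_geneset, fold_change, mean_ctrl,
    mean_treat``.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    base = _baselines(rng, spec.n_genes, *spec.baseline_range)
    perturbed = rng.random(spec.n_genes) < spec.perturbed_fraction
    in_geneset = np.zeros(spec.n_genes, dtype=bool)
    in_geneset[: spec.geneset_size] = True
    lfc = np.where(perturbed, rng.normal(0.0, spec.effect_lfc_sd, spec.n_genes), 0.0)
    lfc = np.where(in_geneset, lfc * spec.geneset_boost, lfc)
    fold = np.exp2(lfc)
    mean_ctrl = base
    mean_treat = base * fold

    blocks, samples, roles = [], [], []
    for role, n, mu in (("CTRL", spec.n_ctrl, mean_ctrl), ("TREAT", spec.n_treat, mean_treat)):
        blocks.append(_nb_counts(rng, np.repeat(mu[:, None], n, axis=1), spec.dispersion))
        samples += [f"{role}{i + 1:02d}" for i in range(n)]
        roles += [role] * n
    values = pd.DataFrame(np.hstack(blocks), index=gene_ids, columns=samples, dtype=float)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "perturbed": perturbed,
            "in_geneset": in_geneset,
            "fold_change": fold,
            "mean_ctrl": mean_ctrl,
            "mean_treat": mean_treat,
        }
    )
    return (
        ExpressionMatrix(values, normalized=False),
        GroupDesign(dict(zip(samples, roles))),
        truth,
    )


def simulate_dose_mortality(
    a: float = -3.3827,
    b: float = 0.0130,
    doses: Sequence[float] = tuple(range(0, 501, 50)),
    n_cell: int | Sequence[int] = 3000,
    covariates: bool = False,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a dose-mortality table from a logistic dose-response.

    n_dead ~ Binomial(n_cell, inverse-logit(a + b*dose)) per dose.  With
    ``covariates=True`` two expression columns are added: ``AG2`` increasing
    linearly in dose with mild noise (a gene mechanistically tied to the
    drug's action) and ``AG1`` pure noise on a similar scale.  Returns the
    table and a truth frame with the per-dose propensity ``p_true``.
    """
    rng = np.random.default_rng(seed)
    doses = np.asarray(list(doses), dtype=float)
    if np.isscalar(n_cell):
        cells = np.full(len(doses), int(n_cell))
    else:
        cells = np.asarray(list(n_cell), dtype=int)
        if len(cells) != len(doses):
            raise ValueError("n_cell sequence must match doses")
    if (cells < 1).any():
        raise ValueError("n_cell must be >= 1 at every dose")
    p_true = 1.0 / (1.0 + np.exp(-(a + b * doses)))
    n_dead = rng.binomial(cells, p_true)
    table = pd.DataFrame({"Dose": doses, "N_Cell": cells, "N_Dead": n_dead})
    if covariates:
        span = doses.max() - doses.min() or 1.0
        table["AG1"] = rng.uniform(0, 2000, len(doses)).round(1)
        table["AG2"] = (
            100.0 + 1900.0 * (doses - doses.min()) / span + rng.normal(0, 60.0, len(doses))
        ).round(1)
    truth = pd.DataFrame({"Dose": doses, "p_true": p_true})
    return table, truth
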