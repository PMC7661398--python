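"""Grouped-binomial models of dose-dependent cancer-cell mortality.

The mortality propensity p of tumor cells is modeled with a logistic
regression: for a row with dose d and counts (n_dead out of n_cell),

    n_dead ~ Binomial(n_cell, p),   logit(p) = a + b * d,

fitted by maximum likelihood (IRLS, via statsmodels' binomial GLM).  The same
machinery regresses mortality on apoptosis-gene expression covariates, with
model selection over main-effect subsets and pairwise interactions by AIC
(ties by BIC, then parsimony) plus likelihood-ratio tests of nested pairs.

Two weighting conventions coexist and matter:

* ``grouped=True`` (default for :class:`DoseResponseModel`) uses the cell
  counts as binomial denominators.  This is the right scale for the
  dose-mortality curve itself, where every counted cell is an observation.
* ``grouped=False`` treats each row's observed mortality *proportion* as one
  binomial-family observation.  With thousands of cells per row the grouped
  fit declares biologically negligible covariate effects significant, so the
  expression-covariate screening (:func:`select_mortality_model`) defaults to
  the propensity scale, where a row — not a cell — is the replication unit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "load_dose_table",
    "validate_dose_table",
    "BinomialFit",
    "DoseResponseModel",
    "fit_binomial_logit",
    "predict_mortality",
    "ModelSelection",
    "select_mortality_model",
]

_REQUIRED = ("Dose", "N_Cell", "N_Dead")


def validate_dose_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the (dose, cells counted, cells dead, covariates...) invariants."""
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"dose table is missing required columns {missing}")
    if len(table) < 2:
        raise ValueError("dose table needs >= 2 rows")
    n_cell = table["N_Cell"].to_numpy()
    n_dead = table["N_Dead"].to_numpy()
    if (n_cell <= 0).any():
        raise ValueError("N_Cell must be positive in every row")
    if ((n_dead < 0) | (n_dead > n_cell)).any():
        raise ValueError("need 0 <= N_Dead <= N_Cell in every row")
    return table


def load_dose_table(path, delimiter: str = ",") -> pd.DataFrame:
    """Read a CSV with header ``Dose,N_Cell,N_Dead,<covariate...>``."""
    return validate_dose_table(pd.read_csv(path, sep=delimiter))


def _interaction_name(a: str, b: str) -> str:
    return f"{a}:{b}"


def _design_matrix(
    table: pd.DataFrame, terms: Sequence[str], interactions: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    X = pd.DataFrame({"Intercept": np.ones(len(table))}, index=table.index)
    for t in terms:
        if t not in table.columns:
            raise ValueError(f"covariate {t!r} not in table")
        X[t] = table[t].to_numpy(dtype=float)
    for a, b in interactions:
        for t in (a, b):
            if t not in terms:
                raise ValueError(f"interaction {a}:{b} requires main effect {t!r}")
        X[_interaction_name(a, b)] = (
            table[a].to_numpy(dtype=float) * table[b].to_numpy(dtype=float)
        )
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} columns): "
            f"collinear terms among {list(X.columns)}"
        )
    return X


@dataclass(frozen=True)
class BinomialFit:
    """Maximum-likelihood binomial-logit fit.

    ``params`` etc. are indexed by coefficient name ('Intercept', main
    effects, 'A:B' interactions).  ``converged`` is False on separation or
    IRLS failure; diagnostics then sit in ``message`` instead of being
    raised, so a selection sweep can continue past a pathological model.
    """

    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    llf: float
    aic: float
    bic: float
    deviance: float
    df_resid: int
    converged: bool
    iterations: int
    grouped: bool
    terms: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...]
    message: str = ""

    @property
    def n_params(self) -> int:
        return len(self.params)

    def predict(self, new_rows: pd.DataFrame) -> np.ndarray:
        """Mortality propensities (inverse-logit of the linear predictor)."""
        if not self.converged:
            raise ValueError(f"cannot predict from a non-converged fit: {self.message}")
        missing = [t for t in self.terms if t not in new_rows.columns]
        if missing:
            raise ValueError(f"new rows are missing model covariates {missing}")
        eta = np.full(len(new_rows), self.params["Intercept"], dtype=float)
        for t in self.terms:
            eta += self.params[t] * new_rows[t].to_numpy(dtype=float)
        for a, b in self.interactions:
            eta += self.params[_interaction_name(a, b)] * (
                new_rows[a].to_numpy(dtype=float) * new_rows[b].to_numpy(dtype=float)
            )
        return 1.0 / (1.0 + np.exp(-eta))

    def summary(self) -> str:
        tab = pd.DataFrame(
            {"coef": self.params, "se": self.bse, "z": self.zvalues, "p": self.pvalues}
        )
        head = (
            f"Binomial logit fit ({'grouped counts' if self.grouped else 'propensity scale'}; "
            f"converged={self.converged}, {self.iterations} iter)\n"
            f"logL = {self.llf:.4f}  AIC = {self.aic:.4f}  BIC = {self.bic:.4f}  "
            f"deviance = {self.deviance:.4f}\n"
        )
        return head + tab.to_string(float_format=lambda v: f"{v:.6g}")


class DoseResponseModel:
    """Binomial logistic model of cell mortality on dose and/or expression.

    Parameters
    ----------
    table : DataFrame with columns Dose, N_Cell, N_Dead plus covariates.
    terms : covariate names entering the linear predictor (intercept always
        included).
    interactions : pairs of term names whose product is added.
    grouped : fit dead-cell counts out of counted cells (True) or the per-row
        mortality proportion as a single observation (False).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        terms: Sequence[str] = ("Dose",),
        interactions: Sequence[tuple[str, str]] = (),
        grouped: bool = True,
    ):
        self.table = validate_dose_table(table)
        self.terms = tuple(terms)
        self.interactions = tuple((a, b) for a, b in interactions)
        self.grouped = grouped
        self.exog = _design_matrix(self.table, self.terms, self.interactions)

    def fit(self, maxiter: int = 100, tol: float = 1e-12) -> BinomialFit:
        n_dead = self.table["N_Dead"].to_numpy(dtype=float)
        n_cell = self.table["N_Cell"].to_numpy(dtype=float)
        if self.grouped:
            endog = np.column_stack([n_dead, n_cell - n_dead])
        else:
            endog = n_dead / n_cell
        names = list(self.exog.columns)
        try:
            glm = sm.GLM(endog, self.exog, family=sm.families.Binomial())
            res = glm.fit(maxiter=maxiter, tol=tol, scale=1.0)
            converged = bool(getattr(res, "converged", True))
            iterations = len(getattr(res, "fit_history", {}).get("deviance", [])) or maxiter
            message = "" if converged else "IRLS did not converge"
            # absurd standard errors signal (quasi-)separation
            if converged and np.any(np.asarray(res.bse) > 1e4):
                converged = False
                message = "apparent separation: unbounded coefficient estimates"
            return BinomialFit(
                params=pd.Series(np.asarray(res.params), index=names),
                bse=pd.Series(np.asarray(res.bse), index=names),
                zvalues=pd.Series(np.asarray(res.tvalues), index=names),
                pvalues=pd.Series(np.asarray(res.pvalues), index=names),
                llf=float(res.llf),
                aic=float(res.aic),
                bic=float(res.bic_llf),
                deviance=float(res.deviance),
                df_resid=int(res.df_resid),
                converged=converged,
                iterations=int(iterations),
                grouped=self.grouped,
                terms=self.terms,
                interactions=self.interactions,
                message=message,
            )
        except Exception as exc:  # separation raises in some statsmodels paths
            nan = pd.Series(np.full(len(names), np.nan), index=names)
            return BinomialFit(
                params=nan, bse=nan, zvalues=nan, pvalues=nan,
                llf=np.nan, aic=np.nan, bic=np.nan, deviance=np.nan,
                df_resid=len(self.table) - len(names),
                converged=False, iterations=0, grouped=self.grouped,
                terms=self.terms, interactions=self.interactions,
                message=f"fit failed: {exc}",
            )


def fit_binomial_logit(
    table: pd.DataFrame,
    formula_terms: Sequence[str] = ("Dose",),
    include_interactions: Sequence[tuple[str, str]] = (),
    grouped: bool = True,
) -> BinomialFit:
    """Functional form of :class:`DoseResponseModel` + ``fit``."""
    return DoseResponseModel(table, formula_terms, include_interactions, grouped=grouped).fit()


def predict_mortality(fit: BinomialFit, new_rows: pd.DataFrame) -> np.ndarray:
    return fit.predict(new_rows)


@dataclass
class ModelSelection:
    """Outcome of an all-subsets covariate screen."""

    models: pd.DataFrame  # one row per candidate model, AIC-ranked
    lr_tests: pd.DataFrame  # likelihood-ratio tests of nested pairs
    best: BinomialFit
    fits: dict = field(repr=False, default_factory=dict)

    @property
    def best_terms(self) -> tuple[str, ...]:
        return self.best.terms

    def summary(self) -> str:
        out = ["Model selection (AIC; ties by BIC, then fewer terms)", ""]
        out.append(self.models.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        out.append("")
        out.append("Likelihood-ratio tests of nested pairs")
        out.append(self.lr_tests.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(out)


def _model_label(terms, interactions) -> str:
    parts = list(terms) + [_interaction_name(a, b) for a, b in interactions]
    return " + ".join(parts) if parts else "1"


def select_mortality_model(
    table: pd.DataFrame,
    candidate_covariates: Sequence[str],
    grouped: bool = False,
) -> ModelSelection:
    """Screen mortality models over expression covariates.

    Fits every subset of the candidate main effects (including the
    intercept-only model) and, for subsets with >= 2 mains, every combination
    of pairwise interactions among the included mains.  Models are ranked by
    AIC with ties broken by BIC and then by parameter count; nested pairs get
    likelihood-ratio tests.  Defaults to the propensity scale (see module
    docstring) — pass ``grouped=True`` to weight by cell counts.
    """
    candidates = list(candidate_covariates)
    if not candidates:
        raise ValueError("need >= 1 candidate covariate")
    specs: list[tuple[tuple[str, ...], tuple[tuple[str, str], ...]]] = []
    for k in range(len(candidates) + 1):
        for mains in itertools.combinations(candidates, k):
            pairs = list(itertools.combinations(mains, 2))
            for j in range(len(pairs) + 1):
                for inters in itertools.combinations(pairs, j):
                    specs.append((mains, inters))
    fits: dict[str, BinomialFit] = {}
    rows = []
    for mains, inters in specs:
        fit = DoseResponseModel(table, mains, inters, grouped=grouped).fit()
        label = _model_label(mains, inters)
        fits[label] = fit
        rows.append(
            {
                "model": label,
                "k": fit.n_params,
                "llf": fit.llf,
                "aic": fit.aic,
                "bic": fit.bic,
                "converged": fit.converged,
            }
        )
    models = pd.DataFrame(rows)
    ranked = models[models["converged"]].sort_values(
        by=["aic", "bic", "k"], kind="mergesort"
    )
    if ranked.empty:
        raise ValueError("no candidate model converged")
    models = pd.concat([ranked, models[~models["converged"]]], ignore_index=True)
    best = fits[models.iloc[0]["model"]]

    lr_rows = []
    labels = [r["model"] for _, r in models.iterrows() if r["converged"]]
    def _cols(label):
        f = fits[label]
        return set(f.params.index)
    for small, big in itertools.combinations(labels, 2):
        cs, cb = _cols(small), _cols(big)
        if cs < cb:
            pair = (small, big)
        elif cb < cs:
            pair = (big, small)
        else:
            continue
        fs, fb = fits[pair[0]], fits[pair[1]]
        lr = 2.0 * (fb.llf - fs.llf)
        dfree = fb.n_params - fs.n_params
        lr_rows.append(
            {
                "reduced": pair[0],
                "full": pair[1],
                "lr_stat": max(lr, 0.0),
                "df": dfree,
                "p": float(stats.chi2.sf(max(lr, 0.0), dfree)),
            }
        )
    lr_tests = pd.DataFrame(lr_rows, columns=["reduced", "full", "lr_stat", "df", "p"])
    return ModelSelection(models=models, lr_tests=lr_tests, best=best, fits=fits)
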