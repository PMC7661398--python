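"""Expression matrices, sample-group designs, CPM normalization and gene filtering.

The central container is :class:`ExpressionMatrix`, a thin validated wrapper
around a genes x samples :class:`pandas.DataFrame` of nonnegative expression
values.  All downstream statistics operate on counts-per-million (CPM)
normalized values: every sample column is scaled so that its total is one
million, which puts libraries of different sequencing depth on a common scale
without any between-sample normalization beyond total-count scaling.

Genes with very low expression carry essentially no information for a
two-sample t statistic (their group means sit at the noise floor), so the
standard preprocessing here is ``normalize_cpm`` followed by
``filter_low_expression`` with a mean-CPM threshold of 10 computed across
*all* samples of the matrix.  Genes whose mean equals the threshold exactly
are kept; only strictly lower means are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CPM_TOTAL",
    "MatrixValidationError",
    "ExpressionMatrix",
    "GroupDesign",
    "read_matrix",
    "write_matrix",
    "read_geneset",
    "normalize_cpm",
    "filter_low_expression",
    "select_geneset",
]

#: Column total after CPM normalization.
CPM_TOTAL = 1_000_000.0

#: Relative tolerance for checking that a normalized column sums to CPM_TOTAL.
_CPM_RTOL = 1e-9


class MatrixValidationError(ValueError):
    """An expression matrix or group design violates a structural invariant."""


def _first_duplicate(items: Sequence) -> object | None:
    seen = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample matrix of nonnegative expression values.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene identifier, columns by sample label.
    normalized : bool
        True once every column has been scaled to sum to one million (CPM).
    filtered : bool
        True once genes have been dropped after normalization (column totals
        then fall below one million by construction, since filtering never
        re-normalizes).

    Invariants checked at construction: unique gene and sample identifiers,
    all values finite and >= 0, and (when ``normalized`` and not
    ``filtered``) column totals equal to one million within relative
    tolerance 1e-9.
    """

    values: pd.DataFrame
    normalized: bool = False
    filtered: bool = False

    def __post_init__(self) -> None:
        df = self.values
        if not isinstance(df, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (genes x samples)")
        dup = _first_duplicate(list(df.index))
        if dup is not None:
            raise MatrixValidationError(f"duplicate gene identifier: {dup!r}")
        dup = _first_duplicate(list(df.columns))
        if dup is not None:
            raise MatrixValidationError(f"duplicate sample identifier: {dup!r}")
        arr = df.to_numpy(dtype=float, copy=False)
        if arr.size and not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise MatrixValidationError(
                f"non-finite value at gene {df.index[i]!r}, sample {df.columns[j]!r}"
            )
        if arr.size and (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise MatrixValidationError(
                f"negative value at gene {df.index[i]!r}, sample {df.columns[j]!r}"
            )
        if self.normalized and not self.filtered and arr.size:
            totals = arr.sum(axis=0)
            bad = np.abs(totals - CPM_TOTAL) > _CPM_RTOL * CPM_TOTAL
            if bad.any():
                j = int(np.argmax(bad))
                raise MatrixValidationError(
                    f"normalized matrix column {df.columns[j]!r} sums to "
                    f"{totals[j]:.6g}, expected {CPM_TOTAL:.0f}"
                )

    # -- basic accessors ---------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    # -- transformations ---------------------------------------------------

    def normalize_cpm(self) -> "ExpressionMatrix":
        """Scale every sample column so that it sums to one million.

        Raises
        ------
        MatrixValidationError
            If the matrix is already normalized, or if a column sums to zero
            (the scale factor would be undefined for that sample).
        """
        if self.normalized:
            raise MatrixValidationError("matrix is already CPM-normalized")
        totals = self.values.sum(axis=0)
        zero = totals[totals == 0]
        if len(zero):
            raise MatrixValidationError(
                f"cannot normalize all-zero sample column {zero.index[0]!r}"
            )
        scaled = self.values * (CPM_TOTAL / totals)
        return ExpressionMatrix(scaled, normalized=True)

    def filter_low_expression(self, threshold: float = 10.0) -> "ExpressionMatrix":
        """Drop genes whose mean value across all samples is strictly below
        ``threshold``; genes at exactly the threshold are kept.

        The mean is taken over every sample of the matrix, and column sums are
        deliberately *not* re-normalized afterwards — the retained values stay
        on the original CPM scale so group means remain comparable.
        """
        if not self.normalized:
            raise MatrixValidationError("filter_low_expression requires a CPM-normalized matrix")
        if threshold < 0:
            raise ValueError("threshold must be >= 0")
        keep = self.values.mean(axis=1) >= threshold
        return ExpressionMatrix(self.values.loc[keep], normalized=True, filtered=True)

    def select_genes(
        self, gene_list: Iterable[str]
    ) -> tuple["ExpressionMatrix", list[str]]:
        """Restrict to the genes in ``gene_list``.

        Returns the sub-matrix (preserving this matrix's gene order) and the
        list of requested identifiers that were not found.  Unmatched
        identifiers are reported, not fatal; an *empty* intersection is an
        error because no statistic can be computed from it.
        """
        wanted = list(dict.fromkeys(gene_list))  # de-dup, keep order
        if not wanted:
            raise ValueError("gene_list is empty")
        wanted_set = set(wanted)
        keep = [g for g in self.values.index if g in wanted_set]
        missing = [g for g in wanted if g not in set(keep)]
        if not keep:
            raise MatrixValidationError(
                "none of the requested gene identifiers are present in the matrix"
            )
        sub = ExpressionMatrix(
            self.values.loc[keep],
            normalized=self.normalized,
            filtered=self.filtered or (self.normalized and len(keep) < self.n_genes),
        )
        return sub, missing

    def subset_samples(self, samples: Sequence[str]) -> np.ndarray:
        """Values for the named sample columns as a float array (genes x k)."""
        return self.values[list(samples)].to_numpy(dtype=float)


@dataclass(frozen=True)
class GroupDesign:
    """Assignment of each sample to an analysis role.

    Role vocabularies in use: ``H`` / ``Pb`` / ``Pa`` (healthy controls,
    patients before and after treatment) for restorative analyses;
    ``CTRL`` / ``TREAT`` for disruptive efficacy; ``NB`` / ``NA`` (normal
    tissue before/after) for disruptive toxicity.  Any role tokens work as
    long as the analysis is told which pair to compare.
    """

    role_of_sample: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.role_of_sample:
            raise MatrixValidationError("group design is empty")

    def samples(self, role: str) -> list[str]:
        """Samples assigned to ``role``, in design order."""
        return [s for s, r in self.role_of_sample.items() if r == role]

    @property
    def roles(self) -> list[str]:
        out: list[str] = []
        for r in self.role_of_sample.values():
            if r not in out:
                out.append(r)
        return out

    def validate_for(
        self,
        matrix: ExpressionMatrix,
        required_roles: Sequence[str],
        min_per_role: int = 2,
    ) -> None:
        """Check that each required role has >= ``min_per_role`` samples and
        that all of its samples exist in ``matrix`` (t tests need a variance
        estimate, hence the minimum of two)."""
        cols = set(matrix.sample_ids)
        for role in required_roles:
            ss = self.samples(role)
            if len(ss) < min_per_role:
                raise MatrixValidationError(
                    f"role {role!r} has {len(ss)} samples; need >= {min_per_role}"
                )
            missing = [s for s in ss if s not in cols]
            if missing:
                raise MatrixValidationError(
                    f"samples {missing} of role {role!r} are absent from the matrix"
                )

    @classmethod
    def from_file(cls, path, delimiter: str = "\t") -> "GroupDesign":
        """Read a two-column (sample_id, role) delimited file, no header."""
        df = pd.read_csv(path, sep=delimiter, header=None, comment="#", dtype=str)
        if df.shape[1] < 2:
            raise MatrixValidationError(
                f"design file {path} must have two columns (sample_id, role)"
            )
        mapping: dict[str, str] = {}
        for sample, role in zip(df.iloc[:, 0], df.iloc[:, 1]):
            if sample in mapping:
                raise MatrixValidationError(f"sample {sample!r} assigned more than one role")
            mapping[sample] = role
        return cls(mapping)


# -- file I/O ---------------------------------------------------------------


def read_matrix(path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a delimited gene x sample matrix.

    First row: header of sample labels; first column: gene identifiers; every
    other cell must parse as a nonnegative number.  Duplicate identifiers and
    negative or non-numeric cells raise :class:`MatrixValidationError` naming
    the offending gene/sample.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
    sample_ids = header[1:]
    dup = _first_duplicate(sample_ids)
    if dup is not None:
        raise MatrixValidationError(f"duplicate sample identifier: {dup!r}")
    raw = pd.read_csv(path, sep=delimiter, index_col=0, header=0)
    raw.columns = sample_ids  # undo any pandas dedup mangling (none expected)
    dup = _first_duplicate(list(raw.index))
    if dup is not None:
        raise MatrixValidationError(f"duplicate gene identifier: {dup!r}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise MatrixValidationError(
            f"non-numeric cell at gene {raw.index[i]!r}, sample {raw.columns[j]!r}: "
            f"{raw.iat[i, j]!r}"
        )
    return ExpressionMatrix(numeric.astype(float), normalized=False)


def write_matrix(m: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    """Write the matrix as delimited text, full float precision (round-trips)."""
    m.values.to_csv(path, sep=delimiter, index_label="gene_id", float_format="%.17g")


def read_geneset(path) -> list[str]:
    """Read a gene-set file: one identifier per line, '#' comments allowed."""
    genes: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.append(line)
    if not genes:
        raise ValueError(f"gene-set file {path} contains no identifiers")
    return genes


# -- functional aliases mirroring the pipeline vocabulary -------------------


def normalize_cpm(m: ExpressionMatrix) -> ExpressionMatrix:
    return m.normalize_cpm()


def filter_low_expression(m: ExpressionMatrix, threshold: float = 10.0) -> ExpressionMatrix:
    return m.filter_low_expression(threshold)


def select_geneset(
    m: ExpressionMatrix, gene_list: Iterable[str]
) -> tuple[ExpressionMatrix, list[str]]:
    return m.select_genes(gene_list)
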