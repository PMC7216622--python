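"""Alignment, filtering and normalization of a pair of circumstance matrices.

The core loop consumes four normalized matrices derived from the two raw
G2M matrices: after restricting both to their shared genes and marks,
dropping genes with pervasive zero signal, and a log2(x+1) transform, each
matrix is standardized per mark (column mean 0, sd 1) to give the
mark-scaled pair, and the mark-scaled matrices are standardized per gene
(row mean 0, sd 1) to give the gene-scaled pair.  Standard deviations use
the sample (n−1) denominator throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circumstance import SignalMatrix


@dataclass
class NormalizedPair:
    """The four matrices the iterative loop consumes.

    ``mark_scaled_*`` are column-standardized (each mark mean 0 / sd 1
    within its condition); ``gene_scaled_*`` are the row-standardized
    versions of the mark-scaled matrices.  All four share identical row
    (gene) and column (mark) label order.  ``filter_report`` records every
    gene removed during preprocessing and why.
    """

    mark_scaled_1: pd.DataFrame
    mark_scaled_2: pd.DataFrame
    gene_scaled_1: pd.DataFrame
    gene_scaled_2: pd.DataFrame
    condition_1: str = "C1"
    condition_2: str = "C2"
    filter_report: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene_id", "reason"])
    )

    def __post_init__(self) -> None:
        mats = [self.mark_scaled_1, self.mark_scaled_2, self.gene_scaled_1, self.gene_scaled_2]
        for m in mats[1:]:
            if not m.index.equals(mats[0].index) or not m.columns.equals(mats[0].columns):
                raise ValueError("all four matrices must share identical row/column labels")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.mark_scaled_1.index)

    @property
    def mark_names(self) -> list[str]:
        return list(self.mark_scaled_1.columns)


def _frame(m: SignalMatrix | pd.DataFrame) -> pd.DataFrame:
    return m.data if isinstance(m, SignalMatrix) else m


def align_matrices(
    m1: SignalMatrix | pd.DataFrame, m2: SignalMatrix | pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both matrices to their shared genes and marks, same order.

    Order follows the first matrix's ordering of the shared labels.
    """
    d1, d2 = _frame(m1), _frame(m2)
    genes = [g for g in d1.index if g in set(d2.index)]
    marks = [m for m in d1.columns if m in set(d2.columns)]
    if len(genes) < 2:
        raise ValueError(f"need >=2 shared genes, found {len(genes)}")
    if len(marks) < 2:
        raise ValueError(f"need >=2 shared marks, found {len(marks)}")
    return d1.loc[genes, marks].copy(), d2.loc[genes, marks].copy()


def filter_low_signal(
    m1: pd.DataFrame, m2: pd.DataFrame, rule: str = "joint"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Drop genes in which at least half of the marks present zero signal.

    Under the default ``joint`` rule a gene is dropped iff the number of
    marks whose signal is exactly 0 in BOTH matrices simultaneously is
    >= ceil(M/2).  The ``independent`` variant drops a gene iff each matrix
    separately has >= ceil(M/2) zero marks for it.  Surviving genes keep
    their original relative order.  Returns the filtered pair plus a
    report of the removed genes.
    """
    if not m1.index.equals(m2.index) or not m1.columns.equals(m2.columns):
        raise ValueError("matrices must be aligned before filtering")
    n_marks = m1.shape[1]
    threshold = math.ceil(n_marks / 2)
    z1 = m1.values == 0.0
    z2 = m2.values == 0.0
    if rule == "joint":
        drop = (z1 & z2).sum(axis=1) >= threshold
    elif rule == "independent":
        drop = (z1.sum(axis=1) >= threshold) & (z2.sum(axis=1) >= threshold)
    else:
        raise ValueError(f"unknown filter rule {rule!r}")
    if drop.all():
        raise ValueError("all genes removed by the low-signal filter")
    report = pd.DataFrame(
        {"gene_id": m1.index[drop], "reason": "low_signal"}
    ).reset_index(drop=True)
    keep = ~drop
    return m1.loc[keep].copy(), m2.loc[keep].copy(), report


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Entrywise log2(x + 1); input must be non-negative."""
    if (matrix.values < 0).any():
        raise ValueError("log_transform requires non-negative input")
    return pd.DataFrame(np.log2(matrix.values + 1.0), index=matrix.index, columns=matrix.columns)


def scale_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each column to mean 0, sd 1 (n−1 denominator).

    A zero-variance column is a degenerate mark — every gene carries the
    same level — and is an error rather than something to silently drop.
    """
    vals = matrix.values.astype(float)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    bad = sd == 0
    if bad.any():
        names = list(matrix.columns[bad])
        raise ValueError(f"zero-variance mark column(s): {names}")
    return pd.DataFrame((vals - mean) / sd, index=matrix.index, columns=matrix.columns)


def scale_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Standardize each row to mean 0, sd 1 (n−1 denominator).

    Zero-variance rows (genes with a flat profile) cannot be standardized;
    they are removed and their ids returned so the caller can drop them
    from both conditions.
    """
    vals = matrix.values.astype(float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    dropped = list(matrix.index[flat])
    if flat.any():
        warnings.warn(f"{flat.sum()} constant-profile gene(s) removed: {dropped}", stacklevel=2)
        vals = vals[~flat]
        mean = mean[~flat]
        sd = sd[~flat]
    out = pd.DataFrame((vals - mean) / sd, index=matrix.index[~flat], columns=matrix.columns)
    return out, dropped


def normalize_pair(
    m1: SignalMatrix | pd.DataFrame,
    m2: SignalMatrix | pd.DataFrame,
    *,
    filter_rule: str = "joint",
    condition_1: str | None = None,
    condition_2: str | None = None,
) -> NormalizedPair:
    """Full preprocessing: align → filter → log → scale by marks → by genes."""
    c1 = condition_1 or (m1.condition if isinstance(m1, SignalMatrix) and m1.condition else "C1")
    c2 = condition_2 or (m2.condition if isinstance(m2, SignalMatrix) and m2.condition else "C2")
    a1, a2 = align_matrices(m1, m2)
    f1, f2, report = filter_low_signal(a1, a2, rule=filter_rule)
    l1, l2 = log_transform(f1), log_transform(f2)
    ms1, ms2 = scale_columns(l1), scale_columns(l2)
    gs1, drop1 = scale_rows(ms1)
    gs2, drop2 = scale_rows(ms2)
    flat = sorted(set(drop1) | set(drop2))
    if flat:
        keep = [g for g in ms1.index if g not in set(flat)]
        if len(keep) < 2:
            raise ValueError("fewer than 2 genes survive preprocessing")
        # re-standardize columns after the row-driven gene drop so the
        # mark-scaled invariant still holds on the final gene set
        ms1 = scale_columns(l1.loc[keep])
        ms2 = scale_columns(l2.loc[keep])
        gs1, _ = scale_rows(ms1)
        gs2, _ = scale_rows(ms2)
        report = pd.concat(
            [report, pd.DataFrame({"gene_id": flat, "reason": "constant_profile"})],
            ignore_index=True,
        )
    return NormalizedPair(ms1, ms2, gs1, gs2, c1, c2, report)


def guan_normalize(context_matrix: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Fisher-z + standard-normal normalization of a correlation matrix.

    Off-diagonal correlations are transformed with atanh (clipped to
    ±(1−eps) first) and standardized to mean 0 / sd 1 over the off-diagonal
    entries; the diagonal is set to the maximum transformed value so that
    self-similarity stays maximal.  Used to harmonize the correlation
    distributions of the two conditions before the iterative comparison.
    """
    c = np.asarray(context_matrix, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("context matrix must be square")
    off = ~np.eye(c.shape[0], dtype=bool)
    z = np.arctanh(np.clip(c, -1 + eps, 1 - eps))
    vals = z[off]
    sd = vals.std(ddof=1)
    if sd <= 1e-12:
        raise ValueError("constant off-diagonal correlations; cannot standardize")
    out = (z - vals.mean()) / sd
    np.fill_diagonal(out, out[off].max())
    return out
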