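"""The iterative gene/mark conservation scoring algorithm.

Given the four normalized matrices of a two-condition pair, the algorithm
alternates between two context levels:

1. gene-context matrices G2G (one per condition) — weighted Pearson
   correlations between every pair of gene rows of the mark-scaled
   matrices, weighted by the current mark weights;
2. a fixed-point inner loop over genes — each gene's score is the weighted
   correlation between its two context rows, weighted by the current gene
   weights; the clipped scores become the next gene weights;
3. mark-context matrices M2M from the gene-scaled matrices, weighted by
   the converged gene weights;
4. the same inner loop over marks;
5. an outer loop that repeats 1–4 until both weight vectors stabilize.

All correlations produced during the iteration are clipped below at 0 (a
negative context similarity carries no biological meaning as a weight),
but the REPORTED gene and mark scores are the final raw inner-loop
correlations and may be negative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .circumstance import gene_signal
from .preprocess import NormalizedPair, guan_normalize, normalize_pair, scale_columns, scale_rows

logger = logging.getLogger(__name__)


@dataclass
class ICGECResult:
    """Converged scores plus the iteration record.

    ``gene_scores`` / ``mark_scores`` are the final raw weighted
    correlations in [−1, 1].  ``weight_trace`` holds the (clipped) gene and
    mark weight vectors after every outer iteration so the recurrence can
    be audited step by step.
    """

    gene_scores: pd.Series
    mark_scores: pd.Series
    n_outer: int
    inner_iteration_counts: list[tuple[int, int]]
    converged: bool
    delta_trace: list[float]
    weight_trace: list[dict[str, np.ndarray]] = field(default_factory=list)
    degenerate_genes: list[str] = field(default_factory=list)
    degenerate_marks: list[str] = field(default_factory=list)


def _check_weights(w: np.ndarray, n: int) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weight vector has length {w.shape}, expected {n}")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if w.sum() <= 0:
        raise ValueError("at least one weight must be positive")
    return w


def weighted_pcc(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted Pearson correlation with weighted means and (co)variances.

    Invariant to positive rescaling of ``w``; equals the ordinary Pearson
    correlation when all weights are equal.  Returns 0 (logged) when
    either vector has zero weighted variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 2:
        raise ValueError("need at least two observations")
    w = _check_weights(w, x.size)
    wn = w / w.sum()
    xc = x - wn @ x
    yc = y - wn @ y
    vx = wn @ (xc * xc)
    vy = wn @ (yc * yc)
    if vx <= 0 or vy <= 0:
        logger.debug("weighted_pcc: zero weighted variance; returning 0")
        return 0.0
    r = (wn @ (xc * yc)) / np.sqrt(vx * vy)
    return float(np.clip(r, -1.0, 1.0))


def _weighted_corr_rows(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted Pearson correlation of every pair of rows of X (vectorized).

    Rows with zero weighted variance get 0 correlation with everything.
    """
    wn = w / w.sum()
    Xc = X - (X @ wn)[:, None]
    C = (Xc * wn) @ Xc.T
    d = np.diag(C).copy()
    ok = d > 0
    denom = np.sqrt(np.outer(np.where(ok, d, 1.0), np.where(ok, d, 1.0)))
    R = C / denom
    R[~ok, :] = 0.0
    R[:, ~ok] = 0.0
    np.clip(R, -1.0, 1.0, out=R)
    return R


def gene_context(
    mark_scaled: pd.DataFrame | np.ndarray,
    w_m: np.ndarray,
    *,
    guan: bool = False,
) -> np.ndarray:
    """Gene × gene context matrix from a mark-scaled matrix.

    Entry (i, j) = max(0, wPCC(row_i, row_j; w_m)); the diagonal is forced
    to 1.  With ``guan=True`` the raw correlations are instead Fisher-z
    transformed and standardized (no clipping: on the z scale negative
    entries are meaningful deviations, and the diagonal carries the
    maximum value).
    """
    X = mark_scaled.values if isinstance(mark_scaled, pd.DataFrame) else np.asarray(mark_scaled)
    w_m = _check_weights(w_m, X.shape[1])
    R = _weighted_corr_rows(X, w_m)
    if guan:
        return guan_normalize(R)
    np.clip(R, 0.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    return R


def mark_context(
    gene_scaled: pd.DataFrame | np.ndarray,
    w_g: np.ndarray,
    *,
    guan: bool = False,
) -> np.ndarray:
    """Mark × mark context matrix from a gene-scaled matrix (columns
    correlated, weighted by gene weights)."""
    X = gene_scaled.values if isinstance(gene_scaled, pd.DataFrame) else np.asarray(gene_scaled)
    return gene_context(X.T, w_g, guan=guan)


def _rowwise_wpcc(A: np.ndarray, B: np.ndarray, w: np.ndarray) -> np.ndarray:
    """wPCC of equivalent rows of A and B under shared weights w."""
    wn = w / w.sum()
    Ac = A - (A @ wn)[:, None]
    Bc = B - (B @ wn)[:, None]
    cov = (Ac * wn * Bc).sum(axis=1)
    va = (Ac * Ac * wn).sum(axis=1)
    vb = (Bc * Bc * wn).sum(axis=1)
    ok = (va > 0) & (vb > 0)
    s = np.zeros(A.shape[0])
    s[ok] = cov[ok] / np.sqrt(va[ok] * vb[ok])
    return np.clip(s, -1.0, 1.0)


def _rowwise_wpcc_nodiag(A: np.ndarray, B: np.ndarray, w: np.ndarray) -> np.ndarray:
    """As :func:`_rowwise_wpcc` but row i excludes its own index i (the
    self-correlation entries, both 1 by construction)."""
    n = A.shape[0]
    s = np.zeros(n)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        wi = w[mask]
        if wi.sum() <= 0:
            continue
        s[i] = weighted_pcc(A[i, mask], B[i, mask], wi)
    return s


def inner_loop(
    ctx_1: np.ndarray,
    ctx_2: np.ndarray,
    w_init: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 100,
    *,
    include_diagonal: bool = True,
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Fixed-point iteration of weights against a pair of context matrices.

    Each item's raw score is the weighted correlation of its two context
    rows under the current weights; the non-negative part of the scores
    becomes the next weight vector.  Iterates until the maximum absolute
    weight change drops below ``tol``.

    Returns ``(weights, raw_scores, n_iter, converged)``; ``raw_scores``
    are the final unclipped correlations.
    """
    ctx_1 = np.asarray(ctx_1, dtype=float)
    ctx_2 = np.asarray(ctx_2, dtype=float)
    if ctx_1.shape != ctx_2.shape or ctx_1.ndim != 2:
        raise ValueError("context matrices must share shape")
    if tol <= 0:
        raise ValueError("tol must be positive")
    w = _check_weights(w_init, ctx_1.shape[0]).copy()
    score_fn = _rowwise_wpcc if include_diagonal else _rowwise_wpcc_nodiag
    s = np.zeros(ctx_1.shape[0])
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        s = score_fn(ctx_1, ctx_2, w)
        w_new = np.maximum(s, 0.0)
        if w_new.sum() <= 0:
            raise ValueError("degenerate comparison: all weights collapsed to 0")
        delta = float(np.abs(w_new - w).max())
        w = w_new
        if delta < tol:
            converged = True
            break
    return w, s, n_iter, converged


def _resolve_init(init, n: int, rng: np.random.Generator | None) -> np.ndarray:
    if isinstance(init, str):
        if init == "equal":
            return np.ones(n)
        if init == "random":
            if rng is None:
                raise ValueError("random initial weights require a seed/rng")
            return rng.uniform(0.5, 1.5, size=n)
        raise ValueError(f"unknown weight initialization {init!r}")
    return _check_weights(init, n).copy()


def run_icgec(
    pair: NormalizedPair,
    w_m_init="equal",
    w_g_init="equal",
    inner_tol: float = 1e-4,
    outer_tol: float = 1e-4,
    max_inner: int = 100,
    max_outer: int = 50,
    *,
    guan: bool = False,
    update_mark_weights: bool = True,
    include_diagonal: bool = True,
    seed: int | None = None,
) -> ICGECResult:
    """Run the full outer/inner-loop algorithm to convergence.

    Inner loops warm-start from the weight vectors carried over from the
    previous outer iteration; the outer loop stops when both the gene and
    the mark weight vectors change by less than ``outer_tol`` (max norm)
    across one outer iteration.  With ``update_mark_weights=False`` the
    mark weights stay at their initial values and the mark scores are a
    single post-hoc correlation pass (the equal-mark-weight predecessor
    mode of the method).
    """
    rng = np.random.default_rng(seed) if seed is not None else None
    X1m = pair.mark_scaled_1.values
    X2m = pair.mark_scaled_2.values
    X1g = pair.gene_scaled_1.values
    X2g = pair.gene_scaled_2.values
    n_genes, n_marks = X1m.shape
    w_m = _resolve_init(w_m_init, n_marks, rng)
    w_g = _resolve_init(w_g_init, n_genes, rng)

    s_g = np.zeros(n_genes)
    s_m = np.zeros(n_marks)
    inner_counts: list[tuple[int, int]] = []
    delta_trace: list[float] = []
    weight_trace: list[dict[str, np.ndarray]] = []
    converged = False
    n_outer = 0
    for n_outer in range(1, max_outer + 1):
        G1 = gene_context(X1m, w_m, guan=guan)
        G2 = gene_context(X2m, w_m, guan=guan)
        w_g_new, s_g, it_g, _ = inner_loop(
            G1, G2, w_g, inner_tol, max_inner, include_diagonal=include_diagonal
        )
        M1 = mark_context(X1g, w_g_new, guan=guan)
        M2 = mark_context(X2g, w_g_new, guan=guan)
        if update_mark_weights:
            w_m_new, s_m, it_m, _ = inner_loop(
                M1, M2, w_m, inner_tol, max_inner, include_diagonal=include_diagonal
            )
        else:
            score_fn = _rowwise_wpcc if include_diagonal else _rowwise_wpcc_nodiag
            s_m = score_fn(M1, M2, w_m)
            w_m_new, it_m = w_m, 0
        inner_counts.append((it_g, it_m))
        delta = max(
            float(np.abs(w_g_new - w_g).max()), float(np.abs(w_m_new - w_m).max())
        )
        delta_trace.append(delta)
        w_g, w_m = w_g_new, w_m_new
        weight_trace.append({"w_g": w_g.copy(), "w_m": w_m.copy()})
        if delta < outer_tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"outer loop did not converge in {max_outer} iterations "
            f"(last delta {delta_trace[-1]:.3g})",
            stacklevel=2,
        )
    genes = pair.gene_ids
    marks = pair.mark_names
    return ICGECResult(
        gene_scores=pd.Series(s_g, index=genes, name="gene_score"),
        mark_scores=pd.Series(s_m, index=marks, name="mark_score"),
        n_outer=n_outer,
        inner_iteration_counts=inner_counts,
        converged=converged,
        delta_trace=delta_trace,
        weight_trace=weight_trace,
        degenerate_genes=[g for g, v in zip(genes, s_g) if v == 0.0],
        degenerate_marks=[m for m, v in zip(marks, s_m) if v == 0.0],
    )


def run_icc(pair: NormalizedPair, **kwargs) -> ICGECResult:
    """Equal-mark-weight mode: the predecessor algorithm, in which only
    gene weights iterate and mark scores are a single post-hoc pass."""
    kwargs.pop("update_mark_weights", None)
    kwargs.setdefault("w_m_init", "equal")
    return run_icgec(pair, update_mark_weights=False, **kwargs)


def leave_marks_out(pair: NormalizedPair, drop: Sequence[str] | set[str], **kwargs) -> ICGECResult:
    """Re-run the algorithm with a set of marks removed.

    The dropped columns are removed from the mark-scaled matrices and the
    standardization is re-applied on the reduced matrices (column scaling
    is idempotent under column removal; row scaling must be recomputed)
    before running the full algorithm.
    """
    drop = set(drop)
    unknown = drop - set(pair.mark_names)
    if unknown:
        raise ValueError(f"unknown mark(s) to drop: {sorted(unknown)}")
    keep = [m for m in pair.mark_names if m not in drop]
    if len(keep) < 2:
        raise ValueError("at least 2 marks must remain")
    if not drop:
        return run_icgec(pair, **kwargs)
    ms1 = scale_columns(pair.mark_scaled_1[keep])
    ms2 = scale_columns(pair.mark_scaled_2[keep])
    gs1, flat1 = scale_rows(ms1)
    gs2, flat2 = scale_rows(ms2)
    flat = set(flat1) | set(flat2)
    if flat:
        keep_genes = [g for g in ms1.index if g not in flat]
        ms1 = scale_columns(ms1.loc[keep_genes])
        ms2 = scale_columns(ms2.loc[keep_genes])
        gs1, _ = scale_rows(ms1)
        gs2, _ = scale_rows(ms2)
    reduced = NormalizedPair(ms1, ms2, gs1, gs2, pair.condition_1, pair.condition_2)
    return run_icgec(reduced, **kwargs)


def _binned_signal(
    peaks, window_start: int, window_end: int, bin_bp: int
) -> np.ndarray:
    """Per-bin weighted signal (gene_signal with fixed-width bins as regions)."""
    n_bins = (window_end - window_start) // bin_bp
    acc = np.zeros(n_bins)
    for p in peaks:
        s = max(p.start, window_start)
        e = min(p.end, window_end)
        if e <= s:
            continue
        b0 = (s - window_start) // bin_bp
        b1 = (e - 1 - window_start) // bin_bp
        for b in range(b0, b1 + 1):
            bs = window_start + b * bin_bp
            acc[b] += (min(e, bs + bin_bp) - max(s, bs)) * p.signal
    return acc / bin_bp


def windowed_conservation(
    peaks_by_mark_1: Mapping[str, Sequence],
    peaks_by_mark_2: Mapping[str, Sequence],
    chrom_sizes: Mapping[str, int],
    window_bp: int = 1_000_000,
    bin_bp: int = 1000,
    **run_kwargs,
) -> pd.DataFrame:
    """Genome-wide windowed mark-conservation track.

    The genome is divided into non-overlapping windows of ``window_bp``;
    within each window, fixed ``bin_bp`` bins play the role of genes: a
    bins × marks signal matrix is built per condition, normalized as
    usual, and the algorithm's mark scores for the window are emitted.
    Windows that fail preprocessing (e.g. all-zero signal) appear as NaN
    rows.  Returns a DataFrame indexed by (chrom, window_start).
    """
    if set(peaks_by_mark_1) != set(peaks_by_mark_2):
        raise ValueError("the two conditions must cover the same marks")
    marks = list(peaks_by_mark_1)
    by_chrom_1 = {m: {} for m in marks}
    by_chrom_2 = {m: {} for m in marks}
    for m in marks:
        for p in peaks_by_mark_1[m]:
            by_chrom_1[m].setdefault(p.chrom, []).append(p)
        for p in peaks_by_mark_2[m]:
            by_chrom_2[m].setdefault(p.chrom, []).append(p)

    rows = []
    index = []
    for chrom, size in chrom_sizes.items():
        for start in range(0, size - window_bp + 1, window_bp):
            end = start + window_bp
            cols1, cols2 = [], []
            for m in marks:
                cols1.append(_binned_signal(by_chrom_1[m].get(chrom, []), start, end, bin_bp))
                cols2.append(_binned_signal(by_chrom_2[m].get(chrom, []), start, end, bin_bp))
            bins = [f"{chrom}:{start + i * bin_bp}" for i in range(window_bp // bin_bp)]
            d1 = pd.DataFrame(np.column_stack(cols1), index=bins, columns=marks)
            d2 = pd.DataFrame(np.column_stack(cols2), index=bins, columns=marks)
            index.append((chrom, start))
            try:
                pair = normalize_pair(d1, d2)
                result = run_icgec(pair, **run_kwargs)
                rows.append(result.mark_scores.reindex(marks).values)
            except ValueError as exc:
                logger.warning("window %s:%d-%d skipped: %s", chrom, start, end, exc)
                rows.append(np.full(len(marks), np.nan))
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["chrom", "window_start"]), columns=marks
    )
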