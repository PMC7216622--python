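"""Score-consuming analyses: conservation classes, overlap tests, entropy
calls and mark-dynamics comparisons.

Gene scores from one pairwise comparison feed quartile-based dynamic
(EDG) / conserved (ECG) classes, equal-size score bins and a permutation
overlap test against differential-expression categories.  Scores from
several comparison directions (one per derived cell type) form a
ScoreTable from which Shannon entropy identifies
differentiation-direction-specific (DDSG) and -ubiquitous (DDUG) genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .circumstance import SignalMatrix

NEGATIVE_SCORE_RESET = 1e-6


@dataclass
class OverlapTestResult:
    """Observed overlap of one category with its gene-score class versus a
    size-preserving permutation null."""

    category: str
    observed_count: int
    observed_proportion: float
    permuted_counts: np.ndarray
    empirical_p: float
    seed: int


def _score_order(gene_scores: pd.Series) -> pd.Index:
    """Gene ids sorted by ascending score, ties broken by original order."""
    order = np.argsort(gene_scores.values, kind="stable")
    return gene_scores.index[order]


def classify_edg_ecg(gene_scores: pd.Series) -> tuple[list[str], list[str]]:
    """Quartile classes: EDG = lowest-score quarter, ECG = highest quarter.

    Both classes have ceil(G/4) members; ties are broken by the stable
    input order of the gene ids.
    """
    n = len(gene_scores)
    if n < 4:
        raise ValueError("need at least 4 genes for quartile classes")
    k = -(-n // 4)  # ceil
    ordered = _score_order(gene_scores)
    edg = list(ordered[:k])
    ecg = list(ordered[-k:])
    return edg, ecg


def bin_scores(
    gene_scores: pd.Series, n_bins: int = 20, query: set[str] | None = None
) -> tuple[list[list[str]], np.ndarray | None]:
    """Split genes into ``n_bins`` near-equal bins by ascending score.

    Returns the ordered bins (lists of gene ids) and, when a query gene
    set is given, the per-bin count of query members.
    """
    if n_bins < 1 or n_bins > len(gene_scores):
        raise ValueError("n_bins must be in [1, number of genes]")
    ordered = _score_order(gene_scores)
    bins = [list(chunk) for chunk in np.array_split(np.asarray(ordered, dtype=object), n_bins)]
    counts = None
    if query is not None:
        counts = np.array([sum(g in query for g in b) for b in bins])
    return bins, counts


def permutation_overlap_test(
    deg_categories: dict[str, set[str]],
    edg_sets: dict[str, set[str]],
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, OverlapTestResult]:
    """Permutation test of category/class overlap with sizes preserved.

    The pooled genes from all categories are randomly repartitioned into
    sets matching the observed category sizes; the overlap of each
    permuted set with its matching gene-score class forms the null.  The
    empirical p-value uses the add-one estimator
    (1 + #{permuted >= observed}) / (1 + n_perm), so it is never 0.
    """
    if set(deg_categories) != set(edg_sets):
        raise ValueError("category labels must match between the two mappings")
    labels = list(deg_categories)
    sets = [deg_categories[c] for c in labels]
    for i in range(len(sets)):
        if not sets[i]:
            raise ValueError(f"empty category {labels[i]!r}")
        for j in range(i + 1, len(sets)):
            if sets[i] & sets[j]:
                raise ValueError(f"categories {labels[i]!r} and {labels[j]!r} overlap")
    pool = np.array(sorted(set().union(*sets)), dtype=object)
    sizes = [len(s) for s in sets]
    rng = np.random.default_rng(seed)
    observed = {c: len(deg_categories[c] & edg_sets[c]) for c in labels}
    permuted = {c: np.zeros(n_perm, dtype=int) for c in labels}
    for t in range(n_perm):
        shuffled = rng.permutation(pool)
        offset = 0
        for c, size in zip(labels, sizes):
            chunk = set(shuffled[offset : offset + size])
            permuted[c][t] = len(chunk & edg_sets[c])
            offset += size
    results = {}
    for c in labels:
        obs = observed[c]
        p = (1 + int((permuted[c] >= obs).sum())) / (1 + n_perm)
        results[c] = OverlapTestResult(
            category=c,
            observed_count=obs,
            observed_proportion=obs / len(deg_categories[c]),
            permuted_counts=permuted[c],
            empirical_p=p,
            seed=seed,
        )
    return results


def _reset_negative(scores: np.ndarray) -> np.ndarray:
    """Replace negative scores with the small positive floor used before
    entropy and quantile computations."""
    return np.where(scores < 0, NEGATIVE_SCORE_RESET, scores)


def shannon_entropy(score_row: np.ndarray) -> float:
    """Entropy of a gene's per-direction score profile (natural log).

    Negative scores are reset to 1e-6 first; the (non-negative) scores are
    normalized to a probability vector.  Uniform profiles attain the
    maximum ln(k); a profile dominated by one direction approaches 0.
    """
    s = _reset_negative(np.asarray(score_row, dtype=float))
    total = s.sum()
    if total <= 0:
        raise ValueError("all scores zero; entropy undefined")
    p = s / total
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def score_table_entropy(table: pd.DataFrame) -> pd.Series:
    """Per-gene entropy over the direction columns of a score table."""
    if table.shape[1] < 2:
        raise ValueError("entropy analysis needs >=2 directions")
    return pd.Series(
        [shannon_entropy(row) for row in table.values], index=table.index, name="entropy"
    )


def identify_ddsg(
    table: pd.DataFrame,
    entropy_quantile: float = 0.20,
    fold: float = 2.5,
    score_quantile: float = 0.05,
) -> dict[str, list[str]]:
    """Differentiation-direction-specific genes, one set per direction.

    A gene is direction-specific for direction d iff (a) its entropy over
    the (negative-reset) per-direction scores lies in the bottom
    ``entropy_quantile`` of all genes, (b) its score in d is at least
    ``fold`` times lower than in every other direction, and (c) its score
    in d does not exceed the ``score_quantile`` quantile of the pooled
    score distribution (all genes × all directions, after the reset).
    """
    if table.shape[1] < 2:
        raise ValueError("need >=2 directions")
    reset = _reset_negative(table.values.astype(float))
    ent = score_table_entropy(table).values
    ent_cut = np.quantile(ent, entropy_quantile)
    pooled_cut = np.quantile(reset, score_quantile)
    out: dict[str, list[str]] = {d: [] for d in table.columns}
    low_entropy = ent <= ent_cut
    for i, gene in enumerate(table.index):
        if not low_entropy[i]:
            continue
        row = reset[i]
        for j, d in enumerate(table.columns):
            others = np.delete(row, j)
            if row[j] * fold <= others.min() and row[j] <= pooled_cut:
                out[d].append(gene)
                break  # fold > 1 forbids a second qualifying direction
    return out


def identify_ddug(
    table: pd.DataFrame,
    entropy_quantile: float = 0.20,
    score_quantile: float = 0.80,
) -> list[str]:
    """Differentiation-direction-ubiquitous genes.

    Genes in the top ``entropy_quantile`` of entropy whose minimum
    (negative-reset) score across directions exceeds the
    ``score_quantile`` quantile of the pooled score distribution.
    """
    if table.shape[1] < 2:
        raise ValueError("need >=2 directions")
    reset = _reset_negative(table.values.astype(float))
    ent = score_table_entropy(table).values
    ent_cut = np.quantile(ent, 1 - entropy_quantile)
    pooled_cut = np.quantile(reset, score_quantile)
    keep = (ent >= ent_cut) & (reset.min(axis=1) > pooled_cut)
    return list(table.index[keep])


def hypergeometric_enrichment(query: set[str], annotated: set[str], universe: set[str]) -> float:
    """Upper-tail hypergeometric probability of the observed overlap.

    P(X >= k) for k = |query ∩ annotated| drawn from a universe of size N
    containing |annotated| successes, with |query| draws.
    """
    if not query <= universe or not annotated <= universe:
        raise ValueError("query and annotated sets must be subsets of the universe")
    n_universe = len(universe)
    k = len(query & annotated)
    return float(stats.hypergeom.sf(k - 1, n_universe, len(annotated), len(query)))


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(q, 0, 1)
    return out


def _frames(m1, m2) -> tuple[pd.DataFrame, pd.DataFrame]:
    d1 = m1.data if isinstance(m1, SignalMatrix) else m1
    d2 = m2.data if isinstance(m2, SignalMatrix) else m2
    if not d1.index.equals(d2.index) or not d1.columns.equals(d2.columns):
        raise ValueError("matrices must share genes and marks in the same order")
    return d1, d2


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "pearson":
        r = stats.pearsonr(x, y).statistic
    elif method == "spearman":
        r = stats.spearmanr(x, y).statistic
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r)


def mark_dynamics_correlation(
    m1, m2, group_a: set[str], group_b: set[str], method: str = "pearson"
) -> pd.DataFrame:
    """Per-mark cross-condition correlation of modification levels, for two
    gene groups (typically DEGs vs non-DEGs).

    For each mark and group, correlates the group's condition-1 levels of
    the mark against its condition-2 levels.  Marks are returned sorted by
    (corr_a − corr_b) ascending, so the marks whose dynamics most
    distinguish group a sit first.
    """
    d1, d2 = _frames(m1, m2)
    rows = []
    for mark in d1.columns:
        ra = _corr(d1.loc[list(group_a), mark].values, d2.loc[list(group_a), mark].values, method)
        rb = _corr(d1.loc[list(group_b), mark].values, d2.loc[list(group_b), mark].values, method)
        rows.append((mark, ra, rb, ra - rb))
    out = pd.DataFrame(rows, columns=["mark", "corr_a", "corr_b", "difference"])
    return out.sort_values("difference", kind="stable").reset_index(drop=True)


def relative_change(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(a − b) / (a + b), defined as 0 where a + b = 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    total = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(total == 0, 0.0, (a - b) / np.where(total == 0, 1.0, total))
    return r


def expression_epigenetic_coupling(
    expr1: dict[str, float],
    expr2: dict[str, float],
    m1,
    m2,
    group: set[str],
    method: str = "pearson",
) -> pd.Series:
    """Correlation, per mark, between expression change and epigenetic change.

    Changes are relative: (a − b)/(a + b) across the two conditions, with
    the epigenetic change computed on the raw (pre-log) signal.  The
    correlation runs over the genes of ``group`` present in both the
    expression tables and the matrices.
    """
    d1, d2 = _frames(m1, m2)
    genes = [g for g in d1.index if g in group and g in expr1 and g in expr2]
    if len(genes) < 3:
        raise ValueError("need >=3 group genes with expression in both conditions")
    e1 = np.array([expr1[g] for g in genes])
    e2 = np.array([expr2[g] for g in genes])
    e_change = relative_change(e1, e2)
    out = {}
    for mark in d1.columns:
        m_change = relative_change(d1.loc[genes, mark].values, d2.loc[genes, mark].values)
        out[mark] = _corr(e_change, m_change, method)
    return pd.Series(out, name=f"{method}_coupling")


def two_fold_dynamic_genes(
    expr1: dict[str, float], expr2: dict[str, float], pseudocount: float = 0.01
) -> list[str]:
    """Genes with at least a two-fold expression change:
    |log2((e1+pc)/(e2+pc))| > 1."""
    shared = [g for g in expr1 if g in expr2]
    out = []
    for g in shared:
        fc = np.log2((expr1[g] + pseudocount) / (expr2[g] + pseudocount))
        if abs(fc) > 1:
            out.append(g)
    return out
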