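"""Synthetic paired epigenome data with known conservation structure.

Real multi-mark ChIP-seq matrices carry two kinds of structure the scoring
algorithm depends on: marks differ in their typical level, and genes fall
into co-regulated modules so that gene–gene context correlations are
non-trivial.  The generator plants both, then derives the second condition
from the first by perturbing a chosen fraction of "dynamic" genes on the
log scale, leaving the conserved genes untouched.  Everything is a pure
function of its parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .circumstance import RegionScheme, SignalMatrix, gene_region
from .io_formats import GeneModel, Peak, write_gene_models_bed, write_peaks

DEFAULT_N_MARKS = 16
DEFAULT_N_MODULES = 5
DEFAULT_FRAC_DYNAMIC = 0.2
DEFAULT_PERTURB_SD = 1.0


@dataclass
class SimulationTruth:
    """Ground truth planted by a generator run."""

    seed: int
    dynamic_genes: dict[str, float] = field(default_factory=dict)  # gene -> magnitude
    influential_marks: list[str] = field(default_factory=list)
    redundant_marks: list[str] = field(default_factory=list)
    coupled_marks: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def generate_paired_matrices(
    n_genes: int = 500,
    n_marks: int = DEFAULT_N_MARKS,
    frac_dynamic: float = DEFAULT_FRAC_DYNAMIC,
    perturb_sd: float = DEFAULT_PERTURB_SD,
    seed: int = 0,
    n_modules: int = DEFAULT_N_MODULES,
) -> tuple[SignalMatrix, SignalMatrix, SimulationTruth]:
    """Paired genes × marks matrices with planted dynamic genes.

    The base log2 signal of gene g under mark m is

        mark_mean_m + loading(module(g), m) + noise,

    with genes assigned round-robin to ``n_modules`` co-regulation modules
    whose mark loadings give rise to realistic gene–gene correlation
    structure.  Condition 2 perturbs each dynamic gene's row with additive
    Gaussian noise of sd ``perturb_sd × magnitude`` on the log scale
    (magnitude ~ U(0.5, 1.5) per gene); conserved genes are copied
    unchanged.  Signals are 2**log2-signal, hence strictly positive.
    """
    if not 0 <= frac_dynamic <= 1:
        raise ValueError("frac_dynamic must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    marks = [f"mark{j:02d}" for j in range(n_marks)]

    mark_mean = rng.normal(2.0, 1.0, size=n_marks)
    module_of = np.arange(n_genes) % n_modules
    loadings = rng.normal(0.0, 1.5, size=(n_modules, n_marks))
    log_base = mark_mean + loadings[module_of] + rng.normal(0.0, 0.5, size=(n_genes, n_marks))

    n_dynamic = int(round(frac_dynamic * n_genes))
    dynamic_idx = rng.choice(n_genes, size=n_dynamic, replace=False)
    magnitudes = rng.uniform(0.5, 1.5, size=n_dynamic)
    log_2 = log_base.copy()
    for idx, mag in zip(dynamic_idx, magnitudes):
        log_2[idx] += rng.normal(0.0, perturb_sd * mag, size=n_marks)

    d1 = pd.DataFrame(np.exp2(log_base), index=genes, columns=marks)
    d2 = pd.DataFrame(np.exp2(log_2), index=genes, columns=marks)
    truth = SimulationTruth(
        seed=seed,
        dynamic_genes={genes[i]: float(m) for i, m in zip(dynamic_idx, magnitudes)},
    )
    return (
        SignalMatrix(d1, condition="C1"),
        SignalMatrix(d2, condition="C2"),
        truth,
    )


def inject_noise(matrix: SignalMatrix, s: float, seed: int = 0) -> SignalMatrix:
    """Multiplicative uniform noise: each entry e → e + u·s·e, u ~ U(−1, 1).

    ``s`` in [0, 1] is the noise strength; since |u·s| ≤ 1 the output
    stays non-negative, and E[e'] = e.
    """
    if not 0 <= s <= 1:
        raise ValueError("noise strength s must be in [0, 1]")
    rng = np.random.default_rng(seed)
    u = rng.uniform(-1.0, 1.0, size=matrix.data.shape)
    noisy = matrix.data.values * (1.0 + u * s)
    return SignalMatrix(
        pd.DataFrame(noisy, index=matrix.data.index, columns=matrix.data.columns),
        condition=matrix.condition,
        scheme=matrix.scheme,
    )


def permute_gene_rows(matrix: SignalMatrix, seed: int = 0) -> tuple[SignalMatrix, np.ndarray]:
    """Shuffle row values while keeping the gene labels in place, breaking
    the row correspondence between a matrix pair.  Returns the permutation."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(matrix.data.shape[0])
    out = pd.DataFrame(
        matrix.data.values[perm], index=matrix.data.index, columns=matrix.data.columns
    )
    return SignalMatrix(out, condition=matrix.condition, scheme=matrix.scheme), perm


def permute_mark_columns(matrix: SignalMatrix, seed: int = 0) -> tuple[SignalMatrix, np.ndarray]:
    """Shuffle column values while keeping mark labels in place."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(matrix.data.shape[1])
    out = pd.DataFrame(
        matrix.data.values[:, perm], index=matrix.data.index, columns=matrix.data.columns
    )
    return SignalMatrix(out, condition=matrix.condition, scheme=matrix.scheme), perm


def subsample_genes(
    m1: SignalMatrix, m2: SignalMatrix, fraction: float = 0.25, seed: int = 0
) -> tuple[SignalMatrix, SignalMatrix, np.ndarray]:
    """The same random gene subset applied to both matrices.

    Subset size is round(fraction · G); the original gene order is kept.
    """
    if not m1.data.index.equals(m2.data.index):
        raise ValueError("matrices must share gene order")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = m1.data.shape[0]
    k = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    s1 = SignalMatrix(m1.data.iloc[idx].copy(), condition=m1.condition, scheme=m1.scheme)
    s2 = SignalMatrix(m2.data.iloc[idx].copy(), condition=m2.condition, scheme=m2.scheme)
    return s1, s2, idx


def stratified_subsamples(
    m1: SignalMatrix, m2: SignalMatrix, k: int = 4, seed: int = 0
) -> list[tuple[SignalMatrix, SignalMatrix, np.ndarray]]:
    """Partition the genes into ``k`` disjoint random subsets covering all
    genes; returns one reduced pair per subset."""
    if not m1.data.index.equals(m2.data.index):
        raise ValueError("matrices must share gene order")
    n = m1.data.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    out = []
    for part in np.array_split(perm, k):
        idx = np.sort(part)
        out.append(
            (
                SignalMatrix(m1.data.iloc[idx].copy(), condition=m1.condition, scheme=m1.scheme),
                SignalMatrix(m2.data.iloc[idx].copy(), condition=m2.condition, scheme=m2.scheme),
                idx,
            )
        )
    return out


def generate_toy_genome(
    seed: int = 0,
    out_dir: str | Path | None = None,
    n_genes: int = 50,
    n_marks: int = 4,
    chrom: str = "chrT",
    chrom_size: int = 2_000_000,
    upstream_bp: int = 2000,
) -> dict:
    """A small genome whose peak files realize a prescribed signal matrix.

    Emits ~``n_genes`` genes on both strands of one chromosome, spaced far
    enough apart that no peak can reach a neighbouring gene's region, plus
    per-mark peak files for two conditions.  Each (gene, mark) target
    value T is realized by one peak of length L placed inside the gene's
    promoter+body region with signal S = T·L_g/L, so that the weighted
    peak-sum quantification reproduces T exactly (up to float rounding).

    Returns a dict with the gene models, per-condition peak sets, the two
    target :class:`SignalMatrix` objects and a :class:`SimulationTruth`;
    when ``out_dir`` is given, BED/BroadPeak/JSON files are written there.
    """
    rng = np.random.default_rng(seed)
    spacing = chrom_size // (n_genes + 1)
    if spacing < 3 * upstream_bp:
        raise ValueError("chromosome too small for the requested gene count")
    genes: list[GeneModel] = []
    for i in range(n_genes):
        anchor = spacing * (i + 1)
        length = int(rng.integers(3000, 12000))
        strand = "+" if i % 2 == 0 else "-"
        genes.append(GeneModel(f"g{i:03d}", chrom, anchor, anchor + length, strand))

    marks = [f"mark{j}" for j in range(n_marks)]
    d1 = pd.DataFrame(
        np.exp2(rng.normal(2.0, 1.0, size=(n_genes, n_marks))),
        index=[g.gene_id for g in genes],
        columns=marks,
    )
    # condition 2: perturb a fifth of the genes
    n_dyn = max(1, n_genes // 5)
    dyn_idx = rng.choice(n_genes, size=n_dyn, replace=False)
    vals2 = d1.values.copy()
    vals2[dyn_idx] *= np.exp2(rng.normal(0.0, 1.0, size=(n_dyn, n_marks)))
    d2 = pd.DataFrame(vals2, index=d1.index, columns=marks)

    scheme = RegionScheme("promoter_body", upstream_bp)
    peaks_1: dict[str, list[Peak]] = {m: [] for m in marks}
    peaks_2: dict[str, list[Peak]] = {m: [] for m in marks}
    for gi, g in enumerate(genes):
        (rs, re), = gene_region(g, scheme)
        lg = re - rs
        peak_len = min(1000, lg)
        start = rs + (lg - peak_len) // 2
        for j, m in enumerate(marks):
            for target, store in ((d1.iloc[gi, j], peaks_1), (d2.iloc[gi, j], peaks_2)):
                signal = target * lg / peak_len
                store[m].append(Peak(chrom, start, start + peak_len, signal, name=f"{g.gene_id}_{m}"))

    truth = SimulationTruth(
        seed=seed, dynamic_genes={d1.index[i]: 1.0 for i in sorted(dyn_idx)}
    )
    result = {
        "genes": genes,
        "peaks_1": peaks_1,
        "peaks_2": peaks_2,
        "target_1": SignalMatrix(d1, condition="C1", scheme=scheme),
        "target_2": SignalMatrix(d2, condition="C2", scheme=scheme),
        "truth": truth,
        "chrom_sizes": {chrom: chrom_size},
        "scheme": scheme,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_gene_models_bed(genes, out_dir / "genes.bed")
        for m in marks:
            write_peaks(peaks_1[m], out_dir / f"c1_{m}.broadPeak")
            write_peaks(peaks_2[m], out_dir / f"c2_{m}.broadPeak")
        truth.to_json(out_dir / "truth.json")
    return result
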