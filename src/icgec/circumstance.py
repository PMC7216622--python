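"""Build the genes × marks epigenetic circumstance matrix from peak files.

The signal level of a histone mark on a gene is the weighted sum of peak
signal values over all peaks intersecting a gene-anchored region,

    sum_p (L_p * S_p) / L_g

where ``S_p`` is the peak's signalValue, ``L_p`` the length of the overlap
between the peak and the region, and ``L_g`` the region length.  Four
region schemes are supported: the default spans 2 kb upstream of the TSS
through the TTS; alternatives use the promoter alone, the gene body alone,
or promoter and body as separate columns (doubling the mark columns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, Peak

SCHEME_TAGS = ("promoter_body", "promoter_only", "body_only", "promoter_and_body_separate")


@dataclass(frozen=True)
class RegionScheme:
    """Which gene-anchored region(s) to quantify signal over.

    ``upstream_bp`` is the promoter extent upstream of the TSS (default
    2000 bp, the value used throughout the analyses here).
    """

    tag: str = "promoter_body"
    upstream_bp: int = 2000

    def __post_init__(self) -> None:
        if self.tag not in SCHEME_TAGS:
            raise ValueError(f"unknown region scheme {self.tag!r}; choose from {SCHEME_TAGS}")
        if self.upstream_bp <= 0:
            raise ValueError("upstream_bp must be positive")


@dataclass
class SignalMatrix:
    """Genes × marks signal matrix for one condition (the G2M matrix).

    ``data`` is a pandas DataFrame with unique gene ids as the index and
    unique mark names as columns; all values are >= 0.  Under the
    promoter_and_body_separate scheme the columns are ``mark@promoter`` and
    ``mark@body`` for every mark.
    """

    data: pd.DataFrame
    condition: str = ""
    scheme: RegionScheme | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene ids in SignalMatrix")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate mark names in SignalMatrix")
        if (self.data.values < 0).any():
            raise ValueError("SignalMatrix values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def mark_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.values


def gene_region(gene: GeneModel, scheme: RegionScheme) -> list[tuple[int, int]]:
    """Half-open genomic interval(s) for a gene under a region scheme.

    The promoter sits upstream of the TSS in transcription orientation:
    left of ``start`` on the + strand, right of ``end`` on the − strand.
    Intervals are clipped at coordinate 0; a region clipped to zero length
    is dropped.
    """
    up = scheme.upstream_bp
    if gene.strand == "+":
        promoter = (gene.start - up, gene.start)
        body = (gene.start, gene.end)
        combined = (gene.start - up, gene.end)
    else:
        promoter = (gene.end, gene.end + up)
        body = (gene.start, gene.end)
        combined = (gene.start, gene.end + up)
    if scheme.tag == "promoter_body":
        raw = [combined]
    elif scheme.tag == "promoter_only":
        raw = [promoter]
    elif scheme.tag == "body_only":
        raw = [body]
    else:  # promoter_and_body_separate
        raw = [promoter, body]
    regions = []
    for s, e in raw:
        s = max(s, 0)
        if s < e:
            regions.append((s, e))
    return regions


def gene_signal(
    region: tuple[int, int],
    peaks: Sequence[Peak] | None = None,
    *,
    starts: np.ndarray | None = None,
    ends: np.ndarray | None = None,
    signals: np.ndarray | None = None,
    clip_overlap: bool = True,
) -> float:
    """Weighted peak-signal sum over one region: sum_p L_p*S_p / L_g.

    ``L_p`` is the intersection length between peak and region (the
    default); with ``clip_overlap=False`` the full peak length is used for
    any peak that intersects the region.  Peaks must already be restricted
    to the region's chromosome.  Overlapping peaks are summed independently
    (no merging).
    """
    rs, re = region
    if re <= rs:
        raise ValueError(f"zero-length region [{rs}, {re})")
    if peaks is not None:
        starts = np.fromiter((p.start for p in peaks), dtype=float, count=len(peaks))
        ends = np.fromiter((p.end for p in peaks), dtype=float, count=len(peaks))
        signals = np.fromiter((p.signal for p in peaks), dtype=float, count=len(peaks))
    if starts is None or len(starts) == 0:
        return 0.0
    overlap = np.minimum(ends, re) - np.maximum(starts, rs)
    hit = overlap > 0
    if not hit.any():
        return 0.0
    lp = overlap[hit] if clip_overlap else (ends - starts)[hit]
    return float(np.dot(lp, signals[hit]) / (re - rs))


def _peak_arrays(peaks: Sequence[Peak]) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Group peaks by chromosome into coordinate/signal arrays."""
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    out = {}
    for chrom, plist in by_chrom.items():
        out[chrom] = (
            np.array([p.start for p in plist], dtype=float),
            np.array([p.end for p in plist], dtype=float),
            np.array([p.signal for p in plist], dtype=float),
        )
    return out


def build_matrix(
    genes: Sequence[GeneModel],
    peaks_by_mark: Mapping[str, Sequence[Peak]],
    scheme: RegionScheme | None = None,
    condition_label: str = "",
    *,
    clip_overlap: bool = True,
) -> SignalMatrix:
    """Assemble the G2M circumstance matrix for one condition.

    Entry (g, m) is the weighted peak-signal sum of mark m over gene g's
    region(s).  Genes whose region set is empty after clipping are dropped
    with a warning; marks with no peaks give all-zero columns with a
    warning.
    """
    if len(genes) == 0:
        raise ValueError("need at least one gene")
    if len(peaks_by_mark) < 2:
        raise ValueError("need at least two marks")
    scheme = scheme or RegionScheme()
    separate = scheme.tag == "promoter_and_body_separate"

    kept: list[GeneModel] = []
    regions: list[list[tuple[int, int]]] = []
    for g in genes:
        r = gene_region(g, scheme)
        if not r or (separate and len(r) < 2):
            warnings.warn(f"gene {g.gene_id}: region empty after clipping; dropped", stacklevel=2)
            continue
        kept.append(g)
        regions.append(r)
    if not kept:
        raise ValueError("all genes dropped: every region empty after clipping")

    mark_names = list(peaks_by_mark)
    columns = (
        [f"{m}@promoter" for m in mark_names] + [f"{m}@body" for m in mark_names]
        if separate
        else mark_names
    )
    values = np.zeros((len(kept), len(columns)))
    for j, mark in enumerate(mark_names):
        plist = peaks_by_mark[mark]
        if len(plist) == 0:
            warnings.warn(f"mark {mark!r} has no peaks; column will be all zeros", stacklevel=2)
            continue
        arrays = _peak_arrays(plist)
        for i, (g, regs) in enumerate(zip(kept, regions)):
            if g.chrom not in arrays:
                continue
            starts, ends, signals = arrays[g.chrom]
            if separate:
                values[i, j] = gene_signal(
                    regs[0], starts=starts, ends=ends, signals=signals, clip_overlap=clip_overlap
                )
                values[i, j + len(mark_names)] = gene_signal(
                    regs[1], starts=starts, ends=ends, signals=signals, clip_overlap=clip_overlap
                )
            else:
                values[i, j] = gene_signal(
                    regs[0], starts=starts, ends=ends, signals=signals, clip_overlap=clip_overlap
                )
    df = pd.DataFrame(values, index=[g.gene_id for g in kept], columns=columns)
    return SignalMatrix(df, condition=condition_label, scheme=scheme)
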