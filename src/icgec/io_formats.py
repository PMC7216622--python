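"""Readers and writers for the plain-text formats the tool touches.

Peak files are ENCODE BroadPeak (BED6+3) / NarrowPeak (BED6+4); gene models
come from BED12 or minimal GTF; expression tables, gene lists and labelled
TSV matrices round out the plumbing.  All genomic coordinates are handled
internally as 0-based half-open intervals (BED native); GTF input is
converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass(frozen=True)
class Peak:
    """One ChIP-seq peak: a 0-based half-open interval with a signal value.

    ``signal`` is column 7 (signalValue) of BroadPeak/NarrowPeak — the
    average enrichment over the peak, the only statistic the scoring
    formula consumes.
    """

    chrom: str
    start: int
    end: int
    signal: float
    name: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("peak chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(f"peak start must be < end, got [{self.start}, {self.end})")
        if self.signal < 0:
            raise ValueError(f"peak signal must be >= 0, got {self.signal}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene locus; promoter/body regions are derived from it.

    ``tss``/``tts`` are strand-aware: on the + strand the TSS is ``start``
    and the TTS is ``end``; on the − strand the roles swap.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start >= self.end:
            raise ValueError(f"gene start must be < end, got [{self.start}, {self.end})")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start


_PEAK_MIN_COLS = {"broadpeak": 9, "narrowpeak": 10}


def read_peaks(path: str | Path, dialect: str = "broadpeak") -> list[Peak]:
    """Read a BroadPeak/NarrowPeak file into a list of :class:`Peak`.

    Columns 8-9 (pValue, qValue) and the NarrowPeak point-source column are
    parsed for shape validation but ignored: the method uses only
    signalValue.  Lines are not assumed sorted.
    """
    dialect = dialect.lower()
    if dialect not in _PEAK_MIN_COLS:
        raise ValueError(f"unknown peak dialect {dialect!r}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise FormatError(
                    f"{path}:{lineno}: expected >=7 tab-separated columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                signal = float(fields[6])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed line ({exc})") from None
            if signal < 0:
                raise FormatError(f"{path}:{lineno}: negative signalValue {signal}")
            try:
                peaks.append(Peak(chrom, start, end, signal, name=fields[3]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as BroadPeak (score 0, strand '.', p/q-value -1)."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t.\t{p.signal:.17g}\t-1\t-1\n")


def read_gene_models(path: str | Path, format: str = "bed12") -> list[GeneModel]:
    """Read gene models from BED12 (or any BED6+) or minimal GTF.

    GTF parsing is deliberately minimal: only lines whose feature column is
    ``gene`` (or ``transcript`` when no gene lines exist is NOT supported —
    annotations must carry gene lines) are used, and a ``gene_id`` attribute
    is required.  GTF 1-based inclusive coordinates are converted to 0-based
    half-open.
    """
    format = format.lower()
    if format not in ("bed12", "bed", "gtf"):
        raise ValueError(f"unknown gene model format {format!r}")
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if format in ("bed12", "bed"):
                if len(fields) < 6:
                    raise FormatError(f"{path}:{lineno}: BED gene models need >=6 columns")
                gene_id = fields[3]
                try:
                    gene = GeneModel(gene_id, fields[0], int(fields[1]), int(fields[2]), fields[5])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from None
            else:
                if len(fields) < 9:
                    raise FormatError(f"{path}:{lineno}: GTF needs 9 columns")
                if fields[2] != "gene":
                    continue
                attrs = _parse_gtf_attributes(fields[8])
                if "gene_id" not in attrs:
                    raise FormatError(f"{path}:{lineno}: gene line lacks gene_id attribute")
                try:
                    gene = GeneModel(
                        attrs["gene_id"], fields[0], int(fields[3]) - 1, int(fields[4]), fields[6]
                    )
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from None
            if gene.gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene_id {gene.gene_id!r}")
            seen.add(gene.gene_id)
            genes.append(gene)
    return genes


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.rstrip(";").split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def write_gene_models_bed(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as BED6."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; duplicates de-duplicated with a warning,
    original first-occurrence order preserved."""
    ids: list[str] = []
    seen: set[str] = set()
    dupes = 0
    with open(path) as fh:
        for line in fh:
            gid = line.strip()
            if not gid or gid.startswith("#"):
                continue
            if gid in seen:
                dupes += 1
                continue
            seen.add(gid)
            ids.append(gid)
    if dupes:
        warnings.warn(f"{path}: {dupes} duplicate gene ids dropped", stacklevel=2)
    return ids


def read_expression_table(path: str | Path) -> dict[str, float]:
    """Two-column TSV gene_id → RPKM (non-negative)."""
    table: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected gene_id<TAB>RPKM")
            gid = fields[0]
            try:
                rpkm = float(fields[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric RPKM {fields[1]!r}") from None
            if rpkm < 0:
                raise FormatError(f"{path}:{lineno}: negative RPKM {rpkm}")
            if gid in table:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {gid!r}")
            table[gid] = rpkm
    return table


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Labelled numeric matrix: header row = column names, first column = row ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from None
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate row or column labels")
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Write a labelled matrix; floats carry >=12 significant digits so that
    write∘read is the identity up to float round-trip."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", float_format="%.17g")
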