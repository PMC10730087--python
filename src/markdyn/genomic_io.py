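"""Core genomic containers and text-format readers/writers.

All coordinates are 0-based half-open (BED convention). GTF input, which is
1-based inclusive, is shifted on read. Coverage is modelled as a stepwise
per-chromosome signal; positions not covered by any span read as 0, which
keeps RPM scaling and binned means well defined everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "CoverageTrack",
    "ContrastStat",
    "AbundanceRecord",
    "read_intervals",
    "write_intervals",
    "read_coverage",
    "write_coverage",
    "read_gene_models",
    "write_gene_models",
    "read_abundance",
    "write_abundance",
]

STRANDS = {"+", "-", "."}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open span on a chromosome.

    ``score`` carries the BED score / eigenvector value when present;
    ``meta`` holds extra columns (e.g. broadPeak signalValue/p/q).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    name: str | None = None
    meta: Mapping[str, float] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    """A gene or transcript with a strand-aware TSS/TES.

    For a plus-strand gene the TSS is ``start``; for a minus-strand gene it is
    ``end``. ``exons`` (optional, 0-based half-open, genomic order) feed
    exon/intron classification in peak annotation.
    """

    gene_id: str
    interval: GenomicInterval
    transcript_id: str | None = None
    exons: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.interval.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand is required")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length_bp(self) -> int:
        return self.interval.length


class CoverageTrack:
    """Stepwise per-chromosome signal with fast interval queries.

    Internally each chromosome stores sorted, non-overlapping spans
    ``(starts, ends, values)`` plus a cumulative integral, so the mean over
    any interval (and hence binned means) is an O(log n) prefix-sum lookup.
    """

    def __init__(self, spans: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        total = 0.0
        for chrom, (starts, ends, values) in spans.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if not (len(starts) == len(ends) == len(values)):
                raise ValueError("span arrays must have equal length")
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: empty span")
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise ValueError(
                    f"{chrom}: overlapping spans near {starts[i + 1]} (ambiguous signal)"
                )
            if not np.all(np.isfinite(values)):
                raise ValueError(f"{chrom}: non-finite coverage value")
            cum = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
            self._chroms[chrom] = (starts, ends, values, cum)
            total += float(cum[-1])
        self._total = total

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int, float]]
    ) -> "CoverageTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            by_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        spans = {}
        for chrom, recs in by_chrom.items():
            arr = np.array(recs, dtype=np.float64)
            spans[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
        return cls(spans)

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self._chroms)

    @property
    def total_signal(self) -> float:
        """Integral of the track: sum over spans of value * span length."""
        return self._total

    def iter_spans(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom in sorted(self._chroms):
            starts, ends, values, _ = self._chroms[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def scaled(self, factor: float) -> "CoverageTrack":
        spans = {
            chrom: (starts.copy(), ends.copy(), values * factor)
            for chrom, (starts, ends, values, _) in self._chroms.items()
        }
        return CoverageTrack(spans)

    def to_rpm(self) -> "CoverageTrack":
        """Scale so the track integral equals 1e6 (reads-per-million units)."""
        if self._total <= 0:
            raise ValueError("cannot RPM-normalize a track with zero total signal")
        return self.scaled(1e6 / self._total)

    def _integral(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        entry = self._chroms.get(chrom)
        if entry is None:
            return np.zeros_like(positions, dtype=np.float64)
        starts, ends, values, cum = entry
        pos = np.asarray(positions, dtype=np.float64)
        idx = np.searchsorted(starts, pos, side="right") - 1
        idx_c = np.clip(idx, 0, len(starts) - 1)
        inside = np.clip(pos - starts[idx_c], 0.0, (ends - starts)[idx_c])
        out = cum[idx_c] + values[idx_c] * inside
        return np.where(idx < 0, 0.0, out)

    def mean(self, chrom: str, start: int, end: int) -> float:
        if end <= start:
            raise ValueError("empty query interval")
        lo, hi = self._integral(chrom, np.array([start, end], dtype=float))
        return float(hi - lo) / (end - start)

    def binned_means(self, chrom: str, start: int, end: int, n_bins: int) -> np.ndarray:
        """Mean signal in ``n_bins`` equal-width bins over [start, end).

        Bins falling before position 0 or outside recorded spans read as 0.
        """
        if n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if end <= start:
            raise ValueError("empty query interval")
        edges = np.linspace(start, end, n_bins + 1)
        integ = self._integral(chrom, edges)
        width = (end - start) / n_bins
        return np.diff(integ) / width


def merge_tracks(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Concatenate disjoint tracks (e.g. per-gene tracks) into one."""
    records: list[tuple[str, int, int, float]] = []
    for t in tracks:
        records.extend(t.iter_spans())
    return CoverageTrack.from_records(records)


@dataclass(frozen=True)
class ContrastStat:
    q_value: float
    log2_fold_change: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_value <= 1.0):
            raise ValueError(f"q_value {self.q_value} outside [0, 1]")


@dataclass(frozen=True)
class AbundanceRecord:
    """One transcript's abundance plus per-contrast differential statistics."""

    transcript_id: str
    gene_id: str
    tpm: float
    contrasts: Mapping[str, ContrastStat]

    def __post_init__(self) -> None:
        if self.tpm < 0:
            raise ValueError(f"{self.transcript_id}: negative TPM")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _data_lines(path: Path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _parse_coord(text: str, path: Path, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: non-integer coordinate {text!r}"
        ) from None


def read_intervals(path: str | Path, format: str = "bed") -> list[GenomicInterval]:
    """Read BED3/BED5/BED6 or ENCODE broadPeak into sorted intervals."""
    path = Path(path)
    fmt = format.lower()
    if fmt not in {"bed", "broadpeak"}:
        raise ValueError(f"unknown interval format {format!r}")
    out: list[GenomicInterval] = []
    for lineno, cols in _data_lines(path):
        if len(cols) < 3:
            raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
        chrom = cols[0]
        start = _parse_coord(cols[1], path, lineno)
        end = _parse_coord(cols[2], path, lineno)
        if start >= end:
            raise FormatError(
                f"{path}:{lineno}: start {start} >= end {end}"
            )
        name = cols[3] if len(cols) > 3 and cols[3] != "." else None
        score = None
        if len(cols) > 4 and cols[4] != ".":
            score = float(cols[4])
        strand = cols[5] if len(cols) > 5 and cols[5] in STRANDS else "."
        meta = None
        if fmt == "broadpeak":
            if len(cols) < 9:
                raise FormatError(f"{path}:{lineno}: broadPeak needs 9 columns")
            meta = {
                "signal_value": float(cols[6]),
                "p_value": float(cols[7]),
                "q_value": float(cols[8]),
            }
        out.append(
            GenomicInterval(chrom, start, end, strand=strand, score=score,
                            name=name, meta=meta)
        )
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def write_intervals(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else f"{iv.score:g}"
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_coverage(path: str | Path) -> CoverageTrack:
    """Read a 4-column bedGraph into a CoverageTrack."""
    path = Path(path)
    records = []
    for lineno, cols in _data_lines(path):
        if len(cols) < 4:
            raise FormatError(f"{path}:{lineno}: bedGraph needs 4 columns")
        start = _parse_coord(cols[1], path, lineno)
        end = _parse_coord(cols[2], path, lineno)
        records.append((cols[0], start, end, float(cols[3])))
    try:
        return CoverageTrack.from_records(records)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_coverage(path: str | Path, track: CoverageTrack) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.iter_spans():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.10g}\n")


def read_gene_models(path: str | Path, format: str = "bed12") -> list[GeneModel]:
    """Read gene/transcript models from BED12 or a minimal GTF.

    GTF records (1-based inclusive) are shifted to 0-based half-open; only
    ``gene`` and ``transcript`` features are consumed. Strand is mandatory
    and duplicate IDs are rejected.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "bed12":
        genes = list(_read_bed12(path))
    elif fmt in {"gtf", "gtf-minimal"}:
        genes = list(_read_gtf(path))
    else:
        raise ValueError(f"unknown gene-model format {format!r}")
    seen: set[str] = set()
    for g in genes:
        key = g.transcript_id or g.gene_id
        if key in seen:
            raise FormatError(f"{path}: duplicate id {key!r}")
        seen.add(key)
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def _read_bed12(path: Path) -> Iterator[GeneModel]:
    for lineno, cols in _data_lines(path):
        if len(cols) < 6:
            raise FormatError(f"{path}:{lineno}: BED12 needs >=6 columns")
        chrom = cols[0]
        start = _parse_coord(cols[1], path, lineno)
        end = _parse_coord(cols[2], path, lineno)
        name = cols[3]
        strand = cols[5]
        if strand not in {"+", "-"}:
            raise FormatError(f"{path}:{lineno}: missing strand")
        exons = None
        if len(cols) >= 12:
            n_blocks = int(cols[9])
            sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
            offs = [int(x) for x in cols[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offs) != n_blocks:
                raise FormatError(f"{path}:{lineno}: block count mismatch")
            exons = tuple((start + o, start + o + s) for o, s in zip(offs, sizes))
        interval = GenomicInterval(chrom, start, end, strand=strand)
        yield GeneModel(gene_id=name, interval=interval, exons=exons)


def _parse_gtf_attrs(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


def _read_gtf(path: Path) -> Iterator[GeneModel]:
    for lineno, cols in _data_lines(path):
        if len(cols) < 9:
            raise FormatError(f"{path}:{lineno}: GTF needs 9 columns")
        feature = cols[2]
        if feature not in {"gene", "transcript"}:
            continue
        strand = cols[6]
        if strand not in {"+", "-"}:
            raise FormatError(f"{path}:{lineno}: missing strand")
        start = _parse_coord(cols[3], path, lineno) - 1  # 1-based inclusive -> 0-based
        end = _parse_coord(cols[4], path, lineno)
        attrs = _parse_gtf_attrs(cols[8])
        if "gene_id" not in attrs:
            raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
        interval = GenomicInterval(cols[0], start, end, strand=strand)
        yield GeneModel(
            gene_id=attrs["gene_id"],
            interval=interval,
            transcript_id=attrs.get("transcript_id"),
        )


def write_gene_models(path: str | Path, genes: Iterable[GeneModel]) -> None:
    """Write genes as BED12 (single block when exons are absent)."""
    with open(path, "w") as fh:
        for g in genes:
            exons = g.exons or ((g.start, g.end),)
            sizes = ",".join(str(e - s) for s, e in exons)
            offs = ",".join(str(s - g.start) for s, _ in exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(exons)}\t{sizes}\t{offs}\n"
            )


def read_abundance(
    path: str | Path, contrast_names: Sequence[str]
) -> list[AbundanceRecord]:
    """Read a transcript abundance + differential TSV.

    Expected header: ``transcript_id``, ``gene_id``, ``tpm`` and, per contrast
    ``c``, ``q_value_<c>`` and ``log2fc_<c>``.
    """
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = ["transcript_id", "gene_id", "tpm"]
    for c in contrast_names:
        required += [f"q_value_{c}", f"log2fc_{c}"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing columns {missing}; expected header {required}"
        )
    records = []
    for row in df.itertuples(index=False):
        contrasts = {}
        for c in contrast_names:
            q = float(getattr(row, f"q_value_{c}"))
            if not (0.0 <= q <= 1.0) or math.isnan(q):
                raise FormatError(
                    f"{path}: transcript {row.transcript_id}: q_value {q} outside [0, 1]"
                )
            contrasts[c] = ContrastStat(q, float(getattr(row, f"log2fc_{c}")))
        records.append(
            AbundanceRecord(
                transcript_id=str(row.transcript_id),
                gene_id=str(row.gene_id),
                tpm=float(row.tpm),
                contrasts=contrasts,
            )
        )
    return records


def write_abundance(
    path: str | Path, records: Iterable[AbundanceRecord], contrast_names: Sequence[str]
) -> None:
    header = ["transcript_id", "gene_id", "tpm"]
    for c in contrast_names:
        header += [f"q_value_{c}", f"log2fc_{c}"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in records:
            row = [r.transcript_id, r.gene_id, f"{r.tpm:.10g}"]
            for c in contrast_names:
                cs = r.contrasts[c]
                row += [f"{cs.q_value:.10g}", f"{cs.log2_fold_change:.10g}"]
            fh.write("\t".join(row) + "\n")
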