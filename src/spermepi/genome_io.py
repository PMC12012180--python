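"""Coordinate model and I/O for the interval and track formats the pipeline consumes.

All coordinates are 0-based, half-open (BED convention); any 1-based dialect
must be converted at the parser boundary.  Uncovered track bases read as
signal 0 (the ``mean0`` averaging convention).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STAGE_ORDER",
    "StageSeries",
    "GenomeAssembly",
    "Interval",
    "Peak",
    "SignalTrack",
    "ParseError",
    "parse_intervals",
    "write_intervals",
    "parse_bedgraph",
    "read_tss_table",
    "promoter_windows",
    "mean_signal",
    "spikein_normalize",
]

#: Canonical developmental axis shared by every trajectory and timing
#: computation: mitotic spermatogonia (Undiff, A1, B), meiotic spermatocytes
#: (pL..D), round spermatids (RS2/RS4/RS8), elongating spermatids (LS) and
#: mature sperm.
STAGE_ORDER: tuple[str, ...] = (
    "Undiff", "A1", "B", "pL", "L", "Z", "mP", "D",
    "RS2", "RS4", "RS8", "LS", "Sperm",
)


class ParseError(ValueError):
    """Raised when a text record violates its format contract."""


class StageSeries:
    """An ordered subset of the canonical stage axis.

    Order is inherited from :data:`STAGE_ORDER`; adjacency means consecutive
    positions within this series (not within the full axis).
    """

    def __init__(self, stages: Sequence[str] | None = None):
        stages = list(stages) if stages is not None else list(STAGE_ORDER)
        unknown = [s for s in stages if s not in STAGE_ORDER]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}; expected from {STAGE_ORDER}")
        idx = [STAGE_ORDER.index(s) for s in stages]
        if sorted(idx) != idx or len(set(idx)) != len(idx):
            raise ValueError("stages must be unique and in canonical order")
        self.stages = tuple(stages)

    def __iter__(self) -> Iterator[str]:
        return iter(self.stages)

    def __len__(self) -> int:
        return len(self.stages)

    def __contains__(self, stage: str) -> bool:
        return stage in self.stages

    def index(self, stage: str) -> int:
        return self.stages.index(stage)

    def pairs(self) -> list[tuple[str, str]]:
        """Consecutive stage pairs along the series."""
        return list(zip(self.stages[:-1], self.stages[1:]))

    def __repr__(self) -> str:
        return f"StageSeries({list(self.stages)})"


class GenomeAssembly:
    """Ordered chromosome names with strictly positive sizes."""

    def __init__(self, sizes: Mapping[str, int]):
        names = list(sizes)
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, size in sizes.items():
            if int(size) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive size {size}")
        self.sizes: dict[str, int] = {n: int(sizes[n]) for n in names}

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sizes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def __getitem__(self, chrom: str) -> int:
        return self.sizes[chrom]

    @classmethod
    def from_tsv(cls, source) -> "GenomeAssembly":
        df = pd.read_csv(source, sep="\t", header=None, names=["chrom", "size"])
        return cls(dict(zip(df["chrom"].astype(str), df["size"].astype(int))))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for name, size in self.sizes.items():
                fh.write(f"{name}\t{size}\n")


@dataclass(frozen=True)
class Interval:
    """A genomic span, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Peak:
    """An interval with a mean normalized read density and a source id."""

    interval: Interval
    signal: float = 0.0
    source_id: str = ""

    def __post_init__(self):
        if self.signal < 0:
            raise ValueError(f"peak signal must be >= 0, got {self.signal}")


def _sort_key(iv: Interval) -> tuple[str, int, int]:
    return (iv.chrom, iv.start, iv.end)


def parse_intervals(lines: Iterable[str] | str) -> list[Peak]:
    """Parse BED3/BED6/narrowPeak text into peaks.

    narrowPeak ``signalValue`` (column 7) is mapped to :attr:`Peak.signal`;
    for BED3/BED6 the signal is 0 (the BED5 score column is *not* a density
    and is ignored).  Comment, ``track`` and empty lines are skipped.

    Raises :class:`ParseError` naming the offending line number on malformed
    coordinates.
    """
    if isinstance(lines, str):
        lines = io.StringIO(lines)
    peaks: list[Peak] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"line {lineno}: fewer than 3 columns: {line!r}")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ParseError(f"line {lineno}: non-integer coordinates: {line!r}") from None
        if start >= end:
            raise ParseError(f"line {lineno}: start >= end ({start} >= {end})")
        name = fields[3] if len(fields) >= 4 and fields[3] != "." else f"peak_{lineno}"
        strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
        signal = 0.0
        if len(fields) >= 10:  # narrowPeak: col 7 = signalValue
            try:
                signal = float(fields[6])
            except ValueError:
                raise ParseError(f"line {lineno}: non-numeric signalValue: {fields[6]!r}") from None
        peaks.append(Peak(Interval(chrom, start, end, strand), signal=signal, source_id=name))
    return peaks


def write_intervals(peaks: Iterable[Peak], path) -> None:
    """Write peaks as BED6 in deterministic (chrom, start, end) order."""
    rows = sorted(peaks, key=lambda p: _sort_key(p.interval))
    with open(path, "w") as fh:
        for p in rows:
            iv = p.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.source_id}\t{p.signal:g}\t{iv.strand}\n")


class SignalTrack:
    """A step-function coverage track (bedGraph semantics).

    Per chromosome the segments are stored as sorted, non-overlapping
    ``(starts, ends, values)`` arrays; bases not covered by any segment read
    as 0.
    """

    def __init__(self, segments: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in segments.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise ValueError(f"empty segment on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping segments on {chrom}")
            if not np.all(np.isfinite(values)):
                raise ValueError(f"non-finite value on {chrom}")
            self._chroms[chrom] = (starts, ends, values)

    @property
    def chroms(self) -> list[str]:
        return list(self._chroms)

    def segments(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._chroms.get(
            chrom,
            (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.float64)),
        )

    @classmethod
    def from_bedgraph(cls, lines: Iterable[str] | str) -> "SignalTrack":
        if isinstance(lines, str):
            lines = io.StringIO(lines)
        per: dict[str, list[tuple[int, int, float]]] = {}
        for lineno, raw in enumerate(lines, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"line {lineno}: bedGraph needs 4 columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError:
                raise ParseError(f"line {lineno}: malformed bedGraph record") from None
            if start >= end:
                raise ParseError(f"line {lineno}: start >= end")
            per.setdefault(fields[0], []).append((start, end, value))
        segs = {}
        for chrom, rows in per.items():
            rows.sort()
            segs[chrom] = (
                np.array([r[0] for r in rows]),
                np.array([r[1] for r in rows]),
                np.array([r[2] for r in rows]),
            )
        return cls(segs)

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._chroms):
                starts, ends, values = self._chroms[chrom]
                for s, e, v in zip(starts, ends, values):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")

    def scale(self, factor: float) -> "SignalTrack":
        return SignalTrack(
            {c: (s.copy(), e.copy(), v * factor) for c, (s, e, v) in self._chroms.items()}
        )

    def mean0(self, interval: Interval) -> float:
        """Mean density per base over ``interval``; uncovered bases count 0."""
        starts, ends, values = self.segments(interval.chrom)
        if starts.size == 0:
            return 0.0
        lo = np.searchsorted(ends, interval.start, side="right")
        hi = np.searchsorted(starts, interval.end, side="left")
        if lo >= hi:
            return 0.0
        ov = (
            np.minimum(ends[lo:hi], interval.end)
            - np.maximum(starts[lo:hi], interval.start)
        ).clip(min=0)
        return float(np.dot(ov, values[lo:hi]) / interval.width)


def parse_bedgraph(lines) -> SignalTrack:
    return SignalTrack.from_bedgraph(lines)


def mean_signal(track: SignalTrack, interval: Interval) -> float:
    """Average read density over an interval, ``mean0`` convention."""
    return track.mean0(interval)


def spikein_normalize(
    tracks: Mapping[str, SignalTrack],
    spike_counts: Mapping[str, float],
    reference: float | None = None,
) -> tuple[dict[str, SignalTrack], dict[str, float]]:
    """Scale each sample's track by exogenous spike-in read counts.

    The sample with the fewest spike-in reads is left unchanged and every
    other sample is scaled down: ``factor_i = min_j(count_j) / count_i``.
    Pass ``reference`` to normalize against a fixed count instead.
    """
    if set(tracks) != set(spike_counts):
        raise ValueError("tracks and spike_counts must share sample names")
    for name, c in spike_counts.items():
        if c <= 0:
            raise ValueError(f"spike-in count for {name!r} must be positive, got {c}")
    ref = float(reference) if reference is not None else min(spike_counts.values())
    factors = {name: ref / c for name, c in spike_counts.items()}
    scaled = {name: tracks[name].scale(f) for name, f in factors.items()}
    return scaled, factors


def read_tss_table(source) -> pd.DataFrame:
    """Read a gene annotation TSV with columns gene_id, chrom, strand, tss, tes.

    A header line is optional; extra columns are preserved.
    """
    df = pd.read_csv(source, sep="\t", dtype={0: str})
    expected = {"gene_id", "chrom", "strand", "tss", "tes"}
    if not expected.issubset(df.columns):
        df = pd.read_csv(
            source if not hasattr(source, "seek") else _rewound(source),
            sep="\t", header=None,
            names=["gene_id", "chrom", "strand", "tss", "tes"],
        )
    df["tss"] = df["tss"].astype(int)
    df["tes"] = df["tes"].astype(int)
    df["gene_id"] = df["gene_id"].astype(str)
    return df


def _rewound(handle):
    handle.seek(0)
    return handle


def promoter_windows(
    tss_table: pd.DataFrame,
    flank: int = 2000,
    assembly: GenomeAssembly | None = None,
) -> list[Interval]:
    """Symmetric TSS +/- flank windows, clipped to chromosome bounds.

    The window is strand-independent by symmetry.  A TSS outside its
    chromosome raises :class:`ParseError`.
    """
    out: list[Interval] = []
    for row in tss_table.itertuples(index=False):
        tss = int(row.tss)
        size = assembly[row.chrom] if assembly is not None and row.chrom in assembly else None
        if size is not None and not (0 <= tss <= size):
            raise ParseError(f"gene {row.gene_id}: TSS {tss} outside {row.chrom} (size {size})")
        start = max(0, tss - flank)
        end = tss + flank
        if size is not None:
            end = min(end, size)
        if end > start:
            out.append(Interval(row.chrom, start, end))
    return out
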