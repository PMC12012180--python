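"""Peak consolidation and domain classification.

Implements the broad-domain definition used throughout the analysis: peaks
separated by no more than a 500-bp gap are consolidated, and merged runs
longer than 5 kb are *broad* domains; the rest are *regular*.  Also provides
the sharp/control split of regular peaks, element-wise overlap (Venn)
counting, and ROSE-style stitching with the tangent-slope-1 elbow cutoff for
super-domain identification.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome_io import Interval, Peak, SignalTrack, mean_signal, promoter_windows

__all__ = [
    "MergedDomain",
    "StitchedRegion",
    "SuperDomainResult",
    "merge_peaks",
    "classify_broad",
    "split_promoter_distal",
    "select_sharp_control",
    "overlap_counts",
    "super_domains",
]


@dataclass(frozen=True)
class MergedDomain:
    """A gap-consolidated run of peaks."""

    interval: Interval
    member_peaks: tuple[str, ...]
    mean_signal: float = 0.0
    width_class: str | None = None   # "broad" | "regular"
    location_class: str | None = None  # "promoter" | "distal"

    @property
    def width(self) -> int:
        return self.interval.width


@dataclass(frozen=True)
class StitchedRegion:
    """A stitched enhancer-like region with its rank on the signal curve."""

    interval: Interval
    total_signal: float
    rank: int
    is_super: bool


@dataclass(frozen=True)
class SuperDomainResult:
    regions: tuple[StitchedRegion, ...]
    cutoff: float

    @property
    def supers(self) -> list[StitchedRegion]:
        return [r for r in self.regions if r.is_super]


def merge_peaks(peaks: Iterable[Peak], max_gap: int = 500) -> list[MergedDomain]:
    """Consolidate peaks whose gap is at most ``max_gap`` bp.

    The gap between half-open [a,b) and [c,d) with c >= b is ``c - b``;
    overlapping or touching peaks always merge.  The result is the
    transitive closure of the gap relation per chromosome, sorted by
    (chrom, start), pairwise gaps strictly greater than ``max_gap``.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    ordered = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    out: list[MergedDomain] = []
    run: list[Peak] = []

    def flush():
        if not run:
            return
        iv = Interval(
            run[0].interval.chrom,
            run[0].interval.start,
            max(p.interval.end for p in run),
        )
        out.append(MergedDomain(iv, tuple(p.source_id for p in run)))

    cur_end = None
    for p in ordered:
        if run and p.interval.chrom == run[-1].interval.chrom and p.interval.start - cur_end <= max_gap:
            run.append(p)
            cur_end = max(cur_end, p.interval.end)
        else:
            flush()
            run = [p]
            cur_end = p.interval.end
    flush()
    return out


def classify_broad(domains: Iterable[MergedDomain], broad_min: int = 5000) -> list[MergedDomain]:
    """Label each merged domain broad (width strictly > ``broad_min``) or regular."""
    return [
        replace(d, width_class="broad" if d.width > broad_min else "regular")
        for d in domains
    ]


def _window_tree(tss_table: pd.DataFrame, flank: int) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for w in promoter_windows(tss_table, flank=flank):
        trees.setdefault(w.chrom, IntervalTree()).addi(w.start, w.end)
    return trees


def split_promoter_distal(
    domains: Iterable[MergedDomain],
    tss_table: pd.DataFrame,
    flank: int = 2000,
) -> list[MergedDomain]:
    """Label domains promoter (>= 1 bp overlap with any TSS +/- flank) or distal."""
    trees = _window_tree(tss_table, flank)
    out = []
    for d in domains:
        tree = trees.get(d.interval.chrom)
        hit = bool(tree is not None and tree.overlap(d.interval.start, d.interval.end))
        out.append(replace(d, location_class="promoter" if hit else "distal"))
    return out


def select_sharp_control(
    regular_domains: Sequence[MergedDomain],
    track: SignalTrack | None = None,
    n: int = 500,
    seed: int = 0,
) -> tuple[list[MergedDomain], list[MergedDomain]]:
    """Split regular merged peaks into the top-``n`` *sharp* set and a matched control.

    Peak height is the mean density over the domain (recomputed from
    ``track`` when given, otherwise :attr:`MergedDomain.mean_signal`).  Ties
    break by (chrom, start) so the split is deterministic.  The control set
    is ``n`` domains drawn uniformly without replacement from the remainder.
    """
    doms = list(regular_domains)
    if not doms:
        raise ValueError("no regular domains supplied")
    if track is not None:
        doms = [replace(d, mean_signal=mean_signal(track, d.interval)) for d in doms]
    n = min(n, len(doms))
    ranked = sorted(
        doms,
        key=lambda d: (-d.mean_signal, d.interval.chrom, d.interval.start, d.interval.end),
    )
    sharp = ranked[:n]
    rest = ranked[n:]
    rng = np.random.default_rng(seed)
    k = min(n, len(rest))
    control_idx = rng.choice(len(rest), size=k, replace=False) if rest else np.empty(0, int)
    control = [rest[i] for i in sorted(control_idx)]
    return sharp, control


def _as_interval(x) -> Interval:
    if isinstance(x, Interval):
        return x
    return x.interval


def overlap_counts(set_a: Sequence, set_b: Sequence) -> tuple[int, int, int, int]:
    """Element-wise Venn counts between two interval sets.

    Returns (a overlapping b, b overlapping a, a only, b only); overlap means
    at least one shared base.  Counts are of elements, so the two overlap
    counts may differ when one element spans several on the other side.
    """
    a = [_as_interval(x) for x in set_a]
    b = [_as_interval(x) for x in set_b]
    trees_b: dict[str, IntervalTree] = {}
    for iv in b:
        trees_b.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    trees_a: dict[str, IntervalTree] = {}
    for iv in a:
        trees_a.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    def count_hits(items, trees):
        return sum(
            1 for iv in items
            if iv.chrom in trees and trees[iv.chrom].overlap(iv.start, iv.end)
        )

    a_in_b = count_hits(a, trees_b)
    b_in_a = count_hits(b, trees_a)
    return a_in_b, b_in_a, len(a) - a_in_b, len(b) - b_in_a


def rose_cutoff(signals: np.ndarray) -> float:
    """Elbow cutoff of the ROSE rank-signal curve.

    Signals are sorted ascending and both axes rescaled to [0, 1]; the cutoff
    is the signal at the point where a line of slope 1 is tangent to the
    scaled curve from below (equivalently, the argmin of scaled_signal -
    scaled_rank).  Regions strictly above the cutoff are super.
    """
    y = np.sort(np.asarray(signals, dtype=float))
    n = y.size
    if n < 2:
        raise ValueError("need at least 2 regions for a cutoff")
    span = y[-1] - y[0]
    if span == 0:
        return float(y[-1])  # flat curve: nothing strictly exceeds it
    ys = (y - y[0]) / span
    xs = np.arange(n, dtype=float) / (n - 1)
    i = int(np.argmin(ys - xs))
    return float(y[i])


def super_domains(
    peaks: Iterable[Peak],
    track: SignalTrack,
    stitch: int = 12500,
) -> SuperDomainResult:
    """ROSE-style super-domain identification.

    Peaks within ``stitch`` bp are stitched; each stitched region's total
    signal is its mean density times its width; regions above the
    tangent-slope-1 elbow cutoff of the scaled rank curve are flagged super.
    """
    stitched = merge_peaks(peaks, max_gap=stitch)
    if len(stitched) < 2:
        raise ValueError("need at least 2 stitched regions")
    totals = np.array([mean_signal(track, d.interval) * d.width for d in stitched])
    cutoff = rose_cutoff(totals)
    order = np.argsort(-totals, kind="stable")  # rank 1 = highest signal
    ranks = np.empty(len(stitched), dtype=int)
    ranks[order] = np.arange(1, len(stitched) + 1)
    regions = tuple(
        StitchedRegion(d.interval, float(t), int(r), bool(t > cutoff))
        for d, t, r in zip(stitched, totals, ranks)
    )
    return SuperDomainResult(regions, cutoff)
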