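"""Downstream analytics on chromatin-state segmentations.

Segmentations (a 15-state tiling of the genome per stage, learned elsewhere
from seven histone marks) are consumed as BED4 with ``E<k>`` or bare integer
labels.  This module computes state coverage, the fraction of variable bases
per state between two stages, and the binned state-score matrices used for
ordination (state 1, active promoter, scores highest; state 15, no signal,
scores 1 — score(k) = n_states + 1 - k).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import ParseError

__all__ = [
    "Segmentation",
    "StateModel",
    "parse_segmentation",
    "state_coverage",
    "variable_bases",
    "state_score_matrix",
]


@dataclass(frozen=True)
class StateModel:
    """State labels and the rank-based score used for binned matrices."""

    n_states: int = 15
    labels: Mapping[int, str] = field(default_factory=dict)

    def score(self, state: int) -> int:
        if not 1 <= state <= self.n_states:
            raise ValueError(f"state {state} out of range 1..{self.n_states}")
        return self.n_states + 1 - state


class Segmentation:
    """Per-stage state tiling: sorted, non-overlapping segments per chromosome.

    Gaps are allowed — unassigned bases are excluded from every denominator.
    """

    def __init__(self, stage: str, segments: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
                 n_states: int = 15):
        self.stage = stage
        self.n_states = n_states
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, states) in segments.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            states = np.asarray(states, dtype=np.int64)
            order = np.argsort(starts, kind="stable")
            starts, ends, states = starts[order], ends[order], states[order]
            if np.any(ends <= starts):
                raise ParseError(f"{stage}/{chrom}: empty segment")
            if np.any(starts[1:] < ends[:-1]):
                raise ParseError(f"{stage}/{chrom}: overlapping segments")
            if np.any((states < 1) | (states > n_states)):
                bad = states[(states < 1) | (states > n_states)][0]
                raise ParseError(f"{stage}/{chrom}: state {bad} out of range 1..{n_states}")
            self._chroms[chrom] = (starts, ends, states)

    @property
    def chroms(self) -> list[str]:
        return list(self._chroms)

    def segments(self, chrom: str):
        return self._chroms.get(
            chrom,
            (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.int64)),
        )

    def restrict(self, chrom_whitelist: Sequence[str]) -> "Segmentation":
        """Keep only whitelisted chromosomes (e.g. autosomes)."""
        keep = {c: self._chroms[c] for c in self._chroms if c in set(chrom_whitelist)}
        return Segmentation(self.stage, keep, self.n_states)

    def exclude(self, regions: pd.DataFrame) -> "Segmentation":
        """Mask out intervals (chrom/start/end rows), e.g. DSB hotspots and PARs."""
        out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by_chrom = {c: g for c, g in regions.groupby("chrom")} if len(regions) else {}
        for chrom, (starts, ends, states) in self._chroms.items():
            if chrom not in by_chrom:
                out[chrom] = (starts, ends, states)
                continue
            mask = sorted(zip(by_chrom[chrom]["start"], by_chrom[chrom]["end"]))
            ns, ne, nst = [], [], []
            for s, e, st in zip(starts, ends, states):
                cur = s
                for ms, me in mask:
                    if me <= cur or ms >= e:
                        continue
                    if ms > cur:
                        ns.append(cur); ne.append(ms); nst.append(st)
                    cur = max(cur, me)
                    if cur >= e:
                        break
                if cur < e:
                    ns.append(cur); ne.append(e); nst.append(st)
            out[chrom] = (np.array(ns, np.int64), np.array(ne, np.int64), np.array(nst, np.int64))
        return Segmentation(self.stage, out, self.n_states)


def _parse_state_label(label: str, n_states: int) -> int:
    label = label.strip()
    if label.upper().startswith("E"):
        label = label[1:]
    try:
        return int(label)
    except ValueError:
        raise ParseError(f"unparseable state label {label!r}") from None


def parse_segmentation(lines: Iterable[str] | str, stage: str = "", n_states: int = 15) -> Segmentation:
    """Parse a BED4 segments file with state labels like ``E7`` (or bare ``7``)."""
    if isinstance(lines, str):
        lines = io.StringIO(lines)
    per: dict[str, list[tuple[int, int, int]]] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"line {lineno}: segmentation needs 4 columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ParseError(f"line {lineno}: non-integer coordinates") from None
        if start >= end:
            raise ParseError(f"line {lineno}: start >= end")
        state = _parse_state_label(fields[3], n_states)
        per.setdefault(fields[0], []).append((start, end, state))
    segs = {
        c: (np.array([r[0] for r in rows]), np.array([r[1] for r in rows]),
            np.array([r[2] for r in rows]))
        for c, rows in per.items()
    }
    return Segmentation(stage, segs, n_states)


def state_coverage(seg: Segmentation) -> pd.DataFrame:
    """Assigned base pairs and fraction per state; fractions sum to 1."""
    bp = np.zeros(seg.n_states, dtype=np.int64)
    for chrom in seg.chroms:
        starts, ends, states = seg.segments(chrom)
        np.add.at(bp, states - 1, ends - starts)
    total = bp.sum()
    if total == 0:
        raise ValueError("segmentation assigns no bases")
    return pd.DataFrame({
        "state": np.arange(1, seg.n_states + 1),
        "bp": bp,
        "fraction": bp / total,
    })


def _paired_states(seg_a: Segmentation, seg_b: Segmentation):
    """Elementary intervals where both segmentations assign a state.

    Yields (length, state_a, state_b) arrays per shared chromosome.
    """
    for chrom in seg_a.chroms:
        sa, ea, ka = seg_a.segments(chrom)
        sb, eb, kb = seg_b.segments(chrom)
        if sa.size == 0 or sb.size == 0:
            continue
        # breakpoints where either segmentation changes
        cuts = np.unique(np.concatenate([sa, ea, sb, eb]))
        left, right = cuts[:-1], cuts[1:]
        mids = left  # half-open: the state at `left` holds over [left, right)
        ia = np.searchsorted(ea, mids, side="right")
        ib = np.searchsorted(eb, mids, side="right")
        in_a = (ia < sa.size) & (sa[np.minimum(ia, sa.size - 1)] <= mids)
        in_b = (ib < sb.size) & (sb[np.minimum(ib, sb.size - 1)] <= mids)
        both = in_a & in_b
        if not both.any():
            continue
        yield (
            (right - left)[both],
            ka[np.minimum(ia, sa.size - 1)][both],
            kb[np.minimum(ib, sb.size - 1)][both],
        )


def variable_bases(
    seg_a: Segmentation,
    seg_b: Segmentation,
    denominator: str = "first",
) -> tuple[pd.DataFrame, float]:
    """Per-state fraction of variable bases between two stages, plus overall.

    The comparison is directional (a -> b): for state s, the fraction is
    (bases labeled s in ``seg_a`` whose ``seg_b`` label differs) / (bases
    labeled s in ``seg_a``), restricted to bases both segmentations assign.
    ``denominator='union'`` instead divides by bases labeled s in either
    stage.  States with a zero denominator have NaN fractions.  Overall is
    changed bases over commonly assigned bases.
    """
    if denominator not in ("first", "union"):
        raise ValueError("denominator must be 'first' or 'union'")
    n = seg_a.n_states
    in_state_a = np.zeros(n, dtype=np.int64)
    in_state_b = np.zeros(n, dtype=np.int64)
    changed_a = np.zeros(n, dtype=np.int64)
    changed_b = np.zeros(n, dtype=np.int64)
    total = changed = 0
    for length, ka, kb in _paired_states(seg_a, seg_b):
        total += int(length.sum())
        diff = ka != kb
        changed += int(length[diff].sum())
        np.add.at(in_state_a, ka - 1, length)
        np.add.at(in_state_b, kb - 1, length)
        np.add.at(changed_a, ka[diff] - 1, length[diff])
        np.add.at(changed_b, kb[diff] - 1, length[diff])
    if denominator == "first":
        denom = in_state_a.astype(float)
        num = changed_a
    else:
        denom = (in_state_a + in_state_b - np.minimum(in_state_a - changed_a, in_state_b - changed_b)).astype(float)
        num = changed_a + changed_b  # counted from each side of the union
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(denom > 0, num / denom, np.nan)
    table = pd.DataFrame({
        "state": np.arange(1, n + 1),
        "bases_in_state": in_state_a,
        "changed_bases": changed_a,
        "fraction": frac,
    })
    overall = changed / total if total else float("nan")
    return table, overall


def state_score_matrix(
    segs: Mapping[str, Segmentation],
    model: StateModel | None = None,
    bin_size: int = 5000,
) -> pd.DataFrame:
    """Stage x bin matrix of length-weighted mean state scores.

    The genome is tiled with fixed ``bin_size`` bins; each bin's score is the
    assigned-length-weighted mean of per-state scores.  Bins lacking any
    assignment in at least one stage are dropped.
    """
    model = model or StateModel(next(iter(segs.values())).n_states)
    rows = {}
    for stage, seg in segs.items():
        sums: dict[tuple[str, int], float] = {}
        lens: dict[tuple[str, int], int] = {}
        for chrom in seg.chroms:
            starts, ends, states = seg.segments(chrom)
            for s, e, k in zip(starts, ends, states):
                score = model.score(int(k))
                b0, b1 = s // bin_size, (e - 1) // bin_size
                for b in range(b0, b1 + 1):
                    lo = max(s, b * bin_size)
                    hi = min(e, (b + 1) * bin_size)
                    key = (chrom, b)
                    sums[key] = sums.get(key, 0.0) + score * (hi - lo)
                    lens[key] = lens.get(key, 0) + (hi - lo)
        rows[stage] = pd.Series(
            {f"{c}:{b * bin_size}": sums[(c, b)] / lens[(c, b)] for c, b in sums}
        )
    mat = pd.DataFrame(rows).T
    mat = mat.dropna(axis=1, how="any")
    return mat
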