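"""Bivalent-domain calling and promoter-state trajectories across stages.

A bivalent domain is an H3K4me3 peak overlapping at least one H3K27me3 peak
(the H3K27me3 peak is typically the broader of the two, so the span kept is
the H3K4me3 peak's).  A gene is bivalent at a stage when a bivalent domain
overlaps its promoter, the TSS +/- 2 kb window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .genome_io import Interval, Peak, StageSeries

__all__ = [
    "STATES",
    "BivalentDomain",
    "call_bivalent",
    "promoter_states",
    "track_trajectories",
    "persistence_fractions",
]

#: Promoter mark states, in reporting order.
STATES: tuple[str, ...] = ("bivalent", "K4_only", "K27_only", "none")


@dataclass(frozen=True)
class BivalentDomain:
    interval: Interval
    overlapping_k27_ids: tuple[str, ...]


def _tree(peaks: Iterable[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        iv = p.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, p.source_id)
    return trees


def call_bivalent(k4_peaks: Sequence[Peak], k27_peaks: Sequence[Peak]) -> list[BivalentDomain]:
    """One bivalent domain per H3K4me3 peak with >= 1 bp H3K27me3 overlap."""
    k27_trees = _tree(k27_peaks)
    out: list[BivalentDomain] = []
    for p in k4_peaks:
        iv = p.interval
        tree = k27_trees.get(iv.chrom)
        if tree is None:
            continue
        hits = tree.overlap(iv.start, iv.end)
        if hits:
            out.append(BivalentDomain(iv, tuple(sorted(h.data for h in hits))))
    return out


def promoter_states(
    tss_table: pd.DataFrame,
    k4_peaks: Sequence[Peak],
    k27_peaks: Sequence[Peak],
    bivalent_domains: Sequence[BivalentDomain] | None = None,
    flank: int = 2000,
) -> pd.DataFrame:
    """Classify every gene's promoter into one mark state.

    bivalent: the TSS +/- flank window overlaps a bivalent domain (an
    overlapping K4/K27 peak pair); otherwise K4_only / K27_only / none by
    which individual peak sets hit the window.  A promoter hit by both a K4
    and a K27 peak that do *not* overlap each other is reported K4_only with
    ``both_marks_nonoverlapping`` set — bivalency requires peak-peak overlap.

    Returns a DataFrame with columns gene_id, state, both_marks_nonoverlapping.
    """
    if bivalent_domains is None:
        bivalent_domains = call_bivalent(k4_peaks, k27_peaks)
    k4_trees = _tree(k4_peaks)
    k27_trees = _tree(k27_peaks)
    biv_trees: dict[str, IntervalTree] = {}
    for d in bivalent_domains:
        biv_trees.setdefault(d.interval.chrom, IntervalTree()).addi(d.interval.start, d.interval.end)

    rows = []
    for g in tss_table.itertuples(index=False):
        start = max(0, int(g.tss) - flank)
        end = int(g.tss) + flank
        chrom = g.chrom

        def hit(trees):
            t = trees.get(chrom)
            return bool(t is not None and t.overlap(start, end))

        has_biv = hit(biv_trees)
        has_k4 = hit(k4_trees)
        has_k27 = hit(k27_trees)
        if has_biv:
            state = "bivalent"
        elif has_k4:
            state = "K4_only"
        elif has_k27:
            state = "K27_only"
        else:
            state = "none"
        rows.append(
            {
                "gene_id": g.gene_id,
                "state": state,
                "both_marks_nonoverlapping": bool(has_k4 and has_k27 and not has_biv),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "state", "both_marks_nonoverlapping"])


def _states_matrix(states: pd.DataFrame) -> pd.DataFrame:
    """Pivot long-form (gene_id, stage, state) to a gene x stage matrix."""
    if {"gene_id", "stage", "state"}.issubset(states.columns):
        return states.pivot(index="gene_id", columns="stage", values="state")
    return states


def track_trajectories(
    states: pd.DataFrame,
    stages: StageSeries,
) -> tuple[dict[tuple[str, str], pd.DataFrame], pd.Series]:
    """Per-stage-pair transition counts and per-gene trajectory strings.

    ``states`` is either long-form (gene_id, stage, state) or a gene x stage
    matrix.  Every tracked gene must have a state at every stage of the
    series (the matrix must be complete).  Returns ({(stage_a, stage_b):
    4x4 count table}, trajectory strings indexed by gene).
    """
    mat = _states_matrix(states)
    missing = [s for s in stages if s not in mat.columns]
    if missing:
        raise ValueError(f"states missing stage(s): {missing}")
    mat = mat[list(stages)]
    if mat.isna().any().any():
        bad = mat.index[mat.isna().any(axis=1)].tolist()
        raise ValueError(f"incomplete state matrix for gene(s): {bad[:5]}...")

    transitions: dict[tuple[str, str], pd.DataFrame] = {}
    for a, b in stages.pairs():
        counts = pd.crosstab(mat[a], mat[b]).reindex(
            index=STATES, columns=STATES, fill_value=0
        )
        counts.index.name, counts.columns.name = a, b
        transitions[(a, b)] = counts
    trajectories = mat.apply(lambda row: "->".join(row), axis=1)
    trajectories.name = "trajectory"
    return transitions, trajectories


def persistence_fractions(
    states: pd.DataFrame,
    stage_a: str,
    stage_b: str,
    from_state: str = "bivalent",
) -> pd.Series | None:
    """Among genes in ``from_state`` at stage_a, the state fractions at stage_b.

    Fractions sum to 1 over :data:`STATES`.  Returns None when no gene is in
    ``from_state`` at stage_a (the fraction is undefined).
    """
    mat = _states_matrix(states)
    sel = mat[mat[stage_a] == from_state][stage_b]
    if len(sel) == 0:
        return None
    frac = sel.value_counts(normalize=True).reindex(STATES, fill_value=0.0)
    frac.name = f"{from_state}@{stage_a}->{stage_b}"
    return frac
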