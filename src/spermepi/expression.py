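"""Expression-side analytics: expressed/repressed flags, DE classes, peak
timing, knockout timing shifts, distal-domain gene assignment and eRNA
class comparison.

FPKM matrices are gene x stage DataFrames (stage columns ordered along the
developmental axis); differential-expression tables are consumed, never
fitted, with columns ``gene_id, log2_fc, p_adj``.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .genome_io import Interval

__all__ = [
    "expressed_flags",
    "de_classify",
    "stage_specific_filter",
    "peak_timing",
    "timing_shift_summary",
    "assign_distal_to_gene",
    "enhancer_classes",
    "erna_compare",
    "zscore_rows",
]

EARLY_STAGES = ("RS2", "RS4")
LATE_STAGES = ("RS8", "LS")


def expressed_flags(matrix: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Boolean expressed flag per gene per stage; FPKM < threshold is repressed."""
    if (matrix < 0).any().any():
        raise ValueError("FPKM values must be >= 0")
    return matrix >= threshold


def de_classify(table: pd.DataFrame, lfc_min: float = 0.5, p_max: float = 0.05) -> pd.Series:
    """Classify genes up / down / ns from a differential-expression table.

    up: log2_fc >= lfc_min and p_adj <= p_max; down: log2_fc <= -lfc_min and
    p_adj <= p_max; everything else (including missing p_adj) is ns.
    """
    lfc = table["log2_fc"]
    padj = table["p_adj"]
    if padj.isna().any():
        warnings.warn(f"{int(padj.isna().sum())} gene(s) with missing p_adj classified ns")
    sig = padj.notna() & (padj <= p_max)
    out = pd.Series("ns", index=table.index, name="de_class")
    out[sig & (lfc >= lfc_min)] = "up"
    out[sig & (lfc <= -lfc_min)] = "down"
    if "gene_id" in table.columns:
        out.index = table["gene_id"]
    return out


def stage_specific_filter(
    matrix: pd.DataFrame,
    min_peak_fpkm: float = 1.0,
    specificity_ratio: float = 2.0,
) -> pd.Index:
    """Genes whose expression peaks specifically at one stage.

    Kept iff the maximal stage FPKM reaches ``min_peak_fpkm`` and is at
    least ``specificity_ratio`` times the median of the remaining stages.
    """
    mx = matrix.max(axis=1)
    # median of the non-peak stages, peak excluded per gene
    order = np.sort(matrix.to_numpy(), axis=1)[:, :-1]
    rest_median = np.median(order, axis=1)
    keep = (mx >= min_peak_fpkm) & (mx.to_numpy() >= specificity_ratio * rest_median)
    return matrix.index[keep]


def peak_timing(
    matrix: pd.DataFrame,
    early_stages: Sequence[str] = EARLY_STAGES,
    late_stages: Sequence[str] = LATE_STAGES,
) -> pd.DataFrame:
    """Early/late peak-timing labels for spermatid-expressed genes.

    peak_stage is the argmax stage (ties resolve to the earliest stage in
    column order); the label is early or late by membership, and
    unclassified for all-zero genes or peaks outside both stage sets.
    Returns a DataFrame with columns peak_stage, label.
    """
    needed = set(early_stages) | set(late_stages)
    missing = needed - set(matrix.columns)
    if missing:
        raise ValueError(f"matrix missing stage(s): {sorted(missing)}")
    peak_stage = matrix.idxmax(axis=1)  # first occurrence wins ties
    label = pd.Series("unclassified", index=matrix.index)
    label[peak_stage.isin(early_stages)] = "early"
    label[peak_stage.isin(late_stages)] = "late"
    label[matrix.max(axis=1) <= 0] = "unclassified"
    return pd.DataFrame({"peak_stage": peak_stage, "label": label})


def timing_shift_summary(
    timing: pd.DataFrame,
    de_by_stage: Mapping[str, pd.DataFrame],
    early_stages: Sequence[str] = EARLY_STAGES,
    late_stages: Sequence[str] = LATE_STAGES,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Count the knockout timing-shift signature per gene class.

    Given KO-vs-control DE tables per stage, counts genes that are: early
    and down at an early stage; early and up at a late stage ("early up
    late"); late and down at a late stage; late and up at an early stage
    ("late up early").  A gene counts once per category if it qualifies at
    any stage of the category's stage set.  Returns (counts table, gene
    lists per category).
    """
    classes = {s: de_classify(t) for s, t in de_by_stage.items()}

    def genes_with(call: str, stage_set: Sequence[str]) -> set[str]:
        hit: set[str] = set()
        for s in stage_set:
            if s in classes:
                cls = classes[s]
                hit |= set(cls.index[cls == call])
        return hit

    early_genes = set(timing.index[timing["label"] == "early"])
    late_genes = set(timing.index[timing["label"] == "late"])
    lists = {
        "early_down_early": early_genes & genes_with("down", early_stages),
        "early_up_late": early_genes & genes_with("up", late_stages),
        "late_down_late": late_genes & genes_with("down", late_stages),
        "late_up_early": late_genes & genes_with("up", early_stages),
    }
    counts = pd.DataFrame(
        {"count": {k: len(v) for k, v in lists.items()}}
    )
    return counts, lists


def assign_distal_to_gene(
    domains: Sequence,
    tss_table: pd.DataFrame,
    max_dist: int = 100_000,
) -> pd.DataFrame:
    """Assign each distal domain to its nearest gene within ``max_dist``.

    Distance is |domain center - TSS| with center = floor((start+end)/2);
    exact distance ties resolve to the lexicographically smaller gene id.
    Domains may be Interval/MergedDomain objects or (chrom, start, end) rows.
    Returns a DataFrame with columns chrom, start, end, gene_id, distance
    (gene_id None when unassigned).
    """
    per_chrom: dict[str, pd.DataFrame] = {
        c: g.sort_values(["tss", "gene_id"]).reset_index(drop=True)
        for c, g in tss_table.groupby("chrom")
    }
    rows = []
    for d in domains:
        iv = d if isinstance(d, Interval) else getattr(d, "interval", None)
        if iv is None:
            chrom, start, end = d.chrom, int(d.start), int(d.end)
        else:
            chrom, start, end = iv.chrom, iv.start, iv.end
        center = (start + end) // 2
        gene, best = None, None
        g = per_chrom.get(chrom)
        if g is not None:
            dist = (g["tss"] - center).abs()
            best = int(dist.min())
            if best <= max_dist:
                cand = g.loc[dist == best, "gene_id"]
                gene = sorted(cand)[0]
            else:
                best = None
        rows.append({"chrom": chrom, "start": start, "end": end,
                     "gene_id": gene, "distance": best})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "distance"])


def _tree_of(intervals) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for x in intervals:
        iv = x if isinstance(x, Interval) else x.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def enhancer_classes(
    k27_peaks: Sequence,
    tss_table: pd.DataFrame,
    broad_k4_domains: Sequence,
    super_enhancers: Sequence,
    tss_flank: int = 2000,
) -> pd.DataFrame:
    """Classify active enhancers by broad-H3K4me3 and super-enhancer overlap.

    Enhancers are distal H3K27ac peaks — no overlap with any TSS +/-
    ``tss_flank`` window.  Classes by >= 1 bp overlap of the enhancer with
    each set: Broad_SEplus (broad H3K4me3 domain and super-enhancer),
    Broad_SEminus (broad domain only), typical (neither).
    """
    tss_trees: dict[str, IntervalTree] = {}
    for g in tss_table.itertuples(index=False):
        tss_trees.setdefault(g.chrom, IntervalTree()).addi(
            max(0, int(g.tss) - tss_flank), int(g.tss) + tss_flank
        )
    broad_trees = _tree_of(broad_k4_domains)
    se_trees = _tree_of(super_enhancers)
    rows = []
    for p in k27_peaks:
        iv = p if isinstance(p, Interval) else p.interval
        t = tss_trees.get(iv.chrom)
        if t is not None and t.overlap(iv.start, iv.end):
            continue  # proximal: not an enhancer
        def hit(trees):
            tr = trees.get(iv.chrom)
            return bool(tr is not None and tr.overlap(iv.start, iv.end))
        if hit(broad_trees):
            cls = "Broad_SEplus" if hit(se_trees) else "Broad_SEminus"
        else:
            cls = "typical"
        rows.append({"chrom": iv.chrom, "start": iv.start, "end": iv.end, "enhancer_class": cls})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "enhancer_class"])


def erna_compare(
    erna_values: pd.Series,
    classes: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class eRNA summaries and pairwise two-sided rank-sum tests.

    ``erna_values`` and ``classes`` are aligned per enhancer.  Classes with
    fewer than 2 members are skipped from testing (noted with NaN p).
    Returns (summary with n/median/q25/q75, pairwise p-value table).
    """
    df = pd.DataFrame({"value": erna_values, "cls": classes}).dropna()
    groups = {c: g["value"].to_numpy() for c, g in df.groupby("cls")}
    if sum(len(v) > 0 for v in groups.values()) < 2:
        raise ValueError("need at least 2 non-empty classes")
    summary = pd.DataFrame({
        c: {
            "n": len(v),
            "median": float(np.median(v)) if len(v) else np.nan,
            "q25": float(np.percentile(v, 25)) if len(v) else np.nan,
            "q75": float(np.percentile(v, 75)) if len(v) else np.nan,
        }
        for c, v in groups.items()
    }).T
    names = sorted(groups)
    pvals = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if len(groups[a]) < 2 or len(groups[b]) < 2:
                continue  # skipped: single-element class
            p = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided").pvalue
            pvals.loc[a, b] = pvals.loc[b, a] = float(p)
    return summary, pvals


def zscore_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Row-standardize a gene x stage matrix (mean 0, sd 1 per row).

    Constant rows become all-zero and are flagged in the returned Series.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 stages")
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=0)
    constant = sd == 0
    z = matrix.sub(mean, axis=0).div(sd.where(~constant, 1.0), axis=0)
    z[constant] = 0.0
    return z, constant.rename("constant_row")
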