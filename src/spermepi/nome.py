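"""NOMe-seq engine: cytosine contexts, methylation/accessibility levels and NDR calling.

In NOMe-seq an exogenous GpC methyltransferase labels accessible DNA, so GCH
(GCA/GCC/GCT) methylation reads out chromatin accessibility while WCG
(ACG/TCG) methylation reads out endogenous CpG methylation; GCG is excluded
from both because the two signals are confounded there.  Cytosine calls are
held as a pandas DataFrame with columns ``chrom, pos, strand, context, meth,
unmeth`` (0-based position of the C on its strand).

Nucleosome-depleted regions (NDRs) are regions whose pooled GCH
accessibility is significantly above the whole-genome background by a
Pearson chi-square test on the 2x2 methylated/unmethylated table
(p <= 1e-10), with more than 5 GCH sites and more than 140 bp of length,
seeded from a 100-bp window scan with a 20-bp step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

__all__ = [
    "BackgroundModel",
    "derive_context",
    "cytosine_report",
    "site_levels",
    "region_mean",
    "fit_background",
    "chi2_accessibility_test",
    "scan_candidate_windows",
    "call_ndrs",
    "classify_ndrs",
    "merge_ndrs_across_samples",
    "bin_level_matrix",
    "merged_region_matrix",
    "gene_body_profile",
    "tss_accessibility_profile",
    "hypomethylation_flags",
]

CALL_COLUMNS = ["chrom", "pos", "strand", "context", "meth", "unmeth"]


@dataclass(frozen=True)
class BackgroundModel:
    """Pooled genome-wide GCH counts; ``rate`` is the background accessibility."""

    meth_total: int
    unmeth_total: int

    def __post_init__(self):
        if self.meth_total + self.unmeth_total <= 0:
            raise ValueError("background requires positive total depth")

    @property
    def rate(self) -> float:
        return self.meth_total / (self.meth_total + self.unmeth_total)


def derive_context(sequence: str, pos: int, strand: str = "+") -> str:
    """Trinucleotide context class of the cytosine at ``pos`` on ``strand``.

    WCG = (A|T)CG, GCH = GC(A|C|T); everything else (notably GCG and CCG) is
    ``other``.  On the minus strand the context is read 5'->3' on that
    strand, i.e. from the reverse complement.  Sequence edges are ``other``.
    """
    if pos - 1 < 0 or pos + 1 >= len(sequence):
        return "other"
    s = sequence.upper()
    if strand == "+":
        if s[pos] != "C":
            raise ValueError(f"position {pos} is not a C on the + strand")
        prev_b, next_b = s[pos - 1], s[pos + 1]
    elif strand == "-":
        if s[pos] != "G":
            raise ValueError(f"position {pos} is not a C on the - strand")
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        prev_b = comp.get(s[pos + 1], "N")
        next_b = comp.get(s[pos - 1], "N")
    else:
        raise ValueError(f"invalid strand {strand!r}")
    if prev_b in "AT" and next_b == "G":
        return "WCG"
    if prev_b == "G" and next_b in "ACT":
        return "GCH"
    return "other"


def cytosine_report(genome: Mapping[str, str]) -> pd.DataFrame:
    """Enumerate every cytosine on both strands with its context class.

    Returns a DataFrame (chrom, pos, strand, context) for all C positions;
    counts can then be attached by a caller or simulator.
    """
    frames = []
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        C, G, A, T = ord("C"), ord("G"), ord("A"), ord("T")
        n = arr.size
        prev = np.empty(n, dtype=np.uint8)
        nxt = np.empty(n, dtype=np.uint8)
        prev[1:], prev[0] = arr[:-1], 0
        nxt[:-1], nxt[-1] = arr[1:], 0

        # plus strand: C at pos; context from literal neighbors
        plus = np.flatnonzero(arr == C)
        p_prev, p_next = prev[plus], nxt[plus]
        p_ctx = np.full(plus.size, "other", dtype=object)
        p_ctx[((p_prev == A) | (p_prev == T)) & (p_next == G)] = "WCG"
        p_ctx[(p_prev == G) & ((p_next == A) | (p_next == C) | (p_next == T))] = "GCH"
        p_ctx[(plus == 0) | (plus == n - 1)] = "other"

        # minus strand: C is a reference G; WCG <=> ref C G [A|T], GCH <=> ref [^C] G C
        minus = np.flatnonzero(arr == G)
        m_prev, m_next = prev[minus], nxt[minus]
        m_ctx = np.full(minus.size, "other", dtype=object)
        m_ctx[(m_prev == C) & ((m_next == A) | (m_next == T))] = "WCG"
        m_ctx[(m_prev != C) & (m_next == C)] = "GCH"
        m_ctx[(minus == 0) | (minus == n - 1)] = "other"

        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": np.concatenate([plus, minus]),
            "strand": ["+"] * plus.size + ["-"] * minus.size,
            "context": np.concatenate([p_ctx, m_ctx]),
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)


def site_levels(calls: pd.DataFrame, min_depth: int = 3) -> pd.DataFrame:
    """Per-site methylation/accessibility levels for depth-qualified sites.

    level = meth / (meth + unmeth); sites with depth below ``min_depth`` are
    dropped.  The input needs columns meth and unmeth (plus chrom/pos for
    downstream region queries).
    """
    depth = calls["meth"] + calls["unmeth"]
    keep = calls.loc[depth >= min_depth].copy()
    keep["depth"] = depth[keep.index]
    keep["level"] = keep["meth"] / keep["depth"]
    return keep.reset_index(drop=True)


def region_mean(
    levels: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    min_sites: int = 3,
) -> float:
    """Unweighted mean site level inside [start, end); NaN below ``min_sites`` sites."""
    sel = levels.loc[
        (levels["chrom"] == chrom) & (levels["pos"] >= start) & (levels["pos"] < end),
        "level",
    ]
    if len(sel) < min_sites:
        return float("nan")
    return float(sel.mean())


def fit_background(gch_calls: pd.DataFrame, min_depth: int = 3) -> BackgroundModel:
    """Pool counts over all depth-qualified GCH sites into the genome background."""
    if "context" in gch_calls.columns:
        gch_calls = gch_calls[gch_calls["context"] == "GCH"]
    depth = gch_calls["meth"] + gch_calls["unmeth"]
    q = gch_calls[depth >= min_depth]
    if len(q) == 0:
        raise ValueError("no depth-qualified GCH sites")
    return BackgroundModel(int(q["meth"].sum()), int(q["unmeth"].sum()))


def _chi2_p(meth: np.ndarray, unmeth: np.ndarray, bg: BackgroundModel) -> np.ndarray:
    """Vectorized Pearson chi-square (1 df, no continuity correction) p-values
    for the 2x2 table [[meth, unmeth], [bg.meth_total, bg.unmeth_total]].
    Degenerate tables (a zero margin) get p = 1."""
    a = np.asarray(meth, dtype=float)
    b = np.asarray(unmeth, dtype=float)
    c, d = float(bg.meth_total), float(bg.unmeth_total)
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    degenerate = (r1 == 0) | (r2 == 0) | (c1 == 0) | (c2 == 0)
    stat = np.where(degenerate, 0.0, stat)
    return stats.chi2.sf(stat, df=1)


def chi2_accessibility_test(
    window_counts: tuple[int, int],
    background: BackgroundModel,
) -> float:
    """P-value for pooled window counts against the genome background.

    Pearson chi-square on the 2x2 methylated/unmethylated table, 1 df, no
    continuity correction.  The test itself is two-sided; NDR calling
    additionally requires the window rate to exceed the background rate.
    """
    meth, unmeth = window_counts
    if meth + unmeth <= 0:
        raise ValueError("window totals must be positive")
    return float(_chi2_p(np.array([meth]), np.array([unmeth]), background)[0])


def _per_chrom(levels: pd.DataFrame):
    for chrom, grp in levels.groupby("chrom", sort=True):
        grp = grp.sort_values("pos", kind="stable")
        yield chrom, (
            grp["pos"].to_numpy(np.int64),
            grp["meth"].to_numpy(np.int64),
            grp["unmeth"].to_numpy(np.int64),
            grp["level"].to_numpy(float),
        )


def scan_candidate_windows(
    gch_levels: pd.DataFrame,
    background: BackgroundModel,
    window: int = 100,
    step: int = 20,
    p_max: float = 1e-10,
) -> pd.DataFrame:
    """Sliding-window scan for accessibility above background.

    Windows are [k*step, k*step + window) anchored at coordinate 0 of each
    chromosome, so the grid phase is deterministic.  A window is a candidate
    when its pooled GCH rate exceeds the background rate and its chi-square
    p-value is at most ``p_max``.
    """
    out = []
    for chrom, (pos, meth, unmeth, _lv) in _per_chrom(gch_levels):
        if pos.size == 0:
            continue
        cm = np.concatenate([[0], np.cumsum(meth)])
        cu = np.concatenate([[0], np.cumsum(unmeth)])
        last = int(pos[-1])
        starts = np.arange(0, last + 1, step, dtype=np.int64)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window, side="left")
        wm = cm[hi] - cm[lo]
        wu = cu[hi] - cu[lo]
        tot = wm + wu
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = np.where(tot > 0, wm / np.maximum(tot, 1), 0.0)
        enriched = (tot > 0) & (rate > background.rate)
        if not enriched.any():
            continue
        p = np.ones(starts.size)
        p[enriched] = _chi2_p(wm[enriched], wu[enriched], background)
        keep = enriched & (p <= p_max)
        if keep.any():
            out.append(pd.DataFrame({
                "chrom": chrom,
                "start": starts[keep],
                "end": starts[keep] + window,
                "meth": wm[keep],
                "unmeth": wu[keep],
                "n_gch": (hi - lo)[keep],
                "p_value": p[keep],
            }))
    if not out:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "meth", "unmeth", "n_gch", "p_value"]
        )
    return pd.concat(out, ignore_index=True)


def _merge_intervals(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Merge intervals whose gap is <= ``gap`` (book-ended intervals merge at 0)."""
    if df.empty:
        return df[["chrom", "start", "end"]].copy()
    df = df.sort_values(["chrom", "start", "end"], kind="stable")
    rows = []
    cur = None
    for chrom, start, end in zip(df["chrom"], df["start"], df["end"]):
        if cur is not None and chrom == cur[0] and start - cur[2] <= gap:
            cur[2] = max(cur[2], end)
        else:
            if cur is not None:
                rows.append(tuple(cur))
            cur = [chrom, start, end]
    rows.append(tuple(cur))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def call_ndrs(
    candidates: pd.DataFrame,
    gch_levels: pd.DataFrame,
    background: BackgroundModel,
    p_max: float = 1e-10,
    min_sites_exclusive: int = 5,
    min_width_exclusive: int = 140,
) -> pd.DataFrame:
    """Merge candidate windows into regions and enforce the NDR criteria.

    Overlapping/book-ended candidates merge; region counts are re-pooled
    from the qualified GCH sites and the chi-square test recomputed at
    region level.  Because a merged window run overhangs the accessible run
    by up to one window length on each side, boundaries are then refined:
    terminal GCH sites are greedily dropped while removing them increases
    the region's Pearson statistic, so the final span ends at the outermost
    evidence-bearing sites (a region whose terminal sites all support the
    enrichment is left untrimmed).  A refined region is an NDR iff
    p <= ``p_max`` AND the number of GCH sites is strictly greater than
    ``min_sites_exclusive`` AND the width is strictly greater than
    ``min_width_exclusive`` AND the region rate exceeds the background
    rate.  Output is disjoint and sorted.
    """
    cols = ["chrom", "start", "end", "n_gch", "level", "p_value"]
    if candidates.empty:
        return pd.DataFrame(columns=cols)
    regions = _merge_intervals(candidates, gap=0)
    by_chrom = {c: arrs for c, arrs in _per_chrom(gch_levels)}
    rows = []
    c_bg, d_bg = float(background.meth_total), float(background.unmeth_total)

    def pearson_stat(m: float, u: float) -> float:
        n = m + u + c_bg + d_bg
        denom = (m + u) * (c_bg + d_bg) * (m + c_bg) * (u + d_bg)
        if denom == 0:
            return 0.0
        return n * (m * d_bg - u * c_bg) ** 2 / denom

    for chrom, start, end in zip(regions["chrom"], regions["start"], regions["end"]):
        if chrom not in by_chrom:
            continue
        pos, meth, unmeth, lv = by_chrom[chrom]
        lo, hi = np.searchsorted(pos, [start, end], side="left")
        if hi - lo == 0:
            continue
        start, end = int(start), int(end)
        # Boundary refinement.  The merged window run overhangs the
        # accessible run by up to one window per side, so trim depths (a, b)
        # are chosen to maximize the two-component binomial profile
        # likelihood: trimmed terminal sites follow the background rate, the
        # retained core its own MLE rate.  Ties favor least trimming.
        k = hi - lo
        cm = np.concatenate([[0], np.cumsum(meth[lo:hi])]).astype(float)
        cu = np.concatenate([[0], np.cumsum(unmeth[lo:hi])]).astype(float)
        p0 = min(max(background.rate, 1e-12), 1 - 1e-12)
        lp0, lq0 = np.log(p0), np.log1p(-p0)

        def loglik(a: int, b: int) -> float:
            m_in = cm[k - b] - cm[a]
            u_in = cu[k - b] - cu[a]
            if m_in + u_in == 0:
                return -np.inf
            m_out = cm[k] - m_in
            u_out = cu[k] - u_in
            p_in = min(max(m_in / (m_in + u_in), 1e-12), 1 - 1e-12)
            return (
                m_in * np.log(p_in) + u_in * np.log1p(-p_in)
                + m_out * lp0 + u_out * lq0
            )

        max_trim = min(k - 1, 32)
        best = (loglik(0, 0), 0, 0)
        for a in range(max_trim + 1):
            for b in range(min(max_trim, k - 1 - a) + 1):
                ll = loglik(a, b)
                if ll > best[0] + 1e-9:
                    best = (ll, a, b)
        _, a, b = best
        lo += a
        hi -= b
        # The true edge lies somewhere between the outermost retained site
        # and the nearest flanking (background) site; take the midpoint,
        # never extending beyond the merged window span.
        if lo > 0:
            start = max(start, (int(pos[lo - 1]) + 1 + int(pos[lo])) // 2)
        if hi < pos.size:
            end = min(end, (int(pos[hi - 1]) + 1 + int(pos[hi])) // 2)
        m, u = int(meth[lo:hi].sum()), int(unmeth[lo:hi].sum())
        n_sites = int(hi - lo)
        if m + u == 0:
            continue
        rate = m / (m + u)
        p = float(_chi2_p(np.array([m]), np.array([u]), background)[0])
        if (
            p <= p_max
            and n_sites > min_sites_exclusive
            and (end - start) > min_width_exclusive
            and rate > background.rate
        ):
            rows.append({
                "chrom": chrom, "start": int(start), "end": int(end),
                "n_gch": n_sites, "level": float(lv[lo:hi].mean()), "p_value": p,
            })
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def classify_ndrs(
    ndrs: pd.DataFrame,
    tss_table: pd.DataFrame,
    flank: int = 1500,
) -> pd.DataFrame:
    """Label each NDR proximal (>= 1 bp overlap with a TSS +/- flank window) or distal."""
    trees: dict[str, IntervalTree] = {}
    for g in tss_table.itertuples(index=False):
        start = max(0, int(g.tss) - flank)
        trees.setdefault(g.chrom, IntervalTree()).addi(start, int(g.tss) + flank)
    out = ndrs.copy()
    labels = []
    for chrom, start, end in zip(out["chrom"], out["start"], out["end"]):
        t = trees.get(chrom)
        labels.append("proximal" if t is not None and t.overlap(start, end) else "distal")
    out["location_class"] = labels
    return out


def merge_ndrs_across_samples(ndr_sets: Sequence[pd.DataFrame], gap: int = 10) -> pd.DataFrame:
    """Union of per-sample NDRs merged within ``gap`` bp; idempotent and order-invariant."""
    frames = [df[["chrom", "start", "end"]] for df in ndr_sets if not df.empty]
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return _merge_intervals(pd.concat(frames, ignore_index=True), gap=gap)


def _bin_means(levels: pd.DataFrame, bin_size: int, min_sites: int) -> pd.Series:
    """Mean level per (chrom, bin-start) bin with at least ``min_sites`` sites."""
    grp = levels.groupby(
        [levels["chrom"], levels["pos"] // bin_size], sort=True
    )["level"].agg(["mean", "count"])
    grp = grp[grp["count"] >= min_sites]["mean"]
    grp.index = [f"{c}:{int(b) * bin_size}" for c, b in grp.index]
    return grp


def bin_level_matrix(
    level_sets: Mapping[str, pd.DataFrame],
    bin_size: int = 1000,
    min_sites: int = 3,
) -> pd.DataFrame:
    """Sample x bin matrix of mean levels over fixed genome bins.

    A bin is kept only when it has at least ``min_sites`` qualified sites in
    *every* sample (bins undefined in any sample are dropped).  The matrix
    feeds ordination downstream; the decomposition itself is out of scope.
    """
    series = {name: _bin_means(df, bin_size, min_sites) for name, df in level_sets.items()}
    mat = pd.DataFrame(series).T
    mat = mat.dropna(axis=1, how="any")
    if mat.shape[1] == 0:
        raise ValueError("all bins were undefined in at least one sample")
    return mat


def merged_region_matrix(
    level_sets: Mapping[str, pd.DataFrame],
    regions: pd.DataFrame,
    min_sites: int = 3,
) -> pd.DataFrame:
    """Sample x region matrix of mean levels over merged NDR intervals.

    Regions with fewer than ``min_sites`` sites in any sample are dropped,
    mirroring the bin-matrix rule.
    """
    cols = {}
    for name, df in level_sets.items():
        vals = [
            region_mean(df, r.chrom, int(r.start), int(r.end), min_sites=min_sites)
            for r in regions.itertuples(index=False)
        ]
        cols[name] = vals
    mat = pd.DataFrame(cols, index=[f"{r.chrom}:{r.start}-{r.end}" for r in regions.itertuples(index=False)]).T
    return mat.dropna(axis=1, how="any")


def _gene_bin_edges(tss: int, tes: int, body_bins: int, flank: int, flank_bin: int) -> np.ndarray:
    """Genomic (left-to-right) bin edges for the extended gene-body profile;
    minus-strand genes are mirrored by the caller after binning."""
    lo, hi = (tss, tes) if tss < tes else (tes, tss)
    n_flank = flank // flank_bin
    up = [lo - flank + i * flank_bin for i in range(n_flank + 1)]
    body = [lo + (hi - lo) * i / body_bins for i in range(body_bins + 1)]
    down = [hi + i * flank_bin for i in range(n_flank + 1)]
    return np.array(up[:-1] + body + down[1:], dtype=float)


def gene_body_profile(
    levels: pd.DataFrame,
    gene_table: pd.DataFrame,
    body_bins: int = 100,
    flank: int = 5000,
    flank_bin: int = 500,
    min_sites: int = 3,
) -> np.ndarray:
    """Metagene profile over extended gene bodies.

    Each gene contributes 10 fixed 500-bp 5'-flank bins, ``body_bins``
    fractional gene-body bins, and 10 fixed 3'-flank bins; minus-strand
    genes are mirrored so bin 1 is always 5'.  Per gene and bin the level is
    the mean of qualified site levels (NaN below ``min_sites`` sites); the
    profile is the nan-mean across genes.
    """
    n_flank = flank // flank_bin
    total = 2 * n_flank + body_bins
    per_chrom = {
        c: (g.sort_values("pos")["pos"].to_numpy(np.int64),
            g.sort_values("pos")["level"].to_numpy(float))
        for c, g in levels.groupby("chrom")
    }
    rows = []
    for g in gene_table.itertuples(index=False):
        if g.chrom not in per_chrom:
            continue
        pos, lv = per_chrom[g.chrom]
        edges = _gene_bin_edges(int(g.tss), int(g.tes), body_bins, flank, flank_bin)
        idx = np.searchsorted(pos, edges, side="left")
        vals = np.full(total, np.nan)
        for k in range(total):
            lo, hi = idx[k], idx[k + 1]
            if hi - lo >= min_sites:
                vals[k] = lv[lo:hi].mean()
        if g.strand == "-":
            vals = vals[::-1]
        rows.append(vals)
    if not rows:
        raise ValueError("no genes on covered chromosomes")
    with np.errstate(invalid="ignore"):
        return np.nanmean(np.vstack(rows), axis=0)


def tss_accessibility_profile(
    gch_levels: pd.DataFrame,
    tss_table: pd.DataFrame,
    flank: int = 2000,
    bin_size: int = 20,
    subtract_baseline: bool = True,
) -> np.ndarray:
    """Mean GCH accessibility in fixed bins across TSS +/- flank windows.

    Sites are pooled per bin offset across all genes (strand-flipped so the
    bin axis runs 5'->3').  The per-sample genome-wide mean GCH site level —
    the "basic line" — is subtracted unless ``subtract_baseline`` is False.
    """
    n_bins = 2 * flank // bin_size
    per_chrom = {
        c: (g.sort_values("pos")["pos"].to_numpy(np.int64),
            g.sort_values("pos")["level"].to_numpy(float))
        for c, g in gch_levels.groupby("chrom")
    }
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for g in tss_table.itertuples(index=False):
        if g.chrom not in per_chrom:
            continue
        pos, lv = per_chrom[g.chrom]
        w_start = int(g.tss) - flank
        lo, hi = np.searchsorted(pos, [w_start, int(g.tss) + flank], side="left")
        if lo == hi:
            continue
        offs = (pos[lo:hi] - w_start) // bin_size
        if g.strand == "-":
            offs = n_bins - 1 - offs
        np.add.at(sums, offs, lv[lo:hi])
        np.add.at(counts, offs, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if subtract_baseline:
        profile = profile - float(gch_levels["level"].mean())
    return profile


def hypomethylation_flags(
    domains: pd.DataFrame,
    wcg_levels: pd.DataFrame,
    threshold: float = 0.3,
    min_sites: int = 3,
) -> pd.DataFrame:
    """Flag domains with mean WCG methylation strictly below ``threshold``.

    Domains with fewer than ``min_sites`` WCG sites are indeterminate:
    ``hypomethylated`` False with ``defined`` False, reported separately.
    ``domains`` needs chrom/start/end columns.
    """
    out = domains.copy()
    means = [
        region_mean(wcg_levels, r.chrom, int(r.start), int(r.end), min_sites=min_sites)
        for r in domains.itertuples(index=False)
    ]
    out["mean_wcg"] = means
    out["defined"] = ~np.isnan(means)
    out["hypomethylated"] = [bool(m < threshold) if m == m else False for m in means]
    return out
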