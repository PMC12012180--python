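"""Synthetic-data generators with ground truth for every pipeline input.

Each generator emulates the statistical structure the analysis assumes —
stage-structured peak landscapes with planted broad/regular domains, GCH/WCG
cytosine calls under a binomial read-count model, Markov-perturbed
chromatin-state segmentations, and stage-peaked expression with knockout
effects — and records the planted truth so every downstream operation is
verifiable at desk scale.  All generators are bit-reproducible under
(seed, config).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import Interval, Peak, SignalTrack
from . import nome as _nome

__all__ = [
    "SimulationConfig",
    "demo_config",
    "make_genome",
    "plant_peak_landscape",
    "simulate_bivalency",
    "simulate_nome",
    "simulate_segmentations",
    "simulate_expression",
    "write_dataset",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Planted study conditions for the demo dataset.

    Defaults describe the desk-scale demo: two 2-Mb chromosomes, 200 genes,
    40 planted broad H3K4me3 domains plus 400 regular peaks across five
    stages, 50 planted 300-bp NDRs (accessibility 0.6 against a 0.1
    background at mean depth 10), 15-state segmentations perturbed at
    per-state rates around 1-3% per stage step, and a spermatid expression
    matrix with a dampen-the-peak / leak-off-peak knockout model.
    """

    seed: int = 0
    chrom_sizes: dict = field(default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000})
    gc_content: float = 0.42
    stages: tuple = ("Undiff", "B", "Z", "mP", "RS4")

    # peak landscape
    n_broad: int = 40
    broad_width_range: tuple = (5_100, 20_000)
    n_regular: int = 400
    regular_width_range: tuple = (500, 2_000)
    min_entity_gap: int = 600          # > the 500-bp merge gap by construction
    broad_stages: tuple = ("mP", "RS4")
    broad_signal_range: tuple = (20.0, 50.0)
    regular_signal_range: tuple = (1.0, 10.0)
    broad_promoter_fraction: float = 0.5
    n_genes: int = 200
    spikein_counts: dict = field(default_factory=lambda: {"rep1": 100_000, "rep2": 150_000})

    # bivalency
    n_erased: int = 30     # bivalent -> K4_only (B..Z) -> bivalent (from mP)
    n_stable_bivalent: int = 40
    n_k4_only: int = 30
    n_k27_only: int = 20

    # NOMe
    n_ndrs: int = 50
    ndr_width: int = 300
    p_background: float = 0.1
    p_ndr: float = 0.6
    mean_depth: float = 10.0
    wcg_meth_rate: float = 0.75

    # segmentation
    n_states: int = 15
    seg_bin: int = 200
    state_change_rates: tuple = tuple(np.round(np.linspace(0.005, 0.03, 15), 4))

    # expression (spermatid stages fixed by the timing definition)
    expr_stages: tuple = ("RS2", "RS4", "RS8", "LS")
    peak_fpkm: float = 20.0
    offpeak_fpkm: float = 2.0
    expr_noise_sd: float = 0.1         # lognormal sigma on the natural log
    ko_dampening: float = 0.5
    ko_leak: float = 2.0
    ko_affected_fraction: float = 0.5

    def __post_init__(self):
        if not (0 < self.p_background < 1 and 0 < self.p_ndr < 1):
            raise ValueError("accessibility probabilities must lie in (0,1)")
        if self.p_ndr <= self.p_background:
            raise ValueError("p_ndr must exceed p_background")
        if self.ko_dampening <= 0 or self.ko_leak <= 0:
            raise ValueError("knockout factors must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator per stream, reproducible under the seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def demo_config(seed: int = 0, **overrides) -> SimulationConfig:
    return SimulationConfig(seed=seed, **overrides)


def make_genome(config: SimulationConfig) -> dict[str, str]:
    """Random sequence per chromosome at the configured GC content.

    WCG/GCH sites then occur at realistic densities emerging from
    composition rather than being laid on a grid, so window-phase edge cases
    are exercised naturally.
    """
    rng = config.rng(1)
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    genome = {}
    for chrom, size in config.chrom_sizes.items():
        if size < 10_000:
            raise ValueError(f"{chrom}: genome chromosomes must be >= 10 kb")
        idx = rng.choice(4, size=size, p=probs)
        genome[chrom] = BASES[idx].tobytes().decode()
    return genome


def _layout_entities(rng, widths: np.ndarray, region: tuple[int, int], min_gap: int) -> np.ndarray:
    """Place widths sequentially with random gaps > ``min_gap``; returns starts."""
    lo, hi = region
    slack = (hi - lo) - int(widths.sum()) - min_gap * len(widths)
    if slack <= 0:
        raise ValueError("infeasible packing: entities exceed available span")
    extra = rng.multinomial(min(slack - 1, 4 * min_gap * len(widths)), np.full(len(widths), 1 / len(widths)))
    starts = lo + np.concatenate([[0], np.cumsum(widths[:-1])]) + np.cumsum(min_gap + extra)
    return starts.astype(np.int64)


def plant_peak_landscape(config: SimulationConfig):
    """Per-stage peak sets with planted broad/regular truth and a TSS table.

    Broad domains (width > 5 kb) appear only in ``broad_stages`` and are
    emitted as 1-3 sub-peaks with internal gaps <= 500 bp so domain merging
    is exercised; regular peaks appear at every stage.  A configured
    fraction of broads carries a TSS at its center (promoter class); filler
    genes live in a reserved peak-free tail of each chromosome, so planted
    location classes are exact.

    Returns (peaks_by_stage, tss_table, track, truth).
    """
    rng = config.rng(2)
    chroms = list(config.chrom_sizes)
    n_b, n_r = config.n_broad, config.n_regular
    widths_b = rng.integers(*config.broad_width_range, size=n_b, endpoint=True)
    widths_r = rng.integers(*config.regular_width_range, size=n_r, endpoint=True)
    kinds = np.array(["broad"] * n_b + ["regular"] * n_r)
    widths = np.concatenate([widths_b, widths_r])
    order = rng.permutation(len(widths))
    kinds, widths = kinds[order], widths[order]

    # round-robin chromosomes; peaks live in [10 kb, 70% of length)
    assign = np.arange(len(widths)) % len(chroms)
    starts = np.empty(len(widths), dtype=np.int64)
    for ci, chrom in enumerate(chroms):
        sel = assign == ci
        region = (10_000, int(0.7 * config.chrom_sizes[chrom]))
        starts[sel] = _layout_entities(rng, widths[sel], region, config.min_entity_gap)

    sig_b = rng.uniform(*config.broad_signal_range, size=len(widths))
    sig_r = rng.uniform(*config.regular_signal_range, size=len(widths))
    signals = np.where(kinds == "broad", sig_b, sig_r)

    # genes: promoter-broads carry a TSS at their center; fillers go to the
    # reserved tail ([80% .. end-10 kb]) where no peak can reach them
    genes = []
    broad_rows = []
    is_promoter = rng.random(len(widths)) < config.broad_promoter_fraction
    gid = 0
    for i in np.flatnonzero(kinds == "broad"):
        chrom = chroms[assign[i]]
        s, e = int(starts[i]), int(starts[i] + widths[i])
        promoter = bool(is_promoter[i])
        if promoter:
            tss = (s + e) // 2
            genes.append((f"gene{gid:04d}", chrom, "+", tss, tss + 3000))
            gid += 1
        broad_rows.append({"chrom": chrom, "start": s, "end": e,
                           "location_class": "promoter" if promoter else "distal"})
    for chrom in chroms:
        lo = int(0.8 * config.chrom_sizes[chrom])
        hi = config.chrom_sizes[chrom] - 10_000
        pos = lo
        while gid < config.n_genes and pos < hi:
            strand = "+" if gid % 2 == 0 else "-"
            tss, tes = (pos, pos + 3000) if strand == "+" else (pos + 3000, pos)
            genes.append((f"gene{gid:04d}", chrom, strand, tss, tes))
            gid += 1
            pos += 4_000
    tss_table = pd.DataFrame(genes, columns=["gene_id", "chrom", "strand", "tss", "tes"])

    regular_rows = [
        {"chrom": chroms[assign[i]], "start": int(starts[i]), "end": int(starts[i] + widths[i])}
        for i in np.flatnonzero(kinds == "regular")
    ]

    def emit_peak(chrom, s, e, sig, pid, out):
        """Emit an entity as 1-3 sub-peaks with internal gaps <= 500 bp."""
        width = e - s
        if width > 2_000 and rng.random() < 0.7:
            n_sub = int(rng.integers(2, 4))
            gaps = rng.integers(100, 501, size=n_sub - 1)
            usable = width - int(gaps.sum())
            cuts = np.sort(rng.choice(np.arange(1, usable), size=n_sub - 1, replace=False))
            lens = np.diff(np.concatenate([[0], cuts, [usable]]))
            pos = s
            for k, ln in enumerate(lens):
                out.append(Peak(Interval(chrom, pos, pos + int(ln)), float(sig), f"{pid}.{k}"))
                pos += int(ln) + (int(gaps[k]) if k < n_sub - 1 else 0)
        else:
            out.append(Peak(Interval(chrom, s, e), float(sig), pid))

    peaks_by_stage: dict[str, list[Peak]] = {}
    for stage in config.stages:
        out: list[Peak] = []
        for i in range(len(widths)):
            if kinds[i] == "broad" and stage not in config.broad_stages:
                continue
            chrom = chroms[assign[i]]
            emit_peak(chrom, int(starts[i]), int(starts[i] + widths[i]),
                      signals[i], f"{stage}_p{i:04d}", out)
        peaks_by_stage[stage] = out

    # a constant-per-peak density track over the full landscape
    track_segs: dict[str, list] = {c: [] for c in chroms}
    for i in range(len(widths)):
        chrom = chroms[assign[i]]
        track_segs[chrom].append((int(starts[i]), int(starts[i] + widths[i]), float(signals[i])))
    track = SignalTrack({
        c: (np.array([r[0] for r in rows]), np.array([r[1] for r in rows]),
            np.array([r[2] for r in rows]))
        for c, rows in track_segs.items() if rows
    })

    truth = {
        "broad_domains": broad_rows,
        "regular_peaks": regular_rows,
        "broad_stages": list(config.broad_stages),
    }
    return peaks_by_stage, tss_table, track, truth


def simulate_bivalency(config: SimulationConfig):
    """Per-stage H3K4me3/H3K27me3 peak sets with planted promoter trajectories.

    Gene classes: ``erased`` genes are bivalent before stage B, lose their
    H3K27me3 peak over B..Z, and regain it from mP on (the
    bivalent -> K4_only -> bivalent pattern); ``stable`` genes stay bivalent;
    ``k4_only`` and ``k27_only`` genes carry a single mark throughout.

    Returns (k4_by_stage, k27_by_stage, tss_table, truth) where truth holds
    the expected state of every gene at every stage.
    """
    chroms = list(config.chrom_sizes)
    stage_idx = {s: i for i, s in enumerate(config.stages)}
    if not {"B", "Z"} & set(config.stages):
        raise ValueError("bivalency scenario needs B and/or Z in the stage list")
    erased_range = {
        s for s in config.stages
        if "B" in stage_idx and "mP" in stage_idx
        and stage_idx["B"] <= stage_idx[s] < stage_idx["mP"]
    }

    classes = (
        ["erased"] * config.n_erased
        + ["stable"] * config.n_stable_bivalent
        + ["k4_only"] * config.n_k4_only
        + ["k27_only"] * config.n_k27_only
    )
    genes, truth_states = [], {}
    k4_by_stage = {s: [] for s in config.stages}
    k27_by_stage = {s: [] for s in config.stages}
    for g, cls in enumerate(classes):
        chrom = chroms[g % len(chroms)]
        tss = 50_000 + (g // len(chroms)) * 20_000
        gene_id = f"bgene{g:04d}"
        genes.append((gene_id, chrom, "+", tss, tss + 2000))
        states = {}
        for stage in config.stages:
            has_k4 = cls in ("erased", "stable", "k4_only")
            has_k27 = (
                cls == "stable"
                or cls == "k27_only"
                or (cls == "erased" and stage not in erased_range)
            )
            if has_k4:
                k4_by_stage[stage].append(
                    Peak(Interval(chrom, tss - 500, tss + 500), 5.0, f"{gene_id}_k4")
                )
            if has_k27:
                k27_by_stage[stage].append(
                    Peak(Interval(chrom, tss - 1500, tss + 1500), 3.0, f"{gene_id}_k27")
                )
            if has_k4 and has_k27:
                states[stage] = "bivalent"
            elif has_k4:
                states[stage] = "K4_only"
            elif has_k27:
                states[stage] = "K27_only"
            else:
                states[stage] = "none"
        truth_states[gene_id] = states
    tss_table = pd.DataFrame(genes, columns=["gene_id", "chrom", "strand", "tss", "tes"])
    truth = {
        "states": truth_states,
        "erased_genes": [f"bgene{g:04d}" for g, c in enumerate(classes) if c == "erased"],
    }
    return k4_by_stage, k27_by_stage, tss_table, truth


def simulate_nome(
    config: SimulationConfig,
    genome: dict[str, str] | None = None,
    report: pd.DataFrame | None = None,
):
    """Cytosine-call table under a binomial read model with planted NDRs.

    Every GCH site draws depth ~ Poisson(mean_depth) and methylated count ~
    Binomial(depth, p) with p = ``p_ndr`` inside planted NDRs and
    ``p_background`` elsewhere; WCG sites draw from ``wcg_meth_rate``.
    Returns (calls DataFrame, truth) with the planted NDR intervals.  A
    precomputed cytosine ``report`` for the same genome may be passed to
    avoid re-deriving contexts across replicate draws (contexts are fixed by
    the sequence).
    """
    if genome is None:
        genome = make_genome(config)
    rng = config.rng(3)
    if report is None:
        report = _nome.cytosine_report(genome)
        report = report[report["context"].isin(["WCG", "GCH"])].reset_index(drop=True)

    # planted NDRs: evenly spread anchors with a random phase, well separated
    chroms = list(genome)
    ndrs = []
    per_chrom = max(1, config.n_ndrs // len(chroms)) if config.n_ndrs else 0
    counts = [per_chrom] * len(chroms)
    counts[-1] += config.n_ndrs - sum(counts)
    counts = [max(0, k) for k in counts]
    for chrom, k in zip(chroms, counts):
        size = len(genome[chrom])
        slots = np.linspace(20_000, size - 20_000 - config.ndr_width, num=k).astype(int)
        jitter = rng.integers(-2_000, 2_000, size=k)
        for s in slots + jitter:
            ndrs.append({"chrom": chrom, "start": int(s), "end": int(s + config.ndr_width)})
    ndr_df = pd.DataFrame(ndrs, columns=["chrom", "start", "end"])
    ndr_df = ndr_df.sort_values(["chrom", "start"]).reset_index(drop=True)

    in_ndr = np.zeros(len(report), dtype=bool)
    for chrom, grp in ndr_df.groupby("chrom"):
        sel = report["chrom"] == chrom
        pos = report.loc[sel, "pos"].to_numpy()
        mask = np.zeros(pos.size, dtype=bool)
        for s, e in zip(grp["start"], grp["end"]):
            mask |= (pos >= s) & (pos < e)
        in_ndr[np.flatnonzero(sel.to_numpy())] = mask

    depth = rng.poisson(config.mean_depth, size=len(report))
    is_gch = (report["context"] == "GCH").to_numpy()
    p = np.where(
        is_gch,
        np.where(in_ndr, config.p_ndr, config.p_background),
        config.wcg_meth_rate,
    )
    meth = rng.binomial(depth, p)
    calls = report.copy()
    calls["meth"] = meth
    calls["unmeth"] = depth - meth
    truth = {"ndrs": ndr_df.to_dict("records")}
    return calls, truth


def simulate_segmentations(config: SimulationConfig):
    """Markov-perturbed 15-state segmentations over 200-bp bins.

    Stage 1 draws each bin from a fixed state-frequency vector; each later
    stage relabels a bin with its state's change rate, the new state uniform
    over the other states.  Truth records the realized changed bases per
    state for every consecutive stage pair.

    Returns (segmentations_text_by_stage, truth); the text is BED4 with
    ``E<k>`` labels, runs of equal states compressed.
    """
    rng = config.rng(4)
    n = config.n_states
    rates = np.asarray(config.state_change_rates, dtype=float)
    if rates.size != n:
        raise ValueError("need one change rate per state")
    if np.any((rates < 0) | (rates > 1)):
        raise ValueError("change rates must lie in [0,1]")
    # mildly skewed stationary start: low states rarer (promoters are small)
    freqs = np.linspace(1.0, 3.0, n)
    freqs /= freqs.sum()

    bins = {c: size // config.seg_bin for c, size in config.chrom_sizes.items()}
    states = {c: rng.choice(np.arange(1, n + 1), size=b, p=freqs) for c, b in bins.items()}

    def to_bed(stage_states) -> str:
        lines = []
        for chrom, arr in stage_states.items():
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change]) * config.seg_bin
            ends = np.concatenate([change, [arr.size]]) * config.seg_bin
            for s, e, k in zip(starts, ends, arr[np.concatenate([[0], change])]):
                lines.append(f"{chrom}\t{s}\t{e}\tE{k}")
        return "\n".join(lines) + "\n"

    texts = {config.stages[0]: to_bed(states)}
    truth_pairs = {}
    for a, b in zip(config.stages[:-1], config.stages[1:]):
        changed_per_state = np.zeros(n, dtype=np.int64)
        in_state = np.zeros(n, dtype=np.int64)
        new_states = {}
        for chrom, arr in states.items():
            flip = rng.random(arr.size) < rates[arr - 1]
            shift = rng.integers(1, n, size=arr.size)
            nxt = arr.copy()
            nxt[flip] = (arr[flip] - 1 + shift[flip]) % n + 1
            np.add.at(in_state, arr - 1, config.seg_bin)
            np.add.at(changed_per_state, arr[flip] - 1, config.seg_bin)
            new_states[chrom] = nxt
        truth_pairs[f"{a}->{b}"] = {
            "changed_bp_per_state": changed_per_state.tolist(),
            "bp_in_state": in_state.tolist(),
        }
        states = new_states
        texts[b] = to_bed(states)
    truth = {"pairs": truth_pairs, "rates": rates.tolist()}
    return texts, truth


def simulate_expression(config: SimulationConfig):
    """Control and knockout FPKM matrices with planted timing and DE truth.

    Each gene peaks at one spermatid stage in control (peak vs off-peak
    FPKM, multiplicative lognormal noise).  For the affected (broad-domain)
    genes the knockout multiplies the peak-stage FPKM by ``ko_dampening``
    (< 1) and every off-peak FPKM by ``ko_leak`` (> 1) — the
    dampen-and-leak timing-shift model.  DE tables carry the planted
    noiseless fold changes with small adjusted p for affected genes and
    uniform p elsewhere.

    Returns (control, ko, de_by_stage, truth).
    """
    rng = config.rng(5)
    stages = list(config.expr_stages)
    n = config.n_genes
    gene_ids = [f"egene{g:04d}" for g in range(n)]
    peak_idx = rng.integers(0, len(stages), size=n)
    affected = rng.random(n) < config.ko_affected_fraction

    base = np.full((n, len(stages)), config.offpeak_fpkm)
    base[np.arange(n), peak_idx] = config.peak_fpkm
    ko_base = base.copy()
    ko_base[affected] *= config.ko_leak
    ko_base[np.arange(n), peak_idx] = np.where(
        affected,
        config.peak_fpkm * config.ko_dampening,
        config.peak_fpkm,
    )

    def noisy(x):
        if config.expr_noise_sd == 0:
            return x.copy()
        return x * rng.lognormal(0.0, config.expr_noise_sd, size=x.shape)

    control = pd.DataFrame(noisy(base), index=gene_ids, columns=stages)
    ko = pd.DataFrame(noisy(ko_base), index=gene_ids, columns=stages)

    lfc = np.log2(ko_base / base)
    de_by_stage = {}
    for j, stage in enumerate(stages):
        sig = np.abs(lfc[:, j]) >= 0.5
        padj = np.where(sig, 1e-4, rng.uniform(0.1, 1.0, size=n))
        de_by_stage[stage] = pd.DataFrame({
            "gene_id": gene_ids,
            "log2_fc": lfc[:, j],
            "p_adj": padj,
        })

    early = {"RS2", "RS4"}
    labels = ["early" if stages[i] in early else "late" for i in peak_idx]
    # planted effects only count when they clear the DE fold-change threshold
    leak_up = abs(np.log2(config.ko_leak)) >= 0.5
    damp_down = abs(np.log2(config.ko_dampening)) >= 0.5
    n_aff_early = int(sum(a and l == "early" for a, l in zip(affected, labels)))
    n_aff_late = int(sum(a and l == "late" for a, l in zip(affected, labels)))
    truth = {
        "labels": dict(zip(gene_ids, labels)),
        "peak_stage": {g: stages[i] for g, i in zip(gene_ids, peak_idx)},
        "affected": [g for g, a in zip(gene_ids, affected) if a],
        "planted_counts": {
            "early_up_late": n_aff_early if leak_up else 0,
            "late_up_early": n_aff_late if leak_up else 0,
            "early_down_early": n_aff_early if damp_down else 0,
            "late_down_late": n_aff_late if damp_down else 0,
        },
    }
    return control, ko, de_by_stage, truth


def write_dataset(config: SimulationConfig, outdir) -> dict:
    """Emit the full demo input tree (BED/TSV/FASTA) plus ground-truth JSON.

    Returns the truth dictionary that was written.
    """
    from .genome_io import write_intervals

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth: dict = {"config": {k: _jsonable(v) for k, v in dataclasses.asdict(config).items()}}

    peaks_by_stage, tss, track, peak_truth = plant_peak_landscape(config)
    (out / "peaks").mkdir(exist_ok=True)
    for stage, peaks in peaks_by_stage.items():
        write_intervals(peaks, out / "peaks" / f"{stage}_H3K4me3.bed")
    tss.to_csv(out / "genes.tsv", sep="\t", index=False)
    track.to_bedgraph(out / "H3K4me3.bedgraph")
    truth["peaks"] = peak_truth

    k4_by_stage, k27_by_stage, btss, biv_truth = simulate_bivalency(config)
    (out / "bivalency").mkdir(exist_ok=True)
    for stage in config.stages:
        write_intervals(k4_by_stage[stage], out / "bivalency" / f"{stage}_K4.bed")
        write_intervals(k27_by_stage[stage], out / "bivalency" / f"{stage}_K27.bed")
    btss.to_csv(out / "bivalency" / "genes.tsv", sep="\t", index=False)
    truth["bivalency"] = biv_truth

    genome = make_genome(config)
    with open(out / "genome.fa", "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    calls, nome_truth = simulate_nome(config, genome)
    calls.to_csv(out / "cytosine_calls.tsv", sep="\t", index=False)
    truth["nome"] = nome_truth

    seg_texts, seg_truth = simulate_segmentations(config)
    (out / "segmentation").mkdir(exist_ok=True)
    for stage, text in seg_texts.items():
        (out / "segmentation" / f"{stage}_segments.bed").write_text(text)
    truth["segmentation"] = seg_truth

    control, ko, de_by_stage, expr_truth = simulate_expression(config)
    (out / "expression").mkdir(exist_ok=True)
    control.rename_axis("gene_id").to_csv(out / "expression" / "control_fpkm.tsv", sep="\t")
    ko.rename_axis("gene_id").to_csv(out / "expression" / "ko_fpkm.tsv", sep="\t")
    for stage, table in de_by_stage.items():
        table.to_csv(out / "expression" / f"de_{stage}.tsv", sep="\t", index=False)
    truth["expression"] = expr_truth

    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=_jsonable)
    return truth


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (tuple, set)):
        return list(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return x
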