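import math

import numpy as np
import pandas as pd
import pytest

from spermepi import nome
from spermepi.nome import (
    BackgroundModel,
    bin_level_matrix,
    call_ndrs,
    chi2_accessibility_test,
    classify_ndrs,
    cytosine_report,
    derive_context,
    fit_background,
    gene_body_profile,
    hypomethylation_flags,
    merge_ndrs_across_samples,
    region_mean,
    scan_candidate_windows,
    site_levels,
    tss_accessibility_profile,
)
from spermepi.simulate import demo_config, make_genome, simulate_nome

from conftest import tss_frame


def calls_frame(rows):
    """rows: (chrom, pos, strand, context, meth, unmeth)"""
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "meth", "unmeth"])


class TestDeriveContext:
    @pytest.mark.parametrize("tri,expected", [
        ("ACG", "WCG"), ("TCG", "WCG"),
        ("GCA", "GCH"), ("GCC", "GCH"), ("GCT", "GCH"),
        ("GCG", "other"), ("CCG", "other"), ("TCT", "other"),
    ])
    def test_plus_strand_trinucleotides(self, tri, expected):
        assert derive_context("A" + tri + "A", 2, "+") == expected

    def test_minus_strand_reads_reverse_complement(self):
        # reference CGA: minus-strand C at the G, context TCG -> WCG
        assert derive_context("ACGTA", 2, "-") == "WCG"
        # reference AGC: minus-strand context GCT -> GCH
        assert derive_context("AAGCA", 2, "-") == "GCH"

    def test_sequence_edge_is_other(self):
        assert derive_context("CG", 0, "+") == "other"
        assert derive_context("ACG", 2, "-") == "other"

    def test_wrong_base_rejected(self):
        with pytest.raises(ValueError):
            derive_context("AAA", 1, "+")

    def test_report_agrees_with_scalar(self, rng):
        bases = np.array(list("ACGT"))
        seq = "".join(bases[rng.integers(0, 4, size=500)])
        report = cytosine_report({"c": seq})
        for row in report.itertuples(index=False):
            assert derive_context(seq, row.pos, row.strand) == row.context


class TestSiteLevels:
    def test_level_arithmetic(self):
        df = site_levels(calls_frame([("c", 1, "+", "GCH", 3, 1)]), min_depth=3)
        assert df.loc[0, "level"] == pytest.approx(0.75)

    def test_depth_filter(self):
        df = site_levels(calls_frame([
            ("c", 1, "+", "GCH", 1, 1),   # depth 2: dropped
            ("c", 2, "+", "GCH", 0, 5),   # level 0 kept
        ]), min_depth=3)
        assert list(df["pos"]) == [2]
        assert df.loc[0, "level"] == 0.0


class TestRegionMean:
    def test_mean_and_min_sites(self):
        lv = site_levels(calls_frame([
            ("c", 10, "+", "GCH", 2, 8),
            ("c", 20, "+", "GCH", 4, 6),
            ("c", 30, "+", "GCH", 6, 4),
        ]))
        assert region_mean(lv, "c", 0, 100) == pytest.approx(0.4)
        assert math.isnan(region_mean(lv, "c", 0, 25))  # 2 sites

    def test_matches_brute_force(self, rng):
        n = 200
        lv = site_levels(calls_frame([
            ("c", int(p), "+", "GCH", int(m), 10 - int(m))
            for p, m in zip(np.sort(rng.choice(10_000, n, replace=False)), rng.integers(0, 11, n))
        ]))
        for _ in range(30):
            a = int(rng.integers(0, 9000))
            b = a + int(rng.integers(100, 1000))
            inside = lv[(lv.pos >= a) & (lv.pos < b)]["level"]
            got = region_mean(lv, "c", a, b)
            if len(inside) < 3:
                assert math.isnan(got)
            else:
                assert got == pytest.approx(inside.mean())


class TestBackground:
    def test_pooling(self):
        bg = fit_background(calls_frame([
            ("c", 1, "+", "GCH", 3, 7),
            ("c", 2, "+", "GCH", 1, 9),
        ]))
        assert (bg.meth_total, bg.unmeth_total) == (4, 16)
        assert bg.rate == pytest.approx(0.2)

    def test_all_unmethylated(self):
        bg = fit_background(calls_frame([("c", 1, "+", "GCH", 0, 5)]))
        assert bg.rate == 0.0

    def test_recovers_simulated_rate(self):
        cfg = demo_config(seed=3, chrom_sizes={"chr1": 300_000}, n_ndrs=0)
        calls, _ = simulate_nome(cfg)
        bg = fit_background(calls)
        n = bg.meth_total + bg.unmeth_total
        se = math.sqrt(0.1 * 0.9 / n)
        assert abs(bg.rate - 0.1) < 3 * se


def chi2_oracle(a, b, c, d):
    """Closed-form Pearson chi-square (1 df) survival function via erfc,
    independent of scipy's chi2 distribution machinery."""
    n = a + b + c + d
    e = [
        (a + b) * (a + c) / n, (a + b) * (b + d) / n,
        (c + d) * (a + c) / n, (c + d) * (b + d) / n,
    ]
    stat = sum((o - ei) ** 2 / ei for o, ei in zip((a, b, c, d), e))
    return math.erfc(math.sqrt(stat / 2))


class TestChi2:
    def test_null_case_p_near_one(self):
        bg = BackgroundModel(1000, 9000)
        assert chi2_accessibility_test((10, 90), bg) == pytest.approx(1.0, abs=1e-9)

    def test_strong_enrichment_below_1e10(self):
        bg = BackgroundModel(100_000, 900_000)
        assert chi2_accessibility_test((30, 10), bg) < 1e-10

    def test_row_swap_symmetry(self):
        bg = BackgroundModel(50, 950)
        p1 = chi2_accessibility_test((30, 10), bg)
        p2 = chi2_accessibility_test((50, 950), BackgroundModel(30, 10))
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_agrees_with_closed_form_oracle_on_grid(self):
        """10x10 grid of 2x2 tables agrees with the erfc closed form to
        1e-10 relative."""
        bg = BackgroundModel(10_000, 90_000)
        for meth in np.linspace(1, 200, 10).astype(int):
            for unmeth in np.linspace(1, 200, 10).astype(int):
                p = chi2_accessibility_test((int(meth), int(unmeth)), bg)
                expect = chi2_oracle(meth, unmeth, 10_000, 90_000)
                assert p == pytest.approx(expect, rel=1e-10, abs=1e-300)

    def test_degenerate_margin_p_one(self):
        bg = BackgroundModel(0, 1000)
        assert chi2_accessibility_test((0, 10), bg) == 1.0


def dense_gch(start, end, spacing, meth, unmeth, chrom="c"):
    return [
        (chrom, p, "+", "GCH", meth, unmeth) for p in range(start, end, spacing)
    ]


class TestScanWindows:
    def setup_method(self):
        self.bg = BackgroundModel(10_000, 90_000)  # rate 0.1

    def test_accessible_cluster_yields_window_run(self):
        rows = dense_gch(0, 10_000, 15, 1, 9) + dense_gch(5_000, 5_300, 15, 9, 1)
        lv = site_levels(calls_frame(rows))
        cand = scan_candidate_windows(lv, self.bg)
        assert len(cand) >= 11
        assert cand["start"].min() >= 4_800 and cand["end"].max() <= 5_500

    def test_window_grid_definition(self):
        rows = dense_gch(1_000, 1_300, 15, 10, 0)
        lv = site_levels(calls_frame(rows))
        cand = scan_candidate_windows(lv, self.bg, window=100, step=20)
        assert (cand["start"] % 20 == 0).all()
        assert ((cand["end"] - cand["start"]) == 100).all()

    def test_background_genome_no_candidates(self):
        rows = dense_gch(0, 20_000, 15, 1, 9)  # exactly at background rate
        lv = site_levels(calls_frame(rows))
        assert len(scan_candidate_windows(lv, self.bg)) == 0


class TestCallNdrs:
    def setup_method(self):
        self.bg = BackgroundModel(10_000, 90_000)

    def _call(self, rows, candidates=None):
        lv = site_levels(calls_frame(rows))
        if candidates is None:
            candidates = scan_candidate_windows(lv, self.bg)
        return call_ndrs(candidates, lv, self.bg)

    def test_emitted_ndrs_satisfy_all_criteria(self):
        rows = dense_gch(0, 50_000, 15, 1, 9) + dense_gch(20_000, 20_400, 15, 9, 1)
        ndrs = self._call(rows)
        assert len(ndrs) == 1
        assert (ndrs["p_value"] <= 1e-10).all()
        assert (ndrs["n_gch"] > 5).all()
        assert ((ndrs["end"] - ndrs["start"]) > 140).all()

    def test_exactly_five_sites_rejected(self):
        # 5 highly accessible sites inside a 141-bp candidate region
        rows = [("c", p, "+", "GCH", 30, 0) for p in (0, 30, 60, 90, 120)]
        cand = pd.DataFrame([{"chrom": "c", "start": 0, "end": 141}])
        assert len(self._call(rows, cand)) == 0
        # a sixth site flips the count criterion
        rows6 = rows + [("c", 135, "+", "GCH", 30, 0)]
        assert len(self._call(rows6, cand)) == 1

    def test_width_exactly_140_rejected_141_eligible(self):
        rows = [("c", p, "+", "GCH", 30, 0) for p in range(0, 140, 20)]  # 7 sites
        cand140 = pd.DataFrame([{"chrom": "c", "start": 0, "end": 140}])
        cand141 = pd.DataFrame([{"chrom": "c", "start": 0, "end": 141}])
        assert len(self._call(rows, cand140)) == 0
        assert len(self._call(rows, cand141)) == 1

    def test_translation_equivariance_modulo_window_phase(self):
        shift = 20 * 37
        rows = dense_gch(0, 50_000, 15, 1, 9) + dense_gch(20_000, 20_400, 15, 9, 1)
        shifted = [(c, p + shift, s, ctx, m, u) for c, p, s, ctx, m, u in rows]
        a = self._call(rows)
        b = self._call(shifted)
        assert list(b["start"] - shift) == list(a["start"])
        assert list(b["end"] - shift) == list(a["end"])


class TestClassifyAndMerge:
    def test_proximal_within_1500(self):
        ndrs = pd.DataFrame([
            {"chrom": "c", "start": 9_000, "end": 9_200},
            {"chrom": "c", "start": 20_000, "end": 20_200},
        ])
        tss = tss_frame([("g", "c", "+", 10_000, 12_000)])
        out = classify_ndrs(ndrs, tss, flank=1500)
        assert list(out["location_class"]) == ["proximal", "distal"]

    def test_merge_gap_boundary(self):
        a = pd.DataFrame([{"chrom": "c", "start": 0, "end": 100}])
        b = pd.DataFrame([{"chrom": "c", "start": 110, "end": 200}])
        merged = merge_ndrs_across_samples([a, b], gap=10)
        assert len(merged) == 1
        c = pd.DataFrame([{"chrom": "c", "start": 111, "end": 200}])
        assert len(merge_ndrs_across_samples([a, c], gap=10)) == 2

    def test_merge_idempotent_and_order_invariant(self, rng):
        sets = []
        for _ in range(3):
            starts = np.sort(rng.choice(10_000, 20, replace=False))
            sets.append(pd.DataFrame({
                "chrom": "c", "start": starts, "end": starts + int(rng.integers(5, 50)),
            }))
        m1 = merge_ndrs_across_samples(sets)
        m2 = merge_ndrs_across_samples(sets[::-1])
        m3 = merge_ndrs_across_samples([m1])
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(m1, m3)


class TestMatricesAndProfiles:
    def test_bin_matrix_drop_rule(self):
        s1 = site_levels(calls_frame(
            [("c", p, "+", "WCG", 5, 5) for p in range(0, 3000, 100)]
        ))
        s2 = site_levels(calls_frame(
            [("c", p, "+", "WCG", 5, 5) for p in range(0, 2000, 100)]  # bin 2 missing
        ))
        mat = bin_level_matrix({"a": s1, "b": s2}, bin_size=1000)
        assert mat.shape == (2, 2)
        assert list(mat.index) == ["a", "b"]

    def test_identical_samples_identical_rows(self):
        s = site_levels(calls_frame([("c", p, "+", "WCG", 5, 5) for p in range(0, 5000, 100)]))
        mat = bin_level_matrix({"a": s, "b": s})
        assert (mat.loc["a"] == mat.loc["b"]).all()

    def test_all_bins_dropped_rejected(self):
        s1 = site_levels(calls_frame([("c", 1, "+", "WCG", 5, 5)]))
        with pytest.raises(ValueError):
            bin_level_matrix({"a": s1})

    def test_cells_match_region_mean(self, rng):
        rows = [
            ("c", int(p), "+", "WCG", int(m), 10 - int(m))
            for p, m in zip(np.sort(rng.choice(10_000, 300, replace=False)), rng.integers(0, 11, 300))
        ]
        s = site_levels(calls_frame(rows))
        mat = bin_level_matrix({"a": s}, bin_size=1000)
        for name, v in mat.loc["a"].items():
            start = int(name.split(":")[1])
            assert v == pytest.approx(region_mean(s, "c", start, start + 1000))

    def _uniform_levels(self, level=0.5, span=60_000):
        m = int(level * 10)
        return site_levels(calls_frame(
            [("c", p, "+", "GCH", m, 10 - m) for p in range(0, span, 20)]
        ))

    def test_gene_body_profile_flat_field(self):
        lv = self._uniform_levels(0.5)
        genes = tss_frame([("g", "c", "+", 10_000, 30_000)])
        prof = gene_body_profile(lv, genes)
        assert prof.shape == (120,)
        np.testing.assert_allclose(prof[~np.isnan(prof)], 0.5, atol=1e-12)

    def test_gene_body_minus_strand_mirrors(self, rng):
        rows = [
            ("c", int(p), "+", "GCH", int(m), 10 - int(m))
            for p, m in zip(np.sort(rng.choice(40_000, 4000, replace=False)), rng.integers(0, 11, 4000))
        ]
        lv = site_levels(calls_frame(rows))
        plus = gene_body_profile(lv, tss_frame([("g", "c", "+", 10_000, 30_000)]))
        minus = gene_body_profile(lv, tss_frame([("g", "c", "-", 30_000, 10_000)]))
        np.testing.assert_allclose(minus, plus[::-1], equal_nan=True)

    def test_tss_profile_baseline_subtraction(self):
        lv = self._uniform_levels(0.5)
        tss = tss_frame([("g", "c", "+", 30_000, 40_000)])
        prof = tss_accessibility_profile(lv, tss)
        assert prof.shape == (200,)
        np.testing.assert_allclose(prof, 0.0, atol=1e-12)
        raw = tss_accessibility_profile(lv, tss, subtract_baseline=False)
        np.testing.assert_allclose(raw - 0.5, prof, atol=1e-12)

    def test_tss_profile_detects_planted_bump(self):
        rows = dense_gch(0, 60_000, 20, 1, 9) + dense_gch(29_800, 30_200, 20, 9, 1)
        lv = site_levels(calls_frame(rows))
        tss = tss_frame([("g", "c", "+", 30_000, 40_000)])
        prof = tss_accessibility_profile(lv, tss)
        # bump bins mix planted 0.9 sites with background 0.1 sites, so the
        # baseline-subtracted center sits well above zero but below 0.8
        center = prof[95:105]
        flanks = np.concatenate([prof[:20], prof[-20:]])
        assert np.nanmean(center) > 0.25
        assert abs(np.nanmean(flanks)) < 0.05


class TestHypomethylation:
    def test_threshold_strict(self):
        doms = pd.DataFrame([
            {"chrom": "c", "start": 0, "end": 100},
            {"chrom": "c", "start": 100, "end": 200},
            {"chrom": "c", "start": 200, "end": 300},
        ])
        rows = (
            [("c", p, "+", "WCG", 29, 71) for p in (10, 40, 70)]     # 0.29
            + [("c", p, "+", "WCG", 30, 70) for p in (110, 140, 170)]  # 0.30
            + [("c", 210, "+", "WCG", 0, 10)]                          # < 3 sites
        )
        out = hypomethylation_flags(doms, site_levels(calls_frame(rows)))
        assert list(out["hypomethylated"]) == [True, False, False]
        assert list(out["defined"]) == [True, True, False]
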