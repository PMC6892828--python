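"""Window tiling, FST and pooled-heterozygosity estimators, Z-transforms,
and outlier calling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sweepscan as sw
from sweepscan.scan_stats import (
    WindowStatRecord,
    fst_series,
    window_fst,
    write_outliers_bed,
)


def brute_fst(p1, p2, r=2):
    """Independent straight-line evaluation of the variance-based estimator."""
    pbar = (p1 + p2) / r
    s2 = sum((p - pbar) ** 2 for p in (p1, p2)) / (r - 1)
    denom = pbar * (1 - pbar) + s2 / r
    return None if denom == 0 else s2 / denom


class TestMakeWindows:
    @pytest.mark.parametrize(
        "length, expected",
        [
            (
                250_000,
                [(0, 100_000), (50_000, 150_000), (100_000, 200_000),
                 (150_000, 250_000), (200_000, 250_000)],
            ),
            (100_000, [(0, 100_000), (50_000, 100_000)]),
            (40_000, [(0, 40_000)]),
        ],
    )
    def test_tiling_enumeration(self, length, expected):
        ws = sw.make_windows({"1": length})
        assert [(w.start, w.end) for w in ws] == expected
        assert [w.index for w in ws] == list(range(len(expected)))

    def test_step_size_between_successive_starts(self):
        ws = sw.make_windows({"1": 1_000_000}, 100_000, 50_000)
        starts = [w.start for w in ws]
        assert all(b - a == 50_000 for a, b in zip(starts, starts[1:]))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"chrom_lengths": {"1": 0}},
            {"chrom_lengths": {"1": 100}, "step": 0},
            {"chrom_lengths": {"1": 100}, "window_size": 10, "step": 20},
        ],
    )
    def test_invalid_geometry_raises(self, kwargs):
        with pytest.raises(ValueError):
            sw.make_windows(**kwargs)


class TestPerSnpFst:
    @pytest.mark.parametrize(
        "p1, p2, expected",
        [
            (0.5, 0.5, 0.0),
            (1.0, 0.0, 1.0),  # fixed difference
            (0.8, 0.2, 0.18 / (0.25 + 0.09)),
        ],
    )
    def test_reference_values(self, p1, p2, expected):
        res = sw.per_snp_fst(p1, p2)
        assert res.fst == pytest.approx(expected, abs=1e-12)

    def test_components_reported(self):
        res = sw.per_snp_fst(0.8, 0.2)
        assert res.s2 == pytest.approx(0.18)
        assert res.pbar == pytest.approx(0.5)
        assert res.r == 2

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_monomorphic_in_both_is_unevaluable(self, p):
        assert not sw.per_snp_fst(p, p).evaluable

    @pytest.mark.parametrize("p1, p2", [(-0.1, 0.5), (0.5, 1.5)])
    def test_out_of_range_frequency_raises(self, p1, p2):
        with pytest.raises(ValueError):
            sw.per_snp_fst(p1, p2)

    @settings(max_examples=300, derandomize=True)
    @given(st.integers(0, 2000), st.integers(0, 2000))
    def test_symmetry_and_allele_label_invariance(self, k1, k2):
        p1, p2 = k1 / 2000, k2 / 2000
        a = sw.per_snp_fst(p1, p2).fst
        b = sw.per_snp_fst(p2, p1).fst
        c = sw.per_snp_fst(1 - p1, 1 - p2).fst
        if math.isnan(a):
            assert math.isnan(b) and math.isnan(c)
        else:
            assert a == pytest.approx(b, abs=1e-12)
            assert a == pytest.approx(c, abs=1e-9)
            assert 0.0 <= a <= 1.0

    def test_monotone_in_divergence_at_fixed_mean(self):
        vals = [sw.per_snp_fst(0.5 + d, 0.5 - d).fst for d in np.linspace(0, 0.5, 51)]
        assert all(b >= a - 1e-15 for a, b in zip(vals, vals[1:]))

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(0)
        p1, p2 = rng.random(500), rng.random(500)
        vec = fst_series(p1, p2)
        for a, b, v in zip(p1, p2, vec):
            assert v == pytest.approx(sw.per_snp_fst(a, b).fst, abs=1e-12)


class TestWindowFst:
    def test_mean_of_values_in_window(self):
        pos0 = np.array([10, 20, 60_000])
        vals = np.array([0.0, 1.0, 0.3])
        means, counts = window_fst(
            pos0, vals, [sw.Window("1", 0, 100, 0)], min_snps=1
        )
        assert means[0] == pytest.approx(0.5)
        assert counts[0] == 2

    def test_empty_window_unevaluable(self):
        means, counts = window_fst(
            np.array([500]), np.array([0.2]), [sw.Window("1", 0, 100, 0)], 1
        )
        assert np.isnan(means[0]) and counts[0] == 0

    def test_overlapping_windows_share_snps(self):
        # a SNP at 60 kb lies in both [0,100k) and [50k,150k)
        windows = sw.make_windows({"1": 150_000})
        means, counts = window_fst(
            np.array([60_000]), np.array([0.7]), windows, min_snps=1
        )
        assert counts[0] == counts[1] == 1
        assert means[0] == means[1] == pytest.approx(0.7)

    def test_nan_snps_do_not_count(self):
        means, counts = window_fst(
            np.array([1, 2, 3]), np.array([np.nan, 0.4, np.nan]),
            [sw.Window("1", 0, 10, 0)], min_snps=2,
        )
        assert counts[0] == 1 and np.isnan(means[0])


class TestWindowHp:
    @pytest.mark.parametrize(
        "s_maj, s_min, expected",
        [(20, 20, 0.5), (30, 0, 0.0), (30, 10, 0.375)],
    )
    def test_reference_values(self, s_maj, s_min, expected):
        assert sw.window_hp(s_maj, s_min) == expected

    def test_zero_counts_raise(self):
        with pytest.raises(ValueError):
            sw.window_hp(0, 0)

    @settings(max_examples=300, derandomize=True)
    @given(st.integers(0, 10**6), st.integers(0, 10**6))
    def test_bounded_and_label_invariant(self, a, b):
        if a + b == 0:
            return
        hp = sw.window_hp(a, b)
        assert 0.0 <= hp <= 0.5
        assert hp == sw.window_hp(b, a)  # tie/relabel invariance


class TestZTransform:
    def test_two_point_example(self):
        z = sw.z_transform(np.array([0.0, 2.0]))
        assert z == pytest.approx([-math.sqrt(0.5), math.sqrt(0.5)], abs=1e-9)

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            sw.z_transform(np.array([3.0, 3.0, 3.0]))

    def test_centering_and_scaling(self):
        rng = np.random.default_rng(1)
        z = sw.z_transform(rng.random(1000))
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_nan_windows_excluded_and_propagated(self):
        z = sw.z_transform(np.array([0.0, np.nan, 2.0]))
        assert np.isnan(z[1])
        assert z[0] == pytest.approx(-math.sqrt(0.5))

    def test_population_sd_convention_available(self):
        z = sw.z_transform(np.array([0.0, 2.0]), ddof=0)
        assert z == pytest.approx([-1.0, 1.0])


def _records(zfst_values, zhp_values=None, chrom="1"):
    recs = []
    zhp_values = zhp_values or [0.0] * len(zfst_values)
    for i, (zf, zh) in enumerate(zip(zfst_values, zhp_values)):
        recs.append(
            WindowStatRecord(
                window=sw.Window(chrom, i * 50_000, i * 50_000 + 100_000, i),
                n_snps=50, n_fst=50, fst_mean=0.1, zfst=zf,
                n_typed={"AB": 50}, hp={"AB": 0.3}, zhp={"AB": zh},
            )
        )
    return recs


class TestOutlierCalling:
    @pytest.mark.parametrize("n, fraction, k", [(200, 0.01, 2), (50, 0.01, 1)])
    def test_top_fraction_uses_ceiling(self, n, fraction, k):
        rng = np.random.default_rng(2)
        out = sw.call_fst_outliers(_records(rng.normal(size=n)), fraction)
        assert len(out) == k

    def test_fraction_one_flags_all(self):
        out = sw.call_fst_outliers(_records([0.1, 0.2, 0.3]), 1.0)
        assert len(out) == 3

    def test_flags_highest_zfst(self):
        out = sw.call_fst_outliers(_records([0.0, 5.0, 1.0, -2.0]), 0.25)
        assert out.records[0].zfst == 5.0

    def test_ties_broken_by_position_exactly_k(self):
        recs = _records([1.0, 1.0, 1.0, 1.0])
        out = sw.call_fst_outliers(recs, 0.5)
        assert len(out) == 2
        assert [r.window.start for r in out.records] == [0, 50_000]

    def test_unevaluable_windows_not_counted(self):
        recs = _records([0.5, np.nan, 1.0, np.nan])
        out = sw.call_fst_outliers(recs, 0.5)
        assert len(out) == 1  # ceil(0.5 * 2 evaluable)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            sw.call_fst_outliers([], 0.01)

    @pytest.mark.parametrize(
        "zhp, flagged", [(-4.0, True), (-3.99, False), (-7.2, True)]
    )
    def test_hp_threshold_boundary_inclusive(self, zhp, flagged):
        recs = _records([0.0, 0.0], zhp_values=[zhp, 0.0])
        out = sw.call_hp_outliers(recs, "AB")
        assert (len(out) == 1) is flagged

    def test_hp_all_above_threshold_is_legal_empty(self):
        out = sw.call_hp_outliers(_records([0.0] * 5), "AB")
        assert len(out) == 0

    def test_hp_unknown_population_raises(self):
        with pytest.raises(KeyError):
            sw.call_hp_outliers(_records([0.0]), "ZZ")

    def test_hp_count_matches_threshold_rule_exactly(self):
        rng = np.random.default_rng(3)
        zh = rng.normal(scale=3, size=500)
        out = sw.call_hp_outliers(_records([0.0] * 500, list(zh)), "AB")
        assert len(out) == int((zh <= -4.0).sum())

    def test_bed_output_sorted_half_open(self, tmp_path):
        out = sw.call_fst_outliers(_records([0.0, 5.0, 1.0, 4.0]), 0.5)
        path = tmp_path / "o.bed"
        write_outliers_bed(out, path)
        lines = path.read_text().strip().split("\n")
        starts = [int(l.split("\t")[1]) for l in lines]
        assert starts == sorted(starts)


class TestScanWindows:
    def test_scan_on_small_simulation(self, small_sim):
        cfg, out = small_sim
        vt = sw.read_vcf(out.vcf, out.sample_map)
        vt, _ = sw.filter_variants(vt)
        records = sw.scan_windows(vt, ("AB", "BG"), ("AB",))
        assert len(records) == 2 * len(sw.make_windows({"1": cfg.chrom_length}))
        zf = np.array([r.zfst for r in records])
        ev = np.isfinite(zf)
        assert abs(zf[ev].mean()) < 1e-9
        assert zf[ev].std(ddof=1) == pytest.approx(1.0, abs=1e-9)
        zh = np.array([r.zhp["AB"] for r in records])
        assert abs(zh[np.isfinite(zh)].mean()) < 1e-9
        for r in records:
            if np.isfinite(r.hp["AB"]):
                assert 0.0 <= r.hp["AB"] <= 0.5

    def test_swept_windows_rank_extreme(self, small_sim):
        """Planted sweeps collapse Hp and inflate FST in the swept windows."""
        cfg, out = small_sim
        vt = sw.read_vcf(out.vcf, out.sample_map)
        vt, _ = sw.filter_variants(vt)
        records = sw.scan_windows(vt, ("AB", "BG"), ("AB",))
        by_zhp = sorted(records, key=lambda r: r.zhp["AB"])
        lowest = {(r.window.chrom, r.window.start) for r in by_zhp[:2]}
        assert lowest == {("1", 500_000), ("2", 1_200_000)}
        by_zfst = sorted(records, key=lambda r: -r.zfst)
        assert {(r.window.chrom, r.window.start) for r in by_zfst[:2]} == lowest

    def test_requires_two_distinct_populations(self, small_sim):
        _, out = small_sim
        vt = sw.read_vcf(out.vcf, out.sample_map)
        with pytest.raises(ValueError):
            sw.scan_windows(vt, ("AB", "AB"))
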