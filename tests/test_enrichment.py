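"""Centering, windowed one-sided KS scoring, and region calling."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as hst

from medipmark.enrichment import (PeakCallerConfig, annotate_regions,
                                  biweight_mean, call_regions,
                                  center_log2_ratios, ks_one_sided,
                                  score_probes)
from medipmark.errors import InputError
from medipmark.simulate import TilingSimConfig, simulate_tiling_groups


def oracle_biweight(values, c=5.0, tol=1e-12, iters=500):
    """Direct fixed-point iteration of the biweight estimating equation."""
    x = np.asarray(values, float)
    m = np.median(x)
    mad = np.median(np.abs(x - m))
    if mad == 0:
        return m
    for _ in range(iters):
        u = (x - m) / (c * mad)
        w = np.where(np.abs(u) < 1, (1 - u ** 2) ** 2, 0.0)
        m2 = (w * x).sum() / w.sum()
        if abs(m2 - m) < tol:
            break
        m = m2
    return m2


class TestBiweightMean:
    def test_degenerate_scale_returns_common_value(self):
        assert biweight_mean([0.7] * 5) == 0.7

    def test_symmetric_sample(self):
        assert biweight_mean([-1.0, 0.0, 1.0]) == pytest.approx(0.0, abs=1e-12)

    def test_outlier_nearly_rejected(self):
        # the gross outlier at 10 falls outside the c*MAD window and gets
        # zero weight, so the estimate stays near the bulk of the data
        data = [0.0, 0.1, 0.2, 10.0]
        m = biweight_mean(data)
        med, mean = np.median(data), np.mean(data)
        assert abs(m - med) < abs(m - mean)
        assert m < 0.25  # far from the arithmetic mean of 2.575
        assert m == pytest.approx(oracle_biweight(data), abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_fixed_point_oracle(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.standard_t(3, size=50)
        assert biweight_mean(data, tol=1e-10) == pytest.approx(
            oracle_biweight(data), abs=1e-8)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=40)
        assert biweight_mean(data + 2.0) == pytest.approx(
            biweight_mean(data) + 2.0, abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            biweight_mean([])


class TestCentering:
    def test_constant_array_centers_to_zero(self, tiny_probe_table):
        df = tiny_probe_table.assign(log2_ratio=0.7)
        out = center_log2_ratios(df)
        assert (out["centered_ratio"] == 0.0).all()

    def test_centering_is_idempotent(self, tiny_probe_table):
        rng = np.random.default_rng(2)
        df = tiny_probe_table.assign(log2_ratio=rng.normal(0.4, 1.0, 10))
        out = center_log2_ratios(df)
        assert abs(biweight_mean(out["centered_ratio"])) < 1e-6

    def test_shifted_copy_centers_identically(self, tiny_probe_table):
        rng = np.random.default_rng(3)
        df = tiny_probe_table.assign(log2_ratio=rng.normal(size=10))
        shifted = df.assign(log2_ratio=df["log2_ratio"] + 2.0)
        a = center_log2_ratios(df)["centered_ratio"]
        b = center_log2_ratios(shifted)["centered_ratio"]
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_non_finite_ratio_names_probe(self, tiny_probe_table):
        df = tiny_probe_table.copy()
        df.loc[3, "log2_ratio"] = np.nan
        with pytest.raises(InputError, match=str(df.loc[3, "probe_id"])):
            center_log2_ratios(df)


def oracle_ks_enumeration(window, background):
    """Independent permutation oracle: enumerate every labeling."""
    w = np.asarray(window, float)
    bg = np.asarray(background, float)
    m, n = len(w), len(bg)
    pooled = np.concatenate([w, bg])

    def kstat(wv, bv):
        wv, bv = np.sort(wv), np.sort(bv)
        cnt = np.searchsorted(bv, wv, side="left")
        return int(np.max(m * cnt - n * np.arange(m)))

    k_obs = kstat(w, bg)
    d_obs = max(k_obs, 0) / (m * n)
    hits = total = 0
    for comb in combinations(range(m + n), m):
        rest = [i for i in range(m + n) if i not in comb]
        hits += kstat(pooled[list(comb)], pooled[rest]) >= k_obs
        total += 1
    return d_obs, hits / total


class TestKsOneSided:
    def test_interleaved_null_window(self):
        d, p = ks_one_sided([0.0, 0.1], [0.05, 0.15])
        assert d <= 0.5
        assert p > 0.5

    def test_complete_separation_matches_permutation_tail(self):
        # window above all background: D+ = 1, one favourable assignment of 10
        d, p = ks_one_sided([5.0, 6.0], [0.0, 1.0, 2.0])
        assert d == 1.0
        assert p == pytest.approx(0.1, abs=0)

    def test_shift_monotonicity(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            w = rng.normal(size=5)
            bg = rng.normal(size=30)
            d1, _ = ks_one_sided(w, bg)
            d2, _ = ks_one_sided(w + 10.0, bg)
            assert d2 >= d1

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_paths_agree_with_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 7))
        n = int(rng.integers(1, 10))
        w = rng.normal(0.5, 1, m)
        bg = rng.normal(0, 1, n)
        d_o, p_o = oracle_ks_enumeration(w, bg)
        d1, p1 = ks_one_sided(w, bg)                       # enumeration path
        d2, p2 = ks_one_sided(w, bg, enumeration_limit=0)  # lattice path
        assert (d1, p1) == (d_o, p_o)
        assert (d2, p2) == (d_o, p_o)

    def test_tied_values_use_enumeration(self):
        w = [1, 1, 3]
        bg = [0, 1, 2, 2]
        d_o, p_o = oracle_ks_enumeration(w, bg)
        d, p = ks_one_sided(w, bg)
        assert (d, p) == (d_o, p_o)

    def test_agrees_with_scipy_one_sided_exact(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            w = rng.normal(0.8, 1, int(rng.integers(2, 9)))
            bg = rng.normal(0, 1, int(rng.integers(30, 200)))
            d, p = ks_one_sided(w, bg, enumeration_limit=0)
            res = st.ks_2samp(w, bg, alternative="less", method="exact")
            assert d == pytest.approx(res.statistic, abs=1e-12)
            assert p == pytest.approx(res.pvalue, rel=1e-9)

    def test_asymptotic_bound_for_large_windows(self):
        rng = np.random.default_rng(6)
        w = rng.normal(1, 1, 50)
        bg = rng.normal(0, 1, 200)
        d, p = ks_one_sided(w, bg)
        assert p == pytest.approx(math.exp(-2 * d * d * 50 * 200 / 250), rel=1e-12)

    def test_empty_inputs_rejected(self):
        with pytest.raises(InputError):
            ks_one_sided([], [1.0])
        with pytest.raises(InputError):
            ks_one_sided([1.0], [])


class TestScoreProbes:
    def _centered(self, df):
        return center_log2_ratios(df)

    def test_requires_centering_and_sorting(self, tiny_probe_table):
        with pytest.raises(InputError, match="centered"):
            score_probes(tiny_probe_table)
        shuffled = self._centered(tiny_probe_table).iloc[::-1].reset_index(drop=True)
        with pytest.raises(InputError, match="sorted"):
            score_probes(shuffled)

    def test_isolated_probe_skipped(self):
        # probes 10 kb apart: every window holds one probe < min_probes_per_window
        starts = np.arange(5) * 10_000
        df = pd.DataFrame({
            "probe_id": [f"chr1:{s}" for s in starts], "chrom": "chr1",
            "start": starts, "end": starts + 50,
            "log2_ratio": [0.0, 1.0, 2.0, 3.0, 4.0],
        })
        scores = score_probes(self._centered(df))
        assert (scores["score"] == 0.0).all()
        assert (scores["p_value"] == 1.0).all()

    def test_matches_ks_one_sided_on_each_window(self, tiny_probe_table):
        rng = np.random.default_rng(8)
        df = self._centered(tiny_probe_table.assign(
            log2_ratio=rng.normal(size=10)))
        cfg = PeakCallerConfig(window_width=300.0, min_probes_per_window=2)
        scores = score_probes(df, cfg)
        vals = df["centered_ratio"].to_numpy()
        mids = (df["start"] + df["end"]).to_numpy() / 2
        for i in range(len(df)):
            member = np.abs(mids - mids[i]) <= 150.0
            d, p = ks_one_sided(vals[member], vals[~member])
            assert scores.loc[i, "p_value"] == pytest.approx(p, rel=1e-9)

    def test_planted_interior_probes_reach_cutoff(self):
        # sparse planting so the background stays essentially null: interior
        # probes (whole window inside the planted promoter) should almost
        # always clear the score cutoff at effect 1.5 / noise 0.5
        cfg = TilingSimConfig(
            n_chromosomes=1, chrom_length=300_000, n_promoters=75,
            promoter_width=2000, planted_fraction_scc=0.1,
            planted_fraction_ac=0.0, planted_fraction_normal=0.0,
            effect_size=1.5, noise_sd=0.5, fragment_smoothing_bp=0, seed=17,
        )
        tables, truth = simulate_tiling_groups(cfg)
        probes = center_log2_ratios(tables["SCC"])
        scores = score_probes(probes)
        mids = (probes["start"] + probes["end"]).to_numpy() / 2
        interior = np.zeros(len(probes), dtype=bool)
        for r in truth[truth.group == "SCC"].itertuples():
            interior |= (mids >= r.start + 250) & (mids < r.end - 250)
        assert interior.sum() > 100
        frac = (scores.loc[interior, "score"] >= 2.0).mean()
        assert frac >= 0.9

    def test_calls_invariant_under_global_shift(self, tiny_probe_table):
        rng = np.random.default_rng(9)
        base = tiny_probe_table.assign(log2_ratio=rng.normal(size=10))
        cfg = PeakCallerConfig(window_width=300.0, score_cutoff=0.5)
        r1 = call_regions(score_probes(self._centered(base), cfg), base, cfg)
        shifted = base.assign(log2_ratio=base["log2_ratio"] + 7.0)
        r2 = call_regions(score_probes(self._centered(shifted), cfg), shifted, cfg)
        pd.testing.assert_frame_equal(r1, r2)


def _mkscores(starts, scores, chrom="chr1", width=50):
    probes = pd.DataFrame({
        "probe_id": [f"{chrom}:{s}" for s in starts], "chrom": chrom,
        "start": starts, "end": np.asarray(starts) + width,
    })
    sdf = pd.DataFrame({"probe_id": probes["probe_id"], "d_plus": 0.5,
                        "p_value": 10.0 ** -np.asarray(scores),
                        "score": np.asarray(scores, float)})
    return sdf, probes


class TestCallRegions:
    def test_no_qualifying_probes_gives_empty(self):
        sdf, probes = _mkscores([0, 100, 200], [0.1, 0.5, 1.9])
        assert call_regions(sdf, probes).empty

    def test_merge_rule_joins_nearby_probes(self):
        sdf, probes = _mkscores([1000, 1100, 1200], [3.0, 2.5, 2.2])
        out = call_regions(sdf, probes)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row.start, row.end, row.n_probes) == (1000, 1250, 3)
        assert row.peak_score == 3.0

    def test_gap_rule_splits_distant_clusters(self):
        sdf, probes = _mkscores([0, 100, 5000, 5100], [3, 3, 3, 3])
        out = call_regions(sdf, probes, PeakCallerConfig(merge_gap=500.0))
        assert len(out) == 2

    def test_min_probe_support_drops_singletons(self):
        sdf, probes = _mkscores([0, 5000], [3, 3])
        out = call_regions(sdf, probes)
        assert out.empty


class TestAnnotateRegions:
    promoters = pd.DataFrame({
        "chrom": ["chr1", "chr1"], "start": [1999, 3000],
        "end": [3000, 4000], "gene": ["GA", "GB"],
    })

    def _regions(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                           "peak_score", "n_probes"])

    def test_one_bp_overlap_counts(self):
        regions = self._regions([("chr1", 1000, 2000, 2.5, 3)])
        out = annotate_regions(regions, self.promoters)
        assert list(out["gene"]) == ["GA"]

    def test_half_open_boundary_no_overlap(self):
        regions = self._regions([("chr1", 1000, 1999, 2.5, 3)])
        out = annotate_regions(regions, self.promoters)
        assert out.empty

    def test_two_regions_one_gene_dedup_max_score(self):
        regions = self._regions([("chr1", 2000, 2100, 2.5, 2),
                                 ("chr1", 2500, 2600, 4.0, 2)])
        out = annotate_regions(regions, self.promoters)
        assert len(out) == 1
        assert out.iloc[0]["peak_score"] == 4.0
        assert out.iloc[0]["n_regions"] == 2

    def test_unknown_chromosome_is_an_error(self):
        regions = self._regions([("chrX", 0, 100, 3.0, 2)])
        with pytest.raises(InputError, match="chrX"):
            annotate_regions(regions, self.promoters)


@settings(derandomize=True, deadline=None, max_examples=40)
@given(hst.lists(hst.floats(-5, 5, allow_nan=False), min_size=1, max_size=8),
       hst.lists(hst.floats(-5, 5, allow_nan=False), min_size=1, max_size=8))
def test_ks_p_is_valid_probability_and_d_in_unit_interval(w, bg):
    d, p = ks_one_sided(w, bg)
    assert 0.0 <= d <= 1.0
    assert 0.0 < p <= 1.0
    assert math.isclose(-math.log10(p), -math.log10(p))  # finite score
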