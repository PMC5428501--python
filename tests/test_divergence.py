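import numpy as np
import pandas as pd
import pytest

from pedscan import divergence as dg

from conftest import make_matrix


def two_group_matrix(calls_a, calls_b, **kw):
    calls = np.hstack([np.asarray(calls_a, dtype=np.int8),
                       np.asarray(calls_b, dtype=np.int8)])
    gm = make_matrix(calls, **kw)
    na = np.asarray(calls_a).shape[1]
    return gm, gm.samples[:na], gm.samples[na:]


class TestWindowedFst:
    def test_complete_fixation_gives_fst_one(self):
        gm, a, b = two_group_matrix(
            np.ones((5, 4)), np.zeros((5, 4)), chrom_size=100)
        w = dg.windowed_fst(gm, a, b, window_bp=100, step_bp=100)
        assert w["fst"].tolist() == [1.0]

    def test_equal_frequencies_hand_value(self):
        # p = 0.5 in both groups, n = 10 each, one site:
        # Hb = 0.5; Hw = 2·0.25·(10/9) = 0.5556; Fst = −1/9
        calls_a = np.array([[0, 0, 0, 0, 0, 1, 1, 1, 1, 1]])
        calls_b = np.array([[0, 0, 0, 0, 0, 1, 1, 1, 1, 1]])
        gm, a, b = two_group_matrix(calls_a, calls_b, chrom_size=100)
        w = dg.windowed_fst(gm, a, b, window_bp=100, step_bp=100)
        assert w["fst"][0] == pytest.approx(-1.0 / 9.0, rel=1e-12)

    def test_group_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 2, size=(40, 12)).astype(np.int8)
        gm = make_matrix(calls, chrom_size=500)
        a, b = gm.samples[:6], gm.samples[6:]
        w1 = dg.windowed_fst(gm, a, b, 500, 500)
        w2 = dg.windowed_fst(gm, b, a, 500, 500)
        assert np.allclose(w1["fst"], w2["fst"])

    def test_monomorphic_window_dropped(self):
        gm, a, b = two_group_matrix(
            np.zeros((3, 3)), np.zeros((3, 3)), chrom_size=100)
        w = dg.windowed_fst(gm, a, b, window_bp=100, step_bp=100)
        assert len(w) == 0

    def test_group_overlap_rejected(self):
        gm = make_matrix(np.zeros((2, 6), dtype=np.int8))
        with pytest.raises(ValueError, match="overlap"):
            dg.windowed_fst(gm, gm.samples[:4], gm.samples[3:])

    def test_small_group_rejected(self):
        gm = make_matrix(np.zeros((2, 4), dtype=np.int8))
        with pytest.raises(ValueError, match="≥2"):
            dg.windowed_fst(gm, gm.samples[:1], gm.samples[1:])


class TestZfst:
    def _windows(self, fst):
        return pd.DataFrame(
            {"chrom": "chr1", "start": 1, "end": 100, "fst": fst})

    def test_simple_standardization(self):
        out = dg.zfst(self._windows([1.0, 2.0, 3.0]))
        assert np.allclose(out["zfst"], [-1.0, 0.0, 1.0])

    def test_normalization_identity(self):
        rng = np.random.default_rng(0)
        out = dg.zfst(self._windows(rng.uniform(0, 1, 500).tolist()))
        assert abs(out["zfst"].mean()) < 1e-12
        assert abs(out["zfst"].std(ddof=1) - 1.0) < 1e-12

    def test_shift_and_scale_invariance(self):
        vals = [0.1, 0.4, 0.2, 0.9, 0.5]
        base = dg.zfst(self._windows(vals))["zfst"]
        shifted = dg.zfst(self._windows([v + 0.3 for v in vals]))["zfst"]
        scaled = dg.zfst(self._windows([v * 7 for v in vals]))["zfst"]
        assert np.allclose(base, shifted)
        assert np.allclose(base, scaled)

    def test_single_window_rejected(self):
        with pytest.raises(ValueError):
            dg.zfst(self._windows([0.5]))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            dg.zfst(self._windows([0.5, 0.5, 0.5]))


class TestPiRatio:
    def _grid(self, pis):
        n = len(pis)
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": [1 + 100 * i for i in range(n)],
                "end": [100 + 100 * i for i in range(n)],
                "pi": pis,
            }
        )

    def test_log2_of_fourfold_ratio(self):
        out = dg.pi_ratio(self._grid([0.004]), self._grid([0.001]))
        assert out["log2_ratio"][0] == pytest.approx(2.0)

    def test_equal_pi_gives_zero(self):
        out = dg.pi_ratio(self._grid([0.002]), self._grid([0.002]))
        assert out["log2_ratio"][0] == 0.0

    def test_zero_denominator_dropped(self):
        out = dg.pi_ratio(self._grid([0.004, 0.004]),
                          self._grid([0.0, 0.001]))
        assert len(out) == 1
        assert out["start"][0] == 101

    def test_inf_policy_keeps_one_sided_zero(self):
        out = dg.pi_ratio(self._grid([0.004, 0.0]),
                          self._grid([0.0, 0.0]), pseudo_policy="inf")
        assert len(out) == 1  # 0/0 still dropped
        assert np.isinf(out["log2_ratio"][0])

    def test_grid_mismatch_rejected(self):
        a = self._grid([0.1, 0.2])
        b = self._grid([0.1, 0.2])
        b.loc[1, "start"] = 999
        with pytest.raises(ValueError, match="grid"):
            dg.pi_ratio(a, b)


class TestCallSweeps:
    def test_toy_grid_against_independent_threshold(self):
        rng = np.random.default_rng(9)
        n = 100
        windows = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": [1 + 100 * i for i in range(n)],
                "end": [100 + 100 * i for i in range(n)],
                "log2_ratio": rng.normal(0, 0.3, n),
                "zfst": rng.normal(0, 1, n),
            }
        )
        # plant 3 overlapping windows exceeding both 95% quantiles
        windows.loc[40:42, "log2_ratio"] = 5.0
        windows.loc[40:42, "zfst"] = 6.0
        # abutting grid: end+1 == next start, so consecutive passers merge
        regions = dg.call_sweeps(windows, tail=0.05)
        thr_r = np.quantile(windows["log2_ratio"], 0.95)
        thr_z = np.quantile(windows["zfst"], 0.95)
        expected = windows[(windows["log2_ratio"] > thr_r)
                           & (windows["zfst"] > thr_z)]
        assert expected.index.tolist() == [40, 41, 42]
        assert len(regions) == 1
        assert regions["start"][0] == windows.loc[40, "start"]
        assert regions["end"][0] == windows.loc[42, "end"]

    def test_tail_zero_is_empty(self):
        windows = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": [1, 101],
                "end": [100, 200],
                "log2_ratio": [1.0, 2.0],
                "zfst": [0.5, 1.5],
            }
        )
        assert len(dg.call_sweeps(windows, tail=0.0)) == 0

    def test_no_passing_windows_is_empty_not_error(self):
        windows = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": [1, 101, 201],
                "end": [100, 200, 300],
                "log2_ratio": [1.0, 2.0, 3.0],
                "zfst": [3.0, 2.0, 1.0],  # tails anti-correlated
            }
        )
        regions = dg.call_sweeps(windows, tail=0.34)
        assert len(regions) == 0


class TestSnpSets:
    def test_venn_counts_and_inclusion_exclusion(self):
        sets = {
            "A": {("c", 1), ("c", 2), ("c", 3)},
            "B": {("c", 2), ("c", 3)},
            "C": {("c", 3)},
        }
        out = dg.snp_set_compare(sets)
        assert out["common_all"] == 1
        assert out["A_unique"] == 1
        assert out["B_unique"] == 0
        assert out["A&B"] == 2
        # inclusion–exclusion reproduces the union exactly
        ie = (out["A"] + out["B"] + out["C"] - out["A&B"] - out["A&C"]
              - out["B&C"] + out["common_all"])
        assert ie == out["union"] == 3

    def test_disjoint_and_identical_sets(self):
        disjoint = dg.snp_set_compare(
            {"A": {("c", 1)}, "B": {("c", 2)}})
        assert disjoint["A&B"] == 0 and disjoint["A_unique"] == 1
        same = dg.snp_set_compare(
            {"A": {("c", 1)}, "B": {("c", 1)}})
        assert same["A_unique"] == same["B_unique"] == 0

    def test_segregating_sites_uses_subset(self):
        calls = np.array([[0, 1, 0, 0], [1, 1, 0, 0], [0, 0, 0, 0]],
                         dtype=np.int8)
        gm = make_matrix(calls)
        assert dg.segregating_sites(gm, gm.samples[:2]) == {("chr1", 10)}
        assert dg.segregating_sites(gm, gm.samples) == {("chr1", 10),
                                                        ("chr1", 20)}


class TestPedigreeSpecific:
    def test_exclusive_uniform_allele(self):
        calls = np.array([[1, 1, 1, 0, 0, 0]], dtype=np.int8)
        gm = make_matrix(calls)
        groups = {"G": gm.samples[:3], "H": gm.samples[3:]}
        out = dg.pedigree_specific_genotypes(gm, groups)
        # ALT specific to G and REF specific to H at the same site
        assert set(zip(out["group"], out["allele"])) == {("G", "T"), ("H", "A")}

    def test_shared_allele_not_specific(self):
        calls = np.array([[1, 1, 1, 1, 0, 0]], dtype=np.int8)
        gm = make_matrix(calls)
        groups = {"G": gm.samples[:3], "H": gm.samples[3:]}
        out = dg.pedigree_specific_genotypes(gm, groups)
        assert not ((out["group"] == "G") & (out["allele"] == "T")).any()

    def test_missing_tolerated_within_call_rate(self):
        calls = np.array([[1, 1, 1, 1, -1, 0, 0, 0, 0, 0]], dtype=np.int8)
        gm = make_matrix(calls)
        groups = {"G": gm.samples[:5], "H": gm.samples[5:]}
        out = dg.pedigree_specific_genotypes(gm, groups, min_call_rate=0.8)
        assert ("G", "T") in set(zip(out["group"], out["allele"]))

    def test_low_call_rate_skipped(self):
        calls = np.array([[1, 1, -1, -1, -1, 0, 0, 0, 0, 0]], dtype=np.int8)
        gm = make_matrix(calls)
        groups = {"G": gm.samples[:5], "H": gm.samples[5:]}
        out = dg.pedigree_specific_genotypes(gm, groups, min_call_rate=0.8)
        assert not ((out["group"] == "G") & (out["allele"] == "T")).any()

    def test_needs_two_groups(self):
        gm = make_matrix(np.zeros((1, 4), dtype=np.int8))
        with pytest.raises(ValueError):
            dg.pedigree_specific_genotypes(gm, {"G": gm.samples})
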