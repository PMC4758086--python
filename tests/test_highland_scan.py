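import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from poolscan import (
    ScanThresholds,
    bh_fdr,
    chi2_allele_test,
    combine_outliers,
    di_statistic,
    fst_table,
    pair_moments,
)

from conftest import make_counts
from test_diversity import freq_table


def build_fst(table1_meta, freq_rows):
    freqs = freq_table(freq_rows, table1_meta)
    pairs = [(h, l) for h in ("BG", "RT") for l in ("CDM", "NJ", "IM", "LN")]
    return fst_table(freqs, pairs)


class TestPairMoments:
    def test_hand_mean_and_sd(self, table1_meta):
        # two SNPs engineered so that every pair sees distinct Fst values
        fst = build_fst(
            table1_meta,
            [[0.1, 0.1, 0.5, 0.5, 0.5, 0.5], [0.9, 0.9, 0.2, 0.2, 0.2, 0.2]],
        )
        moments = pair_moments(fst, table1_meta)
        assert len(moments.pairs) == 8  # all eight highland x lowland pairs
        vals = fst.pair_values("BG", "CDM").to_numpy()
        assert moments.mu[0] == pytest.approx(vals.mean())
        assert moments.sigma[0] == pytest.approx(np.std(vals, ddof=1))

    def test_two_value_pair_hand_check(self, table1_meta):
        fst = build_fst(table1_meta, np.full((2, 6), 0.5))
        # overwrite one pair column with {0.1, 0.3}: mu 0.2, sd ~ 0.1414
        col = fst.pair_column("BG", "CDM")
        fst.frame[col] = [0.1, 0.3]
        for h in ("BG", "RT"):
            for l in ("CDM", "NJ", "IM", "LN"):
                if (h, l) != ("BG", "CDM"):
                    fst.frame[fst.pair_column(h, l)] = [0.0, 0.4]
        moments = pair_moments(fst, table1_meta)
        assert moments.mu[0] == pytest.approx(0.2)
        assert moments.sigma[0] == pytest.approx(0.1414, abs=1e-4)

    def test_constant_pair_rejected(self, table1_meta):
        fst = build_fst(table1_meta, np.full((3, 6), 0.5))
        # all pairwise fst are 0 at every SNP -> zero variance
        with pytest.raises(ValueError, match="zero Fst variance"):
            pair_moments(fst, table1_meta)

    def test_moments_equal_looped_oracle(self, table1_meta):
        rng = np.random.default_rng(3)
        fst = build_fst(table1_meta, rng.random((50, 6)))
        moments = pair_moments(fst, table1_meta)
        for k, (a, b) in enumerate(moments.pairs):
            vals = [float(v) for v in fst.pair_values(a, b) if not np.isnan(v)]
            mean = sum(vals) / len(vals)
            sd = (sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
            np.testing.assert_allclose(moments.mu[k], mean, rtol=1e-12)
            np.testing.assert_allclose(moments.sigma[k], sd, rtol=1e-12)


class TestDiStatistic:
    def test_snp_at_the_mean_scores_zero_and_plus_one_sd_scores_eight(
        self, table1_meta
    ):
        rng = np.random.default_rng(4)
        fst = build_fst(table1_meta, rng.random((40, 6)))
        moments = pair_moments(fst, table1_meta)
        for k, (a, b) in enumerate(moments.pairs):
            col = fst.pair_column(a, b)
            fst.frame.loc[0, col] = moments.mu[k]
            fst.frame.loc[1, col] = moments.mu[k] + moments.sigma[k]
        di = di_statistic(fst, moments)
        assert di["di"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert di["di"].iloc[1] == pytest.approx(8.0)
        assert (di["n_pairs"] == 8).all()

    def test_vectorized_equals_looped_oracle(self, table1_meta):
        rng = np.random.default_rng(5)
        fst = build_fst(table1_meta, rng.random((50, 6)))
        moments = pair_moments(fst, table1_meta)
        di = di_statistic(fst, moments)
        for i in range(50):
            total = 0.0
            for k, (a, b) in enumerate(moments.pairs):
                v = fst.pair_values(a, b).iloc[i]
                total += (v - moments.mu[k]) / moments.sigma[k]
            np.testing.assert_allclose(di["di"].iloc[i], total, rtol=1e-12)

    def test_per_highland_columns_sum_to_di(self, table1_meta):
        rng = np.random.default_rng(15)
        fst = build_fst(table1_meta, rng.random((30, 6)))
        moments = pair_moments(fst, table1_meta)
        di = di_statistic(fst, moments, per_highland=True)
        np.testing.assert_allclose(di["di"], di["di_BG"] + di["di_RT"], rtol=1e-12)

    def test_undefined_pair_contributes_zero(self, table1_meta):
        rng = np.random.default_rng(6)
        fst = build_fst(table1_meta, rng.random((30, 6)))
        moments = pair_moments(fst, table1_meta)
        fst.frame.loc[0, fst.pair_column("BG", "CDM")] = np.nan
        di = di_statistic(fst, moments)
        assert di["n_pairs"].iloc[0] == 7
        assert di["n_pairs"].iloc[1] == 8

    def test_invariant_to_pair_shift_after_restandardization(self, table1_meta):
        rng = np.random.default_rng(7)
        fst = build_fst(table1_meta, rng.random((30, 6)))
        base = di_statistic(fst, pair_moments(fst, table1_meta))
        col = fst.pair_column("RT", "LN")
        fst.frame[col] = fst.frame[col] + 0.17
        shifted = di_statistic(fst, pair_moments(fst, table1_meta))
        np.testing.assert_allclose(base["di"], shifted["di"], atol=1e-9)


class TestChi2AlleleTest:
    def test_hand_computed_2x2(self, two_pops):
        # highland (ref 90, alt 10) vs lowland (ref 50, alt 50):
        # chi2 = 200 * (90*50 - 10*50)^2 / (100 * 100 * 140 * 60) ~ 38.10
        table = make_counts([("1", 1, "A", "C", [(90, 10), (50, 50)])], two_pops)
        out = chi2_allele_test(table, count_mode="reads")
        assert out["chi2"].iloc[0] == pytest.approx(200 * 4000**2 / (100 * 100 * 140 * 60))
        assert out["p"].iloc[0] < 1e-9

    def test_identical_group_proportions_score_zero(self, two_pops):
        table = make_counts([("1", 1, "A", "C", [(60, 40), (30, 20)])], two_pops)
        out = chi2_allele_test(table, count_mode="reads")
        assert out["chi2"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_all_reference_snp_flagged_zero_margin(self, two_pops):
        table = make_counts([("1", 1, "A", "C", [(90, 0), (80, 0)])], two_pops)
        out = chi2_allele_test(table, count_mode="reads")
        assert bool(out["zero_margin"].iloc[0])
        assert out["p"].iloc[0] == 1.0 and out["chi2"].iloc[0] == 0.0

    def test_effective_alleles_cap_evidence_at_chromosome_count(self, two_pops):
        # same frequencies at 10x the depth: reads mode inflates chi2,
        # effective-alleles mode does not change
        shallow = make_counts([("1", 1, "A", "C", [(90, 10), (50, 50)])], two_pops)
        deep = make_counts([("1", 1, "A", "C", [(900, 100), (500, 500)])], two_pops)
        r_shallow = chi2_allele_test(shallow, count_mode="reads")["chi2"].iloc[0]
        r_deep = chi2_allele_test(deep, count_mode="reads")["chi2"].iloc[0]
        assert r_deep == pytest.approx(10 * r_shallow)
        e_shallow = chi2_allele_test(shallow)["chi2"].iloc[0]
        e_deep = chi2_allele_test(deep)["chi2"].iloc[0]
        assert e_deep == pytest.approx(e_shallow)

    def test_matches_scipy_contingency_oracle(self, two_pops):
        rng = np.random.default_rng(8)
        records = []
        for i in range(100):
            counts = rng.integers(1, 200, size=4)
            records.append(("1", i + 1, "A", "C", [tuple(counts[:2]), tuple(counts[2:])]))
        table = make_counts(records, two_pops)
        out = chi2_allele_test(table, count_mode="reads")
        for i, (_, _, _, _, pools) in enumerate(records):
            (hr, ha), (lr, la) = pools
            expected, p, _, _ = chi2_contingency([[ha, hr], [la, lr]], correction=False)
            np.testing.assert_allclose(out["chi2"].iloc[i], expected, rtol=1e-12)
            np.testing.assert_allclose(out["p"].iloc[i], p, rtol=1e-9)

    def test_requires_both_groups(self, table1_meta):
        only_high = [p for p in table1_meta if p.group == "highland"]
        table = make_counts([("1", 1, "A", "C", [(5, 5)] * 2)], only_high)
        with pytest.raises(ValueError, match="highland"):
            chi2_allele_test(table)


class TestBhFdr:
    def test_single_p_value_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_step_up_hand_computation(self):
        # min over j >= i of p_j * m / j: all become 0.04
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_hand_computation_mixed(self):
        p = [0.005, 0.04, 0.03, 0.9]
        # sorted: 0.005 -> 0.02; 0.03 -> min(0.04*4/3=0.0533, 0.03*2? ) step-up:
        # q(4)=0.9, q(3)=min(0.9, 0.04*4/3)=0.05333, q(2)=min(0.05333, 0.03*2)=0.0533
        # wait ranks: sorted p = [0.005, 0.03, 0.04, 0.9]
        # q4 = 0.9; q3 = min(0.9, 0.04*4/3) = 0.05333; q2 = min(q3, 0.03*4/2) = 0.05333
        # q1 = min(q2, 0.005*4) = 0.02
        np.testing.assert_allclose(
            bh_fdr(p), [0.02, 0.0533333333333333, 0.0533333333333333, 0.9], rtol=1e-12
        )

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(9)
        p = rng.random(200)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q <= 1).all() and (q >= p - 1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestCombineOutliers:
    def _components(self, table1_meta, n=10, seed=10):
        rng = np.random.default_rng(seed)
        fst = build_fst(table1_meta, rng.random((n, 6)))
        moments = pair_moments(fst, table1_meta)
        di = di_statistic(fst, moments)
        chi2 = pd.DataFrame(
            {
                "chrom": fst.frame["chrom"],
                "pos": fst.frame["pos"],
                "chi2": rng.random(n) * 5,
                "p": rng.random(n),
                "zero_margin": False,
            }
        )
        return fst, di, chi2

    def test_hand_set_flags_on_toy_table(self, table1_meta):
        fst, di, chi2 = self._components(table1_meta)
        fst.frame["fst_global"] = np.linspace(0.01, 0.10, 10)
        di["di"] = [20, 20, 0, 0, 0, 0, 0, 0, 20, 20]
        chi2["p"] = [1e-9, 0.5, 1e-9, 0.5, 0.5, 0.5, 0.5, 0.5, 1e-9, 1e-9]
        result = combine_outliers(
            fst, di, chi2, ScanThresholds(global_fraction=0.2, di_min=13.5, q_max=0.01)
        )
        # top 20% of global fst = positions with the 2 largest values (rows 8, 9)
        assert result.frame["global_outlier"].tolist() == [False] * 8 + [True] * 2
        # high-lowland set needs di > 13.5 AND q < 0.01 -> rows 0, 8, 9
        assert result.frame["common"].tolist() == [False] * 8 + [True, True]
        assert result.overlap["n_common"] == 2
        assert result.overlap["n_high_lowland"] == 3
        assert result.overlap["n_high_lowland_only"] == 1

    def test_disjoint_sets_have_empty_intersection(self, table1_meta):
        fst, di, chi2 = self._components(table1_meta)
        fst.frame["fst_global"] = [0.9] + [0.1] * 9
        di["di"] = [0] + [20] * 9
        chi2["p"] = [0.9] + [1e-9] * 9
        result = combine_outliers(
            fst, di, chi2, ScanThresholds(global_fraction=0.1, di_min=13.5, q_max=0.01)
        )
        assert result.overlap["n_common"] == 0
        assert result.overlap["n_global"] == 1

    def test_fully_open_thresholds_flag_every_snp(self, table1_meta):
        fst, di, chi2 = self._components(table1_meta)
        result = combine_outliers(
            fst, di, chi2, ScanThresholds(global_fraction=1.0, di_min=-np.inf, q_max=1.1)
        )
        assert result.frame["common"].all()

    def test_misaligned_keys_rejected(self, table1_meta):
        fst, di, chi2 = self._components(table1_meta)
        di = di.iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="aligned"):
            combine_outliers(fst, di, chi2)
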