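import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melascan.genodata import Region, RegionSet
from melascan.popdiff import (
    hudson_fst_overall,
    EmpiricalDistribution,
    attach_empirical_p,
    diversity_scan,
    empirical_p,
    hudson_fst,
    lnrh,
    lsbl,
    lsbl_table,
    pairwise_fst,
    region_significance_counts,
    sliding_windows,
    tajima_constants,
    tajimas_d,
    wc84_fst,
    window_diversity,
)
from melascan.synthsim import PanelSpec, simulate_panel


class TestFst:
    def test_equal_freqs_near_zero(self):
        assert hudson_fst(0.5, 10000, 0.5, 10000) == pytest.approx(0.0, abs=1e-3)

    def test_fixed_difference_is_one(self):
        assert hudson_fst(1.0, 200, 0.0, 200) == pytest.approx(1.0)

    def test_small_sample_returns_nan(self):
        assert np.isnan(hudson_fst(0.5, 1, 0.5, 200))

    def test_wc84_fixed_difference(self):
        assert wc84_fst(1.0, 200, 0.0, 200) == pytest.approx(1.0, abs=0.01)

    def test_calibration_balding_nichols(self):
        # simulation oracle: two pops each drawn at F=0.1 around a shared
        # ancestral frequency have pairwise FST 0.10; the ratio-of-averages
        # Hudson combination recovers it within 0.01
        pac = simulate_panel(
            PanelSpec(n_snps=5000, fst=(0.1, 0.1, 0.0), seed=21)
        )
        assert hudson_fst_overall(pac, "pop1", "pop2") == pytest.approx(
            0.10, abs=0.01
        )
        # per-SNP mean-of-ratios is biased low but still in the ballpark
        est = pairwise_fst(pac, "pop1", "pop2", estimator="hudson")
        assert 0.06 < np.nanmean(est) < 0.10

    def test_unknown_estimator(self):
        pac = simulate_panel(PanelSpec(n_snps=10, seed=0))
        with pytest.raises(ValueError, match="unknown estimator"):
            pairwise_fst(pac, "pop1", "pop2", estimator="nope")


class TestLsbl:
    def test_arithmetic(self):
        a, b, c = lsbl(0.3, 0.2, 0.1)
        assert a == pytest.approx(0.2)
        assert b == pytest.approx(0.1)
        assert c == pytest.approx(0.0)

    def test_symmetry_equal_distances(self):
        assert lsbl(0.4, 0.4, 0.4) == pytest.approx((0.2, 0.2, 0.2))

    def test_missing_input_gives_nan(self):
        assert all(np.isnan(x) for x in lsbl(float("nan"), 0.2, 0.1))

    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1)
    )
    def test_reconstruction_identity(self, d_ab, d_ac, d_bc):
        a, b, _ = lsbl(d_ab, d_ac, d_bc)
        assert a + b == pytest.approx(d_ab, abs=1e-12)

    def test_single_pop_drift_concentrates_branch(self):
        # only pop1 drifts: its branch should dominate, others near zero
        pac = simulate_panel(PanelSpec(n_snps=3000, fst=(0.1, 0.0, 0.0), seed=4))
        tbl = lsbl_table(pac)
        assert tbl["lsbl_pop1"].mean() > 5 * abs(tbl["lsbl_pop2"].mean())
        assert abs(tbl["lsbl_pop2"].mean()) < 0.01
        assert abs(tbl["lsbl_pop3"].mean()) < 0.01


class TestSlidingWindows:
    def test_starts_on_step_grid(self):
        wins = sliding_windows(0, 200_000)
        assert wins[0] == (0, 100_000)
        assert wins[1] == (25_000, 125_000)

    def test_interior_position_in_four_windows(self):
        wins = sliding_windows(0, 1_000_000)
        covering = [w for w in wins if w[0] <= 130_000 < w[1]]
        assert len(covering) == 4

    def test_short_span_single_window(self):
        assert sliding_windows(0, 50_000) == [(0, 100_000)]

    def test_bad_params(self):
        with pytest.raises(ValueError):
            sliding_windows(0, 100, size=0)


class TestWindowDiversity:
    def test_monomorphic_gives_zero(self):
        pac = simulate_panel(PanelSpec(n_snps=20, seed=1))
        pac.count_b[0, :] = 0  # force monomorphic in pop1
        dw = window_diversity(pac, "pop1", (0, 60_000_000), min_snps=1)
        assert dw.S == 0
        assert dw.pi == 0.0

    def test_single_snp_hand_arithmetic(self):
        # one SNP, p=0.5, 2n=100: h = (100/99) * 0.5 = 0.50505...
        pac = simulate_panel(PanelSpec(n_snps=1, n_chrom=(100, 100, 100), seed=2))
        pac.count_b[0, 0] = 50
        dw = window_diversity(pac, "pop1", (0, 60_000_000), min_snps=1)
        assert dw.H_mean == pytest.approx(100 / 99 * 0.5, abs=1e-12)
        assert dw.pi == pytest.approx(100 / 99 * 0.5, abs=1e-12)

    def test_below_min_snps_returns_none(self):
        pac = simulate_panel(PanelSpec(n_snps=5, seed=3))
        assert window_diversity(pac, "pop1", (0, 60_000_000), min_snps=10) is None


class TestTajimasD:
    def test_zero_numerator(self):
        k = tajima_constants(20)
        S = 7
        assert tajimas_d(S, S / k["a1"], 20) == pytest.approx(0.0, abs=1e-12)

    def test_constants_against_independent_oracle(self):
        # independent re-derivation of the constant formulas
        def oracle_d(S, pi, n):
            a1 = sum(1.0 / i for i in range(1, n))
            a2 = sum(1.0 / i**2 for i in range(1, n))
            b1 = (n + 1) / (3.0 * (n - 1))
            b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
            c1 = b1 - 1.0 / a1
            c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
            e1 = c1 / a1
            e2 = c2 / (a1 * a1 + a2)
            return (pi - S / a1) / (e1 * S + e2 * S * (S - 1)) ** 0.5

        assert tajimas_d(5, 3.0, 10) == pytest.approx(oracle_d(5, 3.0, 10), abs=1e-10)
        assert tajimas_d(40, 11.5, 120) == pytest.approx(
            oracle_d(40, 11.5, 120), abs=1e-10
        )

    def test_agrees_with_tskit_exactly(self):
        # same data, independent implementation (tskit's site-mode D)
        msprime = pytest.importorskip("msprime")
        ts = msprime.sim_ancestry(
            samples=10, ploidy=1, sequence_length=1e5,
            recombination_rate=1e-8, population_size=1e4, random_seed=5,
        )
        ts = msprime.sim_mutations(ts, rate=2e-8, random_seed=5)
        geno = ts.genotype_matrix()
        n = geno.shape[1]
        p = geno.mean(axis=1)
        seg = (p > 0) & (p < 1)
        S = int(seg.sum())
        pi = float((n / (n - 1) * 2 * p * (1 - p)).sum())
        assert tajimas_d(S, pi, n) == pytest.approx(ts.Tajimas_D(), abs=1e-10)

    def test_neutral_coalescent_mean_near_zero(self):
        # oracle simulator: constant-size neutral coalescent samples
        msprime = pytest.importorskip("msprime")
        model = msprime.BinaryMutationModel()  # avoid multiallelic hits
        ds = []
        for rep in range(400):
            ts = msprime.sim_ancestry(
                samples=15, ploidy=1, sequence_length=5e4,
                population_size=1e4, random_seed=rep + 1,
            )
            ts = msprime.sim_mutations(
                ts, rate=2e-8, random_seed=rep + 1, model=model,
                discrete_genome=False,
            )
            geno = ts.genotype_matrix()
            if geno.size == 0:
                continue
            n = geno.shape[1]
            p = (geno > 0).mean(axis=1)
            S = int(((p > 0) & (p < 1)).sum())
            if S < 1:
                continue
            pi = float((n / (n - 1) * 2 * p * (1 - p)).sum())
            ds.append(tajimas_d(S, pi, n))
        assert abs(float(np.mean(ds))) < 0.15

    def test_sweep_panel_mean_negative(self):
        # excess of rare derived variants after a sweep drives D down
        from melascan.synthsim import SweepSpec, simulate_sweep

        ds = []
        for seed in range(8):
            hs = simulate_sweep(SweepSpec(seed=seed, s=0.08, stop_freq=0.9))
            p = hs.haps.mean(axis=0)
            seg = (p > 0) & (p < 1)
            S = int(seg.sum())
            n = hs.n_haps
            pi = float((n / (n - 1) * 2 * p * (1 - p))[seg].sum())
            ds.append(tajimas_d(S, pi, n))
        neutral_ds = []
        for seed in range(8):
            hs = simulate_sweep(SweepSpec(seed=seed + 100, s=0.0, init_freq=0.5,
                                          stop_freq=0.99, max_generations=50))
            p = hs.haps.mean(axis=0)
            seg = (p > 0) & (p < 1)
            S = int(seg.sum())
            n = hs.n_haps
            pi = float((n / (n - 1) * 2 * p * (1 - p))[seg].sum())
            neutral_ds.append(tajimas_d(S, pi, n))
        assert np.mean(ds) < np.mean(neutral_ds)

    def test_s_zero_missing(self):
        assert np.isnan(tajimas_d(0, 0.0, 20))


class TestLnrh:
    def test_equal_heterozygosity_zero(self):
        assert lnrh(0.3, 0.3) == 0.0

    def test_antisymmetry(self):
        assert lnrh(0.4, 0.2) == pytest.approx(-lnrh(0.2, 0.4))

    def test_hand_arithmetic(self):
        # theta(0.5) = 3, theta(0.25) = (4/3)^2 - 1 = 7/9
        assert lnrh(0.5, 0.25) == pytest.approx(np.log(3 / (7 / 9)), abs=1e-9)
        assert lnrh(0.5, 0.25) == pytest.approx(1.3499, abs=1e-4)

    def test_scale_invariance_of_theta_variant(self):
        # multiplying both theta estimators by 1/2 leaves lnRH unchanged
        h1, h2 = 0.37, 0.22
        t1 = (1 / (1 - h1)) ** 2 - 1
        t2 = (1 / (1 - h2)) ** 2 - 1
        assert lnrh(h1, h2) == pytest.approx(np.log((0.5 * t1) / (0.5 * t2)))

    def test_floor_gives_nan(self):
        assert np.isnan(lnrh(0.0005, 0.3))

    def test_symmetric_on_equal_diversity_pops(self):
        pac = simulate_panel(PanelSpec(n_snps=4000, seed=17))
        scan = diversity_scan(pac, "pop1", ref_pop="pop2", min_snps=2)
        vals = scan["lnrh"].dropna()
        se = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean()) < 2 * se + 1e-3


class TestEmpiricalP:
    def test_median_of_1_to_100(self):
        dist = EmpiricalDistribution("x", np.arange(1, 101), "upper")
        assert empirical_p(50, dist) == 0.50

    def test_max_upper_is_zero(self):
        dist = EmpiricalDistribution("x", np.arange(1, 101), "upper")
        assert empirical_p(100, dist) == 0.0

    def test_ties_excluded_by_strict_inequality(self):
        # enumeration on a small tied list: values {1,2,2,2,3}
        dist = EmpiricalDistribution("x", np.array([1, 2, 2, 2, 3]), "upper")
        assert empirical_p(2, dist) == pytest.approx(1 / 5)  # only 3 is > 2
        lower = EmpiricalDistribution("x", np.array([1, 2, 2, 2, 3]), "lower")
        assert lower.empirical_p(2) == pytest.approx(1 / 5)  # only 1 is < 2

    def test_neutral_windows_uniform(self):
        # fraction of windows below 0.05 lies in [0.03, 0.07] on a null panel
        pac = simulate_panel(
            PanelSpec(n_snps=25000, span=120_000_000, seed=23)
        )
        scan = diversity_scan(pac, "pop1", min_snps=2)
        assert len(scan) >= 2000
        scan = attach_empirical_p(scan, "tajima_d", tail="lower")
        frac = (scan["empirical_p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07


class TestRegionCounts:
    def _table(self, ps):
        return pd.DataFrame(
            {
                "chrom": ["1"] * len(ps),
                "pos": np.arange(1, len(ps) + 1) * 100,
                "empirical_p": ps,
            }
        )

    def test_exclusive_binning(self):
        regions = RegionSet([Region("r1", "1", 0, 10_000)])
        out = region_significance_counts(
            self._table([0.0005, 0.005, 0.04, 0.5]), regions
        )
        row = out.iloc[0]
        assert (row["n_p_lt_0.001"], row["n_p_lt_0.01"], row["n_p_lt_0.05"]) == (1, 1, 1)

    def test_cumulative_binning(self):
        regions = RegionSet([Region("r1", "1", 0, 10_000)])
        out = region_significance_counts(
            self._table([0.0005, 0.005, 0.04, 0.5]), regions, mode="cumulative"
        )
        row = out.iloc[0]
        assert (row["n_p_lt_0.001"], row["n_p_lt_0.01"], row["n_p_lt_0.05"]) == (1, 2, 3)

    def test_empty_region(self):
        regions = RegionSet([Region("empty", "2", 0, 10_000)])
        out = region_significance_counts(self._table([0.5]), regions)
        row = out.iloc[0]
        assert (row["n_p_lt_0.001"], row["n_p_lt_0.01"], row["n_p_lt_0.05"]) == (0, 0, 0)

    def test_injected_differentiation_region_ranks_first(self):
        # panels where pop1 drifts only inside [10Mb, 12Mb): that region's
        # significant-LSBL count should beat a matched null region
        hits = 0
        reps = 12
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            pac = simulate_panel(PanelSpec(n_snps=4000, seed=seed + 500))
            pos = pac.positions
            inside = (pos - 1 >= 10_000_000) & (pos - 1 < 12_000_000)
            # drift pop1 inside the region (Balding-Nichols at F=0.15)
            p_anc = pac.count_b[1] / pac.n_chrom[1]
            f = 0.15
            p_new = rng.beta(
                np.clip(p_anc[inside], 0.01, 0.99) * (1 - f) / f,
                np.clip(1 - p_anc[inside], 0.01, 0.99) * (1 - f) / f,
            )
            pac.count_b[0, inside] = rng.binomial(
                pac.n_chrom[0, inside], p_new
            )
            tbl = lsbl_table(pac)
            tbl = attach_empirical_p(tbl, "lsbl_pop1", tail="upper")
            regions = RegionSet(
                [
                    Region("sweep", "1", 10_000_000, 12_000_000),
                    Region("null", "1", 30_000_000, 32_000_000),
                ]
            )
            counts = region_significance_counts(
                tbl, regions, mode="cumulative"
            ).set_index("region")
            if (
                counts.loc["sweep", "n_p_lt_0.05"]
                > counts.loc["null", "n_p_lt_0.05"]
            ):
                hits += 1
        assert hits / reps >= 0.9
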