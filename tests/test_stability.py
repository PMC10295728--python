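"""The four stability algorithms against hand examples, brute-force oracles
and their structural invariants."""

import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import make_ct_matrix, random_ct_matrix
from refstab.exceptions import InsufficientDataError
from refstab.qpcr import ct_to_log_quantity
from refstab.simulate import SimulationConfig, simulate_ct_dataset
from refstab.stability import (
    bestkeeper_stats,
    delta_ct_stability,
    genorm_m_values,
    genorm_pairwise_variation,
    genorm_rank,
    genorm_stability,
    normfinder_stability,
)


def rows_dict(matrix):
    return {g: matrix.data.loc[g].tolist() for g in matrix.data.index}


class TestDeltaCt:
    def test_hand_enumeration(self, small_matrix):
        """Pair SDs of A=(20,20,20), B=(22,23,24), C=(25,25,26) are
        (AB 1.000, AC 0.577, BC 0.577) giving values (0.789, 0.789, 0.577)."""
        res = delta_ct_stability(small_matrix)
        assert res.values["A"] == pytest.approx(0.7887, abs=2e-4)
        assert res.values["B"] == pytest.approx(0.7887, abs=2e-4)
        assert res.values["C"] == pytest.approx(0.5774, abs=2e-4)
        assert res.ranks["C"] == 1 and res.ranks["A"] == 2 and res.ranks["B"] == 2

    def test_duplicated_gene_pair_sd_zero(self):
        m = make_ct_matrix([[20, 21, 22], [20, 21, 22], [25, 24, 26]])
        res = delta_ct_stability(m)
        # the duplicated pair only carries the SD against gene 3
        third = np.std(np.array([20, 21, 22]) - np.array([25, 24, 26]), ddof=1)
        assert res.values["G01"] == pytest.approx(third / 2)

    def test_matches_brute_force(self, rng):
        m = random_ct_matrix(rng, k=6, n=8)
        res = delta_ct_stability(m)
        expected = oracles.naive_pairwise_sd_mean(rows_dict(m))
        for g in m.data.index:
            assert res.values[g] == pytest.approx(expected[g], abs=1e-12)

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            delta_ct_stability(make_ct_matrix([[20, 21], [22, 23], [24, 25]]))


class TestBestKeeper:
    def test_constant_gene_most_stable(self):
        m = make_ct_matrix([[22, 22, 22], [20, 24, 22], [25, 26, 27]])
        res = bestkeeper_stats(m)
        assert res.values["G01"] == 0.0
        assert res.ranks["G01"] == 1
        assert bool(res.table.loc["G01", "r_undefined"])
        assert not res.table.loc["G01", "unstable"]

    def test_hand_arithmetic(self):
        m = make_ct_matrix([[20, 22, 24], [21, 21, 21], [23, 24, 25]])
        res = bestkeeper_stats(m)
        row = res.table.loc["G01"]
        assert row["arith_mean"] == pytest.approx(22.0)
        assert row["sd"] == pytest.approx(4.0 / 3.0)
        assert row["min_ct"] == 20 and row["max_ct"] == 24
        sd_flavor = bestkeeper_stats(m, sd_flavor="sample_sd")
        assert sd_flavor.table.loc["G01", "sd"] == pytest.approx(2.0)

    def test_sd_cutoff_flags_unstable(self):
        m = make_ct_matrix([[20.0, 23.6, 21.2], [21, 21, 21.1], [22, 22, 22.1]])
        res = bestkeeper_stats(m)
        assert res.table.loc["G01", "sd"] > 1
        assert bool(res.table.loc["G01", "unstable"])
        assert not res.table.loc["G02", "unstable"]

    def test_matches_brute_force(self, rng):
        m = random_ct_matrix(rng, k=5, n=6)
        res = bestkeeper_stats(m)
        expected = oracles.naive_bestkeeper(rows_dict(m))
        assert np.allclose(res.extras["index"], expected["_index"], atol=1e-10)
        for g in m.data.index:
            for col in ("geo_mean", "arith_mean", "min_ct", "max_ct", "sd", "cv_pct", "r"):
                assert res.table.loc[g, col] == pytest.approx(
                    expected[g][col], abs=1e-10
                ), (g, col)


class TestNormFinder:
    def test_symmetric_panel_has_equal_rho_and_centered_group_means(self, rng):
        """iid genes with equal variance: no gene stands out (rho values stay
        within a factor of 3 of each other — the |shrunken difference| term
        carries real Monte-Carlo scatter) and the centered values sum to zero
        per sample exactly."""
        ct = 24 + rng.normal(0, 0.5, (6, 200)) + rng.normal(0, 1.0, 200)
        m = make_ct_matrix(ct, groups=["g1"] * 100 + ["g2"] * 100)
        res, internals = normfinder_stability(m, grouped=True)
        assert np.allclose(internals.z.sum(axis=0), 0.0, atol=1e-9)
        assert np.allclose(internals.d.sum(axis=0), 0.0, atol=1e-9)
        assert res.values.max() < 3 * res.values.min()
        assert res.values.max() < 0.2  # all small: sigma=0.5 over n=100

    def test_group_biased_gene_ranked_worst(self):
        """A +1-cycle offset in one of two groups makes that gene the least
        stable in >= 95% of 200 seeded simulations."""
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            ct = 24 + rng.normal(0, 0.3, (6, 12)) + rng.normal(0, 0.8, 12)
            ct[0, 6:] += 1.0
            m = make_ct_matrix(ct, groups=["g1"] * 6 + ["g2"] * 6)
            res, _ = normfinder_stability(m, grouped=True)
            hits += res.values.idxmax() == "G01"
        assert hits >= 190

    def test_intragroup_estimator_calibration(self):
        """Mean of the bias-corrected intragroup variance over 1000 reps is
        within 10% of the true variance for each of k=6 genes.

        The design keeps every sigma well above its estimator's sampling
        noise (sigma >= 0.3, 40 samples) so the non-negativity clamp almost
        never engages; at tiny sigma the clamp would inflate the mean."""
        sigma = np.array([0.3, 0.4, 0.5, 0.7, 0.9, 1.2])
        rng = np.random.default_rng(42)
        acc = np.zeros(6)
        reps = 1000
        for _ in range(reps):
            ct = (
                24
                + rng.normal(0, 1.0, 40)  # sample effects, removed by centering
                + rng.normal(0, 1.0, (6, 40)) * sigma[:, None]
            )
            m = make_ct_matrix(ct)
            _, internals = normfinder_stability(m, grouped=False)
            acc += internals.sigma2["all"].to_numpy()
        mean_est = acc / reps
        assert np.allclose(mean_est, sigma**2, rtol=0.10)

    def test_matches_brute_force_grouped_and_ungrouped(self, rng):
        m = random_ct_matrix(rng, k=5, n=6, n_groups=2)
        res_u, _ = normfinder_stability(m, grouped=False)
        exp_u = oracles.naive_normfinder_ungrouped(rows_dict(m))
        res_g, _ = normfinder_stability(m, grouped=True)
        exp_g = oracles.naive_normfinder_grouped(rows_dict(m), m.groups.tolist())
        for g in m.data.index:
            assert res_u.values[g] == pytest.approx(exp_u[g], abs=1e-10)
            assert res_g.values[g] == pytest.approx(exp_g[g], abs=1e-10)

    def test_requires_three_genes(self):
        with pytest.raises(InsufficientDataError):
            normfinder_stability(make_ct_matrix([[20, 21, 22], [23, 24, 25]]), grouped=False)

    def test_single_sample_group_rejected(self):
        m = make_ct_matrix(np.random.default_rng(0).uniform(20, 25, (4, 5)),
                           groups=["a", "a", "a", "a", "b"])
        with pytest.raises(InsufficientDataError, match="b"):
            normfinder_stability(m, grouped=True)


class TestGenorm:
    def test_full_panel_m_equals_delta_ct_at_e2(self, rng):
        m = random_ct_matrix(rng, k=7, n=9)
        logq = ct_to_log_quantity(m)
        mvals = genorm_m_values(logq)
        dct = delta_ct_stability(m)
        assert np.allclose(mvals.to_numpy(), dct.values.to_numpy(), atol=1e-12)

    def test_matches_brute_force(self, rng):
        m = random_ct_matrix(rng, k=5, n=6)
        logq = ct_to_log_quantity(m)
        expected = oracles.naive_pairwise_sd_mean(
            {g: logq.loc[g].tolist() for g in logq.index}
        )
        got = genorm_m_values(logq)
        for g in logq.index:
            assert got[g] == pytest.approx(expected[g], abs=1e-12)

    def test_noisiest_gene_excluded_first(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            ct = np.vstack(
                [
                    24 + rng.normal(0, 0.1, 8),
                    23 + rng.normal(0, 0.1, 8),
                    25 + rng.normal(0, 1.0, 8),  # double-digit noise gene
                ]
            )
            m = make_ct_matrix(ct, genes=["A", "B", "C"])
            res = genorm_rank(ct_to_log_quantity(m))
            hits += res.exclusion_order[0] == "C"
            assert res.final_pair == ("A", "B") or res.exclusion_order[0] != "C"
        assert hits >= 47

    def test_degenerate_identical_panel(self):
        m = make_ct_matrix(np.tile([20.0, 21.0, 22.0, 23.0], (4, 1)))
        res = genorm_rank(ct_to_log_quantity(m))
        assert res.degenerate
        # lexicographically-last tie rule: G04 leaves first, then G03
        assert res.exclusion_order == ["G04", "G03"]
        assert res.final_pair == ("G01", "G02")

    def test_exclusion_order_matches_brute_force(self, rng):
        for _ in range(5):
            m = random_ct_matrix(rng, k=6, n=8)
            logq = ct_to_log_quantity(m)
            res = genorm_rank(logq)
            exp_order, exp_pair = oracles.naive_genorm_exclusion(
                {g: logq.loc[g].tolist() for g in logq.index}
            )
            assert res.exclusion_order == exp_order
            assert res.final_pair == exp_pair

    def test_v2_zero_for_identical_top_genes(self):
        ct = np.vstack([
            np.array([20, 21, 22, 23.0]),
            np.array([20, 21, 22, 23.0]) + 1.0,
            np.array([20, 21, 22, 23.0]) + 2.0,
            [25, 24, 26, 23.0],
        ])
        m = make_ct_matrix(ct)
        logq = ct_to_log_quantity(m)
        v = genorm_pairwise_variation(logq, ["G01", "G02", "G03", "G04"])
        assert v["v_series"][2] == pytest.approx(0.0, abs=1e-12)

    def test_v_series_matches_brute_force(self, rng):
        m = random_ct_matrix(rng, k=6, n=8)
        logq = ct_to_log_quantity(m)
        res = genorm_rank(logq)
        expected = oracles.naive_v_series(
            {g: logq.loc[g].tolist() for g in logq.index}, res.ranking
        )
        for n, val in expected.items():
            assert res.v_series[n] == pytest.approx(val, abs=1e-12)

    def test_all_v_below_cutoff_recommends_two(self):
        rng = np.random.default_rng(1)
        ct = 24 + rng.normal(0, 0.05, (6, 10)) + rng.normal(0, 1.0, 10)
        res = genorm_rank(ct_to_log_quantity(make_ct_matrix(ct)))
        assert (res.v_series < 0.15).all()
        assert res.recommended_n == 2

    def test_final_pair_shares_rank_one(self, rng):
        m = random_ct_matrix(rng, k=6, n=8)
        res = genorm_stability(m)
        pair_ranks = res.ranks[list(res.extras.final_pair)]
        assert (pair_ranks == 1).all()
        third = res.extras.ranking[2]
        assert res.ranks[third] == 3


class TestInvariances:
    """Shift/location invariances across the four methods."""

    def _methods(self, m):
        nf, _ = normfinder_stability(m, grouped=True)
        return {
            "delta_ct": delta_ct_stability(m).values,
            "bestkeeper": bestkeeper_stats(m).values,
            "normfinder": nf.values,
            "genorm": genorm_m_values(ct_to_log_quantity(m)),
        }

    def test_per_sample_shift(self, rng):
        """Adding a constant to every gene of one sample (a loading shift)
        leaves delta-Ct, geNorm and NormFinder untouched; BestKeeper sees it."""
        vals = rng.uniform(20, 26, (5, 8))
        groups = ["a"] * 4 + ["b"] * 4
        base = self._methods(make_ct_matrix(vals, groups=groups))
        shifted = vals.copy()
        shifted[:, 1] += 2.0
        after = self._methods(make_ct_matrix(shifted, groups=groups))
        for name in ("delta_ct", "normfinder", "genorm"):
            assert np.allclose(base[name], after[name], atol=1e-9), name
        assert (after["bestkeeper"] > base["bestkeeper"] + 1e-6).any()

    def test_per_gene_shift(self, rng):
        """A constant Ct offset on one gene (primer efficiency scale) leaves
        all four methods' values unchanged."""
        vals = rng.uniform(20, 26, (5, 8))
        groups = ["a"] * 4 + ["b"] * 4
        base = self._methods(make_ct_matrix(vals, groups=groups))
        shifted = vals.copy()
        shifted[2] += 3.0
        after = self._methods(make_ct_matrix(shifted, groups=groups))
        for name, series in base.items():
            assert np.allclose(series, after[name], atol=1e-9), name

    def test_values_non_negative_ranks_are_competition(self, rng):
        m = random_ct_matrix(rng, k=7, n=9)
        for name, values in self._methods(m).items():
            assert (values.to_numpy() >= 0).all(), name


class TestParameterRecovery:
    def test_stable_genes_found_by_each_method(self):
        """On the default-style simulation, each method puts the designed
        stable genes (sigma 0.1) into its top 5 in >= 95% of 200 seeds."""
        from refstab.qpcr import collapse_replicates

        counts = {"delta_ct": 0, "bestkeeper": 0, "normfinder": 0, "genorm": 0}
        n_runs = 200
        sd = np.empty(12)
        sd[:3] = 0.1
        sd[3:8] = np.linspace(0.5, 1.5, 5)
        sd[8:] = 0.3
        b = np.zeros((12, 3))
        b[8:, 2] = np.array([-1.0, 1.0, -1.0, 1.0]) * np.linspace(0.5, 2.0, 4)
        for seed in range(n_runs):
            cfg = SimulationConfig(
                n_genes=12, gene_noise_sd=sd, group_effect=b, seed=seed,
            )
            table, _ = simulate_ct_dataset(cfg)
            m = collapse_replicates(table)
            stable = {"HKG01", "HKG02", "HKG03"}
            nf, _ = normfinder_stability(m, grouped=True)
            tops = {
                "delta_ct": delta_ct_stability(m).values.nsmallest(5).index,
                "bestkeeper": bestkeeper_stats(m).values.nsmallest(5).index,
                "normfinder": nf.values.nsmallest(5).index,
                "genorm": genorm_m_values(ct_to_log_quantity(m)).nsmallest(5).index,
            }
            for name, top in tops.items():
                counts[name] += stable <= set(top)
        for name, c in counts.items():
            assert c >= 0.95 * n_runs, (name, c)
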