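"""Paired tests and the Westfall-Young maxT sign-flip permutation machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import twinmeth as tm
from twinmeth.differential import DegenerateTestError

from conftest import make_beta, make_paired_design


class TestPairedDifferences:
    def test_identical_cotwins_give_zero_vectors(self):
        design = make_paired_design(3)
        values = np.tile(np.linspace(0.1, 0.9, 4)[:, None], (1, 6))
        beta = make_beta(values, sample_ids=list(design.samples.index))
        diffs = tm.paired_differences(beta, design)
        assert (diffs == 0).all().all()

    def test_sign_convention_t2d_minus_control(self):
        design = make_paired_design(2)
        values = np.array([[0.139, 0.090, 0.5, 0.5]])
        beta = make_beta(values, sample_ids=list(design.samples.index))
        diffs = tm.paired_differences(beta, design)
        assert diffs.loc["p0", "pair01"] == pytest.approx(4.9)

    def test_masked_twin_removes_only_that_pair_probe(self):
        design = make_paired_design(3)
        rng = np.random.default_rng(1)
        values = rng.uniform(0, 1, (4, 6))
        values[2, 0] = np.nan  # pair01_T2D at probe p2
        beta = make_beta(values, sample_ids=list(design.samples.index))
        diffs = tm.paired_differences(beta, design)
        assert np.isnan(diffs.loc["p2", "pair01"])
        assert diffs.drop(index="p2").notna().all().all()
        assert diffs.loc["p2"].drop("pair01").notna().all()

    def test_probes_below_min_pairs_dropped(self):
        design = make_paired_design(3)
        values = np.full((2, 6), 0.5)
        values[0, :4] = np.nan  # probe p0 keeps only one complete pair
        beta = make_beta(values, sample_ids=list(design.samples.index))
        diffs = tm.paired_differences(beta, design)
        assert list(diffs.index) == ["p1"]


class TestPairedT:
    def test_antisymmetric_vector_is_exact_null(self):
        mean, t, p = tm.paired_t([-2.0, 2.0, -5.0, 5.0])
        assert mean == 0.0 and t == 0.0 and p == pytest.approx(1.0)

    def test_zero_variance_nonzero_mean_signalled(self):
        with pytest.raises(DegenerateTestError):
            tm.paired_t([5.0, 5.0, 5.0, 5.0, 5.0])

    def test_all_zero_vector_is_null(self):
        mean, t, p = tm.paired_t([0.0, 0.0, 0.0])
        assert (mean, t, p) == (0.0, 0.0, 1.0)

    def test_arithmetic_oracle_one_to_five(self):
        """t for {1..5} equals mean/(sd/sqrt(5)) computed by hand."""
        mean, t, p = tm.paired_t([1.0, 2.0, 3.0, 4.0, 5.0])
        sd = np.std([1, 2, 3, 4, 5], ddof=1)  # 1.5811
        assert mean == pytest.approx(3.0)
        assert t == pytest.approx(3.0 / (sd / np.sqrt(5)), abs=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(t, 4), abs=1e-12)

    def test_too_short_vector_rejected(self):
        with pytest.raises(ValueError):
            tm.paired_t([1.0])


class TestShapiroFraction:
    def test_normal_differences_reject_at_nominal_rate(self):
        rng = np.random.default_rng(2)
        diffs = pd.DataFrame(rng.normal(0, 5, (2000, 11)))
        frac, pvals = tm.shapiro_fraction(diffs)
        se = np.sqrt(0.05 * 0.95 / 2000)
        assert frac == pytest.approx(0.05, abs=4 * se)

    def test_skewed_differences_reject_much_more(self):
        rng = np.random.default_rng(3)
        diffs = pd.DataFrame(rng.exponential(5, (500, 11)) ** 2)
        frac, _ = tm.shapiro_fraction(diffs)
        assert frac > 0.5

    def test_fixed_vector_matches_r_reference(self):
        """SW statistic for a fixed 11-vector agrees with R shapiro.test."""
        d = pd.DataFrame(
            [[4.9, -1.2, 2.2, 3.1, 0.3, -0.1, 9.3, -3.4, 5.0, -4.8, 7.3]],
            index=["probe"],
        )
        _, pvals = tm.shapiro_fraction(d)
        w = stats.shapiro(d.loc["probe"]).statistic
        assert w == pytest.approx(0.9807861978, abs=1e-6)
        assert pvals["probe"] == pytest.approx(0.9703748241, abs=1e-4)

    def test_short_vectors_counted_as_untestable(self):
        diffs = pd.DataFrame(
            {"pair01": [1.0, 2.0], "pair02": [2.0, np.nan], "pair03": [3.0, np.nan]},
            index=["ok", "short"],
        )
        frac, pvals = tm.shapiro_fraction(diffs)
        assert np.isnan(pvals["short"]) and not np.isnan(pvals["ok"])


def brute_force_maxT(diffs: pd.DataFrame) -> pd.Series:
    """Exhaustive step-down maxT written as plain loops over sign tuples."""
    d = diffs.to_numpy()
    m, n = d.shape

    def tstat(vec):
        sd = vec.std(ddof=1)
        if sd == 0:
            return 0.0 if vec.mean() == 0 else np.inf
        return abs(vec.mean() / (sd / np.sqrt(len(vec))))

    t_obs = np.array([tstat(d[j]) for j in range(m)])
    order = np.argsort(-t_obs, kind="stable")
    counts = np.zeros(m)
    total = 0
    for signs in itertools.product([1, -1], repeat=n):
        flipped = d * np.array(signs)
        t_perm = np.array([tstat(flipped[j]) for j in range(m)])
        # successive maxima over the |t|-ordered probes, least significant up
        running = -np.inf
        succ = np.empty(m)
        for rank in range(m - 1, -1, -1):
            running = max(running, t_perm[order[rank]])
            succ[rank] = running
        for rank in range(m):
            if succ[rank] >= t_obs[order[rank]] - 1e-12:
                counts[rank] += 1
        total += 1
    p_sorted = counts / total
    p_sorted = np.minimum.accumulate(p_sorted[::-1])[::-1]
    out = np.empty(m)
    out[order] = p_sorted
    return pd.Series(out, index=diffs.index)


class TestWestfallYoung:
    def test_single_probe_equals_sign_flip_permutation_p(self):
        rng = np.random.default_rng(4)
        d = pd.DataFrame(rng.normal(1.0, 2.0, (1, 8)), index=["p"])
        res = tm.westfall_young_maxT(d, tm.PermutationPlan(mode="exhaustive"))
        vec = d.loc["p"].to_numpy()
        t_obs = abs(vec.mean() / (vec.std(ddof=1) / np.sqrt(8)))
        count = 0
        for signs in itertools.product([1, -1], repeat=8):
            f = vec * np.array(signs)
            t = abs(f.mean() / (f.std(ddof=1) / np.sqrt(8)))
            count += t >= t_obs - 1e-12
        assert res.loc["p", "p_adj"] == pytest.approx(count / 256)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        d = pd.DataFrame(rng.normal(0.5, 1.0, (6, 6)),
                         index=[f"p{i}" for i in range(6)])
        expected = brute_force_maxT(d)
        res = tm.westfall_young_maxT(d, tm.PermutationPlan(mode="exhaustive"))
        np.testing.assert_allclose(res["p_adj"], expected, atol=1e-12)

    def test_step_down_monotone_and_adjusted_geq_raw(self):
        rng = np.random.default_rng(6)
        d = pd.DataFrame(rng.normal(0.3, 1.0, (30, 11)))
        res = tm.westfall_young_maxT(d, tm.PermutationPlan(mode="exhaustive"))
        ordered = res.sort_values("abs_t", ascending=False)
        assert (np.diff(ordered["p_adj"]) >= -1e-12).all()
        assert (res["p_adj"] >= res["p_perm_raw"] - 1e-12).all()

    def test_sign_symmetry(self):
        """Negating every difference vector leaves |t| and all P unchanged."""
        rng = np.random.default_rng(7)
        d = pd.DataFrame(rng.normal(0.5, 1.0, (10, 9)))
        a = tm.westfall_young_maxT(d, tm.PermutationPlan(mode="exhaustive"))
        b = tm.westfall_young_maxT(-d, tm.PermutationPlan(mode="exhaustive"))
        np.testing.assert_allclose(a["abs_t"], b["abs_t"])
        np.testing.assert_allclose(a["p_adj"], b["p_adj"])

    def test_sampled_converges_to_exhaustive(self):
        """B = 10,000 random flips reproduce the exhaustive 2^11 adjusted
        P-values within binomial Monte-Carlo error on 50 probes."""
        rng = np.random.default_rng(8)
        d = pd.DataFrame(rng.normal(0.8, 2.0, (50, 11)))
        exact = tm.westfall_young_maxT(d, tm.PermutationPlan(mode="exhaustive"))
        sampled = tm.westfall_young_maxT(
            d, tm.PermutationPlan(mode="sampled", B=10_000, seed=1)
        )
        p = exact["p_adj"].to_numpy()
        tol = 3 * np.sqrt(p * (1 - p) / 10_000) + 2 / 10_000
        assert (np.abs(sampled["p_adj"].to_numpy() - p) <= tol + 1e-12).all()

    def test_missing_pairs_use_complete_pair_statistics(self):
        rng = np.random.default_rng(9)
        d = pd.DataFrame(rng.normal(0.5, 1.0, (5, 8)))
        d.iloc[0, 3] = np.nan
        res = tm.westfall_young_maxT(d, tm.PermutationPlan(mode="exhaustive"))
        vec = d.iloc[0].dropna().to_numpy()
        t_expected = abs(vec.mean() / (vec.std(ddof=1) / np.sqrt(len(vec))))
        assert res["abs_t"].iloc[0] == pytest.approx(t_expected)

    def test_exhaustive_over_cap_rejected(self):
        d = pd.DataFrame(np.random.default_rng(0).normal(0, 1, (2, 20)))
        with pytest.raises(ValueError, match="cap"):
            tm.westfall_young_maxT(d, tm.PermutationPlan(mode="exhaustive"))


class TestAnalysisScoping:
    def test_effect_outside_candidates_leaves_candidate_results_unchanged(
        self, small_manifest
    ):
        manifest, _ = small_manifest
        non_candidate = manifest.table.index[~manifest.table["candidate"]][0]
        cfg0 = tm.SimulationConfig(n_pairs=8, n_probes=100)
        cfg1 = tm.SimulationConfig(n_pairs=8, n_probes=100,
                                   effect_sites={non_candidate: 20.0})
        plan = tm.PermutationPlan(mode="exhaustive")
        out = []
        for cfg in (cfg0, cfg1):
            beta, design, _ = tm.generate_twin_beta(manifest, cfg, seed=10)
            res, _ = tm.run_candidate_analysis(beta, design, manifest, plan=plan)
            out.append(res)
        pd.testing.assert_frame_equal(out[0], out[1])

    def test_genome_wide_uses_only_retained_probes(self, small_manifest):
        manifest, _ = small_manifest
        beta, design, _ = tm.generate_twin_beta(
            manifest, tm.SimulationConfig(n_pairs=6, n_probes=100), seed=11
        )
        res, counts = tm.run_genome_wide(
            beta, design, manifest, plan=tm.PermutationPlan(mode="exhaustive")
        )
        assert counts["n_probes"] == 92  # 100 - 5 multi - 3 snp
        flagged = manifest.table.index[
            manifest.table["multi_aligned"] | manifest.table["snp_in_cpg"]
        ]
        assert not set(res.index) & set(flagged)

    def test_null_raw_significance_near_nominal(self, small_manifest):
        manifest, _ = small_manifest
        rates = []
        for seed in range(5):
            beta, design, _ = tm.generate_twin_beta(
                manifest, tm.SimulationConfig(n_pairs=11, n_probes=100), seed=seed
            )
            res, counts = tm.run_genome_wide(
                beta, design, manifest, plan=tm.PermutationPlan(mode="exhaustive")
            )
            rates.append(counts["n_raw_significant"] / counts["n_probes"])
        mean_rate = np.mean(rates)
        se = np.sqrt(0.05 * 0.95 / (5 * 92))
        assert mean_rate == pytest.approx(0.05, abs=4 * se)
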