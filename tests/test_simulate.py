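"""Generator behaviour: determinism, calibration structure, ground truth."""

import io

import numpy as np
import pandas as pd
import pytest

import twinmeth as tm
from twinmeth.simulate import CANDIDATE_GENES

from conftest import make_paired_design


class TestProbeManifest:
    def test_counts_and_flags(self, small_manifest):
        manifest, _ = small_manifest
        tab = manifest.table
        assert tab["multi_aligned"].sum() == 5
        assert tab["snp_in_cpg"].sum() == 3
        assert (tab["multi_aligned"] & tab["snp_in_cpg"]).sum() == 0
        assert tab["candidate"].sum() == 10
        assert set(tab.loc[tab["candidate"], "gene_symbol"]) <= set(CANDIDATE_GENES)

    def test_no_flags_all_retained(self):
        manifest, _ = tm.generate_probe_manifest(10, 0, 0, 0, seed=1)
        kept, report = tm.qc_filter(manifest)
        assert report.n_retained == 10 and len(kept.table) == 10

    def test_same_seed_byte_identical(self, tmp_path):
        outs = []
        for _ in range(2):
            manifest, ref = tm.generate_probe_manifest(50, 4, 2, 5, seed=42)
            buf = io.StringIO()
            manifest.table.to_csv(buf, sep="\t")
            outs.append((buf.getvalue(), ref))
        assert outs[0] == outs[1]

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ValueError):
            tm.generate_probe_manifest(10, 8, 5, 0, seed=0)
        with pytest.raises(ValueError):
            tm.generate_probe_manifest(10, 2, 2, 9, seed=0)

    def test_sequences_embedded_in_reference(self, small_manifest):
        """Every probe's converted segment occurs in the converted reference;
        multi-flagged probes occur at least twice."""
        manifest, reference = small_manifest
        forward = reference.replace("C", "T")
        for probe, row in manifest.table.head(20).iterrows():
            n = forward.count(row["probe_sequence"])
            assert n >= (2 if row["multi_aligned"] else 1)


class TestTwinBeta:
    def test_values_within_unit_interval(self, twin_data):
        beta, _, _ = twin_data
        arr = beta.values.to_numpy()
        assert np.nanmin(arr) >= 0 and np.nanmax(arr) <= 1

    def test_zero_noise_makes_cotwins_identical(self, small_manifest):
        manifest, _ = small_manifest
        cfg = tm.SimulationConfig(n_pairs=4, n_probes=50, sigma_ind=0.0)
        beta, design, _ = tm.generate_twin_beta(manifest, cfg, seed=3)
        for pair, cols in design.pair_columns().iterrows():
            np.testing.assert_array_equal(
                beta.values[cols["t2d"]], beta.values[cols["control"]]
            )

    def test_seed_reproducibility(self, small_manifest):
        manifest, _ = small_manifest
        a = tm.generate_twin_beta(manifest, tm.MUSCLE_CONFIG, seed=9)[0]
        b = tm.generate_twin_beta(manifest, tm.MUSCLE_CONFIG, seed=9)[0]
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_effect_injection_does_not_perturb_latent_world(self, small_manifest):
        """The same seed yields identical non-effect probes whatever
        effect_sites requests, so effects are cleanly attributable."""
        manifest, _ = small_manifest
        probe = manifest.table.index[0]
        cfg0 = tm.SimulationConfig(n_pairs=5, n_probes=50)
        cfg1 = tm.SimulationConfig(n_pairs=5, n_probes=50,
                                   effect_sites={probe: 10.0})
        b0 = tm.generate_twin_beta(manifest, cfg0, seed=4)[0]
        b1 = tm.generate_twin_beta(manifest, cfg1, seed=4)[0]
        pd.testing.assert_frame_equal(b0.values.drop(index=probe),
                                      b1.values.drop(index=probe))

    def test_injected_effect_recovered_at_large_n(self, small_manifest):
        """Mean estimated T2D − nonT2D difference approaches the injected
        effect as the number of pairs grows."""
        manifest, _ = small_manifest
        cfg0 = tm.SimulationConfig(n_pairs=400, n_probes=20)
        _, _, truth = tm.generate_twin_beta(manifest, cfg0, seed=5)
        # mid-methylated probe so [0,1] truncation cannot bias the estimate
        probe = (truth.baseline - 0.5).abs().idxmin()
        cfg = tm.SimulationConfig(
            n_pairs=400, n_probes=20, effect_sites={probe: 6.0}
        )
        beta, design, truth = tm.generate_twin_beta(manifest, cfg, seed=5)
        diffs = tm.paired_differences(beta, design, [probe])
        est = diffs.loc[probe].mean()
        se = 100 * np.sqrt(2) * cfg.sigma_ind / np.sqrt(cfg.n_pairs)
        assert est == pytest.approx(6.0, abs=3.5 * se)

    def test_unknown_effect_site_rejected(self, small_manifest):
        manifest, _ = small_manifest
        cfg = tm.SimulationConfig(effect_sites={"cgFFFFFFFF": 5.0})
        with pytest.raises(KeyError):
            tm.generate_twin_beta(manifest, cfg, seed=0)

    def test_null_type_one_error_calibrated(self, small_manifest):
        """With no injected effects, per-probe paired t-tests reject at
        roughly the nominal 5% rate."""
        manifest, _ = small_manifest
        rejections, total = 0, 0
        for seed in range(10):
            cfg = tm.SimulationConfig(n_pairs=11, n_probes=100)
            beta, design, _ = tm.generate_twin_beta(manifest, cfg, seed=seed)
            diffs = tm.paired_differences(beta, design)
            for _, row in diffs.iterrows():
                _, _, p = tm.paired_t(row)
                rejections += p < 0.05
                total += 1
        rate = rejections / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert rate == pytest.approx(0.05, abs=4 * se)


class TestPhenotypes:
    def test_large_sample_means_match_configuration(self):
        phenos = tm.generate_phenotypes(4000, seed=1)
        bmi = phenos["BMI"].unstack("status")
        assert bmi["nonT2D"].mean() == pytest.approx(30.2, abs=0.4)
        assert bmi["T2D"].mean() == pytest.approx(32.3, abs=0.4)
        assert bmi["nonT2D"].std() == pytest.approx(6.3, rel=0.1)

    def test_zero_sd_collapses_to_means(self, monkeypatch):
        monkeypatch.setattr(
            tm.simulate,
            "PHENOTYPE_PARAMS",
            {"BMI": (30.2, 32.3, 0.0, 0.0)},
        )
        phenos = tm.generate_phenotypes(3, seed=0)
        assert (phenos.xs("T2D", level="status")["BMI"] == 32.3).all()
        assert (phenos.xs("nonT2D", level="status")["BMI"] == 30.2).all()

    def test_seed_reproducibility(self):
        a = tm.generate_phenotypes(12, seed=6)
        b = tm.generate_phenotypes(12, seed=6)
        pd.testing.assert_frame_equal(a, b)


class TestRepeatPanel:
    @staticmethod
    def _panel_cor(design, cfg, seed):
        panel, _ = tm.generate_repeat_panel(design, cfg, seed=seed)
        summary = tm.intrapair_variation_sd(
            panel.elements["LINE1"], design, scope="per_pair", label="LINE1"
        )
        return tm.correlate_variation_phenotype(
            summary, design.phenotype_delta("BMI")
        )[0]

    @staticmethod
    def _design(n_pairs, seed):
        design = make_paired_design(n_pairs)
        return tm.StudyDesign(design.samples,
                              tm.generate_phenotypes(n_pairs, seed=seed))

    def test_zero_coupling_gives_no_correlation(self):
        cfg = tm.SimulationConfig(repeat_coupling=0.0)
        rs = [self._panel_cor(self._design(20, s), cfg, seed=s) for s in range(15)]
        assert abs(np.mean(rs)) < 0.12  # ~2 SE of a null mean over 15 x 20 pairs

    def test_coupled_correlation_matches_direct_simulation_oracle(self):
        """The per-pair SD vs |ΔBMI| correlation of the generator at
        n_pairs=200 (averaged over seeds) agrees with a large Monte-Carlo
        simulation of the same generative equations written independently
        below."""
        cfg = tm.SimulationConfig()
        observed = np.mean(
            [self._panel_cor(self._design(200, s), cfg, seed=s + 100)
             for s in range(6)]
        )

        # independent oracle: simulate the model's per-pair quantities directly
        rng = np.random.default_rng(123)
        n = 100_000
        rho, sd_c, sd_t = 0.6, 6.3, 6.4
        shared = rng.normal(0, 1, n)
        z_t = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.normal(0, 1, n)
        z_c = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.normal(0, 1, n)
        dbmi = np.abs((32.3 + sd_t * z_t) - (30.2 + sd_c * z_c))
        scale = np.maximum(
            cfg.repeat_base + cfg.repeat_coupling * dbmi
            + rng.normal(0, cfg.repeat_noise, n),
            0.5,
        )
        site_base = 70.0 + rng.normal(0, 5.0, (n, 8))  # 8 LINE1 sites
        shared_site = site_base + rng.normal(0, 3.0, (n, 8))
        s2 = scale[:, None] / np.sqrt(2.0)
        twin_a = np.clip(shared_site + rng.normal(0, 1, (n, 8)) * s2, 0, 100)
        twin_b = np.clip(shared_site + rng.normal(0, 1, (n, 8)) * s2, 0, 100)
        sd_pair = np.abs(twin_a - twin_b).std(axis=1, ddof=1)
        expected = np.corrcoef(sd_pair, dbmi)[0, 1]
        assert observed == pytest.approx(expected, abs=0.05)

    def test_repeat_variation_exceeds_promoter_variation(self, twin_data):
        beta, design, _ = twin_data
        panel, _ = tm.generate_repeat_panel(design, tm.MUSCLE_CONFIG, seed=2)
        rep = tm.intrapair_variation_sd(panel.pooled(), design, scope="pooled",
                                        label="repeats_all")
        prom = tm.intrapair_variation_sd(beta, design, scope="pooled",
                                         label="promoters")
        assert rep.sd > prom.sd

    def test_percentages_bounded(self, twin_data):
        _, design, _ = twin_data
        panel, _ = tm.generate_repeat_panel(design, tm.MUSCLE_CONFIG, seed=3)
        for frame in panel.elements.values():
            assert frame.min().min() >= 0 and frame.max().max() <= 100


class TestCloneTable:
    def test_extremes(self):
        full = tm.generate_clone_table({"s1": 100.0, "s2": 100.0}, 12, seed=0)
        assert (full.counts["n_methylated"] == 12).all()
        none = tm.generate_clone_table({"s1": 0.0}, 12, seed=0)
        assert (none.counts["n_methylated"] == 0).all()

    def test_binomial_mean(self):
        """At 50% truth with 12 clones the mean methylated count is 6,
        within binomial standard error over 10^4 sites."""
        sites = {f"s{i}": 50.0 for i in range(10_000)}
        table = tm.generate_clone_table(sites, 12, seed=4)
        mean = table.counts["n_methylated"].mean()
        se = np.sqrt(12 * 0.25 / 10_000)
        assert mean == pytest.approx(6.0, abs=4 * se)

    def test_clone_totals_conserved(self):
        table = tm.generate_clone_table({"a": 30.0, "b": 70.0}, n_clones=9, seed=1)
        assert (table.n_clones == 9).all()
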