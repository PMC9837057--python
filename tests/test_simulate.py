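import numpy as np
import pytest

from sexstrat.simulate import (
    SimConfig,
    marginal_association,
    simulate_coloc_scenario,
    simulate_genotypes,
    simulate_h2_estimates,
    simulate_mr_scenario,
    simulate_sex_stratified_gwas,
)
from sexstrat.sexdiff import sex_difference_z
from oracles import ols_slope


def _r2(dosages):
    r = np.corrcoef(dosages.astype(float), rowvar=False)
    return r * r


class TestGenotypes:
    def test_same_seed_is_bit_identical(self):
        cfg = SimConfig(n_male=200, m=20, seed=11)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_no_ld_when_rho_zero(self):
        cfg = SimConfig(n_male=2000, m=50, ld_rho=0.0, seed=5)
        panel = simulate_genotypes(cfg)
        r2 = _r2(panel.dosages)
        off = r2[np.triu_indices(50, k=1)]
        assert off.mean() < 0.01

    def test_high_rho_gives_decaying_ld(self):
        cfg = SimConfig(n_male=2000, m=50, ld_rho=0.9, block_size=50, seed=6)
        panel = simulate_genotypes(cfg)
        r2 = _r2(panel.dosages)
        adjacent = np.array([r2[i, i + 1] for i in range(49)])
        distant = np.array([r2[i, j] for i in range(50) for j in range(i + 5, 50)])
        assert adjacent.mean() > distant.mean()

    def test_blocks_are_independent(self):
        cfg = SimConfig(n_male=3000, m=20, ld_rho=0.9, block_size=10, seed=7)
        panel = simulate_genotypes(cfg)
        r2 = _r2(panel.dosages)
        cross = r2[:10, 10:]
        assert cross.mean() < 0.01

    def test_realized_maf_close_to_target(self):
        cfg = SimConfig(n_male=4000, m=40, maf_range=(0.05, 0.5), seed=8)
        panel = simulate_genotypes(cfg)
        from sexstrat.simulate import _target_mafs
        assert np.max(np.abs(panel.maf - _target_mafs(cfg))) < 0.05


class TestMarginalAssociation:
    def test_tiny_fixture_matches_normal_equations(self):
        g = np.array([[0.0], [1.0], [2.0], [1.0]], dtype=np.int8)
        y = np.array([0.1, 1.1, 2.0, 0.9])
        from sexstrat.simulate import GenotypePanel
        import pandas as pd
        panel = GenotypePanel(
            dosages=g,
            keys=pd.DataFrame({"variant_id": ["1:100:A:G"], "chrom": "1", "pos": [100],
                               "effect_allele": ["A"], "other_allele": ["G"]}),
            maf=np.array([0.25]),
        )
        table = marginal_association(y, panel)
        slope, _, se = ols_slope(g[:, 0], y)
        assert table.df["beta"].iloc[0] == pytest.approx(slope, abs=1e-12)
        assert table.df["se"].iloc[0] == pytest.approx(se, abs=1e-12)

    def test_perfect_fit_clamps_instead_of_zero(self):
        cfg = SimConfig(n_male=100, m=5, ld_rho=0.0, seed=9)
        panel = simulate_genotypes(cfg)
        y = panel.dosages[:, 2].astype(float)
        table = marginal_association(y, panel)
        row = table.df[table.df["pos"] == panel.keys["pos"][2]].iloc[0]
        assert row["beta"] == pytest.approx(1.0)
        assert row["se"] > 0 and row["pval"] > 0

    def test_type_one_error_near_nominal(self):
        cfg = SimConfig(n_male=500, m=1000, ld_rho=0.0, seed=10)
        panel = simulate_genotypes(cfg)
        rng = np.random.default_rng(123)
        y = rng.normal(size=500)
        table = marginal_association(y, panel)
        frac = float((table.df["pval"] < 0.05).mean())
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_analytic_se_matches_empirical_sd(self):
        cfg = SimConfig(n_male=300, m=3, ld_rho=0.0, seed=12)
        panel = simulate_genotypes(cfg)
        rng = np.random.default_rng(99)
        betas, ses = [], []
        for _ in range(500):
            y = rng.normal(size=300)
            t = marginal_association(y, panel)
            betas.append(t.df["beta"].to_numpy())
            ses.append(t.df["se"].to_numpy())
        emp_sd = np.std(np.array(betas), axis=0)
        mean_se = np.mean(np.array(ses), axis=0)
        assert np.all(np.abs(mean_se / emp_sd - 1) < 0.10)

    def test_covariate_adjustment_removes_confounding(self):
        rng = np.random.default_rng(3)
        cfg = SimConfig(n_male=1000, m=5, ld_rho=0.0, seed=13)
        panel = simulate_genotypes(cfg)
        confounder = panel.dosages[:, 0] + rng.normal(size=1000)
        y = 2.0 * confounder + rng.normal(size=1000)
        raw = marginal_association(y, panel)
        adj = marginal_association(y, panel, covariates=confounder[:, None])
        assert raw.df["pval"].iloc[0] < 1e-10       # confounded signal
        assert adj.df["pval"].iloc[0] > 1e-4        # gone after adjustment


class TestSexStratifiedGwas:
    def test_same_seed_identical_tables(self):
        cfg = SimConfig(n_male=300, n_female=300, m=20, seed=21,
                        causal_spec=[(3, 0.3, 0.0)])
        m1, f1, _ = simulate_sex_stratified_gwas(cfg)
        m2, f2, _ = simulate_sex_stratified_gwas(cfg)
        np.testing.assert_array_equal(m1.df["beta"], m2.df["beta"])
        np.testing.assert_array_equal(f1.df["beta"], f2.df["beta"])

    def test_sexes_share_keys_but_not_noise(self):
        cfg = SimConfig(n_male=300, n_female=300, m=20, seed=22)
        m, f, _ = simulate_sex_stratified_gwas(cfg)
        assert m.df["variant_id"].tolist() == f.df["variant_id"].tolist()
        assert not np.allclose(m.df["beta"], f.df["beta"])

    def test_planted_effect_recovered_within_3_se(self):
        hits = 0
        for seed in range(30):
            cfg = SimConfig(n_male=4000, n_female=4000, m=10, ld_rho=0.0, seed=seed,
                            causal_spec=[(4, 0.3, 0.0)])
            m, _, _ = simulate_sex_stratified_gwas(cfg)
            row = m.df.iloc[4]
            hits += abs(row["beta"] - 0.3) < 3 * row["se"]
        assert hits >= 29

    def test_equalize_n_downsamples_larger_sex(self):
        cfg = SimConfig(n_male=500, n_female=200, m=10, seed=23, equalize_n=True)
        m, f, _ = simulate_sex_stratified_gwas(cfg)
        assert m.df["n"].iloc[0] == 200 and f.df["n"].iloc[0] == 200

    def test_binary_liability_threshold(self):
        cfg = SimConfig(n_male=800, n_female=800, m=8, seed=24, ld_rho=0.0,
                        trait_type="binary", prevalence=0.3,
                        causal_spec=[(2, 0.8, 0.8)])
        m, f, _ = simulate_sex_stratified_gwas(cfg)
        assert m.trait_type == "binary"
        assert m.df["n_cases"].iloc[0] == pytest.approx(240, abs=1)
        assert m.df["beta"].iloc[2] > 0  # log-odds effect in the planted direction

    def test_binary_too_few_cases_is_config_error(self):
        cfg = SimConfig(n_male=100, n_female=100, m=8, seed=25,
                        trait_type="binary", prevalence=0.01)
        with pytest.raises(ValueError, match="cases"):
            simulate_sex_stratified_gwas(cfg)


class TestH2Estimates:
    def test_zero_noise_returns_truth(self):
        df = simulate_h2_estimates((0.4, 0.2), (0.0, 0.0), 10, seed=1)
        assert np.all(df["h2_m"] == 0.4) and np.all(df["h2_f"] == 0.2)

    def test_null_z_calibration(self):
        df = simulate_h2_estimates((0.3, 0.3), (0.05, 0.05), 5000, seed=2)
        _, p = sex_difference_z(df["h2_f"], df["se_f"], df["h2_m"], df["se_m"])
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.012)

    def test_alternative_z_centered_at_analytic_value(self):
        # female-minus-male: (0.2 - 0.4) / sqrt(2 * 0.05^2) = -2.8284
        df = simulate_h2_estimates((0.4, 0.2), (0.05, 0.05), 4000, seed=3)
        z, _ = sex_difference_z(df["h2_f"], df["se_f"], df["h2_m"], df["se_m"])
        assert np.mean(z) == pytest.approx(-0.2 / np.sqrt(0.005), abs=0.1)


class TestMrScenario:
    def test_noise_free_proportionality(self):
        exp, out, truth = simulate_mr_scenario(0.5, pleiotropy_mode="none",
                                               se_x=0.0, se_y=0.0, n_inst=10, seed=4)
        np.testing.assert_allclose(out.df["beta"], 0.5 * exp.df["beta"], atol=1e-12)

    def test_directional_mode_shifts_mean_pleiotropy(self):
        _, _, truth = simulate_mr_scenario(0.3, pleiotropy_mode="directional",
                                           alpha_sd=0.01, n_inst=500, seed=5)
        assert truth.alpha.mean() == pytest.approx(0.05, abs=0.005)

    def test_too_few_instruments_rejected(self):
        with pytest.raises(ValueError):
            simulate_mr_scenario(0.3, n_inst=2)

    def test_determinism(self):
        a = simulate_mr_scenario(0.3, seed=6)[0]
        b = simulate_mr_scenario(0.3, seed=6)[0]
        np.testing.assert_array_equal(a.df["beta"], b.df["beta"])


class TestColocScenario:
    def test_modes_place_causals_as_documented(self):
        cfg = SimConfig(n_male=200, n_female=200, m=30, block_size=10, seed=7)
        _, _, shared = simulate_coloc_scenario("shared", cfg)
        assert shared.causal_index_a == shared.causal_index_b is not None
        _, _, distinct = simulate_coloc_scenario("distinct", cfg)
        assert distinct.causal_index_a != distinct.causal_index_b
        assert abs(distinct.causal_index_a - distinct.causal_index_b) >= cfg.block_size
        _, _, single = simulate_coloc_scenario("single_stratum", cfg)
        assert single.causal_index_a is not None and single.causal_index_b is None
        _, _, null = simulate_coloc_scenario("null", cfg)
        assert null.causal_index_a is None

    def test_determinism(self):
        cfg = SimConfig(n_male=200, n_female=200, m=20, seed=8)
        a1 = simulate_coloc_scenario("shared", cfg)[0]
        a2 = simulate_coloc_scenario("shared", cfg)[0]
        np.testing.assert_array_equal(a1.df["beta"], a2.df["beta"])

    def test_small_locus_rejected(self):
        with pytest.raises(ValueError):
            simulate_coloc_scenario("shared", SimConfig(m=5))
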