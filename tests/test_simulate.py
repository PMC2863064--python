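"""Disease-model calibration, LD haplotype model, and dataset simulation."""

import numpy as np
import pytest

from dassomb import (
    SimConfig,
    calibrate,
    genotype_probs_given_status,
    hwe_genotype_probs,
    ld_haplotype_freqs,
    odds_table,
    simulate_dataset,
)

GRID = [(1, 0.3), (2, 0.3), (3, 0.6)]
MAFS = (0.05, 0.1, 0.2, 0.5)


class TestHWEProbs:
    @pytest.mark.parametrize(
        "maf,expected",
        [
            (0.5, (0.25, 0.5, 0.25)),
            (0.0, (1.0, 0.0, 0.0)),
            (0.2, (0.64, 0.32, 0.04)),
        ],
    )
    def test_values(self, maf, expected):
        np.testing.assert_allclose(hwe_genotype_probs(maf), expected)

    def test_sums_to_one(self):
        for maf in np.linspace(0.01, 0.5, 17):
            assert hwe_genotype_probs(maf).sum() == pytest.approx(1.0, abs=1e-12)


class TestOddsTable:
    def test_model1_multiplicative(self):
        t = odds_table(1, 2.0, 0.5)
        assert t[2, 2] == pytest.approx(2.0 * 1.5**4)
        assert t[1, 2] == pytest.approx(2.0 * 1.5**3)

    def test_model2_needs_both_loci(self):
        t = odds_table(2, 2.0, 0.5)
        np.testing.assert_allclose(t[0, :], 2.0)  # first row all baseline
        np.testing.assert_allclose(t[:, 0], 2.0)  # first column all baseline
        assert t[2, 2] == pytest.approx(2.0 * 1.5**4)
        assert t[1, 2] == pytest.approx(2.0 * 1.5**2)

    def test_model3_plateau(self):
        t = odds_table(3, 2.0, 0.5)
        assert t[1, 1] == t[2, 2] == t[1, 2] == pytest.approx(3.0)
        np.testing.assert_allclose(t[0, :], 2.0)

    def test_theta_zero_is_null_model(self):
        np.testing.assert_allclose(odds_table(2, 0.7, 0.0), 0.7)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            odds_table(4, 1.0, 0.5)
        with pytest.raises(ValueError):
            odds_table(1, -1.0, 0.5)
        with pytest.raises(ValueError):
            odds_table(1, 1.0, -1.5)


class TestCalibration:
    @pytest.mark.parametrize("model_id,lambda_", GRID)
    @pytest.mark.parametrize("maf", MAFS)
    def test_self_consistency(self, model_id, lambda_, maf):
        spec = calibrate(model_id, lambda_, maf, prevalence=0.1)
        probs = hwe_genotype_probs(maf)
        prevalence = probs @ spec.penetrance @ probs
        assert prevalence == pytest.approx(0.1, abs=1e-8)
        p_marg = spec.penetrance @ probs
        odds_marg = p_marg / (1 - p_marg)
        assert odds_marg[1] / odds_marg[0] == pytest.approx(1 + lambda_, abs=1e-8)

    def test_lambda_zero_closed_form(self):
        spec = calibrate(1, 0.0, 0.3, prevalence=0.1)
        assert spec.genotypic_effect == pytest.approx(0.0, abs=1e-12)
        assert spec.baseline_effect == pytest.approx(0.1 / 0.9, rel=1e-8)

    def test_penetrance_in_open_unit_interval(self):
        spec = calibrate(3, 0.6, 0.05, prevalence=0.1)
        assert np.all(spec.penetrance > 0) and np.all(spec.penetrance < 1)


class TestConditionalGenotypeProbs:
    def test_tables_sum_to_one(self):
        spec = calibrate(2, 0.3, 0.2)
        case, control = genotype_probs_given_status(spec, 0.2)
        assert case.sum() == pytest.approx(1.0, abs=1e-12)
        assert control.sum() == pytest.approx(1.0, abs=1e-12)

    def test_null_model_matches_hwe_product(self):
        spec = calibrate(1, 0.0, 0.3)
        case, control = genotype_probs_given_status(spec, 0.3)
        probs = hwe_genotype_probs(0.3)
        joint = np.outer(probs, probs)
        np.testing.assert_allclose(case, joint, atol=1e-12)
        np.testing.assert_allclose(control, joint, atol=1e-12)

    @pytest.mark.parametrize("model_id,lambda_", GRID)
    def test_mixture_identity(self, model_id, lambda_):
        maf, prev = 0.2, 0.1
        spec = calibrate(model_id, lambda_, maf, prev)
        case, control = genotype_probs_given_status(spec, maf)
        probs = hwe_genotype_probs(maf)
        joint = np.outer(probs, probs)
        np.testing.assert_allclose(
            prev * case + (1 - prev) * control, joint, atol=1e-10
        )


class TestLDHaplotypes:
    def test_r2_one_same_freq_perfect_copy(self):
        f = ld_haplotype_freqs(0.2, 0.2, 1.0)
        assert f[1] == pytest.approx(0.0, abs=1e-12)  # dM
        assert f[2] == pytest.approx(0.0, abs=1e-12)  # Dm

    def test_r2_zero_linkage_equilibrium(self):
        f = ld_haplotype_freqs(0.2, 0.3, 0.0)
        np.testing.assert_allclose(
            f, [0.06, 0.14, 0.24, 0.56], atol=1e-12
        )

    def test_round_trip_r2(self):
        p_d = p_m = 0.2
        f = ld_haplotype_freqs(p_d, p_m, 0.7)
        d = f[0] - p_d * p_m
        r2 = d**2 / (p_d * (1 - p_d) * p_m * (1 - p_m))
        assert r2 == pytest.approx(0.7, abs=1e-12)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)

    def test_infeasible_combination_raises(self):
        with pytest.raises(ValueError):
            ld_haplotype_freqs(0.05, 0.45, 1.0)


class TestSimulateDataset:
    def test_shapes_and_balance(self):
        cfg = SimConfig(model_id=1, marginal_effect=0.3, maf_disease=0.5, seed=0)
        study = simulate_dataset(cfg)
        d = study.dataset
        assert d.genotypes.shape == (2000, 100)
        assert int(d.phenotype.sum()) == 1000
        assert set(study.truth) <= set(d.snp_ids)
        assert len(set(study.truth)) == 2

    def test_bit_for_bit_determinism(self):
        cfg = SimConfig(model_id=2, marginal_effect=0.3, maf_disease=0.2, seed=9)
        a, b = simulate_dataset(cfg), simulate_dataset(cfg)
        assert a.dataset == b.dataset
        assert a.truth == b.truth

    def test_r2_one_marker_equals_disease_genotype(self):
        cfg = SimConfig(model_id=3, marginal_effect=0.6, maf_disease=0.1, seed=4)
        study = simulate_dataset(cfg)
        for locus, snp in enumerate(study.truth):
            col = study.dataset.genotypes[:, study.dataset.snp_column(snp)]
            np.testing.assert_array_equal(col, study.disease_genotypes[:, locus])

    def test_empirical_penetrance_pattern(self):
        # observed case fraction per genotype cell tracks the calibrated
        # penetrance after reweighting to the case-control design
        cfg = SimConfig(model_id=1, marginal_effect=0.3, maf_disease=0.5, seed=12)
        study = simulate_dataset(cfg)
        d = study.dataset
        ga = d.genotypes[:, d.snp_column(study.truth[0])]
        gb = d.genotypes[:, d.snp_column(study.truth[1])]
        prev = cfg.prevalence
        pen = study.spec.penetrance
        for i in range(3):
            for j in range(3):
                cell = (ga == i) & (gb == j)
                n = int(cell.sum())
                if n < 50:
                    continue
                # P(case | cell) in the 1000/1000 design
                p_case_design = (pen[i, j] / prev) / (
                    pen[i, j] / prev + (1 - pen[i, j]) / (1 - prev)
                )
                observed = d.phenotype[cell].mean()
                se = np.sqrt(p_case_design * (1 - p_case_design) / n)
                assert abs(observed - p_case_design) < 4 * se

    def test_control_maf_near_population_maf(self):
        cfg = SimConfig(model_id=3, marginal_effect=0.6, maf_disease=0.2, seed=21)
        study = simulate_dataset(cfg)
        d = study.dataset
        controls = d.phenotype == 0
        for snp in study.truth:
            col = d.genotypes[controls, d.snp_column(snp)]
            maf_hat = col.mean() / 2
            se = np.sqrt(0.2 * 0.8 / (2 * controls.sum()))
            assert abs(maf_hat - 0.2) < 3.5 * se

    def test_latent_r2_matches_config(self):
        cfg = SimConfig(
            model_id=1, marginal_effect=0.3, maf_disease=0.5, ld_r2=0.7, seed=33,
            n_cases=5000, n_controls=5000, n_markers=2,
        )
        study = simulate_dataset(cfg)
        d = study.dataset
        for locus, snp in enumerate(study.truth):
            marker = d.genotypes[:, d.snp_column(snp)].astype(float)
            latent = study.disease_genotypes[:, locus].astype(float)
            r2_hat = np.corrcoef(marker, latent)[0, 1] ** 2
            assert r2_hat == pytest.approx(0.7, abs=0.03)

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            SimConfig(model_id=1, marginal_effect=0.3, maf_disease=0.6)
        with pytest.raises(ValueError):
            SimConfig(model_id=1, marginal_effect=0.3, maf_disease=0.2, n_markers=1)
        with pytest.raises(ValueError):
            SimConfig(model_id=5, marginal_effect=0.3, maf_disease=0.2)
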