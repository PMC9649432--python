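"""Generator tests: forward-model exactness, noise calibration, genotype
sampling, protein-panel power, and determinism."""

import numpy as np
import pytest
from scipy import stats

from hepatofat.synthetic import (
    GRE_ECHO_TIMES_MS,
    forward_signal,
    gre_protocol,
    ideal_protocol,
    inject_swap_region,
    simulate_cohort,
    simulate_multiecho,
    simulate_parameter_maps,
    simulate_proteome,
    simulate_staging_dataset,
)
from hepatofat.types import Protocol


class TestParameterMaps:
    def test_point_mass_zero_pdff_gives_zero_fat(self):
        maps = simulate_parameter_maps((32, 32), pdff_dist=("point", 0.0), seed=1)
        assert np.all(maps.rho_f == 0)
        assert np.all(maps.rho_w[maps.mask] > 0)

    def test_uniform_pdff_mean_matches_resampling_oracle(self):
        maps = simulate_parameter_maps((64, 64), pdff_dist=("uniform", 0.0, 0.4), seed=7)
        n = int(maps.mask.sum())
        # oracle: mean of U(0, 0.4) is 0.2 with s.e. 0.4/sqrt(12 n)
        se = 0.4 / np.sqrt(12 * n)
        assert abs(maps.pdff()[maps.mask].mean() - 0.2) < 3 * se

    def test_zero_polynomial_gives_zero_field(self):
        maps = simulate_parameter_maps((32, 32), field_poly=(0.0,), seed=0)
        assert np.all(maps.field_map == 0)

    def test_polynomial_field_evaluated_over_coordinates(self):
        maps = simulate_parameter_maps((33, 33), field_poly=(5.0, 2.0, -3.0), seed=0)
        # center voxel has normalized coordinates (0, 0)
        assert maps.field_map[16, 16] == pytest.approx(5.0)

    def test_mask_is_filled_ellipse_inside_frame(self):
        maps = simulate_parameter_maps((48, 40), seed=3)
        assert maps.mask.any()
        assert not maps.mask[0].any() and not maps.mask[-1].any()
        assert not maps.mask[:, 0].any() and not maps.mask[:, -1].any()
        # filled: every row of the mask is a contiguous run
        for row in maps.mask:
            idx = np.where(row)[0]
            if idx.size:
                assert idx.size == idx[-1] - idx[0] + 1

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError):
            simulate_parameter_maps((16, 64), seed=0)
        with pytest.raises(ValueError):
            simulate_parameter_maps((64, 64), r2star_range=(0, 900), seed=0)

    def test_true_pdff_within_unit_interval(self):
        maps = simulate_parameter_maps((32, 32), pdff_dist=("uniform", 0.0, 1.0), seed=2)
        pdff = maps.pdff()
        assert np.all((pdff >= 0) & (pdff <= 1))


class TestMultiEcho:
    def test_noise_free_equals_signal_model(self, voxel_model):
        maps = simulate_parameter_maps((32, 32), pdff_dist=("uniform", 0, 0.4),
                                       r2star_range=(20, 80), field_poly=(10.0, 5.0), seed=5)
        prot = ideal_protocol()
        image = simulate_multiecho(maps, prot, seed=0)
        r, c = 16, 16
        assert maps.mask[r, c]
        expected = voxel_model(
            maps.rho_w[r, c], maps.rho_f[r, c], maps.field_map[r, c],
            maps.r2star[r, c], prot.echo_times_s,
        )
        np.testing.assert_allclose(image.data[r, c], expected, rtol=1e-13, atol=1e-15)

    def test_water_only_no_decay_magnitude_constant(self):
        maps = simulate_parameter_maps((32, 32), pdff_dist=("point", 0.0),
                                       r2star_range=(0, 0), field_poly=(0.0,), seed=1)
        image = simulate_multiecho(maps, gre_protocol(), seed=0)
        mags = np.abs(image.data[maps.mask])
        expected = np.repeat(maps.rho_w[maps.mask][:, None], mags.shape[1], axis=1)
        np.testing.assert_allclose(mags, expected, rtol=1e-12)

    def test_out_of_phase_echo_cancels_equal_water_fat(self):
        # choose an echo where fat_shift * t = 0.5 cycles exactly
        fat_shift = 217.0
        t_opposed = 0.5 / fat_shift
        prot = Protocol(echo_times_s=(t_opposed / 2, t_opposed, 2 * t_opposed),
                        fat_shift_hz=fat_shift)
        maps = simulate_parameter_maps((32, 32), pdff_dist=("point", 0.5),
                                       r2star_range=(0, 0), field_poly=(0.0,), seed=1)
        image = simulate_multiecho(maps, prot, seed=0)
        assert np.max(np.abs(image.data[maps.mask][:, 1])) < 1e-12

    def test_gre_protocol_echo_times(self, gre):
        assert gre.n_echo == 10
        assert gre.echo_times_ms[0] == pytest.approx(2.38)
        assert gre.echo_times_ms[-1] == pytest.approx(23.82)
        assert GRE_ECHO_TIMES_MS[1] == 4.76 and GRE_ECHO_TIMES_MS[3] == 9.53

    def test_noise_sd_calibrated(self):
        maps = simulate_parameter_maps((128, 128), seed=2)
        prot = ideal_protocol(noise_sd=0.05)
        clean = forward_signal(maps, prot)
        noisy = simulate_multiecho(maps, prot, seed=9).data
        resid = (noisy - clean).ravel()
        assert resid.size >= 1e4
        assert resid.real.std() == pytest.approx(0.05, rel=0.05)
        assert resid.imag.std() == pytest.approx(0.05, rel=0.05)

    def test_identical_seed_bit_identical(self):
        maps = simulate_parameter_maps((32, 32), seed=4)
        prot = gre_protocol(noise_sd=0.01)
        a = simulate_multiecho(maps, prot, seed=77).data
        b = simulate_multiecho(maps, prot, seed=77).data
        assert np.array_equal(a, b)


class TestSwapInjection:
    def test_empty_region_is_identity(self):
        maps = simulate_parameter_maps((32, 32), seed=0)
        out = inject_swap_region(maps, None)
        np.testing.assert_array_equal(out.field_map, maps.field_map)
        out2 = inject_swap_region(maps, (5, 5, 0, 0))
        np.testing.assert_array_equal(out2.field_map, maps.field_map)

    def test_shift_is_half_fat_shift_exactly(self):
        maps = simulate_parameter_maps((32, 32), field_poly=(7.0,), seed=0)
        out = inject_swap_region(maps, (10, 10, 8, 8), fat_shift_hz=217.0)
        np.testing.assert_allclose(
            out.field_map[10:18, 10:18], maps.field_map[10:18, 10:18] + 108.5
        )
        outside = np.ones_like(maps.mask)
        outside[10:18, 10:18] = False
        np.testing.assert_array_equal(out.field_map[outside], maps.field_map[outside])

    def test_region_outside_image_rejected(self):
        maps = simulate_parameter_maps((32, 32), seed=0)
        with pytest.raises(ValueError):
            inject_swap_region(maps, (30, 30, 10, 10))
        with pytest.raises(ValueError):
            inject_swap_region(maps, (0, 0, 2, 2))  # corner outside ellipse mask


class TestCohort:
    def test_allele_frequency_within_binomial_error(self):
        cohort = simulate_cohort(n=10_000, mafs=[0.5], seed=11)
        freq = cohort.genotypes.iloc[:, 0].mean() / 2
        se = np.sqrt(0.5 * 0.5 / (2 * 10_000))
        assert abs(freq - 0.5) < 3 * se

    def test_hwe_genotype_counts(self):
        cohort = simulate_cohort(n=5000, mafs=[0.3], seed=21)
        counts = np.bincount(cohort.genotypes.iloc[:, 0], minlength=3)
        p = 0.3
        expected = 5000 * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=2)

    def test_null_effects_trait_independent_of_genotype(self):
        pvals = []
        for seed in range(40):
            cohort = simulate_cohort(n=300, mafs=[0.3], beta=[0.0], gamma=0.0, seed=seed)
            g = cohort.genotypes.iloc[:, 0].to_numpy()
            y = cohort.traits["trait"].to_numpy()
            pvals.append(stats.pearsonr(g, y).pvalue)
        # under the null the p-values are uniform; check no gross excess
        assert np.mean(np.array(pvals) < 0.05) < 0.25
        assert stats.kstest(pvals, "uniform").pvalue > 0.001

    def test_invalid_maf_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(n=100, mafs=[0.7], seed=0)
        with pytest.raises(ValueError):
            simulate_cohort(n=100, mafs=[0.0], seed=0)
        with pytest.raises(ValueError):
            simulate_cohort(n=10, mafs=[0.3], seed=0)
        with pytest.raises(ValueError):
            simulate_cohort(n=100, mafs=[0.3], beta=[np.inf], seed=0)

    def test_planted_effects_enter_trait(self):
        cohort = simulate_cohort(
            n=4000, mafs=[0.4, 0.4], beta=[0.5, 0.0], noise_sd=0.5, seed=3
        )
        g = cohort.genotypes.iloc[:, 0].to_numpy()
        y = cohort.traits["trait"].to_numpy()
        slope = np.polyfit(g, y, 1)[0]
        assert slope == pytest.approx(0.5, abs=0.06)


class TestProteome:
    def test_no_effect_panel_exchangeable(self):
        cohort = simulate_cohort(n=200, mafs=[0.3], disease_model={"intercept": 0.0}, seed=5)
        panel = simulate_proteome(cohort, n_proteins=50, n_informative=10, effect=0.0, seed=5)
        labels = panel.labels.to_numpy()
        z = []
        for col in panel.levels.columns:
            x = panel.levels[col].to_numpy()
            z.append(stats.ttest_ind(x[labels], x[~labels]).pvalue)
        assert np.mean(np.array(z) < 0.05) < 0.2

    def test_informative_analyte_power_matches_z_oracle(self):
        # closed-form two-sample z power at effect 0.8, n=300+300, alpha 0.05:
        # power = Phi(0.8/sqrt(1/300+1/300) - 1.96) ~ 1.0, so >95% expected
        hits = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            cohort = simulate_cohort(
                n=600, mafs=[0.3], disease_model={"intercept": 0.0}, seed=seed
            )
            panel = simulate_proteome(cohort, n_proteins=5, n_informative=1, effect=0.8, seed=seed)
            labels = panel.labels.to_numpy()
            if labels.sum() < 2 or (~labels).sum() < 2:
                continue
            x = panel.levels.iloc[:, 0].to_numpy()
            p = stats.ttest_ind(x[labels], x[~labels]).pvalue
            hits += p < 0.05
        assert hits / reps > 0.95

    def test_zero_informative_empty_ids(self):
        cohort = simulate_cohort(n=100, mafs=[0.3], seed=1)
        panel = simulate_proteome(cohort, n_proteins=10, n_informative=0, seed=1)
        assert panel.informative_ids == []

    def test_informative_count_validated(self):
        cohort = simulate_cohort(n=100, mafs=[0.3], seed=1)
        with pytest.raises(ValueError):
            simulate_proteome(cohort, n_proteins=10, n_informative=11, seed=1)

    def test_staging_dataset_shapes_and_balance(self):
        panel, covs = simulate_staging_dataset(n_cases=50, n_controls=70, n_proteins=30,
                                               n_informative=5, seed=9)
        assert panel.levels.shape == (120, 30)
        assert panel.labels.sum() == 50
        assert set(covs.columns) == {"age", "sex", "bmi", "alt", "ast", "ggt"}
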