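import numpy as np
import pandas as pd
import pytest

from segtail.data import TimeCourse
from segtail.fitting import (
    FitConfig,
    FitError,
    aggregate_replicates,
    fit_global,
    fit_local,
)
from segtail.kinetics import (
    LN2,
    KineticParams,
    rate_from_half_life,
    simulate_closed_form,
)
from segtail.simulate import (
    FLUORESCENCE_GRID,
    SimulationDesign,
    VariantSpec,
    make_preset,
    simulate_experiment,
)

K_MAT = rate_from_half_life(60.0)
L_FLUOR = rate_from_half_life(179.0)


def _make_course(lambda_rna, k_trans, variant="v", replicate=1, cell="HEK293T"):
    p = KineticParams(lambda_rna, k_trans, K_MAT, L_FLUOR)
    fluor = simulate_closed_form(p, FLUORESCENCE_GRID).fluor
    return TimeCourse(cell, variant, replicate, FLUORESCENCE_GRID, fluor)


class TestFitLocal:
    def test_noise_free_recovery(self):
        true_rate = LN2 / 400.0
        tc = _make_course(true_rate, 2.0)
        fit = fit_local(tc, K_MAT, L_FLUOR)
        assert fit.lambda_rna == pytest.approx(true_rate, rel=1e-4)
        assert fit.k_trans == pytest.approx(2.0, rel=1e-4)
        # residual MAE floor is search precision x signal scale
        assert fit.mae <= 1e-4 * float(np.mean(tc.signal))

    def test_deterministic(self):
        tc = _make_course(LN2 / 300.0, 1.0)
        fits = [fit_local(tc, K_MAT, L_FLUOR) for _ in range(2)]
        assert fits[0] == fits[1]

    def test_adding_starts_never_worsens_objective(self):
        rng = np.random.default_rng(5)
        noisy = _make_course(LN2 / 500.0, 1.0).signal * rng.lognormal(
            0, 0.05, FLUORESCENCE_GRID.size
        )
        tc = TimeCourse("HEK293T", "v", 1, FLUORESCENCE_GRID, noisy)
        base_starts = [LN2 / 400.0]
        more_starts = [LN2 / 400.0, LN2 / 100.0, LN2 / 1600.0]
        obj_few = fit_local(tc, K_MAT, L_FLUOR, starts=base_starts).objective
        obj_more = fit_local(tc, K_MAT, L_FLUOR, starts=more_starts).objective
        assert obj_more <= obj_few + 1e-12

    def test_constant_signal_fits_without_crash(self):
        tc = TimeCourse(
            "HEK293T", "v", 1, FLUORESCENCE_GRID, np.full(FLUORESCENCE_GRID.size, 5.0)
        )
        fit = fit_local(tc, K_MAT, L_FLUOR)
        assert fit.mae > 0
        assert fit.lambda_rna > 0

    def test_all_zero_signal_raises(self):
        tc = TimeCourse(
            "HEK293T", "v", 1, FLUORESCENCE_GRID, np.zeros(FLUORESCENCE_GRID.size)
        )
        with pytest.raises(FitError):
            fit_local(tc, K_MAT, L_FLUOR)

    def test_objective_consistency(self):
        tc = _make_course(LN2 / 350.0, 1.5)
        fit = fit_local(tc, K_MAT, L_FLUOR)
        p = KineticParams(fit.lambda_rna, fit.k_trans, K_MAT, L_FLUOR)
        recomputed = np.mean(
            np.abs(tc.signal - simulate_closed_form(p, tc.times).fluor)
        )
        assert fit.mae == pytest.approx(recomputed, abs=1e-10)

    def test_invalid_inputs(self):
        tc = _make_course(LN2 / 350.0, 1.0)
        with pytest.raises(ValueError):
            fit_local(tc, -1.0, L_FLUOR)
        with pytest.raises(ValueError):
            fit_local(tc, K_MAT, L_FLUOR, starts=[])


@pytest.fixture(scope="module")
def noise_free_fit():
    courses = [
        _make_course(LN2 / 280.0, 1.0, variant="slow"),
        _make_course(LN2 / 350.0, 2.0, variant="mid"),
        _make_course(LN2 / 440.0, 4.0, variant="fast"),
    ]
    return fit_global(courses)


class TestFitGlobal:
    def test_exact_recovery_noise_free(self, noise_free_fit):
        res = noise_free_fit
        assert res.k_mat_hat == pytest.approx(K_MAT, rel=1e-3)
        assert res.lambda_fluor_hat == pytest.approx(L_FLUOR, rel=1e-3)
        expected = {"slow": 280.0, "mid": 350.0, "fast": 440.0}
        for _, row in res.per_variant.iterrows():
            assert row["rna_half_life"] == pytest.approx(
                expected[row["variant"]], rel=1e-3
            )

    def test_global_labels_follow_time_scale_convention(self, noise_free_fit):
        # maturation is reported as the faster of the two shared rates
        assert noise_free_fit.k_mat_hat >= noise_free_fit.lambda_fluor_hat

    def test_half_life_column_consistent(self, noise_free_fit):
        pv = noise_free_fit.per_variant
        assert pv["rna_half_life"].to_numpy() == pytest.approx(
            LN2 / pv["lambda_rna_hat"].to_numpy()
        )

    def test_identical_curves_give_identical_estimates(self):
        tc = _make_course(LN2 / 350.0, 2.0)
        courses = [
            TimeCourse("HEK293T", v, 1, tc.times, tc.signal) for v in ("a", "b", "c")
        ]
        res = fit_global(courses)
        rates = res.per_variant["lambda_rna_hat"].to_numpy()
        assert np.allclose(rates, rates[0], rtol=1e-9)

    def test_mixed_cell_lines_rejected(self):
        courses = [
            _make_course(LN2 / 350.0, 1.0, variant="a", cell="HEK293T"),
            _make_course(LN2 / 350.0, 1.0, variant="b", cell="A549"),
        ]
        with pytest.raises(ValueError, match="mixed cell lines"):
            fit_global(courses)

    def test_single_variant_flagged_non_identifiable(self):
        courses = [_make_course(LN2 / 350.0, 1.0, replicate=r) for r in (1, 2)]
        with pytest.warns(UserWarning, match="single-variant"):
            res = fit_global(courses)
        assert not res.identifiable

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            fit_global([])


class TestParameterRecoveryUnderNoise:
    def test_recovery_across_seeds(self):
        """Median recovery error across simulated datasets stays small.

        Run at reduced size (4 variants x 2 replicates, 2x2 outer start
        grid) so the whole sweep stays cheap; the acceptance tests exercise
        the full 10-variant x 3-replicate condition.
        """
        cfg = FitConfig(
            k_mat_start_half_lives=(40.0, 160.0),
            lambda_fluor_start_half_lives=(100.0, 400.0),
        )
        variants = (
            VariantSpec("v1", 0.8, 1.0),
            VariantSpec("v2", 1.0, 2.0),
            VariantSpec("v3", 1.1, 3.0),
            VariantSpec("v4", 1.25, 5.0),
        )
        rna_errors, protein_errors = [], []
        for seed in range(1, 21):
            preset = make_preset("HEK293T")
            sim = SimulationDesign(
                cell_line=preset, variants=variants, n_replicates=2, seed=seed
            )
            res = fit_global(simulate_experiment(sim), config=cfg)
            protein_errors.append(abs(res.protein_half_life - 179.0) / 179.0)
            mults = {v.label: v.rna_half_life_multiplier for v in variants}
            for _, row in res.replicate_summary.iterrows():
                truth = 350.0 * mults[row["variant"]]
                rna_errors.append(abs(row["half_life_mean"] - truth) / truth)
        assert np.median(rna_errors) <= 0.10
        assert np.median(protein_errors) <= 0.15


class TestAggregateReplicates:
    @staticmethod
    def _table(half_lives, variant="v1"):
        return pd.DataFrame(
            {
                "variant": [variant] * len(half_lives),
                "rna_half_life": half_lives,
                "k_trans_hat": [1.0] * len(half_lives),
            }
        )

    def test_equal_replicates(self):
        out = aggregate_replicates(self._table([400.0, 400.0, 400.0]))
        assert out.loc[0, "half_life_mean"] == 400.0
        assert out.loc[0, "half_life_sd"] == 0.0

    def test_sample_sd_uses_n_minus_1(self):
        out = aggregate_replicates(self._table([350.0, 370.0, 390.0]))
        assert out.loc[0, "half_life_mean"] == pytest.approx(370.0)
        assert out.loc[0, "half_life_sd"] == pytest.approx(20.0)

    def test_single_replicate_flagged(self):
        out = aggregate_replicates(self._table([259.0]))
        assert out.loc[0, "half_life_mean"] == 259.0
        assert out.loc[0, "half_life_sd"] == 0.0
        assert bool(out.loc[0, "single_replicate"])

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            aggregate_replicates(pd.DataFrame({"variant": ["a"]}))
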