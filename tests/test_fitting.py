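"""Parameter recovery, marker inversion and goodness-of-fit."""

import math

import numpy as np
import pytest

import ebeamkin as ek
from ebeamkin.exceptions import (
    InsufficientDataError,
    NoSignalError,
    UnidentifiableError,
)
from ebeamkin.fitting import ProductFormationModel
from ebeamkin.synthetic_data import GeneratorConfig, generate

from _oracles import pearson_r


class TestAntibioticRecovery:
    @pytest.mark.parametrize(
        "name", ["tetracycline", "benzylpenicillin", "doxycycline", "chloramphenicol"]
    )
    def test_noiseless_alpha_recovery(self, registry, name, experimental_doses):
        table = ek.simulate_noiseless(registry, experimental_doses)
        res = ek.fit_antibiotic(table, name, fix_c0_at_100=True)
        true = registry.antibiotics[name].alpha
        assert abs(res.alpha - true) / true <= 1e-6
        assert res.r_corr > 0.999999
        assert res.nobs == len(experimental_doses)

    def test_free_c0_recovery(self, registry, experimental_doses):
        table = ek.simulate_noiseless(registry, experimental_doses)
        res = ek.fit_antibiotic(table, "tetracycline", fix_c0_at_100=False)
        assert abs(res.alpha - 1.28) / 1.28 <= 1e-6
        assert abs(res.c0 - 100.0) / 100.0 <= 1e-6

    def test_constant_series_gives_alpha_zero_and_flagged_r(self):
        rows = tuple(
            ek.Observation(d, 1, "inert", 1.0, None, 100.0)
            for d in (0.0, 1.0, 3.0, 7.0)
        )
        res = ek.fit_antibiotic(ek.PeakTable(rows), "inert")
        assert res.alpha == pytest.approx(0.0, abs=1e-8)
        assert math.isnan(res.r_corr)

    def test_insufficient_doses_rejected(self):
        rows = tuple(
            ek.Observation(d, 1, "x", 1.0, None, 100.0) for d in (0.0, 1.0)
        )
        with pytest.raises(InsufficientDataError):
            ek.fit_antibiotic(ek.PeakTable(rows), "x")

    def test_missing_dose0_rejected(self):
        rows = tuple(
            ek.Observation(d, 1, "x", 1.0, None, 50.0) for d in (1.0, 3.0, 7.0)
        )
        with pytest.raises(InsufficientDataError):
            ek.fit_antibiotic(ek.PeakTable(rows), "x")


class TestProductRecovery:
    @pytest.mark.parametrize(
        "label, parent",
        [("461.1549", "tetracycline"), ("416.1334", "tetracycline")],
    )
    def test_noiseless_triple_recovery(self, registry, label, parent):
        """(beta, D0, k) recovered from a noiseless 0:0.25:7 dose series with
        the parent law frozen; D0 precision is grid-limited."""
        doses = np.arange(0.0, 7.0 + 0.125, 0.25)
        table = ek.simulate_noiseless(registry, doses)
        parent_fit = ek.fit_antibiotic(table, parent)
        res = ek.fit_product(table, label, parent_fit)
        true = registry.products[label]
        assert abs(res.beta - true.beta) / true.beta <= 1e-3
        assert abs(res.d0 - true.d0) / true.d0 <= 1e-3
        assert abs(res.k - true.k) / true.k <= 1e-3

    def test_threshold_not_below_last_zero_dose(self, tc_registry):
        """With the product censored to zero below its threshold, the fitted
        D0 never lands below the largest all-zero dose, whatever the seed."""
        for seed in range(12):
            cfg = GeneratorConfig(
                registry=tc_registry, seed=seed, noise_cv=0.10, lod_fraction=1e-4
            )
            table = generate(cfg)
            d, y = table.arrays("461.1549")
            last_zero = float(np.max(d[y == 0.0][d[y == 0.0] < 0.98]))
            parent_fit = ek.fit_antibiotic(table, "tetracycline")
            res = ek.fit_product(table, "461.1549", parent_fit, d0_grid_step=0.05)
            assert res.d0 >= last_zero - 1e-9

    def test_refinement_never_increases_objective(self, registry):
        doses = np.arange(0.0, 7.0 + 0.125, 0.25)
        table = ek.simulate_noiseless(registry, doses)
        parent_fit = ek.fit_antibiotic(table, "tetracycline")
        m = ProductFormationModel(table, "461.1549", parent_fit, d0_grid_step=0.1)
        res = m.fit()
        grid_sses = [
            m._profile_beta(d0)[2] for d0 in np.arange(0.0, 1.01, 0.1)
        ]
        assert res.sse <= min(grid_sses) + 1e-12

    def test_all_zero_signal_rejected(self, tc_registry):
        rows = tuple(
            ek.Observation(d, 1, "461.1549", 461.15, None, 0.0, censored=True)
            for d in (0.0, 1.0, 3.0, 7.0)
        )
        with pytest.raises(NoSignalError):
            ek.fit_product(
                ek.PeakTable(rows), "461.1549", tc_registry.antibiotics["tetracycline"]
            )

    def test_standard_errors_shrink_with_replication(self, tc_registry):
        """Gauss-Newton SEs contract (in expectation) as replicates double."""

        def mean_se(reps: int) -> float:
            ses = []
            for seed in range(10):
                cfg = GeneratorConfig(
                    registry=tc_registry, replicates=reps, noise_cv=0.10, seed=seed
                )
                table = generate(cfg)
                res = ek.fit_antibiotic(table, "tetracycline")
                ses.append(res.se_alpha)
            return float(np.mean(ses))

        assert mean_se(6) < mean_se(3)


class TestReconstructInitial:
    def test_exact_on_noiseless_data(self, tc_registry):
        table = ek.simulate_noiseless(tc_registry, [1.0, 3.0, 7.0])
        est = ek.reconstruct_initial(
            table, "461.1549", tc_registry.products["461.1549"]
        )
        assert est.c0 == pytest.approx(100.0, rel=1e-12)
        assert est.se == pytest.approx(0.0, abs=1e-9)

    def test_linear_in_areas(self, tc_registry):
        table = ek.simulate_noiseless(tc_registry, [1.0, 3.0, 7.0])
        doubled = ek.PeakTable(
            tuple(
                ek.Observation(
                    o.dose_kGy, o.replicate, o.analyte, o.mz, o.rt_min, 2.0 * o.area
                )
                for o in table.observations
            )
        )
        est = ek.reconstruct_initial(
            doubled, "461.1549", tc_registry.products["461.1549"]
        )
        assert est.c0 == pytest.approx(200.0, rel=1e-12)

    def test_unidentifiable_below_threshold(self, tc_registry):
        rows = tuple(
            ek.Observation(d, 1, "461.1549", 461.15, None, 0.0, censored=True)
            for d in (0.0, 0.1, 0.5)
        )
        with pytest.raises(UnidentifiableError):
            ek.reconstruct_initial(
                ek.PeakTable(rows), "461.1549", tc_registry.products["461.1549"]
            )

    def test_monte_carlo_mean_within_2_percent(self, tc_registry):
        """CV=10%, 3 replicates at {1, 3, 7} kGy: the linear inversion is
        unbiased, so the Monte-Carlo mean lands within 2% of the truth."""
        prod = tc_registry.products["461.1549"]
        c0s = []
        for seed in range(300):
            cfg = GeneratorConfig(
                registry=tc_registry, doses=(1.0, 3.0, 7.0), seed=seed
            )
            c0s.append(ek.reconstruct_initial(generate(cfg), "461.1549", prod).c0)
        assert abs(float(np.mean(c0s)) - 100.0) / 100.0 <= 0.02


class TestGoodnessRcorr:
    def test_perfect_fit(self):
        assert ek.goodness_r_corr([1.0, 2.0, 5.0], [1.0, 2.0, 5.0]) == 1.0

    def test_orthogonal_vectors(self):
        assert ek.goodness_r_corr([1.0, 0.0, -1.0], [0.0, 1.0, 0.0]) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(size=10)
        y = 0.5 * x + rng.normal(size=10)
        expected = min(max(pearson_r(x, y), 0.0), 1.0)
        assert ek.goodness_r_corr(x, y) == pytest.approx(expected, rel=1e-12)

    def test_constant_input_flagged(self):
        assert math.isnan(ek.goodness_r_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))
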