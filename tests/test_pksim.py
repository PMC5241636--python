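import logging

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import chainpk as cp
from chainpk.pksim import (
    COMPOUND_INFO,
    DegenerateParameterError,
    InteractionCoefficients,
    concentration_at,
    pk_from_composition,
    simulate_dataset,
)


class TestConcentrationCurve:
    def test_zero_up_to_lag_and_nonnegative(self):
        p = cp.PKParameters(tlag=30.0, dose=100.0)
        t = np.linspace(0, 480, 500)
        c = concentration_at(t, p)
        assert np.all(c[t <= 30.0] == 0.0)
        assert np.all(c >= 0.0)

    def test_peak_time_matches_closed_form(self):
        p = cp.PKParameters(ka=0.1, ke=0.01, tlag=0.0, dose=100.0, V_F=1.0)
        t = np.linspace(0, 600, 600001)
        c = concentration_at(t, p)
        tmax_grid = t[np.argmax(c)]
        tmax_exact = np.log(0.1 / 0.01) / (0.1 - 0.01)
        assert tmax_exact == pytest.approx(np.log(10) / 0.09)
        assert tmax_grid == pytest.approx(tmax_exact, abs=2e-3)
        assert p.tmax == pytest.approx(tmax_exact)

    def test_total_exposure_matches_closed_form(self):
        p = cp.PKParameters(ka=0.1, ke=0.01, tlag=0.0, dose=100.0, V_F=1.0)
        t = np.linspace(0, 5000, 2_000_001)
        auc = np.trapezoid(concentration_at(t, p), t)
        assert p.auc_inf == pytest.approx(10000.0)
        assert auc == pytest.approx(10000.0, rel=1e-3)

    def test_equal_rates_rejected(self):
        with pytest.raises(DegenerateParameterError):
            cp.PKParameters(ka=0.01, ke=0.01)

    @given(
        ka=st.floats(0.02, 0.3),
        ratio=st.floats(1.5, 20.0),
        tlag=st.floats(0.0, 4.0),
    )
    def test_curves_are_unimodal_on_the_grid(self, ka, ratio, tlag):
        p = cp.PKParameters(ka=ka, ke=ka / ratio, tlag=tlag, dose=50.0)
        c = concentration_at(cp.standard_time_grid().asarray(), p)
        d = np.diff(c)
        signs = np.sign(d[d != 0])
        # rises to a single maximum, then declines: at most one sign change
        assert np.sum(np.diff(signs) != 0) <= 1


class TestComposition:
    def test_zero_source_herb_gives_zero_curve(self):
        row = cp.builtin_design().row("10#")  # coptis only
        p = pk_from_composition(row, COMPOUND_INFO["pae"])  # peony compound
        assert p.dose == 0.0
        assert np.all(concentration_at(cp.standard_time_grid().asarray(), p) == 0.0)

    def test_zero_interaction_is_identity_on_rates(self):
        row = cp.builtin_design().row("5#")
        base = cp.PKParameters()
        zero = InteractionCoefficients(ka_coef=(0, 0, 0), ke_coef=(0, 0, 0))
        p = pk_from_composition(row, COMPOUND_INFO["ber"], base=base, interaction=zero)
        assert p.ka == base.ka and p.ke == base.ke

    def test_dose_and_curve_are_linear_in_source_herb(self):
        base = cp.PKParameters()
        row1 = cp.DesignRow("a", 0.5, 0.3, 0.3)
        row2 = cp.DesignRow("b", 1.0, 0.3, 0.3)
        p1 = pk_from_composition(row1, COMPOUND_INFO["ber"], base=base)
        p2 = pk_from_composition(row2, COMPOUND_INFO["ber"], base=base)
        assert p2.dose == pytest.approx(2 * p1.dose)
        t = cp.standard_time_grid().asarray()
        np.testing.assert_allclose(
            concentration_at(t, p2), 2 * concentration_at(t, p1), rtol=1e-12
        )

    def test_rate_crossing_is_clipped_with_warning(self, caplog):
        row = cp.DesignRow("hot", 1.0, 2.0, 2.0)
        aggressive = InteractionCoefficients(ka_coef=(-2.0,) * 3, ke_coef=(2.0,) * 3)
        with caplog.at_level(logging.WARNING, logger="chainpk.pksim"):
            p = pk_from_composition(row, COMPOUND_INFO["ber"], interaction=aggressive)
        assert p.ka == pytest.approx(1.05 * p.ke)
        assert any("clipping" in r.message for r in caplog.records)


class TestSimulateDataset:
    def test_default_configuration_yields_36_samples(self):
        ds = simulate_dataset(compound="ber", noise=cp.NoiseModel(seed=1))
        assert ds.n_samples == 36 and ds.n_targets == 9
        assert len(set(ds.group_ids)) == 12

    def test_no_noise_makes_replicates_identical(self):
        ds = simulate_dataset(
            compound="pal", replicates=3, noise=cp.NoiseModel(cv=0.0, seed=1),
            latent_cv=0.0,
        )
        Y = ds.Y.reshape(12, 3, 9)
        np.testing.assert_array_equal(Y[:, 0], Y[:, 1])
        np.testing.assert_array_equal(Y[:, 0], Y[:, 2])

    def test_fixed_seed_is_reproducible(self):
        a = simulate_dataset(compound="evo", noise=cp.NoiseModel(seed=9))
        b = simulate_dataset(compound="evo", noise=cp.NoiseModel(seed=9))
        np.testing.assert_array_equal(a.Y, b.Y)
        c = simulate_dataset(compound="evo", noise=cp.NoiseModel(seed=10))
        assert not np.array_equal(a.Y, c.Y)

    def test_consecutive_targets_are_strongly_correlated(self):
        """The serial correlation the chain exploits: adjacent time points of
        the same samples correlate well beyond 0.5 under default settings."""
        cors = []
        for seed in range(5):
            ds = simulate_dataset(compound="ber", noise=cp.NoiseModel(seed=seed))
            for j in range(ds.n_targets - 1):
                a, b = ds.Y[:, j], ds.Y[:, j + 1]
                if a.std() > 0 and b.std() > 0:
                    cors.append(np.corrcoef(a, b)[0, 1])
        assert np.mean(cors) > 0.5

    def test_multiplicative_noise_has_mean_one(self):
        """Monte Carlo: the noisy concentration is unbiased for the noiseless
        curve within a 4-sigma confidence band."""
        p = cp.PKParameters(dose=100.0, tlag=0.0)
        t = cp.standard_time_grid().asarray()
        truth = concentration_at(t, p)
        design = cp.DesignTable((cp.DesignRow("x", 1.0, 1.0, 1.0),))
        reps = 4000
        ds = simulate_dataset(
            design=design,
            compound="ber",
            base=p,
            interaction=cp.InteractionCoefficients((0,) * 3, (0,) * 3),
            replicates=reps,
            noise=cp.NoiseModel(cv=0.15, seed=0),
            latent_cv=0.10,
            unit_dose=100.0 / (1.0 * 0.2303),  # dose back to 100
        )
        mean = ds.Y.mean(axis=0)
        cv_tot = np.sqrt((1 + 0.15**2) * (1 + 0.10**2) - 1)
        se = truth * cv_tot / np.sqrt(reps)
        assert np.all(np.abs(mean - truth) < 4 * se + 1e-12)

    def test_default_suite_covers_all_compounds(self):
        suite = cp.default_suite(seed=2)
        assert set(suite) == {"ber", "pal", "evo", "rut", "pae"}
        for ds in suite.values():
            assert ds.n_samples == 36
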