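import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import edufert as ef
from conftest import single_cell_inputs

rates7 = st.lists(
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=7, max_size=7
)


class TestDeterministicIdentities:
    def test_tfr_is_five_times_age_sum_examples(self):
        assert ef.derive_tfr(np.zeros(7)) == 0.0
        assert ef.derive_tfr(np.full(7, 0.2)) == pytest.approx(7.0)
        assert ef.derive_tfr([0.05, 0.20, 0.22, 0.18, 0.10, 0.04, 0.01]) == pytest.approx(4.0)
        assert ef.derive_etfr(np.full(7, 0.1)) == pytest.approx(3.5)

    @settings(max_examples=50, deadline=None)
    @given(rates7)
    def test_tfr_identity_property(self, asfr):
        assert ef.derive_tfr(asfr) == pytest.approx(5.0 * sum(asfr))
        assert ef.derive_etfr(asfr) == ef.derive_tfr(asfr)

    def test_tfr_rejects_wrong_length(self):
        with pytest.raises(ValueError):
            ef.derive_tfr([0.1, 0.2])

    def test_aggregate_asfr_examples(self):
        assert ef.aggregate_asfr(
            [0.30, 0.25, 0.15, 0.10], [0.5, 0.3, 0.15, 0.05]
        ) == pytest.approx(0.2525)
        assert ef.aggregate_asfr([0.3, 0.9, 0.9, 0.9], [1, 0, 0, 0]) == pytest.approx(0.3)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4),
        st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
    )
    def test_aggregate_is_convex_combination(self, eafr, raw_w):
        w = np.asarray(raw_w) / np.sum(raw_w)
        out = ef.aggregate_asfr(eafr, w)
        assert min(eafr) - 1e-12 <= out <= max(eafr) + 1e-12

    def test_aggregate_rejects_bad_weight_sum(self):
        with pytest.raises(ValueError, match="weights sum"):
            ef.aggregate_asfr([0.1] * 4, [0.5, 0.5, 0.2, 0.0])


class TestModelStructure:
    def test_no_ssa_countries_no_consistency_terms(self, world, glm):
        inputs = ef.build_inputs(world, glm, use_prev_etfr=False)
        assert inputs.prev_etfr is None
        assert inputs.n_observed_nodes == int(np.isfinite(inputs.benchmark).sum())

    def test_holdout_drops_one_observed_node(self, inputs):
        bench = inputs.benchmark.copy()
        bench[0, 0, 0] = np.nan
        reduced = ef.ModelInputs(
            lattice=inputs.lattice,
            init_mean=inputs.init_mean,
            weights=inputs.weights,
            benchmark=bench,
            prior_stats=inputs.prior_stats,
            prior_spec=inputs.prior_spec,
            prev_etfr=inputs.prev_etfr,
            tau_asfr=inputs.tau_asfr,
        )
        assert reduced.n_observed_nodes == inputs.n_observed_nodes - 1

    def test_prev_etfr_for_non_ssa_country_rejected(self, inputs):
        lat = inputs.lattice
        prev = np.full(
            (len(lat.countries), len(lat.periods), len(lat.education_levels)), np.nan
        )
        non_ssa = [i for i, c in enumerate(lat.countries) if c not in lat.ssa_countries()]
        prev[non_ssa[0], 0, 0] = 3.0
        with pytest.raises(ValueError, match="sub-Saharan"):
            ef.ModelInputs(
                lattice=lat,
                init_mean=inputs.init_mean,
                weights=inputs.weights,
                benchmark=inputs.benchmark,
                prior_stats=inputs.prior_stats,
                prior_spec=inputs.prior_spec,
                prev_etfr=prev,
                tau_asfr=inputs.tau_asfr,
            )


class TestSampler:
    def test_draws_deterministic_under_seed(self, small_inputs):
        kw = dict(chains=2, warmup=50, iterations=100, random_state=9)
        m1 = ef.EAFRModel(**kw).fit(small_inputs)
        m2 = ef.EAFRModel(**kw).fit(small_inputs)
        np.testing.assert_array_equal(m1.draws_.eafr, m2.draws_.eafr)
        np.testing.assert_array_equal(m1.draws_.etfr_est, m2.draws_.etfr_est)

    def test_per_draw_identities_and_support(self, fitted):
        d = fitted.draws_
        assert (d.eafr > 0).all()
        assert ((d.etfr_est > 0) & (d.etfr_est < 10)).all()
        np.testing.assert_allclose(
            d.tfr, 5.0 * d.asfr.sum(axis=4), rtol=0, atol=1e-12
        )
        np.testing.assert_allclose(
            d.etfr_derived, 5.0 * d.eafr.sum(axis=4), rtol=0, atol=1e-12
        )
        np.testing.assert_allclose(
            d.asfr, np.einsum("kdcyae,cyae->kdcya", d.eafr, d.weights), atol=1e-12
        )

    def test_zero_weight_cells_flagged_benchmark_uninformed(self, fitted, world):
        flags = fitted.benchmark_uninformed_
        assert flags.shape == world.lattice.shape
        # higher education at ages 15-19 has zero weight by construction
        assert flags[:, :, 0, 3].all()
        assert (fitted.draws_.eafr[:, :, flags] > 0).all()

    def test_convergence_diagnostics_reported(self, fitted):
        assert fitted.rhat_max_ < 1.05
        assert fitted.ess_min_ > 100
        assert fitted.converged_

    def test_conjugate_single_cell_oracle(self):
        """Posterior with degenerate weight and fixed precisions matches the
        closed-form positive-truncated-normal combination of benchmark
        likelihood and prior."""
        inputs, tau0 = single_cell_inputs(m0=0.2, tau0=400.0, bench=0.25, tau_asfr=400.0)
        model = ef.EAFRModel(
            chains=2,
            warmup=200,
            iterations=3000,
            random_state=17,
            include_etfr_level=False,
            fixed_tau_eafr=tau0,
        ).fit(inputs)
        x = model.draws_.flat(model.draws_.eafr).ravel()
        prec = tau0 + inputs.tau_asfr
        mu = (tau0 * 0.2 + inputs.tau_asfr * 0.25) / prec
        sd = 1.0 / np.sqrt(prec)
        ref = stats.truncnorm(-mu / sd, np.inf, loc=mu, scale=sd)
        n = x.size  # draws are iid here: the update samples the exact posterior
        assert abs(x.mean() - ref.mean()) < 3 * ref.std() / np.sqrt(n)
        assert abs(x.std(ddof=1) - ref.std()) < 3 * ref.std() / np.sqrt(2 * n)

    def test_strong_benchmark_pins_degenerate_weight_cell(self):
        """With tau_asfr huge and weight (1,0,0,0) the posterior median rate
        approaches the benchmark value."""
        inputs, tau0 = single_cell_inputs(
            m0=0.2, tau0=400.0, bench=0.25, tau_asfr=1e9
        )
        model = ef.EAFRModel(
            chains=2,
            warmup=100,
            iterations=500,
            random_state=3,
            include_etfr_level=False,
            fixed_tau_eafr=tau0,
        ).fit(inputs)
        med = np.median(model.draws_.eafr)
        assert med == pytest.approx(0.25, rel=0.01)

    def test_benchmark_anchoring_reduces_asfr_rmse(self, inputs, fitted):
        med = ef.summarize(fitted.draws_.asfr)["median"]
        mask = np.isfinite(inputs.benchmark)
        rmse_post = np.sqrt(np.mean((med[mask] - inputs.benchmark[mask]) ** 2))
        agg_init = (inputs.init_mean * inputs.weights).sum(axis=3)
        rmse_init = np.sqrt(np.mean((agg_init[mask] - inputs.benchmark[mask]) ** 2))
        assert rmse_post < rmse_init


class TestSummaries:
    def test_constant_draws_collapse_interval(self, world):
        arr = np.full((2, 10, 3), 0.3)
        s = ef.summarize(arr, 0.9)
        assert (s["median"] == 0.3).all()
        assert (s["lower"] == 0.3).all() and (s["upper"] == 0.3).all()

    def test_quantile_oracle_1_to_100(self):
        draws = np.arange(1.0, 101.0).reshape(2, 50, 1)
        s = ef.summarize(draws, 0.90)
        ref_lo, ref_hi = np.quantile(np.arange(1.0, 101.0), [0.05, 0.95])
        assert s["lower"][0] == pytest.approx(ref_lo)
        assert s["upper"][0] == pytest.approx(ref_hi)

    def test_summary_ordering_and_schema(self, fitted):
        df = fitted.summary_eafr(0.95)
        assert tuple(df.columns) == ef.ESTIMATE_COLUMNS
        assert (df["Lower_CI"] <= df["Median"]).all()
        assert (df["Median"] <= df["Upper_CI"]).all()
        assert len(df) == fitted.draws_.lattice.n_cells

    def test_build_model_and_run_mcmc_wrappers(self, small_inputs):
        model = ef.build_model(small_inputs, chains=2, warmup=50, iterations=80)
        draws = ef.run_mcmc(model, seed=4)
        assert draws.eafr.shape[:2] == (2, 80)
        assert draws.seed == 4


class TestGenerativeSimulation:
    def test_simulated_inputs_keep_pattern_and_truth_positive(self, inputs):
        x_true, gen = ef.simulate_from_model(inputs, seed=8)
        assert (x_true > 0).all()
        np.testing.assert_array_equal(
            np.isfinite(gen.benchmark), np.isfinite(inputs.benchmark)
        )
        assert gen.tau_asfr == inputs.tau_asfr

    def test_simulation_deterministic(self, inputs):
        a1, g1 = ef.simulate_from_model(inputs, seed=8)
        a2, g2 = ef.simulate_from_model(inputs, seed=8)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(g1.benchmark, g2.benchmark)
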