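import numpy as np
import pandas as pd
import pytest

import edufert as ef
from edufert.glm import CleanConfig, clean_observations


def _row(education="No Education", births=5, rate=0.2, country="Country A", age="25-29"):
    return {
        "Country": country,
        "Region": "sub-Saharan Africa",
        "Year": "2000-2005",
        "Age Group": age,
        "Education": education,
        "Value": rate,
        "Births": births,
        "Exposure": 100.0,
        "SurveyYear": 2010,
    }


class TestCleaning:
    def test_higher_education_birth_count_rule_is_education_specific(self):
        df = pd.DataFrame(
            [_row("Higher Education", births=31), _row("No Education", births=31)]
        )
        kept, removed = clean_observations(df)
        assert list(kept["Education"]) == ["No Education"]
        assert list(removed["Education"]) == ["Higher Education"]
        assert (removed["Reason"] == "higher-education birth count above threshold").all()

    def test_boundary_birth_count_is_retained(self):
        df = pd.DataFrame([_row("Higher Education", births=30)])
        kept, removed = clean_observations(df)
        assert len(kept) == 1 and removed.empty

    def test_rate_ceiling(self):
        df = pd.DataFrame([_row(rate=1.7), _row(rate=0.9)])
        kept, removed = clean_observations(df)
        assert list(kept["Value"]) == [0.9]
        assert (removed["Reason"] == "rate above plausibility ceiling").all()

    def test_robust_outlier_screen(self):
        rows = [_row(rate=r) for r in [0.20, 0.21, 0.19, 0.20, 0.22, 0.18, 0.95]]
        kept, removed = clean_observations(rows and pd.DataFrame(rows))
        assert 0.95 not in kept["Value"].values
        assert len(removed) == 1

    def test_cleaning_is_idempotent(self, world):
        kept1, _ = clean_observations(world.surveys)
        kept2, removed2 = clean_observations(kept1)
        assert removed2.empty
        pd.testing.assert_frame_equal(kept1, kept2)

    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValueError):
            CleanConfig(mad_multiplier=0)


def _structured_observations(lattice, b_edu, b_age, intercept=-1.5, exposure=1e5):
    """Noise-free rates from an education+age linear predictor, full coverage."""
    rows = []
    for c in lattice.countries:
        for y in lattice.periods:
            for ai, a in enumerate(lattice.age_groups):
                for ei, e in enumerate(lattice.education_levels):
                    rate = np.exp(intercept + b_edu[ei] + b_age[ai])
                    rows.append(
                        {
                            "Country": c,
                            "Region": lattice.regions[c],
                            "Year": y,
                            "Age Group": a,
                            "Education": e,
                            "Value": rate,
                            "Births": rate * exposure,
                            "Exposure": exposure,
                            "SurveyYear": 2020,
                        }
                    )
    return pd.DataFrame(rows)


class TestGLMFit:
    def test_noise_free_recovery(self, world):
        lat = world.lattice
        b_edu = np.array([0.0, -0.1, -0.5, -0.9])
        b_age = np.array([-1.0, 0.2, 0.4, 0.1, -0.4, -1.2, -2.5])
        obs = _structured_observations(lat, b_edu, b_age)
        glm = ef.GLMInitializer(lat, clean=None).fit(obs)
        truth = lat.array(obs.drop_duplicates(["Country", "Year", "Age Group", "Education"]))
        rel = np.abs(glm.predicted_ - truth) / truth
        assert glm.family_used_ == "poisson"
        assert rel.max() < 1e-6

    def test_lattice_complete_despite_missing_periods(self, world):
        lat = world.lattice
        obs = world.surveys[world.surveys["Year"].map(lambda p: int(p[:4])) >= 1990]
        glm = ef.GLMInitializer(lat).fit(obs)
        assert glm.predicted_.shape == lat.shape
        assert np.isfinite(glm.predicted_).all() and (glm.predicted_ > 0).all()
        assert np.isfinite(glm.se_).all() and (glm.se_ > 0).all()

    def test_region_assignment_changes_predictions(self, world):
        # moving a country out of a shared region changes the pooling
        # (a pure relabeling of a single-country region would not)
        lat = world.lattice
        regions2 = dict(lat.regions)
        regions2["Country B"] = "West Asia"
        lat2 = ef.Lattice(
            countries=lat.countries,
            regions=regions2,
            periods=lat.periods,
            age_groups=lat.age_groups,
            education_levels=lat.education_levels,
        )
        obs2 = world.surveys.copy()
        obs2.loc[obs2["Country"] == "Country B", "Region"] = "West Asia"
        g1 = ef.GLMInitializer(lat).fit(world.surveys)
        g2 = ef.GLMInitializer(lat2).fit(obs2)
        assert not np.allclose(g1.predicted_, g2.predicted_)

    def test_predictions_invariant_to_row_order(self, world):
        lat = world.lattice
        shuffled = world.surveys.sample(frac=1.0, random_state=3).reset_index(drop=True)
        g1 = ef.GLMInitializer(lat).fit(world.surveys)
        g2 = ef.GLMInitializer(lat).fit(shuffled)
        np.testing.assert_allclose(g1.predicted_, g2.predicted_, rtol=1e-8)


class TestPriorStatistics:
    def test_constant_ses_zero_spread(self, world):
        lat = world.lattice
        pred = np.full(lat.shape, 0.2)
        se = np.full(lat.shape, 0.03)
        st = ef.derive_prior_statistics(pred, se, lat)
        np.testing.assert_allclose(st.sigma_e, 0.0, atol=1e-12)
        np.testing.assert_allclose(st.mu_e, 0.03)
        assert st.sigma2_pooled == pytest.approx(0.0, abs=1e-12)

    def test_two_point_sd_oracle(self):
        lat = ef.Lattice(
            countries=("Country A",),
            regions={"Country A": "Europe"},
            periods=("2000-2005", "2005-2010"),
            age_groups=("25-29",),
            education_levels=("No Education",),
        )
        se = np.array([0.01, 0.03]).reshape(1, 2, 1, 1)
        st = ef.derive_prior_statistics(np.full_like(se, 0.2), se, lat)
        assert st.sigma_e[0] == pytest.approx(np.std([0.01, 0.03], ddof=1))
        assert st.sigma_e[0] == pytest.approx(0.01414, abs=1e-5)
        assert st.mu_e[0] == pytest.approx(0.02)

    def test_sigma_etfr_uses_highest_education_only(self, world):
        lat = world.lattice
        rng = np.random.default_rng(0)
        pred = rng.uniform(0.05, 0.3, lat.shape)
        se = np.full(lat.shape, 0.02)
        st = ef.derive_prior_statistics(pred, se, lat)
        etfr4 = 5.0 * pred[..., -1].sum(axis=2)
        assert st.sigma_etfr_e4 == pytest.approx(np.std(etfr4, ddof=1))
        # perturbing a lower education level leaves it unchanged
        pred2 = pred.copy()
        pred2[..., 0] *= 2
        st2 = ef.derive_prior_statistics(pred2, se, lat)
        assert st2.sigma_etfr_e4 == pytest.approx(st.sigma_etfr_e4)

    def test_group_shapes(self, inputs):
        st = inputs.prior_stats
        assert st.sigma_e.shape == (4,)
        assert st.sigma_ae.shape == (7, 4)
        assert st.var_mean_ratio > 0
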