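"""Parameter model: distribution fitting, composite utility, config I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quitcea.errors import ConfigurationError, InfeasibleMomentsError, ValidationError
from quitcea.parameters import (
    AgeCurve,
    CVDUtilityComponents,
    DEFAULT_CVD_COMPONENTS,
    UncertainValue,
    composite_cvd_utility,
    default_parameters,
    fit_distribution,
    load_parameters,
    save_parameters,
)


class TestUncertainValue:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mean=1.2, se=0.1, family="beta"),       # beta needs mean in (0,1)
            dict(mean=-5.0, se=1.0, family="gamma"),     # gamma needs mean > 0
            dict(mean=0.0, se=0.1, family="lognormal"),  # lognormal needs mean > 0
            dict(mean=0.5, se=0.0, family="beta"),       # zero se must be 'fixed'
            dict(mean=0.5, se=0.1, family="fixed"),      # fixed cannot carry an se
            dict(mean=0.5, se=-0.1, family="beta"),      # negative se
        ],
    )
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            UncertainValue(**kwargs)

    def test_fixed_iff_se_absent_or_zero(self):
        assert UncertainValue(0.181).is_fixed
        assert UncertainValue(0.181, 0.0, "fixed").is_fixed
        assert not UncertainValue(0.5, 0.1, "beta").is_fixed


class TestFitDistribution:
    def test_beta_method_of_moments_closed_form(self):
        # mean 0.5, se 0.1 -> nu = 0.25/0.01 - 1 = 24 -> (a, b) = (12, 12)
        dist = fit_distribution(UncertainValue(0.5, 0.1, "beta"))
        a, b = dist.args
        assert (a, b) == pytest.approx((12.0, 12.0))

    def test_gamma_method_of_moments_closed_form(self):
        # shape = mean^2/var = 100, scale = var/mean = 1
        dist = fit_distribution(UncertainValue(100.0, 10.0, "gamma"))
        assert dist.kwds["a"] == pytest.approx(100.0)
        assert dist.kwds["scale"] == pytest.approx(1.0)

    def test_fixed_family_is_point_mass(self):
        dist = fit_distribution(UncertainValue(0.181))
        draws = dist.rvs(size=100, random_state=np.random.default_rng(0))
        assert np.all(draws == 0.181)
        assert dist.std() == 0.0

    def test_beta_infeasible_moments_rejected(self):
        # se^2 >= mean(1-mean) cannot come from any beta
        with pytest.raises(InfeasibleMomentsError):
            fit_distribution(UncertainValue(0.5, 0.6, "beta"))

    @settings(derandomize=True, max_examples=60)
    @given(
        family=st.sampled_from(["beta", "gamma", "lognormal"]),
        mean=st.floats(0.05, 0.95),
        cv=st.floats(0.02, 0.4),
    )
    def test_analytic_moments_match_inputs(self, family, mean, cv):
        """Fitted distributions reproduce (mean, se) analytically."""
        if family in ("gamma", "lognormal"):
            mean = mean * 1000  # cost-like scale
        uv = UncertainValue(mean, cv * mean, family)
        dist = fit_distribution(uv)
        assert dist.mean() == pytest.approx(uv.mean, rel=1e-9)
        assert dist.std() == pytest.approx(uv.se, rel=1e-9)

    @pytest.mark.parametrize(
        "uv",
        [
            UncertainValue(0.352, 0.047, "beta"),
            UncertainValue(1.42, 0.031, "lognormal"),
            UncertainValue(23_970.0, 4_000.0, "gamma"),
        ],
    )
    def test_empirical_moments_match_within_mc_error(self, uv):
        """10^5 draws land within 4 Monte-Carlo standard errors of (mean, se)."""
        n = 100_000
        draws = fit_distribution(uv).rvs(size=n, random_state=np.random.default_rng(7))
        se_mean = uv.se / math.sqrt(n)
        assert abs(draws.mean() - uv.mean) < 4 * se_mean
        # sd of the sample sd is roughly se/sqrt(2n) for near-normal shapes
        assert abs(draws.std(ddof=1) - uv.se) < 6 * uv.se / math.sqrt(2 * n)


class TestCompositeCvdUtility:
    def test_published_components_give_composite(self):
        assert composite_cvd_utility(DEFAULT_CVD_COMPONENTS) == pytest.approx(0.611)

    def test_order_invariant_and_bounded(self):
        shuffled = CVDUtilityComponents(tuple(reversed(DEFAULT_CVD_COMPONENTS.components)))
        value = composite_cvd_utility(shuffled)
        assert value == composite_cvd_utility(DEFAULT_CVD_COMPONENTS)
        utils = [u for _, u, _ in DEFAULT_CVD_COMPONENTS.components]
        assert min(utils) <= value <= max(utils)

    def test_degenerate_and_perfect_weightings(self):
        assert composite_cvd_utility(
            CVDUtilityComponents((("chf", 0.493, 100.0),))
        ) == pytest.approx(0.493)
        all_perfect = CVDUtilityComponents(
            tuple((n, 1.0, w) for n, _, w in DEFAULT_CVD_COMPONENTS.components)
        )
        assert composite_cvd_utility(all_perfect) == pytest.approx(1.0)

    def test_weights_must_sum_to_one_hundred(self):
        bad = CVDUtilityComponents((("cad", 0.629, 54.9), ("stroke", 0.649, 30.0)))
        with pytest.raises(ValidationError):
            composite_cvd_utility(bad)


class TestAgeCurve:
    def test_gap_in_ages_rejected(self):
        with pytest.raises(ValidationError):
            AgeCurve("male", [40, 41, 43], [0.1, 0.1, 0.1])

    def test_probability_range_enforced(self):
        with pytest.raises(ValidationError):
            AgeCurve("male", [40, 41], [0.5, 1.5])

    def test_endpoints_held_outside_range(self):
        c = AgeCurve("female", [40, 41, 42], [0.1, 0.2, 0.3])
        assert c.value_at(30) == 0.1
        assert c.value_at(99) == 0.3
        assert list(c.slice(41, 44)) == [0.2, 0.3, 0.3]


class TestDefaultsAndConfig:
    def test_defaults_reproduce_published_scalars(self, params):
        assert params.cvd_rr_smoker.mean == 1.42
        assert params.cvd_rr_smoker.se == 0.031
        assert params.utility_well_smoking == 0.800
        assert params.utility_well_quit == 0.830
        assert params.quit_rate[("adherent_intervention", "male")].mean == 0.352
        assert params.quit_rate[("usual_care", "female")].mean == 0.197
        assert params.background_mortality["male"].value_at(65) == pytest.approx(0.01071)
        assert params.excess_costs["lc_first_year"]["female"].value_at(65) == 22_256.0
        assert params.utility_cvd == pytest.approx(0.611)
        assert params.discount_rate == 0.035

    def test_round_trip_through_config_files(self, params, tmp_path):
        save_parameters(params, tmp_path)
        reloaded = load_parameters(tmp_path)
        assert reloaded.to_config_dict() == params.to_config_dict()
        for sex in ("male", "female"):
            assert reloaded.background_mortality[sex] == params.background_mortality[sex]
            assert reloaded.excess_costs["cvd_terminal_6mo"][sex] == (
                params.excess_costs["cvd_terminal_6mo"][sex]
            )

    def test_missing_key_names_the_key(self, params, tmp_path):
        save_parameters(params, tmp_path)
        cfg = (tmp_path / "params.yaml").read_text()
        (tmp_path / "params.yaml").write_text(cfg.replace("wtp_threshold", "wtp_thresh"))
        with pytest.raises(ConfigurationError, match="wtp_threshold"):
            load_parameters(tmp_path)

    def test_stage_proportions_must_sum_to_one(self, params):
        bad = params.copy()
        bad.lc_early_prop = 0.3  # 0.3 + 0.8 != 1
        with pytest.raises(ValidationError):
            bad.validate()
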