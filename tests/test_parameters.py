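import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from coilcea import (
    HtiEfficacySpec,
    beta_from_moments,
    default_parameter_table,
    gamma_from_moments,
    load_parameter_table,
    per_cycle_probability,
    sample_draw,
    sample_draws,
    sample_ordered_truncated_normal_group,
)
from coilcea.errors import (
    DegenerateProbabilityError,
    InfeasibleMomentsError,
    SchemaError,
)
from coilcea.parameters import expected_recanalization_with_hti


class TestLoadTable:
    def test_default_table_reproduces_published_rows(self, specs):
        assert len(specs) == 25
        by_id = {s.id: s for s in specs}
        assert by_id[1].mean == 0.048
        assert by_id[1].se == 0.005944
        assert by_id[1].dist_family == "beta"
        assert by_id[4].mean == 0.244 and by_id[4].source_duration_years == 6
        assert by_id[18].dist_family == "gamma" and by_id[18].mean == 93_440
        assert by_id[22].mean == -0.07
        assert by_id[25].mean == 10_000
        assert by_id[25].dist_family == "deterministic"

    def test_sensitivity_bounds_bracket_means(self, specs):
        for s in specs:
            if s.id == 22 or not np.isfinite(s.sens_low):
                continue
            assert s.sens_low <= s.mean <= s.sens_high, s.id

    def test_incomplete_table_rejected(self, tmp_path):
        from importlib import resources

        import pandas as pd

        full = pd.read_csv(
            resources.files("coilcea.data") / "parameters.csv", comment="#"
        )
        trimmed = tmp_path / "short.csv"
        full.iloc[:-1].to_csv(trimmed, index=False)
        with pytest.raises(SchemaError):
            load_parameter_table(trimmed)

    def test_duplicate_and_nonnumeric_rejected(self, tmp_path):
        from importlib import resources

        import pandas as pd

        full = pd.read_csv(
            resources.files("coilcea.data") / "parameters.csv", comment="#"
        )
        dup = full.copy()
        dup.loc[dup.index[-1], "id"] = 1
        p = tmp_path / "dup.csv"
        dup.to_csv(p, index=False)
        with pytest.raises(SchemaError):
            load_parameter_table(p)

        bad = full.copy()
        bad.loc[0, "mean"] = "not-a-number"
        p2 = tmp_path / "bad.csv"
        bad.to_csv(p2, index=False)
        with pytest.raises(SchemaError, match="mean"):
            load_parameter_table(p2)


class TestMomentMatching:
    def test_symmetric_beta_closed_form(self):
        a, b = beta_from_moments(0.5, 0.05)
        assert a == pytest.approx(49.5)
        assert b == pytest.approx(49.5)

    @pytest.mark.parametrize("mean,se", [(0.048, 0.005944), (0.244, 0.03592),
                                         (0.02, 0.002136), (0.07, 0.04082)])
    def test_beta_recovers_published_moments(self, mean, se):
        a, b = beta_from_moments(mean, se)
        m, v = stats.beta.stats(a, b, moments="mv")
        assert m == pytest.approx(mean, rel=1e-10)
        assert math.sqrt(v) == pytest.approx(se, rel=1e-10)

    def test_beta_infeasible_variance(self):
        with pytest.raises(InfeasibleMomentsError):
            beta_from_moments(0.2, 0.5)

    def test_gamma_closed_form_and_moments(self):
        assert gamma_from_moments(1, 1) == pytest.approx((1.0, 1.0))
        shape, scale = gamma_from_moments(93_440, 539)
        assert shape == pytest.approx(30047.4, rel=1e-3)
        assert scale == pytest.approx(3.1096, rel=1e-3)
        m, v = stats.gamma.stats(shape, scale=scale, moments="mv")
        assert m == pytest.approx(93_440, rel=1e-10)
        assert math.sqrt(v) == pytest.approx(539, rel=1e-10)

    def test_gamma_rejects_nonpositive(self):
        with pytest.raises(InfeasibleMomentsError):
            gamma_from_moments(10, 0)

    def test_truncated_normal_parent_solver(self):
        from coilcea import truncated_normal_from_moments

        mu, sigma = truncated_normal_from_moments(30_013, 15_905, 0.0, math.inf)
        a = (0.0 - mu) / sigma
        m, v = stats.truncnorm.stats(a, math.inf, loc=mu, scale=sigma, moments="mv")
        assert float(m) == pytest.approx(30_013, rel=1e-6)
        assert math.sqrt(float(v)) == pytest.approx(15_905, rel=1e-6)

    def test_truncated_normal_cv_bound(self):
        from coilcea import truncated_normal_from_moments

        # a non-negative truncated normal cannot reach CV >= 1
        with pytest.raises(InfeasibleMomentsError):
            truncated_normal_from_moments(100.0, 100.0, 0.0, math.inf)


class TestPerCycleProbability:
    def test_published_conversions(self):
        assert per_cycle_probability(0.0, 6.0) == 0.0
        assert per_cycle_probability(0.244, 6.0) == pytest.approx(
            1 - (1 - 0.244) ** (0.5 / 6), abs=1e-12
        )
        assert per_cycle_probability(0.244, 6.0) == pytest.approx(0.02303, abs=5e-5)
        assert per_cycle_probability(0.014, 1.0) == pytest.approx(
            1 - 0.986 ** 0.5, abs=1e-12
        )
        assert per_cycle_probability(0.014, 1.0) == pytest.approx(0.00703, abs=5e-5)

    def test_linear_method(self):
        assert per_cycle_probability(0.244, 6.0, method="linear") == pytest.approx(
            0.244 / 12
        )

    def test_per_event_passthrough(self):
        assert per_cycle_probability(0.124, 0.0) == 0.124
        assert per_cycle_probability(1.0, 0.0) == 1.0

    def test_degenerate_probability(self):
        with pytest.raises(DegenerateProbabilityError):
            per_cycle_probability(1.0, 6.0)

    @given(
        p=st.floats(1e-6, 0.99),
        p2=st.floats(1e-6, 0.99),
        cycle=st.floats(0.1, 2.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_p_and_cycle(self, p, p2, cycle):
        lo, hi = sorted((p, p2))
        assert per_cycle_probability(lo, 6.0, cycle) <= per_cycle_probability(
            hi, 6.0, cycle
        )
        assert per_cycle_probability(p, 6.0, cycle) <= per_cycle_probability(
            p, 6.0, cycle * 1.5
        )

    @given(p=st.floats(1e-6, 0.99))
    @settings(max_examples=100, deadline=None)
    def test_half_cycle_composition(self, p):
        half = per_cycle_probability(p, 1.0, 0.25)
        full = per_cycle_probability(p, 1.0, 0.5)
        assert 1 - (1 - half) ** 2 == pytest.approx(full, abs=1e-12)

    def test_expected_recanalization_under_adjunct(self):
        assert expected_recanalization_with_hti(0.244, 0.5) == pytest.approx(0.122)


class TestOrderedSampling:
    def test_utility_group_ordering_holds(self, specs, rng):
        group = [s for s in specs if s.order_group == "utility"]
        draws = sample_ordered_truncated_normal_group(group, rng, n=5_000)
        assert np.all(draws[19] >= draws[20])
        assert np.all(draws[20] >= draws[21])

    def test_cost_group_ordering_and_bounds(self, specs, rng):
        group = [s for s in specs if s.order_group == "procedure_cost"]
        draws = sample_ordered_truncated_normal_group(group, rng, n=20_000)
        assert np.all(draws[12] <= draws[13])
        assert np.all(draws[13] <= draws[14])
        assert all(np.all(v >= 0) for v in draws.values())

    def test_degenerate_group_returns_means(self, specs, rng):
        from dataclasses import replace

        group = [replace(s, se=0.0) for s in specs if s.order_group == "care_cost"]
        draws = sample_ordered_truncated_normal_group(group, rng, n=10)
        assert np.all(draws[15] == 11_197)
        assert np.all(draws[17] == 42_257)

    def test_marginal_means_close_to_published(self, specs, rng):
        group = [s for s in specs if s.order_group == "care_cost"]
        n = 20_000
        draws = sample_ordered_truncated_normal_group(group, rng, n=n)
        for s in group:
            tol = 4 * s.se / math.sqrt(n) + 0.005 * s.se  # residual rejection
            assert abs(draws[s.id].mean() - s.mean) < tol


class TestSampleDraw:
    def test_fixed_efficacy_is_exact(self, specs, rng):
        d = sample_draw(specs, HtiEfficacySpec("fixed", fixed_value=0.0), rng)
        assert d.rrr == 0.0

    def test_uniform_efficacy_mean_half(self, specs, rng):
        ds = sample_draws(specs, HtiEfficacySpec("uniform01"), 100_000, rng)
        assert ds.rrr.mean() == pytest.approx(0.5, abs=0.005)

    def test_bounded_normal_stays_in_unit_interval(self, specs, rng):
        ds = sample_draws(
            specs, HtiEfficacySpec("bounded_normal", mu=0.1, sigma=0.3), 20_000, rng
        )
        assert ds.rrr.min() >= 0.0 and ds.rrr.max() <= 1.0

    def test_disutility_negative_beta_magnitude(self, specs, rng):
        ds = sample_draws(specs, HtiEfficacySpec("uniform01"), 50_000, rng)
        d22 = ds.values[22]
        assert np.all(d22 <= 0) and np.all(d22 >= -1)
        assert d22.mean() == pytest.approx(-0.07, abs=4 * 0.04082 / math.sqrt(50_000))

    def test_moment_matching_every_stochastic_variable(self, specs, rng):
        # beta/gamma rows and the tightly-bounded ordered groups reproduce
        # their printed means; the 0-truncated procedure costs (SEs close to
        # their means) shift upward by truncation and ordering, which is
        # inherent to sampling a normal(mean, se) under those constraints
        n = 100_000
        ds = sample_draws(specs, HtiEfficacySpec("uniform01"), n, rng)
        proc_cost_ids = {12, 13, 14}
        for s in specs:
            if s.se == 0 or s.group == "hti":
                continue
            emp = ds.values[s.id].mean()
            if s.id in proc_cost_ids:
                assert s.mean <= emp <= s.mean + s.se, s.id
                continue
            target = abs(s.mean) if s.id == 22 else s.mean
            emp = np.abs(ds.values[s.id]).mean() if s.id == 22 else emp
            slack = 4 * s.se / math.sqrt(n)
            if s.order_group:  # residual rejection and truncation shift a little
                slack += 0.01 * s.se
            assert abs(emp - target) < max(slack, 1e-9), s.id

    def test_draw_invariants_hold_in_bulk(self, specs, rng):
        ds = sample_draws(specs, HtiEfficacySpec("uniform01"), 10_000, rng)
        for pid in range(1, 12):
            v = ds.values[pid]
            assert v.min() >= 0 and v.max() <= 1
        assert np.all(ds.values[12] <= ds.values[13])
        assert np.all(ds.values[13] <= ds.values[14])
        assert np.all(ds.values[15] <= ds.values[16])
        assert np.all(ds.values[16] <= ds.values[17])
        assert np.all(ds.values[19] >= ds.values[20])
        assert np.all(ds.values[20] >= ds.values[21])
        assert np.all((ds.mrs0_bands >= 0) & (ds.mrs0_bands <= 1))

    def test_age_bands_share_one_offset(self, specs, rng):
        ds = sample_draws(specs, HtiEfficacySpec("uniform01"), 1_000, rng)
        offsets = ds.mrs0_bands - np.array([0.87, 0.85, 0.86, 0.84])
        assert np.allclose(offsets, offsets[:, [0]], atol=1e-12)
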