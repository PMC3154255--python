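import math

import numpy as np
import pytest
import yaml
from hypothesis import given, strategies as st

from depscreen import (
    DistributionSpec,
    ParamValidationError,
    annual_to_cycle_prob,
    cycle_to_annual_prob,
    dist_mean,
    dist_sample,
    load_params,
    moments_to_gamma,
    save_params,
    validate_paramset,
    write_fixture_bundle,
)
from depscreen.parameters import CurveSpec, load_curve_csv


class TestAnnualToCycle:
    @pytest.mark.parametrize(
        "p_year, expected, tol",
        [
            (21 / 111, 0.016, 5e-4),  # control-arm one-year incidence -> 1.6%/cycle
            (14 / 109, 0.011, 5e-4),  # treated-arm one-year incidence -> 1.1%/cycle
            (0.0, 0.0, 0.0),
            (1.0, 1.0, 0.0),
        ],
    )
    def test_constant_hazard_transform(self, p_year, expected, tol):
        assert annual_to_cycle_prob(p_year, 13) == pytest.approx(expected, abs=max(tol, 1e-15))

    @pytest.mark.parametrize("bad", [-0.1, 1.1, 2.0])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            annual_to_cycle_prob(bad, 13)

    @given(p=st.floats(0.0, 1.0), cpy=st.integers(1, 52))
    def test_roundtrip_is_identity(self, p, cpy):
        assert cycle_to_annual_prob(annual_to_cycle_prob(p, cpy), cpy) == pytest.approx(
            p, abs=1e-12
        )

    @given(p=st.floats(0.0, 1.0))
    def test_cycle_prob_never_exceeds_annual(self, p):
        assert annual_to_cycle_prob(p, 13) <= p + 1e-15

    def test_monotone_in_annual_probability(self):
        grid = np.linspace(0, 1, 101)
        vals = [annual_to_cycle_prob(p, 13) for p in grid]
        assert all(a <= b for a, b in zip(vals, vals[1:]))


class TestDistributions:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(106, 11, 0.906), (3826, 1452, 0.725), (364, 3463, 0.095),
         (217, 148, 0.595), (1, 1, 0.5)],
    )
    def test_beta_mean_matches_published_point(self, a, b, expected):
        spec = DistributionSpec("beta", a, b, expected, 0.0, 1.0)
        assert dist_mean(spec) == pytest.approx(expected, abs=1e-3)

    def test_beta_sampling_converges_to_mean(self):
        spec = DistributionSpec("beta", 106, 11, 0.906, 0.847, 0.952)
        draws = dist_sample(spec, 50_000, seed=7)
        assert draws.mean() == pytest.approx(0.906, abs=0.005)
        assert ((draws >= 0) & (draws <= 1)).all()

    def test_gamma_support_positive(self):
        spec = moments_to_gamma(132, 73, 207)
        draws = dist_sample(spec, 10_000, seed=3)
        assert (draws > 0).all()
        assert draws.mean() == pytest.approx(132, rel=0.02)

    def test_degenerate_spec_short_circuits(self):
        spec = DistributionSpec("gamma", 1.0, 1.0, 268.0, 268.0, 268.0)
        assert (dist_sample(spec, 100, seed=0) == 268.0).all()

    def test_same_seed_same_draws(self):
        spec = DistributionSpec("beta", 21, 90, 0.016, 0.010, 0.023)
        a = dist_sample(spec, 64, seed=11)
        b = dist_sample(spec, 64, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_invalid_family_rejected(self):
        with pytest.raises(ValueError):
            DistributionSpec("lognormal", 1.0, 1.0, 0.5, 0.0, 1.0)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            DistributionSpec("beta", -1.0, 2.0, 0.5, 0.0, 1.0)
        with pytest.raises(ValueError):
            DistributionSpec("beta", 2.0, 2.0, 1.5, 0.0, 2.0)
        with pytest.raises(ValueError):
            DistributionSpec("gamma", 1.0, 1.0, 5.0, 6.0, 7.0)  # point below CI


class TestMomentsToGamma:
    def test_mean_and_sd_recovered_from_shape_scale(self):
        spec = moments_to_gamma(132, 73, 207)
        assert spec.shape_a * spec.shape_b == pytest.approx(132, abs=1e-9)
        sd = math.sqrt(spec.shape_a) * spec.shape_b
        assert sd == pytest.approx((207 - 73) / 3.92, abs=1e-9)

    def test_point_estimate_preserved_for_inconsistent_printed_pair(self):
        # printed gamma(13, 11) does not reproduce its printed mean of 268
        spec = moments_to_gamma(268, 150, 419)
        assert dist_mean(spec) == 268
        assert spec.shape_a * spec.shape_b == pytest.approx(268, abs=1e-9)

    def test_zero_width_ci_is_degenerate(self):
        spec = moments_to_gamma(50.0, 50.0, 50.0)
        assert spec.is_degenerate
        assert (dist_sample(spec, 10, seed=0) == 50.0).all()

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            moments_to_gamma(0.0, 0.0, 1.0)


class TestCollapse:
    def test_beta_collapses_to_sampling_mean(self):
        spec = DistributionSpec("beta", 21, 90, 0.016, 0.010, 0.023)
        col = spec.collapsed()
        assert col.is_degenerate
        assert col.point_estimate == pytest.approx(21 / 111)

    def test_gamma_collapses_to_its_mean(self):
        spec = moments_to_gamma(615, 308, 1022)
        assert spec.collapsed().point_estimate == pytest.approx(615, abs=1e-9)


class TestParamFileIO:
    def test_fixture_bundle_round_trips(self, tmp_path):
        write_fixture_bundle(tmp_path)
        params = load_params(tmp_path / "params.yaml")
        assert params.weights.dw_mde == 0.46
        assert params.weights.dw_sub == 0.097
        assert params.grid.horizon_cycles == 65

        save_params(params, tmp_path / "again" / "params.yaml")
        again = load_params(tmp_path / "again" / "params.yaml")
        assert again == params  # bit-equal round trip

    def test_missing_curve_is_validation_error(self, tmp_path):
        write_fixture_bundle(tmp_path)
        doc = yaml.safe_load((tmp_path / "params.yaml").read_text())
        del doc["transitions"]["recovery_curve"]
        bad = tmp_path / "bad.yaml"
        bad.write_text(yaml.safe_dump(doc))
        with pytest.raises(ParamValidationError, match="recovery_curve"):
            load_params(bad)

    def test_schema_errors_name_offending_keys(self, tmp_path):
        doc = {"schema": "depscreen-params-v1"}
        bad = tmp_path / "bad.yaml"
        bad.write_text(yaml.safe_dump(doc))
        with pytest.raises(ParamValidationError, match="grid"):
            load_params(bad)

    def test_curve_csv_requires_contiguous_index(self, tmp_path):
        f = tmp_path / "c.csv"
        f.write_text("cycle_index,probability\n1,0.2\n3,0.1\n")
        with pytest.raises(ParamValidationError, match="without gaps"):
            load_curve_csv(f)


class TestCurveSpec:
    def test_tail_rules(self):
        curve = CurveSpec(p=(0.3, 0.2, 0.1), tail_rule="hold_last")
        assert curve.prob(3) == 0.1
        assert curve.prob(10) == 0.1
        zero = CurveSpec(p=(0.3, 0.2, 0.1), tail_rule="zero")
        assert zero.prob(10) == 0.0
        np.testing.assert_allclose(curve.extended(5), [0.3, 0.2, 0.1, 0.1, 0.1])

    def test_probability_range_enforced(self):
        with pytest.raises(ValueError):
            CurveSpec(p=(0.5, 1.2))


class TestValidateParamset:
    def test_base_case_passes_every_check(self, base_params):
        checks = validate_paramset(base_params)
        failures = [(n, d) for n, ok, d in checks if not ok]
        assert failures == []

    def test_beta_consistency_checks_cover_incidence_rows(self, base_params):
        names = [n for n, _, _ in validate_paramset(base_params)]
        assert any("p_year_ref" in n for n in names)
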