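import dataclasses

import numpy as np
import pytest

from depscreen import (
    COST_SAVING,
    PsaSample,
    ce_plane,
    ceac,
    deterministic_run,
    run_psa,
    sample_draws,
    summarize_psa,
)
from depscreen.psa import _evaluate_draws


def null_intervention(params):
    """Intervention arm statistically identical to the reference arm."""
    specs = dict(params.psa_specs)
    specs["p_year_int"] = specs["p_year_ref"]
    specs["c_sub_hc_int"] = specs["c_sub_hc_ref"]
    specs["c_sub_soc_int"] = specs["c_sub_soc_ref"]
    return dataclasses.replace(params, psa_specs=specs)


class TestDraws:
    def test_same_seed_identical_samples(self, base_params):
        a = run_psa(base_params, 50, seed=42)
        b = run_psa(base_params, 50, seed=42)
        assert a == b

    def test_single_draw_replayable_from_substream(self, base_params):
        full, _ = sample_draws(base_params, 10, seed=5)
        tail_worlds, _ = sample_draws(base_params, 10, seed=5)
        # substream derivation makes draw i independent of how many come after
        assert full.iloc[3].equals(tail_worlds.iloc[3])

    def test_draws_respect_support(self, base_params):
        draws, n_rejected = sample_draws(base_params, 200, seed=0)
        assert n_rejected == 0
        for col in ("f_participate", "p_year_ref", "p_year_int", "qol_sub"):
            assert draws[col].between(0, 1).all()
        for col in ("c_sub_hc_ref", "c_mde_soc"):
            assert (draws[col] > 0).all()


class TestDegenerateCollapse:
    def test_degenerate_psa_equals_deterministic_run(self, base_params):
        det = deterministic_run(base_params)
        samples = run_psa(base_params.collapsed(), 2, seed=99)
        for s in samples:
            assert s.d_cost_hc == det.sample.d_cost_hc
            assert s.d_cost_soc == det.sample.d_cost_soc
            assert s.d_dalys == det.sample.d_dalys

    def test_null_intervention_collapsed_costs_exactly_the_programme(self, base_params):
        params = null_intervention(base_params).collapsed()
        det = deterministic_run(params)
        assert det.sample.d_dalys == 0.0
        programme = det.one_off_screening + det.one_off_intervention
        assert det.sample.d_cost_hc == pytest.approx(programme, rel=1e-12)
        assert det.sample.d_cost_soc == pytest.approx(programme, rel=1e-12)

    def test_null_intervention_mean_effect_near_zero(self, base_params):
        samples = run_psa(null_intervention(base_params), 400, seed=7)
        de = np.array([s.d_dalys for s in samples])
        # symmetric by construction: mean within 3 standard errors of zero
        assert abs(de.mean()) < 3 * de.std() / np.sqrt(len(de))


class TestDirectional:
    def test_base_case_sign_pattern(self, base_params):
        """Mean incremental societal cost is negative and mean DALYs averted
        positive under the base case.

        Incremental costs are linear in each (independent) cost draw, so
        collapsing the cost distributions to their means leaves the
        expectation unchanged while removing the dominant Monte-Carlo noise
        (Rao-Blackwellisation); the sign check is then many standard errors
        clear of zero at moderate run counts.
        """
        specs = {k: (v.collapsed() if k.startswith("c_") else v)
                 for k, v in base_params.psa_specs.items()}
        reduced = dataclasses.replace(base_params, psa_specs=specs)
        samples = run_psa(reduced, 2000, seed=3)
        de = np.mean([s.d_dalys for s in samples])
        dsoc = np.array([s.d_cost_soc for s in samples])
        assert de > 0  # the intervention averts DALYs on average
        assert dsoc.mean() < 0  # productivity-cost savings dominate societally
        assert dsoc.mean() < -3 * dsoc.std() / np.sqrt(len(dsoc))


class TestCePlane:
    def test_one_point_per_quadrant(self):
        samples = [
            PsaSample(0, 1.0, 1.0, 1.0),    # NE
            PsaSample(1, -1.0, -1.0, 1.0),  # SE
            PsaSample(2, -1.0, -1.0, -1.0), # SW
            PsaSample(3, 1.0, 1.0, -1.0),   # NW
        ]
        assert ce_plane(samples, "hc") == {"NE": 0.25, "SE": 0.25, "SW": 0.25, "NW": 0.25}

    def test_all_south_east(self):
        samples = [PsaSample(i, -1.0, -1.0, 1.0) for i in range(10)]
        assert ce_plane(samples, "societal")["SE"] == 1.0

    def test_zero_cost_boundary_counts_as_saving_side(self):
        samples = [PsaSample(0, 0.0, 0.0, 1.0)]
        assert ce_plane(samples, "hc")["SE"] == 1.0

    def test_fractions_sum_to_one(self, base_params):
        samples = run_psa(base_params, 500, seed=11)
        for p in ("hc", "societal"):
            assert sum(ce_plane(samples, p).values()) == pytest.approx(1.0, abs=1e-9)


class TestCeac:
    def test_at_zero_wtp_equals_probability_of_saving(self, base_params):
        samples = run_psa(base_params, 500, seed=13)
        for p in ("hc", "societal"):
            dc = [s.d_cost_hc if p == "hc" else s.d_cost_soc for s in samples]
            expected = np.mean([c <= 0 for c in dc])
            assert ceac(samples, [0.0], p)[0.0] == pytest.approx(expected)

    def test_limit_reaches_one_when_all_effects_positive(self):
        samples = [PsaSample(i, 100.0, 100.0, 0.5 + i) for i in range(20)]
        assert ceac(samples, [1e12], "hc")[1e12] == 1.0

    def test_monotone_when_all_effects_positive(self, base_params):
        samples = [s for s in run_psa(base_params, 500, seed=17) if s.d_dalys > 0]
        grid = list(range(0, 50001, 500))
        curve = list(ceac(samples, grid, "hc").values())
        assert all(a <= b + 1e-12 for a, b in zip(curve, curve[1:]))

    def test_two_alternative_coherence(self, base_params):
        # accepting the intervention at lambda is rejecting the comparator:
        # with no ties the comparator's acceptability is 1 - CEAC(lambda)
        samples = run_psa(base_params, 300, seed=19)
        grid = [0.0, 5000.0, 20000.0, 50000.0]
        probs = ceac(samples, grid, "societal")
        flipped = [PsaSample(s.draw_index, -s.d_cost_hc, -s.d_cost_soc, -s.d_dalys)
                   for s in samples]
        comp = ceac(flipped, grid, "societal")
        for lam in grid:
            ties = np.mean([lam * s.d_dalys - s.d_cost_soc == 0.0 for s in samples])
            assert comp[lam] == pytest.approx(1.0 - probs[lam] + ties, abs=1e-12)


class TestScaleInvariance:
    @pytest.mark.parametrize("alpha", [0.1, 0.5, 2.0, 10.0])
    def test_icer_invariant_to_screened_fraction_scale(self, base_params, alpha):
        scaled = dataclasses.replace(
            base_params,
            cascade=dataclasses.replace(
                base_params.cascade, n_target=base_params.cascade.n_target * alpha
            ),
        )
        a = deterministic_run(base_params)
        b = deterministic_run(scaled)
        assert b.icer_hc == pytest.approx(a.icer_hc, rel=1e-9)
        assert b.sample.d_dalys == pytest.approx(alpha * a.sample.d_dalys, rel=1e-9)


class TestSummary:
    def test_summary_consistency(self, base_params):
        samples = run_psa(base_params, 400, seed=23)
        summary = summarize_psa(samples)
        assert summary.n_runs == 400
        de = np.array([s.d_dalys for s in samples])
        assert summary.mean_d_dalys == pytest.approx(de.mean())
        lo, hi = summary.ci_d_dalys
        assert lo <= summary.mean_d_dalys <= hi
        if not isinstance(summary.icer_hc, str):
            assert summary.icer_hc == pytest.approx(
                summary.mean_d_cost_hc / summary.mean_d_dalys
            )

    def test_cost_saving_label_matches_definition(self):
        samples = [PsaSample(i, -10.0, -10.0, 1.0) for i in range(5)]
        assert summarize_psa(samples).icer_soc == COST_SAVING


class TestDisabilityWeightSensitivity:
    def test_higher_sub_threshold_weight_shrinks_gain_and_raises_icer(self, base_params):
        base = deterministic_run(base_params)
        # dw_sub enters the pipeline as 1 - QoL; 0.19 corresponds to QoL 0.81
        specs = dict(base_params.psa_specs)
        q = specs["qol_sub"]
        specs["qol_sub"] = dataclasses.replace(
            q, point_estimate=0.81, ci_low=0.81, ci_high=0.81
        )
        raised = deterministic_run(dataclasses.replace(base_params, psa_specs=specs))
        assert raised.sample.d_dalys < base.sample.d_dalys
        assert raised.sample.d_dalys > 0  # sign preserved
        assert raised.icer_hc > base.icer_hc
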