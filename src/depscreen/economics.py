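"""Discounted DALYs, discounted costs and incremental cost-effectiveness ratios.

Health effects are expressed as disability-adjusted life years: time spent in
each state (in years) weighted by that state's disability weight.  There is no
mortality in the model, so the DALY stream is pure years-lived-with-disability.
Costs and effects are discounted at different annual rates (Dutch guideline:
4% for costs, 1.5% for effects) with exact fractional-year exponents per
cycle.  One-off screening and intervention outlays fall at t=0 and are not
discounted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cascade import cascade_costs, cascade_counts
from .cohort import Trajectory
from .parameters import CostSet, DisabilityWeights, DiscountRates, ParamSet

__all__ = [
    "COST_SAVING",
    "DOMINATED",
    "PERSPECTIVES",
    "ScenarioEconomics",
    "IncrementalResult",
    "discount_factor",
    "dalys",
    "costs",
    "icer",
    "scenario_economics",
    "incremental",
]

COST_SAVING = "cost saving"
DOMINATED = "dominated"
PERSPECTIVES = ("hc", "societal")


def discount_factor(rate: float, cycle: int, cycles_per_year: int = 13) -> float:
    """Present-value factor (1 + rate)^(-cycle / cycles_per_year); 1 at cycle 0."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    return (1.0 + rate) ** (-cycle / cycles_per_year)


def _discount_vector(rate: float, n_cycles: int, cycles_per_year: int) -> np.ndarray:
    return (1.0 + rate) ** (-np.arange(n_cycles) / cycles_per_year)


def _state_weights(traj: Trajectory, w: DisabilityWeights) -> np.ndarray:
    return np.array([
        w.dw_mde if s.startswith("MDE") else (w.dw_rec if s.startswith("REC") else w.dw_sub)
        for s in traj.states
    ])


def dalys(traj: Trajectory, w: DisabilityWeights, r: DiscountRates) -> float:
    """Discounted DALYs accrued over the trajectory.

    Each cycle contributes occupancy x cohort size x disability weight x
    cycle length in years, discounted at the effects rate.  Membership is
    counted at cycle start, so the accrual runs over cycles 0..horizon-1.
    """
    h = traj.horizon_cycles
    df = _discount_vector(r.rate_effects, h, traj.cycles_per_year)
    weights = _state_weights(traj, w)
    per_cycle = traj.occupancy[:h] @ weights  # weighted occupancy per cycle
    return float((per_cycle * df).sum() * traj.cohort_size / traj.cycles_per_year)


def costs(
    traj: Trajectory,
    cs: CostSet,
    scenario: str,
    r: DiscountRates,
    perspective: str,
    effect_duration_cycles: int = 13,
    one_off_costs: float = 0.0,
) -> float:
    """Discounted costs (euro) of a trajectory from one perspective.

    The societal columns already include health care, so each perspective
    reads a single cost column per state.  Sub-threshold persons in the
    intervention scenario carry the intervention-arm cost during the one-year
    effect window and the reference cost afterwards; recovered persons always
    cost the same as (reference) sub-threshold persons.  ``one_off_costs``
    (screening + intervention outlays) are added undiscounted at t=0.
    """
    if perspective not in PERSPECTIVES:
        raise ValueError(f"unknown perspective {perspective!r}")
    if scenario not in ("reference", "intervention"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if perspective == "hc":
        c_sub_ref, c_sub_int, c_mde, c_rec = cs.sub_hc_ref, cs.sub_hc_int, cs.mde_hc, cs.rec_hc
    else:
        c_sub_ref, c_sub_int, c_mde, c_rec = cs.sub_soc_ref, cs.sub_soc_int, cs.mde_soc, cs.rec_soc

    h = traj.horizon_cycles
    df = _discount_vector(r.rate_costs, h, traj.cycles_per_year)
    sub = traj.sub()[:h]
    mde = traj.mde_total()[:h]
    rec = traj.rec_total()[:h]

    c_sub = np.full(h, c_sub_ref)
    if scenario == "intervention":
        c_sub[: min(effect_duration_cycles, h)] = c_sub_int

    total = ((sub * c_sub + mde * c_mde + rec * c_rec) * df).sum() * traj.cohort_size
    return float(total + one_off_costs)


def icer(mean_d_cost: float, mean_d_dalys: float) -> float | str:
    """Incremental cost-effectiveness ratio: mean incremental cost per DALY averted.

    Returns the label ``"cost saving"`` when the intervention both saves money
    and averts DALYs, ``"dominated"`` when it costs more and loses health, and
    NaN (undefined ratio, not an exception) when the effect difference is
    exactly zero.
    """
    if mean_d_dalys == 0.0:
        return math.nan
    if mean_d_cost < 0.0 and mean_d_dalys > 0.0:
        return COST_SAVING
    if mean_d_cost > 0.0 and mean_d_dalys < 0.0:
        return DOMINATED
    return mean_d_cost / mean_d_dalys


@dataclass(frozen=True)
class ScenarioEconomics:
    """Discounted outcomes of one scenario: DALYs, costs per perspective, one-offs."""

    dalys: float
    cost_hc: float
    cost_soc: float
    one_off_screening: float = 0.0
    one_off_intervention: float = 0.0


@dataclass(frozen=True)
class IncrementalResult:
    """Intervention-minus-reference costs and reference-minus-intervention DALYs."""

    d_cost_hc: float
    d_cost_soc: float
    d_dalys_averted: float
    icer_hc: float | str
    icer_soc: float | str


def scenario_economics(
    traj: Trajectory,
    params: ParamSet,
    scenario: str,
    include_one_off: bool | None = None,
) -> ScenarioEconomics:
    """Full discounted accounting of one scenario under a ParamSet.

    One-off screening and intervention costs are charged to the intervention
    scenario by default (the reference scenario has no programme).
    """
    if include_one_off is None:
        include_one_off = scenario == "intervention"
    screening = intervention_cost = 0.0
    if include_one_off:
        screening, intervention_cost = cascade_costs(
            cascade_counts(params.cascade), params.cascade
        )
    one_off = screening + intervention_cost
    eff_cycles = params.transitions.effect_duration_cycles
    return ScenarioEconomics(
        dalys=dalys(traj, params.weights, params.discounts),
        cost_hc=costs(traj, params.costs, scenario, params.discounts, "hc",
                      eff_cycles, one_off),
        cost_soc=costs(traj, params.costs, scenario, params.discounts, "societal",
                       eff_cycles, one_off),
        one_off_screening=screening,
        one_off_intervention=intervention_cost,
    )


def incremental(ref: ScenarioEconomics, interv: ScenarioEconomics) -> IncrementalResult:
    """Incremental result with DALYs averted reported as reference minus intervention."""
    d_cost_hc = interv.cost_hc - ref.cost_hc
    d_cost_soc = interv.cost_soc - ref.cost_soc
    d_dalys = ref.dalys - interv.dalys
    return IncrementalResult(
        d_cost_hc=d_cost_hc,
        d_cost_soc=d_cost_soc,
        d_dalys_averted=d_dalys,
        icer_hc=icer(d_cost_hc, d_dalys),
        icer_soc=icer(d_cost_soc, d_dalys),
    )
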