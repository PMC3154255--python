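"""Probabilistic sensitivity analysis, cost-effectiveness plane and CEAC.

Each Monte-Carlo run draws every uncertain input once (screening-cascade
fractions, one-year incidence probabilities, per-cycle costs, sub-threshold
quality of life), rebuilds both scenarios as an internally consistent world,
runs the cohort model, and records incremental costs (two perspectives) and
incremental DALYs averted.  All inputs are sampled independently — only
marginal distributions are available — and each draw has its own
deterministically derived random substream so single draws are replayable.

The deterministic base case is, by construction, the same pipeline evaluated
with every distribution collapsed to its mean: a degenerate PSA reproduces it
exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cascade import CascadeCounts
from .cohort import _step_arrays, _tunnel_probs
from .economics import icer
from .parameters import DistributionSpec, ParamSet, dist_sample

__all__ = [
    "PSA_INPUT_NAMES",
    "PsaSample",
    "PsaSummary",
    "DeterministicResult",
    "sample_draws",
    "run_psa",
    "deterministic_run",
    "ce_plane",
    "ceac",
    "summarize_psa",
    "samples_to_frame",
]

logger = logging.getLogger("depscreen.psa")

#: Model inputs resampled in every PSA run, in draw order.
PSA_INPUT_NAMES = (
    "f_participate",
    "f_screened_to_interview",
    "f_treated_given_interviewed",
    "p_year_ref",
    "p_year_int",
    "c_sub_hc_ref",
    "c_sub_hc_int",
    "c_sub_soc_ref",
    "c_sub_soc_int",
    "c_mde_hc",
    "c_mde_soc",
    "qol_sub",
)

_FRACTION_NAMES = (
    "f_participate", "f_screened_to_interview", "f_treated_given_interviewed",
    "p_year_ref", "p_year_int", "qol_sub",
)


@dataclass(frozen=True)
class PsaSample:
    """One draw's incremental costs (both perspectives) and DALYs averted."""

    draw_index: int
    d_cost_hc: float
    d_cost_soc: float
    d_dalys: float


@dataclass(frozen=True)
class PsaSummary:
    """Means, uncertainty intervals, plane quadrants, CEAC and ICERs of a PSA."""

    n_runs: int
    mean_d_cost_hc: float
    mean_d_cost_soc: float
    mean_d_dalys: float
    ci_d_cost_hc: tuple[float, float]
    ci_d_cost_soc: tuple[float, float]
    ci_d_dalys: tuple[float, float]
    quadrants: Mapping[str, Mapping[str, float]]
    ceac: Mapping[str, Mapping[float, float]]
    icer_hc: float | str
    icer_soc: float | str
    n_rejected: int = 0


@dataclass(frozen=True)
class DeterministicResult:
    """Point-estimate (collapsed-distribution) run with its full breakdown."""

    sample: PsaSample
    counts: CascadeCounts
    one_off_screening: float
    one_off_intervention: float
    dalys_ref: float
    dalys_int: float
    cost_hc_ref: float
    cost_hc_int: float
    cost_soc_ref: float
    cost_soc_int: float
    icer_hc: float | str
    icer_soc: float | str


def _fallback_spec(name: str, params: ParamSet) -> DistributionSpec:
    """Degenerate spec at the deterministic value, for inputs without a
    distribution in the ParamSet catalogue."""
    c, t, w = params.cascade, params.transitions, params.weights
    value = {
        "f_participate": c.f_participate_screen,
        "f_screened_to_interview": c.f_screened_to_interview,
        "f_treated_given_interviewed": c.f_not_excluded,
        "p_year_ref": t.p_inc_year_ref,
        "p_year_int": t.p_inc_year_int,
        "c_sub_hc_ref": params.costs.sub_hc_ref,
        "c_sub_hc_int": params.costs.sub_hc_int,
        "c_sub_soc_ref": params.costs.sub_soc_ref,
        "c_sub_soc_int": params.costs.sub_soc_int,
        "c_mde_hc": params.costs.mde_hc,
        "c_mde_soc": params.costs.mde_soc,
        "qol_sub": 1.0 - w.dw_sub,
    }[name]
    family = "gamma" if name.startswith("c_") else "beta"
    return DistributionSpec(family, 1.0, 1.0, value, value, value, "point estimate")


def _draw_valid(draw: dict[str, float]) -> bool:
    if any(not 0.0 <= draw[k] <= 1.0 for k in _FRACTION_NAMES):
        return False
    return all(draw[k] >= 0.0 for k in PSA_INPUT_NAMES if k.startswith("c_"))


def sample_draws(params: ParamSet, n_runs: int, seed: int) -> tuple[pd.DataFrame, int]:
    """Sample ``n_runs`` parameter worlds; returns (draws, n_rejected).

    Draw *i* uses the *i*-th child of ``SeedSequence(seed)``, so any single
    draw can be regenerated without rerunning the others.  Draws producing an
    out-of-support probability or a negative cost are rejected and redrawn
    from the same substream (counted and logged; cannot occur with beta/gamma
    families but kept as a guard for user-supplied specs).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    specs = {
        name: params.psa_specs.get(name) or _fallback_spec(name, params)
        for name in PSA_INPUT_NAMES
    }
    children = np.random.SeedSequence(seed).spawn(n_runs)
    rows = []
    n_rejected = 0
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        for _attempt in range(100):
            draw = {name: float(dist_sample(specs[name], 1, rng)[0])
                    for name in PSA_INPUT_NAMES}
            if _draw_valid(draw):
                break
            n_rejected += 1
        else:
            raise RuntimeError(f"draw {i}: no valid sample after 100 attempts")
        rows.append(draw)
    if n_rejected:
        logger.info("PSA rejected and redrew %d invalid draws", n_rejected)
    draws = pd.DataFrame(rows)
    draws.index.name = "draw_index"
    return draws, n_rejected


def _batch_accumulators(
    p_cycle: np.ndarray,
    p_cycle_late: np.ndarray,
    params: ParamSet,
) -> dict[str, np.ndarray]:
    """Run n cohorts in parallel and accumulate discounted person-cycles.

    ``p_cycle`` applies during the effect window (cycles 0..eff-1) and
    ``p_cycle_late`` afterwards; passing the same array twice gives the
    reference scenario.  Returns, per unit cohort, effect-discounted
    person-cycles by super-state and cost-discounted person-cycles with the
    sub-threshold time split at the effect-window boundary.
    """
    grid = params.grid
    n = p_cycle.shape[0]
    nm = params.transitions.recovery_curve.span_cycles + 1
    nr = params.transitions.relapse_curve.span_cycles + 1
    r_ext = _tunnel_probs(params.transitions.recovery_curve)
    s_ext = _tunnel_probs(params.transitions.relapse_curve)
    eff = params.transitions.effect_duration_cycles

    t_idx = np.arange(grid.horizon_cycles)
    df_eff = (1.0 + params.discounts.rate_effects) ** (-t_idx / grid.cycles_per_year)
    df_cost = (1.0 + params.discounts.rate_costs) ** (-t_idx / grid.cycles_per_year)

    sub = np.ones(n)
    mde = np.zeros((n, nm))
    rec = np.zeros((n, nr))
    acc = {k: np.zeros(n) for k in (
        "eff_sub", "eff_mde", "eff_rec",
        "cost_sub_early", "cost_sub_late", "cost_mde", "cost_rec",
    )}
    for t in range(grid.horizon_cycles):
        mde_tot = mde.sum(axis=1)
        rec_tot = rec.sum(axis=1)
        acc["eff_sub"] += sub * df_eff[t]
        acc["eff_mde"] += mde_tot * df_eff[t]
        acc["eff_rec"] += rec_tot * df_eff[t]
        acc["cost_sub_early" if t < eff else "cost_sub_late"] += sub * df_cost[t]
        acc["cost_mde"] += mde_tot * df_cost[t]
        acc["cost_rec"] += rec_tot * df_cost[t]
        p = p_cycle if t < eff else p_cycle_late
        sub, mde, rec = _step_arrays(sub, mde, rec, p, r_ext, s_ext)
    return acc


def _evaluate_draws(
    draws: pd.DataFrame, params: ParamSet
) -> tuple[list[PsaSample], dict[str, np.ndarray]]:
    """Turn sampled parameter worlds into incremental outcomes (vectorised)."""
    grid = params.grid
    cpy = grid.cycles_per_year
    g = lambda name: draws[name].to_numpy()

    # cascade counts and one-off outlays per draw
    n_screened = params.cascade.n_target * g("f_participate")
    n_interviewed = n_screened * g("f_screened_to_interview")
    n_treated = n_interviewed * g("f_treated_given_interviewed")
    one_off_screening = (n_screened * params.costs.screen_step1
                         + n_interviewed * params.costs.screen_step2)
    one_off_intervention = n_treated * params.costs.intervention
    one_off = one_off_screening + one_off_intervention

    # one-year incidence draws -> per-cycle probabilities (constant hazard)
    p_cycle_ref = 1.0 - (1.0 - g("p_year_ref")) ** (1.0 / cpy)
    p_cycle_int = 1.0 - (1.0 - g("p_year_int")) ** (1.0 / cpy)

    acc_ref = _batch_accumulators(p_cycle_ref, p_cycle_ref, params)
    acc_int = _batch_accumulators(p_cycle_int, p_cycle_ref, params)

    dw_sub = 1.0 - g("qol_sub")
    dw_mde = params.weights.dw_mde
    dalys_ref = (dw_sub * (acc_ref["eff_sub"] + acc_ref["eff_rec"])
                 + dw_mde * acc_ref["eff_mde"]) / cpy * n_treated
    dalys_int = (dw_sub * (acc_int["eff_sub"] + acc_int["eff_rec"])
                 + dw_mde * acc_int["eff_mde"]) / cpy * n_treated

    def scenario_cost(acc, c_sub_early, c_sub_late, c_mde, c_rec, extra):
        per_unit = (c_sub_early * acc["cost_sub_early"]
                    + c_sub_late * acc["cost_sub_late"]
                    + c_mde * acc["cost_mde"]
                    + c_rec * acc["cost_rec"])
        return per_unit * n_treated + extra

    zero = np.zeros_like(n_treated)
    # recovered persons cost the same as reference sub-threshold persons
    cost_hc_ref = scenario_cost(acc_ref, g("c_sub_hc_ref"), g("c_sub_hc_ref"),
                                g("c_mde_hc"), g("c_sub_hc_ref"), zero)
    cost_hc_int = scenario_cost(acc_int, g("c_sub_hc_int"), g("c_sub_hc_ref"),
                                g("c_mde_hc"), g("c_sub_hc_ref"), one_off)
    cost_soc_ref = scenario_cost(acc_ref, g("c_sub_soc_ref"), g("c_sub_soc_ref"),
                                 g("c_mde_soc"), g("c_sub_soc_ref"), zero)
    cost_soc_int = scenario_cost(acc_int, g("c_sub_soc_int"), g("c_sub_soc_ref"),
                                 g("c_mde_soc"), g("c_sub_soc_ref"), one_off)

    d_cost_hc = cost_hc_int - cost_hc_ref
    d_cost_soc = cost_soc_int - cost_soc_ref
    d_dalys = dalys_ref - dalys_int

    samples = [
        PsaSample(i, float(d_cost_hc[i]), float(d_cost_soc[i]), float(d_dalys[i]))
        for i in range(len(draws))
    ]
    detail = {
        "n_screened": n_screened, "n_interviewed": n_interviewed,
        "n_treated": n_treated,
        "one_off_screening": one_off_screening,
        "one_off_intervention": one_off_intervention,
        "dalys_ref": dalys_ref, "dalys_int": dalys_int,
        "cost_hc_ref": cost_hc_ref, "cost_hc_int": cost_hc_int,
        "cost_soc_ref": cost_soc_ref, "cost_soc_int": cost_soc_int,
    }
    return samples, detail


def run_psa(params: ParamSet, n_runs: int, seed: int) -> list[PsaSample]:
    """Monte-Carlo propagation of all input distributions (default study: 5000 runs)."""
    draws, _ = sample_draws(params, n_runs, seed)
    samples, _ = _evaluate_draws(draws, params)
    return samples


def deterministic_run(params: ParamSet) -> DeterministicResult:
    """Point-estimate run: every distribution collapsed to its sampling mean,
    evaluated through the identical PSA pipeline."""
    collapsed = params.collapsed()
    draws, _ = sample_draws(collapsed, 1, seed=0)
    samples, detail = _evaluate_draws(draws, collapsed)
    s = samples[0]
    counts = CascadeCounts(
        n_screened=float(detail["n_screened"][0]),
        n_positive=float(detail["n_screened"][0] * params.cascade.f_screen_positive),
        n_interviewed=float(detail["n_interviewed"][0]),
        n_treated=float(detail["n_treated"][0]),
    )
    return DeterministicResult(
        sample=s,
        counts=counts,
        one_off_screening=float(detail["one_off_screening"][0]),
        one_off_intervention=float(detail["one_off_intervention"][0]),
        dalys_ref=float(detail["dalys_ref"][0]),
        dalys_int=float(detail["dalys_int"][0]),
        cost_hc_ref=float(detail["cost_hc_ref"][0]),
        cost_hc_int=float(detail["cost_hc_int"][0]),
        cost_soc_ref=float(detail["cost_soc_ref"][0]),
        cost_soc_int=float(detail["cost_soc_int"][0]),
        icer_hc=icer(s.d_cost_hc, s.d_dalys),
        icer_soc=icer(s.d_cost_soc, s.d_dalys),
    )


def _cost_effect(samples: Sequence[PsaSample], perspective: str) -> tuple[np.ndarray, np.ndarray]:
    if perspective not in ("hc", "societal"):
        raise ValueError(f"unknown perspective {perspective!r}")
    dc = np.array([s.d_cost_hc if perspective == "hc" else s.d_cost_soc for s in samples])
    de = np.array([s.d_dalys for s in samples])
    return dc, de


def ce_plane(samples: Sequence[PsaSample], perspective: str) -> dict[str, float]:
    """Cost-effectiveness plane quadrant fractions (x = DALYs averted, y = cost).

    Boundary convention: a draw with exactly zero incremental cost counts on
    the cost-saving (southern) side, and zero incremental effect on the
    no-gain (western) side.
    """
    if len(samples) == 0:
        raise ValueError("need at least one sample")
    dc, de = _cost_effect(samples, perspective)
    gain = de > 0
    extra = dc > 0
    n = len(samples)
    return {
        "NE": float((gain & extra).sum() / n),
        "SE": float((gain & ~extra).sum() / n),
        "SW": float((~gain & ~extra).sum() / n),
        "NW": float((~gain & extra).sum() / n),
    }


def ceac(
    samples: Sequence[PsaSample],
    wtp_grid: Sequence[float],
    perspective: str,
) -> dict[float, float]:
    """Probability of cost-effectiveness per willingness-to-pay threshold.

    Uses the net-monetary-benefit rule P(lambda * dE - dC >= 0), which handles
    draws with negative health effects correctly (an ICER-threshold rule does
    not).
    """
    if len(wtp_grid) == 0:
        raise ValueError("wtp_grid must be non-empty")
    dc, de = _cost_effect(samples, perspective)
    return {
        float(lam): float(np.mean(lam * de - dc >= 0.0))
        for lam in wtp_grid
    }


def summarize_psa(
    samples: Sequence[PsaSample],
    wtp_grid: Sequence[float] = tuple(range(0, 50001, 500)),
    n_rejected: int = 0,
) -> PsaSummary:
    """Summarise a PSA: means, 2.5/97.5 percentiles, quadrants, CEAC, ICERs.

    ICERs use the ratio-of-means estimator (mean incremental cost over mean
    incremental effect), not the mean of per-draw ratios.
    """
    dc_hc, de = _cost_effect(samples, "hc")
    dc_soc, _ = _cost_effect(samples, "societal")
    pct = lambda x: (float(np.percentile(x, 2.5)), float(np.percentile(x, 97.5)))
    return PsaSummary(
        n_runs=len(samples),
        mean_d_cost_hc=float(dc_hc.mean()),
        mean_d_cost_soc=float(dc_soc.mean()),
        mean_d_dalys=float(de.mean()),
        ci_d_cost_hc=pct(dc_hc),
        ci_d_cost_soc=pct(dc_soc),
        ci_d_dalys=pct(de),
        quadrants={p: ce_plane(samples, p) for p in ("hc", "societal")},
        ceac={p: ceac(samples, wtp_grid, p) for p in ("hc", "societal")},
        icer_hc=icer(float(dc_hc.mean()), float(de.mean())),
        icer_soc=icer(float(dc_soc.mean()), float(de.mean())),
        n_rejected=n_rejected,
    )


def samples_to_frame(samples: Sequence[PsaSample]) -> pd.DataFrame:
    """PSA samples as a tidy table (draw, d_cost_hc, d_cost_soc, d_dalys)."""
    return pd.DataFrame({
        "draw": [s.draw_index for s in samples],
        "d_cost_hc": [s.d_cost_hc for s in samples],
        "d_cost_soc": [s.d_cost_soc for s in samples],
        "d_dalys": [s.d_dalys for s in samples],
    })
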