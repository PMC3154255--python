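"""Synthetic stand-ins for model inputs that exist only graphically.

The recovery and relapse probability curves of the original model were
estimated from Dutch (NEMESIS) and Australian epidemiological data and are
published only as figures, without a numeric table.  This module generates
clearly-labelled synthetic curves with the same qualitative structure — a
per-cycle exit probability that declines with time in state over a two-year
span — plus pseudo-trial event counts whose beta fits regenerate the published
incidence distributions, so the whole pipeline is testable end to end.

Synthetic default calibration (configuration, not published fact):
recovery starts at 0.25/cycle decaying at 0.10 per cycle (median episode
length around 3-4 cycles, consistent with short median depressive episodes);
relapse starts at 0.04/cycle decaying at 0.08 per cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import beta as beta_dist

from .cascade import CascadeParams
from .parameters import (
    CostSet,
    CurveSpec,
    CycleGrid,
    DisabilityWeights,
    DiscountRates,
    DistributionSpec,
    ParamSet,
    TransitionParams,
    moments_to_gamma,
    save_params,
)

__all__ = [
    "CurveFamily",
    "TrialCounts",
    "gen_curve",
    "gen_trial_counts",
    "fit_incidence_beta",
    "default_recovery_curve",
    "default_relapse_curve",
    "default_paramset",
    "write_fixture_bundle",
]


@dataclass(frozen=True)
class CurveFamily:
    """Parametric family for a declining per-cycle probability curve."""

    family: str  # "exponential_decay" | "power_decay"
    p_initial: float
    decay: float
    span_cycles: int = 26

    def __post_init__(self) -> None:
        if self.family not in ("exponential_decay", "power_decay"):
            raise ValueError(f"unknown curve family {self.family!r}")
        if not 0.0 <= self.p_initial <= 1.0:
            raise ValueError("p_initial must be in [0, 1]")
        if self.decay < 0:
            raise ValueError("decay must be >= 0")
        if self.span_cycles < 1:
            raise ValueError("span_cycles must be >= 1")


def gen_curve(fam: CurveFamily, tail_rule: str = "hold_last") -> CurveSpec:
    """Generate a non-increasing per-cycle probability curve.

    exponential_decay: p(k) = p_initial * exp(-decay * (k - 1));
    power_decay:       p(k) = p_initial * k ** (-decay).
    """
    k = np.arange(1, fam.span_cycles + 1, dtype=float)
    if fam.family == "exponential_decay":
        p = fam.p_initial * np.exp(-fam.decay * (k - 1.0))
    else:
        p = fam.p_initial * k ** (-fam.decay)
    return CurveSpec(p=tuple(float(v) for v in p), tail_rule=tail_rule)


@dataclass(frozen=True)
class TrialCounts:
    """Pseudo-trial one-year incident MDE counts per arm."""

    n_control: int
    events_control: int
    n_treated: int
    events_treated: int


def gen_trial_counts(
    n_control: int,
    n_treated: int,
    p_year_ref: float,
    rate_ratio: float,
    seed: int,
) -> TrialCounts:
    """Simulate one-year incident major-depression counts in a two-arm trial.

    The treated arm's one-year probability follows from the hazard (rate)
    ratio under the constant-hazard assumption:
    p_int = 1 - (1 - p_ref) ** rate_ratio.
    """
    if not 0.0 <= p_year_ref <= 1.0:
        raise ValueError("p_year_ref must be in [0, 1]")
    if rate_ratio < 0:
        raise ValueError("rate_ratio must be >= 0")
    rng = np.random.default_rng(seed)
    p_int = 1.0 - (1.0 - p_year_ref) ** rate_ratio
    return TrialCounts(
        n_control=n_control,
        events_control=int(rng.binomial(n_control, p_year_ref)),
        n_treated=n_treated,
        events_treated=int(rng.binomial(n_treated, p_int)),
    )


def fit_incidence_beta(events: int, n: int, provenance: str = "") -> DistributionSpec:
    """Beta(events, non-events) posterior-style fit to one-year event counts.

    Point estimate and 95% CI are the beta mean and central quantiles on the
    one-year scale.  With zero events or zero non-events the corresponding
    shape is floored at 0.5 to keep the distribution proper.
    """
    if not 0 <= events <= n:
        raise ValueError("require 0 <= events <= n")
    a = max(float(events), 0.5)
    b = max(float(n - events), 0.5)
    mean = a / (a + b)
    lo = float(beta_dist.ppf(0.025, a, b))
    hi = float(beta_dist.ppf(0.975, a, b))
    return DistributionSpec("beta", a, b, mean, lo, hi, provenance)


def default_recovery_curve() -> CurveSpec:
    """SYNTHETIC recovery curve: 0.25/cycle at episode onset, exp decay 0.10."""
    return gen_curve(CurveFamily("exponential_decay", 0.25, 0.10, 26))


def default_relapse_curve() -> CurveSpec:
    """SYNTHETIC relapse curve: 0.04/cycle just after recovery, exp decay 0.08."""
    return gen_curve(CurveFamily("exponential_decay", 0.04, 0.08, 26))


def default_paramset() -> ParamSet:
    """Base-case ParamSet: published parameters plus the synthetic curves.

    Published values: cascade fractions 0.725 / 0.266 / 0.357 / (1 - 0.405),
    target population 7.2 million, one-year incidence beta(21, 90) (control)
    and beta(14, 95) (treated), per-cycle costs and disability weights as in
    the source cost table, discounting 4%/1.5%, 13 cycles/year over 5 years.
    Recovery/relapse curves are SYNTHETIC stand-ins (see module docstring).
    """
    transitions = TransitionParams(
        p_inc_year_ref=21.0 / 111.0,
        p_inc_year_int=14.0 / 109.0,
        recovery_curve=default_recovery_curve(),
        relapse_curve=default_relapse_curve(),
        effect_duration_cycles=13,
    )
    psa_specs = {
        "f_participate": DistributionSpec(
            "beta", 3826, 1452, 0.725, 0.713, 0.737,
            "screening participation, beta(3826, 1452)"),
        "f_screened_to_interview": DistributionSpec(
            "beta", 364, 3463, 0.095, 0.086, 0.105,
            "screened included for diagnostic interview, beta(364, 3463)"),
        "f_treated_given_interviewed": DistributionSpec(
            "beta", 217, 148, 0.595, 0.544, 0.645,
            "interviewed included in intervention, beta(217, 148)"),
        "p_year_ref": DistributionSpec(
            "beta", 21, 90, 0.016, 0.010, 0.023,
            "one-year incidence, control arm events; printed per-cycle 0.016"),
        "p_year_int": DistributionSpec(
            "beta", 14, 95, 0.011, 0.006, 0.017,
            "one-year incidence, treated arm events; printed per-cycle 0.011"),
        "c_sub_hc_ref": moments_to_gamma(
            132, 73, 207, "sub-threshold health-care cost/cycle; printed gamma(15, 108)"),
        "c_sub_hc_int": moments_to_gamma(
            139, 94, 192, "sub-threshold health-care cost/cycle, intervention year; printed gamma(31, 55)"),
        "c_sub_soc_ref": moments_to_gamma(
            439, 219, 691, "sub-threshold total cost/cycle; printed gamma(33, 258)"),
        "c_sub_soc_int": moments_to_gamma(
            384, 138, 692, "sub-threshold total cost/cycle, intervention year; printed gamma(16, 433)"),
        "c_mde_hc": moments_to_gamma(
            268, 150, 419, "major depression health-care cost/cycle; printed gamma(13, 11)"),
        "c_mde_soc": moments_to_gamma(
            615, 308, 1022, "major depression total cost/cycle; printed gamma(14, 26)"),
        "qol_sub": DistributionSpec(
            "beta", 106, 11, 0.906, 0.847, 0.952,
            "quality of life, sub-threshold depression, beta(106, 11)"),
    }
    return ParamSet(
        grid=CycleGrid(cycles_per_year=13, horizon_cycles=65),
        transitions=transitions,
        costs=CostSet(),
        weights=DisabilityWeights(dw_sub=0.097, dw_mde=0.46),
        discounts=DiscountRates(rate_costs=0.04, rate_effects=0.015),
        cascade=CascadeParams(),
        psa_specs=psa_specs,
    )


_FIXTURE_README = """\
depscreen base-case fixture bundle
==================================

params.yaml          full base-case parameter set
recovery_curve.csv   per-cycle recovery probability by episode duration
relapse_curve.csv    per-cycle relapse probability by time since recovery

Provenance of values
--------------------
PAPER-sourced: target population 7.2e6; cascade fractions 0.725 / 0.266 /
0.357 / 0.595; one-year incidence beta(21, 90) and beta(14, 95); per-cycle
costs 132 / 139 / 439 / 384 / 268 / 615 EUR (gamma distributions rebuilt by
method of moments from the printed means and 95% CIs); unit costs EUR 5 /
119 / 423; disability weights 0.46 (major depression) and 0.097
(sub-threshold = recovered); quality-of-life beta(106, 11); discount rates
4% (costs) and 1.5% (effects); 13 four-week cycles/year over 5 years.

SYNTHETIC: recovery_curve.csv and relapse_curve.csv.  The source curves are
published only as figures; these files are exponential-decay stand-ins
(recovery 0.25 * exp(-0.10 (k-1)), relapse 0.04 * exp(-0.08 (k-1)), 26-cycle
span, hold-last tail) with the same qualitative shape.  Population-level
cost and DALY magnitudes computed from them are therefore illustrative.
"""


def write_fixture_bundle(out_dir: str | Path) -> list[Path]:
    """Write the base-case parameter file, curve CSVs and provenance README."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = default_paramset()
    save_params(params, out / "params.yaml")
    (out / "README.txt").write_text(_FIXTURE_README)
    return [out / "params.yaml", out / "recovery_curve.csv",
            out / "relapse_curve.csv", out / "README.txt"]
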