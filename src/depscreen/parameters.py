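"""Model inputs, probability transforms and sensitivity-analysis distributions.

Every input of the decision model lives here with its provenance: transition
probabilities (with the annual -> 4-week constant-hazard transform), per-cycle
health-care and societal costs, disability weights, differential discount
rates, the screening cascade, and the beta/gamma distributions that drive the
probabilistic sensitivity analysis.  A :class:`ParamSet` bundles everything a
model run needs and round-trips through a YAML parameter file plus two-column
curve CSVs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .cascade import CascadeParams

__all__ = [
    "annual_to_cycle_prob",
    "cycle_to_annual_prob",
    "DistributionSpec",
    "dist_mean",
    "dist_sample",
    "moments_to_gamma",
    "CurveSpec",
    "CycleGrid",
    "TransitionParams",
    "CostSet",
    "DisabilityWeights",
    "DiscountRates",
    "ParamSet",
    "ParamValidationError",
    "load_params",
    "save_params",
    "validate_paramset",
]


# ---------------------------------------------------------------------------
# Probability transforms
# ---------------------------------------------------------------------------

def annual_to_cycle_prob(p_year: float, cycles_per_year: int = 13) -> float:
    """Convert a one-year event probability to a per-cycle probability.

    Assumes a constant hazard over the year, so the per-cycle probability is
    ``1 - (1 - p_year)**(1 / cycles_per_year)``.  The result is always <= the
    annual probability and monotone increasing in it.

    Raises
    ------
    ValueError
        If ``p_year`` is outside [0, 1] or ``cycles_per_year < 1``.
    """
    if not 0.0 <= p_year <= 1.0:
        raise ValueError(f"annual probability must be in [0, 1], got {p_year}")
    if cycles_per_year < 1:
        raise ValueError("cycles_per_year must be >= 1")
    return 1.0 - (1.0 - p_year) ** (1.0 / cycles_per_year)


def cycle_to_annual_prob(p_cycle: float, cycles_per_year: int = 13) -> float:
    """Inverse of :func:`annual_to_cycle_prob` under the same constant-hazard rule."""
    if not 0.0 <= p_cycle <= 1.0:
        raise ValueError(f"cycle probability must be in [0, 1], got {p_cycle}")
    if cycles_per_year < 1:
        raise ValueError("cycles_per_year must be >= 1")
    return 1.0 - (1.0 - p_cycle) ** cycles_per_year


# ---------------------------------------------------------------------------
# PSA distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionSpec:
    """A beta or gamma uncertainty distribution with its published provenance.

    ``shape_a``/``shape_b`` are (alpha, beta) for the beta family and
    (shape, scale) for the gamma family.  ``point_estimate`` is the published
    central value *on its published scale*, which for the incidence rows is the
    4-week scale even though sampling happens on the one-year scale; use
    :meth:`sampling_mean` for the mean on the scale the draws live on.
    A spec with ``ci_low == ci_high`` is degenerate: every draw equals the
    point estimate.
    """

    family: str
    shape_a: float
    shape_b: float
    point_estimate: float
    ci_low: float
    ci_high: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.shape_a <= 0 or self.shape_b <= 0:
            raise ValueError("shape parameters must be positive")
        if self.family == "beta" and not 0.0 <= self.point_estimate <= 1.0:
            raise ValueError("beta point estimate must be in [0, 1]")
        if not self.ci_low <= self.point_estimate <= self.ci_high:
            raise ValueError(
                f"point estimate {self.point_estimate} outside CI "
                f"[{self.ci_low}, {self.ci_high}]"
            )

    @property
    def is_degenerate(self) -> bool:
        return self.ci_low == self.ci_high

    def sampling_mean(self) -> float:
        """Mean of the distribution on the scale draws are made on."""
        if self.is_degenerate:
            return self.point_estimate
        if self.family == "beta":
            return self.shape_a / (self.shape_a + self.shape_b)
        return self.shape_a * self.shape_b  # gamma: shape * scale

    def collapsed(self) -> "DistributionSpec":
        """Degenerate copy fixed at :meth:`sampling_mean` (zero spread).

        Collapsing happens on the sampling scale so that downstream
        transforms (e.g. the annual -> cycle conversion applied to incidence
        draws) act on the collapsed value exactly as they act on real draws.
        """
        m = self.sampling_mean()
        return DistributionSpec(
            family=self.family,
            shape_a=self.shape_a,
            shape_b=self.shape_b,
            point_estimate=m,
            ci_low=m,
            ci_high=m,
            provenance=self.provenance,
        )


def dist_mean(spec: DistributionSpec) -> float:
    """Central value used for reporting: beta mean a/(a+b), gamma point estimate.

    Gamma rows keep their published point estimate because the published
    (shape, scale) pairs for several cost rows are not internally consistent
    with the published means; the specs built by :func:`moments_to_gamma`
    have ``shape * scale == point_estimate`` anyway.
    """
    if spec.is_degenerate:
        return spec.point_estimate
    if spec.family == "beta":
        return spec.shape_a / (spec.shape_a + spec.shape_b)
    return spec.point_estimate


def dist_sample(
    spec: DistributionSpec,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` i.i.d. values from the spec's family, reproducibly.

    ``seed`` may be an integer or an existing :class:`numpy.random.Generator`.
    Degenerate specs short-circuit to a constant vector at the point estimate.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if spec.is_degenerate:
        return np.full(n, spec.point_estimate)
    if spec.family == "beta":
        return rng.beta(spec.shape_a, spec.shape_b, size=n)
    if spec.family == "gamma":
        return rng.gamma(spec.shape_a, spec.shape_b, size=n)
    raise ValueError(f"unknown distribution family {spec.family!r}")


def moments_to_gamma(
    mean: float, ci_low: float, ci_high: float, provenance: str = ""
) -> DistributionSpec:
    """Method-of-moments gamma from a published mean and symmetric 95% CI.

    The standard deviation is taken as the CI half-width divided by 1.96
    (normal approximation); shape = (mean/sd)^2 and scale = sd^2/mean, so the
    returned spec has mean exactly ``mean``.  A zero-width CI yields a
    degenerate spec.
    """
    if mean <= 0:
        raise ValueError("gamma mean must be positive")
    if not ci_low <= mean <= ci_high:
        raise ValueError("require ci_low <= mean <= ci_high")
    sd = (ci_high - ci_low) / (2.0 * 1.96)
    if sd == 0.0:
        return DistributionSpec("gamma", 1.0, mean, mean, mean, mean, provenance)
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return DistributionSpec("gamma", shape, scale, mean, ci_low, ci_high, provenance)


# ---------------------------------------------------------------------------
# Duration-dependent probability curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurveSpec:
    """Per-cycle transition probabilities indexed by time already spent in state.

    ``p[k-1]`` is the probability of leaving during the k-th cycle in state
    (k = 1..span_cycles).  Beyond the span the ``tail_rule`` applies:
    ``hold_last`` continues the final value indefinitely, ``zero`` switches
    the hazard off.
    """

    p: tuple[float, ...]
    tail_rule: str = "hold_last"

    def __post_init__(self) -> None:
        if len(self.p) < 1:
            raise ValueError("curve must have at least one cycle")
        if any(not 0.0 <= v <= 1.0 for v in self.p):
            raise ValueError("curve probabilities must be in [0, 1]")
        if self.tail_rule not in ("hold_last", "zero"):
            raise ValueError(f"unknown tail rule {self.tail_rule!r}")

    @property
    def span_cycles(self) -> int:
        return len(self.p)

    def is_monotone_nonincreasing(self) -> bool:
        return all(a >= b - 1e-12 for a, b in zip(self.p, self.p[1:]))

    def prob(self, duration: int) -> float:
        """Exit probability for a person in their ``duration``-th cycle in state."""
        if duration < 1:
            raise ValueError("duration is 1-based")
        if duration <= self.span_cycles:
            return self.p[duration - 1]
        return self.p[-1] if self.tail_rule == "hold_last" else 0.0

    def extended(self, n_buckets: int) -> np.ndarray:
        """Probabilities for duration buckets 1..n_buckets, tail rule applied."""
        return np.array([self.prob(k) for k in range(1, n_buckets + 1)])


def load_curve_csv(path: str | Path) -> CurveSpec:
    """Read a curve from a 2-column CSV (cycle_index starting at 1, probability)."""
    rows: list[tuple[int, float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if len(header) < 2:
            raise ParamValidationError(f"{path}: expected 2 columns, got {header}")
        for rec in reader:
            if not rec:
                continue
            rows.append((int(rec[0]), float(rec[1])))
    if not rows:
        raise ParamValidationError(f"{path}: empty curve")
    rows.sort()
    if [k for k, _ in rows] != list(range(1, len(rows) + 1)):
        raise ParamValidationError(f"{path}: cycle_index must run 1..n without gaps")
    return CurveSpec(p=tuple(v for _, v in rows))


def save_curve_csv(curve: CurveSpec, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cycle_index", "probability"])
        for k, v in enumerate(curve.p, start=1):
            writer.writerow([k, repr(float(v))])


# ---------------------------------------------------------------------------
# Structured parameter blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CycleGrid:
    """Time discretisation: 13 four-week cycles per year, five-year horizon."""

    cycles_per_year: int = 13
    horizon_cycles: int = 65

    def __post_init__(self) -> None:
        if self.cycles_per_year < 1 or self.horizon_cycles < 1:
            raise ValueError("cycle grid must be positive")

    @property
    def cycle_years(self) -> float:
        return 1.0 / self.cycles_per_year


@dataclass(frozen=True)
class TransitionParams:
    """Incidence probabilities (one-year scale) and recovery/relapse curves.

    ``p_inc_year_ref`` is the one-year probability that a person with
    sub-threshold depression develops a major depressive episode under usual
    care; ``p_inc_year_int`` the same under minimal contact psychotherapy.
    The intervention effect expires after ``effect_duration_cycles`` (one
    year), after which both arms share the reference incidence.
    """

    p_inc_year_ref: float
    p_inc_year_int: float
    recovery_curve: CurveSpec
    relapse_curve: CurveSpec
    effect_duration_cycles: int = 13

    def __post_init__(self) -> None:
        for name in ("p_inc_year_ref", "p_inc_year_int"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.effect_duration_cycles < 0:
            raise ValueError("effect_duration_cycles must be >= 0")

    def p_cycle_ref(self, cycles_per_year: int = 13) -> float:
        return annual_to_cycle_prob(self.p_inc_year_ref, cycles_per_year)

    def p_cycle_int(self, cycles_per_year: int = 13) -> float:
        return annual_to_cycle_prob(self.p_inc_year_int, cycles_per_year)


@dataclass(frozen=True)
class CostSet:
    """Per-cycle state costs (euro / 4 weeks) and one-off unit costs (euro).

    ``*_hc`` columns are health-care costs; ``*_soc`` are total societal costs
    which already *include* health care, so the societal perspective uses the
    ``_soc`` column alone.  Sub-threshold costs differ between arms during the
    intervention year only; recovered persons cost the same as sub-threshold
    (reference) persons.
    """

    sub_hc_ref: float = 132.0
    sub_hc_int: float = 139.0
    sub_soc_ref: float = 439.0
    sub_soc_int: float = 384.0
    mde_hc: float = 268.0
    mde_soc: float = 615.0
    screen_step1: float = 5.0
    screen_step2: float = 119.0
    intervention: float = 423.0

    def __post_init__(self) -> None:
        for f_ in (
            "sub_hc_ref", "sub_hc_int", "sub_soc_ref", "sub_soc_int",
            "mde_hc", "mde_soc", "screen_step1", "screen_step2", "intervention",
        ):
            if getattr(self, f_) < 0:
                raise ValueError(f"cost {f_} must be non-negative")

    # Recovered-state costs are tied to sub-threshold (reference) by assumption.
    @property
    def rec_hc(self) -> float:
        return self.sub_hc_ref

    @property
    def rec_soc(self) -> float:
        return self.sub_soc_ref


@dataclass(frozen=True)
class DisabilityWeights:
    """Disability weights in [0, 1]; recovered equals sub-threshold by assumption."""

    dw_sub: float = 0.097
    dw_mde: float = 0.46
    dw_rec: float | None = None

    def __post_init__(self) -> None:
        for v in (self.dw_sub, self.dw_mde):
            if not 0.0 <= v <= 1.0:
                raise ValueError("disability weights must be in [0, 1]")
        if self.dw_rec is None:
            object.__setattr__(self, "dw_rec", self.dw_sub)
        elif not 0.0 <= self.dw_rec <= 1.0:
            raise ValueError("disability weights must be in [0, 1]")


@dataclass(frozen=True)
class DiscountRates:
    """Differential annual discount rates: 4% for costs, 1.5% for effects."""

    rate_costs: float = 0.04
    rate_effects: float = 0.015

    def __post_init__(self) -> None:
        if self.rate_costs < 0 or self.rate_effects < 0:
            raise ValueError("discount rates must be >= 0")


@dataclass(frozen=True)
class ParamSet:
    """Everything one scenario pair needs: grid, transitions, costs, weights,
    discounts, cascade and the PSA distribution catalogue."""

    grid: CycleGrid
    transitions: TransitionParams
    costs: CostSet
    weights: DisabilityWeights
    discounts: DiscountRates
    cascade: CascadeParams
    psa_specs: Mapping[str, DistributionSpec] = field(default_factory=dict)

    def collapsed(self) -> "ParamSet":
        """Copy with every PSA distribution collapsed to its sampling mean."""
        return ParamSet(
            grid=self.grid,
            transitions=self.transitions,
            costs=self.costs,
            weights=self.weights,
            discounts=self.discounts,
            cascade=self.cascade,
            psa_specs={k: v.collapsed() for k, v in self.psa_specs.items()},
        )


# ---------------------------------------------------------------------------
# Parameter file I/O
# ---------------------------------------------------------------------------

class ParamValidationError(ValueError):
    """A parameter file failed schema or invariant validation."""


_SCHEMA_ID = "depscreen-params-v1"

_REQUIRED_TOP = ("schema", "grid", "transitions", "costs", "weights", "discounts", "cascade")


def _require_keys(block: Mapping, keys: Iterable[str], where: str) -> None:
    missing = [k for k in keys if k not in block]
    if missing:
        raise ParamValidationError(f"{where}: missing keys {missing}")


def load_params(path: str | Path) -> ParamSet:
    """Load a ParamSet from a YAML file; curve CSV paths resolve relative to it."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ParamValidationError(f"{path}: expected a mapping at top level")
    _require_keys(doc, _REQUIRED_TOP, str(path))
    if doc["schema"] != _SCHEMA_ID:
        raise ParamValidationError(f"{path}: unsupported schema {doc['schema']!r}")

    g = doc["grid"]
    _require_keys(g, ("cycles_per_year", "horizon_cycles"), "grid")
    grid = CycleGrid(int(g["cycles_per_year"]), int(g["horizon_cycles"]))

    t = doc["transitions"]
    _require_keys(
        t,
        ("p_inc_year_ref", "p_inc_year_int", "effect_duration_cycles",
         "recovery_curve", "relapse_curve"),
        "transitions",
    )
    curves = {}
    for key in ("recovery_curve", "relapse_curve"):
        spec = t[key]
        _require_keys(spec, ("path", "tail_rule"), f"transitions.{key}")
        curve = load_curve_csv(path.parent / spec["path"])
        curves[key] = CurveSpec(p=curve.p, tail_rule=spec["tail_rule"])
    transitions = TransitionParams(
        p_inc_year_ref=float(t["p_inc_year_ref"]),
        p_inc_year_int=float(t["p_inc_year_int"]),
        recovery_curve=curves["recovery_curve"],
        relapse_curve=curves["relapse_curve"],
        effect_duration_cycles=int(t["effect_duration_cycles"]),
    )

    c = doc["costs"]
    cost_keys = ("sub_hc_ref", "sub_hc_int", "sub_soc_ref", "sub_soc_int",
                 "mde_hc", "mde_soc", "screen_step1", "screen_step2", "intervention")
    _require_keys(c, cost_keys, "costs")
    costs = CostSet(**{k: float(c[k]) for k in cost_keys})

    w = doc["weights"]
    _require_keys(w, ("dw_sub", "dw_mde"), "weights")
    weights = DisabilityWeights(
        dw_sub=float(w["dw_sub"]),
        dw_mde=float(w["dw_mde"]),
        dw_rec=float(w["dw_rec"]) if "dw_rec" in w else None,
    )

    d = doc["discounts"]
    _require_keys(d, ("rate_costs", "rate_effects"), "discounts")
    discounts = DiscountRates(float(d["rate_costs"]), float(d["rate_effects"]))

    ca = doc["cascade"]
    cascade_keys = ("n_target", "f_participate_screen", "f_screen_positive",
                    "f_interview_participate", "f_not_excluded")
    _require_keys(ca, cascade_keys, "cascade")
    cascade = CascadeParams(
        **{k: float(ca[k]) for k in cascade_keys},
        cost_screen_step1=costs.screen_step1,
        cost_screen_step2=costs.screen_step2,
        cost_intervention=costs.intervention,
    )

    psa_specs: dict[str, DistributionSpec] = {}
    for name, s in (doc.get("psa") or {}).items():
        _require_keys(s, ("family", "shape_a", "shape_b", "point_estimate",
                          "ci_low", "ci_high"), f"psa.{name}")
        try:
            psa_specs[name] = DistributionSpec(
                family=str(s["family"]),
                shape_a=float(s["shape_a"]),
                shape_b=float(s["shape_b"]),
                point_estimate=float(s["point_estimate"]),
                ci_low=float(s["ci_low"]),
                ci_high=float(s["ci_high"]),
                provenance=str(s.get("provenance", "")),
            )
        except ValueError as exc:
            raise ParamValidationError(f"psa.{name}: {exc}") from exc

    return ParamSet(grid, transitions, costs, weights, discounts, cascade, psa_specs)


def save_params(params: ParamSet, path: str | Path) -> None:
    """Write a ParamSet to YAML plus sibling curve CSVs (round-trips bit-equal)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    save_curve_csv(params.transitions.recovery_curve, path.parent / "recovery_curve.csv")
    save_curve_csv(params.transitions.relapse_curve, path.parent / "relapse_curve.csv")
    doc = {
        "schema": _SCHEMA_ID,
        "grid": {
            "cycles_per_year": params.grid.cycles_per_year,
            "horizon_cycles": params.grid.horizon_cycles,
        },
        "transitions": {
            "p_inc_year_ref": float(params.transitions.p_inc_year_ref),
            "p_inc_year_int": float(params.transitions.p_inc_year_int),
            "effect_duration_cycles": params.transitions.effect_duration_cycles,
            "recovery_curve": {
                "path": "recovery_curve.csv",
                "tail_rule": params.transitions.recovery_curve.tail_rule,
            },
            "relapse_curve": {
                "path": "relapse_curve.csv",
                "tail_rule": params.transitions.relapse_curve.tail_rule,
            },
        },
        "costs": {
            k: float(getattr(params.costs, k))
            for k in ("sub_hc_ref", "sub_hc_int", "sub_soc_ref", "sub_soc_int",
                      "mde_hc", "mde_soc", "screen_step1", "screen_step2",
                      "intervention")
        },
        "weights": {
            "dw_sub": float(params.weights.dw_sub),
            "dw_mde": float(params.weights.dw_mde),
            "dw_rec": float(params.weights.dw_rec),
        },
        "discounts": {
            "rate_costs": float(params.discounts.rate_costs),
            "rate_effects": float(params.discounts.rate_effects),
        },
        "cascade": {
            "n_target": float(params.cascade.n_target),
            "f_participate_screen": float(params.cascade.f_participate_screen),
            "f_screen_positive": float(params.cascade.f_screen_positive),
            "f_interview_participate": float(params.cascade.f_interview_participate),
            "f_not_excluded": float(params.cascade.f_not_excluded),
        },
        "psa": {
            name: {
                "family": s.family,
                "shape_a": float(s.shape_a),
                "shape_b": float(s.shape_b),
                "point_estimate": float(s.point_estimate),
                "ci_low": float(s.ci_low),
                "ci_high": float(s.ci_high),
                "provenance": s.provenance,
            }
            for name, s in params.psa_specs.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Invariant checks (shared by the CLI `validate` command)
# ---------------------------------------------------------------------------

def validate_paramset(params: ParamSet) -> list[tuple[str, bool, str]]:
    """Run every invariant check, returning (check name, passed, detail) rows."""
    checks: list[tuple[str, bool, str]] = []

    rec = params.transitions.recovery_curve
    rel = params.transitions.relapse_curve
    checks.append((
        "recovery curve non-increasing", rec.is_monotone_nonincreasing(),
        _first_increase(rec.p),
    ))
    checks.append((
        "relapse curve non-increasing", rel.is_monotone_nonincreasing(),
        _first_increase(rel.p),
    ))
    checks.append((
        "intervention incidence <= reference",
        params.transitions.p_inc_year_int <= params.transitions.p_inc_year_ref,
        f"{params.transitions.p_inc_year_int} vs {params.transitions.p_inc_year_ref}",
    ))
    checks.append((
        "horizon equals 5 years of cycles",
        params.grid.horizon_cycles == 5 * params.grid.cycles_per_year,
        f"{params.grid.horizon_cycles} cycles at {params.grid.cycles_per_year}/yr",
    ))
    checks.append((
        "recovered weight equals sub-threshold weight",
        params.weights.dw_rec == params.weights.dw_sub,
        f"{params.weights.dw_rec} vs {params.weights.dw_sub}",
    ))
    f2 = params.cascade.f_screened_to_interview
    checks.append((
        "collapsed screened->interview fraction ~ 0.095",
        abs(f2 - 0.095) <= 0.001,
        f"{f2:.4f}",
    ))

    for name, spec in params.psa_specs.items():
        if spec.family != "beta" or spec.is_degenerate:
            continue
        mean = spec.shape_a / (spec.shape_a + spec.shape_b)
        if name.startswith("p_year"):
            # printed point estimates for incidence are on the 4-week scale
            value = annual_to_cycle_prob(mean, params.grid.cycles_per_year)
        else:
            value = mean
        checks.append((
            f"beta mean consistent with point estimate: {name}",
            abs(value - spec.point_estimate) <= 0.001,
            f"mean-derived {value:.4f} vs printed {spec.point_estimate}",
        ))

    return checks


def _first_increase(p: Sequence[float]) -> str:
    for i, (a, b) in enumerate(zip(p, p[1:]), start=1):
        if b > a + 1e-12:
            return f"increase at cycle {i}->{i + 1} ({a} -> {b})"
    return "ok"
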