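"""Markov cohort engine with duration-dependent recovery and relapse.

A closed cohort of people with sub-threshold depression is simulated over
four-week cycles through three health states: sub-threshold (SUB), major
depressive episode (MDE) and recovered (REC).  Recovery and relapse hazards
depend on time already spent in state, which a memoryless chain cannot
express directly; the MDE and REC states are therefore expanded into tunnel
states indexed by duration (1..span cycles, plus a final ``span+`` bucket
governed by the curve's tail rule).  There is no remission from sub-threshold
depression and no mortality, so occupancy is conserved exactly.

The intervention (minimal contact psychotherapy) acts only by lowering the
per-cycle SUB -> MDE incidence during its one-year effect window.

``microsim_oracle`` re-implements the same transition rules as an
individual-level stochastic simulation and serves as an independent check on
the cohort recursion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import CurveSpec, ParamSet, annual_to_cycle_prob

__all__ = [
    "SCENARIOS",
    "state_labels",
    "Trajectory",
    "incidence_for_cycle",
    "step",
    "run_cohort",
    "microsim_oracle",
]

SCENARIOS = ("reference", "intervention")


def state_labels(params: ParamSet) -> tuple[str, ...]:
    """State labels: SUB, MDE_1..MDE_n, MDE_n+, REC_1..REC_m, REC_m+."""
    ns = params.transitions.recovery_curve.span_cycles
    nr = params.transitions.relapse_curve.span_cycles
    labels = ["SUB"]
    labels += [f"MDE_{k}" for k in range(1, ns + 1)] + [f"MDE_{ns}+"]
    labels += [f"REC_{j}" for j in range(1, nr + 1)] + [f"REC_{nr}+"]
    return tuple(labels)


@dataclass(frozen=True)
class Trajectory:
    """Cohort occupancy per state per cycle (rows 0..horizon sum to 1)."""

    occupancy: np.ndarray  # (horizon+1, n_states) cohort fractions
    states: tuple[str, ...]
    cohort_size: float
    cycles_per_year: int

    def __post_init__(self) -> None:
        if self.occupancy.ndim != 2 or self.occupancy.shape[1] != len(self.states):
            raise ValueError("occupancy shape does not match state labels")
        if (self.occupancy < -1e-12).any():
            raise ValueError("negative occupancy")

    @property
    def horizon_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def _mask(self, prefix: str) -> np.ndarray:
        return np.array([s.startswith(prefix) for s in self.states])

    def sub(self) -> np.ndarray:
        return self.occupancy[:, 0]

    def mde_total(self) -> np.ndarray:
        return self.occupancy[:, self._mask("MDE")].sum(axis=1)

    def rec_total(self) -> np.ndarray:
        return self.occupancy[:, self._mask("REC")].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (cycle, state, occupancy) table for export."""
        h, s = self.occupancy.shape
        return pd.DataFrame({
            "cycle": np.repeat(np.arange(h), s),
            "state": np.tile(np.array(self.states, dtype=object), h),
            "occupancy": self.occupancy.ravel(),
        })


def incidence_for_cycle(params: ParamSet, scenario: str, cycle_index: int) -> float:
    """Per-cycle SUB -> MDE probability, honouring the one-year effect window."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    t = params.transitions
    cpy = params.grid.cycles_per_year
    if scenario == "intervention" and cycle_index < t.effect_duration_cycles:
        return annual_to_cycle_prob(t.p_inc_year_int, cpy)
    return annual_to_cycle_prob(t.p_inc_year_ref, cpy)


def _tunnel_probs(curve: CurveSpec) -> np.ndarray:
    """Exit probabilities for duration buckets 1..span plus the tail bucket."""
    return curve.extended(curve.span_cycles + 1)


def _step_arrays(sub, mde, rec, p_inc, r_ext, s_ext):
    """One transition cycle, vectorised over arbitrary leading batch axes.

    ``sub`` has shape (...,); ``mde`` (..., n_mde_buckets); ``rec``
    (..., n_rec_buckets); ``p_inc`` scalar or (...,).  Duration buckets shift
    by one each cycle, the last bucket accumulating (tail behaviour lives in
    the extended probability vectors, so the recursion itself is uniform).
    """
    inc = sub * p_inc
    recov = mde * r_ext
    relapse = rec * s_ext
    stay_m = mde - recov
    stay_r = rec - relapse

    new_sub = sub - inc
    new_mde = np.empty_like(mde)
    new_mde[..., 0] = inc + relapse.sum(axis=-1)
    new_mde[..., 1:] = stay_m[..., :-1]
    new_mde[..., -1] += stay_m[..., -1]
    new_rec = np.empty_like(rec)
    new_rec[..., 0] = recov.sum(axis=-1)
    new_rec[..., 1:] = stay_r[..., :-1]
    new_rec[..., -1] += stay_r[..., -1]
    return new_sub, new_mde, new_rec


def step(
    occupancy_row: np.ndarray,
    cycle_index: int,
    scenario: str,
    params: ParamSet,
) -> np.ndarray:
    """Advance one occupancy row by a single four-week cycle."""
    labels = state_labels(params)
    row = np.asarray(occupancy_row, dtype=float)
    if row.shape != (len(labels),):
        raise ValueError(f"expected occupancy row of length {len(labels)}")
    if not np.isclose(row.sum(), 1.0, atol=1e-9):
        raise ValueError("occupancy row must sum to 1")
    nm = params.transitions.recovery_curve.span_cycles + 1
    nr = params.transitions.relapse_curve.span_cycles + 1
    p_inc = incidence_for_cycle(params, scenario, cycle_index)
    sub, mde, rec = _step_arrays(
        row[0],
        row[1:1 + nm].copy(),
        row[1 + nm:1 + nm + nr].copy(),
        p_inc,
        _tunnel_probs(params.transitions.recovery_curve),
        _tunnel_probs(params.transitions.relapse_curve),
    )
    return np.concatenate(([sub], mde, rec))


def run_cohort(scenario: str, params: ParamSet, cohort_size: float = 1.0) -> Trajectory:
    """Deterministic cohort run from 100% sub-threshold over the full horizon."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    horizon = params.grid.horizon_cycles
    if horizon < 1:
        raise ValueError("horizon must be >= 1 cycle")
    labels = state_labels(params)
    nm = params.transitions.recovery_curve.span_cycles + 1
    nr = params.transitions.relapse_curve.span_cycles + 1
    r_ext = _tunnel_probs(params.transitions.recovery_curve)
    s_ext = _tunnel_probs(params.transitions.relapse_curve)

    occ = np.zeros((horizon + 1, len(labels)))
    occ[0, 0] = 1.0
    sub, mde, rec = 1.0, np.zeros(nm), np.zeros(nr)
    for t in range(horizon):
        p_inc = incidence_for_cycle(params, scenario, t)
        sub, mde, rec = _step_arrays(sub, mde, rec, p_inc, r_ext, s_ext)
        occ[t + 1, 0] = sub
        occ[t + 1, 1:1 + nm] = mde
        occ[t + 1, 1 + nm:] = rec
    return Trajectory(occ, labels, cohort_size, params.grid.cycles_per_year)


def microsim_oracle(
    scenario: str,
    params: ParamSet,
    n_individuals: int,
    seed: int,
) -> Trajectory:
    """Individual-level stochastic simulation of the same transition rules.

    Each of ``n_individuals`` starts sub-threshold and moves through the
    identical duration-indexed hazards by Bernoulli draws; the empirical
    occupancy converges to :func:`run_cohort` as n grows.  Intended as an
    independent validation oracle, not as the production engine.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    horizon = params.grid.horizon_cycles
    labels = state_labels(params)
    nm = params.transitions.recovery_curve.span_cycles + 1
    nr = params.transitions.relapse_curve.span_cycles + 1
    r_ext = _tunnel_probs(params.transitions.recovery_curve)
    s_ext = _tunnel_probs(params.transitions.relapse_curve)
    n_states = len(labels)

    # state codes: 0 = SUB, 1..nm = MDE duration bucket, nm+1..nm+nr = REC bucket
    state = np.zeros(n_individuals, dtype=np.int64)
    occ = np.zeros((horizon + 1, n_states))
    occ[0] = np.bincount(state, minlength=n_states) / n_individuals

    for t in range(horizon):
        p_inc = incidence_for_cycle(params, scenario, t)
        u = rng.random(n_individuals)
        new = state.copy()

        is_sub = state == 0
        new[is_sub & (u < p_inc)] = 1  # enter MDE_1

        is_mde = (state >= 1) & (state <= nm)
        k = state[is_mde]
        recovers = u[is_mde] < r_ext[k - 1]
        dest = np.minimum(k + 1, nm)  # advance duration, cap at tail bucket
        dest[recovers] = nm + 1  # enter REC_1
        new[is_mde] = dest

        is_rec = state > nm
        j = state[is_rec] - nm
        relapses = u[is_rec] < s_ext[j - 1]
        dest_r = nm + np.minimum(j + 1, nr)
        dest_r[relapses] = 1  # back to MDE_1
        new[is_rec] = dest_r

        state = new
        occ[t + 1] = np.bincount(state, minlength=n_states) / n_individuals

    return Trajectory(occ, labels, float(n_individuals), params.grid.cycles_per_year)
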