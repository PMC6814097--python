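"""Synthetic long-term-care cohorts from known true parameters.

The restricted linked cohort behind the published summaries is not publicly
available, so this module generates stand-in cohorts whose generating law is
calibrated to the printed marginal summaries: women enter at baseline as
non-users (State 1) and move through home/community care (HACC, State 2) and
residential care (RAC, State 3) toward death (State 4), with administrative
censoring at 10 years.

Calibrated default intensities (events/year) come from the printed mean
sojourn times and transition rate ratios: the State-1 total exit rate 1/7.95
is split by the next-state probabilities implied by the printed TRRs 11.08
and 7.72; the State-2 total exit 1/5.04 is split .63/.37; the State-3 exit
is 1/2.51. Baseline covariates are drawn to match the printed cohort
marginals (median age 78, 56.7% outside major cities, 45.9% widowed, ...),
independently of one another.

Event times are simulated exactly: one exponential clock per allowed exit
(competing risks), the earliest fires. A single master seed deterministically
spawns one stream per subject, so cohorts are reproducible and independent
of simulation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import IntensityParameters, TransitionStructure, build_generator
from .data import (
    CovariateDictionary,
    OBS_EXACT_DEATH,
    OBS_EXACT_TRANSITION,
    OBS_SNAPSHOT,
    PanelDataset,
    PanelObservation,
    Subject,
)
from .errors import StructureError

__all__ = [
    "CALIBRATED_RATES",
    "TABLE_HAZARD_RATIOS",
    "COVARIATE_PREVALENCES",
    "CovariateGenerator",
    "ObservationScheme",
    "TrueModel",
    "default_true_model",
    "simulate_subject",
    "simulate_cohort",
    "observe_cohort",
]

#: Baseline intensities (events/year) calibrated to the printed sojourn
#: times and transition rate ratios; keys are 1-based state pairs.
CALIBRATED_RATES: dict[tuple[int, int], float] = {
    (1, 2): 0.10312,
    (1, 3): 0.00931,
    (1, 4): 0.01336,
    (2, 3): 0.12500,
    (2, 4): 0.07341,
    (3, 4): 0.39841,
}

#: Published per-year / per-indicator hazard ratios of the main model,
#: one value per transition in the order (1,2),(1,3),(1,4),(2,3),(2,4),(3,4).
TABLE_HAZARD_RATIOS: dict[str, tuple[float, ...]] = {
    "age": (1.05, 1.26, 1.12, 1.14, 1.03, 1.01),
    "remote_area": (1.17, 0.85, 0.92, 0.89, 1.12, 1.02),
    "widowed": (1.08, 0.96, 1.31, 0.98, 0.85, 0.89),
    "income_difficulty": (1.13, 0.86, 0.92, 1.01, 0.91, 0.90),
    "arthritis": (1.16, 1.00, 0.83, 0.96, 0.97, 0.98),
    "heart_problem": (1.20, 0.98, 1.29, 1.04, 1.62, 1.20),
    "diabetes": (1.17, 1.39, 1.31, 1.12, 1.17, 1.13),
    "asthma": (1.16, 1.04, 1.28, 0.95, 1.37, 1.06),
    "falls_injury": (1.04, 1.34, 1.15, 1.12, 1.03, 0.92),
}

#: Cohort prevalences of the baseline indicators.
COVARIATE_PREVALENCES: dict[str, float] = {
    "remote_area": 0.567,
    "widowed": 0.459,
    "income_difficulty": 0.256,
    "arthritis": 0.488,
    "heart_problem": 0.191,
    "diabetes": 0.096,
    "asthma": 0.133,
    "falls_injury": 0.123,
}

#: Baseline age is uniform on [75, 82] years (median ~78, range as printed).
AGE_RANGE = (75.0, 82.0)


@dataclass(frozen=True)
class CovariateGenerator:
    """Marginal distribution of one baseline covariate."""

    name: str
    kind: str  # "bernoulli" | "uniform"
    params: tuple[float, ...]

    def mean(self) -> float:
        if self.kind == "bernoulli":
            return self.params[0]
        if self.kind == "uniform":
            return 0.5 * (self.params[0] + self.params[1])
        raise StructureError(f"unknown covariate kind {self.kind!r}")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "bernoulli":
            return (rng.random(n) < self.params[0]).astype(float)
        if self.kind == "uniform":
            return rng.uniform(self.params[0], self.params[1], n)
        raise StructureError(f"unknown covariate kind {self.kind!r}")

    def dictionary_kind(self) -> str:
        return "indicator" if self.kind == "bernoulli" else "continuous"


@dataclass(frozen=True)
class ObservationScheme:
    """How simulated trajectories are turned into panel observations.

    ``grid`` lists snapshot times; ``exact_events`` records every care entry
    (``exact_transition``) and death (``exact_death``) at its true time. The
    default administrative-data emulation is exact events plus a censoring
    snapshot at the horizon.
    """

    name: str
    grid: tuple[float, ...] | None
    exact_events: bool

    @classmethod
    def from_name(cls, name: str, horizon: float) -> "ObservationScheme":
        if name == "exact":
            return cls("exact", None, True)
        if name == "panel-3yr":
            return cls(name, tuple(np.arange(0.0, horizon, 3.0)), False)
        if name == "panel-6mo":
            return cls(name, tuple(np.arange(0.0, horizon, 0.5)), False)
        if name == "mixed-3yr":
            return cls(name, tuple(np.arange(0.0, horizon, 3.0)), True)
        raise StructureError(
            f"unknown observation scheme {name!r}; known: exact, panel-3yr, "
            "panel-6mo, mixed-3yr"
        )


@dataclass
class TrueModel:
    """The generating law of a synthetic cohort (the simulation 'truth')."""

    structure: TransitionStructure
    params: IntensityParameters
    covariate_generators: tuple[CovariateGenerator, ...]
    scheme: ObservationScheme
    horizon: float = 10.0
    n: int = 9007
    seed: int = 0

    def __post_init__(self):
        if self.horizon <= 0:
            raise StructureError("horizon must be > 0")
        if self.n < 1:
            raise StructureError("cohort size must be >= 1")

    def to_dict(self) -> dict:
        st = self.structure
        return {
            "note": (
                "synthetic stand-in cohort; baseline rates calibrated to "
                "published marginal summaries, not fitted to any real data"
            ),
            "structure": st.to_config(),
            "baseline_rates": {
                st.transition_label(i, j): math.exp(self.params.log_baseline[k])
                for k, (i, j) in enumerate(st.transitions)
            },
            "log_hazard_ratios": [dict(c) for c in self.params.coefficients],
            "covariates": [
                {"name": g.name, "kind": g.kind, "params": list(g.params)}
                for g in self.covariate_generators
            ],
            "scheme": self.scheme.name,
            "horizon": self.horizon,
            "n": self.n,
            "seed": self.seed,
        }


def _default_covariate_generators() -> tuple[CovariateGenerator, ...]:
    gens = [CovariateGenerator("age", "uniform", AGE_RANGE)]
    gens += [
        CovariateGenerator(name, "bernoulli", (p,))
        for name, p in COVARIATE_PREVALENCES.items()
    ]
    return tuple(gens)


def default_true_model(
    effects: str = "none",
    n: int = 9007,
    seed: int = 0,
    scheme: str = "exact",
    horizon: float = 10.0,
) -> TrueModel:
    """The calibrated synthetic-cohort generating model.

    ``effects`` selects the covariate truth:

    - ``"none"`` — all coefficients zero (rates as calibrated, covariates
      drawn but inert);
    - ``"single"`` — one binary covariate ``high_need`` (prevalence 0.5)
      with a true hazard ratio of 1.5 on the 1->2 transition;
    - ``"table"`` — the published hazard ratios of the main model as truth
      on every transition.

    For the effect presets the baseline log-intensities are shifted by
    -beta' E[z] so that the cohort-average linear predictor still reproduces
    the calibrated rates.
    """
    structure = TransitionStructure.default()
    gens = list(_default_covariate_generators())
    coefficients: dict[tuple[int, int], dict[str, float]] = {
        key: {} for key in CALIBRATED_RATES
    }
    if effects == "single":
        gens.append(CovariateGenerator("high_need", "bernoulli", (0.5,)))
        coefficients[(1, 2)] = {"high_need": math.log(1.5)}
    elif effects == "table":
        order = list(CALIBRATED_RATES)  # (1,2),(1,3),(1,4),(2,3),(2,4),(3,4)
        for name, hrs in TABLE_HAZARD_RATIOS.items():
            for key, hr in zip(order, hrs):
                coefficients[key][name] = math.log(hr)
    elif effects != "none":
        raise StructureError(
            f"unknown effects preset {effects!r}; known: none, single, table"
        )

    means = {g.name: g.mean() for g in gens}
    rates = {}
    for key, q in CALIBRATED_RATES.items():
        shift = sum(b * means[nm] for nm, b in coefficients[key].items())
        rates[key] = q * math.exp(-shift) if shift else q
    params = IntensityParameters.from_rates(structure, rates, coefficients)
    return TrueModel(
        structure=structure,
        params=params,
        covariate_generators=tuple(gens),
        scheme=ObservationScheme.from_name(scheme, horizon),
        horizon=horizon,
        n=n,
        seed=seed,
    )


def simulate_subject(
    params: IntensityParameters,
    z: Mapping[str, float],
    horizon: float,
    rng: np.random.Generator,
    Q: np.ndarray | None = None,
) -> list[tuple[float, int]]:
    """Exact trajectory of one subject as (entry time, 0-based state) pairs.

    Starts in the first state at time 0; draws one exponential clock per
    allowed exit from the current state and follows the earliest, until
    absorption or administrative censoring at the horizon.
    """
    st = params.structure
    if Q is None:
        Q = build_generator(params, z)
    t, s = 0.0, 0
    traj = [(0.0, 0)]
    while not st.is_absorbing(s):
        succ = [j for j in st.successors(s) if Q[s, j] > 0]
        if not succ:
            break
        waits = [rng.exponential(1.0 / Q[s, j]) for j in succ]
        k = int(np.argmin(waits))
        t += waits[k]
        if t >= horizon:
            break
        s = succ[k]
        traj.append((t, s))
    return traj


def simulate_cohort(
    true_model: TrueModel,
) -> tuple[list[list[tuple[float, int]]], pd.DataFrame]:
    """Simulate every subject's exact trajectory and baseline covariates.

    Returns the list of trajectories and a covariate DataFrame indexed by
    subject id. Stream ``seed`` spawns one child per subject plus one for
    the covariate draws, so results do not depend on evaluation order.
    """
    tm = true_model
    root = np.random.SeedSequence(tm.seed)
    children = root.spawn(tm.n + 1)
    cov_rng = np.random.default_rng(children[0])
    ids = [f"S{k + 1:06d}" for k in range(tm.n)]
    cov = pd.DataFrame(
        {g.name: g.draw(cov_rng, tm.n) for g in tm.covariate_generators},
        index=ids,
    )
    used = set(tm.params.covariate_names)
    q_cache: dict[tuple, np.ndarray] = {}
    trajectories = []
    for k in range(tm.n):
        z = cov.iloc[k].to_dict()
        key = tuple(z[nm] for nm in sorted(used))
        if key not in q_cache:
            q_cache[key] = build_generator(tm.params, z)
        rng = np.random.default_rng(children[k + 1])
        trajectories.append(
            simulate_subject(tm.params, z, tm.horizon, rng, Q=q_cache[key])
        )
    return trajectories, cov


def observe_cohort(
    trajectories: Sequence[Sequence[tuple[float, int]]],
    covariates: pd.DataFrame,
    scheme: ObservationScheme,
    structure: TransitionStructure,
    horizon: float,
) -> PanelDataset:
    """Apply an observation scheme to exact trajectories.

    Exact schemes yield one ``exact_transition`` row per care entry, one
    ``exact_death`` row per death and a censoring snapshot at the horizon
    for survivors; snapshot schemes record the occupied state at each grid
    time up to and including the first grid time in the absorbing state.
    """
    dictionary = CovariateDictionary(
        {
            name: ("indicator" if set(np.unique(covariates[name])) <= {0.0, 1.0}
                   else "continuous")
            for name in covariates.columns
        }
    )
    subjects = []
    for sid, traj in zip(covariates.index, trajectories):
        times = [t for t, _ in traj]
        states = [s for _, s in traj]
        obs: dict[float, PanelObservation] = {}
        if scheme.grid is not None:
            for g in scheme.grid:
                idx = int(np.searchsorted(times, g, side="right") - 1)
                s = states[idx]
                obs[g] = PanelObservation(float(g), s, OBS_SNAPSHOT)
                if structure.is_absorbing(s):
                    break
        if scheme.exact_events:
            obs.setdefault(0.0, PanelObservation(0.0, states[0], OBS_SNAPSHOT))
            for t, s in traj[1:]:
                kind = (
                    OBS_EXACT_DEATH
                    if structure.is_absorbing(s)
                    else OBS_EXACT_TRANSITION
                )
                obs[t] = PanelObservation(float(t), s, kind)
            if not structure.is_absorbing(states[-1]):
                obs.setdefault(
                    float(horizon),
                    PanelObservation(float(horizon), states[-1], OBS_SNAPSHOT),
                )
        rows = [obs[t] for t in sorted(obs)]
        # drop anything recorded after absorption (grid point on the death
        # time itself, etc.)
        cleaned = []
        for o in rows:
            cleaned.append(o)
            if structure.is_absorbing(o.state):
                break
        subjects.append(
            Subject(
                id=str(sid),
                observations=cleaned,
                covariates={k: float(v) for k, v in covariates.loc[sid].items()},
            )
        )
    return PanelDataset(
        structure=structure,
        subjects=subjects,
        covariate_dictionary=dictionary,
        fully_observed=scheme.exact_events,
    )
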