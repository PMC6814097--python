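"""Summaries derived from a generator matrix or fitted model.

Everything an applied multi-state analysis reports comes from the generator:

- transition rate ratios (TRR), comparing competing or analogous moves;
- the probability that each allowed successor is the next state,
  ``q_ij / sum_k q_ik``;
- mean sojourn times ``1 / (-Q_ii)``;
- expected total length of stay in a state over a horizon,
  ``integral_0^T P[start, target](t) dt``;
- survival probabilities ``1 - P[from, Death](t)``;
- the multi-state frequency table of observed cohort trajectories; and
- observed-versus-expected state prevalences over time (goodness of fit).

Each function accepts a raw generator matrix, an
:class:`~ltcmsm.core.IntensityParameters`, or a fitted model; confidence
intervals (log-scale for ratios and durations, logit-scale for
probabilities, by the delta method) are produced when a fitted model with a
covariance is supplied. Fitted quantities are evaluated at the covariate
reference profile (all covariates zero) unless a profile is given.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.integrate

from .core import (
    IntensityParameters,
    TransitionStructure,
    build_generator,
    transition_probability_matrix,
)
from .data import PanelDataset
from .errors import AbsorbingStateError, NumericRangeError, StructureError
from .fitting import FittedModel, _unpack, delta_method_ci

__all__ = [
    "TransitionSummary",
    "PrevalenceSeries",
    "transition_rate_ratio",
    "next_state_probabilities",
    "next_state_probability",
    "mean_sojourn_time",
    "sojourn_summary",
    "total_length_of_stay",
    "survival_probability",
    "multistate_frequency_table",
    "prevalence_gof",
]


@dataclass(frozen=True)
class TransitionSummary:
    """One reported quantity with its CI and evaluation context."""

    kind: str  # TRR | next_state_probability | sojourn | total_length_of_stay | survival
    value: float
    lower: float | None
    upper: float | None
    states: tuple
    profile: Mapping[str, float] | None = None

    def __post_init__(self):
        if self.lower is not None and not (
            self.lower <= self.value + 1e-12 and self.value <= self.upper + 1e-12
        ):
            raise NumericRangeError(
                f"CI ({self.lower}, {self.upper}) does not bracket {self.value}"
            )


# ---------------------------------------------------------------------------
# model dispatch


def _reference_profile(params: IntensityParameters) -> dict[str, float]:
    return {name: 0.0 for name in params.covariate_names}


def _resolve_model(model, structure, profile):
    """Return (Q, structure, fit-or-None, profile) for any accepted input."""
    if isinstance(model, FittedModel):
        params = model.params
        profile = dict(profile) if profile else _reference_profile(params)
        return build_generator(params, profile), params.structure, model, profile
    if isinstance(model, IntensityParameters):
        profile = dict(profile) if profile else _reference_profile(model)
        return build_generator(model, profile), model.structure, None, profile
    Q = np.asarray(model, dtype=float)
    if structure is None:
        if Q.shape[0] == len(TransitionStructure.default().states):
            structure = TransitionStructure.default()
        else:
            raise StructureError(
                "a TransitionStructure is required with a raw generator matrix"
            )
    return Q, structure, None, profile


def _theta_rate(fitted: FittedModel, profile):
    """Callable theta -> generator matrix at the given covariate profile."""

    def QQ(theta):
        params = _unpack(
            np.asarray(theta, float), fitted.params, fitted.free_baselines
        )
        return build_generator(params, profile)

    return QQ


# ---------------------------------------------------------------------------


def transition_rate_ratio(
    model,
    numerator,
    denominator,
    *,
    structure: TransitionStructure | None = None,
    profile: Mapping[str, float] | None = None,
) -> TransitionSummary:
    """Ratio of two transition intensities, q_num / q_den.

    With a fitted model the 95% CI is the log-scale delta interval.
    """
    Q, st, fitted, profile = _resolve_model(model, structure, profile)
    a = st.resolve_transition(numerator)
    b = st.resolve_transition(denominator)
    if Q[b] == 0:
        raise NumericRangeError(
            f"denominator rate {st.transition_label(*b)} is zero"
        )
    value = float(Q[a] / Q[b])
    lower = upper = None
    if fitted is not None and fitted.covariance is not None:
        QQ = _theta_rate(fitted, profile)
        est = delta_method_ci(
            fitted, lambda th: QQ(th)[a] / QQ(th)[b], transform="log"
        )
        lower, upper = est.lower, est.upper
    return TransitionSummary("TRR", value, lower, upper, (a, b), profile)


def next_state_probabilities(
    model,
    from_state,
    *,
    structure: TransitionStructure | None = None,
    profile: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Distribution of the next state from a transient state,
    ``p_j = q_ij / sum_k q_ik`` over the allowed successors."""
    Q, st, _, _ = _resolve_model(model, structure, profile)
    i = st.resolve_state(from_state)
    if st.is_absorbing(i):
        raise AbsorbingStateError(
            f"state {st.states[i]!r} is absorbing; it has no next state"
        )
    succ = st.successors(i)
    total = float(sum(Q[i, j] for j in succ))
    if total <= 0:
        raise NumericRangeError(
            f"state {st.states[i]!r} has zero total exit rate"
        )
    return {st.states[j]: float(Q[i, j] / total) for j in succ}


def next_state_probability(
    model,
    transition,
    *,
    structure: TransitionStructure | None = None,
    profile: Mapping[str, float] | None = None,
) -> TransitionSummary:
    """One next-state probability with a logit-scale delta CI when fitted."""
    Q, st, fitted, profile = _resolve_model(model, structure, profile)
    i, j = st.resolve_transition(transition)
    probs = next_state_probabilities(Q, i + 1, structure=st)
    value = probs[st.states[j]]
    lower = upper = None
    if fitted is not None and fitted.covariance is not None:
        succ = st.successors(i)
        QQ = _theta_rate(fitted, profile)

        def g(th):
            q = QQ(th)
            return q[i, j] / sum(q[i, k] for k in succ)

        if len(succ) == 1:  # degenerate: probability identically 1
            lower = upper = value
        else:
            est = delta_method_ci(fitted, g, transform="logit")
            lower, upper = est.lower, est.upper
    return TransitionSummary(
        "next_state_probability", value, lower, upper, (i, j), profile
    )


def mean_sojourn_time(
    model,
    state,
    *,
    structure: TransitionStructure | None = None,
    profile: Mapping[str, float] | None = None,
) -> float:
    """Mean duration of a single stay in a transient state, 1 / (-Q_ii)."""
    Q, st, _, _ = _resolve_model(model, structure, profile)
    i = st.resolve_state(state)
    if st.is_absorbing(i):
        raise AbsorbingStateError(
            f"state {st.states[i]!r} is absorbing; sojourn time is infinite"
        )
    q = -Q[i, i]
    if q <= 0:
        raise NumericRangeError(f"state {st.states[i]!r} has zero exit rate")
    return float(1.0 / q)


def sojourn_summary(
    model,
    state,
    *,
    structure: TransitionStructure | None = None,
    profile: Mapping[str, float] | None = None,
) -> TransitionSummary:
    """Mean sojourn time with a log-scale delta CI when fitted."""
    Q, st, fitted, profile = _resolve_model(model, structure, profile)
    i = st.resolve_state(state)
    value = mean_sojourn_time(Q, i + 1, structure=st)
    lower = upper = None
    if fitted is not None and fitted.covariance is not None:
        QQ = _theta_rate(fitted, profile)
        est = delta_method_ci(
            fitted, lambda th: -1.0 / QQ(th)[i, i], transform="log"
        )
        lower, upper = est.lower, est.upper
    return TransitionSummary("sojourn", value, lower, upper, (i,), profile)


def total_length_of_stay(
    model,
    start_state,
    target_state,
    horizon: float | None = 10.0,
    *,
    structure: TransitionStructure | None = None,
    profile: Mapping[str, float] | None = None,
) -> float:
    """Expected cumulative time in ``target_state`` over ``[0, horizon]``
    starting from ``start_state``: the integral of P[start, target](t).

    ``horizon=None`` (or ``inf``) uses the closed form via the fundamental
    matrix of the transient class, valid when the target is transient.
    """
    Q, st, _, _ = _resolve_model(model, structure, profile)
    s = st.resolve_state(start_state)
    j = st.resolve_state(target_state)
    if horizon is None or np.isinf(horizon):
        if st.is_absorbing(j):
            raise AbsorbingStateError(
                f"total stay in absorbing state {st.states[j]!r} diverges "
                "over an infinite horizon"
            )
        transient = [k for k in range(st.n_states) if not st.is_absorbing(k)]
        sub = Q[np.ix_(transient, transient)]
        try:
            N = -np.linalg.inv(sub)
        except np.linalg.LinAlgError as exc:
            raise NumericRangeError(
                f"transient class is not absorbed almost surely: {exc}"
            ) from None
        return float(N[transient.index(s), transient.index(j)])
    if horizon <= 0:
        raise ValueError(f"horizon must be > 0, got {horizon}")
    val, _ = scipy.integrate.quad(
        lambda t: transition_probability_matrix(Q, t)[s, j],
        0.0,
        float(horizon),
        limit=200,
        epsabs=1e-10,
        epsrel=1e-10,
    )
    return float(val)


def survival_probability(
    model,
    from_state,
    t: float,
    *,
    structure: TransitionStructure | None = None,
    profile: Mapping[str, float] | None = None,
) -> float:
    """Probability of being alive at time t starting from a state:
    ``1 - P[from, Death](t)`` (summing over absorbing states)."""
    Q, st, _, _ = _resolve_model(model, structure, profile)
    i = st.resolve_state(from_state)
    P = transition_probability_matrix(Q, t)
    dead = float(sum(P[i, a] for a in st.absorbing))
    return float(1.0 - dead)


# ---------------------------------------------------------------------------
# cohort summaries


def multistate_frequency_table(data: PanelDataset) -> pd.DataFrame:
    """Square count table of observed moves over the follow-up period.

    Entry (i, j), j != i, counts subjects whose trajectory left state i next
    entering state j; the diagonal counts subjects whose last observed state
    was i (those remaining in i at the end of the study — for an absorbing
    state, everyone who entered it). Row totals therefore equal the number
    of subjects who ever occupied the row's state.
    """
    st = data.structure
    n = st.n_states
    counts = np.zeros((n, n), dtype=int)
    for subj in data.subjects:
        seq = []
        for o in subj.observations:
            if not seq or seq[-1] != o.state:
                seq.append(o.state)
        for a, b in zip(seq, seq[1:]):
            counts[a, b] += 1
        counts[seq[-1], seq[-1]] += 1
    return pd.DataFrame(counts, index=list(st.states), columns=list(st.states))


@dataclass
class PrevalenceSeries:
    """Observed and model-expected state counts on a time grid."""

    times: np.ndarray
    observed: np.ndarray  # (n_times, n_states) counts
    expected: np.ndarray  # (n_times, n_states) expected counts
    n: int
    states: tuple[str, ...]

    def max_normalized_discrepancy(self) -> float:
        return float(np.abs(self.observed - self.expected).max() / self.n)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, t in enumerate(self.times):
            for s, label in enumerate(self.states):
                rows.append(
                    {
                        "time": float(t),
                        "state": label,
                        "observed": float(self.observed[k, s]),
                        "expected": float(self.expected[k, s]),
                    }
                )
        return pd.DataFrame(rows)


def prevalence_gof(
    model,
    data: PanelDataset,
    times: Sequence[float],
    *,
    structure: TransitionStructure | None = None,
) -> PrevalenceSeries:
    """Observed versus expected state prevalence over time.

    Observed counts carry each subject's last observation forward to every
    grid time; expected counts sum each subject's transition-probability row
    from the baseline state under the model (rebuilt per subject from their
    covariates when the model has covariate effects).
    """
    times = np.asarray(list(times), dtype=float)
    if (times < 0).any():
        raise ValueError("grid times must be >= 0")
    st = structure if structure is not None else data.structure
    n_states = st.n_states

    observed = np.zeros((times.size, n_states))
    for subj in data.subjects:
        ot = np.array([o.time for o in subj.observations])
        os_ = np.array([o.state for o in subj.observations])
        idx = np.searchsorted(ot, times, side="right") - 1
        idx = np.clip(idx, 0, len(ot) - 1)
        for k in range(times.size):
            observed[k, os_[idx[k]]] += 1

    expected = np.zeros_like(observed)
    if isinstance(model, FittedModel):
        params = model.params
    elif isinstance(model, IntensityParameters):
        params = model
    else:
        params = None

    if params is None:
        Q, st2, _, _ = _resolve_model(model, st, None)
        Ps = [transition_probability_matrix(Q, t) for t in times]
        for k in range(times.size):
            expected[k] = data.n_subjects * Ps[k][0]
    else:
        names = params.covariate_names
        groups: dict[tuple, int] = {}
        for subj in data.subjects:
            key = tuple(float(subj.covariates.get(nm, 0.0)) for nm in names)
            groups[key] = groups.get(key, 0) + 1
        for key, count in groups.items():
            Q = build_generator(params, dict(zip(names, key)))
            for k, t in enumerate(times):
                expected[k] += count * transition_probability_matrix(Q, t)[0]

    return PrevalenceSeries(
        times=times,
        observed=observed,
        expected=expected,
        n=data.n_subjects,
        states=tuple(st.states),
    )
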