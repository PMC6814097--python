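"""Likelihood of panel-observed multi-state data.

Each consecutive pair of observations of a subject contributes one factor,
chosen by the type of the later observation (``dt`` is the elapsed time and
``Q`` the subject's generator):

snapshot
    ``P[from, to](dt)`` — the transition probability, integrating over every
    unobserved path between the two states.
exact_transition
    ``exp(-q_from dt) * q[from, to]`` — the subject is known to have held
    ``from`` for the whole interval and then jumped (``q_from`` is the total
    exit rate ``-Q[from, from]``).
exact_death
    The death time is exact. If the dataset is fully observed the state just
    before death is the interval's from-state and the contribution is the
    same competing-risks density as an exact transition; otherwise the
    pre-death state is unknown and the contribution sums over the live
    states: ``sum_r P[from, r](dt) * q[r, death]``.

For acyclic (progressive) structures ``P[s, s](dt) = exp(-q_s dt)`` exactly,
which the dataset-level evaluator exploits so that fully observed cohorts
need no matrix exponentials at all.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    IntensityParameters,
    LINEAR_PREDICTOR_BOUND,
    TransitionStructure,
    build_generator,
    transition_probability_matrix,
)
from .data import (
    OBS_EXACT_DEATH,
    OBS_EXACT_TRANSITION,
    OBS_SNAPSHOT,
    PanelDataset,
    PanelObservation,
)
from .errors import DataValidationError, NumericRangeError

__all__ = ["interval_log_likelihood", "dataset_log_likelihood"]


def interval_log_likelihood(
    from_state,
    to_obs: PanelObservation,
    dt: float,
    Q: np.ndarray,
    structure: TransitionStructure,
    *,
    pre_death_state_known: bool = False,
) -> float:
    """Log-likelihood contribution of one observation interval.

    ``from_state`` is a state label or 1-based state number; ``to_obs.state``
    is the 0-based internal index stored on the observation.
    """
    if dt <= 0:
        raise DataValidationError(
            [f"interval length dt={dt} must be strictly positive"]
        )
    f = structure.resolve_state(from_state)
    t = to_obs.state
    q_exit = -Q[f, f]
    if to_obs.obs_type == OBS_SNAPSHOT:
        p = transition_probability_matrix(Q, dt)[f, t]
        return float(np.log(p)) if p > 0 else -np.inf
    if to_obs.obs_type == OBS_EXACT_TRANSITION or (
        to_obs.obs_type == OBS_EXACT_DEATH and pre_death_state_known
    ):
        rate = Q[f, t]
        if rate <= 0:
            return -np.inf
        return float(np.log(rate) - q_exit * dt)
    if to_obs.obs_type == OBS_EXACT_DEATH:
        P = transition_probability_matrix(Q, dt)
        live = [r for r in range(structure.n_states) if not structure.is_absorbing(r)]
        dens = float(sum(P[f, r] * Q[r, t] for r in live))
        return float(np.log(dens)) if dens > 0 else -np.inf
    raise DataValidationError([f"unknown obs_type {to_obs.obs_type!r}"])


# ---------------------------------------------------------------------------
# compiled dataset representation for fast repeated evaluation during fitting

_K_SNAP_DIAG = 0  # snapshot, same state, acyclic structure -> closed form
_K_SNAP_GEN = 1  # snapshot needing a matrix exponential
_K_EXACT = 2  # exact transition / exact death with known pre-death state
_K_DEATH_SUM = 3  # exact death, pre-death state unknown


@dataclass
class _Compiled:
    names: tuple[str, ...]
    Z: np.ndarray  # (n_profiles, n_names) unique covariate rows
    profile: np.ndarray
    from_idx: np.ndarray
    to_idx: np.ndarray
    dt: np.ndarray
    kind: np.ndarray
    trans_idx: np.ndarray  # index into structure.transitions for _K_EXACT
    labels: list[str]  # "subject_id[row]" for diagnostics
    person_years: np.ndarray
    event_counts: np.ndarray
    exit_transitions: list[list[int]]  # per state, transition indices


def _compile(data: PanelDataset) -> _Compiled:
    st = data.structure
    names = data.covariate_dictionary.names
    if not names:
        seen: list[str] = []
        for s in data.subjects:
            for n in s.covariates:
                if n not in seen:
                    seen.append(n)
        names = tuple(seen)
    if data.subjects:
        Zfull = np.array(
            [[float(s.covariates.get(n, np.nan)) for n in names] for s in data.subjects]
        )
        if np.isnan(Zfull).any():
            raise DataValidationError(
                ["some subjects are missing covariate values; run validate()"]
            )
    else:
        Zfull = np.zeros((0, len(names)))
    if Zfull.size:
        Zu, inverse = np.unique(Zfull, axis=0, return_inverse=True)
    else:
        Zu, inverse = np.zeros((1, len(names))), np.zeros(len(data.subjects), int)

    acyclic = st.is_acyclic()
    prof, fidx, tidx_, dts, kinds, trans, labels = [], [], [], [], [], [], []
    person_years = np.zeros(st.n_states)
    event_counts = np.zeros(st.n_transitions)
    for si, subj in enumerate(data.subjects):
        obs = subj.observations
        for k in range(1, len(obs)):
            a, b = obs[k - 1], obs[k]
            dt = b.time - a.time
            if dt <= 0:
                raise DataValidationError(
                    [f"subject {subj.id}, rows {k - 1}-{k}: non-positive dt"]
                )
            if b.obs_type == OBS_SNAPSHOT:
                kind = _K_SNAP_DIAG if (a.state == b.state and acyclic) else _K_SNAP_GEN
                ti = -1
            elif b.obs_type == OBS_EXACT_TRANSITION or (
                b.obs_type == OBS_EXACT_DEATH and data.fully_observed
            ):
                kind = _K_EXACT
                ti = st.transition_index(a.state, b.state)
            elif b.obs_type == OBS_EXACT_DEATH:
                kind = _K_DEATH_SUM
                ti = -1
            else:
                raise DataValidationError(
                    [f"subject {subj.id}, row {k}: unknown obs_type {b.obs_type!r}"]
                )
            prof.append(inverse[si])
            fidx.append(a.state)
            tidx_.append(b.state)
            dts.append(dt)
            kinds.append(kind)
            trans.append(ti)
            labels.append(f"{subj.id}[{k}]")
            person_years[a.state] += dt
            if a.state != b.state and (a.state, b.state) in st.transitions:
                event_counts[st.transition_index(a.state, b.state)] += 1
    exit_transitions = [
        [k for k, (i, _) in enumerate(st.transitions) if i == s]
        for s in range(st.n_states)
    ]
    return _Compiled(
        names=names,
        Z=Zu,
        profile=np.asarray(prof, int),
        from_idx=np.asarray(fidx, int),
        to_idx=np.asarray(tidx_, int),
        dt=np.asarray(dts, float),
        kind=np.asarray(kinds, int),
        trans_idx=np.asarray(trans, int),
        labels=labels,
        person_years=person_years,
        event_counts=event_counts,
        exit_transitions=exit_transitions,
    )


def _compiled(data: PanelDataset) -> _Compiled:
    if data._compiled is None:
        data._compiled = _compile(data)
    return data._compiled


def _rates(comp: _Compiled, params: IntensityParameters):
    """Per-profile transition rates and total exit rates.

    Returns ``(LP, R, qtot)`` where ``LP`` and ``R = exp(LP)`` are
    (n_profiles, n_transitions) and ``qtot`` is (n_profiles, n_states).
    """
    st = params.structure
    lb = np.asarray(params.log_baseline)
    LP = np.tile(lb, (comp.Z.shape[0], 1))
    col = {n: c for c, n in enumerate(comp.names)}
    for k, cmap in enumerate(params.coefficients):
        for name, beta in cmap.items():
            if name not in col:
                from .errors import CovariateError

                raise CovariateError(
                    f"covariate {name!r} in the model formula is absent "
                    "from the dataset"
                )
            LP[:, k] += beta * comp.Z[:, col[name]]
    if LP.size and np.abs(LP).max() > LINEAR_PREDICTOR_BOUND:
        k = np.unravel_index(np.abs(LP).argmax(), LP.shape)[1]
        i, j = st.transitions[k]
        raise NumericRangeError(
            f"linear predictor for transition {st.transition_label(i, j)} "
            f"outside safe range +-{LINEAR_PREDICTOR_BOUND}"
        )
    R = np.exp(LP)
    qtot = np.zeros((comp.Z.shape[0], st.n_states))
    for k, (i, _) in enumerate(st.transitions):
        qtot[:, i] += R[:, k]
    return LP, R, qtot


def _profile_generator(
    R_row: np.ndarray, qtot_row: np.ndarray, st: TransitionStructure
) -> np.ndarray:
    Q = np.zeros((st.n_states, st.n_states))
    for k, (i, j) in enumerate(st.transitions):
        Q[i, j] = R_row[k]
    np.fill_diagonal(Q, -qtot_row)
    return Q


def dataset_log_likelihood(
    data: PanelDataset, params: IntensityParameters
) -> float:
    """Total log-likelihood of a panel dataset under the intensity model.

    The sum over subjects of the interval contributions described in the
    module docstring, with the generator rebuilt from each subject's baseline
    covariates. Returns ``-inf`` (with a warning naming the first offending
    subject and interval) when some observed move has probability zero.
    """
    comp = _compiled(data)
    if comp.dt.size == 0:
        return 0.0
    st = params.structure
    LP, R, qtot = _rates(comp, params)

    # per-interval contributions; summed with fsum so the total is exactly
    # invariant under subject reordering
    contrib = np.zeros(comp.dt.size)
    m = comp.kind == _K_SNAP_DIAG
    contrib[m] = -qtot[comp.profile[m], comp.from_idx[m]] * comp.dt[m]
    m = comp.kind == _K_EXACT
    contrib[m] = (
        LP[comp.profile[m], comp.trans_idx[m]]
        - qtot[comp.profile[m], comp.from_idx[m]] * comp.dt[m]
    )

    live = [r for r in range(st.n_states) if not st.is_absorbing(r)]
    cache: dict[tuple[int, float], np.ndarray] = {}
    Qs: dict[int, np.ndarray] = {}
    for k in np.nonzero((comp.kind == _K_SNAP_GEN) | (comp.kind == _K_DEATH_SUM))[0]:
        p = int(comp.profile[k])
        if p not in Qs:
            Qs[p] = _profile_generator(R[p], qtot[p], st)
        key = (p, float(comp.dt[k]))
        if key not in cache:
            cache[key] = transition_probability_matrix(Qs[p], comp.dt[k])
        P = cache[key]
        f, t = comp.from_idx[k], comp.to_idx[k]
        if comp.kind[k] == _K_SNAP_GEN:
            v = P[f, t]
        else:
            v = float(sum(P[f, r] * Qs[p][r, t] for r in live))
        if v <= 0:
            warnings.warn(
                f"zero-probability contribution at interval {comp.labels[k]} "
                f"({st.states[f]} -> {st.states[t]}, dt={comp.dt[k]:.4g})",
                RuntimeWarning,
                stacklevel=2,
            )
            return -np.inf
        contrib[k] = np.log(v)
    return math.fsum(contrib)
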