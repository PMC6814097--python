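"""State spaces, intensity models and transition-probability machinery.

A continuous-time Markov multi-state model is specified by a
:class:`TransitionStructure` (which directed moves between states are
possible, and which states are absorbing) together with
:class:`IntensityParameters` (how fast each allowed move happens and how
baseline covariates scale each intensity on a proportional-hazards scale):

    q_ij(z) = q_ij0 * exp(beta_ij' z)

The intensities are collected in a generator matrix ``Q`` with non-negative
off-diagonal entries and zero row sums; transition probabilities over an
interval of length ``t`` follow as ``P(t) = expm(t Q)``.

The default structure is the progressive four-state long-term-care model:
State 1 Non-user, State 2 HACC (home and community care), State 3 RAC
(residential aged care), State 4 Death, with the six forward transitions
1->2, 1->3, 1->4, 2->3, 2->4, 3->4 and no reverse moves.

States are 1-based in user-facing I/O (matching the State 1..4 convention of
the applied literature) and 0-based internally; every public function accepts
either a state label or a 1-based state number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.linalg

from .errors import (
    AbsorbingStateError,
    CovariateError,
    NumericRangeError,
    StructureError,
)

__all__ = [
    "DEFAULT_STATES",
    "LINEAR_PREDICTOR_BOUND",
    "TransitionStructure",
    "IntensityParameters",
    "build_generator",
    "transition_probability_matrix",
    "chapman_kolmogorov_check",
    "validate_generator",
]

DEFAULT_STATES = ("Non-user", "HACC", "RAC", "Death")

#: Linear predictors log q_ij0 + beta'z beyond this magnitude raise rather
#: than silently saturating exp().
LINEAR_PREDICTOR_BOUND = 30.0


@dataclass(frozen=True)
class TransitionStructure:
    """The state space and the set of allowed directed transitions.

    Parameters
    ----------
    states
        Ordered state labels.
    transitions
        Allowed directed transitions as 0-based ``(from, to)`` index pairs.
        They are stored sorted, and this order fixes the layout of every
        parameter vector in the package.
    absorbing
        0-based indices of absorbing states (no outgoing transitions).
    """

    states: tuple[str, ...]
    transitions: tuple[tuple[int, int], ...]
    absorbing: frozenset[int]

    def __init__(self, states, transitions, absorbing):
        object.__setattr__(self, "states", tuple(str(s) for s in states))
        object.__setattr__(
            self,
            "transitions",
            tuple(sorted((int(i), int(j)) for i, j in transitions)),
        )
        object.__setattr__(self, "absorbing", frozenset(int(a) for a in absorbing))
        self._validate()

    # -- construction ---------------------------------------------------

    @classmethod
    def default(cls) -> "TransitionStructure":
        """The progressive four-state long-term-care structure."""
        return cls(
            states=DEFAULT_STATES,
            transitions=((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)),
            absorbing={3},
        )

    @classmethod
    def from_config(cls, cfg: Mapping) -> "TransitionStructure":
        """Build from the config mapping: state labels, ``"From>To"``
        transition strings and absorbing labels."""
        states = list(cfg["states"])
        idx = {s: k for k, s in enumerate(states)}
        transitions = []
        for spec in cfg["transitions"]:
            try:
                a, b = (part.strip() for part in str(spec).split(">"))
                transitions.append((idx[a], idx[b]))
            except (ValueError, KeyError) as exc:
                raise StructureError(f"bad transition spec {spec!r}") from exc
        absorbing = {idx[s] for s in cfg.get("absorbing", [])}
        return cls(states, transitions, absorbing)

    def to_config(self) -> dict:
        return {
            "states": list(self.states),
            "transitions": [
                f"{self.states[i]}>{self.states[j]}" for i, j in self.transitions
            ],
            "absorbing": [self.states[a] for a in sorted(self.absorbing)],
        }

    def _validate(self) -> None:
        n = len(self.states)
        if n < 2:
            raise StructureError("need at least two states")
        if len(set(self.states)) != n:
            raise StructureError("state labels must be unique")
        seen = set()
        for i, j in self.transitions:
            if not (0 <= i < n and 0 <= j < n):
                raise StructureError(f"transition ({i}, {j}) out of range")
            if i == j:
                raise StructureError(f"self-transition ({i}, {j}) not allowed")
            if (i, j) in seen:
                raise StructureError(f"duplicate transition ({i}, {j})")
            seen.add((i, j))
        for a in self.absorbing:
            if not 0 <= a < n:
                raise StructureError(f"absorbing index {a} out of range")
            if any(i == a for i, _ in self.transitions):
                raise StructureError(
                    f"absorbing state {self.states[a]!r} has outgoing transitions"
                )

    # -- queries ---------------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    def resolve_state(self, state) -> int:
        """Map a state label or 1-based state number to a 0-based index."""
        if isinstance(state, str):
            try:
                return self.states.index(state)
            except ValueError:
                raise StructureError(
                    f"unknown state {state!r}; states are {self.states}"
                ) from None
        k = int(state)
        if not 1 <= k <= self.n_states:
            raise StructureError(
                f"state number {k} out of range 1..{self.n_states}"
            )
        return k - 1

    def resolve_transition(self, transition) -> tuple[int, int]:
        """Map a ``(from, to)`` pair of labels / 1-based numbers to 0-based
        indices, checking the transition is allowed."""
        i, j = (self.resolve_state(s) for s in transition)
        if (i, j) not in self.transitions:
            raise StructureError(
                f"transition {self.states[i]}->{self.states[j]} is not allowed"
            )
        return i, j

    def transition_index(self, i: int, j: int) -> int:
        """Position of 0-based pair ``(i, j)`` in the parameter ordering."""
        try:
            return self.transitions.index((i, j))
        except ValueError:
            raise StructureError(f"transition ({i}, {j}) is not allowed") from None

    def is_absorbing(self, i: int) -> bool:
        return i in self.absorbing

    def successors(self, i: int) -> tuple[int, ...]:
        return tuple(j for a, j in self.transitions if a == i)

    def is_acyclic(self) -> bool:
        graph: dict[int, set[int]] = {k: set() for k in range(self.n_states)}
        for i, j in self.transitions:
            graph[j].add(i)  # predecessors
        try:
            tuple(TopologicalSorter(graph).static_order())
            return True
        except CycleError:
            return False

    def reachable(self) -> np.ndarray:
        """Boolean matrix; entry (i, j) is True when j can be reached from i
        through zero or more allowed transitions."""
        n = self.n_states
        r = np.eye(n, dtype=bool)
        for i, j in self.transitions:
            r[i, j] = True
        for _ in range(n):  # transitive closure, n is tiny
            r = r | (r @ r)
        return r

    def transition_label(self, i: int, j: int) -> str:
        return f"{self.states[i]}->{self.states[j]}"


@dataclass(frozen=True)
class IntensityParameters:
    """Baseline log-intensities and covariate effects for every allowed
    transition.

    ``log_baseline[k]`` is log q_ij0 (log events/year) for the k-th
    transition in ``structure.transitions``; ``coefficients[k]`` maps a
    covariate name to its log hazard ratio beta on that transition.
    """

    structure: TransitionStructure
    log_baseline: tuple[float, ...]
    coefficients: tuple[Mapping[str, float], ...] = None  # type: ignore[assignment]

    def __init__(self, structure, log_baseline, coefficients=None):
        object.__setattr__(self, "structure", structure)
        lb = tuple(float(v) for v in log_baseline)
        if len(lb) != structure.n_transitions:
            raise StructureError(
                f"expected {structure.n_transitions} log-baselines, got {len(lb)}"
            )
        if not all(np.isfinite(lb)):
            raise NumericRangeError("log-baseline intensities must be finite")
        object.__setattr__(self, "log_baseline", lb)
        if coefficients is None:
            coefficients = tuple({} for _ in lb)
        coefs = tuple(dict(c) for c in coefficients)
        if len(coefs) != len(lb):
            raise StructureError("one coefficient mapping per transition required")
        object.__setattr__(self, "coefficients", coefs)

    @classmethod
    def from_rates(
        cls,
        structure: TransitionStructure,
        rates: Mapping,
        coefficients: Mapping | None = None,
    ) -> "IntensityParameters":
        """Build from baseline rates (events/year) keyed by transition pairs
        (labels or 1-based numbers), optionally with per-transition
        ``{covariate: log hazard ratio}`` mappings keyed the same way."""
        lb = np.full(structure.n_transitions, np.nan)
        for key, rate in rates.items():
            i, j = structure.resolve_transition(key)
            if rate <= 0:
                raise NumericRangeError(
                    f"rate for {structure.transition_label(i, j)} must be > 0"
                )
            lb[structure.transition_index(i, j)] = np.log(rate)
        if np.isnan(lb).any():
            missing = [
                structure.transition_label(i, j)
                for k, (i, j) in enumerate(structure.transitions)
                if np.isnan(lb[k])
            ]
            raise StructureError(f"no rate given for transitions: {missing}")
        coefs = [dict() for _ in range(structure.n_transitions)]
        for key, cmap in (coefficients or {}).items():
            i, j = structure.resolve_transition(key)
            coefs[structure.transition_index(i, j)] = dict(cmap)
        return cls(structure, lb, coefs)

    @property
    def covariate_names(self) -> tuple[str, ...]:
        """All covariate names used by any transition, in first-seen order."""
        names: list[str] = []
        for cmap in self.coefficients:
            for name in cmap:
                if name not in names:
                    names.append(name)
        return tuple(names)

    def formulas(self) -> tuple[tuple[str, ...], ...]:
        return tuple(tuple(c) for c in self.coefficients)

    def baseline_rate(self, transition) -> float:
        i, j = self.structure.resolve_transition(transition)
        return float(np.exp(self.log_baseline[self.structure.transition_index(i, j)]))

    # -- flat parameter vector -------------------------------------------
    # Layout: log-baselines in structure.transitions order, then the betas
    # of each transition (same order), covariates in formula order.

    def to_theta(self) -> np.ndarray:
        parts = [list(self.log_baseline)]
        for cmap in self.coefficients:
            parts.append(list(cmap.values()))
        return np.concatenate([np.asarray(p, dtype=float) for p in parts])

    def with_theta(self, theta: Sequence[float]) -> "IntensityParameters":
        theta = np.asarray(theta, dtype=float)
        nt = self.structure.n_transitions
        lb = theta[:nt]
        pos = nt
        coefs = []
        for cmap in self.coefficients:
            new = {}
            for name in cmap:
                new[name] = float(theta[pos])
                pos += 1
            coefs.append(new)
        if pos != theta.size:
            raise StructureError(
                f"theta has length {theta.size}, expected {pos}"
            )
        return IntensityParameters(self.structure, lb, coefs)


def build_generator(
    params: IntensityParameters,
    z: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Assemble the subject-specific generator matrix Q.

    Each allowed entry is ``q_ij = exp(log q_ij0 + beta_ij' z)``; the
    diagonal is set to minus the row sum and absorbing rows are zero.

    Raises
    ------
    CovariateError
        If a covariate named in a formula is absent from ``z``.
    NumericRangeError
        If a linear predictor exceeds +-30, where exp() would overflow or
        vanish meaninglessly.
    """
    st = params.structure
    z = {} if z is None else z
    Q = np.zeros((st.n_states, st.n_states))
    for k, (i, j) in enumerate(st.transitions):
        lp = params.log_baseline[k]
        for name, beta in params.coefficients[k].items():
            try:
                lp += beta * float(z[name])
            except KeyError:
                raise CovariateError(
                    f"covariate {name!r} required by transition "
                    f"{st.transition_label(i, j)} is missing"
                ) from None
        if not np.isfinite(lp) or abs(lp) > LINEAR_PREDICTOR_BOUND:
            raise NumericRangeError(
                f"linear predictor {lp:.3g} for transition "
                f"{st.transition_label(i, j)} outside safe range "
                f"+-{LINEAR_PREDICTOR_BOUND}"
            )
        Q[i, j] = np.exp(lp)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def validate_generator(
    Q: np.ndarray, structure: TransitionStructure | None = None, tol: float = 1e-12
) -> None:
    """Check the generator-matrix invariants, raising ``StructureError``."""
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise StructureError("Q must be square")
    off = Q - np.diag(np.diag(Q))
    if (off < 0).any():
        raise StructureError("off-diagonal entries of Q must be non-negative")
    if np.abs(Q.sum(axis=1)).max() > tol:
        raise StructureError("rows of Q must sum to zero")
    if structure is not None:
        if Q.shape[0] != structure.n_states:
            raise StructureError("Q size does not match the structure")
        allowed = np.zeros_like(Q, dtype=bool)
        for i, j in structure.transitions:
            allowed[i, j] = True
        if (off[~allowed & ~np.eye(Q.shape[0], dtype=bool)] != 0).any():
            raise StructureError("Q has a non-zero entry on a disallowed transition")


def transition_probability_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """Transition probability matrix P(t) = expm(tQ).

    Uses scipy's scaling-and-squaring Pade matrix exponential on the full
    matrix, which is robust to near-repeated eigenvalues. Entries are clipped
    to [0, 1] to remove rounding dust of order 1e-16.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    Q = np.asarray(Q, dtype=float)
    if t == 0:
        return np.eye(Q.shape[0])
    P = scipy.linalg.expm(Q * float(t))
    return np.clip(P, 0.0, 1.0)


def chapman_kolmogorov_check(Q: np.ndarray, s: float, t: float) -> float:
    """Max absolute deviation of P(s+t) - P(s) P(t).

    For a time-homogeneous chain this is zero up to numerical error
    (semigroup property); the test suite uses it as a self-check.
    """
    Ps = transition_probability_matrix(Q, s)
    Pt = transition_probability_matrix(Q, t)
    Pst = transition_probability_matrix(Q, s + t)
    return float(np.abs(Pst - Ps @ Pt).max())
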