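"""Panel datasets: timed state observations with baseline covariates.

A cohort is stored in long format — one row per subject per observation
time — with three observation types:

``snapshot``
    The state was ascertained at that time (survey wave, or administrative
    censoring at the end of follow-up); the exact transition times inside the
    preceding interval are unknown (interval censoring).
``exact_transition``
    The subject is known to have entered the recorded state exactly at that
    time, having remained in the previous state until then (administratively
    dated care entry).
``exact_death``
    The time of entry into the absorbing state is exact; whether the state
    immediately before death is known depends on the observation scheme (see
    :attr:`PanelDataset.fully_observed`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import TransitionStructure
from .errors import DataValidationError

__all__ = [
    "OBS_TYPES",
    "PanelObservation",
    "Subject",
    "CovariateDictionary",
    "PanelDataset",
]

OBS_SNAPSHOT = "snapshot"
OBS_EXACT_TRANSITION = "exact_transition"
OBS_EXACT_DEATH = "exact_death"
OBS_TYPES = (OBS_SNAPSHOT, OBS_EXACT_TRANSITION, OBS_EXACT_DEATH)


@dataclass(frozen=True)
class PanelObservation:
    """One timed state observation of one subject.

    ``state`` is a 0-based index into the structure's states; ``time`` is in
    years from baseline.
    """

    time: float
    state: int
    obs_type: str = OBS_SNAPSHOT


@dataclass
class Subject:
    """A subject's ordered observations plus their baseline covariates."""

    id: str
    observations: list[PanelObservation]
    covariates: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CovariateDictionary:
    """Covariate names with their kinds.

    ``kinds`` maps each name to ``"indicator"`` (coded 0/1; reference level
    0) or ``"continuous"``.
    """

    kinds: Mapping[str, str]

    def __init__(self, kinds: Mapping[str, str] | Iterable[str] | None = None):
        if kinds is None:
            kinds = {}
        if not isinstance(kinds, Mapping):
            kinds = {name: "indicator" for name in kinds}
        kinds = dict(kinds)
        for name, kind in kinds.items():
            if kind not in ("indicator", "continuous"):
                raise DataValidationError(
                    [f"covariate {name!r} has unknown kind {kind!r}"]
                )
        object.__setattr__(self, "kinds", kinds)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.kinds)

    def __contains__(self, name: str) -> bool:
        return name in self.kinds


@dataclass
class PanelDataset:
    """A collection of subjects sharing one structure and one covariate
    dictionary.

    ``fully_observed`` declares that every transition of every subject was
    recorded exactly (administrative-record emulation): between consecutive
    rows the subject is known to have stayed in the earlier row's state, and
    the state immediately before an ``exact_death`` row is known. When False
    (survey panels), unrecorded intermediate moves are possible and
    likelihood contributions integrate over them.
    """

    structure: TransitionStructure
    subjects: list[Subject]
    covariate_dictionary: CovariateDictionary = field(
        default_factory=CovariateDictionary
    )
    fully_observed: bool = False

    # cache slot filled by the likelihood compiler; invalidated never —
    # datasets are treated as immutable once built
    _compiled: object = field(default=None, repr=False, compare=False)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return sum(len(s.observations) for s in self.subjects)

    def validate(self) -> None:
        """Check every dataset invariant, collecting all violations.

        Raises
        ------
        DataValidationError
            Listing each violating subject and observation.
        """
        st = self.structure
        problems: list[str] = []
        reach = st.reachable()
        seen_ids: set[str] = set()
        for subj in self.subjects:
            if subj.id in seen_ids:
                problems.append(f"duplicate subject id {subj.id!r}")
            seen_ids.add(subj.id)
            obs = subj.observations
            if not obs:
                problems.append(f"subject {subj.id}: no observations")
                continue
            if obs[0].time != 0.0:
                problems.append(
                    f"subject {subj.id}: first observation at t={obs[0].time}, "
                    "expected t=0"
                )
            for name in self.covariate_dictionary.names:
                if name not in subj.covariates:
                    problems.append(
                        f"subject {subj.id}: covariate {name!r} missing"
                    )
                elif self.covariate_dictionary.kinds[name] == "indicator":
                    v = subj.covariates[name]
                    if v not in (0, 1, 0.0, 1.0):
                        problems.append(
                            f"subject {subj.id}: indicator {name!r} has "
                            f"value {v!r}, expected 0/1"
                        )
            for k, o in enumerate(obs):
                if not 0 <= o.state < st.n_states:
                    problems.append(
                        f"subject {subj.id}, row {k}: state index {o.state} "
                        "out of range"
                    )
                    break
                if o.obs_type not in OBS_TYPES:
                    problems.append(
                        f"subject {subj.id}, row {k}: unknown obs_type "
                        f"{o.obs_type!r}"
                    )
                if o.obs_type == OBS_EXACT_DEATH and not st.is_absorbing(o.state):
                    problems.append(
                        f"subject {subj.id}, row {k}: exact_death on "
                        f"non-absorbing state {st.states[o.state]!r}"
                    )
                if k == 0:
                    continue
                prev = obs[k - 1]
                if o.time <= prev.time:
                    problems.append(
                        f"subject {subj.id}, rows {k - 1}-{k}: times "
                        f"{prev.time} -> {o.time} not strictly increasing"
                    )
                if st.is_absorbing(prev.state):
                    problems.append(
                        f"subject {subj.id}, row {k}: observation after "
                        f"absorbing state {st.states[prev.state]!r}"
                    )
                if not reach[prev.state, o.state]:
                    problems.append(
                        f"subject {subj.id}, rows {k - 1}-{k}: move "
                        f"{st.states[prev.state]} -> {st.states[o.state]} "
                        "violates the transition structure"
                    )
                if o.obs_type == OBS_EXACT_TRANSITION and (
                    (prev.state, o.state) not in st.transitions
                ):
                    problems.append(
                        f"subject {subj.id}, rows {k - 1}-{k}: exact "
                        f"transition {st.states[prev.state]} -> "
                        f"{st.states[o.state]} is not a direct allowed move"
                    )
        if problems:
            raise DataValidationError(problems)

    def covariate_frame(self):
        """Baseline covariates as a pandas DataFrame indexed by subject id."""
        import pandas as pd

        return pd.DataFrame(
            [s.covariates for s in self.subjects],
            index=[s.id for s in self.subjects],
        )
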