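"""Readers and writers: panel CSV, fitted-model archives, YAML config.

The single tabular interchange format is long-format CSV with a header,
UTF-8, dot decimal: columns ``subject_id``, ``time``, ``state`` (label),
``obs_type`` plus one column per baseline covariate (repeated on every row
of a subject).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .core import TransitionStructure
from .data import (
    CovariateDictionary,
    OBS_TYPES,
    PanelDataset,
    PanelObservation,
    Subject,
)
from .errors import DataValidationError
from .fitting import FittedModel
from .simulate import TrueModel

__all__ = [
    "REQUIRED_COLUMNS",
    "read_panel_csv",
    "write_panel_csv",
    "load_config",
    "write_truth_file",
]

REQUIRED_COLUMNS = ("subject_id", "time", "state", "obs_type")


def read_panel_csv(
    path,
    dictionary: CovariateDictionary | None = None,
    structure: TransitionStructure | None = None,
    fully_observed: bool | None = None,
) -> PanelDataset:
    """Read and validate a long-format panel CSV.

    All contract violations (missing columns, unknown state labels,
    non-increasing times, observations after absorption, ...) are collected
    with row numbers and raised together as a single
    :class:`~ltcmsm.errors.DataValidationError`.

    ``fully_observed=None`` infers the flag from the file: the dataset is
    treated as fully observed (every transition exactly recorded) when no
    state change appears on a snapshot row.
    """
    if structure is None:
        structure = TransitionStructure.default()
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError([f"missing required column {c!r}" for c in missing])

    cov_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    if dictionary is None:
        kinds = {}
        for c in cov_cols:
            vals = set(pd.unique(df[c].dropna()))
            kinds[c] = "indicator" if vals <= {0, 1, 0.0, 1.0} else "continuous"
        dictionary = CovariateDictionary(kinds)

    problems: list[str] = []
    label_to_idx = {s: k for k, s in enumerate(structure.states)}
    subjects: list[Subject] = []
    # preserve file order of subjects; rows within a subject follow file order
    for sid, group in df.groupby("subject_id", sort=False):
        observations = []
        covs: dict[str, float] = {}
        for row_no, row in zip(group.index, group.itertuples(index=False)):
            state = getattr(row, "state")
            if state not in label_to_idx:
                problems.append(
                    f"row {row_no + 2}: unknown state label {state!r}"
                )
                continue
            obs_type = getattr(row, "obs_type")
            if obs_type not in OBS_TYPES:
                problems.append(
                    f"row {row_no + 2}: unknown obs_type {obs_type!r}"
                )
                continue
            observations.append(
                PanelObservation(
                    time=float(getattr(row, "time")),
                    state=label_to_idx[state],
                    obs_type=obs_type,
                )
            )
            for c in cov_cols:
                v = getattr(row, c)
                if c in covs and not np.isclose(covs[c], float(v)):
                    problems.append(
                        f"row {row_no + 2}: covariate {c!r} changes within "
                        f"subject {sid!r} (baseline covariates are constant)"
                    )
                covs[c] = float(v)
        subjects.append(Subject(id=str(sid), observations=observations, covariates=covs))

    data = PanelDataset(
        structure=structure,
        subjects=subjects,
        covariate_dictionary=dictionary,
        fully_observed=False,
    )
    try:
        data.validate()
    except DataValidationError as exc:
        problems.extend(exc.problems)
    if problems:
        raise DataValidationError(problems)
    if fully_observed is None:
        # administrative-record emulation: every state change exactly dated,
        # snapshots only at baseline and censoring
        fully_observed = all(
            o.obs_type != "snapshot"
            or k == 0
            or o.state == s.observations[k - 1].state
            for s in data.subjects
            for k, o in enumerate(s.observations)
        )
    data.fully_observed = bool(fully_observed)
    return data


def write_panel_csv(data: PanelDataset, path) -> None:
    """Write a dataset in the long CSV format (inverse of read_panel_csv)."""
    st = data.structure
    rows = []
    for subj in data.subjects:
        for o in subj.observations:
            row = {
                "subject_id": subj.id,
                "time": o.time,
                "state": st.states[o.state],
                "obs_type": o.obs_type,
            }
            row.update(subj.covariates)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a YAML run configuration; returns an empty dict for None."""
    if path is None:
        return {}
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise DataValidationError(["config file must contain a mapping"])
    return cfg


def write_truth_file(true_model: TrueModel, path) -> None:
    """Persist the generating parameters of a synthetic cohort."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(true_model.to_dict(), fh, indent=1)
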