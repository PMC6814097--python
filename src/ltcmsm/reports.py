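"""Paper-style report frames: frequency table, transition summaries,
hazard-ratio table, probability curves and prevalence series.

Report CSVs carry full precision; the aligned-text renderings round
probabilities, rate ratios and years to two decimals, matching the
conventions of the applied literature.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import TransitionStructure, transition_probability_matrix
from .data import PanelDataset
from .derived import (
    _resolve_model,
    multistate_frequency_table,
    next_state_probability,
    prevalence_gof,
    sojourn_summary,
    transition_rate_ratio,
)
from .fitting import FittedModel, hazard_ratios

__all__ = [
    "table1_frame",
    "table2_frame",
    "table3_frame",
    "curves_frame",
    "survival_frame",
    "prevalence_frame",
    "render_text",
]


def table1_frame(data: PanelDataset) -> pd.DataFrame:
    """Multi-state frequency table with a row-total column."""
    tab = multistate_frequency_table(data)
    tab["Total"] = tab.sum(axis=1)
    return tab


def _trr_comparisons(st: TransitionStructure) -> list[tuple[tuple, tuple]]:
    """The reported TRR pairs: competing exits of each transient state, and
    transitions into an absorbing state compared across origins."""
    pairs = []
    for i in range(st.n_states):
        succ = st.successors(i)
        for a in range(len(succ)):
            for b in range(a + 1, len(succ)):
                pairs.append(((i, succ[a]), (i, succ[b])))
    for j in sorted(st.absorbing):
        origins = [i for i, k in st.transitions if k == j]
        for a in range(len(origins)):
            for b in range(a + 1, len(origins)):
                pairs.append(((origins[b], j), (origins[a], j)))
    return pairs


def table2_frame(
    model,
    *,
    structure: TransitionStructure | None = None,
    profile: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Transition rate ratios, next-state probabilities and mean sojourn
    times (with CIs when a fitted model is given), in one long frame."""
    Q, st, fitted, profile = _resolve_model(model, structure, profile)
    src = fitted if fitted is not None else Q
    rows = []
    for num, den in _trr_comparisons(st):
        est = transition_rate_ratio(
            src, tuple(x + 1 for x in num), tuple(x + 1 for x in den),
            structure=st, profile=profile,
        )
        rows.append(
            {
                "quantity": "TRR",
                "description": (
                    f"{st.transition_label(*num)} vs. {st.transition_label(*den)}"
                ),
                "value": est.value,
                "lower": est.lower,
                "upper": est.upper,
            }
        )
    for i, j in st.transitions:
        est = next_state_probability(
            src, (i + 1, j + 1), structure=st, profile=profile
        )
        rows.append(
            {
                "quantity": "next_state_probability",
                "description": f"from {st.states[i]} to {st.states[j]}",
                "value": est.value,
                "lower": est.lower,
                "upper": est.upper,
            }
        )
    for i in range(st.n_states):
        if st.is_absorbing(i):
            continue
        est = sojourn_summary(src, i + 1, structure=st, profile=profile)
        rows.append(
            {
                "quantity": "mean_sojourn_years",
                "description": st.states[i],
                "value": est.value,
                "lower": est.lower,
                "upper": est.upper,
            }
        )
    return pd.DataFrame(rows)


def table3_frame(fit: FittedModel) -> pd.DataFrame:
    """Hazard ratios with 95% CIs, one row per covariate per transition."""
    st = fit.structure
    rows = []
    for k, (i, j) in enumerate(st.transitions):
        for name in fit.params.coefficients[k]:
            est = hazard_ratios(fit, (i + 1, j + 1), name)
            rows.append(
                {
                    "covariate": name,
                    "transition": st.transition_label(i, j),
                    "hazard_ratio": est.value,
                    "lower": est.lower,
                    "upper": est.upper,
                }
            )
    return pd.DataFrame(
        rows, columns=["covariate", "transition", "hazard_ratio", "lower", "upper"]
    )


def curves_frame(
    model,
    times: Sequence[float],
    *,
    structure: TransitionStructure | None = None,
    profile: Mapping[str, float] | None = None,
    from_states: Sequence | None = None,
) -> pd.DataFrame:
    """Transition-probability curves: one row per time per (from, to)."""
    Q, st, _, _ = _resolve_model(model, structure, profile)
    if from_states is None:
        origins = [i for i in range(st.n_states) if not st.is_absorbing(i)]
    else:
        origins = [st.resolve_state(s) for s in from_states]
    rows = []
    for t in times:
        P = transition_probability_matrix(Q, float(t))
        for i in origins:
            for j in range(st.n_states):
                rows.append(
                    {
                        "time": float(t),
                        "from": st.states[i],
                        "to": st.states[j],
                        "probability": float(P[i, j]),
                    }
                )
    return pd.DataFrame(rows)


def survival_frame(
    model,
    times: Sequence[float],
    *,
    structure: TransitionStructure | None = None,
    profile: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Survival curves 1 - P[from, Death](t) from each transient state."""
    Q, st, _, _ = _resolve_model(model, structure, profile)
    rows = []
    for t in times:
        P = transition_probability_matrix(Q, float(t))
        for i in range(st.n_states):
            if st.is_absorbing(i):
                continue
            dead = float(sum(P[i, a] for a in st.absorbing))
            rows.append(
                {"time": float(t), "from": st.states[i], "survival": 1.0 - dead}
            )
    return pd.DataFrame(rows)


def prevalence_frame(model, data: PanelDataset, times: Sequence[float]) -> pd.DataFrame:
    return prevalence_gof(model, data, times).to_frame()


def render_text(df: pd.DataFrame, title: str | None = None) -> str:
    """Aligned text rendering with 2-decimal rounding of numeric columns."""
    shown = df.copy()
    for c in shown.columns:
        if pd.api.types.is_float_dtype(shown[c]):
            shown[c] = shown[c].round(2)
    body = shown.to_string(index=isinstance(shown.index, pd.MultiIndex) or
                           not isinstance(shown.index, pd.RangeIndex))
    return (f"{title}\n{body}\n" if title else body + "\n")
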