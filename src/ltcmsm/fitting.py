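"""Maximum-likelihood estimation of transition intensities.

Fitting works on the unconstrained scale (log baseline intensities, raw
covariate coefficients) by quasi-Newton ascent, initialised from crude
occurrence/exposure rates (observed direct moves divided by person-years at
risk) with all coefficients at zero. The covariance of the estimator is the
inverse of the observed information, obtained by central finite differences
of the negative log-likelihood at the maximum; 95% intervals use the normal
1.96 quantile throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import scipy.optimize

from .core import IntensityParameters, TransitionStructure
from .data import PanelDataset
from .errors import (
    BoundaryDiagnostic,
    LtcmsmError,
    NumericRangeError,
    StructureError,
)
from .likelihood import _compiled, dataset_log_likelihood

__all__ = ["Estimate", "FittedModel", "fit", "hazard_ratios", "delta_method_ci"]

_Z95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass(frozen=True)
class Estimate:
    """A point estimate with a 95% confidence interval."""

    value: float
    lower: float | None = None
    upper: float | None = None
    se: float | None = None

    def __iter__(self):
        return iter((self.value, self.lower, self.upper))


@dataclass
class FittedModel:
    """A fitted intensity model: point estimates, covariance and metadata.

    ``theta`` stacks the free log-baseline intensities (in transition order,
    skipping frozen transitions) followed by each transition's coefficients
    in formula order. ``covariance`` is on the same scale and may be ``None``
    when the observed information was singular.
    """

    params: IntensityParameters
    theta: np.ndarray
    covariance: np.ndarray | None
    loglik: float
    converged: bool
    n_iter: int
    message: str
    n_subjects: int
    n_observations: int
    free_baselines: tuple[int, ...]
    frozen: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def structure(self) -> TransitionStructure:
        return self.params.structure

    # -- parameter bookkeeping -------------------------------------------

    def _baseline_position(self, transition) -> int:
        st = self.structure
        k = st.transition_index(*st.resolve_transition(transition))
        if k not in self.free_baselines:
            raise StructureError(
                f"transition {transition!r} was frozen during fitting"
            )
        return self.free_baselines.index(k)

    def _beta_position(self, transition, covariate: str) -> int:
        st = self.structure
        k = st.transition_index(*st.resolve_transition(transition))
        pos = len(self.free_baselines)
        for kk, cmap in enumerate(self.params.coefficients):
            for name in cmap:
                if kk == k and name == covariate:
                    return pos
                pos += 1
        raise StructureError(
            f"covariate {covariate!r} is not in the formula of transition "
            f"{transition!r}"
        )

    def se_theta(self) -> np.ndarray | None:
        if self.covariance is None:
            return None
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    def log_baseline_estimate(self, transition) -> Estimate:
        """Log baseline intensity of a transition, with its normal CI."""
        pos = self._baseline_position(transition)
        v = float(self.theta[pos])
        se = self.se_theta()
        if se is None:
            return Estimate(v)
        s = float(se[pos])
        return Estimate(v, v - _Z95 * s, v + _Z95 * s, s)

    def hazard_ratio(self, transition, covariate: str) -> Estimate:
        return hazard_ratios(self, transition, covariate)

    # -- persistence ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "structure": self.structure.to_config(),
            "log_baseline": list(self.params.log_baseline),
            "coefficients": [dict(c) for c in self.params.coefficients],
            "theta": np.asarray(self.theta).tolist(),
            "covariance": (
                None
                if self.covariance is None
                else np.asarray(self.covariance).tolist()
            ),
            "loglik": self.loglik,
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "message": self.message,
            "n_subjects": int(self.n_subjects),
            "n_observations": int(self.n_observations),
            "free_baselines": list(self.free_baselines),
            "frozen": {f"{i}>{j}": v for (i, j), v in self.frozen.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FittedModel":
        st = TransitionStructure.from_config(d["structure"])
        params = IntensityParameters(st, d["log_baseline"], d["coefficients"])
        cov = d.get("covariance")
        frozen = {}
        for key, v in (d.get("frozen") or {}).items():
            i, j = (int(x) for x in key.split(">"))
            frozen[(i, j)] = float(v)
        return cls(
            params=params,
            theta=np.asarray(d["theta"], dtype=float),
            covariance=None if cov is None else np.asarray(cov, dtype=float),
            loglik=float(d["loglik"]),
            converged=bool(d["converged"]),
            n_iter=int(d["n_iter"]),
            message=str(d.get("message", "")),
            n_subjects=int(d["n_subjects"]),
            n_observations=int(d["n_observations"]),
            free_baselines=tuple(d["free_baselines"]),
            frozen=frozen,
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "FittedModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------


def _resolve_formulas(
    structure: TransitionStructure, formulas
) -> list[tuple[str, ...]]:
    per = [() for _ in structure.transitions]
    if formulas is None:
        return per
    if isinstance(formulas, Mapping):
        for key, names in formulas.items():
            i, j = structure.resolve_transition(key)
            per[structure.transition_index(i, j)] = tuple(names)
    else:  # one covariate list shared by every transition
        per = [tuple(formulas) for _ in structure.transitions]
    return per


def _pack(params: IntensityParameters, free: Sequence[int]) -> np.ndarray:
    parts = [np.asarray(params.log_baseline)[list(free)]]
    for cmap in params.coefficients:
        parts.append(np.fromiter(cmap.values(), dtype=float, count=len(cmap)))
    return np.concatenate(parts) if parts else np.zeros(0)


def _unpack(
    theta: np.ndarray, template: IntensityParameters, free: Sequence[int]
) -> IntensityParameters:
    lb = np.asarray(template.log_baseline, dtype=float).copy()
    lb[list(free)] = theta[: len(free)]
    pos = len(free)
    coefs = []
    for cmap in template.coefficients:
        new = {}
        for name in cmap:
            new[name] = float(theta[pos])
            pos += 1
        coefs.append(new)
    return IntensityParameters(template.structure, lb, coefs)


def _crude_initial(
    data: PanelDataset, structure: TransitionStructure, frozen_idx: set[int]
) -> np.ndarray:
    """Occurrence/exposure starting rates; diagnoses unobserved transitions."""
    comp = _compiled(data)
    lb = np.zeros(structure.n_transitions)
    never = []
    for k, (i, j) in enumerate(structure.transitions):
        if k in frozen_idx:
            continue
        events = comp.event_counts[k]
        if events == 0:
            never.append(structure.transition_label(i, j))
            continue
        py = max(comp.person_years[i], 1e-12)
        lb[k] = np.log(events / py)
    if never:
        raise BoundaryDiagnostic(
            "structurally allowed transitions never observed in the data: "
            + ", ".join(never)
            + "; the likelihood maximum lies on the boundary. Freeze these "
            "transitions (fit(..., frozen={...})) or revise the structure."
        )
    return lb


def _numerical_hessian(f: Callable, x: np.ndarray) -> np.ndarray:
    """Central finite-difference Hessian, relative steps."""
    p = x.size
    h = 1e-4 * (1.0 + np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def fit(
    data: PanelDataset,
    formulas=None,
    init: IntensityParameters | None = None,
    *,
    frozen: Mapping | None = None,
    gtol: float = 1e-5,
    maxiter: int = 500,
) -> FittedModel:
    """Fit the intensity model to a panel dataset by maximum likelihood.

    Parameters
    ----------
    data
        Validated :class:`~ltcmsm.data.PanelDataset`.
    formulas
        Per-transition covariate lists: a mapping from transition (labels or
        1-based pairs) to covariate names, or a single covariate list shared
        by every transition, or ``None`` for the intercept-only model.
    init
        Optional starting values; defaults to crude occurrence/exposure
        rates with zero coefficients.
    frozen
        Transitions whose baseline rate (events/year) is held fixed instead
        of estimated — required for structurally allowed transitions that
        the data never exhibit.

    Raises
    ------
    BoundaryDiagnostic
        If an allowed, non-frozen transition is never observed.
    """
    structure = data.structure
    per_formulas = _resolve_formulas(structure, formulas)
    frozen_rates: dict[tuple[int, int], float] = {}
    for key, rate in (frozen or {}).items():
        ij = structure.resolve_transition(key)
        frozen_rates[ij] = float(rate)
    frozen_idx = {structure.transition_index(i, j) for i, j in frozen_rates}
    free = tuple(k for k in range(structure.n_transitions) if k not in frozen_idx)

    if init is None:
        lb = _crude_initial(data, structure, frozen_idx)
        coefs = [{name: 0.0 for name in names} for names in per_formulas]
        template = IntensityParameters(structure, lb, coefs)
    else:
        template = IntensityParameters(
            structure,
            init.log_baseline,
            [{name: c.get(name, 0.0) for name in names}
             for names, c in zip(per_formulas, init.coefficients)],
        )
    if frozen_rates:
        lb = np.asarray(template.log_baseline, dtype=float).copy()
        for (i, j), rate in frozen_rates.items():
            lb[structure.transition_index(i, j)] = np.log(rate)
        template = IntensityParameters(structure, lb, template.coefficients)

    theta0 = _pack(template, free)

    # scale the objective to a per-interval magnitude so the gradient-norm
    # tolerance is independent of cohort size
    scale = max(1.0, float(_compiled(data).dt.size))

    def nll(theta: np.ndarray) -> float:
        try:
            ll = dataset_log_likelihood(data, _unpack(theta, template, free))
        except NumericRangeError:
            return 1e10
        if not np.isfinite(ll):
            return 1e10
        return -ll / scale

    if nll(theta0) >= 1e10:
        raise LtcmsmError("log-likelihood is not finite at the starting values")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = scipy.optimize.minimize(
            nll,
            theta0,
            method="BFGS",
            options={"gtol": gtol, "maxiter": maxiter},
        )
    theta_hat = res.x
    # "precision loss" at a stationary point (e.g. when the crude start is
    # already the maximum) still counts as converged if the gradient is small
    grad_ok = res.jac is not None and np.max(np.abs(res.jac)) <= 10 * gtol
    converged = bool(res.success or grad_ok)
    message = res.message

    cov = None
    if theta_hat.size:
        H = _numerical_hessian(nll, theta_hat) * scale
        H = 0.5 * (H + H.T)
        try:
            eigmin = float(np.linalg.eigvalsh(H).min())
            if eigmin <= 0:
                raise np.linalg.LinAlgError("information not positive definite")
            cov = np.linalg.inv(H)
            cov = 0.5 * (cov + cov.T)
        except np.linalg.LinAlgError as exc:
            warnings.warn(
                f"observed information is singular ({exc}); covariance "
                "unavailable, point estimates retained",
                RuntimeWarning,
                stacklevel=2,
            )
            message += " [covariance unavailable: singular information]"

    if not converged:
        warnings.warn(
            f"optimizer did not converge: {message}", RuntimeWarning, stacklevel=2
        )

    return FittedModel(
        params=_unpack(theta_hat, template, free),
        theta=theta_hat,
        covariance=cov,
        loglik=-float(res.fun) * scale,
        converged=converged,
        n_iter=int(res.nit),
        message=str(message),
        n_subjects=data.n_subjects,
        n_observations=data.n_observations,
        free_baselines=free,
        frozen=frozen_rates,
    )


def hazard_ratios(fit: FittedModel, transition, covariate: str) -> Estimate:
    """Hazard ratio exp(beta) of a covariate on a transition, with the
    normal-theory 95% CI exp(beta +- 1.96 SE)."""
    pos = fit._beta_position(transition, covariate)
    b = float(fit.theta[pos])
    se = fit.se_theta()
    if se is None:
        return Estimate(float(np.exp(b)))
    s = float(se[pos])
    return Estimate(
        float(np.exp(b)),
        float(np.exp(b - _Z95 * s)),
        float(np.exp(b + _Z95 * s)),
        s,
    )


def delta_method_ci(
    fit: FittedModel,
    g: Callable[[np.ndarray], float],
    *,
    transform: str | None = None,
) -> Estimate:
    """Delta-method 95% CI for a scalar function g of the parameter vector.

    ``transform="log"`` (for positive quantities) or ``"logit"`` (for
    probabilities) propagates the variance on the transformed scale and
    back-transforms the interval, keeping it inside the admissible range.
    The gradient is taken by central finite differences.
    """
    if fit.covariance is None:
        raise LtcmsmError("covariance unavailable; cannot form a delta-method CI")
    theta = np.asarray(fit.theta, dtype=float)
    value = float(g(theta))

    if transform == "log":
        if value <= 0:
            raise NumericRangeError("log transform needs a positive estimate")
        h = lambda th: float(np.log(g(th)))
        back = np.exp
        hv = np.log(value)
    elif transform == "logit":
        if not 0 < value < 1:
            raise NumericRangeError("logit transform needs an estimate in (0,1)")
        h = lambda th: float(np.log(g(th) / (1.0 - g(th))))
        back = lambda x: 1.0 / (1.0 + np.exp(-x))
        hv = float(np.log(value / (1 - value)))
    elif transform is None:
        h, back, hv = (lambda th: float(g(th))), (lambda x: x), value
    else:
        raise ValueError(f"unknown transform {transform!r}")

    p = theta.size
    step = 1e-5 * (1.0 + np.abs(theta))
    grad = np.empty(p)
    for i in range(p):
        e = np.zeros(p)
        e[i] = step[i]
        grad[i] = (h(theta + e) - h(theta - e)) / (2 * step[i])
    if not np.all(np.isfinite(grad)):
        raise NumericRangeError("non-finite gradient in delta method")
    var = float(grad @ fit.covariance @ grad)
    se_h = float(np.sqrt(max(var, 0.0)))
    lo = float(back(hv - _Z95 * se_h))
    hi = float(back(hv + _Z95 * se_h))
    # SE reported on the original scale via the chain rule
    if transform == "log":
        se = se_h * value
    elif transform == "logit":
        se = se_h * value * (1 - value)
    else:
        se = se_h
    return Estimate(value, lo, hi, se)
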