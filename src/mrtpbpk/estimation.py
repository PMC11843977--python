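"""Naive-pooled maximum-likelihood estimation of MRT parameters.

All observations (one animal per tissue per time point in the destructive
design) are pooled into a single Gaussian likelihood with the combined
residual error model

    SD(t) = delta_intercept + delta_slope * Y(t),

where Y(t) is the model-predicted concentration at the record's tissue and
time.  Optimisation runs in log-parameter space under box bounds
(L-BFGS-B); standard errors come from the inverse observed information
(finite-difference Hessian of the negative log-likelihood), with the delta
method mapping log-space variances back to the natural scale.  Staged fits
(estimate a subset, fix it, then estimate the rest) are supported, mirroring
how barrier parameters are usually fixed before luminal flows.

No inter-animal random effects are modelled; with one measurement per animal
the naive-pooled and population likelihoods coincide up to the residual
error decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model import ModelOptions, PBPKModel, build_model
from .parameters import GlobalKinetics, MrtParameters
from .physiology import MRT_ORGANS, SpeciesPhysiology
from .simulate import DoseEvent, SolverConfig, simulate

__all__ = ["ObservedDataset", "ErrorModel", "FitSpec", "FitResult",
           "negative_log_likelihood", "fit", "cv_percent"]

_LOG_2PI = float(np.log(2.0 * np.pi))
_PENALTY = 1e12

#: parameters whose identifiability is known to be poor in this design
POORLY_IDENTIFIED = ("q_retetestis",)


@dataclass
class ObservedDataset:
    """Tidy records {tissue, time_h, conc_nM, replicate} plus dose metadata."""

    records: pd.DataFrame
    dose: DoseEvent = field(default_factory=DoseEvent)
    perfused: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        req = {"tissue", "time_h", "conc_nM"}
        if not req.issubset(self.records.columns):
            raise ValueError(f"dataset needs columns {sorted(req)}")
        if len(self.records) == 0:
            raise ValueError("dataset is empty")
        if (self.records["conc_nM"] < 0).any():
            raise ValueError("concentrations must be non-negative")
        if (self.records["time_h"] < 0).any():
            raise ValueError("times must be non-negative")

    @property
    def n(self) -> int:
        return len(self.records)

    def tissues(self) -> list[str]:
        return sorted(self.records["tissue"].unique())


@dataclass(frozen=True)
class ErrorModel:
    """Combined additive + proportional residual SD."""

    delta_intercept: float = 0.1   # nmol/L
    delta_slope: float = 0.2       # dimensionless

    def __post_init__(self) -> None:
        if self.delta_intercept < 0 or self.delta_slope < 0:
            raise ValueError("error-model parameters must be non-negative")
        if self.delta_intercept == 0 and self.delta_slope == 0:
            raise ValueError("error model is degenerate (both deltas zero)")

    def sd(self, y: float | np.ndarray) -> float | np.ndarray:
        return self.delta_intercept + self.delta_slope * np.maximum(y, 0.0)


@dataclass
class FitSpec:
    """What to estimate and from where to start.

    ``names`` must be fields of :class:`MrtParameters`.  Bounds default to
    a factor of 100 around the initial value on each side; fitting is done
    on log-parameters. ``stages`` optionally partitions ``names`` into
    sequential stages (earlier stages are fixed at their estimates while
    later stages are fitted).
    """

    names: tuple[str, ...]
    initials: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    stages: tuple[tuple[str, ...], ...] | None = None

    def __post_init__(self) -> None:
        valid = {f.name for f in fields(MrtParameters)}
        bad = [n for n in self.names if n not in valid]
        if bad:
            raise ValueError(f"unknown parameter(s): {bad}")
        if self.stages is not None:
            flat = [n for st in self.stages for n in st]
            if sorted(flat) != sorted(self.names):
                raise ValueError("stages must partition the fitted names")
        for n, (lo, hi) in self.bounds.items():
            if not (0 < lo < hi):
                raise ValueError(f"bounds for {n} must satisfy 0 < lo < hi")

    def initial(self, name: str, base: MrtParameters) -> float:
        return self.initials.get(name, getattr(base, name))

    def bound(self, name: str, base: MrtParameters) -> tuple[float, float]:
        if name in self.bounds:
            return self.bounds[name]
        p0 = self.initial(name, base)
        return (p0 / 100.0, p0 * 100.0)


@dataclass
class FitResult:
    estimates: dict[str, float]
    se: dict[str, float]
    cv_percent: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    nll: float
    nll_initial: float
    converged: bool
    n_obs: int
    message: str = ""
    warnings: list[str] = field(default_factory=list)
    predictions: pd.DataFrame | None = None


class _Objective:
    """Cached likelihood evaluation: rebuilds the model per parameter set and
    predicts only at the observation times (exact linear propagation)."""

    def __init__(self, dataset: ObservedDataset, em: ErrorModel,
                 sp: SpeciesPhysiology, gk: GlobalKinetics,
                 base: MrtParameters, options: ModelOptions | None,
                 solver: SolverConfig):
        self.dataset = dataset
        self.em = em
        self.sp, self.gk, self.base = sp, gk, base
        self.options = options
        self.solver = solver
        rec = dataset.records
        self.obs = rec["conc_nM"].to_numpy(dtype=float)
        self.grid = np.unique(np.concatenate(
            [[0.0, dataset.dose.time], rec["time_h"].to_numpy(dtype=float)]))
        self.t_pos = {t: i for i, t in enumerate(self.grid)}
        self.row_time = [self.t_pos[t] for t in rec["time_h"]]
        self.row_tissue = rec["tissue"].to_list()

    def predict(self, mrt: MrtParameters) -> np.ndarray:
        model = build_model(self.sp, self.gk, mrt, self.options)
        res = simulate(model, self.dataset.dose, self.grid, solver=self.solver)
        by_tissue: dict[str, np.ndarray] = {}
        for tissue in set(self.row_tissue):
            by_tissue[tissue] = (
                res.plasma_concentration() if tissue == "plasma"
                else res.tissue_concentration(tissue,
                                              perfused=self.dataset.perfused))
        return np.array([by_tissue[ts][it]
                         for ts, it in zip(self.row_tissue, self.row_time)])

    def nll(self, mrt: MrtParameters) -> float:
        try:
            pred = self.predict(mrt)
        except Exception:
            return _PENALTY
        if not np.all(np.isfinite(pred)):
            return _PENALTY
        sd = self.em.sd(pred)
        if np.any(sd <= 0):
            return _PENALTY
        z = (self.obs - pred) / sd
        return float(np.sum(0.5 * _LOG_2PI + np.log(sd) + 0.5 * z * z))


def negative_log_likelihood(params: dict[str, float], dataset: ObservedDataset,
                            em: ErrorModel, sp: SpeciesPhysiology,
                            gk: GlobalKinetics,
                            base: MrtParameters | None = None,
                            options: ModelOptions | None = None,
                            solver: SolverConfig | None = None) -> float:
    """Gaussian NLL of the dataset at the given MRT parameter values.

    Non-simulable or non-finite parameter sets return a large penalized
    objective rather than raising.
    """
    base = base or MrtParameters.default()
    obj = _Objective(dataset, em, sp, gk, base, options,
                     solver or SolverConfig(method="expm"))
    return obj.nll(base.with_updates(**params))


def _fd_hessian(f, x0: np.ndarray, rel_step: float = 1e-3) -> np.ndarray:
    """Central finite-difference Hessian (x0 is in log-parameter space)."""
    n = len(x0)
    h = np.full(n, rel_step)
    H = np.empty((n, n))
    f0 = f(x0)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        fpp = f(x0 + ei); fmm = f(x0 - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = h[j]
            fab = f(x0 + ei + ej); fa_b = f(x0 + ei - ej)
            f_ab = f(x0 - ei + ej); f_a_b = f(x0 - ei - ej)
            H[i, j] = H[j, i] = (fab - fa_b - f_ab + f_a_b) / (4 * h[i] * h[j])
    return H


def fit(dataset: ObservedDataset, spec: FitSpec, em: ErrorModel,
        sp: SpeciesPhysiology, gk: GlobalKinetics,
        base: MrtParameters | None = None,
        options: ModelOptions | None = None,
        solver: SolverConfig | None = None,
        maxiter: int = 500) -> FitResult:
    """Bounded ML fit in log-parameter space, with SEs from the observed
    information.  Supports staged estimation via ``spec.stages``."""
    base = base or MrtParameters.default()
    obj = _Objective(dataset, em, sp, gk, base, options,
                     solver or SolverConfig(method="expm"))

    warnings_ = [f"parameter {n!r} is expected to be poorly identified by "
                 "this sampling design" for n in spec.names
                 if n in POORLY_IDENTIFIED]

    current = base.with_updates(**{n: spec.initial(n, base) for n in spec.names})
    nll_initial = obj.nll(current)
    stages = spec.stages or (spec.names,)
    converged = True
    message = ""
    for stage_names in stages:
        names = tuple(stage_names)
        x0 = np.log([getattr(current, n) for n in names])
        lb = np.log([spec.bound(n, base)[0] for n in names])
        ub = np.log([spec.bound(n, base)[1] for n in names])

        def f(x, names=names):
            p = {n: float(np.exp(v)) for n, v in zip(names, x)}
            return obj.nll(current.with_updates(**p))

        res = minimize(f, x0, method="L-BFGS-B",
                       bounds=list(zip(lb, ub)),
                       options={"maxiter": maxiter, "ftol": 1e-12,
                                "gtol": 1e-8})
        converged = converged and bool(res.success)
        message = str(res.message)
        current = current.with_updates(
            **{n: float(np.exp(v)) for n, v in zip(names, res.x)})

    # observed information over all fitted parameters jointly
    names = tuple(spec.names)
    x_hat = np.log([getattr(current, n) for n in names])

    def f_all(x):
        p = {n: float(np.exp(v)) for n, v in zip(names, x)}
        return obj.nll(current.with_updates(**p))

    nll_hat = f_all(x_hat)
    H = _fd_hessian(f_all, x_hat)
    se_log = np.full(len(names), np.nan)
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        se_log = np.sqrt(np.where(d > 0, d, np.nan))
        if np.any(d <= 0):
            warnings_.append("observed information is not positive definite; "
                             "some SEs unavailable")
    except np.linalg.LinAlgError:
        warnings_.append("singular observed information; SEs unavailable")

    estimates = {n: float(getattr(current, n)) for n in names}
    se = {n: float(estimates[n] * s) if np.isfinite(s) else float("nan")
          for n, s in zip(names, se_log)}
    ci = {n: (float(estimates[n] * np.exp(-1.959963985 * s)),
              float(estimates[n] * np.exp(1.959963985 * s)))
          if np.isfinite(s) else (float("nan"), float("nan"))
          for n, s in zip(names, se_log)}
    cv = {n: (100.0 * se[n] / abs(estimates[n])
              if estimates[n] != 0 and np.isfinite(se[n]) else float("nan"))
          for n in names}

    pred = obj.predict(current)
    pred_frame = dataset.records.copy()
    pred_frame["pred_nM"] = pred

    return FitResult(estimates=estimates, se=se, cv_percent=cv, ci95=ci,
                     nll=float(nll_hat), nll_initial=float(nll_initial),
                     converged=converged, n_obs=dataset.n, message=message,
                     warnings=warnings_, predictions=pred_frame)


def cv_percent(estimate: float, se: float) -> float:
    """Coefficient of variation of an estimate, percent: 100*SE/|estimate|."""
    if estimate == 0:
        return float("nan")
    if se < 0:
        raise ValueError("SE must be non-negative")
    return 100.0 * se / abs(estimate)
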