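"""Integration of the PBPK system and tissue-concentration reconstruction.

Two solution paths are provided.  The default is a stiff ODE solver
(``scipy.integrate.solve_ivp`` with the analytic constant Jacobian, rtol 1e-8
/ atol 1e-10).  Because the system is linear and autonomous, an exact
matrix-exponential propagator (``method="expm"``) is also available; it is
used by the estimation and sensitivity modules, where thousands of solves are
required.  IV bolus doses are applied as instantaneous state jumps at segment
boundaries (event restart, never smoothed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .model import BC, E_B, E_UB, EP_B, EP_UB, IS, LU, MU, RT, VASC, PBPKModel
from .physiology import MRT_ORGANS, MUSCULAR_ORGANS, PLATFORM_ORGANS

__all__ = ["DoseEvent", "SolverConfig", "SimulationResult", "simulate",
           "observed_tissue_concentration", "STUDY_PLASMA_TIMES",
           "STUDY_TISSUE_TIMES"]

#: destructive-sampling schedule of the mouse biodistribution study (hours)
STUDY_PLASMA_TIMES = (5.0 / 60.0, 6.0, 24.0, 96.0, 168.0)
STUDY_TISSUE_TIMES = (6.0, 24.0, 96.0, 168.0)

DEFAULT_MOLECULAR_WEIGHT = 1.5e5  # g/mol, intact IgG


@dataclass(frozen=True)
class DoseEvent:
    """IV bolus into the plasma pool."""

    time: float = 0.0                    # h
    dose_mg_per_kg: float = 10.0
    body_weight: float = 0.028           # kg
    molecular_weight: float = DEFAULT_MOLECULAR_WEIGHT

    def __post_init__(self) -> None:
        if self.dose_mg_per_kg < 0:
            raise ValueError("dose must be non-negative")
        if self.body_weight <= 0 or self.molecular_weight <= 0:
            raise ValueError("body weight and molecular weight must be positive")

    @property
    def amount_nmol(self) -> float:
        # mg -> nmol: mg/kg * kg gives mg; mg/(g/mol) = mmol; *1e6 -> nmol
        return self.dose_mg_per_kg * self.body_weight / self.molecular_weight * 1e6


@dataclass(frozen=True)
class SolverConfig:
    method: str = "bdf"     # "bdf" | "lsoda" | "expm"
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        if self.method not in ("bdf", "lsoda", "expm"):
            raise ValueError(f"unknown solver method {self.method!r}")


class IntegrationError(RuntimeError):
    pass


@dataclass
class SimulationResult:
    """Trajectory on the requested time grid (amounts, nmol)."""

    model: PBPKModel
    time: np.ndarray            # (nt,), h, strictly increasing
    amounts: np.ndarray         # (nt, n_states)
    doses: tuple[DoseEvent, ...] = field(default_factory=tuple)

    def concentration(self, organ: str, comp: str) -> np.ndarray:
        """Sub-compartment concentration trace, nmol/L."""
        i = self.model.idx(organ, comp)
        v = self.model.volumes[i]
        if not v > 0:
            raise ValueError(f"{organ}:{comp} has no positive volume")
        return self.amounts[:, i] / v

    def plasma_concentration(self) -> np.ndarray:
        return self.amounts[:, self.model.i_plasma] / self.model.species.plasma_volume

    def tissue_concentration(self, organ: str,
                             perfused: bool | None = None) -> np.ndarray:
        if perfused is None:
            perfused = self.model.options.perfused
        return observed_tissue_concentration(self, organ, perfused=perfused)

    def total_amount(self, include_sinks: bool = True) -> np.ndarray:
        x = self.amounts
        if include_sinks:
            return x.sum(axis=1)
        keep = np.ones(x.shape[1], dtype=bool)
        keep[[self.model.i_degraded, self.model.i_excreted]] = False
        return x[:, keep].sum(axis=1)

    def to_frame(self, tissues: tuple[str, ...] | None = None,
                 perfused: bool | None = None) -> pd.DataFrame:
        """Tidy long table: species, tissue, time_h, conc_nM."""
        tissues = tissues if tissues is not None else ("plasma",) + MRT_ORGANS
        rows = []
        for tissue in tissues:
            conc = (self.plasma_concentration() if tissue == "plasma"
                    else self.tissue_concentration(tissue, perfused=perfused))
            rows.append(pd.DataFrame({
                "species": self.model.species.species, "tissue": tissue,
                "time_h": self.time, "conc_nM": conc}))
        return pd.concat(rows, ignore_index=True)


def _propagate_expm(A: np.ndarray, x0: np.ndarray,
                    times: np.ndarray) -> np.ndarray:
    """Exact linear propagation x(t) = expm(A t) x0, reusing per-step kernels."""
    out = np.empty((len(times), len(x0)))
    cache: dict[float, np.ndarray] = {}
    x = x0
    prev = 0.0
    for k, t in enumerate(times):
        dt = t - prev
        if dt > 0:
            P = cache.get(dt)
            if P is None:
                P = expm(A * dt)
                cache[dt] = P
            x = P @ x
        out[k] = x
        prev = t
    return out


def _solve_segment(model: PBPKModel, x0: np.ndarray, t0: float,
                   times: np.ndarray, cfg: SolverConfig) -> np.ndarray:
    if len(times) == 0:
        return np.empty((0, model.n_states))
    if cfg.method == "expm":
        return _propagate_expm(model.A, x0, times - t0)
    method = {"bdf": "BDF", "lsoda": "LSODA"}[cfg.method]
    t_end = float(times[-1])
    if t_end == t0:
        return np.tile(x0, (len(times), 1))
    sol = solve_ivp(model.rhs, (t0, t_end), x0, method=method,
                    t_eval=times, jac=model.jac, rtol=cfg.rtol, atol=cfg.atol)
    if not sol.success:
        last = sol.t[-1] if len(sol.t) else t0
        raise IntegrationError(
            f"solver failed at t={last:.4g} h: {sol.message}")
    return sol.y.T


def simulate(model: PBPKModel, doses: list[DoseEvent] | DoseEvent,
             t_eval: np.ndarray | list[float],
             solver: SolverConfig | None = None) -> SimulationResult:
    """Integrate the model for a dosing schedule.

    ``t_eval`` must be non-decreasing and cover every dose time.  Dose events
    restart the integration with a plasma-amount jump.
    """
    if isinstance(doses, DoseEvent):
        doses = [doses]
    cfg = solver or SolverConfig()
    times = np.asarray(t_eval, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("t_eval must be a non-empty 1-D grid")
    if np.any(np.diff(times) < 0):
        raise ValueError("t_eval must be non-decreasing")
    dose_times = [d.time for d in doses]
    if doses and (min(dose_times) < times[0] or max(dose_times) > times[-1]):
        raise ValueError("time grid must cover all dose times")

    events = sorted(doses, key=lambda d: d.time)
    x = np.zeros(model.n_states)
    out = np.empty((len(times), model.n_states))
    t_cursor = float(times[0])
    pending = list(events)
    while pending and pending[0].time <= t_cursor:
        x[model.i_plasma] += pending.pop(0).amount_nmol

    filled = np.zeros(len(times), dtype=bool)
    boundaries = sorted({d.time for d in pending}) + [float(times[-1])]
    for t_edge in boundaries:
        mask = ~filled & (times <= t_edge)
        seg_times = times[mask]
        if len(seg_times):
            out[mask] = _solve_segment(model, x, t_cursor, seg_times, cfg)
            x = out[mask][-1].copy()
            t_cursor = float(seg_times[-1])
            filled |= mask
        if t_edge > t_cursor:  # advance to the dose instant itself
            x = _solve_segment(model, x, t_cursor,
                               np.array([t_edge]), cfg)[0]
            t_cursor = t_edge
        while pending and pending[0].time <= t_edge:
            x[model.i_plasma] += pending.pop(0).amount_nmol
    out[~filled] = x  # grid points coinciding with the final edge

    neg = out.min()
    tol = 1e3 * cfg.atol + 1e-12
    if neg < -tol and cfg.method != "expm":
        raise IntegrationError(f"state went negative beyond tolerance ({neg:.3e})")
    return SimulationResult(model=model, time=times, amounts=out,
                            doses=tuple(events))


def observed_tissue_concentration(result: SimulationResult, organ: str,
                                  perfused: bool = True) -> np.ndarray:
    """Whole-tissue concentration as the volume-weighted mean of its
    sub-compartments (nmol/L).

    Testis and epididymis aggregate vascular, blood-cell, endosomal
    (bound + unbound), interstitial, epithelial (bound + unbound) and luminal
    content; vas deferens, seminal vesicle and prostate additionally include
    the muscular layer.  Platform organs aggregate vascular, blood-cell,
    endosomal and interstitial spaces.  With ``perfused=True`` the vascular
    and blood-cell terms are zeroed (residual blood removed at necropsy) while
    the denominator keeps the full anatomical volume.
    """
    model = result.model
    if organ == "plasma":
        return result.plasma_concentration()
    if organ in PLATFORM_ORGANS:
        comps = [VASC, BC, E_UB, E_B, IS]
    elif organ in MRT_ORGANS:
        comps = [VASC, BC, E_UB, E_B, IS, EP_UB, EP_B, LU]
        if organ in MUSCULAR_ORGANS and (organ, MU) in model.index:
            comps.insert(-1, MU)
    else:
        raise KeyError(f"unknown organ {organ!r}")

    amount = np.zeros(len(result.time))
    v_total = 0.0
    for comp in comps:
        i = model.idx(organ, comp)
        if comp not in (E_B, EP_B):
            # bound and unbound states share one endosomal volume: count once
            v_total += model.volumes[i]
        if perfused and comp in (VASC, BC):
            continue
        amount = amount + result.amounts[:, i]
    if not v_total > 0:
        raise ValueError(f"organ {organ!r} has zero total volume")
    return amount / v_total


def study_result_frame(result: SimulationResult,
                       perfused: bool | None = None) -> pd.DataFrame:
    """Predictions on the study schedule: plasma at 5 min-168 h, MRT tissues
    at 6-168 h."""
    df = result.to_frame(perfused=perfused)
    keep_plasma = df["tissue"].eq("plasma") & df["time_h"].isin(STUDY_PLASMA_TIMES)
    keep_tissue = ~df["tissue"].eq("plasma") & df["time_h"].isin(STUDY_TISSUE_TIMES)
    return df[keep_plasma | keep_tissue].reset_index(drop=True)
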