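"""Synthetic observed-data generation with the study's sampling design.

The generator emulates the destructive-sampling biodistribution study: a
single 10 mg/kg IV bolus, plasma sampled at 5 min, 6, 24, 96 and 168 h, and
the five reproductive tissues sampled (after perfusion) at 6, 24, 96 and
168 h, three animals per time point.  Noise follows the combined residual
error model SD(t) = delta_intercept + delta_slope * Y(t); generated
concentrations are truncated at zero (which introduces a slight positive
bias only when the noise is large relative to the signal).

The fitted residual-error magnitudes were never reported for the original
study; the defaults here (delta_slope = 0.2, delta_intercept = 0.1 nM) are
package test settings, not literature values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import ErrorModel, ObservedDataset
from .model import PBPKModel
from .physiology import MRT_ORGANS
from .simulate import (DoseEvent, SolverConfig, STUDY_PLASMA_TIMES,
                       STUDY_TISSUE_TIMES, simulate)

__all__ = ["StudyDesign", "generate_dataset"]


@dataclass(frozen=True)
class StudyDesign:
    """Sampling schedule and dosing of one synthetic study."""

    plasma_times: tuple[float, ...] = STUDY_PLASMA_TIMES
    tissue_times: tuple[float, ...] = STUDY_TISSUE_TIMES
    tissues: tuple[str, ...] = MRT_ORGANS
    replicates: int = 3
    dose: DoseEvent = field(default_factory=DoseEvent)
    perfused: bool = True

    def __post_init__(self) -> None:
        for ts in (self.plasma_times, self.tissue_times):
            a = np.asarray(ts)
            if np.any(a <= 0) or np.any(np.diff(a) <= 0):
                raise ValueError("sampling times must be positive and increasing")
        if self.replicates < 1:
            raise ValueError("need at least one replicate per time point")


def predictions(model: PBPKModel, design: StudyDesign,
                solver: SolverConfig | None = None) -> pd.DataFrame:
    """Noise-free model output on the design schedule (tissue, time_h, conc_nM)."""
    grid = np.unique(np.concatenate([[0.0], design.plasma_times,
                                     design.tissue_times]))
    res = simulate(model, design.dose, grid,
                   solver=solver or SolverConfig(method="expm"))
    rows = []
    for t in design.plasma_times:
        i = int(np.nonzero(grid == t)[0][0])
        rows.append(("plasma", t, float(res.plasma_concentration()[i])))
    for tissue in design.tissues:
        conc = res.tissue_concentration(tissue, perfused=design.perfused)
        for t in design.tissue_times:
            i = int(np.nonzero(grid == t)[0][0])
            rows.append((tissue, t, float(conc[i])))
    return pd.DataFrame(rows, columns=["tissue", "time_h", "conc_nM"])


def generate_dataset(model: PBPKModel, design: StudyDesign, em: ErrorModel,
                     seed: int, solver: SolverConfig | None = None,
                     ) -> ObservedDataset:
    """Draw one synthetic study; identical seeds give identical datasets."""
    pred = predictions(model, design, solver=solver)
    rng = np.random.default_rng(seed)
    rows = []
    for row in pred.itertuples(index=False):
        sd = em.sd(row.conc_nM)
        eps = rng.normal(0.0, sd, size=design.replicates)
        for rep, e in enumerate(eps, start=1):
            rows.append((row.tissue, row.time_h,
                         max(0.0, row.conc_nM + float(e)), rep))
    frame = pd.DataFrame(rows, columns=["tissue", "time_h", "conc_nM",
                                        "replicate"])
    return ObservedDataset(records=frame, dose=design.dose,
                           perfused=design.perfused,
                           meta={"seed": seed, "delta_intercept": em.delta_intercept,
                                 "delta_slope": em.delta_slope})
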