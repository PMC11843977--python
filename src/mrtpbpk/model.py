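"""Whole-body antibody PBPK system assembly.

The model is a linear, time-invariant compartmental ODE system in antibody
*amounts* (nmol).  Organs are wired in the usual whole-body arrangement: the
plasma pool feeds the lung, the lung feeds every organ in parallel, splanchnic
organs (spleen, pancreas, intestines) drain through the liver, venous outflows
return to plasma, and all interstitial lymph collects in a lymph-node pool
that empties into plasma.  Each organ has vascular plasma / blood-cell /
endosomal (FcRn-bound and unbound) / interstitial spaces; the five
male-reproductive-tract (MRT) organs additionally carry an epithelial-barrier
endosome, a luminal space, a muscular transit layer (vas deferens, seminal
vesicle, prostate) and, for the testis, a rete-testis compartment.  Seminal
fluid links the MRT lumens in a feed-forward chain ending in an excretion
sink at the prostate.

Because free FcRn is treated as a constant concentration, the entire system
is linear: the state derivative is ``dx/dt = A x`` for a constant matrix
``A``.  The matrix is assembled exclusively through conservative ``clearance``
(concentration-driven) and ``rate`` (amount-driven) transfer primitives, so
every efflux term appears as an influx somewhere else (or in an explicit sink
state), and global mass balance holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import GlobalKinetics, MrtParameters
from .physiology import (
    LUMINAL_CHAIN,
    MRT_ORGANS,
    MUSCULAR_ORGANS,
    PLATFORM_ORGANS,
    SPLANCHNIC_ORGANS,
    SpeciesPhysiology,
)

__all__ = ["ModelOptions", "PBPKModel", "build_model", "mass_balance",
           "MassBalanceReport"]

# sub-compartment keys
VASC, BC, E_UB, E_B, IS = "vascular", "blood_cell", "endo_unbound", "endo_bound", "interstitial"
EP_UB, EP_B, MU, LU, RT = "epi_unbound", "epi_bound", "muscular", "luminal", "rete_testis"


@dataclass
class ModelOptions:
    """Structural switches.

    ``muscular_transit``: route interstitial <-> epithelial traffic of the
    vas deferens / seminal vesicle / prostate through a well-mixed muscular
    compartment (False collapses it to a pass-through, as in testis and
    epididymis).
    ``perfused``: default reporting mode for reconstructed tissue
    concentrations (vascular and blood-cell content excluded, emulating
    perfusion at necropsy).
    """

    muscular_transit: bool = True
    perfused: bool = True


@dataclass
class PBPKModel:
    """Assembled system: constant matrix ``A``, state index, volumes."""

    species: SpeciesPhysiology
    kinetics: GlobalKinetics
    mrt: MrtParameters
    options: ModelOptions
    A: np.ndarray
    index: dict[tuple[str, str], int]
    volumes: np.ndarray          # state volume (L); sinks/amount states -> nan
    state_names: list[str]
    i_plasma: int
    i_bc_pool: int
    i_lymph_node: int
    i_degraded: int
    i_excreted: int

    @property
    def n_states(self) -> int:
        return self.A.shape[0]

    def idx(self, organ: str, comp: str) -> int:
        try:
            return self.index[(organ, comp)]
        except KeyError:
            raise KeyError(f"no state for {organ!r}/{comp!r}") from None

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        """State derivative contract for ODE solvers (autonomous linear)."""
        return self.A @ x

    def jac(self, t: float, x: np.ndarray) -> np.ndarray:
        return self.A

    def organ_states(self, organ: str) -> dict[str, int]:
        return {comp: i for (org, comp), i in self.index.items() if org == organ}

    def specification(self) -> dict:
        """Regenerable structured dump of every compartment and flux."""
        comps = [{"state": name, "index": i,
                  "volume_L": None if np.isnan(self.volumes[i]) else float(self.volumes[i])}
                 for i, name in enumerate(self.state_names)]
        fluxes = []
        for j in range(self.n_states):
            for i in range(self.n_states):
                if i != j and self.A[i, j] != 0.0:
                    fluxes.append({"from": self.state_names[j],
                                   "to": self.state_names[i],
                                   "rate_per_h": float(self.A[i, j])})
        return {"species": self.species.species,
                "body_weight_kg": self.species.body_weight,
                "n_states": self.n_states,
                "compartments": comps, "fluxes": sorted(
                    fluxes, key=lambda d: (d["from"], d["to"]))}


class _Builder:
    def __init__(self, n: int):
        self.A = np.zeros((n, n))

    def clearance(self, src: int, dst: int, q: float, v_src: float) -> None:
        """Concentration-driven transfer: flux = q * x_src / v_src."""
        if q == 0.0:
            return
        if v_src <= 0.0:
            raise ValueError("clearance from a compartment with non-positive "
                             "volume")
        k = q / v_src
        self.A[dst, src] += k
        self.A[src, src] -= k

    def rate(self, src: int, dst: int, k: float) -> None:
        """First-order amount-driven transfer: flux = k * x_src."""
        if k == 0.0:
            return
        self.A[dst, src] += k
        self.A[src, src] -= k


def build_model(sp: SpeciesPhysiology, gk: GlobalKinetics, mrt: MrtParameters,
                options: ModelOptions | None = None) -> PBPKModel:
    """Assemble the state matrix for one species.

    Raises ``PhysiologyError``/``KeyError`` when the topology references an
    organ absent from ``sp``; raises ``ValueError`` on a zero-volume
    compartment that carries flow.
    """
    options = options or ModelOptions()
    sp.require(PLATFORM_ORGANS)
    sp.require(MRT_ORGANS)

    index: dict[tuple[str, str], int] = {}
    volumes: list[float] = []
    names: list[str] = []

    def add(organ: str, comp: str, volume: float) -> int:
        i = len(names)
        index[(organ, comp)] = i
        volumes.append(volume)
        names.append(f"{organ}:{comp}")
        return i

    i_plasma = add("plasma", "pool", sp.plasma_volume)
    i_bc_pool = add("blood_cell", "pool", sp.blood_cell_volume)
    i_ln = add("lymph_node", "pool", sp.lymph_node_volume)

    all_organs = PLATFORM_ORGANS + MRT_ORGANS
    for organ in all_organs:
        o = sp.organ(organ)
        add(organ, VASC, o.vascular_volume)
        add(organ, BC, o.blood_cell_volume)
        add(organ, E_UB, o.endosomal_volume)
        add(organ, E_B, o.endosomal_volume)
        add(organ, IS, o.interstitial_volume)
        if organ in MRT_ORGANS:
            v_ep = (mrt.beb_volume_epididymis if organ == "epididymis"
                    else o.epithelial_volume)
            add(organ, EP_UB, v_ep)
            add(organ, EP_B, v_ep)
            add(organ, LU, o.luminal_volume)
            if organ in MUSCULAR_ORGANS and options.muscular_transit:
                add(organ, MU, o.muscular_volume)
            if organ == "testis":
                add(organ, RT, o.rete_testis_volume)

    i_deg = add("sink", "degraded", float("nan"))
    i_exc = add("sink", "excreted", float("nan"))

    b = _Builder(len(names))
    vol = np.array(volumes)

    lung = sp.organ("lung")
    # plasma pool -> lung vascular (total arterial plasma flow)
    b.clearance(i_plasma, index[("lung", VASC)], lung.plasma_flow,
                sp.plasma_volume)
    b.clearance(i_bc_pool, index[("lung", BC)], lung.blood_cell_flow,
                sp.blood_cell_volume)

    total_lymph = 0.0
    liver_inflow_plq = sp.organ("liver").plasma_flow
    liver_inflow_bcq = sp.organ("liver").blood_cell_flow

    for organ in all_organs:
        o = sp.organ(organ)
        sv = gk.sigma_v(organ)
        i_v, i_bc = index[(organ, VASC)], index[(organ, BC)]
        i_eub, i_eb, i_is = (index[(organ, E_UB)], index[(organ, E_B)],
                             index[(organ, IS)])

        if organ != "lung":
            # arterial inflow from lung; splanchnic venous drains via liver
            b.clearance(index[("lung", VASC)], i_v, o.plasma_flow,
                        lung.vascular_volume)
            b.clearance(index[("lung", BC)], i_bc, o.blood_cell_flow,
                        lung.blood_cell_volume)
            venous_plq = o.plasma_flow - o.lymph_flow
            if organ == "liver":
                pass  # handled after the loop (inflow includes splanchnic)
            elif organ in SPLANCHNIC_ORGANS:
                b.clearance(i_v, index[("liver", VASC)], venous_plq,
                            o.vascular_volume)
                b.clearance(i_bc, index[("liver", BC)], o.blood_cell_flow,
                            o.blood_cell_volume)
                liver_inflow_plq += venous_plq
                liver_inflow_bcq += o.blood_cell_flow
            else:
                b.clearance(i_v, i_plasma, venous_plq, o.vascular_volume)
                b.clearance(i_bc, i_bc_pool, o.blood_cell_flow,
                            o.blood_cell_volume)

        # transcapillary filtrate and endothelial pinocytosis / recycling
        clup_rate = mrt.clup_e_testis if organ == "testis" else gk.clup
        clup = clup_rate * o.endosomal_volume
        b.clearance(i_v, i_is, (1.0 - sv) * o.lymph_flow, o.vascular_volume)
        b.clearance(i_v, i_eub, clup, o.vascular_volume)
        b.clearance(i_is, i_eub, clup, o.interstitial_volume)
        b.clearance(i_eb, i_v, clup * gk.fr, o.endosomal_volume)
        b.clearance(i_eb, i_is, clup * (1.0 - gk.fr), o.endosomal_volume)
        b.rate(i_eub, i_eb, gk.kon_fcrn * gk.fcrn_endothelium)
        b.rate(i_eb, i_eub, gk.koff_fcrn)
        b.rate(i_eub, i_deg, gk.kdeg)

        # interstitial lymph to the lymph node
        b.clearance(i_is, i_ln, (1.0 - gk.sigma_lymph) * o.lymph_flow,
                    o.interstitial_volume)
        total_lymph += o.lymph_flow

        if organ in MRT_ORGANS:
            _wire_mrt(b, index, sp, gk, mrt, options, organ, i_deg)

    # liver venous outflow carries its own arterial inflow plus splanchnic
    # returns, less liver lymph
    liver = sp.organ("liver")
    b.clearance(index[("liver", VASC)], i_plasma,
                liver_inflow_plq - liver.lymph_flow, liver.vascular_volume)
    b.clearance(index[("liver", BC)], i_bc_pool, liver_inflow_bcq,
                liver.blood_cell_volume)

    # lymph node empties into plasma at the total lymph flow
    b.clearance(i_ln, i_plasma, total_lymph, sp.lymph_node_volume)

    # luminal chain outflow of the prostate leaves the body
    b.clearance(index[("prostate_gland", LU)], i_exc, mrt.q_pg,
                sp.organ("prostate_gland").luminal_volume)

    # enforce exact conservation: every column must sum to zero (all sinks
    # are explicit states), absorbing ~1e-11 accumulation error into the
    # diagonal
    n = b.A.shape[0]
    b.A[np.arange(n), np.arange(n)] -= b.A.sum(axis=0)

    return PBPKModel(species=sp, kinetics=gk, mrt=mrt, options=options,
                     A=b.A, index=index, volumes=vol, state_names=names,
                     i_plasma=i_plasma, i_bc_pool=i_bc_pool, i_lymph_node=i_ln,
                     i_degraded=i_deg, i_excreted=i_exc)


def _wire_mrt(b: _Builder, index, sp: SpeciesPhysiology, gk: GlobalKinetics,
              mrt: MrtParameters, options: ModelOptions, organ: str,
              i_deg: int) -> None:
    """Epithelial barrier, muscular transit, lumen and seminal-fluid chain."""
    o = sp.organ(organ)
    i_is = index[(organ, IS)]
    i_epub, i_epb = index[(organ, EP_UB)], index[(organ, EP_B)]
    i_lu = index[(organ, LU)]

    v_ep = (mrt.beb_volume_epididymis if organ == "epididymis"
            else o.epithelial_volume)
    ep_rate = mrt.clup_btb if organ == "testis" else gk.clup
    clup_ep = ep_rate * v_ep
    fcrn_ep = gk.fcrn_btb if organ == "testis" else gk.fcrn_endothelium

    use_muscular = organ in MUSCULAR_ORGANS and options.muscular_transit
    if use_muscular:
        i_mu = index[(organ, MU)]
        # well-mixed transit layer: forward IS->Mu->Ep, recycle Ep->Mu->IS
        b.clearance(i_is, i_mu, clup_ep, o.interstitial_volume)
        b.clearance(i_mu, i_epub, clup_ep, o.muscular_volume)
        b.clearance(i_mu, i_is, clup_ep, o.muscular_volume)
        b.clearance(i_epb, i_mu, clup_ep * gk.fr, v_ep)
    else:
        b.clearance(i_is, i_epub, clup_ep, o.interstitial_volume)
        b.clearance(i_epb, i_is, clup_ep * gk.fr, v_ep)

    b.rate(i_epub, i_epb, gk.kon_fcrn * fcrn_ep)
    b.rate(i_epb, i_epub, gk.koff_fcrn)
    b.rate(i_epub, i_deg, gk.kdeg)

    # transcytosed fraction delivered to the lumen; paracellular convection
    b.clearance(i_epb, i_lu, clup_ep * (1.0 - gk.fr), v_ep)
    b.clearance(i_is, i_lu, (1.0 - gk.sigma_epithelial) * o.lymph_flow,
                o.interstitial_volume)

    # seminal-fluid chain
    if organ == "testis":
        i_rt = index[(organ, RT)]
        # testis lumen -> rete testis by pinocytosis, then convective outflow
        b.clearance(i_lu, i_rt, mrt.clup_btb * o.rete_testis_volume,
                    o.luminal_volume)
        b.clearance(i_rt, index[("epididymis", LU)], mrt.q_retetestis,
                    o.rete_testis_volume)
    else:
        succ = {"epididymis": "vas_deferens", "vas_deferens": "seminal_vesicle",
                "seminal_vesicle": "prostate_gland"}.get(organ)
        q = getattr(mrt, MrtParameters.LUMINAL_FLOW_BY_ORGAN[organ])
        if succ is not None:
            b.clearance(i_lu, index[(succ, LU)], q, o.luminal_volume)
        # prostate lumen outflow (to the excretion sink) is wired by the caller


@dataclass
class MassBalanceReport:
    dose_nmol: float
    remaining_nmol: float
    degraded_nmol: float
    excreted_nmol: float
    imbalance_nmol: float
    relative_imbalance: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"dose={self.dose_nmol:.6g} remaining={self.remaining_nmol:.6g} "
                f"degraded={self.degraded_nmol:.6g} "
                f"excreted={self.excreted_nmol:.6g} "
                f"rel.imbalance={self.relative_imbalance:.3e}")


def mass_balance(result, dose_nmol: float) -> MassBalanceReport:
    """Audit dose = remaining + degraded + excreted at the final time point.

    ``result`` is a :class:`~mrtpbpk.simulate.SimulationResult` whose state
    trajectory includes the cumulative sink states.
    """
    model = result.model
    x_end = result.amounts[-1]
    degraded = float(x_end[model.i_degraded])
    excreted = float(x_end[model.i_excreted])
    body = np.delete(x_end, [model.i_degraded, model.i_excreted])
    remaining = float(body.sum())
    if dose_nmol == 0.0:
        imb = remaining + degraded + excreted
        rel = abs(imb)
        return MassBalanceReport(0.0, remaining, degraded, excreted, imb, rel)
    imb = dose_nmol - remaining - degraded - excreted
    return MassBalanceReport(dose_nmol, remaining, degraded, excreted, imb,
                             abs(imb) / dose_nmol)
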