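"""Species physiological parameters: loading, validation, units, allometry.

The whole-body model couples 15 "platform" organs (heart, kidney, muscle, ...)
with five male-reproductive-tract (MRT) organs -- testis, epididymis, vas
deferens, seminal vesicle, prostate gland -- plus plasma, blood-cell, and
lymph-node pools.  MRT organ physiology ships as packaged CSV tables mirrored
cell-for-cell from the literature; platform physiology ships as a clearly
labelled synthetic stand-in file and is fully overridable.

Conventions
-----------
* Canonical units: hours, litres, nanomoles (tables printed in L/min are
  converted on ingestion).
* Lymph flow, where not tabulated, is derived as plasma flow / 200.
* Endosomal volume, where not tabulated, is 0.5% of total organ volume.
* Hematocrit 0.45 partitions vascular volume/flow into plasma and blood-cell
  parts where only one is tabulated.
* Allometry: flows scale with body weight^0.75, volumes with body weight^1.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "OrganPhysiology",
    "SpeciesPhysiology",
    "UnitContext",
    "Finding",
    "PhysiologyError",
    "load_species_physiology",
    "allometric_scale",
    "validate_physiology",
    "scale_platform_physiology",
    "PLATFORM_ORGANS",
    "MRT_ORGANS",
    "SPLANCHNIC_ORGANS",
    "LUMINAL_CHAIN",
    "DEFAULT_BODY_WEIGHTS",
    "HEMATOCRIT",
]

PLATFORM_ORGANS = (
    "lung", "heart", "kidney", "muscle", "skin", "brain", "adipose", "thymus",
    "liver", "spleen", "pancreas", "small_intestine", "large_intestine",
    "bone", "other",
)
MRT_ORGANS = ("testis", "epididymis", "vas_deferens", "seminal_vesicle",
              "prostate_gland")
#: organs whose venous outflow drains into the liver vascular space
SPLANCHNIC_ORGANS = ("spleen", "pancreas", "small_intestine", "large_intestine")
#: seminal-fluid path: testis lumen -> rete testis -> ... -> prostate -> exit
LUMINAL_CHAIN = ("testis", "epididymis", "vas_deferens", "seminal_vesicle",
                 "prostate_gland")
#: organs with a smooth-muscle transit layer between interstitium and epithelium
MUSCULAR_ORGANS = ("vas_deferens", "seminal_vesicle", "prostate_gland")

DEFAULT_BODY_WEIGHTS = {"mouse": 0.028, "rat": 0.25, "monkey": 6.2, "human": 71.0}
HEMATOCRIT = 0.45
LYMPH_TO_PLASMA_FLOW = 1.0 / 200.0
ENDOSOMAL_FRACTION = 0.005

FLOW_EXPONENT = 0.75
VOLUME_EXPONENT = 1.0


class PhysiologyError(ValueError):
    """Structural or validation problem in a physiology table."""


class UnitContext:
    """Conversion of tabulated units to canonical hours / litres / nanomoles."""

    _FACTORS = {
        # unit -> (dimension, factor to canonical)
        "L/h": ("flow", 1.0),
        "L/min": ("flow", 60.0),
        "mL/min": ("flow", 0.06),
        "mL/h": ("flow", 1e-3),
        "L": ("volume", 1.0),
        "mL": ("volume", 1e-3),
        "uL": ("volume", 1e-6),
        "h": ("time", 1.0),
        "min": ("time", 1.0 / 60.0),
        "nmol": ("amount", 1.0),
        "umol": ("amount", 1e3),
    }

    def to_canonical(self, value: float, unit: str) -> float:
        try:
            return value * self._FACTORS[unit][1]
        except KeyError:
            raise PhysiologyError(f"unrecognized unit {unit!r}") from None

    def from_canonical(self, value: float, unit: str) -> float:
        return value / self._FACTORS[unit][1]


@dataclass
class OrganPhysiology:
    """Flows and sub-compartment volumes of one organ (canonical L/h, L)."""

    organ_id: str
    plasma_flow: float = 0.0
    blood_cell_flow: float = 0.0
    lymph_flow: float = 0.0
    vascular_volume: float = 0.0
    blood_cell_volume: float = 0.0
    endosomal_volume: float = 0.0
    interstitial_volume: float = 0.0
    epithelial_volume: float = 0.0     # MRT organs only
    muscular_volume: float = 0.0       # vas deferens / seminal vesicle / prostate
    luminal_volume: float = 0.0        # MRT organs only
    rete_testis_volume: float = 0.0    # testis only

    def total_volume(self) -> float:
        return (self.vascular_volume + self.blood_cell_volume
                + self.endosomal_volume + self.interstitial_volume
                + self.epithelial_volume + self.muscular_volume
                + self.luminal_volume + self.rete_testis_volume)


@dataclass
class SpeciesPhysiology:
    species: str
    body_weight: float
    organs: dict[str, OrganPhysiology]
    plasma_volume: float
    blood_cell_volume: float
    lymph_node_volume: float
    notes: list[str] = field(default_factory=list)

    def organ(self, organ_id: str) -> OrganPhysiology:
        try:
            return self.organs[organ_id]
        except KeyError:
            raise PhysiologyError(f"organ {organ_id!r} missing from "
                                  f"{self.species} physiology") from None

    def require(self, organ_ids: Iterable[str]) -> None:
        missing = [o for o in organ_ids if o not in self.organs]
        if missing:
            raise PhysiologyError(
                f"{self.species} physiology is missing required organ(s): "
                + ", ".join(missing))


@dataclass
class Finding:
    level: str  # "error" | "warning"
    organ: str
    fieldname: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.level}] {self.organ}.{self.fieldname}: {self.message}"


def allometric_scale(value: float, bw_ref: float, bw_target: float,
                     exponent: float) -> float:
    """Power-law interspecies scaling: value * (bw_target/bw_ref)**exponent.

    Flows use exponent 0.75; volumes scale linearly (exponent 1).
    """
    if bw_ref <= 0 or bw_target <= 0:
        raise ValueError("body weights must be positive")
    return value * (bw_target / bw_ref) ** exponent


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("mrtpbpk.data") / name))


def _read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    expected = {"organ", "field", "value", "unit"}
    if not expected.issubset(df.columns):
        raise PhysiologyError(
            f"physiology table {path} must have columns {sorted(expected)}")
    return df


def _apply_rows(df: pd.DataFrame, units: UnitContext,
                organs: dict[str, OrganPhysiology],
                pools: dict[str, float]) -> None:
    for row in df.itertuples(index=False):
        value = units.to_canonical(float(row.value), str(row.unit))
        if value < 0:
            raise PhysiologyError(
                f"negative value for {row.organ}.{row.field}: {row.value}")
        if row.field == "pool_volume":
            pools[str(row.organ)] = value
            continue
        org = organs.setdefault(str(row.organ),
                                OrganPhysiology(organ_id=str(row.organ)))
        if not hasattr(org, str(row.field)):
            raise PhysiologyError(f"unknown physiology field {row.field!r}")
        setattr(org, str(row.field), value)


def _fill_derived(org: OrganPhysiology, notes: list[str]) -> None:
    """Fill lymph flow, blood-cell sub-volume and endosomal volume by rule."""
    if org.lymph_flow == 0.0 and org.plasma_flow > 0.0:
        org.lymph_flow = org.plasma_flow * LYMPH_TO_PLASMA_FLOW
    if org.blood_cell_flow == 0.0 and org.plasma_flow > 0.0:
        org.blood_cell_flow = org.plasma_flow * HEMATOCRIT / (1 - HEMATOCRIT)
    if org.blood_cell_volume == 0.0 and org.vascular_volume > 0.0:
        # tables print a single vascular (plasma) volume; partition by hematocrit
        org.blood_cell_volume = org.vascular_volume * HEMATOCRIT / (1 - HEMATOCRIT)
        notes.append(f"{org.organ_id}: blood-cell volume derived from vascular "
                     f"volume at hematocrit {HEMATOCRIT}")
    if org.endosomal_volume == 0.0:
        total = org.total_volume()
        if total > 0:
            org.endosomal_volume = ENDOSOMAL_FRACTION * total
            notes.append(f"{org.organ_id}: endosomal volume set to 0.5% of "
                         "organ volume")


def _rete_testis_transfer(df: pd.DataFrame) -> pd.DataFrame:
    """Fold a standalone 'rete_testis' row into the testis organ."""
    mask = df["organ"] == "rete_testis"
    if mask.any():
        sub = df[mask]
        extra = sub[sub["field"].isin(("luminal_volume", "rete_testis_volume"))]
        rows = [{"organ": "testis", "field": "rete_testis_volume",
                 "value": v, "unit": u}
                for v, u in zip(extra["value"], extra["unit"])]
        df = pd.concat([df[~mask], pd.DataFrame(rows)], ignore_index=True)
    return df


def load_species_physiology(
    species: str,
    source: str | Path | None = None,
    *,
    platform_source: str | Path | None = None,
    body_weight: float | None = None,
) -> SpeciesPhysiology:
    """Load the full organ set for one species in canonical units.

    Parameters
    ----------
    species : one of ``mouse``, ``rat``, ``monkey``, ``human``
    source : optional override CSV for the MRT organ table
    platform_source : optional override CSV for the platform organ table
        (defaults to the packaged synthetic mouse platform file, allometrically
        scaled for non-mouse species)
    body_weight : kg; defaults to 0.028 / 0.25 / 6.2 / 71 by species

    Raises :class:`PhysiologyError` if the species is unknown, a required
    organ is absent, or any tabulated value is negative.
    """
    species = species.lower()
    if species not in DEFAULT_BODY_WEIGHTS:
        raise PhysiologyError(
            f"unknown species {species!r}; expected one of "
            f"{sorted(DEFAULT_BODY_WEIGHTS)}")
    bw = body_weight if body_weight is not None else DEFAULT_BODY_WEIGHTS[species]

    units = UnitContext()
    organs: dict[str, OrganPhysiology] = {}
    pools: dict[str, float] = {}
    notes: list[str] = []

    mrt_path = Path(source) if source is not None else _data_path(f"{species}_mrt.csv")
    mrt_df = _rete_testis_transfer(_read_table(mrt_path))
    _apply_rows(mrt_df, units, organs, pools)

    plat_path = (Path(platform_source) if platform_source is not None
                 else _data_path("platform_mouse_synthetic.csv"))
    _apply_rows(_read_table(plat_path), units, organs, pools)

    plasma_v = pools.get("plasma", 9.44e-4)
    bc_v = pools.get("blood_cell", 7.73e-4)
    ln_v = pools.get("lymph_node", 1.13e-4)

    sp = SpeciesPhysiology(species=species, body_weight=bw, organs=organs,
                           plasma_volume=plasma_v, blood_cell_volume=bc_v,
                           lymph_node_volume=ln_v, notes=notes)

    if species != "mouse" and platform_source is None:
        # platform file is mouse-referenced: scale flows ^0.75, volumes ^1
        sp = scale_platform_physiology(sp, bw_ref=DEFAULT_BODY_WEIGHTS["mouse"],
                                       organs=PLATFORM_ORGANS)

    for org in sp.organs.values():
        _fill_derived(org, sp.notes)

    # circulatory closure: lung receives every organ's nominal plasma flow plus
    # its own lymph filtrate, so total venous return equals lung inflow exactly
    sp.require(("lung",))
    lung = sp.organ("lung")
    total_plq = sum(o.plasma_flow for o in sp.organs.values() if o.organ_id != "lung")
    lung.plasma_flow = total_plq / (1.0 - LYMPH_TO_PLASMA_FLOW)
    lung.lymph_flow = lung.plasma_flow * LYMPH_TO_PLASMA_FLOW
    lung.blood_cell_flow = sum(o.blood_cell_flow for o in sp.organs.values()
                               if o.organ_id != "lung")
    sp.notes.append("lung flows derived from circulatory mass-balance closure")

    sp.require(PLATFORM_ORGANS)
    sp.require(MRT_ORGANS)
    return sp


def scale_platform_physiology(sp: SpeciesPhysiology, bw_ref: float,
                              organs: Iterable[str] | None = None,
                              ) -> SpeciesPhysiology:
    """Allometrically rescale organ flows (^0.75) and volumes (^1) to
    ``sp.body_weight`` from a reference body weight ``bw_ref``."""
    target = dict(sp.organs)
    names = tuple(organs) if organs is not None else tuple(target)
    for name in names:
        if name not in target:
            continue
        o = target[name]
        kw = {}
        for f in ("plasma_flow", "blood_cell_flow", "lymph_flow"):
            kw[f] = allometric_scale(getattr(o, f), bw_ref, sp.body_weight,
                                     FLOW_EXPONENT)
        for f in ("vascular_volume", "blood_cell_volume", "endosomal_volume",
                  "interstitial_volume", "epithelial_volume", "muscular_volume",
                  "luminal_volume", "rete_testis_volume"):
            kw[f] = allometric_scale(getattr(o, f), bw_ref, sp.body_weight,
                                     VOLUME_EXPONENT)
        target[name] = replace(o, **kw)
    ratio = sp.body_weight / bw_ref
    return replace(
        sp, organs=target,
        plasma_volume=sp.plasma_volume * ratio,
        blood_cell_volume=sp.blood_cell_volume * ratio,
        lymph_node_volume=sp.lymph_node_volume * ratio,
        notes=sp.notes + [f"platform organs allometrically scaled x{ratio:g} "
                          "(flows ^0.75, volumes ^1)"])


def validate_physiology(sp: SpeciesPhysiology) -> list[Finding]:
    """Check invariants; returns findings (never raises).

    Errors: negative values, lymph flow exceeding plasma flow.
    Warnings: endosomal volume off the 0.5% rule, implied hematocrit far from
    0.45, one sub-compartment dominating the organ (known anomalies in the
    printed cross-species tables), and the blood-flow column interpretation.
    """
    findings: list[Finding] = []
    numeric = ("plasma_flow", "blood_cell_flow", "lymph_flow", "vascular_volume",
               "blood_cell_volume", "endosomal_volume", "interstitial_volume",
               "epithelial_volume", "muscular_volume", "luminal_volume",
               "rete_testis_volume")
    any_mrt = False
    for org in sp.organs.values():
        for f in numeric:
            if getattr(org, f) < 0:
                findings.append(Finding("error", org.organ_id, f,
                                        "negative value"))
        if org.lymph_flow > org.plasma_flow and org.plasma_flow > 0:
            findings.append(Finding("error", org.organ_id, "lymph_flow",
                                    "lymph flow exceeds plasma flow "
                                    "(rule: plasma flow / 200)"))
        total = org.total_volume()
        # the 0.5% endosome rule is checkable only where the tabulated
        # sub-volumes span the whole organ (MRT tables); platform organs carry
        # an untracked cellular volume
        if org.organ_id in MRT_ORGANS and total > 0 and org.endosomal_volume > 0:
            frac = org.endosomal_volume / total
            if not (0.8 * ENDOSOMAL_FRACTION <= frac <= 1.2 * ENDOSOMAL_FRACTION):
                findings.append(Finding(
                    "warning", org.organ_id, "endosomal_volume",
                    f"endosomal fraction {frac:.3%} deviates from the 0.5% rule"))
        if org.plasma_flow > 0 and org.blood_cell_flow > 0:
            hct = org.blood_cell_flow / (org.blood_cell_flow + org.plasma_flow)
            if abs(hct - HEMATOCRIT) > 0.05:
                findings.append(Finding(
                    "warning", org.organ_id, "blood_cell_flow",
                    f"implied hematocrit {hct:.2f} deviates from {HEMATOCRIT}"))
        if total > 0:
            for f in ("epithelial_volume", "luminal_volume"):
                if getattr(org, f) / total > 0.75:
                    findings.append(Finding(
                        "warning", org.organ_id, f,
                        f"sub-compartment is {getattr(org, f) / total:.0%} of the "
                        "organ volume (ingested as printed)"))
        if org.organ_id in MRT_ORGANS:
            any_mrt = True
    if any_mrt:
        findings.append(Finding(
            "warning", "testis", "blood_cell_flow",
            "source table's 'Blood Flow' column interpreted as blood-cell flow "
            "and 'Plasma Flow' as plasma flow (ratio matches hematocrit 0.45)"))
    return findings
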