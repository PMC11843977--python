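"""Antibody kinetic parameter containers (global and MRT-specific)."""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

__all__ = ["GlobalKinetics", "MrtParameters"]


def _packaged(name: str) -> Path:
    return Path(str(importlib.resources.files("mrtpbpk.data") / name))


def _coerce_floats(raw: dict) -> dict:
    # YAML 1.1 reads exponents without a signed power ("8.06e7") as strings
    out = {}
    for k, v in raw.items():
        if isinstance(v, str):
            out[k] = float(v)
        elif isinstance(v, dict):
            out[k] = {kk: float(vv) for kk, vv in v.items()}
        else:
            out[k] = v
    return out


@dataclass
class GlobalKinetics:
    """Rate constants shared by all organs.

    Free FcRn is held at a constant concentration inside each endosomal
    space, which keeps the whole system linear in antibody amount (no
    receptor depletion). FcRn at the blood-testis barrier defaults to
    one tenth of the endothelial concentration.
    """

    clup: float = 0.55                # L/h per L endosomal volume
    kon_fcrn: float = 8.06e7          # 1/(M*h)
    koff_fcrn: float = 6.55           # 1/h
    kdeg: float = 42.9                # 1/h
    fr: float = 0.715                 # recycling fraction, dimensionless
    fcrn_endothelium: float = 4.98e-5  # M
    fcrn_btb: float = 4.98e-6          # M
    sigma_vascular: float = 0.95
    sigma_vascular_overrides: dict[str, float] = field(default_factory=dict)
    sigma_lymph: float = 0.2
    sigma_epithelial: float = 0.95

    def __post_init__(self) -> None:
        for name in ("clup", "kon_fcrn", "koff_fcrn", "kdeg",
                     "fcrn_endothelium", "fcrn_btb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("fr", "sigma_vascular", "sigma_lymph", "sigma_epithelial"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def sigma_v(self, organ_id: str) -> float:
        return self.sigma_vascular_overrides.get(organ_id, self.sigma_vascular)

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "GlobalKinetics":
        path = Path(path) if path is not None else _packaged("kinetics_default.yaml")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown kinetic parameter(s): {sorted(unknown)}")
        return cls(**_coerce_floats(raw))

    @classmethod
    def default(cls) -> "GlobalKinetics":
        return cls.from_yaml(None)


@dataclass
class MrtParameters:
    """Male-reproductive-tract parameters (defaults: final mouse estimates).

    ``clup_btb`` / ``clup_e_testis`` are the testis epithelial (blood-testis
    barrier) and endothelial pinocytosis rates; the ``q_*`` values are the
    seminal-fluid luminal flows along the chain testis -> epididymis -> vas
    deferens -> seminal vesicle -> prostate; ``beb_volume_epididymis`` is the
    estimated blood-epididymal-barrier volume, which supersedes the literature
    epididymal epithelial volume inside the model.
    """

    clup_btb: float = 6.78e-2        # L/h/L
    clup_e_testis: float = 1.27e2    # L/h/L
    q_retetestis: float = 1.20e-8    # L/h
    q_ep: float = 1.60e-4            # L/h
    q_vd: float = 2.00e-5            # L/h
    q_sv: float = 9.40e-5            # L/h
    q_pg: float = 1.60e-5            # L/h
    beb_volume_epididymis: float = 2.80e-4  # L

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")

    def with_updates(self, **kw: float) -> "MrtParameters":
        return replace(self, **kw)

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "MrtParameters":
        path = (Path(path) if path is not None
                else _packaged("mrt_parameters_default.yaml"))
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown MRT parameter(s): {sorted(unknown)}")
        return cls(**_coerce_floats(raw))

    @classmethod
    def default(cls) -> "MrtParameters":
        return cls.from_yaml(None)

    #: luminal flow parameter governing each organ's lumen outflow
    LUMINAL_FLOW_BY_ORGAN = {
        "epididymis": "q_ep",
        "vas_deferens": "q_vd",
        "seminal_vesicle": "q_sv",
        "prostate_gland": "q_pg",
    }
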