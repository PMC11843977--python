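"""Configuration and tabular I/O shared by the command-line workflows.

All tabular artifacts are plain CSV; configuration is YAML/JSON.  Output
files carry a provenance header (package version, config hash, seed) as
``#``-prefixed comment lines, which the package's own readers skip.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .estimation import ObservedDataset
from .simulate import DoseEvent

__all__ = ["RunConfig", "read_dataset_csv", "write_dataset_csv",
           "write_table", "read_table"]


@dataclass
class RunConfig:
    """Serializable description of one run; re-running a dumped config
    reproduces deterministic outputs bit-for-bit."""

    species: str = "mouse"
    dose_mg_per_kg: float = 10.0
    body_weight: float | None = None
    molecular_weight: float = 1.5e5
    times: list[float] = field(default_factory=lambda: [5 / 60, 6, 24, 96, 168])
    mrt_source: str | None = None
    platform_source: str | None = None
    kinetics_source: str | None = None
    mrt_parameters_source: str | None = None
    solver_method: str = "bdf"
    rtol: float = 1e-8
    atol: float = 1e-10
    perfused: bool = True
    seed: int = 0
    output_dir: str = "."

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = (json.load(fh) if str(path).endswith(".json")
                   else yaml.safe_load(fh)) or {}
        known = set(cls().__dict__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**raw)

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def _provenance_header(config: RunConfig | None = None,
                       seed: int | None = None) -> str:
    parts = [f"mrtpbpk v{__version__}"]
    if config is not None:
        parts.append(f"config sha256:{config.digest()}")
    if seed is not None:
        parts.append(f"seed {seed}")
    return "# " + " | ".join(parts) + "\n"


def write_table(df: pd.DataFrame, path: str | Path,
                config: RunConfig | None = None,
                seed: int | None = None) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_provenance_header(config, seed))
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_dataset_csv(dataset: ObservedDataset, path: str | Path,
                      config: RunConfig | None = None) -> None:
    write_table(dataset.records, path, config=config,
                seed=dataset.meta.get("seed"))


def read_dataset_csv(path: str | Path, dose: DoseEvent | None = None,
                     perfused: bool = True) -> ObservedDataset:
    df = read_table(path)
    if "replicate" not in df.columns:
        df["replicate"] = 1
    return ObservedDataset(records=df, dose=dose or DoseEvent(),
                           perfused=perfused)
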