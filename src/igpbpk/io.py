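"""Observed-PK tables, configuration files and run manifests.

Canonical units at the I/O boundary: time in hours, concentration in mg/L,
dose in mg (or mg/kg, resolved against body weight).  Amounts are carried in
umol internally and converted with the molecular weight at the boundary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import DoseRegimen, DrugProperties

REQUIRED_COLUMNS = ("time_h", "conc_mg_per_L", "dose_id")

#: accepted concentration units and their factor to mg/L
_CONC_FACTORS = {"mg/L": 1.0, "ug/mL": 1.0, "ng/mL": 1e-3, "g/L": 1e3, "uM": None}


@dataclass
class ObservedPK:
    """Observed time–concentration table, the fitting/evaluation currency.

    ``data`` has columns ``time_h``, ``conc_mg_per_L``, ``dose_id`` and a
    boolean ``censored`` column marking samples below the LLOQ (these are kept
    for bookkeeping but excluded from NCA and fitting).
    """

    data: pd.DataFrame
    lloq: float | None = None  # mg/L

    def dose_ids(self) -> list[str]:
        return sorted(self.data["dose_id"].unique())

    def profile(self, dose_id: str, include_censored: bool = False):
        """(times, concentrations) for one dose group, sorted, quantifiable only."""
        sub = self.data[self.data["dose_id"] == dose_id]
        if not include_censored:
            sub = sub[~sub["censored"]]
        sub = sub.sort_values("time_h")
        return sub["time_h"].to_numpy(), sub["conc_mg_per_L"].to_numpy()

    def validate(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"observed PK table missing columns: {missing}")
        if (self.data["conc_mg_per_L"] < 0).any():
            raise ValueError("negative concentrations in observed PK table")
        dup = self.data.duplicated(subset=["dose_id", "time_h"])
        if dup.any():
            raise ValueError("duplicate (dose_id, time_h) rows in observed PK table")


def read_observed_pk(path: str | Path, units: dict | None = None,
                     mw: float | None = None) -> ObservedPK:
    """Read an observed-PK CSV, validating schema and converting units.

    The CSV needs columns ``time_h``, ``conc_mg_per_L`` (header names fix the
    canonical units) and ``dose_id``; an optional boolean ``censored`` column
    marks below-LLOQ samples.  Alternatively a sidecar unit declaration can be
    passed (``units={"conc": "ng/mL"}``) or found next to the file as
    ``<name>.units.yaml``, in which case the concentration column may be named
    ``conc`` and is converted to mg/L (uM additionally requires ``mw``).
    """
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(".units.yaml")
    if units is None and sidecar.exists():
        units = yaml.safe_load(sidecar.read_text())
    if units and "conc" in units and "conc" in df.columns:
        unit = units["conc"]
        if unit not in _CONC_FACTORS:
            raise ValueError(f"unsupported concentration unit {unit!r}")
        factor = _CONC_FACTORS[unit]
        if factor is None:  # uM
            if mw is None:
                raise ValueError("converting uM needs the molecular weight")
            factor = mw / 1000.0
        df = df.rename(columns={"conc": "conc_mg_per_L"})
        df["conc_mg_per_L"] = df["conc_mg_per_L"] * factor
    missing = [c for c in ("time_h", "conc_mg_per_L") if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    if "dose_id" not in df.columns:
        df["dose_id"] = "dose_1"
    if "censored" not in df.columns:
        df["censored"] = False
    df["censored"] = df["censored"].astype(bool)
    df = df.sort_values(["dose_id", "time_h"]).reset_index(drop=True)
    obs = ObservedPK(data=df[["time_h", "conc_mg_per_L", "dose_id", "censored"]])
    obs.validate()
    return obs


def write_observed_pk(obs: ObservedPK, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    obs.data.to_csv(path, index=False)


def drug_to_dict(drug: DrugProperties) -> dict:
    return {
        "name": drug.name, "modality": drug.modality, "mw": drug.mw,
        "kd_human_fcrn": drug.kd_human_fcrn,
        "kd_species_factor": drug.kd_species_factor,
        "cl_add": drug.cl_add, "cl_renal": drug.cl_renal,
        "k_deconj": drug.k_deconj,
    }


def drug_from_dict(d: dict) -> DrugProperties:
    drug = DrugProperties(**d)
    drug.validate()
    return drug


def regimen_to_dict(reg: DoseRegimen) -> dict:
    return {
        "route": reg.route, "dose_mg": reg.dose_mg,
        "dose_mg_per_kg": reg.dose_mg_per_kg,
        "infusion_duration": reg.infusion_duration,
        "dose_times": list(reg.dose_times), "ka": reg.ka, "f_sc": reg.f_sc,
    }


def regimen_from_dict(d: dict) -> DoseRegimen:
    d = dict(d)
    d["dose_times"] = tuple(d.get("dose_times", (0.0,)))
    reg = DoseRegimen(**d)
    reg.validate()
    return reg


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def _plain(obj):
    """Recursively coerce numpy scalars/arrays to plain Python types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_yaml(obj: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(_plain(obj), sort_keys=False))


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI output."""

    command: str
    config_hash: str
    seeds: dict = field(default_factory=dict)
    software_version: str = ""
    input_digests: dict = field(default_factory=dict)
    timestamp: str = ""

    @classmethod
    def create(cls, command: str, config: dict, seeds: dict | None = None,
               inputs: list[str | Path] | None = None) -> "RunManifest":
        from . import __version__

        blob = json.dumps(config, sort_keys=True, default=str).encode()
        digests = {}
        for p in inputs or []:
            p = Path(p)
            digests[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        return cls(
            command=command,
            config_hash=hashlib.sha256(blob).hexdigest()[:16],
            seeds=seeds or {},
            software_version=__version__,
            input_digests=digests,
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )

    def write(self, path: str | Path) -> None:
        write_yaml(self.__dict__, path)


def profile_to_csv(result, path: str | Path) -> None:
    """Write a tidy simulation profile CSV (units in the header names)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    result.to_frame().to_csv(path, index=False)


def plasma_profile_frame(result) -> pd.DataFrame:
    return pd.DataFrame({
        "time_h": result.t,
        "conc_uM": result.plasma_conc_uM,
        "conc_mg_per_L": result.plasma_conc_mg_per_L,
    })


__all__ = [
    "ObservedPK", "read_observed_pk", "write_observed_pk", "RunManifest",
    "drug_to_dict", "drug_from_dict", "regimen_to_dict", "regimen_from_dict",
    "read_yaml", "write_yaml", "profile_to_csv", "plasma_profile_frame",
]
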