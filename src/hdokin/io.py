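"""CSV and YAML input/output for time courses, spectra, profiles and schemes.

Formats (comma-separated, UTF-8, header row, '.' decimal separator):

* time courses — long form with columns ``time, unit, observable, value,
  replicate``;
* spectra — ``velocity_mm_s, absorption, sd`` (sd column optional);
* product profiles — ``isotopologue, product, value, basis``;
* fit reports — ``parameter, value, sd, unit``;
* schemes — YAML with ``species`` (name, role, initial) and ``reactions``
  (source, target, rate_id, rate, unit) blocks.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .errors import InputError
from .fitting import FitResult
from .kie import ProductProfile
from .mossbauer import Spectrum
from .schemes import FirstOrderReaction, KineticScheme, Species, TimeCourse


def write_timecourses(path, tcs: Iterable[TimeCourse]) -> None:
    rows = []
    for tc in tcs:
        for name, vals in tc.observables.items():
            for t, v in zip(tc.times, vals):
                rows.append(
                    {"time": t, "unit": tc.unit, "observable": name,
                     "value": v, "replicate": tc.replicate_id}
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_timecourses(path) -> list[TimeCourse]:
    df = pd.read_csv(path)
    required = {"time", "unit", "observable", "value", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"time-course CSV missing columns: {sorted(missing)}")
    out = []
    for rep, grp in df.groupby("replicate", sort=True):
        units = grp["unit"].unique()
        if len(units) != 1:
            raise InputError("mixed time units within one replicate")
        wide = grp.pivot_table(index="time", columns="observable",
                               values="value", sort=True)
        if wide.isna().any().any():
            raise InputError("observables are not sampled on a common grid")
        out.append(
            TimeCourse(
                wide.index.to_numpy(dtype=float), str(units[0]),
                {c: wide[c].to_numpy(dtype=float) for c in wide.columns},
                replicate_id=int(rep),
            )
        )
    return out


def write_spectrum(path, s: Spectrum) -> None:
    df = pd.DataFrame({"velocity_mm_s": s.velocities, "absorption": s.absorption})
    if s.sd is not None:
        df["sd"] = s.sd
    df.to_csv(path, index=False)


def read_spectrum(path) -> Spectrum:
    df = pd.read_csv(path)
    for col in ("velocity_mm_s", "absorption"):
        if col not in df.columns:
            raise InputError(f"spectrum CSV missing column {col!r}")
    sd = df["sd"].to_numpy(dtype=float) if "sd" in df.columns else None
    return Spectrum(df["velocity_mm_s"].to_numpy(dtype=float),
                    df["absorption"].to_numpy(dtype=float), sd)


def write_profiles(path, profiles: Iterable[ProductProfile]) -> None:
    rows = [
        {"isotopologue": p.isotopologue, "product": prod,
         "value": val, "basis": p.basis}
        for p in profiles
        for prod, val in p.per_product.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_profiles(path) -> list[ProductProfile]:
    df = pd.read_csv(path)
    required = {"isotopologue", "product", "value", "basis"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"profile CSV missing columns: {sorted(missing)}")
    out = []
    for (iso, basis), grp in df.groupby(["isotopologue", "basis"], sort=False):
        out.append(
            ProductProfile(
                str(iso),
                dict(zip(grp["product"], grp["value"].astype(float))),
                basis=str(basis),
            )
        )
    return out


def write_fit_report(path, fits: dict[str, FitResult]) -> None:
    """Flat key-value fit report; one row per parameter, full precision."""
    rows = []
    for label, fit in fits.items():
        for name, value in fit.params.items():
            rows.append(
                {"fit": label, "model": fit.model_id, "parameter": name,
                 "value": value, "sd": fit.param_sd.get(name, float("nan")),
                 "unit": fit.units.get(name, ""),
                 "converged": fit.converged}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_scheme(path, scheme: KineticScheme) -> None:
    doc = {
        "species": [
            {"name": s.name, "role": s.role, "initial": s.initial_amount}
            for s in scheme.species
        ],
        "reactions": [
            {"source": r.source, "target": r.target, "rate_id": r.rate_id,
             "rate": r.rate_value, "unit": "1/min"}
            for r in scheme.reactions
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_scheme(path) -> KineticScheme:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "species" not in doc:
        raise InputError("scheme config must define a 'species' block")
    species = [
        Species(str(s["name"]), str(s.get("role", "intermediate")),
                float(s.get("initial", 0.0)))
        for s in doc["species"]
    ]
    reactions = []
    for r in doc.get("reactions", []):
        rate = float(r["rate"])
        unit = str(r.get("unit", "1/min"))
        if unit == "1/s":
            rate *= 60.0
        elif unit != "1/min":
            raise InputError(f"unknown rate unit {unit!r}")
        reactions.append(
            FirstOrderReaction(str(r["source"]), str(r["target"]),
                               str(r.get("rate_id", f"k{len(reactions)}")), rate)
        )
    return KineticScheme(species, reactions)


def file_checksum(path) -> str:
    """SHA-256 of a file, for report traceability."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_metadata(path, meta: dict) -> None:
    """Sidecar metadata (seed, truth parameters, noise model) as JSON."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    Path(path).write_text(json.dumps(meta, indent=2, default=default))
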