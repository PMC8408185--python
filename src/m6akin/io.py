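"""CSV/config I/O for profiles, traces and melting curves, plus run manifests.

Data files are plain CSV (comma separated, "." decimal, UTF-8, "#"
comments); acquisition metadata that does not fit a per-point column
lives in a YAML sidecar named ``<data>.meta.yaml``.  Floats are
serialized with 12 significant digits so deterministic paths round-trip
bit-identically.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .bloch_mcconnell import CESTProfile, R1rhoProfile
from .exchange_models import NucleusContext
from .imino_exchange import IminoTrace
from .thermodynamics import MeltingCurve

__all__ = [
    "load_profile",
    "save_profile",
    "write_manifest",
    "sidecar_path",
]

FLOAT_FORMAT = "%.12g"

_KINDS = ("cest", "r1rho", "melting", "imino")


def sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".meta.yaml")


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad_rows = df[required].isna().any(axis=1)
    if bad_rows.any():
        rows = [int(i) + 2 for i in df.index[bad_rows]]  # 1-based incl. header
        raise ValueError(f"{path}: missing/NaN cells in rows {rows}")
    return df


def _read_meta(path) -> dict:
    meta_file = sidecar_path(path)
    if meta_file.exists():
        with open(meta_file) as fh:
            return yaml.safe_load(fh) or {}
    return {}


def load_profile(path, kind: str):
    """Load a typed dataset from CSV (+ optional metadata sidecar).

    ``kind`` is one of ``cest``, ``r1rho``, ``melting``, ``imino``.
    Melting-curve temperatures are accepted in Celsius (``temp_C``) and
    converted to Kelvin.  Returns the typed object, and for dispersion
    profiles also the :class:`NucleusContext` from the sidecar.
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown profile kind {kind!r}; one of {_KINDS}")
    meta = _read_meta(path)
    if kind == "cest":
        df = _read_csv(path, ["b1_hz", "offset_hz", "value", "sigma"])
        prof = CESTProfile(
            probe=meta.get("probe", "C"),
            b1_hz=df["b1_hz"].to_numpy(),
            offset_hz=df["offset_hz"].to_numpy(),
            trelax=float(meta.get("trelax", 0.2)),
            intensities=df["value"].to_numpy(),
            sigma=df["sigma"].to_numpy(),
            init_mode=meta.get("init_mode", "gs_only"),
            b1_inhomogeneity=float(meta.get("b1_inhomogeneity", 0.0)),
        )
        ctx = NucleusContext(
            meta.get("nucleus", "13C"), float(meta.get("proton_field_MHz", 600.0))
        )
        return prof, ctx
    if kind == "r1rho":
        df = _read_csv(path, ["b1_hz", "offset_hz", "value", "sigma"])
        prof = R1rhoProfile(
            probe=meta.get("probe", "C"),
            b1_hz=df["b1_hz"].to_numpy(),
            offset_hz=df["offset_hz"].to_numpy(),
            r1rho=df["value"].to_numpy(),
            sigma=df["sigma"].to_numpy(),
            alignment=meta.get("alignment", "auto"),
        )
        ctx = NucleusContext(
            meta.get("nucleus", "13C"), float(meta.get("proton_field_MHz", 600.0))
        )
        return prof, ctx
    if kind == "melting":
        df = _read_csv(path, ["temp_C", "a260"])
        return MeltingCurve(
            temperatures=df["temp_C"].to_numpy() + 273.15,
            a260=df["a260"].to_numpy(),
            Ct=float(meta["Ct"]),
        )
    df = _read_csv(path, ["delay_s", "volume"])
    return IminoTrace(
        delays=df["delay_s"].to_numpy(),
        volumes=df["volume"].to_numpy(),
        W0=float(meta["W0"]),
        E=float(meta["E"]),
        R1w=float(meta["R1w"]),
    )


def save_profile(obj, path, ctx: NucleusContext | None = None) -> None:
    """Write a typed dataset to CSV plus its metadata sidecar."""
    path = Path(path)
    meta: dict = {}
    if isinstance(obj, CESTProfile):
        if obj.intensities is None or obj.sigma is None:
            raise ValueError("profile has no data to save")
        df = pd.DataFrame(
            {
                "b1_hz": obj.b1_hz,
                "offset_hz": obj.offset_hz,
                "value": obj.intensities,
                "sigma": obj.sigma,
            }
        )
        meta = {
            "kind": "cest",
            "probe": obj.probe,
            "trelax": obj.trelax,
            "init_mode": obj.init_mode,
            "b1_inhomogeneity": obj.b1_inhomogeneity,
        }
    elif isinstance(obj, R1rhoProfile):
        if obj.r1rho is None or obj.sigma is None:
            raise ValueError("profile has no data to save")
        df = pd.DataFrame(
            {
                "b1_hz": obj.b1_hz,
                "offset_hz": obj.offset_hz,
                "value": obj.r1rho,
                "sigma": obj.sigma,
            }
        )
        meta = {"kind": "r1rho", "probe": obj.probe, "alignment": obj.alignment}
    elif isinstance(obj, MeltingCurve):
        df = pd.DataFrame(
            {"temp_C": obj.temperatures - 273.15, "a260": obj.a260}
        )
        meta = {"kind": "melting", "Ct": obj.Ct}
    elif isinstance(obj, IminoTrace):
        df = pd.DataFrame({"delay_s": obj.delays, "volume": obj.volumes})
        meta = {"kind": "imino", "W0": obj.W0, "E": obj.E, "R1w": obj.R1w}
    else:
        raise TypeError(f"cannot save object of type {type(obj).__name__}")
    if ctx is not None:
        meta["nucleus"] = ctx.nucleus
        meta["proton_field_MHz"] = ctx.proton_field_MHz
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    with open(sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_path,
    subcommand: str,
    inputs: Mapping[str, str] | None = None,
    config: Mapping | None = None,
    seed: int | None = None,
) -> dict:
    """Write a run manifest tying outputs to inputs, config and seed."""
    manifest = {
        "subcommand": subcommand,
        "package_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": seed,
        "config_hash": (
            hashlib.sha256(
                json.dumps(config, sort_keys=True, default=str).encode()
            ).hexdigest()
            if config is not None
            else None
        ),
        "inputs": {
            name: {"path": str(p), "sha256": _hash_file(p)}
            for name, p in (inputs or {}).items()
        },
    }
    with open(out_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
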