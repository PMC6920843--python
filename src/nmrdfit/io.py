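"""Readers and writers for profiles, fit results and validity scans.

File conventions (stated in every header to avoid unit ambiguity):
frequencies in MHz, rates in s^-1, times in s, angles in degrees, dipolar
constants in rad^2 s^-2.  Profile CSV: ``# key: value`` header lines followed
by ``frequency_MHz,R1_per_s[,sigma_per_s]`` rows.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .fitting import FitResult, RelaxationProfile
from .models import (
    HHComponent,
    HHModelParams,
    HNModelParams,
    QuadrupoleCoupling,
)
from .sle import ValidityScanResult

__all__ = [
    "SCHEMA_VERSION",
    "ProfileFormatError",
    "read_profile",
    "write_profile",
    "write_fit_result",
    "read_fit_result",
    "fit_result_params",
    "write_validity_scan",
    "sha256_of",
]

SCHEMA_VERSION = "1"

_UNITS_NOTE = (
    "frequencies MHz, rates 1/s, times s, angles deg, dipolar constants rad^2/s^2"
)


class ProfileFormatError(ValueError):
    """Malformed profile file; the message carries the offending line number."""


def _coerce(value: str):
    try:
        return int(value)
    except ValueError:
        pass
    try:
        return float(value)
    except ValueError:
        return value


def read_profile(path) -> RelaxationProfile:
    """Read a profile CSV written by :func:`write_profile` (or compatible)."""
    path = Path(path)
    metadata: dict = {}
    header: list[str] | None = None
    freq, rate, sig = [], [], []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    metadata[key.strip()] = _coerce(val.strip())
                continue
            fields = [f.strip() for f in line.split(",")]
            if header is None:
                header = fields
                if "frequency_MHz" not in header:
                    raise ProfileFormatError(
                        f"{path}:{lineno}: missing required column 'frequency_MHz'"
                    )
                if "R1_per_s" not in header:
                    raise ProfileFormatError(
                        f"{path}:{lineno}: missing required column 'R1_per_s'"
                    )
                continue
            if len(fields) != len(header):
                raise ProfileFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            row = dict(zip(header, fields))
            try:
                freq.append(float(row["frequency_MHz"]))
                rate.append(float(row["R1_per_s"]))
                if "sigma_per_s" in row:
                    sig.append(float(row["sigma_per_s"]))
            except ValueError as exc:
                raise ProfileFormatError(f"{path}:{lineno}: {exc}") from None
    if header is None or not freq:
        raise ProfileFormatError(f"{path}: no data rows found")
    metadata.pop("schema_version", None)
    metadata.pop("units", None)
    metadata.pop("columns", None)
    try:
        return RelaxationProfile(
            frequencies=np.array(freq),
            rates=np.array(rate),
            uncertainties=np.array(sig) if sig else None,
            metadata=metadata,
        )
    except ValueError as exc:
        raise ProfileFormatError(f"{path}: {exc}") from None


def write_profile(profile: RelaxationProfile, path) -> None:
    """Write a profile CSV with metadata header (lossless round-trip)."""
    path = Path(path)
    has_sigma = profile.uncertainties is not None
    cols = "frequency_MHz,R1_per_s" + (",sigma_per_s" if has_sigma else "")
    with path.open("w") as fh:
        fh.write(f"# schema_version: {SCHEMA_VERSION}\n")
        fh.write(f"# units: {_UNITS_NOTE}\n")
        for key, val in profile.metadata.items():
            fh.write(f"# {key}: {val}\n")
        fh.write(cols + "\n")
        for i in range(len(profile)):
            row = f"{profile.frequencies[i]:.17g},{profile.rates[i]:.17g}"
            if has_sigma:
                row += f",{profile.uncertainties[i]:.17g}"
            fh.write(row + "\n")


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _hh_to_dict(hh: HHModelParams) -> dict:
    return {
        "C_s": hh.slow.C, "tau_s": hh.slow.tau,
        "C_i": hh.intermediate.C, "tau_i": hh.intermediate.tau,
        "C_f": hh.fast.C, "tau_f": hh.fast.tau,
        "A": hh.A,
    }


def write_fit_result(
    fit: FitResult,
    path,
    config_echo: dict | None = None,
    input_path=None,
) -> None:
    """Serialize a :class:`FitResult` to JSON (schema-versioned, with config
    echo and input checksum when available)."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "units": _UNITS_NOTE,
        "input_checksum_sha256": sha256_of(input_path) if input_path else None,
        "config_echo": config_echo or {},
        "fixed": {"a_Q_MHz": fit.fixed.a_Q, "eta": fit.fixed.eta},
        "parameters": {
            **_hh_to_dict(fit.hh),
            "C_HN": fit.hn.C_HN,
            "tau_Q": fit.hn.tau_Q,
            "theta_deg": fit.hn.theta,
            "phi_deg": fit.hn.phi,
        },
        "relative_uncertainties": dict(fit.uncertainties),
        "relative_error_percent": fit.relative_error,
        "tau_q_init": fit.tau_q_init,
        "success": fit.success,
        "message": fit.message,
        "cost": fit.cost,
        "residuals_relative": [float(r) for r in fit.residuals],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_fit_result(path) -> dict:
    """Load a fit-result JSON back into a plain dictionary."""
    return json.loads(Path(path).read_text())


def fit_result_params(payload: dict) -> tuple[HHModelParams, HNModelParams]:
    """Rebuild the model parameter objects from a fit-result payload."""
    p = payload["parameters"]
    hh = HHModelParams(
        slow=HHComponent(C=p["C_s"], tau=p["tau_s"]),
        intermediate=HHComponent(C=p["C_i"], tau=p["tau_i"]),
        fast=HHComponent(C=p["C_f"], tau=p["tau_f"]),
        A=p["A"],
    )
    hn = HNModelParams(
        C_HN=p["C_HN"], tau_Q=p["tau_Q"], theta=p["theta_deg"], phi=p["phi_deg"],
        quad=QuadrupoleCoupling(
            a_Q=payload["fixed"]["a_Q_MHz"], eta=payload["fixed"]["eta"]
        ),
    )
    return hh, hn


def write_validity_scan(
    scan: ValidityScanResult, path, summary_path=None, config_echo: dict | None = None
) -> None:
    """Write the per-(x, frequency) curves CSV (plus optional summary CSV)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# schema_version: {SCHEMA_VERSION}\n")
        fh.write(f"# units: {_UNITS_NOTE}\n")
        for key, val in (config_echo or {}).items():
            fh.write(f"# {key}: {val}\n")
        scan.curves.to_csv(fh, index=False)
    if summary_path is not None:
        with Path(summary_path).open("w") as fh:
            fh.write(f"# schema_version: {SCHEMA_VERSION}\n")
            scan.summary.to_csv(fh, index=False)
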