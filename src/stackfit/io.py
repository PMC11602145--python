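"""File formats: TSV curves with JSON sidecars, sequences, YAML configs, manifests.

FEC files are tab-separated with header columns ``force_pN  x_nm  se_nm``;
metadata (N, N_loop, salt, dialects, extra columns) travels in a
``<name>.meta.json`` sidecar so the TSV stays trivially plottable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .curves import ForceDistanceCurve, ForceExtensionCurve

__all__ = [
    "read_fec",
    "write_fec",
    "read_fdc",
    "write_fdc",
    "read_sequence",
    "load_config",
    "RunManifest",
]

_FEC_COLUMNS = ("force_pN", "x_nm", "se_nm")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_fec(curve: ForceExtensionCurve, path: str | Path) -> None:
    path = Path(path)
    curve.to_frame().to_csv(path, sep="\t", index=False, float_format="%.9g")
    meta = {
        "per_base": curve.per_base, "N": curve.N, "N_loop": curve.N_loop,
        "salt_M": curve.salt_M, "molecule_id": curve.molecule_id,
        **{k: v for k, v in curve.meta.items()
           if isinstance(v, (str, int, float, bool, type(None), dict, list))},
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1, default=str))


def read_fec(path: str | Path) -> ForceExtensionCurve:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("force_pN", "x_nm") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("force_pN", "x_nm"):
        bad = np.nonzero(~np.isfinite(df[col].to_numpy()))[0]
        if bad.size:
            raise ValueError(f"{path}: non-finite {col} at row {bad[0]}")
    f = df["force_pN"].to_numpy(dtype=float)
    neg = np.nonzero(f < 0)[0]
    if neg.size:
        raise ValueError(f"{path}: negative force at row {neg[0]}")
    non_mono = np.nonzero(np.diff(f) <= 0)[0]
    if non_mono.size:
        raise ValueError(f"{path}: non-monotone force at row {non_mono[0] + 1}")
    se = df["se_nm"].to_numpy(dtype=float) if "se_nm" in df.columns else None
    if se is not None and np.all(~np.isfinite(se)):
        se = None
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    extras = [c for c in df.columns if c not in _FEC_COLUMNS]
    if extras:
        meta.setdefault("extra_columns", {}).update(
            {c: df[c].tolist() for c in extras}
        )
    return ForceExtensionCurve(
        f=f, x=df["x_nm"].to_numpy(dtype=float), se=se,
        per_base=bool(meta.get("per_base", False)),
        N=meta.get("N"), N_loop=meta.get("N_loop"), salt_M=meta.get("salt_M"),
        molecule_id=meta.get("molecule_id"),
        meta={k: v for k, v in meta.items()
              if k not in ("per_base", "N", "N_loop", "salt_M", "molecule_id")},
    )


def write_fdc(fdc: ForceDistanceCurve, path: str | Path) -> None:
    path = Path(path)
    fdc.to_frame().to_csv(path, sep="\t", index=False, float_format="%.9g")
    _sidecar(path).write_text(json.dumps(fdc.meta, indent=1, default=str))


def read_fdc(path: str | Path) -> ForceDistanceCurve:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("lambda_nm", "force_pN") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    return ForceDistanceCurve(
        lam=df["lambda_nm"].to_numpy(dtype=float),
        f=df["force_pN"].to_numpy(dtype=float),
        cycle=df["cycle"].to_numpy(dtype=int) if "cycle" in df.columns else None,
        direction=df["direction"].to_numpy(dtype=object) if "direction" in df.columns else None,
        branch=df["branch"].to_numpy(dtype=object) if "branch" in df.columns else None,
        meta=meta,
    )


def read_sequence(path: str | Path) -> str:
    """First sequence from a FASTA file, or the content of a raw text file."""
    text = Path(path).read_text().strip()
    if not text:
        raise ValueError(f"{path}: empty sequence file")
    if text.startswith(">"):
        records = [r for r in text.split(">") if r.strip()]
        if len(records) > 1:
            warnings_msg = f"{path}: {len(records)} records, using the first"
            import warnings

            warnings.warn(warnings_msg, stacklevel=2)
        lines = records[0].splitlines()
        seq = "".join(lines[1:])
    else:
        seq = "".join(text.split())
    return seq.upper()


_CONFIG_KEYS = {
    "seed": int,
    "multistart": int,
    "bootstrap_n": int,
    "bootstrap_unit": str,
    "f_min_pN": float,
    "f_max_pN": float,
    "df_pN": float,
    "salt_M": float,
    "cation": str,
    "model": str,
    "N": int,
    "N_loop": int,
    "min_track": int,
    "params": dict,
}

_CONFIG_DEFAULTS = {
    "seed": 0,
    "multistart": 8,
    "bootstrap_n": 500,
    "bootstrap_unit": "points",
    "f_min_pN": 5.0,
    "f_max_pN": 45.0,
    "df_pN": 0.5,
}


def load_config(path: str | Path) -> dict:
    """Validated YAML configuration with defaults filled in.

    Unknown keys are rejected exhaustively; physical values carry unit
    suffixes in their key names.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = sorted(set(raw) - set(_CONFIG_KEYS))
    if unknown:
        raise ValueError(f"{path}: unknown config keys {unknown}")
    errors = []
    for k, v in raw.items():
        want = _CONFIG_KEYS[k]
        if want in (int, float) and isinstance(v, bool):
            errors.append(f"{k}: expected {want.__name__}, got bool")
        elif want is float and isinstance(v, (int, float)):
            raw[k] = float(v)
        elif not isinstance(v, want):
            errors.append(f"{k}: expected {want.__name__}, got {type(v).__name__}")
    if errors:
        raise ValueError(f"{path}: invalid config: " + "; ".join(errors))
    out = dict(_CONFIG_DEFAULTS)
    out.update(raw)
    return out


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    command: str
    seed: int
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    dialects: dict[str, str] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    package_version: str = "0.1.0"
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    @staticmethod
    def digest(path: str | Path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))
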