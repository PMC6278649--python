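"""CSV/TOML/JSON input-output for titration datasets, configs and reports.

CSV schema (comma-separated, one header row, optional leading ``# key:
value`` metadata comments):

* exchange datasets — columns ``chi, f_z, kex_s1, kex_sigma``; exactly one
  of ``chi``/``f_z`` populated, depending on the curve being fitted;
* shift datasets — ``P_total_uM, N_total_uM, probe_id, nucleus,
  ddelta_obs_ppm, sigma_ppm, f_z, f_z_sigma``; shift rows carry a
  probe_id, f_Z rows leave it empty and populate ``f_z``.

Concentration columns accept ``_nM``/``_uM``/``_mM`` suffixes and are
converted to uM on read.  Values are written with 17 significant digits so
fixtures round-trip without drift.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DatasetValidationError
from .fitting import FitResult, TitrationDataset

__all__ = [
    "read_titration_csv",
    "write_titration_csv",
    "read_config",
    "config_hash",
    "write_report",
]

_EXCHANGE_COLUMNS = {"chi", "f_z", "kex_s1", "kex_sigma"}
_CONC_PREFIXES = ("P_total", "N_total")
_UNIT_FACTORS = {"uM": 1.0, "nM": 1e-3, "mM": 1e3}


def _split_metadata(text: str) -> tuple[dict, str]:
    metadata: dict = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                key, _, value = stripped.partition(":")
                key, value = key.strip(), value.strip()
                try:
                    metadata[key] = json.loads(value)
                except json.JSONDecodeError:
                    metadata[key] = value
        else:
            body_lines.append(line)
    return metadata, "\n".join(body_lines)


def _convert_concentration_units(df: pd.DataFrame) -> pd.DataFrame:
    renames = {}
    for col in df.columns:
        for prefix in _CONC_PREFIXES:
            for unit, factor in _UNIT_FACTORS.items():
                if col == f"{prefix}_{unit}" and unit != "uM":
                    df[col] = df[col] * factor
                    renames[col] = f"{prefix}_uM"
    return df.rename(columns=renames)


def _check_numeric(df: pd.DataFrame, columns: list[str]) -> None:
    for col in columns:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        raw_na = df[col].isna() | (df[col].astype(str).str.strip() == "")
        bad = coerced.isna() & ~raw_na
        if bad.any():
            row = int(df.index[bad][0]) + 2  # 1-based, counting the header
            raise DatasetValidationError(
                f"non-numeric value in column {col!r}, file line {row}"
            )
        df[col] = coerced


def read_titration_csv(
    path: str | Path, kind: str | None = None
) -> TitrationDataset:
    """Read a titration dataset, validating schema and units.

    The observable kind is taken from an ``# observable_kind: ...``
    metadata comment or the ``kind`` argument; for f_Z-indexed exchange
    data the two cannot be distinguished from the columns alone, so one of
    the two sources is required.
    """
    path = Path(path)
    metadata, body = _split_metadata(path.read_text())
    if not body.strip() or len(body.strip().splitlines()) < 2:
        raise DatasetValidationError(f"{path}: empty data section")
    df = pd.read_csv(_io.StringIO(body), skip_blank_lines=True, float_precision="round_trip")
    if len(df) == 0:
        raise DatasetValidationError(f"{path}: empty data section")
    df = _convert_concentration_units(df)

    kind = kind or metadata.get("observable_kind")
    columns = set(df.columns)
    if kind is None:
        if "kex_s1" in columns:
            if "chi" in columns and df["chi"].notna().any():
                kind = "kex_vs_chi"
            else:
                raise DatasetValidationError(
                    f"{path}: f_Z-indexed exchange data; pass kind='kex_bform' or "
                    "'kex_zform' (or add an '# observable_kind:' header)"
                )
        elif "ddelta_obs_ppm" in columns or "f_z" in columns:
            kind = "shift_and_fz"
        else:
            raise DatasetValidationError(
                f"{path}: cannot infer observable kind from columns {sorted(columns)}"
            )

    if kind == "shift_and_fz":
        for col in ("P_total_uM", "N_total_uM"):
            if col not in df.columns:
                raise DatasetValidationError(
                    f"{path}: missing required column {col!r} — the shift model "
                    "needs absolute concentrations, a molar ratio is not enough"
                )
        _check_numeric(
            df, ["P_total_uM", "N_total_uM", "ddelta_obs_ppm", "sigma_ppm", "f_z", "f_z_sigma"]
        )
        for col in ("P_total_uM", "N_total_uM"):
            neg = df[col] < 0
            if neg.any():
                row = int(df.index[neg][0]) + 2
                raise DatasetValidationError(
                    f"{path}: negative concentration in column {col!r}, file line {row}"
                )
    else:
        _check_numeric(df, ["chi", "f_z", "kex_s1", "kex_sigma"])

    metadata.setdefault("source_file", str(path))
    return TitrationDataset(observable_kind=kind, data=df, metadata=metadata)


def write_titration_csv(dataset: TitrationDataset, path: str | Path) -> Path:
    """Write a dataset with metadata comments; lossless value round-trip."""
    path = Path(path)
    lines = [f"# observable_kind: {dataset.observable_kind}"]
    for key, value in dataset.metadata.items():
        if key in ("observable_kind", "source_file"):
            continue
        lines.append(f"# {key}: {json.dumps(value)}")
    buffer = _io.StringIO()
    dataset.data.to_csv(buffer, index=False, float_format="%.17g")
    path.write_text("\n".join(lines) + "\n" + buffer.getvalue())
    return path


def read_config(path: str | Path) -> dict:
    """Read a TOML run configuration."""
    with open(path, "rb") as handle:
        return tomllib.load(handle)


def config_hash(config: dict) -> str:
    """Stable SHA-256 of a configuration mapping."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _provenance(seed: int | None, config: dict | None) -> dict:
    from . import __version__

    return {
        "tool": "bzfit",
        "version": __version__,
        "seed": seed,
        "config_sha256": config_hash(config or {}),
    }


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def fit_result_payload(result: FitResult) -> dict:
    return _jsonable(
        {
            "estimates": result.estimates,
            "uncertainties": result.uncertainties,
            "objective": result.objective,
            "n_points": result.n_points,
            "converged": result.converged,
            "flags": list(result.flags),
        }
    )


def write_report(
    payload: dict,
    path: str | Path,
    seed: int | None = None,
    config: dict | None = None,
) -> Path:
    """Write a JSON report with a provenance block (version, config hash, seed)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    document = {"provenance": _provenance(seed, config), **_jsonable(payload)}
    path.write_text(json.dumps(document, indent=2, sort_keys=True) + "\n")
    return path
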