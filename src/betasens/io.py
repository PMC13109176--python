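"""Schema-validated delimited-text I/O and unit handling.

All interchange is UTF-8 CSV with a header row.  Output files carry a
provenance comment header (config hash + seed) so reruns can be verified
bit-identical.  HbA1c is canonically mmol/mol (IFCC); percent (NGSP)
columns are auto-detected (values < 20) and converted via the standard
linear relation NGSP% = 0.09148 * IFCC + 2.152.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import pandas as pd

logger = logging.getLogger("betasens")

__all__ = [
    "SCHEMAS",
    "ngsp_percent_from_ifcc",
    "ifcc_from_ngsp_percent",
    "read_table",
    "read_tables",
    "write_table",
    "config_hash",
]

#: required columns per logical table
SCHEMAS: dict[str, tuple[str, ...]] = {
    "participants": ("id", "trial", "arm", "age_years", "sex", "bmi", "bsa"),
    "visits": ("id", "month", "hba1c_mmol_mol", "insulin_dose_u_kg_day"),
    "mmtt": ("id", "month", "minute", "glucose_mmol_l", "cpeptide_nmol_l"),
    "fits": ("id", "month", "beta_gs", "auc_cp", "flagged"),
    "events": ("id", "endpoint", "threshold", "time_months", "event"),
}

_RANGE_CHECKS = {
    "glucose_mmol_l": (1.0, 40.0),
    "cpeptide_nmol_l": (0.0, 10.0),
    "hba1c_mmol_mol": (20.0, 200.0),
}

_NGSP_SLOPE = 0.09148
_NGSP_INTERCEPT = 2.152


def ngsp_percent_from_ifcc(mmol_mol):
    """IFCC mmol/mol -> NGSP percent (53 mmol/mol -> 7.0%)."""
    return _NGSP_SLOPE * mmol_mol + _NGSP_INTERCEPT


def ifcc_from_ngsp_percent(percent):
    """NGSP percent -> IFCC mmol/mol."""
    return (percent - _NGSP_INTERCEPT) / _NGSP_SLOPE


def config_hash(obj) -> str:
    """Short stable hash of any JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read and validate one CSV table.

    Checks the header against the schema (extra columns pass through),
    coerces numeric columns, runs unit sanity checks with per-row warnings,
    and converts percent-unit HbA1c columns to mmol/mol.
    """
    if kind not in SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}; one of {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")

    for col in df.columns:
        if col in ("id", "trial", "arm", "sex", "endpoint", "flag_reason", "stratum", "mode"):
            continue
        if col in ("flagged", "event", "corrupted"):
            df[col] = df[col].astype(bool)
        else:
            df[col] = pd.to_numeric(df[col], errors="raise")

    if kind == "visits" and "hba1c_mmol_mol" in df.columns:
        pct = df["hba1c_mmol_mol"] < 20.0
        if pct.any():
            warnings.warn(
                f"{path.name}: {int(pct.sum())} HbA1c value(s) look like NGSP percent; "
                "converting to mmol/mol",
                stacklevel=2,
            )
            df.loc[pct, "hba1c_mmol_mol"] = ifcc_from_ngsp_percent(df.loc[pct, "hba1c_mmol_mol"])

    for col, (lo, hi) in _RANGE_CHECKS.items():
        if col in df.columns:
            bad = (df[col] < lo) | (df[col] > hi)
            if bad.any():
                rows = df.index[bad].tolist()[:5]
                warnings.warn(
                    f"{path.name}: {int(bad.sum())} value(s) of {col} outside "
                    f"[{lo}, {hi}] (rows {rows}...)",
                    stacklevel=2,
                )
    return df


def read_tables(paths: dict[str, str | Path]) -> dict[str, pd.DataFrame]:
    """Read several tables keyed by schema kind."""
    return {kind: read_table(p, kind) for kind, p in paths.items()}


def write_table(
    df: pd.DataFrame, path: str | Path, seed: int | None = None, cfg_hash: str | None = None
) -> Path:
    """Write a CSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = ""
    if seed is not None or cfg_hash is not None:
        header = f"# betasens seed={seed} config={cfg_hash}\n"
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
    logger.info("wrote %s (%d rows)", path, len(df))
    return path
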