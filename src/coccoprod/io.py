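"""Table schemas, validated CSV readers/writers for the four shared tables.

All tables are UTF-8 CSV with a header row, period decimal separator,
latitudes in signed decimal degrees (north positive), depths positive down
and ages in years BP.  Floats are written with 10 significant digits so a
write-then-read round trip preserves values to that precision.
"""

from __future__ import annotations

from collections.abc import Callable

import numpy as np
import pandas as pd

FLOAT_FORMAT = "%.10g"

#: Column order (and dtype family) per table kind.
SCHEMAS: dict[str, dict[str, str]] = {
    "metadata": {
        "sample_id": "str",
        "latitude": "float",
        "longitude": "float",
        "water_depth_m": "float",
        "age_yr_bp": "float",
    },
    "environment": {
        "sample_id": "str",
        "latitude": "float",
        "sst_c": "float",
        "sss_psu": "float",
        "po4_umol_l": "float",
        "ta_umol_kg": "float",
        "dic_umol_kg": "float",
        "d13c_dic_permil": "float",
        "mld_m": "float",
        "sst_anomaly_c": "float",
        "water_depth_m": "float",
    },
    "census": {
        "sample_id": "str",
        "taxon": "str",
        "count": "int",
        "n_fov": "int",
        "fov_area_mm2": "float",
        "deposition_area_mm2": "float",
        "sediment_mass_g": "float",
    },
    "coccoliths": {
        "sample_id": "str",
        "taxon": "str",
        "length_um": "float",
        "width_um": "float",
        "area_um2": "float",
        "mass_pg": "float",
    },
}


class SchemaError(ValueError):
    """Input table violates its schema or row invariants."""

    def __init__(self, kind: str, problems: list[str]):
        self.kind = kind
        self.problems = problems
        shown = "; ".join(problems[:10])
        more = f" (+{len(problems) - 10} more)" if len(problems) > 10 else ""
        super().__init__(f"{kind} table invalid: {shown}{more}")


def _check_census(df: pd.DataFrame) -> list[str]:
    bad = []
    for i, r in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        if r.count < 0:
            bad.append(f"line {i}: negative count {r.count}")
        if r.n_fov < 1:
            bad.append(f"line {i}: n_fov {r.n_fov} < 1")
        if r.fov_area_mm2 <= 0 or r.deposition_area_mm2 <= 0:
            bad.append(f"line {i}: non-positive slide area")
        if r.sediment_mass_g <= 0:
            bad.append(f"line {i}: non-positive sediment mass")
    return bad


def _check_coccoliths(df: pd.DataFrame) -> list[str]:
    bad = []
    for i, r in enumerate(df.itertuples(index=False), start=2):
        if not 0 < r.width_um <= r.length_um:
            bad.append(
                f"line {i}: invariant 0 < W <= L violated (W={r.width_um}, L={r.length_um})"
            )
        if r.area_um2 <= 0:
            bad.append(f"line {i}: non-positive area")
        if r.mass_pg <= 0:
            bad.append(f"line {i}: non-positive mass")
    return bad


def _check_environment(df: pd.DataFrame) -> list[str]:
    bad = []
    for i, r in enumerate(df.itertuples(index=False), start=2):
        if r.ta_umol_kg <= 0 or r.dic_umol_kg <= 0:
            bad.append(f"line {i}: TA and DIC must be positive")
        if r.po4_umol_l < 0:
            bad.append(f"line {i}: negative phosphate")
    return bad


_CHECKS: dict[str, Callable[[pd.DataFrame], list[str]]] = {
    "census": _check_census,
    "coccoliths": _check_coccoliths,
    "environment": _check_environment,
}


def validate_table(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Check header and row invariants; returns the typed frame or raises."""
    schema = SCHEMAS[kind]
    if list(df.columns) != list(schema):
        raise SchemaError(
            kind,
            [f"header mismatch: expected {list(schema)}, got {list(df.columns)}"],
        )
    out = df.copy()
    for col, dtype in schema.items():
        if dtype == "float":
            out[col] = pd.to_numeric(out[col], errors="raise").astype(float)
        elif dtype == "int":
            out[col] = pd.to_numeric(out[col], errors="raise").astype(int)
        else:
            out[col] = out[col].astype(str)
    check = _CHECKS.get(kind)
    if check is not None:
        problems = check(out)
        if problems:
            raise SchemaError(kind, problems)
    return out


def read_table(path, kind: str) -> pd.DataFrame:
    """Read and validate one of the four shared CSV tables."""
    df = pd.read_csv(path, dtype=str)
    return validate_table(df, kind)


def read_tables(paths: dict[str, str]) -> dict[str, pd.DataFrame]:
    """Read the metadata/environment/census/coccoliths CSVs given as a dict."""
    return {kind: read_table(path, kind) for kind, path in paths.items()}


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table as CSV with 10-significant-digit floats."""
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def series_roundtrip_equal(a: pd.DataFrame, b: pd.DataFrame, rtol: float = 1e-9) -> bool:
    """Value equality of two tables up to float-formatting precision."""
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        return False
    for col in a.columns:
        if a[col].dtype.kind in "fi":
            if not np.allclose(
                a[col].to_numpy(dtype=float), b[col].to_numpy(dtype=float), rtol=rtol
            ):
                return False
        elif not (a[col].astype(str) == b[col].astype(str)).all():
            return False
    return True
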