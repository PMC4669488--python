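"""Schema-checked delimited-text tables for every pipeline stage.

All interchange is plain CSV (UTF-8, '.' decimal) with units encoded in
column names.  ``write_table`` prepends provenance comment lines
('# key=value'); ``read_table`` ignores them and validates the header,
cell types and donor-id uniqueness, reporting offending line numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["TableSchema", "SchemaError", "read_table", "write_table", "SCHEMAS"]


class SchemaError(ValueError):
    """A table does not match its documented schema."""


@dataclass(frozen=True)
class TableSchema:
    """Column names mapped to 'float', 'int', 'str' or 'bool'; optional unique key."""

    name: str
    columns: tuple[tuple[str, str], ...]
    unique_key: Optional[str] = None

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.columns)


SCHEMAS: dict[str, TableSchema] = {
    "donors": TableSchema(
        "donors",
        (
            ("donor_id", "str"), ("age_years", "int"), ("gender", "str"),
            ("bw_kg", "float"), ("smoking", "bool"), ("drinking", "bool"),
            ("diagnosis", "str"), ("co_l_min", "float"),
            ("true_mppgl_mg_g", "float"), ("true_vmax_pmol_min_mg", "float"),
            ("true_km_uM", "float"),
        ),
        unique_key="donor_id",
    ),
    "por_pairs": TableSchema(
        "por_pairs",
        (
            ("donor_id", "str"),
            ("homogenate_rate_nmol_min_g", "float"),
            ("microsome_rate_nmol_min_mg", "float"),
        ),
        unique_key="donor_id",
    ),
    "kinetics": TableSchema(
        "kinetics",
        (("donor_id", "str"), ("concentration_uM", "float"), ("rate_pmol_min_mg", "float")),
    ),
    "mppgl": TableSchema(
        "mppgl",
        (("donor_id", "str"), ("mppgl_mg_g", "float")),
        unique_key="donor_id",
    ),
    "kinetic_params": TableSchema(
        "kinetic_params",
        (
            ("donor_id", "str"), ("vmax_pmol_min_mg", "float"), ("km_uM", "float"),
            ("clint_vitro_ul_min_mg", "float"), ("rss", "float"),
            ("converged", "bool"), ("ill_conditioned", "bool"),
        ),
        unique_key="donor_id",
    ),
    "activities_vm": TableSchema(
        "activities_vm",
        (("donor_id", "str"), ("isoform", "str"), ("vm_pmol_min_mg", "float")),
    ),
    "activities_vl": TableSchema(
        "activities_vl",
        (
            ("donor_id", "str"), ("isoform", "str"), ("vm_pmol_min_mg", "float"),
            ("mppgl_mg_g", "float"), ("vl_nmol_min_g", "float"),
        ),
    ),
    "cohort_params": TableSchema(
        "cohort_params",
        (
            ("donor_id", "str"), ("mppgl", "float"), ("clint_vitro", "float"),
            ("bw", "float"), ("co", "float"),
        ),
        unique_key="donor_id",
    ),
    "predictions": TableSchema(
        "predictions",
        (
            ("donor_id", "str"), ("method", "str"),
            ("clint_liver_ml_min_kg", "float"), ("clh_ml_min_kg", "float"),
        ),
    ),
    "observed": TableSchema(
        "observed",
        (("study", "str"), ("clh_obs_ml_min_kg", "float")),
        unique_key="study",
    ),
    "accuracy": TableSchema(
        "accuracy",
        (
            ("method", "str"), ("afe_mean", "float"), ("afe_sd", "float"),
            ("afe_min", "float"), ("afe_max", "float"),
            ("afe_p2_5", "float"), ("afe_p97_5", "float"),
            ("pct_within_2fold", "float"),
        ),
        unique_key="method",
    ),
}

_DTYPES = {"float": float, "int": "int64", "str": str, "bool": bool}


def write_table(df: pd.DataFrame, path, schema: TableSchema, provenance: Optional[dict] = None) -> None:
    """Write ``df`` under ``schema`` with '#' provenance header lines."""
    missing = set(schema.column_names) - set(df.columns)
    if missing:
        raise SchemaError(f"{schema.name}: cannot write, missing columns {sorted(missing)}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}={value}\n")
        # shortest round-trip float representation so read-back is lossless
        df.loc[:, list(schema.column_names)].to_csv(
            fh, index=False, float_format=lambda v: repr(float(v))
        )


def read_table(path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a stage table; errors carry file line numbers."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # count header comment lines so reported row numbers match the file
    n_comment = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                n_comment += 1
            else:
                break
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    missing = set(schema.column_names) - set(df.columns)
    if missing:
        raise SchemaError(f"{schema.name} ({path.name}): missing columns {sorted(missing)}")
    df = df.loc[:, list(schema.column_names)]
    header_line = n_comment + 1
    for col, kind in schema.columns:
        if kind in ("float", "int"):
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[converted.isna() & df[col].notna()]
            if len(bad):
                lines = [int(i) + header_line + 1 for i in bad[:5]]
                raise SchemaError(
                    f"{schema.name} ({path.name}): non-numeric values in column "
                    f"'{col}' at line(s) {lines}"
                )
            if converted.isna().any():
                lines = [int(i) + header_line + 1 for i in df.index[converted.isna()][:5]]
                raise SchemaError(
                    f"{schema.name} ({path.name}): empty cells in column '{col}' "
                    f"at line(s) {lines}"
                )
            # to_numeric only validates; astype parses with correct rounding
            # so written values read back bit-identical
            df[col] = df[col].astype(float).astype(_DTYPES[kind])
        elif kind == "bool":
            lowered = df[col].str.lower()
            ok = lowered.isin(["true", "false", "1", "0"])
            if not ok.all():
                lines = [int(i) + header_line + 1 for i in df.index[~ok][:5]]
                raise SchemaError(
                    f"{schema.name} ({path.name}): non-boolean values in column "
                    f"'{col}' at line(s) {lines}"
                )
            df[col] = lowered.isin(["true", "1"])
    if schema.unique_key is not None:
        dup = df[schema.unique_key][df[schema.unique_key].duplicated()]
        if len(dup):
            raise SchemaError(
                f"{schema.name} ({path.name}): duplicate {schema.unique_key} "
                f"values: {sorted(set(dup))[:5]}"
            )
    return df
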