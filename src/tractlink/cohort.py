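"""Subject-level cohort table: schema, validation, TSV/CSV/JSON round-trip.

The cohort table is the single entry point of the pipeline: one row per
infant, carrying demographics (gestational age at birth, postmenstrual age
at scan, sex), confounds (socioeconomic deprivation index, global
white-matter volume), the median fractional anisotropy of six tracts
(left/right arcuate fasciculus, cortico-spinal tract, superior longitudinal
fasciculus) and the two BSID-III composite outcomes (language, cognition).
Everything downstream consumes a validated :class:`pandas.DataFrame` in this
canonical column order.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import CohortValidationError, ParseError, SchemaError

logger = logging.getLogger(__name__)

#: Canonical column order of a cohort table.
COLUMNS: tuple[str, ...] = (
    "subject_id",
    "ga_birth",
    "pma_scan",
    "sex",
    "ses",
    "wm_volume",
    "fa_arcuate_L",
    "fa_arcuate_R",
    "fa_cst_L",
    "fa_cst_R",
    "fa_slf_L",
    "fa_slf_R",
    "lang",
    "cog",
)

#: Columns holding fractional anisotropy values, constrained to (0, 1).
FA_COLUMNS: tuple[str, ...] = tuple(c for c in COLUMNS if c.startswith("fa_"))

#: Numeric columns (all but the subject identifier).
NUMERIC_COLUMNS: tuple[str, ...] = tuple(c for c in COLUMNS if c != "subject_id")

#: Tract sets used by the link analyses (X blocks).
TRACT_SETS: dict[str, tuple[str, str]] = {
    "arcuate": ("fa_arcuate_L", "fa_arcuate_R"),
    "cst": ("fa_cst_L", "fa_cst_R"),
    "slf": ("fa_slf_L", "fa_slf_R"),
}

_SEX_TOKENS = {"m": 0, "male": 0, "0": 0, "f": 1, "female": 1, "1": 1}


def _parse_sex(values: pd.Series) -> pd.Series:
    """Map M/F/0/1 tokens (1 = female) to an integer 0/1 column."""
    out = np.empty(len(values), dtype=np.int64)
    for i, v in enumerate(values):
        token = str(v).strip().lower()
        if token.endswith(".0"):  # numeric column read as float
            token = token[:-2]
        if token not in _SEX_TOKENS:
            raise ParseError(
                f"row {i}: cannot interpret sex value {v!r} (accepted: M/F/0/1)"
            )
        out[i] = _SEX_TOKENS[token]
    return pd.Series(out, index=values.index, name="sex")


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Check every cohort invariant; return the table in canonical column order.

    Raises
    ------
    SchemaError
        if a required column is missing.
    CohortValidationError
        if any invariant fails (the message lists offending rows).
    """
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    table = table.loc[:, list(COLUMNS)].reset_index(drop=True)
    problems: list[str] = []

    na_rows = table.index[table.isna().any(axis=1)].tolist()
    if na_rows:
        problems.append(f"missing values in rows {na_rows}")

    dup = table["subject_id"].astype(str)
    dup_rows = table.index[dup.duplicated(keep=False)].tolist()
    if dup_rows:
        problems.append(f"duplicate subject_id in rows {dup_rows}")

    fa = table[list(FA_COLUMNS)].to_numpy(dtype=float)
    bad_fa = np.where(~((fa > 0.0) & (fa < 1.0)))
    if bad_fa[0].size:
        rows = sorted(set(int(r) for r in bad_fa[0]))
        problems.append(f"FA in (0,1) violated in rows {rows}")

    ga = table["ga_birth"].to_numpy(dtype=float)
    pma = table["pma_scan"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad_age = np.where(pma < ga)[0].tolist()
    if bad_age:
        problems.append(f"pma_scan < ga_birth in rows {bad_age}")

    sex = table["sex"].to_numpy()
    bad_sex = np.where(~np.isin(sex, (0, 1)))[0].tolist()
    if bad_sex:
        problems.append(f"sex not coded 0/1 in rows {bad_sex}")

    if problems:
        raise CohortValidationError("; ".join(problems))

    out = table.copy()
    out["subject_id"] = out["subject_id"].astype(str)
    out["sex"] = out["sex"].astype(np.int64)
    for col in NUMERIC_COLUMNS:
        if col != "sex":
            out[col] = out[col].astype(float)
    return out


def read_cohort(path: str | Path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a cohort table from a TSV/CSV file.

    Parameters
    ----------
    path
        File with a header row; the delimiter is inferred from the extension
        (``.csv`` → comma, anything else → tab).
    schema
        Optional mapping ``{canonical_name: column_name_in_file}`` for files
        whose headers differ from the canonical schema.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, dtype=str)

    if schema:
        rename = {v: k for k, v in schema.items()}
        raw = raw.rename(columns=rename)

    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    extra = [c for c in raw.columns if c not in COLUMNS]
    if extra:
        logger.info("%s: ignoring extra column(s): %s", path.name, ", ".join(extra))

    out = pd.DataFrame({"subject_id": raw["subject_id"].astype(str)})
    out["sex"] = _parse_sex(raw["sex"])
    for col in NUMERIC_COLUMNS:
        if col == "sex":
            continue
        try:
            # astype parses with full precision (to_numeric does not round-trip)
            out[col] = raw[col].astype(float)
        except (ValueError, TypeError):
            converted = pd.to_numeric(raw[col], errors="coerce")
            bad = converted.isna() & raw[col].notna()
            idx = bad.idxmax()
            raise ParseError(
                f"{path.name}: non-numeric value {raw[col][idx]!r} in column "
                f"{col!r}, row {int(idx)}"
            ) from None

    return validate_cohort(out)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a validated cohort as TSV in canonical column order.

    Floats are written with 17 significant digits so that
    ``read_cohort(write_cohort(x)) == x`` exactly and a second
    write → read → write cycle is byte-identical.
    """
    cohort = validate_cohort(cohort)
    path = Path(path)
    cohort.to_csv(path, sep="\t", index=False, float_format="%.17g")


def cohort_to_json(cohort: pd.DataFrame, path: str | Path | None = None) -> str:
    """Serialize a validated cohort to JSON (records orientation) for provenance."""
    cohort = validate_cohort(cohort)
    text = json.dumps(
        {
            "columns": list(COLUMNS),
            "n": int(len(cohort)),
            "records": cohort.to_dict(orient="records"),
        },
        indent=2,
        default=float,
    )
    if path is not None:
        Path(path).write_text(text)
    return text
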