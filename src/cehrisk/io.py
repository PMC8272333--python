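"""Cohort TSV reading/writing, validation and genotype annotation.

The cohort dialect is one row per individual::

    sample_id  status  sex  mhc_h1  mhc_h2  d1_h1  d1_h2  d2_h1  d2_h2  d3_h1  d3_h2

tab-separated with a header row; ``status`` in {case, control}, ``sex`` in
{F, M, U}; MHC columns hold haplotype labels or group codes; the non-MHC
columns hold the per-locus haplotype labels ("risk"/"0" for simulated data).
The cohort carries phased labels, but every analysis operates on classified
groups and per-locus risk-copy counts — :func:`annotate_cohort` adds those.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import CEHCatalog, MHCGroup, NONMHC_LOCI, classify_haplotype, make_genotype, risk_category
from .errors import CohortValidationError

__all__ = [
    "COHORT_COLUMNS",
    "STATUS_CODES",
    "SEX_CODES",
    "validate_cohort",
    "read_cohort",
    "write_cohort",
    "annotate_cohort",
]

logger = logging.getLogger(__name__)

COHORT_COLUMNS = [
    "sample_id",
    "status",
    "sex",
    "mhc_h1",
    "mhc_h2",
    "d1_h1",
    "d1_h2",
    "d2_h1",
    "d2_h2",
    "d3_h1",
    "d3_h2",
]

STATUS_CODES = frozenset({"case", "control"})
SEX_CODES = frozenset({"F", "M", "U"})


def _bad_lines(mask: pd.Series, source: str, what: str, values: pd.Series) -> CohortValidationError:
    # +2: header line plus 1-based numbering
    lines = [f"line {i + 2}: {values.iloc[i]!r}" for i in np.flatnonzero(mask.to_numpy())[:5]]
    more = int(mask.sum()) - len(lines)
    suffix = f" (+{more} more)" if more > 0 else ""
    return CohortValidationError(f"{source}: invalid {what}: " + "; ".join(lines) + suffix)


def validate_cohort(df: pd.DataFrame, source: str = "<cohort>") -> pd.DataFrame:
    """Validate column layout and codes; returns the (unchanged) frame."""
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{source}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    if extra:
        raise CohortValidationError(f"{source}: unexpected column(s) {extra}")

    bad_status = ~df["status"].isin(STATUS_CODES)
    if bad_status.any():
        raise _bad_lines(bad_status, source, "status code", df["status"])
    bad_sex = ~df["sex"].isin(SEX_CODES)
    if bad_sex.any():
        raise _bad_lines(bad_sex, source, "sex code", df["sex"])
    dup = df["sample_id"].duplicated(keep=False)
    if dup.any():
        raise _bad_lines(dup, source, "duplicate sample_id", df["sample_id"])
    hap_cols = COHORT_COLUMNS[3:]
    for col in hap_cols:
        empty = df[col].isna() | (df[col].astype(str).str.len() == 0)
        if empty.any():
            raise _bad_lines(empty, source, f"empty {col} label", df[col])
    return df


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort TSV.

    A file holding only the header yields an empty cohort (with a logged
    warning); malformed codes raise :class:`CohortValidationError` naming
    the offending line.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])
    validate_cohort(df, source=str(path))
    if len(df) == 0:
        logger.warning("%s: cohort file contains a header but no records", path)
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort TSV (LF line endings, dot decimals, fixed columns)."""
    validate_cohort(df)
    df.to_csv(path, sep="\t", index=False, columns=COHORT_COLUMNS, lineterminator="\n")


def annotate_cohort(df: pd.DataFrame, catalog: CEHCatalog) -> pd.DataFrame:
    """Classify a validated cohort against a catalog.

    Returns a copy with the analysis columns appended:

    * ``g1``/``g2`` — canonically ordered MHC group values (ints);
    * ``mhc_genotype`` — display code, e.g. ``"(0,H+)"``;
    * ``d1``/``d2``/``d3`` — per-locus risk-copy counts (0/1/2);
    * ``risk_category`` — collapsed single/double-copy category.
    """
    validate_cohort(df)
    out = df.copy()

    labels = pd.unique(pd.concat([df["mhc_h1"], df["mhc_h2"]], ignore_index=True))
    group_of = {lbl: int(classify_haplotype(lbl, catalog)) for lbl in labels}
    a = df["mhc_h1"].map(group_of).to_numpy(dtype=np.int8)
    b = df["mhc_h2"].map(group_of).to_numpy(dtype=np.int8)
    g1, g2 = np.minimum(a, b), np.maximum(a, b)
    out["g1"], out["g2"] = g1, g2

    code_of = {
        (i, j): make_genotype(MHCGroup(i), MHCGroup(j)).code for i in range(5) for j in range(i, 5)
    }
    cat_of = {
        (i, j): risk_category(make_genotype(MHCGroup(i), MHCGroup(j))).value
        for i in range(5)
        for j in range(i, 5)
    }
    pairs = pd.Series(zip(g1.tolist(), g2.tolist()), index=out.index)
    out["mhc_genotype"] = pairs.map(code_of)
    out["risk_category"] = pairs.map(cat_of)

    for locus in NONMHC_LOCI:
        risky = catalog.nonmhc_risk_labels[locus]
        k = df[f"{locus}_h1"].isin(risky).to_numpy(dtype=np.int8) + df[f"{locus}_h2"].isin(
            risky
        ).to_numpy(dtype=np.int8)
        out[locus] = k
    return out
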