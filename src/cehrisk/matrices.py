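"""The two headline matrix analyses plus the stratified OR tables.

* :func:`combination_matrix` — for every MHC genotype column and every
  non-MHC risk-copy combination row, the ln(OR) of that combination versus
  the zero-copy reference *within the same MHC stratum*, so each cell
  isolates what the non-MHC copies add on top of a fixed MHC background.
* :func:`transition_matrix` — the effect of replacing one MHC haplotype by
  another under different companion haplotypes.  A replacement OR is simply
  the case-control OR between the two genotypes, ``OR(C, X->Y) =
  OR((C,Y) vs (C,X))``; a cell holds the ln-ratio of the same replacement
  under two companions.  Because genotypes are unordered, each cell has two
  mathematically equivalent readings (swap which pair is called the
  replacement and which the companions) and the implementation checks they
  agree to machine precision.
* :func:`mhc_genotype_ors` / :func:`risk_combination_ors` — per-genotype
  and per-risk-category OR tables (optionally sex-stratified) against the
  (0,0) reference.

If haplotype effects combined multiplicatively with no interactions, every
transition cell would be ~0; the matrix is the package's direct picture of
MHC haplotype-haplotype interaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import (
    DEFAULT_MIN_MARGINAL,
    ContingencyTable,
    ORComparison,
    ORResult,
    bh_adjust,
    compare_ors,
    odds_ratio,
)
from .catalog import (
    CEHCatalog,
    MHCGenotype,
    MHCGroup,
    NONMHC_LOCI,
    RiskCategory,
    all_genotypes,
    make_genotype,
)
from .errors import DegenerateTableError
from .io import annotate_cohort

__all__ = [
    "CombinationMatrix",
    "TransitionMatrix",
    "RiskCombinationResult",
    "mhc_genotype_ors",
    "risk_combination_ors",
    "combination_matrix",
    "transition_matrix",
    "z_band",
    "genotype_copy_counts",
]

_GENOTYPES = all_genotypes()
_GENO_INDEX = {(int(g.g1), int(g.g2)): i for i, g in enumerate(_GENOTYPES)}


def genotype_copy_counts(ann: pd.DataFrame) -> np.ndarray:
    """Count individuals into a ``(status, mhc_genotype, d1, d2, d3)`` array.

    ``ann`` is an annotated cohort; axis 0 is 0=control, 1=case; axis 1 the
    15 MHC genotypes in display order; axes 2-4 the risk-copy counts.
    """
    geno = np.array(
        [_GENO_INDEX[(a, b)] for a, b in zip(ann["g1"].tolist(), ann["g2"].tolist())],
        dtype=np.int64,
    )
    is_case = (ann["status"] == "case").to_numpy().astype(np.int64)
    idx = (
        (((is_case * 15 + geno) * 3 + ann["d1"].to_numpy()) * 3 + ann["d2"].to_numpy()) * 3
        + ann["d3"].to_numpy()
    )
    counts = np.bincount(idx, minlength=2 * 15 * 27)
    return counts.reshape(2, 15, 3, 3, 3)


def _cell(counts: np.ndarray, geno_idx: int, fixed: dict[int, int]) -> tuple[int, int]:
    """(cases, controls) for one MHC genotype with copy counts fixed at the
    loci in ``fixed`` (locus axis -> copies) and summed over the rest."""
    sub = counts[:, geno_idx]
    index: list = [slice(None)] * 4
    index[0] = slice(None)
    for axis, k in fixed.items():
        index[1 + axis] = k
    sel = sub[tuple(index)]
    return int(np.sum(sel[1])), int(np.sum(sel[0]))


def _observed_genotypes(counts: np.ndarray) -> list[int]:
    totals = counts.sum(axis=(0, 2, 3, 4))
    return [i for i in range(15) if totals[i] > 0]


def _or_row(result: ORResult, p_key: str = "p_value") -> dict:
    return {
        "or": result.or_value,
        "ln_or": result.ln_or,
        "se_ln_or": result.se_ln_or,
        "ci_low": result.ci_low,
        "ci_high": result.ci_high,
        p_key: result.p_value,
        "n_exposed": result.n_exposed,
        "n_reference": result.n_reference,
        "na": result.na_flag,
        "corrected": result.corrected,
    }


def _identity_or(n: int) -> dict:
    return {
        "or": 1.0, "ln_or": 0.0, "se_ln_or": 0.0, "ci_low": 1.0, "ci_high": 1.0,
        "p_value": 1.0, "n_exposed": n, "n_reference": n, "na": False, "corrected": False,
    }


def mhc_genotype_ors(
    cohort: pd.DataFrame,
    catalog: CEHCatalog,
    reference: MHCGenotype | None = None,
    level: float = 0.95,
    min_marginal: int = DEFAULT_MIN_MARGINAL,
    zero_correction: bool = False,
) -> pd.DataFrame:
    """OR of every observed MHC genotype versus a reference genotype
    (default (0,0)), marginal over the non-MHC loci, with a BH-adjusted
    p column (the table is one comparison family)."""
    if reference is None:
        reference = make_genotype(MHCGroup.NEUTRAL, MHCGroup.NEUTRAL)
    ann = annotate_cohort(cohort, catalog)
    counts = genotype_copy_counts(ann)
    ref_idx = _GENO_INDEX[(int(reference.g1), int(reference.g2))]
    ref_cases, ref_controls = _cell(counts, ref_idx, {})
    if ref_cases + ref_controls == 0:
        raise DegenerateTableError(f"reference genotype {reference.code} absent from cohort")

    rows = []
    for gi in _observed_genotypes(counts):
        g = _GENOTYPES[gi]
        if gi == ref_idx:
            rows.append({"mhc_genotype": g.code} | _identity_or(ref_cases + ref_controls))
            continue
        cases, controls = _cell(counts, gi, {})
        try:
            res = odds_ratio(
                ContingencyTable(cases, controls, ref_cases, ref_controls),
                level=level,
                zero_correction=zero_correction,
                min_marginal=min_marginal,
            )
            rows.append({"mhc_genotype": g.code} | _or_row(res))
        except DegenerateTableError:
            rows.append(
                {"mhc_genotype": g.code, "or": np.nan, "ln_or": np.nan, "se_ln_or": np.nan,
                 "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan,
                 "n_exposed": cases + controls, "n_reference": ref_cases + ref_controls,
                 "na": True, "corrected": False}
            )
    out = pd.DataFrame(rows)
    ok = out["p_value"].notna() & (out["mhc_genotype"] != reference.code)
    adj = np.full(len(out), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = bh_adjust(out.loc[ok, "p_value"].to_numpy())
    out["p_bh"] = adj
    return out


@dataclass(frozen=True)
class RiskCombinationResult:
    """Per-risk-category OR table and, when sex-stratified, the z comparison
    of the female vs male single-copy-risk ORs."""

    table: pd.DataFrame
    sex_comparison_single_copy_risk: ORComparison | None = None


def risk_combination_ors(
    cohort: pd.DataFrame,
    catalog: CEHCatalog,
    by_sex: bool = False,
    level: float = 0.95,
    min_marginal: int = DEFAULT_MIN_MARGINAL,
    zero_correction: bool = False,
) -> RiskCombinationResult:
    """ORs of each collapsed risk category versus the (0,0) genotype.

    The reference is the (0,0) MHC genotype itself (not the whole neutral
    category, which also holds (0,c1)).  With ``by_sex``, each category is
    additionally estimated within women and men and the female vs male
    single-copy-risk ORs are compared by z-score.
    """
    ann = annotate_cohort(cohort, catalog)
    ref_code = make_genotype(MHCGroup.NEUTRAL, MHCGroup.NEUTRAL).code
    is_ref = (ann["mhc_genotype"] == ref_code).to_numpy()
    strata = [("all", np.ones(len(ann), dtype=bool))]
    if by_sex:
        strata += [(s, (ann["sex"] == s).to_numpy()) for s in ("F", "M")]

    rows = []
    per_sex_scr: dict[str, ORResult] = {}
    for sex, s_mask in strata:
        ref_cases = int((is_ref & s_mask & (ann["status"] == "case")).sum())
        ref_controls = int((is_ref & s_mask & (ann["status"] == "control")).sum())
        for cat in RiskCategory:
            exp_mask = (ann["risk_category"] == cat.value).to_numpy() & s_mask & ~is_ref
            cases = int((exp_mask & (ann["status"] == "case")).sum())
            controls = int((exp_mask & (ann["status"] == "control")).sum())
            if cases + controls == 0 and cat is not RiskCategory.NEUTRAL:
                continue
            base = {"risk_category": cat.value, "sex": sex}
            try:
                res = odds_ratio(
                    ContingencyTable(cases, controls, ref_cases, ref_controls),
                    level=level,
                    zero_correction=zero_correction,
                    min_marginal=min_marginal,
                )
                rows.append(base | _or_row(res))
                if cat is RiskCategory.SINGLE_COPY_RISK and sex in ("F", "M"):
                    per_sex_scr[sex] = res
            except DegenerateTableError:
                rows.append(
                    base | {"or": np.nan, "ln_or": np.nan, "se_ln_or": np.nan,
                            "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan,
                            "n_exposed": cases + controls,
                            "n_reference": ref_cases + ref_controls,
                            "na": True, "corrected": False}
                )
    comparison = None
    if "F" in per_sex_scr and "M" in per_sex_scr:
        comparison = compare_ors(per_sex_scr["F"], per_sex_scr["M"])
    return RiskCombinationResult(table=pd.DataFrame(rows), sex_comparison_single_copy_risk=comparison)


def z_band(z: float) -> int:
    """Ordinal shading band from |z|: 0 (<1), 1 (1-2), 2 (2-3), 3 (3-4),
    4 (>=4)."""
    az = abs(z)
    return 4 if az >= 4 else int(az)


_COPY_VECTORS = [v for v in product(range(3), repeat=3) if v != (0, 0, 0)]


def _combination_label(copies: Sequence[int]) -> str:
    parts = [f"{locus}={k}" for locus, k in zip(NONMHC_LOCI, copies) if k > 0]
    return ",".join(parts) if parts else "none"


@dataclass(frozen=True)
class CombinationMatrix:
    """Long-format cell table of the MHC x non-MHC combination analysis.

    ``cells`` columns: column_genotype, row_combination, d1/d2/d3, ln_or, z,
    p, p_bh, n_exposed, n_reference, na, band.  Each cell's OR is computed
    within its column's MHC stratum against that stratum's zero-copy
    reference at the loci involved, so cells are invariant to individuals
    outside the stratum.
    """

    cells: pd.DataFrame
    min_marginal: int = DEFAULT_MIN_MARGINAL
    strict_reference: bool = False

    def to_frame(self) -> pd.DataFrame:
        return self.cells.copy()

    def pivot(self, value: str = "ln_or") -> pd.DataFrame:
        return self.cells.pivot(index="row_combination", columns="column_genotype", values=value)


def combination_matrix(
    cohort: pd.DataFrame,
    catalog: CEHCatalog,
    min_marginal: int = DEFAULT_MIN_MARGINAL,
    level: float = 0.95,
    strict_reference: bool = False,
    bh_per_column: bool = False,
    zero_correction: bool = False,
) -> CombinationMatrix:
    """Build the MHC-stratified non-MHC combination matrix.

    Columns are the observed MHC genotypes in increasing-risk order; rows
    are risk-copy combinations over the three non-MHC loci.  A cell's
    exposed group carries the row's copy counts at the loci involved (loci
    with zero copies in the row are unconstrained); its reference carries
    zero copies at those same loci and the same MHC genotype.  With
    ``strict_reference`` both groups are pinned at all three loci (the
    reference to (0,0,0)).  z tests ln(OR) against 0; the BH family is the
    whole matrix unless ``bh_per_column``.
    """
    ann = annotate_cohort(cohort, catalog)
    counts = genotype_copy_counts(ann)

    rows = []
    for gi in _observed_genotypes(counts):
        g = _GENOTYPES[gi]
        for copies in _COPY_VECTORS:
            involved = [j for j in range(3) if copies[j] > 0]
            if strict_reference:
                exp_fixed = {j: copies[j] for j in range(3)}
                ref_fixed = {j: 0 for j in range(3)}
            else:
                exp_fixed = {j: copies[j] for j in involved}
                ref_fixed = {j: 0 for j in involved}
            cases, controls = _cell(counts, gi, exp_fixed)
            ref_cases, ref_controls = _cell(counts, gi, ref_fixed)
            base = {
                "column_genotype": g.code,
                "row_combination": _combination_label(copies),
                "d1": copies[0], "d2": copies[1], "d3": copies[2],
                "n_exposed": cases + controls,
                "n_reference": ref_cases + ref_controls,
            }
            try:
                res = odds_ratio(
                    ContingencyTable(cases, controls, ref_cases, ref_controls),
                    level=level,
                    zero_correction=zero_correction,
                    min_marginal=min_marginal,
                )
                z = res.ln_or / res.se_ln_or if res.se_ln_or > 0 else 0.0
                rows.append(
                    base
                    | {
                        "ln_or": res.ln_or,
                        "se_ln_or": res.se_ln_or,
                        "z": z,
                        "p": float(2 * stats.norm.sf(abs(z))),
                        "na": res.na_flag,
                        "band": z_band(z),
                        "corrected": res.corrected,
                    }
                )
            except DegenerateTableError:
                rows.append(
                    base | {"ln_or": np.nan, "se_ln_or": np.nan, "z": np.nan, "p": np.nan,
                            "na": True, "band": None, "corrected": False}
                )
    cells = pd.DataFrame(rows)
    ok = cells["p"].notna() & ~cells["na"]
    adj = np.full(len(cells), np.nan)
    if bh_per_column:
        for col in cells["column_genotype"].unique():
            m = (ok & (cells["column_genotype"] == col)).to_numpy()
            if m.any():
                adj[m] = bh_adjust(cells.loc[m, "p"].to_numpy())
    elif ok.any():
        adj[ok.to_numpy()] = bh_adjust(cells.loc[ok, "p"].to_numpy())
    cells["p_bh"] = adj
    return CombinationMatrix(cells=cells, min_marginal=min_marginal, strict_reference=strict_reference)


@dataclass(frozen=True)
class TransitionMatrix:
    """Lower-triangular ln-ratio matrix of haplotype replacement ORs.

    ``transitions`` lists the (source, target) group pairs indexing both
    axes; ``cells`` holds one row per populated (row > column) pair with the
    ln-ratio, its z-score and shading band; ``transition_ors`` maps
    ``(companion, source, target)`` codes to the underlying replacement
    :class:`~cehrisk.association.ORResult`.
    """

    groups: tuple[MHCGroup, ...]
    transitions: tuple[tuple[MHCGroup, MHCGroup], ...]
    cells: pd.DataFrame
    transition_ors: dict[tuple[str, str, str], ORResult] = field(repr=False, default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return self.cells.copy()

    def pivot(self, value: str = "ln_ratio") -> pd.DataFrame:
        return self.cells.pivot(index="row_transition", columns="column_transition", values=value)


def transition_matrix(
    cohort: pd.DataFrame,
    catalog: CEHCatalog,
    groups: Sequence[MHCGroup] | None = None,
    min_marginal: int = DEFAULT_MIN_MARGINAL,
    level: float = 0.95,
    zero_correction: bool = False,
) -> TransitionMatrix:
    """Build the haplotype-replacement transition matrix.

    For companions C and transitions X->Y (X before Y in the risk order),
    the replacement OR is ``OR((C,Y) vs (C,X))``.  The cell at column
    (a->b), row (c->d) is ``ln[OR(c, a->b) / OR(d, a->b)]``, which by the
    unordered-genotype identity equals ``ln[OR(a, c->d) / OR(b, c->d)]`` —
    both readings are computed and must agree to machine precision (checked
    whenever no zero-cell correction was applied).  z comes from the
    log-scale comparison of the two replacement ORs; cells touching a
    genotype rarer than ``min_marginal`` or a zero cell (without
    correction) are na.
    """
    if groups is None:
        groups = tuple(MHCGroup)
    groups = tuple(groups)
    if len(groups) < 2:
        raise ValueError("need at least two haplotype groups")
    transitions = tuple(
        (groups[i], groups[j]) for i in range(len(groups)) for j in range(i + 1, len(groups))
    )
    ann = annotate_cohort(cohort, catalog)
    counts = genotype_copy_counts(ann)
    geno_cases = counts[1].sum(axis=(1, 2, 3))
    geno_controls = counts[0].sum(axis=(1, 2, 3))

    def geno_counts(x: MHCGroup, y: MHCGroup) -> tuple[int, int]:
        gi = _GENO_INDEX[(min(int(x), int(y)), max(int(x), int(y)))]
        return int(geno_cases[gi]), int(geno_controls[gi])

    or_cache: dict[tuple[str, str, str], ORResult] = {}

    def replacement_or(companion: MHCGroup, src: MHCGroup, tgt: MHCGroup) -> ORResult | None:
        key = (companion.code, src.code, tgt.code)
        if key in or_cache:
            return or_cache[key]
        exp_cases, exp_controls = geno_counts(companion, tgt)
        ref_cases, ref_controls = geno_counts(companion, src)
        try:
            res = odds_ratio(
                ContingencyTable(exp_cases, exp_controls, ref_cases, ref_controls),
                level=level,
                zero_correction=zero_correction,
                min_marginal=min_marginal,
            )
        except DegenerateTableError:
            res = None
        or_cache[key] = res
        return res

    rows = []
    for ci, (a, b) in enumerate(transitions):
        for ri, (c, d) in enumerate(transitions):
            if ri <= ci:
                continue
            base = {
                "column_transition": f"{a.code}->{b.code}",
                "row_transition": f"{c.code}->{d.code}",
            }
            num = replacement_or(c, a, b)
            den = replacement_or(d, a, b)
            genos = [geno_counts(x, y) for x, y in ((c, a), (c, b), (d, a), (d, b))]
            sparse = any(sum(gc) < min_marginal for gc in genos)
            if num is None or den is None or sparse:
                rows.append(base | {"ln_ratio": np.nan, "z": np.nan, "p": np.nan,
                                    "na": True, "band": None})
                continue
            ln_ratio = num.ln_or - den.ln_or
            alt_num = replacement_or(a, c, d)
            alt_den = replacement_or(b, c, d)
            if (
                alt_num is not None
                and alt_den is not None
                and not any(r.corrected for r in (num, den, alt_num, alt_den))
            ):
                alt = alt_num.ln_or - alt_den.ln_or
                if not math.isclose(ln_ratio, alt, rel_tol=1e-12, abs_tol=1e-12):
                    raise AssertionError(
                        "transition two-reading identity violated: "
                        f"{ln_ratio!r} vs {alt!r} for {base}"
                    )
            cmp = compare_ors(num, den)
            rows.append(
                base
                | {"ln_ratio": ln_ratio, "z": cmp.z, "p": cmp.p, "na": False,
                   "band": z_band(cmp.z)}
            )
    cells = pd.DataFrame(rows)
    return TransitionMatrix(
        groups=groups,
        transitions=transitions,
        cells=cells,
        transition_ors={k: v for k, v in or_cache.items() if v is not None},
    )
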