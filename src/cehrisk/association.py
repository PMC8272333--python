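"""Case-control association statistics.

The statistical engine behind every table and matrix in the package:

* 2x2 odds ratios with Woolf (log-scale) standard errors and Wald
  confidence intervals;
* the z-score comparison of two odds ratios,
  ``z = [ln(OR1) - ln(OR2)] / sqrt(SE1^2 + SE2^2)``;
* re-referencing of ORs through a shared intermediate reference group
  (a chain rule: cross-products over the common reference cancel, so
  pairwise comparisons are independent of the reference chosen);
* Benjamini-Hochberg step-up adjustment;
* an asymptotic Hardy-Weinberg chi-square test for k-allele unordered
  genotype counts.

Odds ratios are used throughout as relative-risk estimates under the
rare-disease assumption (population prevalence ~0.003, where OR and RR are
nearly identical).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateTableError

__all__ = [
    "ContingencyTable",
    "ORResult",
    "ORComparison",
    "HWEResult",
    "build_table",
    "odds_ratio",
    "se_from_ci",
    "compare_ors",
    "ln_or_ratio",
    "rereference",
    "invert_or",
    "bh_adjust",
    "hwe_test",
    "DEFAULT_MIN_MARGINAL",
]

#: Cells with an exposed marginal below this are flagged "na" in figures.
DEFAULT_MIN_MARGINAL = 15


@dataclass(frozen=True)
class ContingencyTable:
    """A 2x2 case-control table.

    ``a``/``b`` are exposed cases/controls, ``c``/``d`` unexposed
    (reference) cases/controls.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")

    @property
    def n_exposed(self) -> int:
        return self.a + self.b

    @property
    def n_reference(self) -> int:
        return self.c + self.d

    @property
    def total(self) -> int:
        return self.n_exposed + self.n_reference

    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


@dataclass(frozen=True)
class ORResult:
    """An odds ratio with log-scale uncertainty and marginal counts."""

    or_value: float
    ln_or: float
    se_ln_or: float
    ci_low: float
    ci_high: float
    p_value: float
    n_exposed: int
    n_reference: int
    na_flag: bool = False
    corrected: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_value <= self.ci_high):
            raise ValueError("CI must bracket the OR")


@dataclass(frozen=True)
class ORComparison:
    """z-score comparison of two odds ratios on the log scale."""

    z: float
    p: float
    ln_ratio: float


@dataclass(frozen=True)
class HWEResult:
    """Hardy-Weinberg goodness-of-fit result."""

    chi2: float
    df: int
    p: float
    n: int
    pooled: bool = False


def build_table(
    cohort: pd.DataFrame,
    exposed: "pd.Series | Callable[[pd.DataFrame], pd.Series]",
    reference: "pd.Series | Callable[[pd.DataFrame], pd.Series]",
    strata: "pd.Series | Callable[[pd.DataFrame], pd.Series] | None" = None,
) -> ContingencyTable:
    """Count a 2x2 table from a cohort.

    ``exposed`` and ``reference`` are boolean masks (or callables producing
    masks) over the cohort rows; they must be disjoint.  An optional
    ``strata`` mask restricts the count to a subgroup first.
    """
    exp_mask = exposed(cohort) if callable(exposed) else exposed
    ref_mask = reference(cohort) if callable(reference) else reference
    exp_mask = np.asarray(exp_mask, dtype=bool)
    ref_mask = np.asarray(ref_mask, dtype=bool)
    if (exp_mask & ref_mask).any():
        raise ValueError("exposed and reference predicates overlap on the cohort")
    if strata is not None:
        s_mask = strata(cohort) if callable(strata) else strata
        s_mask = np.asarray(s_mask, dtype=bool)
        exp_mask = exp_mask & s_mask
        ref_mask = ref_mask & s_mask
    if not ref_mask.any():
        raise DegenerateTableError("reference predicate selects no individuals")
    is_case = (cohort["status"] == "case").to_numpy()
    return ContingencyTable(
        a=int((exp_mask & is_case).sum()),
        b=int((exp_mask & ~is_case).sum()),
        c=int((ref_mask & is_case).sum()),
        d=int((ref_mask & ~is_case).sum()),
    )


def odds_ratio(
    t: ContingencyTable,
    level: float = 0.95,
    zero_correction: bool = False,
    min_marginal: int = DEFAULT_MIN_MARGINAL,
) -> ORResult:
    """Woolf odds ratio with Wald confidence interval.

    ``OR = ad / bc``; ``SE[ln OR] = sqrt(1/a + 1/b + 1/c + 1/d)``.  With
    ``zero_correction`` on, a zero anywhere adds 0.5 to every cell
    (Haldane-Anscombe) and flags the result as ``corrected``; with it off a
    zero cell raises :class:`DegenerateTableError`.
    """
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    a, b, c, d = (float(x) for x in (t.a, t.b, t.c, t.d))
    corrected = False
    if t.has_zero_cell():
        if not zero_correction:
            raise DegenerateTableError(
                f"zero cell in table (a={t.a}, b={t.b}, c={t.c}, d={t.d}) "
                "with zero_correction off"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_value = (a * d) / (b * c)
    ln_or = math.log(or_value)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z_level = stats.norm.ppf(0.5 + level / 2)
    p = 2 * stats.norm.sf(abs(ln_or) / se)
    return ORResult(
        or_value=or_value,
        ln_or=ln_or,
        se_ln_or=se,
        ci_low=math.exp(ln_or - z_level * se),
        ci_high=math.exp(ln_or + z_level * se),
        p_value=float(p),
        n_exposed=t.n_exposed,
        n_reference=t.n_reference,
        na_flag=t.n_exposed < min_marginal,
        corrected=corrected,
    )


def se_from_ci(ci_low: float, ci_high: float, level: float = 0.95) -> float:
    """Recover the log-scale SE from a printed confidence interval.

    ``(ln(hi) - ln(lo)) / (2 z)`` — the plumbing needed to compare published
    ORs given only their CIs.
    """
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    if not 0 < ci_low <= ci_high:
        raise ValueError(f"CI bounds must satisfy 0 < low <= high, got ({ci_low}, {ci_high})")
    z_level = stats.norm.ppf(0.5 + level / 2)
    return (math.log(ci_high) - math.log(ci_low)) / (2 * z_level)


def compare_ors(r1: ORResult, r2: ORResult) -> ORComparison:
    """z-score for the difference of two ORs on the natural-log scale.

    Antisymmetric in its arguments; invariant under joint re-referencing of
    both ORs (the shared reference cancels from the ratio).
    """
    if r1.se_ln_or <= 0 or r2.se_ln_or <= 0:
        raise ValueError("both ORs must carry positive log-scale SEs")
    ln_ratio = r1.ln_or - r2.ln_or
    z = ln_ratio / math.sqrt(r1.se_ln_or**2 + r2.se_ln_or**2)
    return ORComparison(z=z, p=float(2 * stats.norm.sf(abs(z))), ln_ratio=ln_ratio)


def ln_or_ratio(or1: float, or2: float) -> float:
    """``ln(OR1 / OR2)`` for two positive odds ratios."""
    if or1 <= 0 or or2 <= 0:
        raise ValueError("odds ratios must be positive")
    return math.log(or1) - math.log(or2)


def rereference(or_a_vs_b: float, or_b_vs_c: float) -> float:
    """Chain two ORs through a shared intermediate reference:
    ``OR(a vs c) = OR(a vs b) * OR(b vs c)`` (cross-products over the common
    group cancel exactly)."""
    if or_a_vs_b <= 0 or or_b_vs_c <= 0:
        raise ValueError("odds ratios must be positive")
    return or_a_vs_b * or_b_vs_c


def invert_or(or_a_vs_b: float) -> float:
    """Swap exposure and reference: ``OR(b vs a) = 1 / OR(a vs b)``."""
    if or_a_vs_b <= 0:
        raise ValueError("odds ratio must be positive")
    return 1.0 / or_a_vs_b


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Clipped at 1, monotone in rank, input order preserved.  One call spans
    one family of comparisons (by default, one matrix or table = one family).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hwe_test(
    genotype_counts: "Mapping[tuple[Hashable, Hashable], int] | Sequence[int]",
    min_expected: float = 1.0,
) -> HWEResult:
    """Asymptotic Hardy-Weinberg chi-square test on unordered genotype counts.

    Accepts either a mapping ``{(allele_i, allele_j): count}`` over unordered
    genotypes (e.g. the 15 MHC group pairs) or a 3-sequence
    ``(n_AA, n_Aa, n_aa)`` for a biallelic locus.  Haplotype frequencies are
    estimated by allele counting; expected counts are ``n p_i^2`` and
    ``2 n p_i p_j``; df = #genotype cells - #alleles.  Cells with expected
    count below ``min_expected`` are pooled into one cell (df reduced, result
    flagged ``pooled``).
    """
    if not isinstance(genotype_counts, Mapping):
        seq = list(genotype_counts)
        if len(seq) != 3:
            raise ValueError("sequence form must be (n_AA, n_Aa, n_aa)")
        genotype_counts = {("A", "A"): seq[0], ("A", "a"): seq[1], ("a", "a"): seq[2]}

    counts: dict[tuple[Hashable, Hashable], int] = {}
    for (x, y), n in genotype_counts.items():
        key = (x, y) if str(x) <= str(y) else (y, x)
        counts[key] = counts.get(key, 0) + int(n)
    n_total = sum(counts.values())
    if n_total <= 0:
        raise ValueError("total genotype count must be positive")

    allele_counts: dict[Hashable, int] = {}
    for (x, y), n in counts.items():
        allele_counts[x] = allele_counts.get(x, 0) + n
        allele_counts[y] = allele_counts.get(y, 0) + n
    alleles = sorted(allele_counts, key=str)
    freqs = {al: allele_counts[al] / (2 * n_total) for al in alleles}

    observed, expected = [], []
    for i, x in enumerate(alleles):
        for y in alleles[i:]:
            e = n_total * (freqs[x] ** 2 if x == y else 2 * freqs[x] * freqs[y])
            observed.append(counts.get((x, y), 0))
            expected.append(e)

    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    pooled = False
    small = exp < min_expected
    if small.sum() > 0:
        pooled = True
        keep = ~small
        obs = np.append(obs[keep], obs[small].sum())
        exp = np.append(exp[keep], exp[small].sum())
        # a pooled cell with still-tiny expectation cannot support the test
        if exp[-1] <= 0:
            obs, exp = obs[:-1], exp[:-1]

    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    df = len(obs) - len(alleles)
    if df < 1:
        raise ValueError("not enough genotype cells for a Hardy-Weinberg test")
    return HWEResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)), n=n_total, pooled=pooled)
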