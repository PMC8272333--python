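"""Additive vs multiplicative accumulation of risk across the four loci.

Every combination of an MHC genotype with risk-copy states at the three
non-MHC loci gets three numbers: the relative risk actually observed
(odds ratio versus the lowest-risk (AP,AP) baseline, taken as a relative
risk under the rare-disease assumption), and the risks expected if the
per-component effects combined additively (``1 + sum(R_i - 1)``) or
multiplicatively (``prod R_i``) on the baseline-1 scale.

Component estimation
--------------------
A case-control cohort identifies each component only relative to some
reference, and no single number is simultaneously the component's additive
excess and its multiplicative factor once the reference shifts.  Each
component therefore carries two values, each consistent under its own
composition rule:

* ``rr`` (additive scale) — the component's excess risk on the (AP,AP)
  baseline scale, obtained by re-referencing through the (0,0) genotype and
  subtracting the shared (0,0) background;
* ``rr_multiplicative`` — the within-stratum risk ratio, whose background
  factors cancel.

MHC single-haplotype components are identical on both scales by
construction (the AP companion contributes no excess and a unit factor).
Rows whose observed risk is definitional — the (0,X) genotypes and the
(0,0)-stratum non-MHC combinations that anchor the components — satisfy
both expectations identically and score as ties, so the verdict rests
entirely on genuinely combined genotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .association import ContingencyTable, ORResult, odds_ratio
from .catalog import (
    CEHCatalog,
    MHCGenotype,
    MHCGroup,
    NONMHC_LOCI,
    all_genotypes,
    make_genotype,
)
from .errors import DegenerateTableError
from .io import annotate_cohort
from .matrices import genotype_copy_counts, _cell, _GENO_INDEX, _observed_genotypes

__all__ = [
    "RiskModelConfig",
    "ComponentRisk",
    "ModelEvaluation",
    "component_risks",
    "expected_additive",
    "expected_multiplicative",
    "evaluate_combinations",
]

_GENOTYPES = all_genotypes()


@dataclass(frozen=True)
class RiskModelConfig:
    """Knobs of the model evaluation.

    ``baseline_genotype`` is the reference whose risk defines R_b = 1
    (default (AP,AP), the lowest-risk genotype); ``mhc_route`` picks the
    single-haplotype estimator — "zero" estimates (0,X) vs (0,0) and
    re-references (robust when the (AP,AP) stratum is sparse), "ap"
    estimates (AP,X) vs (AP,AP) directly; ``observed_route`` computes
    combined observed risks either chained through the (0,0) stratum
    ("chained", mirroring how sparse baselines are handled in practice) or
    directly against the baseline ("direct").  Zero-cell correction
    defaults on here: a single empty baseline cell should degrade, not
    void, the evaluation.  Under ``rare_disease_or_as_rr`` ORs are read as
    RRs throughout.
    """

    baseline_genotype: MHCGenotype = field(
        default_factory=lambda: make_genotype(MHCGroup.AP, MHCGroup.AP)
    )
    min_marginal: int = 15
    rare_disease_or_as_rr: bool = True
    mhc_route: str = "zero"
    observed_route: str = "chained"
    level: float = 0.95
    zero_correction: bool = True
    baseline_fallback: bool = True

    def __post_init__(self) -> None:
        if self.min_marginal < 1:
            raise ValueError("min_marginal must be >= 1")
        if self.mhc_route not in ("zero", "ap"):
            raise ValueError("mhc_route must be 'zero' or 'ap'")
        if self.observed_route not in ("chained", "direct"):
            raise ValueError("observed_route must be 'chained' or 'direct'")


@dataclass(frozen=True)
class ComponentRisk:
    """One per-haplotype or per-locus-copy-count risk component.

    ``rr`` is the additive-scale relative risk versus the baseline
    (R_b = 1); ``rr_multiplicative`` the multiplicative-scale factor.  The
    two coincide for MHC haplotypes and for every definitional component.
    """

    component_id: str
    rr: float
    rr_multiplicative: float
    source: str  # "observed-definitional" | "re-referenced"
    n: int

    @property
    def valid(self) -> bool:
        return (
            math.isfinite(self.rr)
            and math.isfinite(self.rr_multiplicative)
            and self.rr > 0
            and self.rr_multiplicative > 0
        )


def expected_additive(components: "list[float] | np.ndarray") -> float:
    """Additive combined relative risk: ``1 + sum(rr_i - 1)``."""
    rr = np.asarray(components, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("component relative risks must be positive")
    return float(1.0 + np.sum(rr - 1.0))


def expected_multiplicative(components: "list[float] | np.ndarray") -> float:
    """Multiplicative combined relative risk: ``prod(rr_i)``."""
    rr = np.asarray(components, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("component relative risks must be positive")
    return float(np.prod(rr))


def _safe_or(
    counts, exp_geno, exp_fixed, ref_geno, ref_fixed, cfg: RiskModelConfig
) -> ORResult | None:
    cases, controls = _cell(counts, exp_geno, exp_fixed)
    ref_cases, ref_controls = _cell(counts, ref_geno, ref_fixed)
    try:
        return odds_ratio(
            ContingencyTable(cases, controls, ref_cases, ref_controls),
            level=cfg.level,
            zero_correction=cfg.zero_correction,
            min_marginal=cfg.min_marginal,
        )
    except DegenerateTableError:
        return None


def _resolve_baseline(counts, cfg: RiskModelConfig) -> MHCGenotype:
    """The working baseline: the configured one, or — when it is rarer than
    ``min_marginal`` and ``baseline_fallback`` is on — the (0,0) genotype,
    the conventional fallback when the protective homozygote is too sparse.
    Verdicts are invariant to this re-referencing for all rows not carrying
    a baseline haplotype."""
    base_idx = _GENO_INDEX[(int(cfg.baseline_genotype.g1), int(cfg.baseline_genotype.g2))]
    base_n = sum(_cell(counts, base_idx, {}))
    if base_n >= cfg.min_marginal:
        return cfg.baseline_genotype
    zero = make_genotype(MHCGroup.NEUTRAL, MHCGroup.NEUTRAL)
    if cfg.baseline_fallback and cfg.baseline_genotype != zero:
        zero_n = sum(_cell(counts, _GENO_INDEX[(1, 1)], {}))
        if zero_n >= cfg.min_marginal:
            return zero
    raise DegenerateTableError(
        f"baseline genotype {cfg.baseline_genotype.code} has only {base_n} "
        f"representations (< {cfg.min_marginal}); use a larger cohort or the "
        "(0,0) fallback baseline"
    )


def _baseline_or(counts, cfg: RiskModelConfig, baseline: MHCGenotype) -> tuple[float, int]:
    """OR of (0,0) versus the working baseline genotype, plus the baseline
    marginal count.  Identically 1 when the baseline *is* (0,0)."""
    zero_idx = _GENO_INDEX[(1, 1)]
    base_idx = _GENO_INDEX[(int(baseline.g1), int(baseline.g2))]
    base_n = sum(_cell(counts, base_idx, {}))
    if base_idx == zero_idx:
        return 1.0, base_n
    res = _safe_or(counts, zero_idx, {}, base_idx, {}, cfg)
    if res is None:
        raise DegenerateTableError("cannot estimate the (0,0) vs baseline OR")
    return res.or_value, base_n


def component_risks(
    cohort: pd.DataFrame, catalog: CEHCatalog, cfg: RiskModelConfig | None = None
) -> dict[str, ComponentRisk]:
    """Estimate all per-haplotype and per-locus components.

    Keys: ``"mhc:AP"`` ... ``"mhc:H+"`` for single MHC haplotypes and
    ``"d1:1"`` ... ``"d3:2"`` for non-MHC copy counts.  The working
    baseline's own haplotype is 1 by definition (R_b = R_AP* = 1); the rest
    are estimated from the cohort per the configured route and expressed on
    both scales.
    """
    cfg = cfg or RiskModelConfig()
    ann = annotate_cohort(cohort, catalog)
    counts = genotype_copy_counts(ann)
    baseline = _resolve_baseline(counts, cfg)
    return _component_risks_from_counts(counts, cfg, baseline)


def _component_risks_from_counts(
    counts: np.ndarray, cfg: RiskModelConfig, baseline: MHCGenotype
) -> dict[str, ComponentRisk]:
    r00, base_n = _baseline_or(counts, cfg, baseline)
    r0_add = (r00 + 1.0) / 2.0  # per-copy neutral excess: r00 = 1 + 2(r0 - 1)
    r0_mult = math.sqrt(r00)
    zero_idx = _GENO_INDEX[(1, 1)]
    base_idx = _GENO_INDEX[(int(baseline.g1), int(baseline.g2))]
    base_grp = baseline.g1 if baseline.g1 == baseline.g2 else None

    comps: dict[str, ComponentRisk] = {}
    for grp in MHCGroup:
        cid = f"mhc:{grp.code}"
        if grp is base_grp:
            comps[cid] = ComponentRisk(cid, 1.0, 1.0, "observed-definitional", base_n)
        elif cfg.mhc_route == "ap" and base_grp is not None:
            pair = _GENO_INDEX[(min(int(base_grp), int(grp)), max(int(base_grp), int(grp)))]
            res = _safe_or(counts, pair, {}, base_idx, {}, cfg)
            if res is None:
                comps[cid] = ComponentRisk(cid, math.nan, math.nan, "observed-definitional", 0)
            else:
                comps[cid] = ComponentRisk(
                    cid, res.or_value, res.or_value, "observed-definitional", res.n_exposed
                )
        elif grp is MHCGroup.NEUTRAL:
            comps[cid] = ComponentRisk(
                cid, r0_add, r0_mult, "re-referenced", sum(_cell(counts, zero_idx, {}))
            )
        else:
            pair = _GENO_INDEX[(min(1, int(grp)), max(1, int(grp)))]
            res = _safe_or(counts, pair, {}, zero_idx, {}, cfg)
            if res is None:
                comps[cid] = ComponentRisk(cid, math.nan, math.nan, "re-referenced", 0)
            else:
                rr_add = res.or_value * r00 - r0_add + 1.0
                rr_mult = res.or_value * r0_mult
                comps[cid] = ComponentRisk(cid, rr_add, rr_mult, "re-referenced", res.n_exposed)

    for j, locus in enumerate(NONMHC_LOCI):
        for k in (1, 2):
            cid = f"{locus}:{k}"
            res = _safe_or(counts, zero_idx, {j: k}, zero_idx, {j: 0}, cfg)
            if res is None:
                comps[cid] = ComponentRisk(cid, math.nan, math.nan, "re-referenced", 0)
                continue
            rr_add = 1.0 + r00 * (res.or_value - 1.0)
            comps[cid] = ComponentRisk(cid, rr_add, res.or_value, "re-referenced", res.n_exposed)
    return comps


@dataclass(frozen=True)
class ModelEvaluation:
    """Outcome of :func:`evaluate_combinations`.

    ``rows`` has one line per risk combination with its observed RR, both
    model expectations, the marginal count band and which model sits closer
    in ln distance; ``additive_fraction`` is the share of decisive
    (non-tie) rows closer to additive, and ``verdict`` the majority call.
    """

    rows: pd.DataFrame
    components: dict[str, ComponentRisk]
    additive_fraction: float
    n_decisive: int
    verdict: str
    baseline_used: str = "(AP,AP)"

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()


def _band(n: int, min_marginal: int) -> str:
    return ">=50" if n >= 50 else (f"{min_marginal}-49" if n >= min_marginal else "<15")


def evaluate_combinations(
    cohort: pd.DataFrame,
    catalog: CEHCatalog,
    cfg: RiskModelConfig | None = None,
    max_loci: int = 4,
) -> ModelEvaluation:
    """Compare observed combined risks with both composition models.

    Enumerates every observed MHC genotype combined with risk-copy states
    at up to ``max_loci - 1`` non-MHC loci (``max_loci=1`` is the MHC-only
    analysis).  Rows with fewer than ``cfg.min_marginal`` representations
    are dropped; for the rest, ``closer_model`` picks the expectation with
    the smaller |ln(observed) - ln(expected)| and the summary verdict is
    the majority over decisive rows.
    """
    if not 1 <= max_loci <= 4:
        raise ValueError("max_loci must be in 1..4")
    cfg = cfg or RiskModelConfig()
    ann = annotate_cohort(cohort, catalog)
    counts = genotype_copy_counts(ann)
    baseline = _resolve_baseline(counts, cfg)
    comps = _component_risks_from_counts(counts, cfg, baseline)
    r00, _ = _baseline_or(counts, cfg, baseline)
    zero_idx = _GENO_INDEX[(1, 1)]
    base_idx = _GENO_INDEX[(int(baseline.g1), int(baseline.g2))]

    copy_vectors = [
        v for v in product(range(3), repeat=3) if sum(k > 0 for k in v) <= max_loci - 1
    ]
    rows = []
    for gi in _observed_genotypes(counts):
        g = _GENOTYPES[gi]
        for copies in copy_vectors:
            involved = {j: copies[j] for j in range(3) if copies[j] > 0}
            n_exposed = sum(_cell(counts, gi, involved))
            if n_exposed < cfg.min_marginal:
                continue
            if cfg.observed_route == "chained":
                res = _safe_or(counts, gi, involved, zero_idx, {j: 0 for j in involved}, cfg)
                observed = res.or_value * r00 if res is not None else math.nan
            else:
                res = _safe_or(counts, gi, involved, base_idx, {j: 0 for j in involved}, cfg)
                observed = res.or_value if res is not None else math.nan
            row_comps = [comps[f"mhc:{g.g1.code}"], comps[f"mhc:{g.g2.code}"]] + [
                comps[f"{NONMHC_LOCI[j]}:{k}"] for j, k in involved.items()
            ]
            label = g.code + (
                " + " + ",".join(f"{NONMHC_LOCI[j]}={k}" for j, k in involved.items())
                if involved
                else ""
            )
            base = {
                "combination": label,
                "mhc_genotype": g.code,
                "d1": copies[0], "d2": copies[1], "d3": copies[2],
                "n": n_exposed,
                "band": _band(n_exposed, cfg.min_marginal),
            }
            if not math.isfinite(observed) or observed <= 0 or not all(
                c.valid for c in row_comps
            ):
                rows.append(
                    base | {"observed_rr": math.nan, "additive_expected": math.nan,
                            "multiplicative_expected": math.nan, "closer_model": "na"}
                )
                continue
            add = expected_additive([c.rr for c in row_comps])
            mult = expected_multiplicative([c.rr_multiplicative for c in row_comps])
            if add <= 0:
                closer = "na"
                add = math.nan
            else:
                d_add = abs(math.log(observed) - math.log(add))
                d_mult = abs(math.log(observed) - math.log(mult))
                if math.isclose(d_add, d_mult, rel_tol=0.0, abs_tol=1e-9):
                    closer = "tie"
                else:
                    closer = "additive" if d_add < d_mult else "multiplicative"
            rows.append(
                base | {"observed_rr": observed, "additive_expected": add,
                        "multiplicative_expected": mult, "closer_model": closer}
            )
    frame = pd.DataFrame(rows)
    decisive = frame[frame["closer_model"].isin(["additive", "multiplicative"])]
    n_dec = len(decisive)
    frac = float((decisive["closer_model"] == "additive").mean()) if n_dec else math.nan
    if n_dec == 0:
        verdict = "tie"
    elif frac > 0.5:
        verdict = "additive"
    elif frac < 0.5:
        verdict = "multiplicative"
    else:
        verdict = "tie"
    return ModelEvaluation(
        rows=frame, components=comps, additive_fraction=frac, n_decisive=n_dec,
        verdict=verdict, baseline_used=baseline.code,
    )
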