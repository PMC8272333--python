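"""Synthetic phased case-control cohorts under known genotype relative risks.

The generator emulates the statistical structure the downstream analyses
assume: four loci (the MHC plus three binary non-MHC risk loci) segregating
independently, Hardy-Weinberg genotype frequencies in the source population,
a rare disease (prevalence ~0.003, so odds ratios estimate relative risks),
and configurable per-genotype relative risks composed either additively
(``RR = 1 + sum(R_i - 1)``) or multiplicatively (``RR = prod(R_i)``) from
per-haplotype components, with optional per-genotype overrides for
non-additive MHC interactions (a recessive c1, a dominant-protective AP).

Disease status is assigned by genotype-proportional penetrance scaled
analytically to the configured prevalence, so the configured RRs hold
exactly by construction rather than asymptotically.  Individuals are drawn
fresh until the case and control quotas fill; everything is reproducible
from the single config seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .association import hwe_test
from .catalog import (
    CEHCatalog,
    MHCGenotype,
    MHCGroup,
    NONMHC_LOCI,
    RiskCategory,
    all_genotypes,
    risk_category,
)
from .errors import ConfigurationError, ResourceError
from .io import COHORT_COLUMNS, annotate_cohort, validate_cohort

__all__ = [
    "SimulationConfig",
    "GenotypeRiskTable",
    "compose_genotype_risk",
    "simulate_cohort",
    "simulate_population_prevalence",
    "population_summary",
    "null_config",
]

_GROUP_CODES = np.array([g.code for g in MHCGroup])
_GENOTYPES = all_genotypes()
_GENO_INDEX = {(int(g.g1), int(g.g2)): i for i, g in enumerate(_GENOTYPES)}
#: PAIR_IDX[a, b] -> canonical genotype index for haplotype groups a, b
_PAIR_IDX = np.zeros((5, 5), dtype=np.int64)
for _a in range(5):
    for _b in range(5):
        _PAIR_IDX[_a, _b] = _GENO_INDEX[(min(_a, _b), max(_a, _b))]


def _default_mhc_hap_freqs() -> dict[MHCGroup, float]:
    """Haplotype-group frequencies consistent with the published control-arm
    carrier statistics (derivations in docs/methods.md):

    * H+ from a 23% carrier rate: ``1 - (1-p)^2 = 0.23``;
    * ER from H+ making up 81% of risk haplotypes;
    * AP from an ~8.5% carrier rate;
    * c1 at 6.2%, the frequency ceiling reported for any single combination;
    * the neutral group takes the remainder.
    """
    f_hplus = 1.0 - math.sqrt(1.0 - 0.23)
    f_er = f_hplus * (1.0 - 0.81) / 0.81
    f_ap = 1.0 - math.sqrt(1.0 - 0.085)
    f_c1 = 0.062
    f_0 = 1.0 - (f_hplus + f_er + f_ap + f_c1)
    return {
        MHCGroup.AP: f_ap,
        MHCGroup.NEUTRAL: f_0,
        MHCGroup.C1: f_c1,
        MHCGroup.ER: f_er,
        MHCGroup.H_PLUS: f_hplus,
    }


#: OR of the (0,0) MHC genotype versus the (AP,AP) baseline implied by the
#: published (AP,AP)-vs-(0,0) OR of 0.13.
_OR_00_VS_APAP = 1.0 / 0.13


def _default_hap_rr(composition: str) -> dict[MHCGroup, float]:
    """Per-copy haplotype relative risks versus the AP baseline (R_AP = 1),
    calibrated so that under the chosen composition the cohort reproduces
    (0,H+) vs (0,0) = 3.0, (0,ER) vs (0,0) = 2.0 and (AP,AP) vs (0,0) = 0.13.
    A single c1 copy is neutral (R_c1 = R_0); the recessive c1 behaviour is a
    per-genotype override in the paper-like preset, not a per-copy effect.
    """
    if composition == "additive":
        r0 = (_OR_00_VS_APAP + 1.0) / 2.0
        r_hplus = 3.0 * _OR_00_VS_APAP - r0 + 1.0
        r_er = 2.0 * _OR_00_VS_APAP - r0 + 1.0
    elif composition == "multiplicative":
        r0 = math.sqrt(_OR_00_VS_APAP)
        r_hplus = 3.0 * r0
        r_er = 2.0 * r0
    else:  # pragma: no cover - guarded by SimulationConfig
        raise ConfigurationError(f"unknown composition {composition!r}")
    return {
        MHCGroup.AP: 1.0,
        MHCGroup.NEUTRAL: r0,
        MHCGroup.C1: r0,
        MHCGroup.ER: r_er,
        MHCGroup.H_PLUS: r_hplus,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of a synthetic cohort.

    Frequencies are population haplotype frequencies (Hardy-Weinberg
    genotypes follow by construction); relative risks are per haplotype copy
    against the all-protective baseline ``R_AP = 1``; ``composition`` states
    how per-copy components combine into a genotype relative risk;
    ``genotype_rr_overrides`` replace the *MHC part* of the composed risk for
    specific MHC genotypes (values on the same baseline-1 scale).  Disease
    prevalence must sit in the rare-disease regime (0, 0.05] where OR ~ RR.
    ``female_single_copy_risk_multiplier`` scales female penetrance for
    single-copy-risk MHC genotypes (1.0 = no sex-genotype interaction).
    """

    mhc_hap_freqs: Mapping[MHCGroup, float] = field(default_factory=_default_mhc_hap_freqs)
    nonmhc_risk_freqs: tuple[float, float, float] = (0.02, 0.23, 0.41)
    hap_rr: Mapping[MHCGroup, float] = field(default_factory=lambda: _default_hap_rr("additive"))
    nonmhc_rr: tuple[float, float, float] = (1.35, 1.25, 1.20)
    composition: str = "additive"
    genotype_rr_overrides: Mapping[MHCGenotype, float] = field(default_factory=dict)
    prevalence: float = 0.003
    n_cases: int = 11376
    n_controls: int = 18872
    seed: int = 0
    female_single_copy_risk_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.composition not in ("additive", "multiplicative"):
            raise ConfigurationError(
                f"composition must be 'additive' or 'multiplicative', got {self.composition!r}"
            )
        freqs = {MHCGroup(k) if not isinstance(k, MHCGroup) else k: float(v)
                 for k, v in self.mhc_hap_freqs.items()}
        if set(freqs) != set(MHCGroup):
            raise ConfigurationError("mhc_hap_freqs must cover all five groups")
        if any(not 0 <= f <= 1 for f in freqs.values()):
            raise ConfigurationError("haplotype frequencies must lie in [0, 1]")
        if abs(sum(freqs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("MHC haplotype frequencies must sum to 1 (tol 1e-9)")
        object.__setattr__(self, "mhc_hap_freqs", freqs)
        rrs = {MHCGroup(k) if not isinstance(k, MHCGroup) else k: float(v)
               for k, v in self.hap_rr.items()}
        if set(rrs) != set(MHCGroup):
            raise ConfigurationError("hap_rr must cover all five groups")
        if any(r <= 0 for r in rrs.values()):
            raise ConfigurationError("relative risks must be positive")
        object.__setattr__(self, "hap_rr", rrs)
        if len(self.nonmhc_risk_freqs) != 3 or any(
            not 0 <= f <= 1 for f in self.nonmhc_risk_freqs
        ):
            raise ConfigurationError("nonmhc_risk_freqs must be three values in [0, 1]")
        if len(self.nonmhc_rr) != 3 or any(r <= 0 for r in self.nonmhc_rr):
            raise ConfigurationError("nonmhc_rr must be three positive values")
        if any(v <= 0 for v in self.genotype_rr_overrides.values()):
            raise ConfigurationError("genotype RR overrides must be positive")
        if not 0 < self.prevalence <= 0.05:
            raise ConfigurationError(
                "prevalence must lie in (0, 0.05] (rare-disease regime where OR ~ RR)"
            )
        if self.n_cases < 0 or self.n_controls < 0:
            raise ConfigurationError("sample sizes must be non-negative")
        if self.female_single_copy_risk_multiplier <= 0:
            raise ConfigurationError("sex multiplier must be positive")

    # -- JSON round trip (config files mirror the field names) --------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "mhc_hap_freqs": {g.code: f for g, f in self.mhc_hap_freqs.items()},
            "nonmhc_risk_freqs": list(self.nonmhc_risk_freqs),
            "hap_rr": {g.code: r for g, r in self.hap_rr.items()},
            "nonmhc_rr": list(self.nonmhc_rr),
            "composition": self.composition,
            "genotype_rr_overrides": {g.code: r for g, r in self.genotype_rr_overrides.items()},
            "prevalence": self.prevalence,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "seed": self.seed,
            "female_single_copy_risk_multiplier": self.female_single_copy_risk_multiplier,
        }
        text = json.dumps(payload, indent=2) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SimulationConfig":
        text = Path(source).read_text() if isinstance(source, Path) else source
        if isinstance(source, str) and not source.lstrip().startswith("{"):
            text = Path(source).read_text()
        raw = json.loads(text)
        kwargs = dict(raw)
        if "mhc_hap_freqs" in kwargs:
            kwargs["mhc_hap_freqs"] = {
                MHCGroup.from_code(k): v for k, v in kwargs["mhc_hap_freqs"].items()
            }
        if "hap_rr" in kwargs:
            kwargs["hap_rr"] = {MHCGroup.from_code(k): v for k, v in kwargs["hap_rr"].items()}
        if "genotype_rr_overrides" in kwargs:
            kwargs["genotype_rr_overrides"] = {
                MHCGenotype.from_code(k): v for k, v in kwargs["genotype_rr_overrides"].items()
            }
        for key in ("nonmhc_risk_freqs", "nonmhc_rr"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass(frozen=True)
class GenotypeRiskTable:
    """Relative risks and penetrances for every full multi-locus genotype.

    Arrays are indexed ``[mhc_genotype_index, d1_copies, d2_copies,
    d3_copies]`` with the 15 MHC genotypes in display order.  The baseline
    genotype ((AP,AP) with zero risk copies) has relative risk 1; penetrance
    is ``scale * RR`` (per sex), with ``scale`` solved analytically so the
    expected population prevalence equals the configured value.
    """

    rr: np.ndarray
    penetrance_female: np.ndarray
    penetrance_male: np.ndarray
    scale: float
    mhc_probs: np.ndarray
    nonmhc_probs: np.ndarray  # (3 loci, 3 copy counts)
    prevalence: float

    def _idx(self, genotype: MHCGenotype) -> int:
        return _GENO_INDEX[(int(genotype.g1), int(genotype.g2))]

    def relative_risk(self, genotype: MHCGenotype, copies: tuple[int, int, int] = (0, 0, 0)) -> float:
        return float(self.rr[self._idx(genotype)][tuple(copies)])

    def penetrance(
        self, genotype: MHCGenotype, copies: tuple[int, int, int] = (0, 0, 0), sex: str = "M"
    ) -> float:
        arr = self.penetrance_female if sex == "F" else self.penetrance_male
        return float(arr[self._idx(genotype)][tuple(copies)])

    def expected_prevalence(self) -> float:
        """Population prevalence implied by the table (equals the configured
        prevalence to within numerical round-off; sexes mix 50/50)."""
        joint = (
            self.mhc_probs[:, None, None, None]
            * self.nonmhc_probs[0][None, :, None, None]
            * self.nonmhc_probs[1][None, None, :, None]
            * self.nonmhc_probs[2][None, None, None, :]
        )
        return float(np.sum(joint * (self.penetrance_female + self.penetrance_male) / 2.0))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gi, g in enumerate(_GENOTYPES):
            for k1 in range(3):
                for k2 in range(3):
                    for k3 in range(3):
                        rows.append(
                            {
                                "mhc_genotype": g.code,
                                "d1": k1,
                                "d2": k2,
                                "d3": k3,
                                "rr": self.rr[gi, k1, k2, k3],
                                "penetrance_female": self.penetrance_female[gi, k1, k2, k3],
                                "penetrance_male": self.penetrance_male[gi, k1, k2, k3],
                            }
                        )
        return pd.DataFrame(rows)


def compose_genotype_risk(config: SimulationConfig) -> GenotypeRiskTable:
    """Compose per-genotype relative risks and prevalence-normalised
    penetrances from the per-haplotype components.

    The MHC part composes the two haplotype components; each risk copy at a
    non-MHC locus contributes one further component.  Overrides replace the
    MHC part after composition.  Any resulting penetrance above 1 is a
    configuration error naming the offending genotype.
    """
    r_hap = np.array([config.hap_rr[g] for g in MHCGroup])
    r_d = np.asarray(config.nonmhc_rr, dtype=float)
    additive = config.composition == "additive"

    mhc_part = np.empty(15)
    for gi, g in enumerate(_GENOTYPES):
        ra, rb = r_hap[int(g.g1)], r_hap[int(g.g2)]
        mhc_part[gi] = 1.0 + (ra - 1.0) + (rb - 1.0) if additive else ra * rb
    for g, value in config.genotype_rr_overrides.items():
        mhc_part[_GENO_INDEX[(int(g.g1), int(g.g2))]] = float(value)

    k = np.arange(3)
    rr = np.empty((15, 3, 3, 3))
    if additive:
        d_excess = (
            (k[:, None, None] * (r_d[0] - 1.0))
            + (k[None, :, None] * (r_d[1] - 1.0))
            + (k[None, None, :] * (r_d[2] - 1.0))
        )
        rr[:] = mhc_part[:, None, None, None] + d_excess[None]
    else:
        d_factor = (
            (r_d[0] ** k)[:, None, None]
            * (r_d[1] ** k)[None, :, None]
            * (r_d[2] ** k)[None, None, :]
        )
        rr[:] = mhc_part[:, None, None, None] * d_factor[None]
    if np.any(rr <= 0):
        gi = int(np.argwhere(rr <= 0)[0][0])
        raise ConfigurationError(
            f"non-positive composed relative risk for MHC genotype {_GENOTYPES[gi].code}"
        )

    freqs = np.array([config.mhc_hap_freqs[g] for g in MHCGroup])
    mhc_probs = np.empty(15)
    for gi, g in enumerate(_GENOTYPES):
        a, b = int(g.g1), int(g.g2)
        mhc_probs[gi] = freqs[a] ** 2 if a == b else 2 * freqs[a] * freqs[b]
    f = np.asarray(config.nonmhc_risk_freqs)
    nonmhc_probs = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=1)

    mult = config.female_single_copy_risk_multiplier
    sex_mult = np.array(
        [
            mult if risk_category(g) is RiskCategory.SINGLE_COPY_RISK else 1.0
            for g in _GENOTYPES
        ]
    )
    joint = (
        mhc_probs[:, None, None, None]
        * nonmhc_probs[0][None, :, None, None]
        * nonmhc_probs[1][None, None, :, None]
        * nonmhc_probs[2][None, None, None, :]
    )
    mean_sex = (sex_mult + 1.0) / 2.0
    expected_rr = float(np.sum(joint * rr * mean_sex[:, None, None, None]))
    scale = config.prevalence / expected_rr
    pen_m = scale * rr
    pen_f = pen_m * sex_mult[:, None, None, None]
    worst = max(pen_f.max(), pen_m.max())
    if worst > 1.0:
        gi = int(np.unravel_index(np.argmax(pen_f), pen_f.shape)[0])
        raise ConfigurationError(
            f"penetrance {worst:.3g} > 1 for MHC genotype {_GENOTYPES[gi].code}; "
            "lower the prevalence or the relative risks"
        )
    return GenotypeRiskTable(
        rr=rr,
        penetrance_female=pen_f,
        penetrance_male=pen_m,
        scale=scale,
        mhc_probs=mhc_probs,
        nonmhc_probs=nonmhc_probs,
        prevalence=config.prevalence,
    )


def _draw_batch(rng: np.random.Generator, config: SimulationConfig, table: GenotypeRiskTable, n: int):
    """Draw ``n`` fresh individuals; returns column arrays incl. status."""
    cum = np.cumsum([config.mhc_hap_freqs[g] for g in MHCGroup])
    r = rng.random((10, n))
    h1 = np.minimum(np.searchsorted(cum, r[0], side="right"), 4)
    h2 = np.minimum(np.searchsorted(cum, r[1], side="right"), 4)
    f = np.repeat(np.asarray(config.nonmhc_risk_freqs), 2)
    bits = r[2:8] < f[:, None]  # rows: d1_h1, d1_h2, d2_h1, d2_h2, d3_h1, d3_h2
    female = r[8] < 0.5

    flat = _PAIR_IDX[h1, h2] * 27
    for j in range(3):
        flat += (np.add(bits[2 * j], bits[2 * j + 1], dtype=np.int64)) * 3 ** (2 - j)
    pen_by_sex = np.concatenate(
        [table.penetrance_male.ravel(), table.penetrance_female.ravel()]
    )
    pen = pen_by_sex[flat + female * table.rr.size]
    diseased = r[9] < pen
    return h1, h2, list(bits), female, diseased


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a phased case-control cohort.

    Individuals are drawn independently from the configured population
    (haplotypes independent across loci, Hardy-Weinberg within each locus),
    assigned disease by Bernoulli(penetrance), and accumulated — fresh draws
    each time, never resampled — until ``n_cases`` cases and ``n_controls``
    controls are collected (cases listed first).  Byte-identical output for
    identical config and seed.
    """
    table = compose_genotype_risk(config)
    if config.prevalence * 1e7 < config.n_cases:
        raise ResourceError(
            f"expected case yield per 10^7 draws ({config.prevalence * 1e7:.0f}) "
            f"is below n_cases={config.n_cases}; raise the prevalence or lower n"
        )
    rng = np.random.default_rng(config.seed)

    need = {"case": config.n_cases, "control": config.n_controls}
    parts: dict[str, list] = {"case": [], "control": []}
    got = {"case": 0, "control": 0}
    while got["case"] < need["case"] or got["control"] < need["control"]:
        n_case_missing = need["case"] - got["case"]
        n_ctrl_missing = need["control"] - got["control"]
        batch = int(
            max(
                n_case_missing / max(config.prevalence, 1e-9) * 1.12,
                n_ctrl_missing / (1 - config.prevalence) * 1.05,
                10_000,
            )
        )
        batch = min(batch, 6_000_000)
        h1, h2, bits, female, diseased = _draw_batch(rng, config, table, batch)
        for status, mask in (("case", diseased), ("control", ~diseased)):
            take = min(need[status] - got[status], int(mask.sum()))
            if take <= 0:
                continue
            idx = np.flatnonzero(mask)[:take]
            parts[status].append(
                (h1[idx], h2[idx], [b[idx] for b in bits], female[idx])
            )
            got[status] += take

    frames = []
    for status in ("case", "control"):
        h1 = np.concatenate([p[0] for p in parts[status]]) if parts[status] else np.array([], dtype=np.int8)
        h2 = np.concatenate([p[1] for p in parts[status]]) if parts[status] else np.array([], dtype=np.int8)
        bits = [
            np.concatenate([p[2][j] for p in parts[status]]) if parts[status] else np.array([], dtype=bool)
            for j in range(6)
        ]
        female = np.concatenate([p[3] for p in parts[status]]) if parts[status] else np.array([], dtype=bool)
        n = len(h1)
        frame = pd.DataFrame(
            {
                "sample_id": [f"{status}_{i + 1:06d}" for i in range(n)],
                "status": status,
                "sex": np.where(female, "F", "M"),
                "mhc_h1": _GROUP_CODES[h1],
                "mhc_h2": _GROUP_CODES[h2],
            }
        )
        for j, locus in enumerate(NONMHC_LOCI):
            frame[f"{locus}_h1"] = np.where(bits[2 * j], "risk", "0")
            frame[f"{locus}_h2"] = np.where(bits[2 * j + 1], "risk", "0")
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)[COHORT_COLUMNS]
    return validate_cohort(out)


def simulate_population_prevalence(
    config: SimulationConfig, n_draws: int = 1_000_000, seed: int | None = None
) -> dict:
    """Empirical disease prevalence of the *unsampled* source population.

    Draws ``n_draws`` individuals (without case-control selection) and
    reports the observed disease fraction — a direct check that the analytic
    penetrance normalisation hits the configured prevalence.
    """
    table = compose_genotype_risk(config)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    *_, diseased = _draw_batch(rng, config, table, n_draws)
    n_dis = int(diseased.sum())
    return {"n": n_draws, "n_diseased": n_dis, "prevalence": n_dis / n_draws}


def population_summary(cohort: pd.DataFrame, catalog: CEHCatalog) -> dict[str, pd.DataFrame]:
    """Descriptive summary of a cohort against a catalog.

    Returns a dict of frames: per-status/sex MHC group haplotype frequencies
    (``group_frequencies``), per-group carrier rates (``carrier_rates``),
    non-MHC risk-haplotype frequencies (``nonmhc_frequencies``), the share of
    risk haplotypes (H+ or ER) that are H+ (``risk_share``), and per-locus
    Hardy-Weinberg chi-square tests on the control arm (``hwe``).
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    ann = annotate_cohort(cohort, catalog)

    strata: list[tuple[str, str, pd.DataFrame]] = []
    for status in ("case", "control"):
        sub = ann[ann["status"] == status]
        if len(sub):
            strata.append((status, "all", sub))
            for sex in ("F", "M"):
                sexed = sub[sub["sex"] == sex]
                if len(sexed):
                    strata.append((status, sex, sexed))

    freq_rows, carrier_rows, nonmhc_rows, share_rows = [], [], [], []
    for status, sex, sub in strata:
        n = len(sub)
        haps = np.concatenate([sub["g1"].to_numpy(), sub["g2"].to_numpy()])
        counts = np.bincount(haps, minlength=5)
        freq_rows.append(
            {"status": status, "sex": sex, "n": n}
            | {g.code: counts[int(g)] / (2 * n) for g in MHCGroup}
        )
        carrier_rows.append(
            {"status": status, "sex": sex, "n": n}
            | {
                g.code: float(((sub["g1"] == int(g)) | (sub["g2"] == int(g))).mean())
                for g in MHCGroup
            }
        )
        nonmhc_rows.append(
            {"status": status, "sex": sex, "n": n}
            | {locus: float(sub[locus].mean() / 2.0) for locus in NONMHC_LOCI}
        )
        n_hplus = counts[int(MHCGroup.H_PLUS)]
        n_risk = n_hplus + counts[int(MHCGroup.ER)]
        share_rows.append(
            {
                "status": status,
                "sex": sex,
                "hplus_share_of_risk_haplotypes": (n_hplus / n_risk) if n_risk else np.nan,
            }
        )

    hwe_rows = []
    controls = ann[ann["status"] == "control"]
    if len(controls):
        pairs = list(zip(controls["g1"].tolist(), controls["g2"].tolist()))
        mhc_counts: dict[tuple[int, int], int] = {}
        for p in pairs:
            mhc_counts[p] = mhc_counts.get(p, 0) + 1
        for locus, counts_in in [("mhc", mhc_counts)] + [
            (
                locus,
                {
                    ("A", "A"): int((controls[locus] == 2).sum()),
                    ("A", "a"): int((controls[locus] == 1).sum()),
                    ("a", "a"): int((controls[locus] == 0).sum()),
                },
            )
            for locus in NONMHC_LOCI
        ]:
            try:
                res = hwe_test(counts_in)
                hwe_rows.append(
                    {"locus": locus, "chi2": res.chi2, "df": res.df, "p": res.p,
                     "n": res.n, "pooled": res.pooled}
                )
            except ValueError:
                hwe_rows.append(
                    {"locus": locus, "chi2": np.nan, "df": 0, "p": np.nan,
                     "n": len(controls), "pooled": False}
                )

    return {
        "group_frequencies": pd.DataFrame(freq_rows),
        "carrier_rates": pd.DataFrame(carrier_rows),
        "nonmhc_frequencies": pd.DataFrame(nonmhc_rows),
        "risk_share": pd.DataFrame(share_rows),
        "hwe": pd.DataFrame(hwe_rows),
    }


def null_config(**overrides) -> SimulationConfig:
    """A no-effect configuration (all relative risks 1) — every genotype OR
    is 1 in expectation.  Keyword overrides pass through to the config."""
    base = dict(
        hap_rr={g: 1.0 for g in MHCGroup},
        nonmhc_rr=(1.0, 1.0, 1.0),
    )
    base.update(overrides)
    return SimulationConfig(**base)
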