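"""Five-group classification of MHC conserved extended haplotypes (CEHs).

Every CEH label is assigned to exactly one of five haplotype groups, ordered
by increasing nominal multiple-sclerosis risk::

    AP < 0 < c1 < ER < H+

* ``H+`` — CEHs carrying the DRB1*15:01 ~ DQB1*06:02 ~ a1 class-II motif,
  the strongest risk class;
* ``ER`` — other ("extended") risk CEHs;
* ``AP`` — all-protective CEHs;
* ``c1`` — the single highest-frequency CEH, apparently recessive for risk;
* ``0``  — the residual neutral group (everything not listed above).

An individual's MHC genotype is the *unordered* pair of its two haplotype
groups; :func:`risk_category` collapses the 15 unordered genotypes into the
single/double-copy risk and protective categories used by the stratified
odds-ratio tables.

The three non-MHC loci (d1/d2/d3, near EOMES, ZFP36L1 and CLEC16A) are
reduced to binary risk / non-risk haplotypes; the catalog records which
labels count as "risk" at each locus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .errors import CatalogError

__all__ = [
    "MHCGroup",
    "MHCGenotype",
    "RiskCategory",
    "CEHCatalog",
    "NONMHC_LOCI",
    "load_catalog",
    "default_catalog",
    "write_catalog",
    "classify_haplotype",
    "make_genotype",
    "risk_category",
    "all_genotypes",
]

#: The three non-MHC risk loci, in fixed column order.
NONMHC_LOCI = ("d1", "d2", "d3")


class MHCGroup(IntEnum):
    """One of the five MHC haplotype groups, ordered by increasing risk.

    The integer values define the canonical genotype ordering and the
    display order of matrix columns; they carry no other meaning.
    """

    AP = 0
    NEUTRAL = 1
    C1 = 2
    ER = 3
    H_PLUS = 4

    @property
    def code(self) -> str:
        return _GROUP_TO_CODE[self]

    @classmethod
    def from_code(cls, code: str) -> "MHCGroup":
        try:
            return _CODE_TO_GROUP[code]
        except KeyError:
            raise CatalogError(f"unknown MHC group code: {code!r}") from None

    def __str__(self) -> str:  # pragma: no cover - display sugar
        return self.code


_GROUP_TO_CODE = {
    MHCGroup.AP: "AP",
    MHCGroup.NEUTRAL: "0",
    MHCGroup.C1: "c1",
    MHCGroup.ER: "ER",
    MHCGroup.H_PLUS: "H+",
}
_CODE_TO_GROUP = {code: grp for grp, code in _GROUP_TO_CODE.items()}


@dataclass(frozen=True, order=True)
class MHCGenotype:
    """Canonically ordered unordered pair of MHC haplotype groups.

    Construction from ``(a, b)`` and ``(b, a)`` yields the same value;
    ``g1 <= g2`` under the group risk order.
    """

    g1: MHCGroup
    g2: MHCGroup

    def __post_init__(self) -> None:
        if self.g1 > self.g2:
            raise ValueError("MHCGenotype must be built via make_genotype()")

    @property
    def code(self) -> str:
        """Display form, e.g. ``\"(0,H+)\"``."""
        return f"({self.g1.code},{self.g2.code})"

    @classmethod
    def from_code(cls, code: str) -> "MHCGenotype":
        inner = code.strip()
        if inner.startswith("(") and inner.endswith(")"):
            inner = inner[1:-1]
        a, _, b = inner.partition(",")
        return make_genotype(MHCGroup.from_code(a.strip()), MHCGroup.from_code(b.strip()))

    def __str__(self) -> str:  # pragma: no cover
        return self.code


def make_genotype(a: MHCGroup, b: MHCGroup) -> MHCGenotype:
    """Build the canonical unordered genotype from two haplotype groups."""
    if a > b:
        a, b = b, a
    return MHCGenotype(a, b)


def all_genotypes() -> list[MHCGenotype]:
    """The 15 unordered MHC genotypes in display (increasing-risk) order."""
    groups = list(MHCGroup)
    return [make_genotype(groups[i], groups[j]) for i in range(5) for j in range(i, 5)]


class RiskCategory(Enum):
    """Collapsed risk category of an MHC genotype."""

    SINGLE_COPY_RISK = "single-copy-risk"
    DOUBLE_COPY_RISK = "double-copy-risk"
    SINGLE_COPY_PROTECTIVE = "single-copy-protective"
    DOUBLE_COPY_PROTECTIVE = "double-copy-protective"
    NEUTRAL = "neutral"
    OTHER = "other"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


_RISK_GROUPS = frozenset({MHCGroup.H_PLUS, MHCGroup.ER})


def risk_category(g: MHCGenotype) -> RiskCategory:
    """Map a genotype to its single/double-copy risk category.

    One copy of H+ or ER beside a neutral haplotype is "single copy risk";
    two copies drawn from {H+, ER, c1} are "double copy risk".  A single c1
    beside a neutral haplotype is categorized neutral: on its own, one c1
    copy carries little if any excess risk over (0,0), the c1 effect being
    apparently recessive.  Mixed protective/risk pairs are "other".
    """
    a, b = g.g1, g.g2
    if a == MHCGroup.AP:
        if b == MHCGroup.AP:
            return RiskCategory.DOUBLE_COPY_PROTECTIVE
        if b == MHCGroup.NEUTRAL:
            return RiskCategory.SINGLE_COPY_PROTECTIVE
        return RiskCategory.OTHER  # AP beside c1/ER/H+
    if a == MHCGroup.NEUTRAL:
        if b in _RISK_GROUPS:
            return RiskCategory.SINGLE_COPY_RISK
        return RiskCategory.NEUTRAL  # (0,0) and (0,c1)
    # both copies now in {c1, ER, H+}
    return RiskCategory.DOUBLE_COPY_RISK


@dataclass(frozen=True)
class CEHCatalog:
    """Mapping from haplotype labels to MHC groups and per-locus risk flags.

    ``mhc_map`` lists explicitly classified labels; anything unlisted falls
    back to ``default_group`` (the neutral group by default, since group 0 is
    defined residually).  ``nonmhc_risk_labels`` gives, per locus, the set of
    labels that count as the locus's risk haplotype.
    """

    mhc_map: Mapping[str, MHCGroup]
    nonmhc_risk_labels: Mapping[str, frozenset[str]]
    default_group: MHCGroup = MHCGroup.NEUTRAL
    strict: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        missing = [loc for loc in NONMHC_LOCI if loc not in self.nonmhc_risk_labels]
        if missing:
            raise CatalogError(f"nonmhc_risk is missing loci: {missing}")

    def group_labels(self, group: MHCGroup) -> frozenset[str]:
        return frozenset(lbl for lbl, g in self.mhc_map.items() if g is group)

    def is_nonmhc_risk(self, locus: str, label: str) -> bool:
        return label in self.nonmhc_risk_labels[locus]


def classify_haplotype(label: str, catalog: CEHCatalog) -> MHCGroup:
    """Classify one MHC haplotype label into its group.

    Lookup order: the catalog's explicit label map; then the five group codes
    themselves (so cohorts phased at group resolution classify as written);
    then the catalog's ``default_group``.  Total by design — with
    ``catalog.strict`` set, unlisted labels raise :class:`CatalogError`
    instead of falling back.
    """
    if not label:
        raise CatalogError("empty haplotype label")
    grp = catalog.mhc_map.get(label)
    if grp is not None:
        return grp
    grp = _CODE_TO_GROUP.get(label)
    if grp is not None:
        return grp
    if catalog.strict:
        raise CatalogError(f"unlisted haplotype label in strict mode: {label!r}")
    return catalog.default_group


_JSON_KEYS = {
    "h_plus": MHCGroup.H_PLUS,
    "er": MHCGroup.ER,
    "ap": MHCGroup.AP,
    "c1": MHCGroup.C1,
}


def _build_catalog(raw: Mapping, source: str, strict: bool = False) -> CEHCatalog:
    mhc_map: dict[str, MHCGroup] = {}
    for key, group in _JSON_KEYS.items():
        labels = raw.get(key, [])
        if not isinstance(labels, Iterable) or isinstance(labels, (str, bytes)):
            raise CatalogError(f"{source}: key {key!r} must be a list of labels")
        for lbl in labels:
            if not isinstance(lbl, str) or not lbl:
                raise CatalogError(f"{source}: key {key!r} holds a non-string label: {lbl!r}")
            if lbl in mhc_map:
                raise CatalogError(
                    f"{source}: label {lbl!r} appears in more than one group list"
                )
            mhc_map[lbl] = group
    nonmhc_raw = raw.get("nonmhc_risk", {})
    if not isinstance(nonmhc_raw, Mapping):
        raise CatalogError(f"{source}: key 'nonmhc_risk' must be a mapping")
    nonmhc = {loc: frozenset(nonmhc_raw.get(loc, [])) for loc in NONMHC_LOCI}
    return CEHCatalog(mhc_map=mhc_map, nonmhc_risk_labels=nonmhc, strict=strict)


def load_catalog(path: str | Path, strict: bool = False) -> CEHCatalog:
    """Load and validate a catalog from its JSON dialect.

    The file holds ``{"h_plus": [...], "er": [...], "ap": [...], "c1": [...],
    "nonmhc_risk": {"d1": [...], "d2": [...], "d3": [...]}}``.  Duplicate
    labels across group lists are rejected.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise CatalogError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(raw, Mapping):
        raise CatalogError(f"{path}: top level must be a JSON object")
    return _build_catalog(raw, str(path), strict=strict)


def default_catalog(strict: bool = False) -> CEHCatalog:
    """The shipped catalog: the published ER and AP label lists, c2/c3 as
    H+ examples, c1 as its own group.

    The full H+ membership exists only at CEH resolution in supplementary
    material; users analysing label-resolution cohorts should extend the
    ``h_plus`` list.  Group codes used directly as labels always classify as
    themselves.
    """
    raw = json.loads(
        resources.files("cehrisk.data").joinpath("default_catalog.json").read_text()
    )
    return _build_catalog(raw, "default_catalog.json", strict=strict)


def write_catalog(catalog: CEHCatalog, path: str | Path) -> None:
    """Serialize a catalog back to the JSON dialect (round-trips with
    :func:`load_catalog`)."""
    payload = {
        key: sorted(catalog.group_labels(group)) for key, group in _JSON_KEYS.items()
    }
    payload["nonmhc_risk"] = {
        loc: sorted(catalog.nonmhc_risk_labels[loc]) for loc in NONMHC_LOCI
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
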