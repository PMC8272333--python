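"""End-to-end pipeline: run selected analyses on a cohort and write a
reproducibility manifest.

Outputs are plain CSV or JSON with locale-independent formatting; the
manifest records the run configuration, seed, package version and a sha256
per output, so re-running from the same inputs reproduces outputs
bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .association import bh_adjust
from .catalog import CEHCatalog, default_catalog, load_catalog
from .errors import CehriskError
from .io import read_cohort
from .matrices import combination_matrix, mhc_genotype_ors, risk_combination_ors, transition_matrix
from .models import RiskModelConfig, evaluate_combinations
from .simulate import population_summary

__all__ = ["RunConfig", "ANALYSES", "run_pipeline"]

ANALYSES = ("summary", "mhc-table", "risk-combos", "combo-matrix", "transitions", "models")


@dataclass(frozen=True)
class RunConfig:
    """Analysis-wide knobs shared by the pipeline and CLI."""

    confidence_level: float = 0.95
    min_marginal: int = 15
    bh_family: str = "per-matrix"  # or "global"
    zero_correction: bool = False
    seed: int = 0
    output_format: str = "csv"  # or "json"
    max_loci: int = 4
    by_sex: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.confidence_level < 1:
            raise ValueError("confidence_level must be in (0,1)")
        if self.min_marginal < 1:
            raise ValueError("min_marginal must be >= 1")
        if self.bh_family not in ("per-matrix", "global"):
            raise ValueError("bh_family must be 'per-matrix' or 'global'")
        if self.output_format not in ("csv", "json"):
            raise ValueError("output_format must be 'csv' or 'json'")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(frames: dict[str, pd.DataFrame], name: str, out_dir: Path, fmt: str) -> Path:
    """Write one analysis (possibly several frames) to a single file."""
    if fmt == "json":
        path = out_dir / f"{name}.json"
        payload = {
            key: json.loads(df.to_json(orient="records", double_precision=15))
            for key, df in frames.items()
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        path = out_dir / f"{name}.csv"
        parts = []
        for key, df in frames.items():
            part = df.copy()
            part.insert(0, "table", key)
            parts.append(part)
        pd.concat(parts, ignore_index=True).to_csv(path, index=False, lineterminator="\n")
    return path


def run_pipeline(
    cohort_path: str | Path,
    catalog_path: str | Path | None = None,
    cfg: RunConfig | None = None,
    analyses: "tuple[str, ...] | list[str] | None" = None,
    out_dir: str | Path = ".",
) -> dict:
    """Execute the requested analyses and write outputs plus a manifest.

    ``analyses`` defaults to all six stages.  Any stage failure removes the
    partial outputs and re-raises with the stage name.  Returns the
    manifest dict (also written to ``manifest.json``).
    """
    cfg = cfg or RunConfig()
    requested = tuple(analyses) if analyses else ANALYSES
    unknown = [a for a in requested if a not in ANALYSES]
    if unknown:
        raise ValueError(f"unknown analysis name(s) {unknown}; valid: {', '.join(ANALYSES)}")

    cohort_path = Path(cohort_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    catalog: CEHCatalog = load_catalog(catalog_path) if catalog_path else default_catalog()
    cohort = read_cohort(cohort_path)

    kw = dict(
        level=cfg.confidence_level,
        min_marginal=cfg.min_marginal,
        zero_correction=cfg.zero_correction,
    )
    written: dict[str, Path] = {}
    bh_pool: list[tuple[str, pd.DataFrame, str]] = []  # (analysis, frame, p column)
    staged: dict[str, dict[str, pd.DataFrame]] = {}
    stage = None
    try:
        for stage in requested:
            if stage == "summary":
                frames = {k: v for k, v in population_summary(cohort, catalog).items()}
            elif stage == "mhc-table":
                tab = mhc_genotype_ors(cohort, catalog, **kw)
                bh_pool.append((stage, tab, "p_value"))
                frames = {"mhc_genotype_ors": tab}
            elif stage == "risk-combos":
                res = risk_combination_ors(cohort, catalog, by_sex=cfg.by_sex, **kw)
                frames = {"risk_combination_ors": res.table}
                if res.sex_comparison_single_copy_risk is not None:
                    c = res.sex_comparison_single_copy_risk
                    frames["sex_comparison"] = pd.DataFrame(
                        [{"comparison": "single-copy-risk F vs M", "z": c.z, "p": c.p,
                          "ln_ratio": c.ln_ratio}]
                    )
            elif stage == "combo-matrix":
                mat = combination_matrix(cohort, catalog, **kw)
                bh_pool.append((stage, mat.cells, "p"))
                frames = {"combination_matrix": mat.cells}
            elif stage == "transitions":
                mat = transition_matrix(cohort, catalog, **kw)
                frames = {"transition_matrix": mat.cells}
            elif stage == "models":
                ev = evaluate_combinations(
                    cohort,
                    catalog,
                    RiskModelConfig(
                        min_marginal=cfg.min_marginal, level=cfg.confidence_level
                    ),
                    max_loci=cfg.max_loci,
                )
                comp = pd.DataFrame(
                    [vars(c) for c in ev.components.values()]
                )
                verdict = pd.DataFrame(
                    [{"verdict": ev.verdict, "additive_fraction": ev.additive_fraction,
                      "n_decisive": ev.n_decisive}]
                )
                frames = {"model_rows": ev.rows, "components": comp, "verdict": verdict}
            staged[stage] = frames

        if cfg.bh_family == "global" and bh_pool:
            # one family across every matrix/table produced in this run
            import numpy as np

            masks, pvals = [], []
            for _, frame, col in bh_pool:
                m = frame[col].notna().to_numpy()
                masks.append(m)
                pvals.append(frame.loc[m, col].to_numpy())
            adj = bh_adjust(np.concatenate(pvals)) if pvals else []
            pos = 0
            for (_, frame, col), m in zip(bh_pool, masks):
                vals = np.full(len(frame), np.nan)
                k = int(m.sum())
                vals[m] = adj[pos : pos + k]
                pos += k
                frame["p_bh"] = vals

        for stage, frames in staged.items():
            written[stage] = _write(frames, stage.replace("-", "_"), out_dir, cfg.output_format)
    except Exception as exc:
        for path in written.values():
            path.unlink(missing_ok=True)
        if isinstance(exc, CehriskError):
            raise type(exc)(f"stage {stage!r}: {exc}") from exc
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package": "cehrisk",
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: getattr(cfg, k) for k in RunConfig.__dataclass_fields__},
        "analyses": list(requested),
        "inputs": {
            "cohort": {"path": str(cohort_path), "sha256": _sha256(cohort_path)},
            "catalog": (
                {"path": str(catalog_path), "sha256": _sha256(Path(catalog_path))}
                if catalog_path
                else {"path": "<default>", "sha256": None}
            ),
        },
        "outputs": {
            name: {"path": str(path), "sha256": _sha256(path)} for name, path in written.items()
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
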