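"""End-to-end orchestration: target DB -> extraction -> filtering -> profile.

A pipeline run is deterministic given its config and inputs, and writes
every stage artifact (target DB, per-run area tables, filtered table,
profile summary) plus a JSON provenance record of the effective config
next to the outputs.  Scope is single-run per sample; multi-replicate
profiles are produced by iterating runs and joining on species name — no
cross-run retention-time alignment is attempted.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .mzml_io import read_mzml
from .postfilter import (
    DEFAULT_AREA_MIN,
    DEFAULT_RT_MIN,
    DEFAULT_SCORE_MAX,
    apply_filters,
)
from .quant import ProfileSummary, relative_abundance
from .targets import TargetEntry, read_target_db
from .xic import SpectrumRun, quantify_target

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "extract_areas"]


@dataclass
class PipelineConfig:
    """Fully serializable description of a pipeline run.

    ``mzml_paths`` maps replicate label -> mzML path.  ``score`` for the
    post-filter stage is 1 - isotope_score (keep-if-smaller semantics, so
    the identification-confidence filter applies unchanged).
    """

    mzml_paths: dict[str, str] = field(default_factory=dict)
    target_db: str = ""
    out_dir: str = "."
    tolerance_ppm: float = 10.0
    rt_min: float = DEFAULT_RT_MIN
    area_min: float = DEFAULT_AREA_MIN
    score_max: float = DEFAULT_SCORE_MAX
    min_isotope_score: float | None = 0.7
    min_height: float = 0.0
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.mzml_paths:
            raise ValueError("config names no mzML inputs")
        for label, p in self.mzml_paths.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"mzML for {label!r} not found: {p}")
        if not Path(self.target_db).exists():
            raise FileNotFoundError(f"target DB not found: {self.target_db}")
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance_ppm must be positive")


@dataclass
class PipelineResult:
    areas: pd.DataFrame
    filtered: pd.DataFrame
    profile: ProfileSummary
    artifacts: dict[str, str]


def extract_areas(
    run: SpectrumRun,
    targets: list[TargetEntry],
    *,
    tolerance_ppm: float = 10.0,
    min_height: float = 0.0,
    min_isotope_score: float | None = 0.7,
    sample: str = "sample",
    replicate: int = 1,
) -> pd.DataFrame:
    """Quantify every target against one run.

    One row per target with a selected quantitation peak: species, adduct,
    apex RT, trapezoidal area, height, isotope score, and a keep-if-smaller
    ``score`` column (1 - isotope_score) for downstream filtering.
    """
    rows = []
    for t in targets:
        best, _ = quantify_target(
            run, t,
            tolerance_ppm=tolerance_ppm,
            min_height=min_height,
            min_isotope_score=min_isotope_score,
        )
        if best is None:
            continue
        iso = best.isotope_score if best.isotope_score is not None else 0.0
        rows.append(
            {
                "lipid_ion": t.name,
                "class": t.species.class_name,
                "adduct": t.adduct.label,
                "rt": best.apex_rt,
                "area": best.area,
                "height": best.height,
                "isotope_score": iso,
                "score": 1.0 - iso,
                "sample": sample,
                "replicate": replicate,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["lipid_ion", "class", "adduct", "rt", "area", "height",
                 "isotope_score", "score", "sample", "replicate"],
    )


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run extract -> filter -> profile over the configured inputs."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load-targets"
    try:
        targets = read_target_db(cfg.target_db)
        stage = "extract"
        area_tables = []
        for rep_i, (label, path) in enumerate(sorted(cfg.mzml_paths.items()),
                                              start=1):
            run = read_mzml(path)
            area_tables.append(
                extract_areas(
                    run, targets,
                    tolerance_ppm=cfg.tolerance_ppm,
                    min_height=cfg.min_height,
                    min_isotope_score=cfg.min_isotope_score,
                    sample=label,
                    replicate=rep_i,
                )
            )
        areas = pd.concat(area_tables, ignore_index=True)
        areas.to_csv(out / "areas.tsv", sep="\t", index=False)
        stage = "filter"
        filtered, report = apply_filters(
            areas, rt_min=cfg.rt_min, area_min=cfg.area_min,
            score_max=cfg.score_max,
        )
        filtered.to_csv(out / "filtered.tsv", sep="\t", index=False)
        (out / "filter_report.json").write_text(
            json.dumps(report.to_dict(), indent=2)
        )
        stage = "profile"
        prof_input = filtered.rename(columns={"lipid_ion": "species"})[
            ["species", "replicate", "area"]
        ]
        profile = relative_abundance(prof_input)
        profile.table.to_csv(out / "profile.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    provenance = {
        "gangliotk_version": __version__,
        "config": asdict(cfg),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "n_targets": len(targets),
        "filter_report": report.to_dict(),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    artifacts = {
        name: str(out / fname)
        for name, fname in [
            ("areas", "areas.tsv"),
            ("filtered", "filtered.tsv"),
            ("filter_report", "filter_report.json"),
            ("profile", "profile.tsv"),
            ("provenance", "provenance.json"),
        ]
    }
    return PipelineResult(
        areas=areas, filtered=filtered, profile=profile, artifacts=artifacts
    )
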