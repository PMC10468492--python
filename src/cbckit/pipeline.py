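"""End-to-end orchestration: design -> cohort -> QC -> estimation -> shares.

``run_pipeline`` executes every stage from a single config with one global
seed (per-stage seeds are derived deterministically), writes
publication-style CSV artifacts plus a JSON run manifest, and returns the
in-memory bundle.  Outputs are byte-stable for a fixed config.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .attributes import AttributeSpace, default_attributes, default_prohibitions
from .coding import CodingMap
from .cohort import (
    ArtifactConfig,
    default_segments,
    inject_artifacts,
    make_population,
    simulate_choices,
)
from .dataset import ChoiceDataset
from .design import design_to_json, generate_design
from .hb import HBConfig, fit_hb
from .latent_class import assign_segments, select_K
from .mnl import build_arrays
from .partworths import importance_table, utilities_table, zero_center
from .qc import apply_funnel
from .shares import SimConfig, build_scenarios, simulate_shares


@dataclass
class PipelineConfig:
    """Settings for a full synthetic-cohort analysis run."""

    seed: int = 0
    n_versions: int = 650
    n_tasks: int = 14
    n_concepts: int = 2
    segment_scale: float = 1.0  # multiplies default segment sizes
    logit_scale: float = 50.0
    spread: float = 0.5
    artifact: ArtifactConfig = field(default_factory=ArtifactConfig)
    min_minutes: float = 10.0
    hb: HBConfig | None = None
    k_range: tuple[int, int] = (1, 7)
    lc_starts: int = 10
    sim: SimConfig | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        art = ArtifactConfig(**payload.pop("artifact", {}))
        hb = HBConfig(**payload["hb"]) if "hb" in payload else None
        sim = SimConfig(**payload["sim"]) if "sim" in payload else None
        k_range = tuple(payload.pop("k_range", (1, 7)))
        return cls(artifact=art, hb=hb, sim=sim, k_range=k_range, **payload)


@dataclass
class RunBundle:
    """All artifacts produced by one pipeline run."""

    funnel_report: object
    importance: pd.DataFrame
    utilities: pd.DataFrame
    shares: pd.DataFrame
    criterion_table: pd.DataFrame
    segments: pd.DataFrame
    manifest: dict


def _stage_seed(base: int, stage: int) -> int:
    return int(np.random.SeedSequence([base, stage]).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> RunBundle:
    """Execute the full pipeline and write all artifacts under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    space = default_attributes()
    prohibitions = default_prohibitions()
    manifest: dict = {"stages": {}, "seed": config.seed}

    def log(stage: str, seed: int, t0: float) -> None:
        manifest["stages"][stage] = {
            "seed": seed,
            "seconds": round(time.perf_counter() - t0, 3),
        }

    # design
    t0, seed = time.perf_counter(), _stage_seed(config.seed, 1)
    design = generate_design(
        space,
        prohibitions,
        n_versions=config.n_versions,
        n_tasks=config.n_tasks,
        n_concepts=config.n_concepts,
        seed=seed,
    )
    design_to_json(design, space, prohibitions, outdir / "design.json")
    log("design", seed, t0)

    # cohort
    t0, seed = time.perf_counter(), _stage_seed(config.seed, 2)
    segments = default_segments(spread=config.spread)
    if config.segment_scale != 1.0:
        from .cohort import SegmentDefinition

        segments = [
            SegmentDefinition(
                s.label,
                max(1, int(round(s.size * config.segment_scale))),
                s.level_utilities,
                s.none_utility,
                s.spread,
            )
            for s in segments
        ]
    population = make_population(segments, logit_scale=config.logit_scale, seed=seed)
    dataset = simulate_choices(population, design, seed=seed + 1)
    dataset, _counts = inject_artifacts(dataset, config.artifact, seed=seed + 2)
    dataset.to_csv(outdir / "choices.csv")
    log("cohort", seed, t0)

    # QC
    t0, seed = time.perf_counter(), _stage_seed(config.seed, 3)
    clean, funnel = apply_funnel(dataset, min_minutes=config.min_minutes)
    funnel.to_json(outdir / "funnel.json")
    log("qc", seed, t0)

    # HB estimation
    t0, seed = time.perf_counter(), _stage_seed(config.seed, 4)
    coding = CodingMap(space)
    arrays = build_arrays(clean, coding)
    hb_config = config.hb or HBConfig(n_burn=2000, n_draws=2000, thin=10)
    hb_config = HBConfig(
        **{**hb_config.__dict__, "seed": seed}
    )
    draws = fit_hb(arrays, hb_config)
    estimate = zero_center(draws, coding)
    estimate.utilities_frame().to_csv(outdir / "utilities.csv", index=False)
    estimate.importance_frame().to_csv(outdir / "importance.csv", index=False)
    log("hb", seed, t0)

    # latent-class segmentation
    t0, seed = time.perf_counter(), _stage_seed(config.seed, 5)
    k_lo, k_hi = config.k_range
    best_K, criterion_table, models = select_K(
        arrays,
        range(k_lo, k_hi + 1),
        n_starts=config.lc_starts,
        seed=seed,
    )
    segments_df = assign_segments(models[best_K])
    criterion_table.to_csv(outdir / "criterion_table.csv", index=False)
    segments_df.to_csv(outdir / "segments.csv", index=False)
    log("latent_class", seed, t0)

    # group tables + share simulation
    t0, seed = time.perf_counter(), _stage_seed(config.seed, 6)
    labels = segments_df["segment"].to_numpy()
    ris = importance_table(estimate, labels)
    utils = utilities_table(estimate, labels)
    scenarios = build_scenarios(space, prohibitions)
    sim = config.sim or SimConfig(n_draws=200)
    sim = SimConfig(**{**sim.__dict__, "seed": seed})
    share_report = simulate_shares(estimate, scenarios, labels, sim)
    ris.to_csv(outdir / "ris_by_group.csv")
    utils.to_csv(outdir / "utilities_by_group.csv")
    share_report.shares.to_csv(outdir / "shares.csv")
    log("shares", seed, t0)

    manifest["outputs"] = sorted(p.name for p in outdir.iterdir())
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return RunBundle(
        funnel_report=funnel,
        importance=ris,
        utilities=utils,
        shares=share_report.shares,
        criterion_table=criterion_table,
        segments=segments_df,
        manifest=manifest,
    )


def render_tables(bundle: RunBundle) -> dict[str, str]:
    """Format the bundle's tables as one-decimal publication-style text."""
    def fmt(df: pd.DataFrame) -> str:
        return df.round(1).to_string()

    missing = [
        name
        for name in ("importance", "utilities", "shares", "criterion_table")
        if getattr(bundle, name) is None
    ]
    if missing:
        raise ValueError(f"bundle is missing sections: {missing}")
    return {
        "funnel": str(bundle.funnel_report),
        "relative_importance": fmt(bundle.importance),
        "zero_centered_utilities": fmt(bundle.utilities),
        "share_of_preference": fmt(bundle.shares),
        "class_criteria": fmt(bundle.criterion_table),
    }
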