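"""End-to-end orchestration: load or simulate, vet, bin, analyze, write tables.

`run_pipeline` executes the full study design for a :class:`RunConfig`:
layer merging and vetting, time binning, per-subset similarity curves and
site-shuffling effect sizes, range size / occupancy, and (optionally)
climate turnover.  Every output CSV carries the configuration hash so a
result bundle is traceable to the exact settings and seed that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate as climate_mod
from . import geography, nullmodels, simulate
from .occurrences import (
    STANDARD_SUBSETS,
    OccurrenceDataset,
    TimeBinConfig,
    apply_subset,
    assign_time_bins,
    merge_contemporaneous_layers,
    read_dataset,
    subset_label,
    vet_sites,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for one pipeline run.

    Either ``input_dir`` (holding occurrences.csv / sites.csv / traits.csv)
    or ``generator`` must be given.  ``subsets`` defaults to the six standard
    data variants; ``seed`` drives every stochastic stage.
    """

    seed: int
    output_dir: str
    input_dir: str | None = None
    generator: simulate.GeneratorConfig | None = None
    bins: TimeBinConfig = field(default_factory=TimeBinConfig)
    subsets: tuple = STANDARD_SUBSETS
    metrics: tuple = ("jaccard",)
    null_reps: int = 1000
    climate_path: str | None = None
    run_ranges: bool = True
    grid: geography.GridSpec | None = None

    def __post_init__(self):
        if self.null_reps < 1:
            raise ValueError("null_reps must be >= 1")
        if not self.subsets:
            raise ValueError("at least one subset is required")
        if (self.input_dir is None) == (self.generator is None):
            raise ValueError("give exactly one of input_dir or generator")

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(_jsonable(self), sort_keys=True).encode()).hexdigest()[:12]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class PipelineResult:
    """Result bundle: tidy tables keyed by stage, plus run metadata."""

    config: RunConfig
    similarity: dict  # subset label -> DataFrame of per-bin per-metric summaries
    effects: dict  # subset label -> DataFrame (effect-size table)
    ranges: pd.DataFrame | None
    climate: pd.DataFrame | None
    n_sites: int
    config_hash: str


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    chash = cfg.config_hash()

    # --- stage: data
    try:
        if cfg.generator is not None:
            ds = simulate.generate_dataset(cfg.generator, rng)
            bins = cfg.generator.bins
        else:
            d = Path(cfg.input_dir)
            ds = read_dataset(d / "occurrences.csv", d / "sites.csv", d / "traits.csv")
            bins = cfg.bins
    except Exception as exc:
        raise RuntimeError(f"stage 'data' failed: {exc}") from exc

    # --- stage: vetting and binning
    try:
        sites = merge_contemporaneous_layers(ds.sites)
        sites = vet_sites(sites, ds.traits)
        binned = assign_time_bins(sites, bins, ds.traits)
    except Exception as exc:
        raise RuntimeError(f"stage 'vetting' failed: {exc}") from exc

    # --- stage: similarity + null model per subset
    similarity_tables: dict = {}
    effect_tables: dict = {}
    for name, kwargs in cfg.subsets:
        label = subset_label(name, kwargs)
        try:
            sub = apply_subset(binned, name, **kwargs)
            sim_rows = []
            for metric in cfg.metrics:
                for summ in nullmodels.bin_mean_similarity(sub, metric=metric):
                    sim_rows.append(
                        {"bin": summ.bin_label, "metric": metric, "mean": summ.mean,
                         "sem": summ.sem, "n_pairs": summ.n_pairs}
                    )
            similarity_tables[label] = pd.DataFrame(sim_rows)
            model = nullmodels.HomogenizationModel(sub, metric=cfg.metrics[0])
            res = model.fit(reps=cfg.null_reps, seed=rng)
            effect_tables[label] = res.to_frame()
        except Exception as exc:
            raise RuntimeError(f"stage 'similarity/{label}' failed: {exc}") from exc

    # --- stage: ranges
    ranges = None
    if cfg.run_ranges:
        try:
            grid = cfg.grid or geography.GridSpec.north_america()
            ranges = geography.mean_range_size(binned, grid)
        except Exception as exc:
            raise RuntimeError(f"stage 'ranges' failed: {exc}") from exc

    # --- stage: climate
    climate_table = None
    if cfg.climate_path is not None:
        try:
            samples = pd.read_csv(cfg.climate_path)
            pca = climate_mod.climate_pca(samples)
            turnovers = climate_mod.climate_turnover(pca.scores)
            slice_ages = {t.slice_label: float(t.slice_label) for t in turnovers}
            climate_table = climate_mod.average_slices_to_bins(turnovers, slice_ages, bins)
        except Exception as exc:
            raise RuntimeError(f"stage 'climate' failed: {exc}") from exc

    result = PipelineResult(
        config=cfg,
        similarity=similarity_tables,
        effects=effect_tables,
        ranges=ranges,
        climate=climate_table,
        n_sites=len(binned.all_sites),
        config_hash=chash,
    )
    _write_bundle(result, outdir)
    return result


def _write_bundle(result: PipelineResult, outdir: Path) -> None:
    def stamp(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        out["config_hash"] = result.config_hash
        return out

    for label, df in result.similarity.items():
        stamp(df).to_csv(outdir / f"similarity_{label}.csv", index=False)
    for label, df in result.effects.items():
        stamp(df).to_csv(outdir / f"effect_sizes_{label}.csv", index=False)
    if result.ranges is not None:
        stamp(result.ranges).to_csv(outdir / "ranges.csv", index=False)
    if result.climate is not None:
        stamp(result.climate).to_csv(outdir / "climate.csv", index=False)
    manifest = {
        "seed": result.config.seed,
        "config_hash": result.config_hash,
        "n_sites": result.n_sites,
        "config": _jsonable(result.config),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))


def report(result: PipelineResult) -> str:
    """Textual summary: per subset and bin, observed similarity, SES, and a star."""
    lines = [
        f"paleobeta run  (seed={result.config.seed}, hash={result.config_hash}, "
        f"sites={result.n_sites})"
    ]
    if not result.effects:
        lines.append("no metrics run")
        return "\n".join(lines)
    for label, df in result.effects.items():
        lines.append(f"\nsubset: {label}")
        for row in df.itertuples(index=False):
            star = "*" if row.significant else ""
            lines.append(
                f"  {row.bin:>14}  observed={row.observed:.4f}  SES={row.effect_size:+.2f}{star}"
            )
    return "\n".join(lines)
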