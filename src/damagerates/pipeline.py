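"""End-to-end orchestration: simulate → quantify → score → rates → crossfit.

A single declarative :class:`PipelineConfig` (YAML-serialisable) drives
every stage; all command-line flags are overrides of config keys.  Stages
are pure functions over tables; the missing-data policy (drop with a
logged warning) is centralised here.  Every run writes a manifest with the
config snapshot, package version, seeds and SHA-256 checksums of all
tabular outputs, so identical (config, seed) pairs can be verified to
produce identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cross_species import (
    DEFAULT_EXCLUDED_SPECIES,
    correlate_rates,
    fit_linear_trend,
    fit_multivariate,
    fit_power_trend,
    load_traits,
    old_abundance,
)
from .rates import fit_all_species, rate_fits_to_frame
from .scoring import (
    compute_reference_thresholds,
    summarize_individuals,
    thresholds_to_records,
)
from .simulate import (
    SpeciesSimConfig,
    SyntheticImageSpec,
    generate_cohort,
    read_tiff,
    render_field_2d,
    write_cohort_csv,
    write_tiff,
)
from .imaging import quantify_field_2d

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "run_simulate", "run_quantify", "run_score", "run_rates", "run_crossfit"]


@dataclass
class PipelineConfig:
    """Declarative configuration of a full pipeline run."""

    master_seed: int = 0
    species: list[SpeciesSimConfig] = field(default_factory=list)
    damage_percentile: float = 50.0
    short_telomere_percentile: float = 25.0
    reference_rule: str = "youngest"
    tif_max_distance: float = 2.0
    tif_rim_margin: float = 2.0
    traits_file: str | None = None
    outdir: str = "results"
    include_excluded_species: bool = False
    render_images: bool = False
    nuclei_per_field: int = 30
    field_shape: tuple[int, int] = (512, 512)
    image_psf_sigma: float = 0.0
    image_shot_noise: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.damage_percentile < 100 or not 0 < self.short_telomere_percentile < 100:
            raise ValueError("percentiles must lie strictly between 0 and 100")
        self.species = [
            s if isinstance(s, SpeciesSimConfig) else SpeciesSimConfig(**s) for s in self.species
        ]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["species"] = [dataclasses.asdict(s) for s in self.species]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for s in d.get("species", []):
            for key in ("intensity_neg", "intensity_pos", "age_range"):
                if key in s and isinstance(s[key], list):
                    s[key] = tuple(s[key])
        if isinstance(d.get("field_shape"), list):
            d["field_shape"] = tuple(d["field_shape"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, cfg: PipelineConfig, outputs: list[Path]) -> Path:
    manifest = {
        "config": cfg.to_dict(),
        "version": __version__,
        "master_seed": cfg.master_seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "checksums": {p.name: _sha256(p) for p in sorted(outputs) if p.exists()},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def run_simulate(cfg: PipelineConfig, outdir: Path | None = None) -> pd.DataFrame:
    """Generate all species' cohorts (and optional 2D image fields) and write them."""
    if not cfg.species:
        raise ValueError("config lists no species to simulate")
    outdir = Path(outdir or cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohorts = []
    for si, scfg in enumerate(cfg.species):
        logger.info("simulate: species %s (seed %d.%d)", scfg.species_name, cfg.master_seed, si)
        cohorts.append(generate_cohort(scfg, seed=cfg.master_seed * 1000 + si))
    cohort = pd.concat(cohorts, ignore_index=True)
    write_cohort_csv(cohort, outdir / "cohort.csv")

    outputs = [outdir / "cohort.csv"]
    if cfg.render_images:
        img_dir = outdir / "fields"
        img_dir.mkdir(exist_ok=True)
        field_index = 0
        for (species, ind), group in cohort.groupby(["species", "individual_id"], sort=True):
            n = min(cfg.nuclei_per_field, len(group))
            intensities = group["gh2ax_intensity"].to_numpy()[:n]
            spec = SyntheticImageSpec(
                field_shape=cfg.field_shape,
                n_nuclei=n,
                psf_sigma=cfg.image_psf_sigma,
                shot_noise=cfg.image_shot_noise,
                seed=cfg.master_seed * 100000 + field_index,
            )
            image, labels = render_field_2d(spec, intensities)
            stem = f"field_{field_index:04d}"
            write_tiff(image, img_dir / f"{stem}.tiff")
            sidecar = {
                "species": species,
                "individual_id": ind,
                "age": float(group["age"].iloc[0]),
                "n_nuclei": int(n),
                "assigned_intensities": [float(v) for v in intensities],
                "background_level": spec.background_level,
                "seed": spec.seed,
            }
            (img_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
            outputs.append(img_dir / f"{stem}.tiff")
            field_index += 1
    _write_manifest(outdir, cfg, outputs)
    return cohort


def run_quantify(cfg: PipelineConfig, outdir: Path | None = None) -> pd.DataFrame:
    """Measure per-cell damage intensities from rendered 2D fields.

    Reads every ``fields/field_*.tiff`` with its JSON sidecar and emits a
    per-cell table shaped like a cohort table (without ground truth or
    telomere columns), written as ``cells_from_images.csv``.
    """
    outdir = Path(outdir or cfg.outdir)
    img_dir = outdir / "fields"
    tiffs = sorted(img_dir.glob("field_*.tiff"))
    if not tiffs:
        raise FileNotFoundError(f"no image fields found under {img_dir}")
    frames = []
    for tiff in tiffs:
        sidecar = json.loads(tiff.with_suffix(".json").read_text())
        image = read_tiff(tiff)
        cells = quantify_field_2d(image)
        frames.append(
            pd.DataFrame(
                {
                    "species": sidecar["species"],
                    "individual_id": sidecar["individual_id"],
                    "age": sidecar["age"],
                    "cell_id": cells["nucleus"],
                    "gh2ax_intensity": cells["pan_nuclear_intensity"],
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(outdir / "cells_from_images.csv", index=False)
    return table


def run_score(cfg: PipelineConfig, cells: pd.DataFrame, outdir: Path | None = None) -> pd.DataFrame:
    """Threshold per species from the young reference and score every individual."""
    outdir = Path(outdir or cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = compute_reference_thresholds(
        cells,
        damage_percentile=cfg.damage_percentile,
        telomere_percentile=cfg.short_telomere_percentile,
        reference=cfg.reference_rule,
    )
    (outdir / "thresholds.json").write_text(
        json.dumps(thresholds_to_records(thresholds), indent=2)
    )
    summaries = summarize_individuals(cells, thresholds)
    summaries.to_csv(outdir / "individual_summaries.csv", index=False)
    return summaries


def run_rates(cfg: PipelineConfig, summaries: pd.DataFrame, outdir: Path | None = None) -> pd.DataFrame:
    """Fit per-species rates of increase and write the species-rates table."""
    outdir = Path(outdir or cfg.outdir)
    fits = fit_all_species(summaries)
    frame = rate_fits_to_frame(fits)
    frame.to_csv(outdir / "species_rates.csv", index=False)
    (outdir / "species_rates.json").write_text(frame.to_json(orient="records", indent=2))
    return frame


def _trend_or_error(fn, x, y, predictor, response) -> dict:
    try:
        fit = fn(x, y, predictor=predictor, response=response)
        return {
            "model": fit.model,
            "predictor": predictor,
            "response": response,
            "coefficients": list(fit.coefficients),
            "r_squared": fit.r_squared,
            "r_squared_defined": fit.r_squared_defined,
            "r_squared_original": fit.r_squared_original,
            "n_species": fit.n_species,
        }
    except ValueError as exc:
        logger.warning("crossfit %s vs %s skipped: %s", response, predictor, exc)
        return {"predictor": predictor, "response": response, "error": str(exc)}


def run_crossfit(
    cfg: PipelineConfig,
    rates_frame: pd.DataFrame,
    cohort: pd.DataFrame | None = None,
    outdir: Path | None = None,
) -> dict:
    """Cross-species fits of rates against traits, plus old-individual abundance.

    Requires ``cfg.traits_file``.  Species listed in
    ``DEFAULT_EXCLUDED_SPECIES`` are dropped unless
    ``cfg.include_excluded_species`` is set.
    """
    outdir = Path(outdir or cfg.outdir)
    if cfg.traits_file is None:
        raise ValueError("no traits file configured")
    traits = load_traits(cfg.traits_file)

    wide = rates_frame.pivot(index="species", columns="statistic", values="slope").reset_index()
    wide.columns.name = None
    merged = wide.merge(traits, on="species", how="inner")
    if not cfg.include_excluded_species:
        drop = merged["species"].isin(DEFAULT_EXCLUDED_SPECIES)
        if drop.any():
            logger.info("crossfit: excluding %s", list(merged.loc[drop, "species"]))
        merged = merged[~drop]

    results: dict = {"n_species": int(len(merged)), "species": list(merged["species"])}
    rate_col = "gh2ax_positivity"
    trend_targets = [
        ("max_lifespan_years", "maximum lifespan"),
        ("avg_lifespan_years", "average lifespan"),
        ("body_weight", "body weight"),
        ("heart_rate_bpm", "heart rate"),
    ]
    results["trends"] = []
    for col, label in trend_targets:
        if col not in merged.columns or rate_col not in merged.columns:
            continue
        x = merged[rate_col].to_numpy(dtype=float)
        y = merged[col].to_numpy(dtype=float)
        results["trends"].append(
            _trend_or_error(fit_linear_trend, x, y, "gh2ax rate (%/yr)", label)
        )
        results["trends"].append(
            _trend_or_error(fit_power_trend, x, y, "gh2ax rate (%/yr)", label)
        )
        if "short_telomere" in merged.columns:
            xs = merged["short_telomere"].to_numpy(dtype=float)
            results["trends"].append(
                _trend_or_error(fit_linear_trend, xs, y, "short-telomere rate (%/yr)", label)
            )

    if {"gh2ax_positivity", "short_telomere"}.issubset(merged.columns):
        results["rate_vs_rate"] = _trend_or_error(
            lambda a, b, predictor, response: correlate_rates(a, b, predictor, response),
            merged["gh2ax_positivity"].to_numpy(dtype=float),
            merged["short_telomere"].to_numpy(dtype=float),
            "gh2ax rate (%/yr)",
            "short-telomere rate (%/yr)",
        )
        results["multivariate"] = {}
        for col, label in (("avg_lifespan_years", "average lifespan"), ("max_lifespan_years", "maximum lifespan")):
            try:
                mv = fit_multivariate(merged, col, ["gh2ax_positivity", "short_telomere"])
                results["multivariate"][label] = {
                    "params": mv.params,
                    "bse": mv.bse,
                    "pvalues": mv.pvalues,
                    "f_pvalue": mv.f_pvalue,
                    "r_squared": mv.r_squared,
                    "n_species": mv.n_species,
                }
            except ValueError as exc:
                logger.warning("multivariate %s skipped: %s", label, exc)
                results["multivariate"][label] = {"error": str(exc)}

    if cohort is not None:
        old_rows = []
        for _, t in traits.iterrows():
            ages = (
                cohort[cohort["species"] == t["species"]]
                .groupby("individual_id")["age"]
                .first()
                .to_numpy()
            )
            if ages.size == 0 or not np.isfinite(t["max_lifespan_years"]):
                continue
            oa = old_abundance(ages, float(t["max_lifespan_years"]), species=str(t["species"]))
            old_rows.append(dataclasses.asdict(oa))
        old_frame = pd.DataFrame(old_rows)
        old_frame.to_csv(outdir / "old_abundance.csv", index=False)
        results["old_abundance"] = old_rows

    (outdir / "cross_species.json").write_text(json.dumps(results, indent=2))
    return results


def run_all(cfg: PipelineConfig, outdir: Path | None = None) -> dict:
    """Execute the full chain and write a single results bundle.

    Stages: simulate (cohort tables, optional image fields) → quantify
    (when images were rendered) → score → rates → crossfit (when a traits
    file is configured; otherwise skipped with a warning).  Any stage
    failure is re-raised with the stage name attached.
    """
    outdir = Path(outdir or cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "simulate"
    try:
        cohort = run_simulate(cfg, outdir)
        if cfg.render_images:
            stage = "quantify"
            run_quantify(cfg, outdir)
        stage = "score"
        summaries = run_score(cfg, cohort, outdir)
        stage = "rates"
        rates_frame = run_rates(cfg, summaries, outdir)
        results["rates"] = json.loads(rates_frame.to_json(orient="records"))
        if cfg.traits_file is not None:
            stage = "crossfit"
            results["cross_species"] = run_crossfit(cfg, rates_frame, cohort, outdir)
        else:
            logger.warning("run_all: no traits file configured, crossfit stage skipped")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "results.json").write_text(json.dumps(results, indent=2))
    outputs = [p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"]
    _write_manifest(outdir, cfg, outputs)
    return results
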