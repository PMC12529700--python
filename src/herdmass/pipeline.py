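"""End-to-end orchestration: clean -> sample -> fit -> snapshot -> classify
-> predict -> aggregate -> deflate -> validate.

Every run writes tidy long-format tables, the four serialized model
fits, and a manifest recording the seed, a configuration hash and
per-stage row counts, so a run is reproducible from its output
directory alone.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import aggregate as agg
from . import io as hio
from .cleaning import BreedMap, clean_dataset
from .classifier import ClassifierRules, classify_all
from .errors import HerdmassError
from .segmented import FitSpec, fit_by_sex
from .snapshots import build_snapshots
from .validate import default_category_age_map, validate_value_model

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters for one full pipeline run."""

    slaughter_path: str
    market_path: str
    events_path: str
    cpi_path: str
    output_dir: str
    cpi_base_period: str = "2011-12"
    date_range: tuple = ("2011-01", "2021-12")
    seed: int = 0
    weight_per_class_n: int = 600
    value_per_class_n: int = 1000
    delta_r2_threshold: float = 0.01
    fit_tol: float = 1e-4
    fit_max_iter: int = 50
    breed_map_path: str | None = None
    rules_path: str | None = None
    category_age_map_path: str | None = None
    classify_years: tuple | None = None
    stage_rows: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["date_range"] = tuple(raw.get("date_range", ("2011-01", "2021-12")))
        if raw.get("classify_years"):
            raw["classify_years"] = tuple(raw["classify_years"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("stage_rows", None)
        return d


def _prepare_training(cleaned: pd.DataFrame) -> pd.DataFrame:
    df = cleaned.copy()
    dod = pd.to_datetime(df["date_of_death"])
    dob = pd.to_datetime(df["date_of_birth"])
    df["age_days"] = (dod - dob).dt.days.astype(float)
    df["month"] = dod.dt.month
    df["year"] = dod.dt.year
    return df


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk).

    Any stage failure aborts with the stage name; the partial manifest
    written so far is left in the output directory.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "config_hash": hio.config_hash(config.to_dict()),
        "config": config.to_dict(),
        "stages": {},
    }
    stage = "init"

    def record(name, **info):
        manifest["stages"][name] = info
        hio.write_manifest(outdir / "manifest.json", manifest)

    try:
        stage = "read"
        t0 = time.perf_counter()
        slaughter = hio.read_table(config.slaughter_path, hio.SLAUGHTER_SCHEMA)
        market = hio.read_table(config.market_path, hio.MARKET_SCHEMA)
        events = hio.read_table(config.events_path, hio.EVENTS_SCHEMA)
        cpi_df = hio.read_table(config.cpi_path, hio.CPI_SCHEMA)
        cpi = agg.CPISeries.from_frame(cpi_df, config.cpi_base_period)
        breed_map = (BreedMap.from_yaml(config.breed_map_path)
                     if config.breed_map_path else BreedMap.default())
        rules = (ClassifierRules.from_yaml(config.rules_path)
                 if config.rules_path else ClassifierRules.default())
        cat_map = default_category_age_map()
        if config.category_age_map_path:
            with open(config.category_age_map_path) as fh:
                cat_map = {k: tuple(v) for k, v in
                           yaml.safe_load(fh)["category_age_map"].items()}
        record("read", seconds=round(time.perf_counter() - t0, 2),
               slaughter_rows=len(slaughter), market_rows=len(market),
               events_rows=len(events))

        stage = "clean"
        t0 = time.perf_counter()
        cleaned, report = clean_dataset(slaughter, breed_map)
        hio.write_table(cleaned, outdir / "slaughter_clean.csv")
        record("clean", seconds=round(time.perf_counter() - t0, 2),
               **report.to_dict())

        stage = "fit"
        t0 = time.perf_counter()
        training = _prepare_training(cleaned)
        from .segmented import stratified_sample
        spec = FitSpec(tol=config.fit_tol, max_iter=config.fit_max_iter)
        w_sample = stratified_sample(training, config.weight_per_class_n,
                                     config.seed)
        v_sample = stratified_sample(training, config.value_per_class_n,
                                     config.seed + 1)
        fits = {}
        for resp, sample in (("liveweight", w_sample), ("value", v_sample)):
            for sex, fit in fit_by_sex(sample, resp, spec,
                                       delta_r2_threshold=config.delta_r2_threshold,
                                       response=resp).items():
                fits[(resp, sex)] = fit
                fit.save(outdir / f"fit_{resp}_{sex}.json")
        record("fit", seconds=round(time.perf_counter() - t0, 2),
               weight_sample=len(w_sample), value_sample=len(v_sample),
               breakpoints={f"{r}/{s}": [float(round(p, 1)) for p in f.breakpoints]
                            for (r, s), f in fits.items()})

        stage = "snapshot"
        t0 = time.perf_counter()
        snaps, quarantine = build_snapshots(events, config.date_range)
        hio.write_table(quarantine, outdir / "quarantine.csv")
        record("snapshot", seconds=round(time.perf_counter() - t0, 2),
               snapshot_rows=len(snaps), quarantined=len(quarantine))

        stage = "classify"
        t0 = time.perf_counter()
        classifications = classify_all(snaps, events, rules,
                                       years=config.classify_years,
                                       breed_map=breed_map)
        hio.write_table(classifications, outdir / "herd_classifications.csv")
        record("classify", seconds=round(time.perf_counter() - t0, 2),
               herd_years=len(classifications),
               type_counts=classifications["herd_type"].value_counts().to_dict())

        stage = "predict"
        t0 = time.perf_counter()
        predictions = agg.predict_population(fits, snaps, breed_map)
        record("predict", seconds=round(time.perf_counter() - t0, 2),
               prediction_rows=len(predictions))

        stage = "aggregate"
        t0 = time.perf_counter()
        hmt = agg.herd_month_totals(predictions)
        profile = agg.within_year_profile(hmt, classifications, cpi)
        annual = agg.annual_and_sector(hmt, classifications, cpi)
        hio.write_table(hmt, outdir / "herd_month_totals.csv")
        hio.write_table(profile, outdir / "within_year_profile.csv")
        for level, frame in annual.items():
            hio.write_table(frame, outdir / f"annual_{level}.csv")
        sector = annual["sector"]
        record("aggregate", seconds=round(time.perf_counter() - t0, 2),
               herd_months=len(hmt),
               sector_biomass_tonnes={int(y): round(b / 1e3, 1) for y, b in
                                      zip(sector["year"], sector["biomass_kg"])})

        stage = "validate"
        t0 = time.perf_counter()
        comparison = validate_value_model(
            {"female": fits[("value", "female")], "male": fits[("value", "male")]},
            market, cat_map, breed_map)
        hio.write_table(comparison, outdir / "value_validation.csv")
        record("validate", seconds=round(time.perf_counter() - t0, 2),
               categories=len(comparison),
               within_10pct=int(comparison["within_10pct"].sum()))
    except Exception as exc:
        record("failure", stage=stage, error=str(exc))
        raise HerdmassError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["completed"] = True
    hio.write_manifest(outdir / "manifest.json", manifest)
    return manifest
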