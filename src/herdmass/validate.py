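"""Value-model validation against market data, and reference biomass units.

The market dataset records an animal *category* (calf, weaned, maiden
heifer, ...) but no date of birth, so validation maps each category to an
age range in months, predicts the value at each integer month of age in
the range (covariates fixed at the dataset's median sale month and
year), averages those predictions, and compares the result with the
observed mean market price per category — reported per sector (dairy /
beef) as market mean, predicted mean and signed relative difference.

Also provided are the standard head-count biomass converters: livestock
units (LSU, 650 kg per grazing adult dairy cow), tropical livestock
units (TLU, 250 kg per head) and the population correction unit (PCU,
450 kg per adult cow with lighter weights for younger stock).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .cleaning import BreedMap, resolve_breed
from .errors import ConfigurationError, UnmappableBreedError
from .segmented import SegmentedFit

DAYS_PER_MONTH = 30.4375


def _load_yaml(name: str) -> dict:
    ref = resources.files("herdmass.data") / name
    with resources.as_file(ref) as path:
        with open(path) as fh:
            return yaml.safe_load(fh)


def default_category_age_map() -> dict:
    """Packaged category -> (min_months, max_months) map (user-replaceable)."""
    raw = _load_yaml("category_age_map.yaml")["category_age_map"]
    return {k: tuple(v) for k, v in raw.items()}


DEFAULT_CATEGORY_AGE_MAP = default_category_age_map()


@dataclass(frozen=True)
class UnitConstants:
    """Reference liveweights (kg) of the standard aggregation units."""

    lsu_kg: float = 650.0
    tlu_kg: float = 250.0
    pcu_adult_cow_kg: float = 450.0

    def __post_init__(self):
        if min(self.lsu_kg, self.tlu_kg, self.pcu_adult_cow_kg) <= 0:
            raise ConfigurationError("unit constants must be positive")

    @classmethod
    def default(cls) -> "UnitConstants":
        raw = _load_yaml("unit_constants.yaml")["unit_constants"]
        return cls(lsu_kg=float(raw["lsu_kg"]), tlu_kg=float(raw["tlu_kg"]),
                   pcu_adult_cow_kg=float(raw["pcu_adult_cow_kg"]))


def default_lsu_coefficients() -> dict:
    return dict(_load_yaml("unit_constants.yaml")["lsu_coefficients"])


def default_pcu_weights() -> dict:
    return dict(_load_yaml("unit_constants.yaml")["pcu_weights"])


# ---------------------------------------------------------------------------
# category-level prediction


def predicted_category_mean(fit: SegmentedFit, category: str, cat_map: dict,
                            median_month: int, median_year: int,
                            breed_category: str) -> float:
    """Unweighted mean prediction over each integer month of age in the
    category's range, covariates fixed at the median sale month/year."""
    if category not in cat_map:
        raise ConfigurationError(f"category {category!r} not in the age map")
    lo, hi = cat_map[category]
    months = np.arange(lo, hi + 1)
    ages = months * DAYS_PER_MONTH
    preds = fit.predict(ages, breed_category=[breed_category] * len(ages),
                        month=[median_month] * len(ages),
                        year=[median_year] * len(ages))
    return float(np.mean(preds))


def validate_value_model(fits: dict, market: pd.DataFrame,
                         cat_map: dict | None = None,
                         breed_map: BreedMap | None = None) -> pd.DataFrame:
    """Compare mean market prices with category-mean model predictions.

    ``fits`` holds the sex-specific value fits keyed by sex. Records are
    grouped by sector (dairy vs beef, from the breed code) and category;
    each group's prediction is the category-mean prediction averaged over
    the group's empirical sex x breed composition, at the dataset's
    median sale month and year. Categories missing from the age map are
    listed in the ``excluded_categories`` attribute of the result.
    """
    if market.empty:
        raise ConfigurationError("market table is empty")
    cat_map = cat_map or DEFAULT_CATEGORY_AGE_MAP
    breed_map = breed_map or BreedMap.default()
    df = market.copy()
    dates = pd.to_datetime(df["sale_date"])
    median_month = int(dates.dt.month.median())
    median_year = int(dates.dt.year.median())

    def sector(code):
        try:
            return "dairy" if resolve_breed(code, breed_map) == "dairy" else "beef"
        except UnmappableBreedError:
            return "unknown"

    def breed_cat(code):
        try:
            return resolve_breed(code, breed_map)
        except UnmappableBreedError:
            return None

    df["sector"] = df["breed_code"].map(sector)
    df["breed_category"] = df["breed_code"].map(breed_cat)
    df = df[df["sector"] != "unknown"]

    excluded = sorted(set(df["animal_category"]) - set(cat_map))
    df = df[df["animal_category"].isin(cat_map)]

    rows = []
    for (sec, cat), grp in df.groupby(["sector", "animal_category"], sort=True):
        comp = grp.groupby(["sex", "breed_category"]).size() / len(grp)
        pred = sum(
            w * predicted_category_mean(fits[sex], cat, cat_map,
                                        median_month, median_year, breed)
            for (sex, breed), w in comp.items())
        mkt = float(grp["price"].mean())
        rows.append({
            "sector": sec, "animal_category": cat, "n": len(grp),
            "market_mean_eur": mkt, "predicted_eur": pred,
            "rel_diff": pred / mkt - 1.0,
            "within_10pct": abs(pred / mkt - 1.0) <= 0.10,
        })
    out = pd.DataFrame(rows)
    out.attrs["excluded_categories"] = excluded
    out.attrs["median_month"] = median_month
    out.attrs["median_year"] = median_year
    return out


# ---------------------------------------------------------------------------
# reference biomass units


def reference_biomass(head_counts: dict, mode: str,
                      constants: UnitConstants | None = None,
                      lsu_coefficients: dict | None = None,
                      pcu_weights: dict | None = None) -> float:
    """Convert per-category head counts to kg under a reference-unit scheme.

    ``lsu``: sum of (count x category LSU coefficient) x 650 kg;
    ``tlu``: total head x 250 kg;
    ``pcu``: sum of count x category PCU liveweight (450 kg adult cow).
    Linear in the head counts by construction.
    """
    constants = constants or UnitConstants.default()
    if any(v < 0 for v in head_counts.values()):
        raise ConfigurationError("head counts must be non-negative")
    if mode == "tlu":
        return sum(head_counts.values()) * constants.tlu_kg
    if mode == "lsu":
        coefs = lsu_coefficients or default_lsu_coefficients()
        total = 0.0
        for cat, n in head_counts.items():
            if cat not in coefs:
                raise ConfigurationError(f"no LSU coefficient for category {cat!r}")
            total += n * coefs[cat] * constants.lsu_kg
        return total
    if mode == "pcu":
        weights = pcu_weights or default_pcu_weights()
        scale = constants.pcu_adult_cow_kg / weights.get("adult_cow", 450)
        total = 0.0
        for cat, n in head_counts.items():
            if cat not in weights:
                raise ConfigurationError(f"no PCU weight for category {cat!r}")
            total += n * weights[cat] * scale
        return total
    raise ConfigurationError(f"unknown mode {mode!r}; use lsu, tlu or pcu")
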