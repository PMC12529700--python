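"""Herd-type classification from January/May/September snapshots.

Each herd receives one (type, subtype) label per calendar year from an
ordered decision tree over composition and flow features: calvings mark
breeding herds (dairy / beef / mixed by the breed make-up of the adult
females), herds without calvings split into store/rearing, fattening and
trading by the age profile of their members, inflows and stock turnover,
and herds with no data in all three index months fall back to a
trading / fattening / unclassified sub-rule driven by flows alone.

The operational tree's thresholds are not public; the defaults shipped
in ``data/classifier_rules.yaml`` reproduce the taxonomy's behaviour on
the synthetic archetypes and are user-replaceable. The rule *order* is
fixed and versioned here: permuting rules may change outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .cleaning import BreedMap, resolve_breed
from .errors import UnmappableBreedError

HERD_TYPES = ("beef", "dairy", "fattening", "store_rearing", "mixed",
              "trading", "unclassified")

SUBTYPES_BY_TYPE = {
    "beef": ("BP", "BSB", "BSW", "BSY", "BSY_nR"),
    "dairy": ("D", "DnR_C", "DnR_nC", "DRm"),
    "store_rearing": ("Rdf", "Sbf", "Sbm", "Sbmx", "Sdm"),
    "fattening": ("none",),
    "mixed": ("none",),
    "trading": ("none",),
    "unclassified": ("none",),
}

INDEX_MONTHS = (1, 5, 9)   # January, May, September


@dataclass
class ClassifierRules:
    """Named thresholds plus the fixed rule order of the decision tree."""

    thresholds: dict
    #: evaluation order of the top-level rules (documentation + audit)
    rule_order: tuple = ("no_snapshot_data", "breeding_mixed", "breeding_dairy",
                         "breeding_beef", "trading", "fattening",
                         "store_rearing", "default_unclassified")

    @classmethod
    def from_yaml(cls, path) -> "ClassifierRules":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(thresholds=dict(raw["thresholds"]))

    @classmethod
    def default(cls) -> "ClassifierRules":
        ref = resources.files("herdmass.data") / "classifier_rules.yaml"
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)


@dataclass
class HerdClassification:
    herd_id: str
    year: int
    herd_type: str
    subtype: str
    rule_trace: list = field(default_factory=list)

    def __post_init__(self):
        assert self.subtype in SUBTYPES_BY_TYPE[self.herd_type], \
            f"subtype {self.subtype} invalid for {self.herd_type}"
        assert self.rule_trace, "rule_trace must be non-empty"


# ---------------------------------------------------------------------------
# features


def herd_features(herd_id: str, year: int, snapshots: pd.DataFrame,
                  events: pd.DataFrame, breed_map: BreedMap | None = None,
                  adult_age_days: int = 730, progeny_max_age: int = 1000) -> dict:
    """Deterministic composition/flow feature vector for one herd-year.

    ``snapshots`` is the long snapshot table (any months; the January,
    May and September states of ``year`` are used); ``events`` the full
    event log. Missing index-month snapshots are features, not errors.
    """
    breed_map = breed_map or BreedMap.default()

    def cat(code):
        try:
            return resolve_breed(code, breed_map)
        except UnmappableBreedError:
            return "unknown"

    sdates = pd.to_datetime(snapshots["snapshot_date"]) if len(snapshots) else pd.Series(dtype="datetime64[ns]")
    parts = []
    present = {}
    for m in INDEX_MONTHS:
        mask = (snapshots["herd_id"] == herd_id) & (sdates.dt.year == year) \
            & (sdates.dt.month == m) if len(snapshots) else pd.Series(dtype=bool)
        part = snapshots[mask] if len(snapshots) else snapshots
        present[m] = len(part) > 0
        parts.append(part)
    members = pd.concat(parts) if parts and any(len(p) for p in parts) else \
        pd.DataFrame(columns=["animal_id", "age_days", "sex", "breed_code"])
    n_snapshot_obs = max(sum(present.values()), 1)

    is_dairy = members["breed_code"].map(lambda c: cat(c) == "dairy") \
        if len(members) else pd.Series(dtype=bool)
    adult_f = members[(members["sex"] == "female")
                      & (members["age_days"] > adult_age_days)] if len(members) else members
    adult_f_dairy = int(is_dairy.loc[adult_f.index].sum()) if len(adult_f) else 0
    young = members[members["age_days"] <= adult_age_days] if len(members) else members

    ev = events.copy()
    ev_dates = pd.to_datetime(ev["event_date"])
    in_year = (ev["herd_id"] == herd_id) & (ev_dates.dt.year == year)
    hy = ev[in_year].copy()
    hy["age_at_event"] = (ev_dates[in_year]
                          - pd.to_datetime(hy["date_of_birth"])).dt.days

    births = int((hy["event_kind"] == "birth").sum())
    inflow = hy[hy["event_kind"] == "move_in"]
    outflow = hy[hy["event_kind"] == "move_out"]
    deaths = hy[hy["event_kind"] == "death"]

    # home-bred progeny departures (sold or slaughtered) this year; capped
    # by age so that cull departures of home-bred cows do not count
    homebred = set(ev.loc[(ev["event_kind"] == "birth")
                          & (ev["herd_id"] == herd_id), "animal_id"])
    depart = hy[hy["event_kind"].isin(("move_out", "death"))
                & hy["animal_id"].isin(homebred)
                & (hy["age_at_event"] <= progeny_max_age)]

    # stays: animals that entered this herd and left it again; exits this year
    herd_ev = ev[ev["herd_id"] == herd_id]
    stays = []
    for aid, grp in herd_ev.groupby("animal_id", sort=False):
        grp = grp.sort_values("event_date", kind="mergesort")
        entry = None
        for r in grp.itertuples(index=False):
            if r.event_kind == "move_in":
                entry = r.event_date
            elif r.event_kind in ("move_out", "death") and entry is not None:
                exit_date = pd.Timestamp(r.event_date)
                if exit_date.year == year:
                    stays.append((exit_date - pd.Timestamp(entry)).days)
                entry = None

    n_members = len(members) / n_snapshot_obs
    n_adult_f = len(adult_f)

    def frac(part, whole):
        return part / whole if whole else 0.0

    young_dairy = is_dairy.loc[young.index] if len(young) else pd.Series(dtype=bool)
    codes = adult_f["breed_code"] if len(adult_f) else pd.Series(dtype=object)
    purity = codes.value_counts(normalize=True).max() if len(codes) else 0.0

    return {
        "herd_id": herd_id, "year": year,
        "present_jan": present[1], "present_may": present[5],
        "present_sep": present[9],
        "any_snapshot_data": any(present.values()),
        "n_members_mean": n_members,
        "n_adult_f": n_adult_f,
        "adult_f_dairy_frac": frac(adult_f_dairy, n_adult_f),
        "adult_f_beef_frac": frac(n_adult_f - adult_f_dairy, n_adult_f),
        "adult_breed_purity": float(purity),
        "young_frac": frac(len(young), len(members)),
        "young_per_birth": frac(len(young) / n_snapshot_obs, births),
        "young_male_per_birth": frac(
            len(young[young["sex"] == "male"]) / n_snapshot_obs if len(young) else 0,
            births),
        "young_dairy_female_frac": frac(
            int((young_dairy & (young["sex"] == "female")).sum()) if len(young) else 0,
            len(young)),
        "young_dairy_male_frac": frac(
            int((young_dairy & (young["sex"] == "male")).sum()) if len(young) else 0,
            len(young)),
        "young_beef_female_frac": frac(
            int((~young_dairy & (young["sex"] == "female")).sum()) if len(young) else 0,
            len(young)),
        "young_beef_male_frac": frac(
            int((~young_dairy & (young["sex"] == "male")).sum()) if len(young) else 0,
            len(young)),
        "births": births,
        "n_inflow": len(inflow), "n_outflow": len(outflow), "n_deaths": len(deaths),
        "mean_inflow_age": float(inflow["age_at_event"].mean()) if len(inflow) else np.nan,
        "mean_outflow_age": float(outflow["age_at_event"].mean()) if len(outflow) else np.nan,
        "mean_homebred_departure_age": float(depart["age_at_event"].mean())
        if len(depart) else np.nan,
        "n_homebred_departures": len(depart),
        "mean_stay_days": float(np.mean(stays)) if stays else np.nan,
        "throughput": (len(inflow) + len(outflow)) / max(n_members, 1.0),
        "contract_heifer_inflow": 0,  # filled by classify_all when configured
    }


# ---------------------------------------------------------------------------
# the decision tree


def classify_herd(features: dict, rules: ClassifierRules | None = None) -> HerdClassification:
    """Run the ordered rules over one herd-year feature vector."""
    rules = rules or ClassifierRules.default()
    t = rules.thresholds
    f = features
    trace = []

    def out(herd_type, subtype, rule_id):
        trace.append(rule_id)
        return HerdClassification(f["herd_id"], f["year"], herd_type, subtype,
                                  rule_trace=trace)

    def is_trading():
        return (f["throughput"] >= t["trading_throughput"]
                and (np.isnan(f["mean_stay_days"])
                     or f["mean_stay_days"] <= t["trading_max_stay_days"]))

    def is_fattening():
        return (not np.isnan(f["mean_inflow_age"])
                and f["mean_inflow_age"] >= t["fattening_min_inflow_age"]
                and (f["n_deaths"] > 0 or f["n_outflow"] > 0 or f["n_inflow"] > 0))

    # 1. no data in any index month: flows decide among trading/fattening/unknown
    if not f["any_snapshot_data"]:
        trace.append("no_snapshot_data")
        if (f["n_inflow"] + f["n_outflow"]) > 0 and is_trading():
            return out("trading", "none", "fallback_trading")
        if is_fattening():
            return out("fattening", "none", "fallback_fattening")
        return out("unclassified", "none", "fallback_unclassified")
    trace.append("has_snapshot_data")

    # 2. breeding herds: calvings occurred
    if f["births"] >= t["min_births"] and f["n_adult_f"] > 0:
        trace.append("breeding")
        if (f["adult_f_dairy_frac"] >= t["mixed_cow_fraction"]
                and f["adult_f_beef_frac"] >= t["mixed_cow_fraction"]
                and f["adult_f_dairy_frac"] < t["dairy_cow_fraction"]):
            return out("mixed", "none", "mixed_cows")
        if f["adult_f_dairy_frac"] >= t["dairy_cow_fraction"]:
            trace.append("dairy_majority")
            if f["adult_f_beef_frac"] >= t["mixed_cow_fraction"]:
                return out("mixed", "none", "mixed_cows_dairy_lean")
            if f["young_male_per_birth"] >= t["male_young_fraction"]:
                return out("dairy", "DRm", "dairy_rearing_males")
            if f["young_per_birth"] >= t["rearing_young_per_birth"]:
                return out("dairy", "D", "dairy_standard")
            if f["contract_heifer_inflow"] > 0:
                return out("dairy", "DnR_C", "dairy_nonrearing_contract")
            return out("dairy", "DnR_nC", "dairy_nonrearing")
        trace.append("beef_majority")
        if f["adult_breed_purity"] >= t["breed_purity_pedigree"]:
            return out("beef", "BP", "beef_pedigree")
        dep_age = f["mean_homebred_departure_age"]
        if f["n_homebred_departures"] == 0 or np.isnan(dep_age):
            return out("beef", "BSB", "beef_no_departures_default")
        if dep_age <= t["weanling_max_age"]:
            return out("beef", "BSW", "beef_weanling_seller")
        if dep_age <= t["youngstock_max_age"]:
            if f["young_per_birth"] < t["rearing_young_per_birth"]:
                return out("beef", "BSY_nR", "beef_youngstock_nonrearing")
            return out("beef", "BSY", "beef_youngstock_seller")
        return out("beef", "BSB", "beef_finisher")

    trace.append("non_breeding")
    # 3. no calvings: trading, fattening, store/rearing, else unclassified
    if (f["n_inflow"] + f["n_outflow"]) > 0 and is_trading():
        return out("trading", "none", "trading_throughput")
    if is_fattening():
        return out("fattening", "none", "fattening_inflow_age")
    if f["young_frac"] >= t["youngstock_fraction"] and f["n_members_mean"] > 0:
        trace.append("store_rearing")
        comp = {
            "Rdf": f["young_dairy_female_frac"], "Sdm": f["young_dairy_male_frac"],
            "Sbf": f["young_beef_female_frac"], "Sbm": f["young_beef_male_frac"],
        }
        top = max(comp, key=comp.get)
        if comp[top] >= 0.7:
            return out("store_rearing", top, f"store_{top}")
        if f["young_dairy_female_frac"] + f["young_dairy_male_frac"] < 0.5:
            return out("store_rearing", "Sbmx", "store_beef_mixed")
        return out("store_rearing", top, f"store_{top}_plurality")
    return out("unclassified", "none", "default_unclassified")


def classify_all(snapshots: pd.DataFrame, events: pd.DataFrame,
                 rules: ClassifierRules | None = None,
                 years=None, breed_map: BreedMap | None = None) -> pd.DataFrame:
    """One classification per herd per year, with the fired rule trace."""
    rules = rules or ClassifierRules.default()
    breed_map = breed_map or BreedMap.default()
    herds = sorted(set(events["herd_id"]) | set(snapshots["herd_id"]))
    if years is None:
        years = sorted(pd.to_datetime(snapshots["snapshot_date"]).dt.year.unique())
    lo, hi = rules.thresholds.get("contract_heifer_inflow_age", [550, 1000])
    rows = []
    for year in years:
        for herd in herds:
            feats = herd_features(
                herd, int(year), snapshots, events, breed_map,
                adult_age_days=rules.thresholds["adult_age_days"],
                progeny_max_age=rules.thresholds.get("progeny_max_age", 1000))
            # contract-rearing signature: older heifers flowing back in
            if feats["n_inflow"] and not np.isnan(feats["mean_inflow_age"]):
                feats["contract_heifer_inflow"] = int(
                    lo <= feats["mean_inflow_age"] <= hi)
            c = classify_herd(feats, rules)
            rows.append({"herd_id": c.herd_id, "year": c.year,
                         "herd_type": c.herd_type, "subtype": c.subtype,
                         "rule_trace": ";".join(c.rule_trace)})
    return pd.DataFrame(rows)
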