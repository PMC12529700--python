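"""Record-retention and breed-categorisation rules for slaughter-valuation data.

Three rules are applied, in a fixed, documented order:

1. completeness — records missing value (or with value 0), liveweight,
   date of birth, date of death, sex or breed are dropped;
2. liveweight window — 30-1,400 kg for calves, heifers and steers,
   200-1,400 kg for bulls, cows and pregnant heifers (both endpoints
   inclusive); weights outside these ranges are treated as entry errors;
3. breed mapping — codes are resolved to dairy / continental beef /
   British-Irish beef, stripping cross markers (e.g. ``FRX`` -> ``FR``,
   the sire breed) first; unmappable codes drop the record.

Each dropped record is attributed to the *first* rule it fails, so the
per-rule counts in the report sum to the total dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml

from .errors import ConfigurationError, UnmappableBreedError

LIGHT_CLASSES = ("calf", "heifer", "steer")
HEAVY_CLASSES = ("bull", "cow", "pregnant_heifer")

#: inclusive liveweight retention windows (kg) per animal class
WEIGHT_WINDOWS = {
    **{c: (30.0, 1400.0) for c in LIGHT_CLASSES},
    **{c: (200.0, 1400.0) for c in HEAVY_CLASSES},
}

REQUIRED_FIELDS = ("value", "liveweight", "date_of_birth", "date_of_death",
                   "sex", "breed_code")


@dataclass
class BreedMap:
    """Breed code -> category lookup with cross-marker handling."""

    mapping: dict
    cross_suffixes: tuple = ("X",)

    def __post_init__(self):
        bad = {c for c in self.mapping.values()
               if c not in ("dairy", "continental_beef", "british_irish_beef")}
        if bad:
            raise ConfigurationError(f"unknown breed categories in map: {sorted(bad)}")
        if not self.mapping:
            raise ConfigurationError("breed map is empty")

    @classmethod
    def from_yaml(cls, path) -> "BreedMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(mapping=dict(raw["mapping"]),
                   cross_suffixes=tuple(raw.get("cross_suffixes", ["X"])))

    @classmethod
    def default(cls) -> "BreedMap":
        """The packaged default map (replaceable; the national list is not public)."""
        ref = resources.files("herdmass.data") / "breed_map.yaml"
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)


def resolve_breed(breed_code: str, breed_map: BreedMap) -> str:
    """Resolve a breed code to its category, stripping cross markers.

    A cross code such as ``FRX`` (Friesian cross) is reduced to the sire
    breed ``FR`` before lookup.
    """
    code = str(breed_code).strip().upper()
    if code in breed_map.mapping:
        return breed_map.mapping[code]
    for suf in breed_map.cross_suffixes:
        if code.endswith(suf) and len(code) > len(suf):
            stripped = code[: -len(suf)]
            if stripped in breed_map.mapping:
                return breed_map.mapping[stripped]
    raise UnmappableBreedError(breed_code)


def retain_liveweight(record) -> bool:
    """True iff the record's liveweight is inside its class's window."""
    cls = record["animal_class"]
    if cls not in WEIGHT_WINDOWS:
        raise ConfigurationError(f"unknown animal class {cls!r}")
    w = record["liveweight"]
    if w is None or pd.isna(w):
        return False
    lo, hi = WEIGHT_WINDOWS[cls]
    return lo <= float(w) <= hi


def retain_complete(record) -> bool:
    """True iff no required field is missing and the value is non-zero."""
    for f in REQUIRED_FIELDS:
        v = record.get(f) if isinstance(record, dict) else record[f]
        if v is None or (isinstance(v, float) and pd.isna(v)) or pd.isna(v) or v == "":
            return False
    return float(record["value"]) != 0.0


@dataclass
class CleaningReport:
    n_input: int = 0
    dropped_incomplete: int = 0
    dropped_weight_window: int = 0
    dropped_unmappable_breed: int = 0
    unmappable_codes: list = field(default_factory=list)
    n_retained: int = 0

    @property
    def n_dropped(self) -> int:
        return (self.dropped_incomplete + self.dropped_weight_window
                + self.dropped_unmappable_breed)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "dropped_incomplete": self.dropped_incomplete,
            "dropped_weight_window": self.dropped_weight_window,
            "dropped_unmappable_breed": self.dropped_unmappable_breed,
            "unmappable_codes": sorted(set(self.unmappable_codes)),
            "n_retained": self.n_retained,
        }


def clean_dataset(records: pd.DataFrame,
                  breed_map: BreedMap | None = None) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the three retention rules and attach a ``breed_category`` column."""
    breed_map = breed_map or BreedMap.default()
    report = CleaningReport(n_input=len(records))
    if records.empty:
        out = records.copy()
        out["breed_category"] = pd.Series(dtype=object)
        return out, report

    df = records.copy()

    complete = df.apply(retain_complete, axis=1)
    report.dropped_incomplete = int((~complete).sum())
    df = df[complete]

    if not df.empty:
        in_window = df.apply(retain_liveweight, axis=1)
        report.dropped_weight_window = int((~in_window).sum())
        df = df[in_window]

    cats = []   # categories for resolvable codes, in kept-row order
    keep = []
    for code in df["breed_code"]:
        try:
            cats.append(resolve_breed(code, breed_map))
            keep.append(True)
        except UnmappableBreedError:
            report.unmappable_codes.append(str(code))
            keep.append(False)
    report.dropped_unmappable_breed = len(keep) - sum(keep)
    df = df[pd.Series(keep, index=df.index)].copy()
    df["breed_category"] = cats
    report.n_retained = len(df)
    return df.reset_index(drop=True), report
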