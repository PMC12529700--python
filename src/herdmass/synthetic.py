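"""Synthetic stand-ins for the national cattle databases.

The real inputs to the pipeline are confidential national systems: a
slaughter-valuation dataset of weighed and valued animals, a livestock
market price dataset, and the full registration/movement database. This
module generates structurally equivalent tables with *known* ground
truth, so every downstream stage (cleaning, segmented fitting, snapshot
reconstruction, classification, aggregation, validation) can be tested
end to end without any external data.

Ground truth for weight and value is a continuous piecewise-linear curve
in age (days) per sex and breed category, with additive calendar-month
and year offsets and Gaussian noise — exactly the functional form the
segmented regression assumes, so the generator doubles as the oracle in
parameter-recovery studies. Herd demography is driven by archetypes
(dairy, suckler beef, store/rearing, fattening, trading, ...) whose
calving seasons, sale ages and trade routes produce the seasonal herd
composition patterns the classifier and aggregation stages must detect.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregate import CPISeries
from .errors import ConfigurationError

SEXES = ("female", "male")
BREED_CATEGORIES = ("dairy", "continental_beef", "british_irish_beef")

#: representative breed codes per category (used when emitting raw tables)
BREED_CODES = {
    "dairy": ("FR", "HO", "JE"),
    "continental_beef": ("CH", "LM", "BB", "SI"),
    "british_irish_beef": ("AA", "HE", "SH"),
}

ANIMAL_CLASSES = ("calf", "heifer", "steer", "bull", "cow", "pregnant_heifer")

#: animal class -> (sex restriction or None, age window in days).
#: Class boundaries are a generator convention (configurable), chosen so
#: that each class occupies a plausible, distinct region of the age axis.
CLASS_WINDOWS = {
    "calf": (None, (14, 180)),
    "heifer": ("female", (181, 900)),
    "pregnant_heifer": ("female", (450, 1000)),
    "cow": ("female", (1000, 4000)),
    "steer": ("male", (240, 1100)),
    "bull": ("male", (365, 3500)),
}

DAYS_PER_MONTH = 30.4375


# ---------------------------------------------------------------------------
# piecewise ground truth


@dataclass(frozen=True)
class PiecewiseTruth:
    """Continuous piecewise-linear mean curve with calendar offsets."""

    sex: str
    breed_category: str
    intercept: float
    segment_slopes: tuple            # per-day slopes, length len(break_points)+1
    break_points: tuple              # strictly increasing age-days
    month_effects: tuple = tuple([0.0] * 12)   # offset per calendar month 1..12
    year_effects: dict = field(default_factory=dict)  # year -> offset
    noise_sd: float = 0.0

    def __post_init__(self):
        bps = tuple(self.break_points)
        if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
            raise ConfigurationError("break_points must be strictly increasing")
        if len(self.segment_slopes) != len(bps) + 1:
            raise ConfigurationError("need len(break_points)+1 segment slopes")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if len(self.month_effects) != 12:
            raise ConfigurationError("month_effects must have 12 entries")

    def mean(self, age_days, month=None, year=None):
        """Expected response at an age (days), scalar or array."""
        a = np.asarray(age_days, dtype=float)
        out = np.full_like(a, self.intercept, dtype=float)
        prev = 0.0
        for slope, bp in zip(self.segment_slopes, list(self.break_points) + [np.inf]):
            out = out + slope * (np.clip(a, prev, bp) - prev)
            prev = bp
        if month is not None:
            m = np.asarray(month, dtype=int)
            out = out + np.asarray(self.month_effects)[m - 1]
        if year is not None:
            yr = np.asarray(year, dtype=int)
            eff = np.vectorize(lambda v: self.year_effects.get(int(v), 0.0))
            out = out + (eff(yr) if yr.shape else self.year_effects.get(int(yr), 0.0))
        return float(out) if np.ndim(age_days) == 0 else out


class GrowthTruth(PiecewiseTruth):
    """Liveweight (kg) ground truth."""


class ValueTruth(PiecewiseTruth):
    """Monetary value (EUR) ground truth."""


def _seasonal(amplitude: float) -> tuple:
    m = np.arange(12)
    return tuple(np.round(amplitude * np.sin(2 * np.pi * m / 12), 3))


def _trend(per_year: float, years=(2011, 2021)) -> dict:
    return {y: per_year * (y - years[0]) for y in range(years[0], years[1] + 1)}


def default_growth_truths(noise_sd: float = 40.0, month_amplitude: float = 10.0,
                          year_trend: float = 4.0) -> dict:
    """Liveweight truths keyed by (sex, breed_category).

    Break positions follow the fitted national models (females 608/1878
    days, males 713/1884 days); intercepts and slopes give birthweights
    near 40 kg, rapid growth to ~18-24 months, slower growth to maturity
    and a near-plateau thereafter. Breed categories differ by intercept
    shifts only (continental beef heaviest, dairy lightest).
    """
    breed_shift = {"dairy": 0.0, "british_irish_beef": 25.0, "continental_beef": 60.0}
    base = {
        "female": dict(intercept=40.0, segment_slopes=(0.75, 0.18, 0.04),
                       break_points=(608.0, 1878.0)),
        "male": dict(intercept=42.0, segment_slopes=(0.95, 0.28, 0.05),
                     break_points=(713.0, 1884.0)),
    }
    out = {}
    for sex, kw in base.items():
        for breed, shift in breed_shift.items():
            out[(sex, breed)] = GrowthTruth(
                sex=sex, breed_category=breed,
                intercept=kw["intercept"] + shift,
                segment_slopes=kw["segment_slopes"],
                break_points=kw["break_points"],
                month_effects=_seasonal(month_amplitude),
                year_effects=_trend(year_trend),
                noise_sd=noise_sd,
            )
    return out


def default_value_truths(noise_sd: float = 100.0, month_amplitude: float = 20.0,
                         year_trend: float = 25.0) -> dict:
    """Value (EUR) truths keyed by (sex, breed_category).

    Female value rises to a peak in early lactations and declines slowly
    for older cows; male value climbs steeply for young feeders and then
    flattens. Break positions follow the fitted national models
    (females 682/1254 days, males 335/1041 days).
    """
    breed_shift = {"dairy": 0.0, "british_irish_beef": 60.0, "continental_beef": 150.0}
    base = {
        "female": dict(intercept=150.0, segment_slopes=(1.50, 0.50, -0.05),
                       break_points=(682.0, 1254.0)),
        "male": dict(intercept=150.0, segment_slopes=(2.20, 0.90, 0.05),
                     break_points=(335.0, 1041.0)),
    }
    out = {}
    for sex, kw in base.items():
        for breed, shift in breed_shift.items():
            out[(sex, breed)] = ValueTruth(
                sex=sex, breed_category=breed,
                intercept=kw["intercept"] + shift,
                segment_slopes=kw["segment_slopes"],
                break_points=kw["break_points"],
                month_effects=_seasonal(month_amplitude),
                year_effects=_trend(year_trend),
                noise_sd=noise_sd,
            )
    return out


def _check_truth_coverage(truths: dict, what: str) -> None:
    missing = [(s, b) for s in SEXES for b in BREED_CATEGORIES if (s, b) not in truths]
    if missing:
        raise ConfigurationError(f"{what} truths missing sex/breed combinations: {missing}")


# ---------------------------------------------------------------------------
# slaughter-valuation records


def generate_slaughter_records(truth_w: dict, truth_v: dict, n_per_class: int,
                               seed: int, years: tuple = (2011, 2021),
                               cross_fraction: float = 0.2,
                               heteroscedastic: bool = False) -> pd.DataFrame:
    """Valued, weighed animals at slaughter, ``n_per_class`` per animal class.

    Liveweight and value are the piecewise-linear truth means at the
    animal's age plus month/year offsets plus Gaussian noise (optionally
    heteroscedastic: SD proportional to the mean). Ages are uniform in
    each class's window; slaughter dates uniform over the study years.
    """
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    _check_truth_coverage(truth_w, "liveweight")
    _check_truth_coverage(truth_v, "value")
    rng = np.random.default_rng(seed)
    start = dt.date(years[0], 1, 1)
    end = dt.date(years[1], 12, 31)
    span = (end - start).days
    rows = []
    aid = 0
    for cls in ANIMAL_CLASSES:
        sex_rule, (age_lo, age_hi) = CLASS_WINDOWS[cls]
        for _ in range(n_per_class):
            aid += 1
            sex = sex_rule or ("female" if rng.random() < 0.5 else "male")
            breed_cat = BREED_CATEGORIES[rng.integers(3)]
            code = BREED_CODES[breed_cat][rng.integers(len(BREED_CODES[breed_cat]))]
            is_cross = rng.random() < cross_fraction
            age = int(rng.integers(age_lo, age_hi + 1))
            death = start + dt.timedelta(days=int(rng.integers(0, span + 1)))
            birth = death - dt.timedelta(days=age)
            tw, tv = truth_w[(sex, breed_cat)], truth_v[(sex, breed_cat)]
            mw = tw.mean(age, month=death.month, year=death.year)
            mv = tv.mean(age, month=death.month, year=death.year)
            sw, sv = tw.noise_sd, tv.noise_sd
            if heteroscedastic:
                sw = sw * mw / max(tw.mean((age_lo + age_hi) / 2), 1e-9)
                sv = sv * mv / max(tv.mean((age_lo + age_hi) / 2), 1e-9)
            rows.append({
                "animal_id": f"A{aid:07d}",
                "breed_code": code + "X" if is_cross else code,
                "sire_breed_code": code if is_cross else "",
                "animal_class": cls,
                "sex": sex,
                "date_of_birth": birth,
                "date_of_death": death,
                "liveweight": mw + rng.normal(0.0, sw),
                "value": max(mv + rng.normal(0.0, sv), 1.0),
            })
    return pd.DataFrame(rows)


def simulate_response_sample(truths: dict, sex: str, n: int, seed: int,
                             response_col: str, age_range: tuple = (30, 3800),
                             years: tuple = (2011, 2021)) -> pd.DataFrame:
    """A flat regression sample from the truth curves for one sex.

    Ages are uniform over ``age_range`` (so every segment is well covered),
    breed categories equiprobable, months and years uniform. Used for
    break-point recovery studies where class stratification is irrelevant.
    """
    rng = np.random.default_rng(seed)
    ages = rng.integers(age_range[0], age_range[1] + 1, size=n)
    breeds = np.array(BREED_CATEGORIES)[rng.integers(3, size=n)]
    months = rng.integers(1, 13, size=n)
    yrs = rng.integers(years[0], years[1] + 1, size=n)
    resp = np.empty(n)
    for i in range(n):
        t = truths[(sex, breeds[i])]
        resp[i] = t.mean(ages[i], month=months[i], year=yrs[i]) + rng.normal(0, t.noise_sd)
    return pd.DataFrame({
        "age_days": ages.astype(float), "breed_category": breeds,
        "month": months, "year": yrs, "sex": sex, response_col: resp,
    })


# ---------------------------------------------------------------------------
# livestock market records


#: which sex a market category implies (None -> either)
CATEGORY_SEX = {
    "calf": None, "weaned": None, "maiden_heifer": "female",
    "in_calf_heifer": "female", "young_bull_feeder": "male",
    "light_store": None, "forward_store": None,
    "lactation_1": "female", "lactation_2": "female", "lactation_3": "female",
    "lactation_4plus": "female", "finished": None, "cull_cow": "female",
}


def generate_market_records(truth_v: dict, category_age_map: dict, n: int,
                            seed: int, years: tuple = (2011, 2021),
                            balanced: bool = False) -> pd.DataFrame:
    """Market price records carrying an animal category but no birth date.

    Each record draws a latent age uniformly inside its category's age
    range (months), prices it from the value truth at the sale date, and
    reports only the category — mirroring the real market dataset, where
    birth dates are not recorded. The latent age is kept in a clearly
    marked ground-truth column for testing.

    With ``balanced=True`` the (category, month-of-age, sex, breed
    category) cells receive equal record counts instead of being drawn at
    random, so category means converge deterministically as the price
    noise vanishes — the configuration used for self-consistency checks.
    """
    if n <= 0:
        raise ConfigurationError("n must be positive")
    _check_truth_coverage(truth_v, "value")
    for cat, (lo, hi) in category_age_map.items():
        if lo > hi:
            raise ConfigurationError(f"empty age range for category {cat!r}")
    rng = np.random.default_rng(seed)
    cats = sorted(category_age_map)
    start = dt.date(years[0], 1, 1)
    span = (dt.date(years[1], 12, 31) - start).days

    def cell_sexes(cat):
        fixed = CATEGORY_SEX.get(cat)
        return (fixed,) if fixed else SEXES

    if balanced:
        cells = [(cat, m, sex, breed)
                 for cat in cats
                 for m in range(category_age_map[cat][0],
                                category_age_map[cat][1] + 1)
                 for sex in cell_sexes(cat)
                 for breed in BREED_CATEGORIES]
        per_cell = max(1, round(n / len(cells)))
        draws = [c for c in cells for _ in range(per_cell)]
    else:
        draws = []
        for _ in range(n):
            cat = cats[rng.integers(len(cats))]
            lo_m, hi_m = category_age_map[cat]
            m = int(rng.integers(lo_m, hi_m + 1))
            sex = CATEGORY_SEX.get(cat) or SEXES[rng.integers(2)]
            draws.append((cat, m, sex, BREED_CATEGORIES[rng.integers(3)]))

    rows = []
    for cat, age_months, sex, breed_cat in draws:
        age_days = age_months * DAYS_PER_MONTH
        code = BREED_CODES[breed_cat][rng.integers(len(BREED_CODES[breed_cat]))]
        sale = start + dt.timedelta(days=int(rng.integers(0, span + 1)))
        t = truth_v[(sex, breed_cat)]
        price = t.mean(age_days, month=sale.month, year=sale.year) \
            + rng.normal(0, t.noise_sd)
        rows.append({
            "sale_date": sale, "animal_category": cat, "breed_code": code,
            "sex": sex, "price": max(price, 1.0),
            "latent_age_days": age_days,  # ground truth, not visible to validation
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# consumer price index


def generate_cpi_series(base_period: str = "2011-12", annual_drift: float = 0.02,
                        start: str = "2011-01", end: str = "2021-12",
                        seed: int = 0, noise_sd: float = 0.0) -> CPISeries:
    """Monthly CPI with geometric drift, rebased so the base period is 100.

    The annual view is the December (year-end) value, so with drift ``g``
    the annual index ``k`` years after the base year is ``100 (1+g)^k``.
    """
    periods = pd.period_range(start, end, freq="M")
    base = pd.Period(base_period, freq="M")
    if base not in periods:
        raise ConfigurationError(f"base period {base_period} outside series range")
    rng = np.random.default_rng(seed)
    months_since_base = np.array([(p - base).n for p in periods], dtype=float)
    idx = 100.0 * (1.0 + annual_drift) ** (months_since_base / 12.0)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=len(idx))
        noise[months_since_base == 0] = 0.0  # the base stays exact
        idx = idx + noise
    monthly = pd.Series(idx, index=periods)
    annual = {int(y): float(monthly[pd.Period(f"{y}-12", freq="M")])
              for y in sorted({p.year for p in periods})
              if pd.Period(f"{y}-12", freq="M") in monthly.index}
    return CPISeries(monthly=monthly, annual=annual, base_period=str(base))


# ---------------------------------------------------------------------------
# herd archetypes and the movement event database


@dataclass(frozen=True)
class HerdArchetype:
    """A stylised herd management system driving the movement simulator.

    ``sex_policy`` names the retention/acceptance rule:

    breeding herds
        ``dairy_standard`` (retain heifer calves, sell bull calves young),
        ``dairy_sell_all`` (all calves leave young), ``dairy_rear_males``
        (bull calves reared to stores), ``suckler_to_beef`` (progeny
        finished at home), ``suckler_to_weanling`` (progeny sold at
        weaning), ``mixed_to_beef`` (mixed dairy/beef cows, progeny
        finished at home).
    receiving herds
        ``rear_dairy_females``, ``rear_dairy_males``, ``store_beef_females``,
        ``store_beef_males``, ``store_beef_mixed``, ``fatten``, ``trade``,
        ``hold`` (static hobby herd, ends up unclassified).
    """

    name: str
    herd_type: str
    subtype: str
    size_median: int
    calving_month_distribution: tuple     # 12 probabilities (zeros if non-breeding)
    sale_age_window: tuple                # age-days interval for sales/finishing
    breed_mix: dict                       # breed category -> probability
    sex_policy: str
    release_months: tuple = ()            # calendar months when stores release stock

    def __post_init__(self):
        if self.size_median < 1:
            raise ConfigurationError("size_median must be >= 1")
        tot = sum(self.calving_month_distribution)
        if tot and abs(tot - 1.0) > 1e-9:
            raise ConfigurationError("calving_month_distribution must sum to 1")
        if abs(sum(self.breed_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("breed_mix must sum to 1")


_SPRING = (0.02, 0.18, 0.30, 0.28, 0.12, 0.04, 0.02, 0.01, 0.01, 0.01, 0.005, 0.005)
_NONE = tuple([0.0] * 12)


def default_archetypes() -> dict:
    """The shipped archetype library, keyed by name.

    Median herd sizes follow the national annual medians by herd type
    (beef 31, fattening 31, store/rearing 17, dairy 139, mixed 110,
    unclassified 7, trading 23); calving is spring-dominant, the prevailing
    pattern in a pasture-based system.
    """
    arch = [
        HerdArchetype("D", "dairy", "D", 139, _SPRING, (20, 40),
                      {"dairy": 1.0}, "dairy_standard"),
        HerdArchetype("DnR_nC", "dairy", "DnR_nC", 139, _SPRING, (20, 40),
                      {"dairy": 1.0}, "dairy_sell_all"),
        HerdArchetype("DRm", "dairy", "DRm", 139, _SPRING, (400, 500),
                      {"dairy": 1.0}, "dairy_rear_males"),
        HerdArchetype("BSB", "beef", "BSB", 31, _SPRING, (640, 730),
                      {"continental_beef": 0.5, "british_irish_beef": 0.5},
                      "suckler_to_beef"),
        HerdArchetype("BSW", "beef", "BSW", 31, _SPRING, (180, 300),
                      {"continental_beef": 0.5, "british_irish_beef": 0.5},
                      "suckler_to_weanling"),
        HerdArchetype("mixed", "mixed", "none", 110, _SPRING, (640, 730),
                      {"dairy": 0.5, "continental_beef": 0.25,
                       "british_irish_beef": 0.25}, "mixed_to_beef"),
        HerdArchetype("Rdf", "store_rearing", "Rdf", 17, _NONE, (550, 650),
                      {"dairy": 1.0}, "rear_dairy_females", release_months=(10, 11)),
        HerdArchetype("Sdm", "store_rearing", "Sdm", 17, _NONE, (460, 560),
                      {"dairy": 1.0}, "rear_dairy_males"),
        HerdArchetype("Sbmx", "store_rearing", "Sbmx", 17, _NONE, (550, 650),
                      {"continental_beef": 0.5, "british_irish_beef": 0.5},
                      "store_beef_mixed"),
        HerdArchetype("fattening", "fattening", "none", 31, _NONE, (700, 900),
                      {"continental_beef": 0.5, "british_irish_beef": 0.5}, "fatten"),
        HerdArchetype("trading", "trading", "none", 23, _NONE, (0, 4000),
                      {"continental_beef": 0.5, "british_irish_beef": 0.5}, "trade"),
        HerdArchetype("unclassified", "unclassified", "none", 7, _NONE, (0, 4000),
                      {"dairy": 0.34, "continental_beef": 0.33,
                       "british_irish_beef": 0.33}, "hold"),
    ]
    return {a.name: a for a in arch}


class _Animal:
    __slots__ = ("aid", "sex", "breed_code", "dob", "events")

    def __init__(self, aid, sex, breed_code, dob, natal_herd):
        self.aid = aid
        self.sex = sex
        self.breed_code = breed_code
        self.dob = dob
        self.events = [("birth", natal_herd, dob)]

    def move(self, from_herd, to_herd, date):
        self.events.append(("move_out", from_herd, date))
        self.events.append(("move_in", to_herd, date))

    def die(self, herd, date):
        self.events.append(("death", herd, date))


def _pick_code(rng, breed_mix):
    cats, probs = zip(*sorted(breed_mix.items()))
    cat = rng.choice(cats, p=probs)
    pool = BREED_CODES[cat]
    return pool[rng.integers(len(pool))]


def _rand_date(rng, year, month):
    return dt.date(year, month, int(rng.integers(1, 29)))


def generate_movement_db(archetypes: list, years: tuple, seed: int) -> pd.DataFrame:
    """Birth/death/movement event log for a population of archetype herds.

    Parameters
    ----------
    archetypes:
        list of ``(HerdArchetype, herd_count)`` pairs.
    years:
        inclusive ``(first_year, last_year)`` study window. Founder births
        predate the window; deaths and moves after it are censored (the
        animals simply remain alive at the end of the study).
    seed:
        RNG seed; identical inputs and seed give a byte-identical table.

    Every animal has exactly one birth event; move-out/move-in pairs share
    a date, so each animal is in exactly one herd on any snapshot date.
    """
    if not archetypes:
        raise ConfigurationError("need at least one archetype")
    y0, y1 = int(years[0]), int(years[1])
    if y1 < y0:
        raise ConfigurationError("empty year range")
    rng = np.random.default_rng(seed)
    sim_start = dt.date(y0, 1, 1)
    sim_end = dt.date(y1, 12, 31)

    herds = []          # (herd_id, archetype)
    for arch, count in archetypes:
        for i in range(int(count)):
            herds.append((f"{arch.name}-{i + 1:03d}", arch))

    traders = [h for h, a in herds if a.sex_policy == "trade"]
    fatteners = [h for h, a in herds if a.sex_policy == "fatten"]
    stores = {pol: [h for h, a in herds if a.sex_policy == pol]
              for pol in ("rear_dairy_females", "rear_dairy_males",
                          "store_beef_females", "store_beef_males",
                          "store_beef_mixed")}
    store_arch = {h: a for h, a in herds if a.herd_type == "store_rearing"}
    fatten_arch = {h: a for h, a in herds if a.sex_policy == "fatten"}

    animals = []
    counter = [0]

    def new_animal(sex, code, dob, herd):
        counter[0] += 1
        a = _Animal(f"S{counter[0]:07d}", sex, code, dob, herd)
        animals.append(a)
        return a

    def to_fattener(animal, date, cur):
        if not fatteners:
            animal.die(cur, date)
            return
        dest = fatteners[rng.integers(len(fatteners))]
        animal.move(cur, dest, date)
        stay = int(rng.integers(120, 201))
        animal.die(dest, date + dt.timedelta(days=stay))

    def to_store(animal, date, cur, dest):
        animal.move(cur, dest, date)
        arch = store_arch[dest]
        if arch.release_months:
            # calendar-driven release (autumn turn-off): first release
            # month after the animal reaches its sale age
            ready = animal.dob + dt.timedelta(days=int(rng.integers(*arch.sale_age_window)))
            ry, rm = ready.year, ready.month
            while rm not in arch.release_months:
                rm += 1
                if rm > 12:
                    rm, ry = 1, ry + 1
            release = max(_rand_date(rng, ry, rm), date + dt.timedelta(days=30))
        else:
            release = animal.dob + dt.timedelta(days=int(rng.integers(*arch.sale_age_window)))
            release = max(release, date + dt.timedelta(days=30))
        to_fattener(animal, release, dest)

    def pick_store(sex, code, age):
        is_dairy = code in BREED_CODES["dairy"]
        if is_dairy and age < 500:
            pool = stores["rear_dairy_females" if sex == "female" else "rear_dairy_males"]
        elif not is_dairy and age < 500:
            pool = (stores["store_beef_females"] if sex == "female"
                    else stores["store_beef_males"]) or stores["store_beef_mixed"]
        else:
            pool = []
        return pool[rng.integers(len(pool))] if pool else None

    def route_to_market(animal, date, cur):
        """Sale off a breeding herd: optionally via a trader, then to a
        store, a fattener (older stock), or slaughter/export."""
        age = (date - animal.dob).days
        if traders and rng.random() < 0.5:
            t = traders[rng.integers(len(traders))]
            animal.move(cur, t, date)
            date = date + dt.timedelta(days=int(rng.integers(10, 41)))
            cur = t
            age = (date - animal.dob).days
        dest = pick_store(animal.sex, animal.breed_code, age)
        if dest is not None:
            to_store(animal, date, cur, dest)
        elif age >= 450:
            to_fattener(animal, date, cur)
        else:
            animal.die(cur, date)  # export / slaughter off-market

    # -- breeding herds ------------------------------------------------
    breeding_policies = {"dairy_standard", "dairy_sell_all", "dairy_rear_males",
                         "suckler_to_beef", "suckler_to_weanling", "mixed_to_beef"}
    for herd_id, arch in herds:
        if arch.sex_policy in breeding_policies:
            cows = []  # (animal, cull_date)
            for _ in range(arch.size_median):
                age0 = int(rng.integers(750, 2900))
                dob = sim_start - dt.timedelta(days=age0)
                cull_age = int(rng.integers(max(2900, age0 + 30), 3800))
                cow = new_animal("female", _pick_code(rng, arch.breed_mix), dob, herd_id)
                cull = dob + dt.timedelta(days=cull_age)
                cows.append((cow, cull))
            for year in range(y0, y1 + 1):
                for cow, cull in list(cows):
                    month = 1 + int(rng.choice(12, p=np.asarray(
                        arch.calving_month_distribution)))
                    cdate = _rand_date(rng, year, month)
                    if not (cow.dob + dt.timedelta(days=730) <= cdate < cull):
                        continue
                    if rng.random() >= 0.85:
                        continue
                    sex = "female" if rng.random() < 0.5 else "male"
                    code = _pick_code(rng, arch.breed_mix)
                    calf = new_animal(sex, code, cdate, herd_id)
                    _dispose_progeny(calf, arch, herd_id, rng, cows, route_to_market)
            for cow, cull in cows:
                if cull <= sim_end:
                    cow.die(cow.events[-1][1] if cow.events[-1][0] != "birth"
                            else herd_id, cull)

        elif arch.sex_policy == "hold":
            for _ in range(arch.size_median):
                age0 = int(rng.integers(200, 2500))
                dob = sim_start - dt.timedelta(days=age0)
                sex = "female" if rng.random() < 0.5 else "male"
                a = new_animal(sex, _pick_code(rng, arch.breed_mix), dob, herd_id)
                death = dob + dt.timedelta(days=int(rng.integers(4200, 5500)))
                if death <= sim_end:
                    a.die(herd_id, death)
        # receiver herds (stores, fatteners, traders) are populated by routing

    # -- assemble the event table, censored to the study window --------
    kind_order = {"birth": 0, "move_out": 1, "move_in": 2, "death": 3}
    rows = []
    for a in animals:
        for kind, herd, date in a.events:
            if kind != "birth" and (date > sim_end or date < sim_start):
                continue
            rows.append((a.aid, kind, herd, date, a.sex, a.breed_code, a.dob))
    df = pd.DataFrame(rows, columns=["animal_id", "event_kind", "herd_id",
                                     "event_date", "sex", "breed_code",
                                     "date_of_birth"])
    df["_k"] = df["event_kind"].map(kind_order)
    df = (df.sort_values(["animal_id", "event_date", "_k"], kind="mergesort")
            .drop(columns="_k").reset_index(drop=True))
    return df


def _dispose_progeny(calf, arch, herd_id, rng, cows, route_to_market):
    """Apply the archetype's sex policy to a newborn calf."""
    pol = arch.sex_policy
    sale_age = int(rng.integers(arch.sale_age_window[0], arch.sale_age_window[1] + 1))
    sale_date = calf.dob + dt.timedelta(days=sale_age)
    if pol in ("suckler_to_beef", "mixed_to_beef"):
        if calf.sex == "female" and rng.random() < 0.2:
            # replacement heifer joins the breeding stock
            cull = calf.dob + dt.timedelta(days=int(rng.integers(2900, 3800)))
            cows.append((calf, cull))
        else:
            calf.die(herd_id, sale_date)  # finished and slaughtered at home
    elif pol == "suckler_to_weanling":
        route_to_market(calf, sale_date, herd_id)
    elif pol == "dairy_standard":
        if calf.sex == "male":
            route_to_market(calf, sale_date, herd_id)
        else:
            cull = calf.dob + dt.timedelta(days=int(rng.integers(2900, 3800)))
            cows.append((calf, cull))
    elif pol == "dairy_rear_males":
        if calf.sex == "male":
            route_to_market(calf, sale_date, herd_id)  # sold as reared store
        else:
            cull = calf.dob + dt.timedelta(days=int(rng.integers(2900, 3800)))
            cows.append((calf, cull))
    elif pol == "dairy_sell_all":
        early = calf.dob + dt.timedelta(days=int(rng.integers(20, 41)))
        route_to_market(calf, early, herd_id)
    else:  # pragma: no cover - breeding policies are enumerated above
        raise ConfigurationError(f"unknown sex_policy {pol!r}")


# ---------------------------------------------------------------------------
# dataset bundles


def write_datasets(outdir, seed: int, archetype_counts: list | None = None,
                   years: tuple = (2011, 2021), n_per_class: int = 600,
                   n_market: int = 5000, annual_drift: float = 0.02) -> dict:
    """Generate and write the four synthetic tables plus a manifest.

    Returns the manifest dict (also written as ``manifest.json``); the
    manifest records the seed and all truth parameters so tests can reuse
    the generating truth as an oracle.
    """
    from pathlib import Path

    from .validate import DEFAULT_CATEGORY_AGE_MAP

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_w = default_growth_truths()
    truth_v = default_value_truths()
    if archetype_counts is None:
        lib = default_archetypes()
        archetype_counts = [(lib["D"], 2), (lib["BSB"], 4), (lib["BSW"], 2),
                            (lib["Rdf"], 2), (lib["Sdm"], 2), (lib["fattening"], 2),
                            (lib["trading"], 1), (lib["mixed"], 1),
                            (lib["unclassified"], 1)]
    slaughter = generate_slaughter_records(truth_w, truth_v, n_per_class, seed)
    market = generate_market_records(truth_v, DEFAULT_CATEGORY_AGE_MAP, n_market,
                                     seed + 1, years)
    events = generate_movement_db(archetype_counts, years, seed + 2)
    cpi = generate_cpi_series(base_period=f"{years[0]}-12", annual_drift=annual_drift,
                              start=f"{years[0]}-01", end=f"{years[1]}-12")
    slaughter.to_csv(outdir / "slaughter.csv", index=False)
    market.to_csv(outdir / "market.csv", index=False)
    events.to_csv(outdir / "events.csv", index=False)
    cpi.to_frame().to_csv(outdir / "cpi.csv", index=False)
    manifest = {
        "seed": seed,
        "years": list(years),
        "n_per_class": n_per_class,
        "n_market": n_market,
        "annual_drift": annual_drift,
        "archetypes": [{"name": a.name, "count": c,
                        **{k: v for k, v in dataclasses.asdict(a).items()}}
                       for a, c in archetype_counts],
        "growth_truths": {f"{s}/{b}": dataclasses.asdict(t)
                          for (s, b), t in truth_w.items()},
        "value_truths": {f"{s}/{b}": dataclasses.asdict(t)
                         for (s, b), t in truth_v.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
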