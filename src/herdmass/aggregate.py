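"""Population prediction, biomass/value aggregation and CPI deflation.

The fitted weight and value models are applied to every animal in every
first-of-month snapshot; predictions are summed per herd-month, averaged
into within-year (herd type x calendar month) profiles and annual herd /
herd-type / sector series, and nominal values are deflated to real
prices with a consumer price index (base period = 100).

Units: biomass is carried in kg and value in EUR throughout; conversion
to '000 tonnes or EUR million happens only at the reporting boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cleaning import BreedMap, resolve_breed
from .errors import ConfigurationError, UnmappableBreedError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# consumer price index


@dataclass
class CPISeries:
    """Monthly and annual price index, base period = 100.

    The annual index for a year is its December (year-end) value.
    """

    monthly: pd.Series          # PeriodIndex (freq M) -> index value
    annual: dict = field(default_factory=dict)   # year -> index value
    base_period: str = ""

    def __post_init__(self):
        base = pd.Period(self.base_period, freq="M")
        if base not in self.monthly.index:
            raise ConfigurationError(f"base period {self.base_period} not in series")
        if abs(float(self.monthly[base]) - 100.0) > 1e-9:
            raise ConfigurationError("index at the base period must equal 100")
        if (self.monthly <= 0).any():
            raise ConfigurationError("all index values must be positive")
        if not self.annual:
            self.annual = {
                int(y): float(self.monthly[pd.Period(f"{y}-12", freq="M")])
                for y in sorted({p.year for p in self.monthly.index})
                if pd.Period(f"{y}-12", freq="M") in self.monthly.index
            }

    def index(self, period) -> float:
        """Index value for a ``"YYYY-MM"`` period or integer year."""
        if isinstance(period, (int, np.integer)):
            if int(period) not in self.annual:
                raise ConfigurationError(f"year {period} outside the CPI range")
            return self.annual[int(period)]
        p = pd.Period(period, freq="M")
        if p not in self.monthly.index:
            raise ConfigurationError(f"period {period} outside the CPI range")
        return float(self.monthly[p])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"period": self.monthly.index.astype(str),
                             "index": self.monthly.to_numpy()})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, base_period: str) -> "CPISeries":
        s = pd.Series(df["index"].to_numpy(dtype=float),
                      index=pd.PeriodIndex(df["period"], freq="M"))
        return cls(monthly=s, base_period=base_period)


def deflate(value_nominal, cpi: CPISeries, period):
    """Real value at base-period prices: nominal x 100 / index(period)."""
    return np.asarray(value_nominal, dtype=float) * 100.0 / cpi.index(period)


# ---------------------------------------------------------------------------
# prediction over snapshots


def predict_population(fits: dict, snapshots: pd.DataFrame,
                       breed_map: BreedMap | None = None,
                       min_weight_kg: float = 1.0,
                       min_value_eur: float = 1.0) -> pd.DataFrame:
    """Predict liveweight and nominal value for every snapshot member.

    ``fits`` is keyed ``(response, sex)`` with responses ``"liveweight"``
    and ``"value"`` and sexes ``"female"``/``"male"`` (four models).
    Animals whose breed code cannot be mapped are skipped and counted;
    non-positive predictions are floored at the configured minima.
    """
    for resp in ("liveweight", "value"):
        for sex in ("female", "male"):
            if (resp, sex) not in fits:
                raise ConfigurationError(f"missing fit for ({resp}, {sex})")
    breed_map = breed_map or BreedMap.default()
    if snapshots.empty:
        return pd.DataFrame(columns=["animal_id", "herd_id", "snapshot_date",
                                     "predicted_liveweight",
                                     "predicted_value_nominal"])
    df = snapshots.copy()
    cats = []
    ok = []
    unmapped = 0
    cache: dict[str, str | None] = {}
    for code in df["breed_code"]:
        if code not in cache:
            try:
                cache[code] = resolve_breed(code, breed_map)
            except UnmappableBreedError:
                cache[code] = None
        c = cache[code]
        cats.append(c)
        ok.append(c is not None)
        unmapped += c is None
    if unmapped:
        log.warning("%d snapshot rows skipped: unmappable breed codes", unmapped)
    df = df[pd.Series(ok, index=df.index)].copy()
    df["breed_category"] = [c for c in cats if c is not None]
    dates = pd.to_datetime(df["snapshot_date"])
    df["month"] = dates.dt.month
    df["year"] = dates.dt.year

    out_w = np.empty(len(df))
    out_v = np.empty(len(df))
    for sex in ("female", "male"):
        m = (df["sex"] == sex).to_numpy()
        if not m.any():
            continue
        sub = df[m]
        args = (sub["age_days"].to_numpy(dtype=float),
                sub["breed_category"].to_numpy(),
                sub["month"].to_numpy(), sub["year"].to_numpy())
        out_w[m] = fits[("liveweight", sex)].predict(*args)
        out_v[m] = fits[("value", sex)].predict(*args)
    n_floor = int((out_w < min_weight_kg).sum() + (out_v < min_value_eur).sum())
    if n_floor:
        log.warning("%d predictions floored at the configured minima", n_floor)
    res = df[["animal_id", "herd_id", "snapshot_date"]].copy()
    res["predicted_liveweight"] = np.maximum(out_w, min_weight_kg)
    res["predicted_value_nominal"] = np.maximum(out_v, min_value_eur)
    return res.reset_index(drop=True)


# ---------------------------------------------------------------------------
# aggregation


def herd_month_totals(predictions: pd.DataFrame) -> pd.DataFrame:
    """Sum predictions per herd and month: the herd biomass and stock value."""
    df = predictions.copy()
    dates = pd.to_datetime(df["snapshot_date"])
    df["year"] = dates.dt.year
    df["month"] = dates.dt.month
    out = (df.groupby(["herd_id", "year", "month"], as_index=False)
             .agg(biomass_kg=("predicted_liveweight", "sum"),
                  value_nominal_eur=("predicted_value_nominal", "sum"),
                  n_animals=("animal_id", "size")))
    return out


def _attach_type(hmt: pd.DataFrame, classifications: pd.DataFrame) -> pd.DataFrame:
    cls = classifications[["herd_id", "year", "herd_type"]]
    out = hmt.merge(cls, on=["herd_id", "year"], how="left")
    out["herd_type"] = out["herd_type"].fillna("unclassified")
    return out


def within_year_profile(hmt: pd.DataFrame,
                        classifications: pd.DataFrame,
                        cpi: CPISeries | None = None) -> pd.DataFrame:
    """Monthly average herd biomass/value by herd type, across study years.

    The within-year profile is the mean over herds and years of the
    herd-month totals, per herd type and calendar month. Unclassified
    herds are reported under ``unclassified``, not dropped.
    """
    df = _attach_type(hmt, classifications)
    out = (df.groupby(["herd_type", "month"], as_index=False)
             .agg(biomass_kg=("biomass_kg", "mean"),
                  value_nominal_eur=("value_nominal_eur", "mean"),
                  n_herds=("herd_id", "nunique"),
                  n_animals=("n_animals", "mean")))
    if cpi is not None:
        # deflate each herd-month with its own monthly index, then average
        df["value_real_eur"] = [
            float(deflate(v, cpi, f"{y}-{m:02d}"))
            for v, y, m in zip(df["value_nominal_eur"], df["year"], df["month"])
        ]
        real = (df.groupby(["herd_type", "month"], as_index=False)
                  .agg(value_real_eur=("value_real_eur", "mean")))
        out = out.merge(real, on=["herd_type", "month"])
    return out


def annual_and_sector(hmt: pd.DataFrame, classifications: pd.DataFrame,
                      cpi: CPISeries | None = None,
                      empty_months: str = "zero",
                      sector_mode: str = "sum_of_herd_means") -> dict:
    """Annual herd averages, herd-type averages and sector totals.

    A herd's annual average is the mean of its 12 monthly totals; with
    ``empty_months="zero"`` (default) months in which the herd held no
    animals contribute 0 — a herd destocked half the year carries half
    the biomass — while ``"occupied"`` averages only occupied months.
    The herd-type annual average is the mean over herds of herd annual
    averages, and the sector total their sum (``sector_mode=
    "sum_of_herd_means"``); ``"mean_of_monthly_totals"`` instead averages
    the 12 national monthly sums, which differs only when herds appear or
    disappear mid-year. Real values use the annual CPI.
    """
    if empty_months not in ("zero", "occupied"):
        raise ConfigurationError("empty_months must be 'zero' or 'occupied'")
    df = _attach_type(hmt, classifications)
    denom = 12.0 if empty_months == "zero" else None

    def herd_mean(g):
        n = denom or len(g)
        return pd.Series({
            "biomass_kg": g["biomass_kg"].sum() / n,
            "value_nominal_eur": g["value_nominal_eur"].sum() / n,
            "n_animals": g["n_animals"].sum() / n,
        })

    herd_annual = (df.groupby(["herd_id", "herd_type", "year"])
                     .apply(herd_mean, include_groups=False).reset_index())
    type_annual = (herd_annual.groupby(["herd_type", "year"], as_index=False)
                   .agg(biomass_kg=("biomass_kg", "mean"),
                        value_nominal_eur=("value_nominal_eur", "mean"),
                        n_herds=("herd_id", "nunique"),
                        n_animals=("n_animals", "mean")))
    if sector_mode == "sum_of_herd_means":
        sector = (herd_annual.groupby("year", as_index=False)
                  .agg(biomass_kg=("biomass_kg", "sum"),
                       value_nominal_eur=("value_nominal_eur", "sum"),
                       n_herds=("herd_id", "nunique"),
                       n_animals=("n_animals", "sum")))
    elif sector_mode == "mean_of_monthly_totals":
        monthly_nat = (df.groupby(["year", "month"], as_index=False)
                       .agg(biomass_kg=("biomass_kg", "sum"),
                            value_nominal_eur=("value_nominal_eur", "sum"),
                            n_animals=("n_animals", "sum")))
        sector = (monthly_nat.groupby("year", as_index=False)
                  .agg(biomass_kg=("biomass_kg", "mean"),
                       value_nominal_eur=("value_nominal_eur", "mean"),
                       n_animals=("n_animals", "mean")))
        sector["n_herds"] = df.groupby("year")["herd_id"].nunique().to_numpy()
    else:
        raise ConfigurationError(f"unknown sector_mode {sector_mode!r}")

    if cpi is not None:
        for frame in (herd_annual, type_annual, sector):
            frame["value_real_eur"] = [
                float(deflate(v, cpi, int(y)))
                for v, y in zip(frame["value_nominal_eur"], frame["year"])
            ]
    return {"herd": herd_annual, "herd_type": type_annual, "sector": sector}
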