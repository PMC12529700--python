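"""Aggregation: additivity, group-by oracles, CPI deflation."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import herdmass as hm
from herdmass.aggregate import CPISeries, annual_and_sector, deflate, \
    herd_month_totals, predict_population, within_year_profile
from herdmass.errors import ConfigurationError
from herdmass.synthetic import generate_cpi_series


def random_predictions(n=400, seed=61, n_herds=6, years=(2013, 2014)):
    rng = np.random.default_rng(seed)
    dates = [dt.date(y, m, 1) for y in range(years[0], years[1] + 1)
             for m in range(1, 13)]
    return pd.DataFrame({
        "animal_id": [f"A{i % 80}" for i in range(n)],
        "herd_id": [f"H{rng.integers(n_herds)}" for _ in range(n)],
        "snapshot_date": [dates[rng.integers(len(dates))] for _ in range(n)],
        "predicted_liveweight": rng.uniform(50, 800, n),
        "predicted_value_nominal": rng.uniform(100, 2000, n),
    })


def flat_classifications(pred, herd_type="beef"):
    years = pd.to_datetime(pred["snapshot_date"]).dt.year
    return (pd.DataFrame({"herd_id": pred["herd_id"], "year": years})
            .drop_duplicates()
            .assign(herd_type=herd_type, subtype="BSB", rule_trace="t"))


class TestHerdMonthTotals:
    def test_matches_brute_force_group_by(self):
        pred = random_predictions()
        out = herd_month_totals(pred)
        d = pd.to_datetime(pred["snapshot_date"])
        for r in out.itertuples(index=False):
            mask = ((pred["herd_id"] == r.herd_id) & (d.dt.year == r.year)
                    & (d.dt.month == r.month))
            assert r.biomass_kg == pytest.approx(
                pred.loc[mask, "predicted_liveweight"].sum())
            assert r.n_animals == int(mask.sum())

    def test_sum_over_herds_equals_sum_over_animals(self):
        pred = random_predictions()
        out = herd_month_totals(pred)
        assert out["biomass_kg"].sum() == pytest.approx(
            pred["predicted_liveweight"].sum(), rel=1e-12)


class TestAdditivityChain:
    def test_animal_to_sector_sums_agree(self):
        pred = random_predictions()
        hmt = herd_month_totals(pred)
        cls = flat_classifications(pred)
        out = annual_and_sector(hmt, cls)
        for year, grp in hmt.groupby("year"):
            flat = grp["biomass_kg"].sum() / 12.0
            sector = out["sector"].set_index("year").loc[year, "biomass_kg"]
            assert sector == pytest.approx(flat, rel=1e-6)
            by_type = out["herd_type"].set_index("year").loc[year]
            n_herds = by_type["n_herds"]
            assert by_type["biomass_kg"] * n_herds == pytest.approx(flat, rel=1e-6)

    def test_two_equal_herds_double_the_sector(self):
        rows = []
        for herd in ("H1", "H2"):
            for m in range(1, 13):
                rows.append({"herd_id": herd, "year": 2015, "month": m,
                             "biomass_kg": 1000.0, "value_nominal_eur": 2000.0,
                             "n_animals": 3})
        hmt = pd.DataFrame(rows)
        cls = pd.DataFrame({"herd_id": ["H1", "H2"], "year": 2015,
                            "herd_type": "dairy", "subtype": "D",
                            "rule_trace": "t"})
        out = annual_and_sector(hmt, cls)
        assert out["herd"]["biomass_kg"].tolist() == [1000.0, 1000.0]
        assert out["herd_type"]["biomass_kg"].iloc[0] == pytest.approx(1000.0)
        assert out["sector"]["biomass_kg"].iloc[0] == pytest.approx(2000.0)

    def test_empty_months_count_as_zero_by_default(self):
        hmt = pd.DataFrame([{"herd_id": "H1", "year": 2015, "month": m,
                             "biomass_kg": 1200.0, "value_nominal_eur": 100.0,
                             "n_animals": 2} for m in range(1, 7)])  # 6 months
        cls = pd.DataFrame({"herd_id": ["H1"], "year": [2015],
                            "herd_type": ["beef"], "subtype": ["BSB"],
                            "rule_trace": ["t"]})
        zero = annual_and_sector(hmt, cls)["herd"]["biomass_kg"].iloc[0]
        occ = annual_and_sector(hmt, cls, empty_months="occupied")[
            "herd"]["biomass_kg"].iloc[0]
        assert zero == pytest.approx(600.0)
        assert occ == pytest.approx(1200.0)


class TestWithinYearProfile:
    def test_constant_totals_give_flat_profile(self):
        hmt = pd.DataFrame([{"herd_id": "H1", "year": y, "month": m,
                             "biomass_kg": 500.0, "value_nominal_eur": 900.0,
                             "n_animals": 1}
                            for y in (2014, 2015) for m in range(1, 13)])
        cls = pd.DataFrame({"herd_id": "H1", "year": [2014, 2015],
                            "herd_type": "beef", "subtype": "BSB",
                            "rule_trace": "t"})
        prof = within_year_profile(hmt, cls)
        assert len(prof) == 12
        assert np.allclose(prof["biomass_kg"], 500.0)

    def test_unclassified_herds_reported_not_dropped(self):
        hmt = pd.DataFrame([{"herd_id": "H9", "year": 2015, "month": 1,
                             "biomass_kg": 10.0, "value_nominal_eur": 1.0,
                             "n_animals": 1}])
        prof = within_year_profile(hmt, pd.DataFrame(
            columns=["herd_id", "year", "herd_type"]))
        assert list(prof["herd_type"]) == ["unclassified"]


class TestSeasonalProfiles:
    def test_autumn_releasing_rearing_herds_peak_in_october(
            self, movement_snapshots, noisefree_fits):
        """Rearing herds that take in spring calves and release stock in
        late October carry their maximum biomass at the October snapshot."""
        snaps, _ = movement_snapshots
        rdf = snaps[snaps["herd_id"].str.startswith("Rdf")]
        pred = predict_population(noisefree_fits, rdf)
        hmt = herd_month_totals(pred)
        monthly = hmt.groupby("month")["biomass_kg"].mean()
        assert monthly.idxmax() == 10

    def test_panel_plot_builds_from_tidy_table(self):
        from herdmass.plotting import panel_by_herd_type
        df = pd.DataFrame({"herd_type": ["beef"] * 3 + ["dairy"] * 3,
                           "year": [2011, 2012, 2013] * 2,
                           "biomass_kg": [1e6, 2e6, 3e6, 4e6, 5e6, 6e6]})
        fig = panel_by_herd_type(df, "year", "biomass_kg", unit_scale=1e-6,
                                 ylabel="'000 tonnes")
        assert len(fig.axes) >= 2


class TestDeflation:
    def test_base_period_is_identity(self):
        cpi = generate_cpi_series(annual_drift=0.03)
        assert deflate(500.0, cpi, "2011-12") == pytest.approx(500.0)

    def test_index_110_divides_by_1_1(self):
        monthly = pd.Series([100.0, 110.0],
                            index=pd.PeriodIndex(["2011-12", "2012-01"], freq="M"))
        cpi = CPISeries(monthly=monthly, base_period="2011-12")
        assert deflate(110.0, cpi, "2012-01") == pytest.approx(100.0)

    def test_flat_series_nominal_equals_real(self):
        cpi = generate_cpi_series(annual_drift=0.0)
        vals = np.array([10.0, 250.0, 999.0])
        assert deflate(vals, cpi, "2015-06") == pytest.approx(vals)

    def test_out_of_range_period_rejected(self):
        cpi = generate_cpi_series()
        with pytest.raises(ConfigurationError):
            deflate(1.0, cpi, "2030-01")

    def test_non_100_base_rejected(self):
        monthly = pd.Series([101.0, 102.0],
                            index=pd.PeriodIndex(["2011-12", "2012-01"], freq="M"))
        with pytest.raises(ConfigurationError):
            CPISeries(monthly=monthly, base_period="2011-12")

    def test_annual_deflation_applied_to_annual_series(self):
        pred = random_predictions(years=(2013, 2013))
        hmt = herd_month_totals(pred)
        cls = flat_classifications(pred)
        cpi = generate_cpi_series(base_period="2013-12", annual_drift=0.10,
                                  start="2013-01", end="2014-12")
        out = annual_and_sector(hmt, cls, cpi=cpi)
        sector = out["sector"]
        # 2013 annual index is the December (base) value: identity
        assert sector["value_real_eur"].iloc[0] == pytest.approx(
            sector["value_nominal_eur"].iloc[0])


class TestPredictPopulation:
    def test_empty_snapshot_gives_empty_table(self, noisefree_fits):
        empty = pd.DataFrame(columns=["snapshot_date", "herd_id", "animal_id",
                                      "sex", "breed_code", "age_days"])
        out = predict_population(noisefree_fits, empty)
        assert out.empty

    def test_one_animal_one_year_gives_12_rows(self, noisefree_fits):
        events = pd.DataFrame([{"animal_id": "A1", "event_kind": "birth",
                                "herd_id": "H1", "event_date": dt.date(2014, 12, 20),
                                "sex": "female", "breed_code": "FR",
                                "date_of_birth": dt.date(2014, 12, 20)}])
        snaps, _ = hm.build_snapshots(events, ("2015-01", "2015-12"))
        out = predict_population(noisefree_fits, snaps)
        assert len(out) == 12
        ages = pd.to_datetime(out["snapshot_date"]).map(
            lambda d: (d.date() - dt.date(2014, 12, 20)).days)
        assert (np.diff(sorted(ages)) == [31, 28, 31, 30, 31, 30, 31, 31, 30,
                                          31, 30]).all()

    def test_noise_free_chain_predictions_equal_truth(self, noisefree_fits,
                                                      clean_growth_truths,
                                                      clean_value_truths):
        rows = []
        cases = [("FR", "dairy", "female", 300), ("CH", "continental_beef",
                                                  "male", 900),
                 ("AA", "british_irish_beef", "female", 2500)]
        for i, (code, cat, sex, age) in enumerate(cases):
            rows.append({"snapshot_date": dt.date(2015, 6, 1), "herd_id": "H1",
                         "animal_id": f"A{i}", "sex": sex, "breed_code": code,
                         "age_days": age})
        out = predict_population(noisefree_fits, pd.DataFrame(rows))
        for i, (code, cat, sex, age) in enumerate(cases):
            tw = clean_growth_truths[(sex, cat)]
            tv = clean_value_truths[(sex, cat)]
            row = out[out["animal_id"] == f"A{i}"].iloc[0]
            assert row["predicted_liveweight"] == pytest.approx(tw.mean(age),
                                                                abs=1e-3)
            assert row["predicted_value_nominal"] == pytest.approx(tv.mean(age),
                                                                   abs=1e-2)

    def test_unmappable_breed_skipped(self, noisefree_fits):
        snaps = pd.DataFrame([{"snapshot_date": dt.date(2015, 6, 1),
                               "herd_id": "H1", "animal_id": "A1",
                               "sex": "female", "breed_code": "ZZZZ",
                               "age_days": 500}])
        out = predict_population(noisefree_fits, snaps)
        assert out.empty
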