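"""Generator behaviour: determinism, known ground truth, demography."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import herdmass as hm
from herdmass.errors import ConfigurationError
from herdmass.synthetic import (CLASS_WINDOWS, GrowthTruth, PiecewiseTruth,
                                generate_cpi_series)
from herdmass.validate import DEFAULT_CATEGORY_AGE_MAP


class TestPiecewiseTruth:
    def test_mean_is_continuous_at_breakpoints(self):
        t = GrowthTruth(sex="female", breed_category="dairy", intercept=40.0,
                        segment_slopes=(0.8, 0.2, 0.05), break_points=(600.0, 1800.0))
        for bp in t.break_points:
            left, mid, right = t.mean(bp - 1e-6), t.mean(bp), t.mean(bp + 1e-6)
            assert left == pytest.approx(mid, abs=1e-5)
            assert right == pytest.approx(mid, abs=1e-5)

    def test_mean_matches_segment_arithmetic(self):
        t = GrowthTruth(sex="female", breed_category="dairy", intercept=40.0,
                        segment_slopes=(0.8, 0.2, 0.05), break_points=(600.0, 1800.0))
        assert t.mean(0) == 40.0
        assert t.mean(600) == pytest.approx(40 + 0.8 * 600)
        assert t.mean(2000) == pytest.approx(40 + 0.8 * 600 + 0.2 * 1200 + 0.05 * 200)

    def test_invalid_truths_rejected(self):
        with pytest.raises(ConfigurationError):
            PiecewiseTruth("female", "dairy", 40.0, (0.8, 0.2), (600.0, 500.0))
        with pytest.raises(ConfigurationError):
            PiecewiseTruth("female", "dairy", 40.0, (0.8,), (600.0,))
        with pytest.raises(ConfigurationError):
            PiecewiseTruth("female", "dairy", 40.0, (0.8, 0.2), (600.0,),
                           noise_sd=-1.0)


class TestSlaughterRecords:
    def test_record_count_is_classes_times_n(self):
        truths_w = hm.default_growth_truths(noise_sd=0.0)
        truths_v = hm.default_value_truths(noise_sd=0.0)
        df = hm.generate_slaughter_records(truths_w, truths_v, 600, seed=1)
        assert len(df) == 3600
        assert set(df["animal_class"]) == set(CLASS_WINDOWS)

    def test_deterministic_under_seed(self):
        truths_w = hm.default_growth_truths()
        truths_v = hm.default_value_truths()
        a = hm.generate_slaughter_records(truths_w, truths_v, 50, seed=9)
        b = hm.generate_slaughter_records(truths_w, truths_v, 50, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_noise_free_weights_equal_truth_mean(self, clean_growth_truths,
                                                 clean_value_truths):
        df = hm.generate_slaughter_records(clean_growth_truths,
                                           clean_value_truths, 40, seed=2)
        for r in df.itertuples(index=False):
            age = (r.date_of_death - r.date_of_birth).days
            cat = ("dairy" if r.breed_code.rstrip("X") in ("FR", "HO", "JE")
                   else "continental_beef" if r.breed_code.rstrip("X") in
                   ("CH", "LM", "BB", "SI") else "british_irish_beef")
            truth = clean_growth_truths[(r.sex, cat)]
            assert r.liveweight == pytest.approx(truth.mean(age), abs=1e-9)

    def test_residual_sd_recovers_noise_parameter(self):
        truths_w = hm.default_growth_truths(noise_sd=30.0, month_amplitude=0.0,
                                            year_trend=0.0)
        truths_v = hm.default_value_truths(noise_sd=0.0, month_amplitude=0.0,
                                           year_trend=0.0)
        df = hm.generate_slaughter_records(truths_w, truths_v, 2000, seed=3)
        ages = (pd.to_datetime(df["date_of_death"])
                - pd.to_datetime(df["date_of_birth"])).dt.days
        resid = []
        for (sex, code), grp_idx in df.groupby(["sex", "breed_code"]).groups.items():
            cat = ("dairy" if code.rstrip("X") in ("FR", "HO", "JE")
                   else "continental_beef" if code.rstrip("X") in
                   ("CH", "LM", "BB", "SI") else "british_irish_beef")
            truth = truths_w[(sex, cat)]
            sub = df.loc[grp_idx]
            resid.extend(sub["liveweight"].to_numpy()
                         - truth.mean(ages.loc[grp_idx].to_numpy()))
        sd = float(np.std(resid))
        assert sd == pytest.approx(30.0, rel=0.05)

    def test_missing_truth_combination_rejected(self):
        truths_w = hm.default_growth_truths()
        truths_v = hm.default_value_truths()
        del truths_w[("male", "dairy")]
        with pytest.raises(ConfigurationError):
            hm.generate_slaughter_records(truths_w, truths_v, 10, seed=0)


class TestMarketRecords:
    def test_latent_age_within_category_range(self, clean_value_truths):
        df = hm.generate_market_records(clean_value_truths,
                                        DEFAULT_CATEGORY_AGE_MAP, 500, seed=4)
        for r in df.itertuples(index=False):
            lo, hi = DEFAULT_CATEGORY_AGE_MAP[r.animal_category]
            months = r.latent_age_days / 30.4375
            assert lo - 1e-9 <= months <= hi + 1e-9

    def test_noise_free_price_equals_truth(self, clean_value_truths):
        df = hm.generate_market_records(clean_value_truths,
                                        DEFAULT_CATEGORY_AGE_MAP, 200, seed=5)
        for r in df.itertuples(index=False):
            cat = ("dairy" if r.breed_code in ("FR", "HO", "JE")
                   else "continental_beef" if r.breed_code in
                   ("CH", "LM", "BB", "SI") else "british_irish_beef")
            truth = clean_value_truths[(r.sex, cat)]
            assert r.price == pytest.approx(truth.mean(r.latent_age_days), abs=1e-9)

    def test_deterministic_and_validates_n(self, clean_value_truths):
        a = hm.generate_market_records(clean_value_truths,
                                       DEFAULT_CATEGORY_AGE_MAP, 100, seed=6)
        b = hm.generate_market_records(clean_value_truths,
                                       DEFAULT_CATEGORY_AGE_MAP, 100, seed=6)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ConfigurationError):
            hm.generate_market_records(clean_value_truths,
                                       DEFAULT_CATEGORY_AGE_MAP, 0, seed=6)


class TestCPISeries:
    def test_base_period_is_exactly_100(self):
        cpi = generate_cpi_series(base_period="2011-12", annual_drift=0.02)
        assert cpi.index("2011-12") == pytest.approx(100.0, abs=1e-12)

    def test_zero_drift_is_flat(self):
        cpi = generate_cpi_series(annual_drift=0.0)
        assert np.allclose(cpi.monthly.to_numpy(), 100.0)

    def test_drift_matches_closed_form(self):
        cpi = generate_cpi_series(base_period="2011-12", annual_drift=0.02,
                                  start="2011-01", end="2021-12")
        assert cpi.index(2021) == pytest.approx(100.0 * 1.02 ** 10, rel=1e-12)

    def test_base_outside_range_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_cpi_series(base_period="2005-01", start="2011-01",
                                end="2021-12")


class TestMovementDatabase:
    def test_every_animal_has_exactly_one_birth(self, movement_events):
        births = movement_events[movement_events["event_kind"] == "birth"]
        assert births["animal_id"].is_unique
        assert set(movement_events["animal_id"]) == set(births["animal_id"])

    def test_deaths_postdate_births(self, movement_events):
        deaths = movement_events[movement_events["event_kind"] == "death"]
        dob = pd.to_datetime(deaths["date_of_birth"])
        assert (pd.to_datetime(deaths["event_date"]) > dob).all()

    def test_moves_are_paired_same_date(self, movement_events):
        moves = movement_events[movement_events["event_kind"]
                                .isin(("move_in", "move_out"))]
        for aid, grp in moves.groupby("animal_id"):
            kinds = grp["event_kind"].tolist()
            dates = grp["event_date"].tolist()
            # sorted order is move_out then its matched move_in, same date
            for i in range(0, len(kinds) - 1, 2):
                assert kinds[i] == "move_out" and kinds[i + 1] == "move_in"
                assert dates[i] == dates[i + 1]

    def test_deterministic_under_seed(self):
        lib = hm.default_archetypes()
        counts = [(lib["D"], 1), (lib["trading"], 1), (lib["fattening"], 1)]
        a = hm.generate_movement_db(counts, (2013, 2014), seed=21)
        b = hm.generate_movement_db(counts, (2013, 2014), seed=21)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_archetype_list_rejected(self):
        with pytest.raises(ConfigurationError):
            hm.generate_movement_db([], (2013, 2014), seed=0)

    def test_trading_headcount_peaks_spring_and_autumn(self):
        """Dairy calf sales (spring) and weanling sales (autumn) route via
        traders, so trading herds fill in those seasons."""
        lib = hm.default_archetypes()
        counts = [(lib["DnR_nC"], 2), (lib["BSW"], 8), (lib["trading"], 2),
                  (lib["fattening"], 3), (lib["Sbmx"], 3), (lib["Rdf"], 2)]
        events = hm.generate_movement_db(counts, (2012, 2014), seed=13)
        snaps, _ = hm.build_snapshots(events, ("2013-01", "2014-12"))
        trading = snaps[snaps["herd_id"].str.startswith("trading")]
        monthly = (trading.assign(m=pd.to_datetime(trading["snapshot_date"]).dt.month)
                   .groupby("m").size().reindex(range(1, 13), fill_value=0))
        spring_autumn = monthly[[3, 4, 5, 10, 11, 12]].sum()
        rest = monthly[[1, 2, 6, 7, 8, 9]].sum()
        assert spring_autumn > rest
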