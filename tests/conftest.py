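"""Shared fixtures: synthetic ground truths and a reusable herd population."""

import pandas as pd
import pytest

import herdmass as hm

#: archetype mix used by the shared population (name -> herd count)
ARCH_COUNTS = [("D", 3), ("DnR_nC", 3), ("DRm", 3), ("BSB", 5), ("BSW", 3),
               ("mixed", 2), ("Rdf", 3), ("Sdm", 3), ("Sbmx", 2),
               ("fattening", 3), ("trading", 2), ("unclassified", 2)]

EXPECTED_TYPE = {
    "D": "dairy", "DnR_nC": "dairy", "DRm": "dairy", "BSB": "beef",
    "BSW": "beef", "mixed": "mixed", "Rdf": "store_rearing",
    "Sdm": "store_rearing", "Sbmx": "store_rearing", "fattening": "fattening",
    "trading": "trading", "unclassified": "unclassified",
}

EXPECTED_SUBTYPE = {"D": "D", "DnR_nC": "DnR_nC", "DRm": "DRm", "BSB": "BSB",
                    "BSW": "BSW", "Rdf": "Rdf", "Sdm": "Sdm", "Sbmx": "Sbmx"}


def archetype_of(herd_id: str) -> str:
    return herd_id.rsplit("-", 1)[0]


@pytest.fixture(scope="session")
def clean_growth_truths():
    return hm.default_growth_truths(noise_sd=0.0, month_amplitude=0.0,
                                    year_trend=0.0)


@pytest.fixture(scope="session")
def clean_value_truths():
    return hm.default_value_truths(noise_sd=0.0, month_amplitude=0.0,
                                   year_trend=0.0)


@pytest.fixture(scope="session")
def movement_events():
    lib = hm.default_archetypes()
    counts = [(lib[name], n) for name, n in ARCH_COUNTS]
    return hm.generate_movement_db(counts, (2012, 2014), seed=5)


@pytest.fixture(scope="session")
def movement_snapshots(movement_events):
    snaps, quarantine = hm.build_snapshots(movement_events, ("2012-01", "2014-12"))
    return snaps, quarantine


@pytest.fixture(scope="session")
def herd_classifications(movement_events, movement_snapshots):
    snaps, _ = movement_snapshots
    return hm.classify_all(snaps, movement_events)


@pytest.fixture(scope="session")
def noisefree_fits(clean_growth_truths, clean_value_truths):
    """Four segmented fits trained on noise-free slaughter records with the
    break-point count fixed at the generating value (K=2)."""
    from herdmass.pipeline import _prepare_training
    from herdmass.segmented import FitSpec, fit_by_sex

    slaughter = hm.generate_slaughter_records(clean_growth_truths,
                                              clean_value_truths, 400, seed=11)
    cleaned, _ = hm.clean_dataset(slaughter)
    training = _prepare_training(cleaned)
    fits = {}
    for resp in ("liveweight", "value"):
        for sex, fit in fit_by_sex(training, resp, FitSpec(n_breakpoints=2),
                                   auto_select=False, response=resp).items():
            fits[(resp, sex)] = fit
    return fits
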