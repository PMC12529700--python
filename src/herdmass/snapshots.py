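"""First-of-month herd membership reconstructed from the movement event log.

An animal belongs to herd ``h`` on snapshot date ``d`` iff its latest
event at or before ``d`` places it in ``h``, it was born on or before
``d``, and it has neither died nor left without a matched move-in at or
before ``d``. Events dated exactly on a snapshot date take effect at
that snapshot: a move on the 1st counts in the destination herd, a death
on the 1st removes the animal.

Contradictory per-animal event sequences (death before birth, a move-in
with no preceding location, events before birth) quarantine the animal:
it is excluded from all snapshots and listed in the quarantine report,
and processing continues.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import pandas as pd

_KIND_ORDER = {"birth": 0, "move_out": 1, "move_in": 2, "death": 3}


def animal_age_days(date_of_birth: dt.date, at: dt.date) -> int:
    """Exact calendar-day age; errors if ``at`` precedes birth."""
    days = (at - date_of_birth).days
    if days < 0:
        raise ValueError(f"date {at} precedes date of birth {date_of_birth}")
    return days


@dataclass
class HerdMonthState:
    """Animals present in one herd on the first day of one month."""

    herd_id: str
    snapshot_date: dt.date
    members: pd.DataFrame  # animal_id, age_days, sex, breed_code


def month_firsts(date_range: tuple) -> list:
    """First-of-month dates covering an inclusive (start, end) month range.

    Accepts ``"YYYY-MM"`` strings or dates.
    """
    start = pd.Period(date_range[0], freq="M")
    end = pd.Period(date_range[1], freq="M")
    return [p.to_timestamp().date() for p in pd.period_range(start, end, freq="M")]


def _build_intervals(events: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal residence intervals [start, end) from the event log."""
    ev = events.copy()
    ev["event_date"] = pd.to_datetime(ev["event_date"]).dt.date
    ev["date_of_birth"] = pd.to_datetime(ev["date_of_birth"]).dt.date
    ev["_k"] = ev["event_kind"].map(_KIND_ORDER)
    ev = ev.sort_values(["animal_id", "event_date", "_k"], kind="mergesort")

    intervals = []
    quarantine = []
    for aid, grp in ev.groupby("animal_id", sort=False):
        rows = grp.itertuples(index=False)
        cur_herd = None
        cur_start = None
        dob = None
        sex = breed = None
        problem = None
        spans = []
        open_moveout = False
        for r in rows:
            kind, herd, date = r.event_kind, r.herd_id, r.event_date
            if kind == "birth":
                if cur_herd is not None or dob is not None:
                    problem = "duplicate birth"
                    break
                dob, sex, breed = r.date_of_birth, r.sex, r.breed_code
                if date != dob:
                    problem = "birth event date differs from date_of_birth"
                    break
                cur_herd, cur_start = herd, date
            elif dob is None:
                problem = f"{kind} before birth"
                break
            elif date < dob:
                problem = "event predates birth"
                break
            elif kind == "move_out":
                if cur_herd is None:
                    problem = "move_out while not resident"
                    break
                spans.append((cur_herd, cur_start, date))
                cur_herd, cur_start = None, None
                open_moveout = True
            elif kind == "move_in":
                if cur_herd is not None:
                    # implicit departure: close the previous stay
                    spans.append((cur_herd, cur_start, date))
                cur_herd, cur_start = herd, date
                open_moveout = False
            elif kind == "death":
                if cur_herd is None:
                    problem = "death while not resident"
                    break
                spans.append((cur_herd, cur_start, date))
                cur_herd, cur_start = None, None
                open_moveout = False
                break
        if problem is not None:
            quarantine.append({"animal_id": aid, "reason": problem})
            continue
        if cur_herd is not None:
            spans.append((cur_herd, cur_start, None))  # censored: still resident
        for herd, s, e in spans:
            intervals.append({"animal_id": aid, "herd_id": herd, "start": s,
                              "end": e, "sex": sex, "breed_code": breed,
                              "date_of_birth": dob})
        if open_moveout:
            quarantine.append({"animal_id": aid,
                               "reason": "open move_out (no matched move_in)"})
    iv = pd.DataFrame(intervals, columns=["animal_id", "herd_id", "start", "end",
                                          "sex", "breed_code", "date_of_birth"])
    qr = pd.DataFrame(quarantine, columns=["animal_id", "reason"])
    return iv, qr


def build_snapshots(events: pd.DataFrame,
                    date_range: tuple) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Herd membership on the first of every month in ``date_range``.

    Returns ``(snapshots, quarantine)``: a long table with one row per
    (snapshot_date, herd, animal) carrying ``age_days``, ``sex`` and
    ``breed_code``, and the per-animal quarantine report.
    """
    iv, quarantine = _build_intervals(events)
    dates = month_firsts(date_range)
    out = []
    if not iv.empty:
        starts = pd.to_datetime(iv["start"])
        ends = pd.to_datetime(iv["end"])  # NaT = censored (still resident)
        for d in dates:
            ts = pd.Timestamp(d)
            mask = (starts <= ts) & (ends.isna() | (ends > ts))
            part = iv.loc[mask, ["herd_id", "animal_id", "sex", "breed_code",
                                 "date_of_birth"]].copy()
            part.insert(0, "snapshot_date", d)
            part["age_days"] = [(d - dob).days for dob in part["date_of_birth"]]
            out.append(part)
    cols = ["snapshot_date", "herd_id", "animal_id", "sex", "breed_code",
            "date_of_birth", "age_days"]
    snap = (pd.concat(out, ignore_index=True)[cols]
            if out else pd.DataFrame(columns=cols))
    snap = snap.sort_values(["snapshot_date", "herd_id", "animal_id"],
                            kind="mergesort").reset_index(drop=True)
    return snap, quarantine


def iter_states(snapshots: pd.DataFrame):
    """Yield one ``HerdMonthState`` per (snapshot_date, herd)."""
    for (date, herd), grp in snapshots.groupby(["snapshot_date", "herd_id"],
                                               sort=True):
        yield HerdMonthState(
            herd_id=herd, snapshot_date=date,
            members=grp[["animal_id", "age_days", "sex", "breed_code"]]
            .reset_index(drop=True),
        )
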