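"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from rxadhere.records import DrugClass, FillRecord, StudyWindow


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive; they check the fast paths)


def shift_forward_oracle(fills, window: StudyWindow) -> int:
    """Day-by-day supply-inventory simulation.

    Supply accumulates into an inventory on each fill date and is consumed
    one day at a time; a day is covered when inventory is positive.  This is
    an independent restatement of the shift-forward convention (deferred
    early refills) without any interval arithmetic.
    """
    events: dict[int, int] = {}
    for f in fills:
        if f.fill_day >= window.end_day:
            continue
        events[f.fill_day] = events.get(f.fill_day, 0) + f.days_supply
    if not events:
        return 0
    start = min(min(events), window.start_day)
    inventory = 0
    covered = 0
    for day in range(start, window.end_day):
        inventory += events.get(day, 0)
        if inventory > 0:
            inventory -= 1
            if day >= window.start_day:
                covered += 1
    return covered


def truncate_overlap_oracle(fills, window: StudyWindow) -> int:
    """Boolean day-marking over the window (interval union)."""
    marked = np.zeros(window.length_days, dtype=bool)
    for f in fills:
        if f.fill_day >= window.end_day:
            continue
        lo = max(f.fill_day, window.start_day) - window.start_day
        hi = min(f.fill_day + f.days_supply, window.end_day) - window.start_day
        if hi > lo:
            marked[lo:hi] = True
    return int(marked.sum())


def mantel_haenszel_rr(strata) -> float:
    """Closed-form Mantel-Haenszel common risk ratio.

    ``strata`` is an iterable of (a, n1, c, n2) tuples (exposed events /
    exposed total / unexposed events / unexposed total).
    """
    num = sum(a * n2 / (n1 + n2) for a, n1, c, n2 in strata)
    den = sum(c * n1 / (n1 + n2) for a, n1, c, n2 in strata)
    return num / den


# ---------------------------------------------------------------------------
# small builders


@pytest.fixture
def window():
    return StudyWindow(dt.date(2010, 3, 1), 365)


def make_fill(day_offset: int, supply: int, window: StudyWindow,
              patient="p1", subclass="ACE",
              drug_class=DrugClass.ANTIHYPERTENSIVE) -> FillRecord:
    return FillRecord(
        patient_id=patient,
        drug_class=drug_class,
        subclass=subclass,
        fill_date=window.start + dt.timedelta(days=day_offset),
        days_supply=supply,
    )


@pytest.fixture
def fill_factory(window):
    def _make(day_offset, supply, **kw):
        return make_fill(day_offset, supply, window, **kw)

    return _make


def random_fill_set(rng: np.random.Generator, window: StudyWindow,
                    max_fills: int = 20):
    """Random stream for oracle-equivalence checks: supplies 1-120, offsets 0-364."""
    n = int(rng.integers(0, max_fills + 1))
    return [
        make_fill(int(rng.integers(0, 365)), int(rng.integers(1, 121)), window)
        for _ in range(n)
    ]
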