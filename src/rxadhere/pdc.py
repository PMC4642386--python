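"""Proportion-of-days-covered (PDC) computation.

PDC for one drug subclass is the number of *distinct* days inside a study
window on which the patient has medication supply available, divided by the
window length (365 days by default).  When a patient fills drugs in several
subclasses of a class, one PDC is computed per subclass and the subclass PDCs
are averaged (unweighted) into a single class-level PDC.  A patient is
*adherent* in a window when the class PDC is >= 0.80 (inclusive).

Two carryover policies are supported for early refills:

``shift_forward``
    A fill that arrives while prior supply remains is deferred to start the
    day after the prior supply ends (the prevailing PDC convention); supply
    never extends beyond the window end.
``truncate_overlap``
    Each fill covers exactly ``[fill_date, fill_date + days_supply)``;
    overlapping days count once (interval union).

Both policies are implemented by one vectorized segmented scan so that the
single-stream functions and the bulk table builder share a code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import DrugClass, FillRecord, StudyWindow

__all__ = [
    "PdcResult",
    "covered_days",
    "pdc_subclass",
    "pdc_class",
    "classify_adherent",
    "compute_pdc_table",
    "DEFAULT_THRESHOLD",
    "CARRYOVER_POLICIES",
]

logger = logging.getLogger("rxadhere.pdc")

DEFAULT_THRESHOLD = 0.80
CARRYOVER_POLICIES = ("shift_forward", "truncate_overlap")

# Large offset used to make a global running maximum behave as a per-group
# (segmented) running maximum; must exceed any |value| encountered.
_SEG_OFFSET = 1 << 40


@dataclass(frozen=True)
class PdcResult:
    """Per patient x drug class x period adherence summary.

    ``covered_days`` is the subclass-mean of distinct covered days (rounded
    display value is the raw float); ``pdc`` is the class-level PDC in [0, 1];
    ``adherent`` is ``pdc >= threshold``.
    """

    patient_id: str
    drug_class: DrugClass
    period: str
    covered_days: float
    pdc: float
    adherent: bool
    n_subclasses: int
    per_subclass_pdc: Mapping[str, float]


def _segmented_running_max(values: np.ndarray, group_index: np.ndarray,
                           shifted: bool) -> np.ndarray:
    """Per-group running max of ``values`` (groups must be contiguous).

    With ``shifted`` the maximum is over strictly earlier elements of the
    group; the first element of each group gets -inf (returned as a very
    small number).
    """
    offset = group_index.astype(np.int64) * _SEG_OFFSET
    run = np.maximum.accumulate(values + offset)
    if shifted:
        prev = np.empty_like(run)
        prev[0] = -_SEG_OFFSET  # sentinel below any in-group value
        prev[1:] = run[:-1]
        # first element of each group must not see the previous group
        first = np.empty(len(values), dtype=bool)
        first[0] = True
        first[1:] = group_index[1:] != group_index[:-1]
        prev[first] = offset[first] - _SEG_OFFSET
        return prev - offset
    return run - offset


def covered_days_grouped(
    group_index: np.ndarray,
    fill_days: np.ndarray,
    supplies: np.ndarray,
    window_start: int,
    window_end: int,
    carryover: str = "shift_forward",
) -> np.ndarray:
    """Vectorized covered-day counts for many fill streams at once.

    Parameters
    ----------
    group_index
        Dense group labels ``0..G-1``; rows must be sorted by
        ``(group_index, fill_days)``.
    fill_days, supplies
        Integer day offsets and days-of-supply, one row per fill.
    window_start, window_end
        Half-open window ``[window_start, window_end)`` in the same day units.
    carryover
        One of :data:`CARRYOVER_POLICIES`.

    Returns
    -------
    ndarray of shape (G,): distinct covered days per group, each in
    ``[0, window_end - window_start]``.
    """
    if carryover not in CARRYOVER_POLICIES:
        raise ValueError(f"unknown carryover policy {carryover!r}")
    n_groups = int(group_index.max()) + 1 if len(group_index) else 0
    out = np.zeros(n_groups, dtype=np.int64)
    if len(fill_days) == 0:
        return out
    fill_days = fill_days.astype(np.int64)
    supplies = supplies.astype(np.int64)

    if carryover == "shift_forward":
        # With S_k the in-group cumsum of supplies, the running supply end is
        #   e_k = max(e_{k-1}, d_k) + s_k = S_k + max_{j<=k}(d_j - S_{j-1}),
        # so a segmented prefix max turns the recurrence into array ops.
        cum = np.cumsum(supplies)
        group_base = _group_starts_cum(group_index, cum, supplies)
        seg_cum = cum - group_base  # in-group cumulative supply S_k
        prev_cum = seg_cum - supplies  # S_{k-1}
        m = _segmented_running_max(fill_days - prev_cum, group_index,
                                   shifted=False)
        end = seg_cum + m
        begin = end - supplies
        cov = np.clip(np.minimum(end, window_end)
                      - np.maximum(begin, window_start), 0, None)
    else:  # truncate_overlap: interval union of [d, d+s) clipped to window
        end = fill_days + supplies
        prev_end = _segmented_running_max(end, group_index, shifted=True)
        begin = np.maximum(fill_days, prev_end)
        cov = np.clip(np.minimum(end, window_end)
                      - np.maximum(begin, window_start), 0, None)
    np.add.at(out, group_index, cov)
    return np.minimum(out, window_end - window_start)


def _group_starts_cum(group_index: np.ndarray, cum: np.ndarray,
                      values: np.ndarray) -> np.ndarray:
    """Cumsum value just before each row's group started (for segmenting)."""
    first = np.empty(len(group_index), dtype=bool)
    first[0] = True
    first[1:] = group_index[1:] != group_index[:-1]
    base_per_group = (cum - values)[first]
    return base_per_group[group_index]


def _prepare_stream(fills: Sequence[FillRecord], window: StudyWindow):
    """Sorted (days, supplies) arrays for one patient+subclass stream.

    Fills dated on/after the window end are ignored with a warning (they
    cannot contribute coverage and usually indicate a windowing mistake).
    """
    days, supplies = [], []
    for f in fills:
        if f.fill_day >= window.end_day:
            logger.warning(
                "fill for %s/%s on %s is after window end %s; ignored",
                f.patient_id, f.subclass, f.fill_date, window.end,
            )
            continue
        days.append(f.fill_day)
        supplies.append(f.days_supply)
    order = np.argsort(np.asarray(days, dtype=np.int64), kind="stable")
    return (np.asarray(days, dtype=np.int64)[order],
            np.asarray(supplies, dtype=np.int64)[order])


def covered_days(
    fills: Sequence[FillRecord],
    window: StudyWindow,
    carryover: str = "shift_forward",
) -> int:
    """Distinct days within ``window`` with supply available for one stream.

    All fills must belong to one patient and one subclass; order is
    irrelevant.  An empty fill set yields 0.
    """
    pids = {(f.patient_id, f.subclass) for f in fills}
    if len(pids) > 1:
        raise ValueError(
            f"fills must share one patient and subclass, got {sorted(pids)}"
        )
    days, supplies = _prepare_stream(fills, window)
    if len(days) == 0:
        return 0
    group = np.zeros(len(days), dtype=np.int64)
    return int(
        covered_days_grouped(
            group, days, supplies, window.start_day, window.end_day, carryover
        )[0]
    )


def pdc_subclass(
    fills: Sequence[FillRecord],
    window: StudyWindow,
    carryover: str = "shift_forward",
) -> float:
    """PDC for a single subclass stream: covered days / window length."""
    return covered_days(fills, window, carryover) / window.length_days


def pdc_class(per_subclass_pdc: Mapping[str, float]) -> float:
    """Unweighted mean of subclass PDCs -> one class-level PDC."""
    if not per_subclass_pdc:
        raise ValueError("at least one subclass PDC is required")
    vals = list(per_subclass_pdc.values())
    return float(sum(vals) / len(vals))


def classify_adherent(pdc: float, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """Adherent iff ``pdc >= threshold`` (boundary counts as adherent)."""
    if not 0.0 <= pdc <= 1.0:
        raise ValueError(f"pdc must be in [0, 1], got {pdc}")
    return pdc >= threshold


def compute_pdc_table(
    fills: Iterable[FillRecord] | pd.DataFrame,
    windows: Mapping[str, StudyWindow],
    threshold: float = DEFAULT_THRESHOLD,
    carryover: str = "shift_forward",
) -> pd.DataFrame:
    """PDC table for every patient x drug class x period.

    Parameters
    ----------
    fills
        FillRecords, or a DataFrame with columns ``patient_id, drug_class,
        subclass, fill_day, days_supply`` (``fill_day`` as integer offsets).
    windows
        Mapping period name (e.g. ``"baseline"``, ``"follow_up"``) to its
        :class:`~rxadhere.records.StudyWindow`.  Only fills dated inside a
        period's window enter that period's PDC (no cross-period carryover).

    Returns
    -------
    DataFrame with one row per (patient_id, drug_class, period) for which at
    least one in-window fill exists, columns ``patient_id, drug_class,
    period, covered_days, pdc, adherent, n_subclasses``.
    """
    if isinstance(fills, pd.DataFrame):
        df = fills
    else:
        fills = list(fills)
        df = pd.DataFrame(
            {
                "patient_id": [f.patient_id for f in fills],
                "drug_class": [f.drug_class.value for f in fills],
                "subclass": [f.subclass for f in fills],
                "fill_day": [f.fill_day for f in fills],
                "days_supply": [f.days_supply for f in fills],
            }
        )
    frames = []
    for period, window in windows.items():
        sub = df[
            (df["fill_day"] >= window.start_day)
            & (df["fill_day"] < window.end_day)
        ]
        if sub.empty:
            continue
        key, group_index = np.unique(
            np.char.add(
                np.char.add(sub["patient_id"].to_numpy(str), "\x1f"),
                np.char.add(
                    np.char.add(sub["drug_class"].to_numpy(str), "\x1f"),
                    sub["subclass"].to_numpy(str),
                ),
            ),
            return_inverse=True,
        )
        order = np.lexsort((sub["fill_day"].to_numpy(), group_index))
        cov = covered_days_grouped(
            group_index[order],
            sub["fill_day"].to_numpy()[order],
            sub["days_supply"].to_numpy()[order],
            window.start_day,
            window.end_day,
            carryover,
        )
        parts = np.array([k.split("\x1f") for k in key])
        stream = pd.DataFrame(
            {
                "patient_id": parts[:, 0],
                "drug_class": parts[:, 1],
                "covered_days": cov,
                "pdc": cov / window.length_days,
            }
        )
        agg = stream.groupby(["patient_id", "drug_class"], as_index=False).agg(
            covered_days=("covered_days", "mean"),
            pdc=("pdc", "mean"),
            n_subclasses=("pdc", "size"),
        )
        agg["period"] = period
        frames.append(agg)
    if not frames:
        return pd.DataFrame(
            columns=[
                "patient_id", "drug_class", "period",
                "covered_days", "pdc", "adherent", "n_subclasses",
            ]
        )
    out = pd.concat(frames, ignore_index=True)
    out["adherent"] = out["pdc"] >= threshold
    return out[
        ["patient_id", "drug_class", "period",
         "covered_days", "pdc", "adherent", "n_subclasses"]
    ]
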