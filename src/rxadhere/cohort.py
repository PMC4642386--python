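"""Eligibility filtering and per-drug-class analysis cohort assembly.

A patient enters a drug-class cohort when they (a) are 18-89 years old at the
baseline window start, (b) are enrolled continuously from the baseline start
through the follow-up end, and (c) have at least one fill of the class in
each of the two periods.  Age is evaluated at the baseline start so the
filter is deterministic.  Filters are applied in a fixed order and an
attrition log records how many patients each rule removed; cohort membership
itself does not depend on the order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .records import DrugClass, FillRecord, Group, PatientRecord, StudyWindow

__all__ = ["CohortMember", "build_cohort", "class_membership_summary",
           "cohort_to_frame", "AGE_RANGE"]

logger = logging.getLogger("rxadhere.cohort")

#: Inclusive eligible age range at baseline start.
AGE_RANGE = (18, 89)

#: Attrition rules in application order.
FILTER_ORDER = ("age", "enrollment", "missing_period_claim", "missing_pdc")


@dataclass(frozen=True)
class CohortMember:
    """One analysis-cohort row: arm, adherence flags for both periods, covariates."""

    patient_id: str
    group: Group
    drug_class: DrugClass
    baseline_adherent: bool
    followup_adherent: bool
    covariates: Mapping[str, float | None] = field(default_factory=dict)


class ReferentialIntegrityError(ValueError):
    """A fill references a patient that is absent from the roster."""


def build_cohort(
    patients: Sequence[PatientRecord],
    fills: Iterable[FillRecord] | pd.DataFrame,
    pdc_results: pd.DataFrame,
    drug_class: DrugClass,
    baseline: StudyWindow,
    follow_up: StudyWindow,
    age_range: tuple[int, int] = AGE_RANGE,
) -> tuple[list[CohortMember], dict[str, int]]:
    """Apply eligibility filters and attach adherence flags.

    Parameters
    ----------
    fills
        FillRecords, or a DataFrame with ``patient_id, drug_class,
        fill_day`` columns (integer day offsets), as produced by the
        simulator.
    pdc_results
        Output of :func:`rxadhere.pdc.compute_pdc_table` covering the two
        periods named ``"baseline"`` and ``"follow_up"``.

    Returns
    -------
    (members, attrition) where ``attrition`` counts patients removed per rule
    in application order (each patient is charged to the first rule that
    removed them).

    Raises
    ------
    ReferentialIntegrityError
        If any fill's patient_id is missing from the roster.
    """
    roster = {p.patient_id: p for p in patients}
    per_period_ids: dict[str, set[str]] = {"baseline": set(), "follow_up": set()}
    if isinstance(fills, pd.DataFrame):
        fill_ids = set(fills["patient_id"])
        cls_mask = fills["drug_class"] == drug_class.value
        day = fills["fill_day"]
        per_period_ids["baseline"] = set(
            fills.loc[cls_mask & (day >= baseline.start_day)
                      & (day < baseline.end_day), "patient_id"]
        )
        per_period_ids["follow_up"] = set(
            fills.loc[cls_mask & (day >= follow_up.start_day)
                      & (day < follow_up.end_day), "patient_id"]
        )
    else:
        fills = list(fills)
        fill_ids = {f.patient_id for f in fills}
        for f in fills:
            if f.drug_class is not drug_class:
                continue
            if baseline.contains_day(f.fill_day):
                per_period_ids["baseline"].add(f.patient_id)
            elif follow_up.contains_day(f.fill_day):
                per_period_ids["follow_up"].add(f.patient_id)
    orphans = sorted(fill_ids - roster.keys())
    if orphans:
        raise ReferentialIntegrityError(
            f"fills reference {len(orphans)} patient id(s) absent from "
            f"roster: {orphans[:10]}"
        )

    cls = pdc_results[pdc_results["drug_class"] == drug_class.value]
    adherent = {
        (row.patient_id, row.period): bool(row.adherent)
        for row in cls.itertuples()
    }

    attrition = {rule: 0 for rule in FILTER_ORDER}
    members: list[CohortMember] = []
    for p in patients:
        age_ok = age_range[0] <= p.age <= age_range[1]
        enroll_ok = (
            p.enroll_start <= baseline.start and p.enroll_end >= follow_up.end
        )
        claims_ok = (
            p.patient_id in per_period_ids["baseline"]
            and p.patient_id in per_period_ids["follow_up"]
        )
        pdc_ok = (
            (p.patient_id, "baseline") in adherent
            and (p.patient_id, "follow_up") in adherent
        )
        for rule, ok in zip(
            FILTER_ORDER, (age_ok, enroll_ok, claims_ok, pdc_ok)
        ):
            if not ok:
                attrition[rule] += 1
                break
        else:
            members.append(
                CohortMember(
                    patient_id=p.patient_id,
                    group=p.group,
                    drug_class=drug_class,
                    baseline_adherent=adherent[(p.patient_id, "baseline")],
                    followup_adherent=adherent[(p.patient_id, "follow_up")],
                    covariates=p.covariates(),
                )
            )
    removed = {k: v for k, v in attrition.items() if v}
    logger.info(
        "%s cohort: %d retained of %d roster patients; attrition %s",
        drug_class.value, len(members), len(patients), removed or "none",
    )
    return members, attrition


def class_membership_summary(
    cohorts: Mapping[DrugClass, Sequence[CohortMember]],
) -> dict[str, int]:
    """Counts of patients in both classes / each class only.

    The three counts are mutually exclusive and sum to the size of the union
    cohort.
    """
    htn = {m.patient_id for m in cohorts.get(DrugClass.ANTIHYPERTENSIVE, ())}
    lip = {m.patient_id for m in cohorts.get(DrugClass.ANTIHYPERLIPIDEMIC, ())}
    return {
        "both": len(htn & lip),
        "antihypertensive_only": len(htn - lip),
        "antihyperlipidemic_only": len(lip - htn),
        "union": len(htn | lip),
    }


def cohort_to_frame(members: Sequence[CohortMember]) -> pd.DataFrame:
    """Flatten a cohort into a DataFrame for modelling."""
    rows = []
    for m in members:
        row = {
            "patient_id": m.patient_id,
            "group": m.group.value,
            "intervention": float(m.group is Group.INTERVENTION),
            "baseline_adherent": bool(m.baseline_adherent),
            "followup_adherent": bool(m.followup_adherent),
        }
        row.update(m.covariates)
        rows.append(row)
    return pd.DataFrame(rows)
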