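#!/usr/bin/env python
"""Assemble the per-drug-class analysis cohorts with eligibility filters.

Applies the age (18-89), continuous-enrollment and claim-in-both-periods
filters, reports the attrition per rule and the class-membership overlap
(both classes / antihypertensive only / antihyperlipidemic only), and
writes results/cohorts.json.
"""

import argparse
import datetime as dt
import json
from pathlib import Path

from rxadhere.cohort import build_cohort, class_membership_summary
from rxadhere.pdc import compute_pdc_table
from rxadhere.records import (
    DrugClass, Group, StudyWindow, read_fills, read_patients,
)
from rxadhere.simulate import DEFAULT_BASELINE_START


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--baseline-start", type=dt.date.fromisoformat,
                    default=DEFAULT_BASELINE_START)
    ap.add_argument("--out", type=Path, default=Path("results/cohorts.json"))
    args = ap.parse_args()

    patients = read_patients(args.data / "patients.csv")
    fills = read_fills(args.data / "fills.csv")
    baseline = StudyWindow(args.baseline_start)
    follow_up = StudyWindow(baseline.end)
    windows = {"baseline": baseline, "follow_up": follow_up}
    pdc = compute_pdc_table(fills, windows)

    cohorts, report = {}, {}
    for cls in DrugClass:
        members, attrition = build_cohort(
            patients, fills, pdc, cls, baseline, follow_up
        )
        cohorts[cls] = members
        n_int = sum(m.group is Group.INTERVENTION for m in members)
        report[cls.value] = {
            "n": len(members), "intervention": n_int,
            "control": len(members) - n_int, "attrition": attrition,
        }
        print(f"{cls.value}: {len(members)} members "
              f"({n_int} intervention / {len(members) - n_int} control); "
              f"attrition {dict((k, v) for k, v in attrition.items() if v)}")
    summary = class_membership_summary(cohorts)
    report["membership"] = summary
    print(f"class overlap: {summary['both']} in both, "
          f"{summary['antihypertensive_only']} antihypertensive only, "
          f"{summary['antihyperlipidemic_only']} antihyperlipidemic only "
          f"(union {summary['union']})")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(report, indent=2) + "\n")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
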