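#!/usr/bin/env python
"""Generate the default synthetic two-arm claims study.

Writes the patient roster, both periods' pharmacy fills, and a provenance
file (full generator config + seed) under results/data/.  Arm sizes and
covariate moments follow the emulated study (756 intervention / 1391
control); the follow-up propensity shifts are the frozen calibration
against its follow-up adherence rates.
"""

import argparse
from pathlib import Path

from rxadhere.simulate import SimulationConfig, simulate_study


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed)
    study = simulate_study(cfg)
    paths = study.write(args.out)
    n_bl = (study.fills["fill_day"] < cfg.windows["follow_up"].start_day).sum()
    print(f"roster: {len(study.roster)} patients "
          f"({cfg.n_intervention} intervention / {cfg.n_control} control)")
    print(f"fills: {len(study.fills)} ({n_bl} baseline, "
          f"{len(study.fills) - n_bl} follow-up)")
    for name, p in paths.items():
        print(f"  {name}: {p}")


if __name__ == "__main__":
    main()
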