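#!/usr/bin/env python
"""Simulate the study's data: a demo participant with full multichannel EMG
for all three inspired-oxygen conditions, plus an 18-participant crossover
cohort at the motor-unit property and cardiorespiratory level.

Writes small tables (ground truth, MU properties, breath-by-breath,
session endpoints) under results/sim/ and the bulky raw EMG under
scratch/sim/ (HDF5, one dataset per contraction).
"""

import argparse
from pathlib import Path

import pandas as pd

from hdemg_hypoxia import io
from hdemg_hypoxia.core import CONDITIONS
from hdemg_hypoxia.simulate import (
    ConditionEffects,
    simulate_cohort,
    simulate_mu_property_table,
    simulate_session,
)

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out", type=Path, default=Path("results/sim"))
ap.add_argument("--scratch", type=Path, default=Path("scratch/sim"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)
args.scratch.mkdir(parents=True, exist_ok=True)

effects = ConditionEffects()

# --- demo participant: full 9-contraction HD-sEMG sessions ---------------
for k, cond in enumerate(CONDITIONS):
    session = simulate_session(
        "DEMO", "M", cond, effects=effects, seed=args.seed * 100 + k, n_mus=5,
        noise_rms=1.0,
    )
    io.save_recording_h5(
        args.scratch / f"DEMO_{cond}.h5",
        {f"c{i+1:02d}": rec for i, rec in enumerate(session.contractions)},
    )
    io.save_ground_truth(
        args.out / f"DEMO_{cond}_ground_truth.csv",
        session.ground_truth["specs"],
        session.ground_truth["trains"],
    )
    print(f"DEMO {cond}: {len(session.contractions)} contractions, "
          f"SpO2 end {session.spo2_end:.1f}%")

# --- cohort: property-level observations + cardiorespiratory sessions ----
mu_table = simulate_mu_property_table(effects=effects, seed=args.seed)
mu_table.to_csv(args.out / "cohort_mu_properties.csv", index=False)

sessions = simulate_cohort(
    effects=effects, seed=args.seed + 1, synthesize_signal=False, n_mus=0
)
rows, bxb_rows = [], []
for s in sessions:
    rows.append(
        {"participant": s.participant_id, "sex": s.sex, "condition": s.condition,
         "spo2_end": s.spo2_end}
    )
    for t, hr, ve, vo2 in zip(s.bxb.times, s.bxb.hr, s.bxb.ve, s.bxb.vo2):
        bxb_rows.append(
            {"participant": s.participant_id, "condition": s.condition,
             "time_s": t, "hr": hr, "ve": ve, "vo2": vo2}
        )
pd.DataFrame(rows).to_csv(args.out / "cohort_sessions.csv", index=False)
pd.DataFrame(bxb_rows).to_csv(args.out / "cohort_bxb.csv", index=False)

io.save_config(
    args.out / "config.yaml",
    {
        "grid": {"rows": 13, "cols": 5, "ied_mm": 8.0, "fs_hz": 2048.0},
        "protocol": {"n_contractions": 9, "on_s": 5.0, "off_s": 15.0},
        "conditions": list(CONDITIONS),
        "noise_rms_uv": 1.0,
        "seeds": {"demo": args.seed, "cohort": args.seed + 1},
    },
)
print(f"cohort: {len(sessions)} sessions, {len(mu_table)} MU observations")
print(f"tables -> {args.out}, raw EMG -> {args.scratch}")
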