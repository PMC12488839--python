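#!/usr/bin/env python
"""Filter and select the demo participant's contractions: 20-500 Hz
zero-phase band-pass, then keep the two highest-amplitude (grid-mean RMS)
contractions among the first five of each session.

Writes a selection manifest and the band-passed selected contractions."""

import argparse
from pathlib import Path

import pandas as pd

from hdemg_hypoxia import io
from hdemg_hypoxia.core import CONDITIONS, ContractionSegment
from hdemg_hypoxia.preprocess import bandpass, select_top_contractions

ap = argparse.ArgumentParser()
ap.add_argument("--scratch", type=Path, default=Path("scratch/sim"))
ap.add_argument("--out", type=Path, default=Path("results/sim"))
args = ap.parse_args()

manifest = []
for cond in CONDITIONS:
    recs = io.load_recording_h5(args.scratch / f"DEMO_{cond}.h5")
    segments = [
        ContractionSegment(recording=bandpass(rec), index=i + 1)
        for i, (_, rec) in enumerate(sorted(recs.items()))
    ]
    chosen = select_top_contractions(segments, first_n=5, k=2)
    chosen_idx = {s.index for s in chosen}
    for s in segments:
        manifest.append(
            {"condition": cond, "contraction": s.index,
             "mean_rms_uv": round(s.mean_rms, 3),
             "selected": s.index in chosen_idx}
        )
    io.save_recording_h5(
        args.scratch / f"DEMO_{cond}_selected.h5",
        {f"c{s.index:02d}": s.recording for s in chosen},
    )
    print(f"{cond}: selected contractions {sorted(chosen_idx)} "
          f"(RMS {[round(s.mean_rms,1) for s in chosen]} μV)")

pd.DataFrame(manifest).to_csv(args.out / "selection_manifest.csv", index=False)
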