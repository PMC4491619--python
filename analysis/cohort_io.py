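"""Shared helper: load the simulated cohort written by 01_simulate_cohort."""

from pathlib import Path

import numpy as np

from alphamark.preprocess import Recording

ROOT = Path(__file__).resolve().parents[1]


def load_cohort() -> list[Recording]:
    path = ROOT / "scratch" / "cohort.npz"
    if not path.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    data = np.load(path, allow_pickle=False)
    return [
        Recording(channel_labels=list(data["labels"]),
                  sampling_rate=float(data["sampling_rate"]),
                  samples=data["samples"][i].astype(float),
                  subject_id=str(sid))
        for i, sid in enumerate(data["subjects"])
    ]
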