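#!/usr/bin/env python
"""Individual anchors, bands, and power ratios for the simulated cohort.

For each subject: common-average re-reference, 2-s epochs, artifact
rejection, Welch spectrum, TF/IAF anchors on the electrode-averaged
spectrum, individualized bands, relative band powers, and the
alpha3/alpha2 and theta/gamma ratios. Writes results/band_powers.csv and
a Table-1-style per-group summary to results/group_summary.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from cohort_io import load_cohort  # noqa: E402

from alphamark.pipeline import PipelineConfig, process_subject, _band_table
from alphamark.stats import classify_tertile, group_summary

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    recordings = load_cohort()
    cfg = PipelineConfig(log_level="WARNING")
    results = [process_subject(rec, cfg) for rec in recordings]
    bands = _band_table(results)
    bands["group"] = [classify_tertile(r) for r in bands.alpha3_alpha2]
    bands.to_csv(ROOT / "results" / "band_powers.csv", index=False)

    truth = pd.read_csv(ROOT / "results" / "truth.csv")
    merged = bands.merge(truth[["subject", "group", "age", "education",
                                "mmse"]], on="subject", suffixes=("", "_true"))
    agree = (merged.group == merged.group_true).mean()
    print(f"anchors: mean TF {bands.tf.mean():.1f} Hz, "
          f"mean IAF {bands.iaf.mean():.1f} Hz")
    print(f"tertile classification agrees with ground truth for "
          f"{agree:.0%} of subjects")

    summary = group_summary(merged,
                            ("age", "education", "mmse", "alpha3_alpha2"))
    summary.to_csv(ROOT / "results" / "group_summary.csv", index=False)
    show = summary[["group", "n", "alpha3_alpha2_mean", "alpha3_alpha2_sd",
                    "alpha3_alpha2_min", "alpha3_alpha2_max"]]
    print(show.to_string(index=False, float_format=lambda v: f"{v:.3f}"))


if __name__ == "__main__":
    main()
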