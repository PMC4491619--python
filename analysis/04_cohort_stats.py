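#!/usr/bin/env python
"""Cohort statistics: three-way mixed ANOVAs on coherence, pairwise group
contrasts, correlations, and a W-score demonstration.

Reads the band-power and coherence tables written by the earlier
analyses. For each pair set (left/right intrahemispheric,
interhemispheric) the group x band x pair interaction is tested with
Greenhouse-Geisser correction (results/anova.csv). EEG-covariate Pearson
correlations go to results/correlations.csv. As a W-score demonstration,
the low-ratio group serves as the normative sample for age-corrected
theta power in the high-ratio group (results/w_scores.csv).
"""

from pathlib import Path

import pandas as pd

from alphamark.montage import PAIR_SETS
from alphamark.stats import (fit_control_norm, mixed_anova,
                             pairwise_group_contrasts, pearson_r, w_score)

ROOT = Path(__file__).resolve().parents[1]


def anova_per_pair_set(coh: pd.DataFrame,
                       groups: pd.Series) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    contrast_frames = []
    for set_name in PAIR_SETS:
        sub = coh[coh.pair_set == set_name]
        wide = sub.pivot_table(index="subject", columns=["band", "pair"],
                               values="coherence")
        values = wide.to_numpy().reshape(len(wide), sub.band.nunique(),
                                         sub.pair.nunique())
        labels = groups.loc[wide.index].to_numpy()
        res = mixed_anova(values, labels)
        res["pair_set"] = set_name
        rows.append(res)
        contrasts = pairwise_group_contrasts(values, labels)
        contrasts.insert(0, "pair_set", set_name)
        contrast_frames.append(contrasts)
    return pd.DataFrame(rows), pd.concat(contrast_frames, ignore_index=True)


def main() -> None:
    bands = pd.read_csv(ROOT / "results" / "band_powers.csv")
    coh = pd.read_csv(ROOT / "results" / "coherence.csv")
    truth = pd.read_csv(ROOT / "results" / "truth.csv")
    merged = bands.merge(truth[["subject", "age", "mmse"]], on="subject")

    groups = bands.set_index("subject")["group"]
    anova, contrasts = anova_per_pair_set(coh, groups)
    anova.to_csv(ROOT / "results" / "anova.csv", index=False)
    contrasts.to_csv(ROOT / "results" / "group_contrasts.csv", index=False)
    print("group x band x pair interactions:")
    print(anova[["pair_set", "F", "df_num", "df_den", "gg_epsilon",
                 "gg_p"]].to_string(index=False,
                                    float_format=lambda v: f"{v:.3f}"))

    rows = []
    for measure in ("alpha3_alpha2", "theta_gamma", "theta"):
        for cov in ("age", "mmse"):
            rows.append({"measure": measure, "covariate": cov,
                         **pearson_r(merged[measure], merged[cov])})
    corr = pd.DataFrame(rows)
    corr.to_csv(ROOT / "results" / "correlations.csv", index=False)
    print("\nEEG-covariate Pearson correlations "
          "(covariates carry no signal by construction):")
    print(corr.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

    low = merged[merged.group == "low"]
    high = merged[merged.group == "high"]
    norm = fit_control_norm(low.theta, low.age)
    ws = pd.DataFrame({
        "subject": high.subject,
        "theta_w": [w_score(v, a, norm)
                    for v, a in zip(high.theta, high.age)],
    })
    ws.to_csv(ROOT / "results" / "w_scores.csv", index=False)
    print(f"\nW scores (theta vs age, low group as norm): high-group mean "
          f"{ws.theta_w.mean():+.2f} (n={len(ws)})")


if __name__ == "__main__":
    main()
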