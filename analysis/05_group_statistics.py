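#!/usr/bin/env python
"""Group-level inference on the simulated decoding results.

Reads results/decoding_accuracies.csv (from 03) and
results/permutation_null.json (from 04), then:

 * tests each contrast's group accuracy against the permutation
   baseline (one-tailed one-sample t, Bonferroni over contrasts);
 * runs a 4 (contrasts) x 9 (folds) repeated-measures ANOVA with
   participants as subjects, followed by Tukey HSD on the contrast
   factor (the study's contrasts-by-ROIs ANOVA with folds standing in
   for the ROI factor, since the simulation carries a single ROI);
 * simulates a 7-rater subjective rating experiment from the stimulus
   images (ratings follow each image class's highlight/texture
   statistics plus rater noise) and compares Glossy vs Glossy-Control
   ratings with the exact Wilcoxon signed-rank test.

Writes results/group_stats.csv.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from surfdecode.imstats import image_stats
from surfdecode.stats import (
    one_sample_t_one_tailed,
    rm_anova_two_way,
    tukey_on_factor,
    wilcoxon_signed_rank,
)
from surfdecode.synth import generate_stimulus_image

RES = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 44) -> None:
    acc = pd.read_csv(RES / "decoding_accuracies.csv")
    baseline = json.loads((RES / "permutation_null.json").read_text())["boundary"]
    per_part = (acc.groupby(["contrast", "participant"])["accuracy"]
                   .mean().unstack(level="participant"))

    rows = []
    contrasts = list(per_part.index)
    print(f"one-tailed t vs permutation baseline {100 * baseline:.2f}% "
          f"(Bonferroni m={len(contrasts)}):")
    for name in contrasts:
        r = one_sample_t_one_tailed(per_part.loc[name].to_numpy(), baseline,
                                    m_tests=len(contrasts), contrast=name)
        rows.append({"test": "t_vs_baseline", "contrast": name, "stat": r.t,
                     "p": r.p_one_tailed, "significant": r.significant})
        print(f"  {name:9s} t({r.dof}) = {r.t:5.2f}, p = {r.p_one_tailed:.4f}"
              f"{' *' if r.significant else ''}")

    # contrasts x folds as a two-way within design (participants as subjects)
    wide = (acc.groupby(["participant", "contrast", "fold"])["accuracy"]
               .mean().unstack(["contrast", "fold"]))
    names = ["G_vs_R", "GC_vs_RC", "G_vs_M", "R_vs_M"]
    n_folds = acc["fold"].max() + 1
    cube = np.stack(
        [np.stack([wide[(c, f)].to_numpy() for f in range(n_folds)], axis=1)
         for c in names], axis=1,
    )  # participants x contrasts x folds
    tab = rm_anova_two_way(cube, design_label="4xfolds")
    a = tab.effects["A"]
    print(f"\nrm-ANOVA contrast effect: F({a.df},{a.error_df}) = {a.F:.1f}, "
          f"p = {a.p:.2g}")
    rows.append({"test": "rm_anova_contrast", "contrast": "all",
                 "stat": a.F, "p": a.p, "significant": a.p < 0.05})
    for r in tukey_on_factor(cube, tab, factor="A"):
        pair = f"{names[r.pair[0]]}|{names[r.pair[1]]}"
        rows.append({"test": "tukey_contrast", "contrast": pair, "stat": r.q,
                     "p": r.p, "significant": r.significant})
        if r.significant:
            print(f"  Tukey: {pair} differ (q = {r.q:.2f}, p = {r.p:.3f})")

    # subjective ratings: 7 raters score glossiness of glossy vs control
    rng = np.random.default_rng(seed)
    glossy, matte = [], []
    for rater in range(7):
        g = np.mean([image_stats(generate_stimulus_image("glossy", lv, 96,
                                                         seed=lv)).skew
                     for lv in range(1, 6)])
        m = np.mean([image_stats(generate_stimulus_image("matte", lv, 96,
                                                         seed=lv)).skew
                     for lv in range(1, 6)])
        glossy.append(g + 0.15 * rng.standard_normal())
        matte.append(m + 0.15 * rng.standard_normal())
    z, p = wilcoxon_signed_rank(np.array(matte), np.array(glossy))
    print(f"\nratings (glossiness proxy), Glossy-Control vs Glossy: "
          f"Z = {z:.1f}, p = {p:.4f} (exact, n = 7)")
    rows.append({"test": "wilcoxon_ratings", "contrast": "G_vs_GC",
                 "stat": z, "p": p, "significant": p < 0.05})

    pd.DataFrame(rows).to_csv(RES / "group_stats.csv", index=False)
    print(f"wrote {RES / 'group_stats.csv'}")


if __name__ == "__main__":
    main(*(int(a) for a in sys.argv[1:]))
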