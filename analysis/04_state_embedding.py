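#!/usr/bin/env python
"""Embed bouts in the 2-component ICA space and score drug effects.

Fits the normalization + ICA reference model on the central-region control
bouts, freezes it, projects every condition, tests per-axis distribution
shifts with the kernel-density two-sample permutation test, and computes the
four stimulatory/anxiolytic scores (distance pair and IC pair).
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from swimstates import kinematics, states

OUT = Path(__file__).resolve().parent.parent / "results"
CONDITIONS = ("control", "stress", "drug", "drug_stress")


def _load(cond):
    bouts = pd.read_csv(OUT / f"bouts_{cond}.csv")
    return kinematics.filter_central(bouts, arena_diameter_mm=90.0)


def main(seed=0):
    data = {c: _load(c) for c in CONDITIONS}
    X_ref, idx_ref = states.build_features(data["control"])
    norm, model = states.fit_embedding(X_ref, seed=seed)
    states.save_model(OUT / "ica_model.json", norm, model)

    emb, per_fish = {}, {}
    for cond, bouts in data.items():
        X, idx = states.build_features(bouts)
        e = states.project(X, norm, model)
        kept = bouts.iloc[idx].reset_index(drop=True)
        kept["ic1"], kept["ic2"] = e[:, 0], e[:, 1]
        emb[cond] = kept
        spont = kept[kept.epoch == "spont"]
        per_fish[cond] = spont.groupby("fish")[["ic1", "ic2"]].mean()
    pd.concat([e.assign(condition=c) for c, e in emb.items()],
              ignore_index=True).to_csv(OUT / "embedding.csv", index=False)

    # per-axis distribution shifts during spontaneous swimming
    tests = {}
    spont_c = emb["control"].query("epoch == 'spont'")
    for cond in ("drug", "stress"):
        spont_x = emb[cond].query("epoch == 'spont'")
        for axis in ("ic1", "ic2"):
            r = states.kde_two_sample_test(
                spont_c[axis].to_numpy()[:300],
                spont_x[axis].to_numpy()[:300], n_perm=300, seed=seed)
            tests[f"{cond}_{axis}"] = {"statistic": r.statistic,
                                       "p": r.p_value}
            print(f"spont {cond:7s} vs control, {axis}: p = {r.p_value:.4f}")

    # distance scores from per-fish spontaneous swim distance
    with open(OUT / "cohort_summary.json") as fh:
        cohort = json.load(fh)
    dists = {c: [f["spont_distance_mm"] for f in cohort[c]]
             for c in CONDITIONS}
    sd = states.score_distance_effects(dists["control"], dists["drug"],
                                       dists["stress"], dists["drug_stress"])

    # IC scores from per-fish mean spontaneous IC coordinates
    omr_ic1 = (emb["control"].query("epoch == 'omr'")
               .groupby("fish")["ic1"].mean())
    si = states.score_ic_effects(
        per_fish["control"]["ic1"], omr_ic1, per_fish["drug"]["ic1"],
        per_fish["control"]["ic2"], per_fish["stress"]["ic2"],
        per_fish["drug_stress"]["ic2"])

    scores = {
        "stimulatory_distance": {"mean": sd.stimulatory_distance.mean,
                                 "sem": sd.stimulatory_distance.sem},
        "anxiolytic_distance": {"mean": sd.anxiolytic_distance.mean,
                                "sem": sd.anxiolytic_distance.sem},
        "stimulatory_ic1": {"mean": si.stimulatory_ic1.mean,
                            "sem": si.stimulatory_ic1.sem},
        "anxiolytic_ic2": {"mean": si.anxiolytic_ic2.mean,
                           "sem": si.anxiolytic_ic2.sem},
        "kde_tests": tests,
    }
    with open(OUT / "scores.json", "w") as fh:
        json.dump(scores, fh, indent=2)
    print(f"stimulatory (distance) {sd.stimulatory_distance.mean:+.2f} "
          f"± {sd.stimulatory_distance.sem:.2f}; "
          f"anxiolytic (distance) {sd.anxiolytic_distance.mean:+.2f} "
          f"± {sd.anxiolytic_distance.sem:.2f}")
    print(f"stimulatory (IC1) {si.stimulatory_ic1.mean:+.2f} "
          f"± {si.stimulatory_ic1.sem:.2f}; "
          f"anxiolytic (IC2) {si.anxiolytic_ic2.mean:+.2f} "
          f"± {si.anxiolytic_ic2.sem:.2f}")


if __name__ == "__main__":
    main()
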