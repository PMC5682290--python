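#!/usr/bin/env python
"""Per-base DS/SS calls and the condition-wise DS/(DS+SS) ratio comparison.

Loads the simulated tracks, normalizes them, classifies every base of every
eligible transcript per replicate, and compares the transcript-wise ratio of
confidently paired bases between control and knockdown.  With the default
stabilization-dominated editing mix the ratio drops after knockdown, the
direction the ADAR1 experiment observed.  Writes results/structure/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from parsedit import counts, strclass

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "structure"


def main() -> None:
    tracks = counts.normalize_tracks(counts.load_experiment(ROOT / "results" / "sim"))
    eligible = sorted(strclass.eligible_transcripts(tracks))
    by_key = {(t.meta.condition, t.meta.enzyme, t.meta.replicate): t for t in tracks}

    rows = []
    ratios = {"control": {}, "kd": {}}
    per_rep = {"control": {}, "kd": {}}
    for cond in ("control", "kd"):
        for tid in eligible:
            reps = []
            for rep in (1, 2):
                v1 = by_key[(cond, "V1", rep)].counts[tid]
                s1 = by_key[(cond, "S1", rep)].counts[tid]
                summ = strclass.ds_ratio(strclass.classify_bases(v1, s1), tid, cond)
                reps.append(summ.ratio)
                rows.append(
                    {
                        "transcript": tid,
                        "condition": cond,
                        "replicate": rep,
                        "n_ds": summ.n_ds,
                        "n_ss": summ.n_ss,
                        "ratio": summ.ratio,
                    }
                )
            per_rep[cond][tid] = reps
            vals = [r for r in reps if r is not None]
            if vals:
                ratios[cond][tid] = float(np.mean(vals))

    OUT.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "ds_ratios_per_replicate.tsv", sep="\t", index=False)

    cmp = strclass.compare_conditions(ratios["control"], ratios["kd"])
    swe = {
        tid: strclass.classify_swe(per_rep["control"][tid], per_rep["kd"][tid]).klass
        for tid in eligible
    }
    pd.Series(swe, name="stability_class").rename_axis("transcript").to_csv(
        OUT / "stability_classes.tsv", sep="\t"
    )

    n_swe = sum(1 for k in swe.values() if k == "SWE")
    n_dswe = sum(1 for k in swe.values() if k == "DSWE")
    print(f"{len(eligible)} eligible transcripts")
    print(
        f"DS/(DS+SS) higher in control for {cmp.frac_control_higher:.0%} of transcripts "
        f"(paired Wilcoxon p = {cmp.wilcoxon_p:.2g})"
    )
    print(f"stability classes: {n_swe} SWE, {n_dswe} DSWE")
    print(f"wrote tables under {OUT}")


if __name__ == "__main__":
    main()
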