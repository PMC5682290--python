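#!/usr/bin/env python
"""Recompute the published enrichment folds from their raw counts.

Editing sites and DES density in structure-changed versus unchanged 3'UTR
exons (three coverage tiers), the DSWE-versus-SWE feature enrichments, and
the ADAR1:ADAR2 target ratio, all via region_enrichment on the printed
feature counts and merged region sizes.  Writes results/enrichment/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from parsedit.published import adar1_adar2_target_ratio, enrichment_folds

OUT = Path(__file__).resolve().parents[1] / "results" / "enrichment"


def main() -> None:
    rows = []
    for key, res in enrichment_folds().items():
        rows.append(
            {
                "contrast": key,
                "n_features_1": res.n1,
                "size_1": res.size1,
                "n_features_2": res.n2,
                "size_2": res.size2,
                "fold": round(res.fold, 2),
                "fisher_p": res.p,
            }
        )
    df = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "enrichment_folds.tsv", sep="\t", index=False)
    print(df[["contrast", "fold"]].to_string(index=False))
    print(f"ADAR1:ADAR2 target ratio = {adar1_adar2_target_ratio():.1f}")
    print(f"wrote {OUT / 'enrichment_folds.tsv'}")


if __name__ == "__main__":
    main()
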