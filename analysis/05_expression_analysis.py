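#!/usr/bin/env python
"""Normalise the count table (GeTMM), test differential expression and
classify genes temporally.

Computes gene-length-corrected TMM expression, the share of normalised
expression carried by the two planted non-coding regions, late-vs-early
differential expression at FDR <= 0.01, per-region fold changes relative to
5 min, and every gene's temporal class. Tables go under results/expression/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from phagetu.expression import differential, getmm, region_fraction, temporal_classes

BASE = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    counts = pd.read_csv(
        BASE / "data" / "counts.tsv", sep="\t", index_col=0, header=[0, 1]
    )
    lengths = pd.read_csv(
        BASE / "data" / "gene_lengths.tsv", sep="\t", index_col=0
    )["length"]
    out = BASE / "expression"
    out.mkdir(parents=True, exist_ok=True)

    norm = getmm(counts, lengths)
    norm.values.round(2).to_csv(out / "getmm.tsv", sep="\t")
    norm.tmm_factors.round(4).to_csv(out / "tmm_factors.tsv", sep="\t")

    regions = [g for g in counts.index if g.startswith("ncRNA")]
    share = region_fraction(norm.values, regions) if regions else float("nan")

    early_cols = [c for c in counts.columns if c[0] in ("t5", "t15")]
    late_cols = [c for c in counts.columns if c[0] == "t30"]
    de = differential(counts, early_cols, late_cols)
    de.round(4).to_csv(out / "de_late_vs_early.tsv", sep="\t")

    # per-region fold changes vs 5 min on normalised expression
    tp_means = norm.values.T.groupby(level=0).mean().T
    fc_rows = []
    for g in regions:
        for tp in ("t15", "t30"):
            fc_rows.append(
                {
                    "region": g, "comparison": f"{tp} vs t5",
                    "fold_change": round(
                        (tp_means.loc[g, tp] + 0.5) / (tp_means.loc[g, "t5"] + 0.5), 2
                    ),
                }
            )
    pd.DataFrame(fc_rows).to_csv(out / "ncrna_fold_changes.tsv", sep="\t", index=False)

    classes = temporal_classes(counts, lengths)
    classes.round(2).to_csv(out / "temporal_classes.tsv", sep="\t")
    tally = classes["temporal_class"].value_counts().to_dict()

    n_sig = int(de["significant"].sum())
    print(f"TMM factors: {np.round(norm.tmm_factors.values, 3)}")
    if regions:
        print(
            f"non-coding regions {regions} carry {share:.1f}% of normalised "
            f"expression"
        )
        for row in fc_rows:
            print(f"  {row['region']} {row['comparison']}: FC {row['fold_change']}")
    print(
        f"{n_sig}/{len(counts)} genes significant at FDR<=0.01 "
        f"(late vs pooled early); temporal classes: {tally}"
    )
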