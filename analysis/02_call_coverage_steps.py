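#!/usr/bin/env python
"""Call TSS/TTS candidates as sharp coverage steps and time-classify them.

Reads the genome and the six bedGraph tracks written by 01, detects up- and
down-steps per strand and timepoint, pools 5 and 15 min as the early window,
and writes the timed step table (TSV + BED6) under results/steps/.
"""

from pathlib import Path

import pandas as pd

from phagetu.coverage_steps import StepParams, classify_step_timing, detect_steps, steps_to_bed
from phagetu.genome_io import read_bedgraph, read_fasta, write_bed6

BASE = Path(__file__).resolve().parent.parent / "results"
TIMEPOINTS = ("t5", "t15", "t30")

if __name__ == "__main__":
    genome = read_fasta(BASE / "data" / "genome.fasta")
    params = StepParams()
    by_tp = {}
    for tp in TIMEPOINTS:
        steps = []
        for strand, tag in (("+", "plus"), ("-", "minus")):
            track = read_bedgraph(
                BASE / "data" / f"coverage_{tp}_{tag}.bedgraph",
                genome.length, strand, tp,
            )
            steps.extend(detect_steps(track, params))
        by_tp[tp] = steps
    timed = classify_step_timing(by_tp, params.merge_distance)

    out = BASE / "steps"
    out.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame(
        [
            {
                "position": s.position, "strand": s.strand,
                "direction": s.direction, "timing": s.timing,
                "fold": round(s.fold, 2),
                "high_side_depth": round(s.high_side_depth, 1),
                "timepoints": ",".join(sorted(s.timepoints)),
            }
            for s in timed
        ]
    )
    table.to_csv(out / "steps.tsv", sep="\t", index=False)
    write_bed6(steps_to_bed(timed, genome.id), out / "steps.bed")

    ups = table[table.direction == "up"]
    downs = table[table.direction == "down"]
    print(
        f"{len(ups)} up-steps ({(ups.timing == 'early').sum()} early, "
        f"{(ups.timing == 'late').sum()} late) and {len(downs)} down-steps "
        f"on {genome.length} bp; tables under {out}"
    )
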