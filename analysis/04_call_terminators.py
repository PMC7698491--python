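#!/usr/bin/env python
"""Call Rho-independent terminators at the down-steps from 02.

Scans the 100 bp window around every down-step for a GC-rich, exactly
pairing stem-loop followed by a polyT tract, and estimates per-timepoint
readthrough as the downstream/upstream coverage ratio. Down-steps without
the hairpin+polyT signature (for instance the tail ends of readthrough
transcription) are dropped. Writes results/terminators/terminators.tsv.
"""

from pathlib import Path

import pandas as pd

from phagetu.coverage_steps import CoverageStep, extract_downstep_windows
from phagetu.genome_io import read_bedgraph, read_fasta
from phagetu.terminator_finder import TerminatorParams, annotate_readthrough, call_terminator

BASE = Path(__file__).resolve().parent.parent / "results"
TIMEPOINTS = ("t5", "t15", "t30")

if __name__ == "__main__":
    genome = read_fasta(BASE / "data" / "genome.fasta")
    steps = pd.read_csv(BASE / "steps" / "steps.tsv", sep="\t")
    downs = [
        CoverageStep(
            position=int(r.position), direction="down", strand=r.strand,
            fold=float(r.fold), high_side_depth=float(r.high_side_depth),
        )
        for r in steps[steps.direction == "down"].itertuples()
    ]
    tracks = {
        strand: {
            tp: read_bedgraph(
                BASE / "data" / f"coverage_{tp}_{tag}.bedgraph",
                genome.length, strand, tp,
            )
            for tp in TIMEPOINTS
        }
        for strand, tag in (("+", "plus"), ("-", "minus"))
    }

    params = TerminatorParams()
    calls = []
    for w in extract_downstep_windows(genome, downs, 50):
        call = call_terminator(w, params)
        if call is None:
            continue
        annotate_readthrough(call, tracks[call.strand])
        calls.append(call)

    out = BASE / "terminators"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "position": c.position, "strand": c.strand,
                "stem": c.stem_len, "loop": c.loop_len,
                "gc_fraction": round(c.gc_fraction, 3),
                "polyT": c.polyt_len, "score": c.score,
                **{
                    f"readthrough_{tp}": (round(v, 3) if v is not None else None)
                    for tp, v in c.readthrough.items()
                },
            }
            for c in calls
        ]
    ).to_csv(out / "terminators.tsv", sep="\t", index=False)
    print(
        f"{len(calls)} terminators called from {len(downs)} down-steps "
        f"({len(downs) - len(calls)} windows lacked the hairpin+polyT "
        f"signature); table under {out}"
    )
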