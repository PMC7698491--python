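#!/usr/bin/env python
"""Learn the early and late promoter models and rescan the genome.

Takes 100 bp windows upstream of the early and late up-steps from 02, fits
the two-box early model (-35 TTGACW + ext/-10 TRTGNTATANT, spacer 16-18)
and the late core PWM (TGTTATATTA), sets the rescanning threshold to the
minimum training-site score, and scans both strands. Writes the models in
MEME minimal format, the consensus strings and all promoter hits under
results/promoters/.
"""

from pathlib import Path

import pandas as pd

from phagetu.coverage_steps import CoverageStep, extract_upstream_windows
from phagetu.genome_io import read_fasta
from phagetu.motif_model import (
    consensus_iupac,
    fit_early_model,
    fit_late_pwm,
    genome_background,
    scan_genome,
    write_meme,
)

BASE = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    genome = read_fasta(BASE / "data" / "genome.fasta")
    bg = genome_background(genome)
    steps = pd.read_csv(BASE / "steps" / "steps.tsv", sep="\t")
    ups = steps[steps.direction == "up"]

    hits = []
    models = {}
    out = BASE / "promoters"
    out.mkdir(parents=True, exist_ok=True)
    lines = []
    for timing in ("early", "late"):
        rows = ups[ups.timing == timing]
        step_objs = [
            CoverageStep(
                position=int(r.position), direction="up", strand=r.strand,
                fold=float(r.fold), high_side_depth=float(r.high_side_depth),
            )
            for r in rows.itertuples()
        ]
        windows = [
            w.sequence
            for w in extract_upstream_windows(genome, step_objs, 100)
            if not w.truncated
        ]
        if len(windows) < 2:
            lines.append(f"{timing}: only {len(windows)} windows, no model fit")
            continue
        if timing == "early":
            model = fit_early_model(windows, seed=0, background=bg)
            models["early_minus35"] = model.pwm_35
            models["early_ext_minus10"] = model.pwm_10ext
            lines.append(
                f"early model from {len(windows)} windows: "
                f"-35 {consensus_iupac(model.pwm_35)}, "
                f"ext/-10 {consensus_iupac(model.pwm_10ext)}, "
                f"threshold {model.threshold:.2f} bits"
            )
        else:
            model, sites = fit_late_pwm(windows, seed=1, background=bg)
            models["late_minus10"] = model
            lines.append(
                f"late core from {len(windows)} windows: "
                f"{consensus_iupac(model)}, threshold {model.threshold:.2f} bits"
            )
        for h in scan_genome(model, genome, promoter_class=timing):
            hits.append(
                {
                    "class": timing, "tss": h.tss, "strand": h.strand,
                    "score": round(h.score, 2), "spacer": h.spacer,
                }
            )

    write_meme(models, out / "promoter_models.meme", bg)
    pd.DataFrame(hits).sort_values("tss").to_csv(
        out / "pwm_hits.tsv", sep="\t", index=False
    )
    for line in lines:
        print(line)
    print(f"{len(hits)} PWM hits across both strands; files under {out}")
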