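#!/usr/bin/env python
"""Assemble the transcriptional landscape and score it against the truth.

Runs the full pipeline (steps -> promoter models -> terminators -> TU
assembly) on the files from 01 and compares the result with the planted
architecture: promoter and terminator recovery within 5 bp, the ORF-
partition Jaccard of the assembled units, and the per-unit temporal
classes. Writes the landscape GFF3, the TU table and a recovery summary
under results/landscape/.
"""

import json
from pathlib import Path

import pandas as pd

from phagetu.evaluate import match_positions
from phagetu.genome_io import read_bedgraph, read_fasta, read_gff, write_gff
from phagetu.pipeline import run_landscape
from phagetu.tu_assembly import tus_to_gff

BASE = Path(__file__).resolve().parent.parent / "results"
TIMEPOINTS = ("t5", "t15", "t30")

if __name__ == "__main__":
    data = BASE / "data"
    genome = read_fasta(data / "genome.fasta")
    orfs = read_gff(data / "orfs.gff3")
    tracks = [
        read_bedgraph(
            data / f"coverage_{tp}_{tag}.bedgraph", genome.length, strand, tp
        )
        for tp in TIMEPOINTS
        for strand, tag in (("+", "plus"), ("-", "minus"))
    ]
    result = run_landscape(genome, orfs, tracks)

    out = BASE / "landscape"
    out.mkdir(parents=True, exist_ok=True)
    write_gff(tus_to_gff(result.assembly, genome.id), out / "landscape.gff3")
    pd.DataFrame(result.summary["per_tu"]).to_csv(
        out / "tus.tsv", sep="\t", index=False
    )

    truth_prom = pd.read_csv(data / "truth_promoters.tsv", sep="\t")
    truth_term = pd.read_csv(data / "truth_terminators.tsv", sep="\t")
    truth_tus = pd.read_csv(data / "truth_tus.tsv", sep="\t")

    prom = match_positions(
        list(zip(truth_prom.strand, truth_prom.tss)),
        [(c.strand, c.tss) for c in result.active_promoters],
    )
    term = match_positions(
        list(zip(truth_term.strand, truth_term.position)),
        [(t.strand, t.position) for t in result.terminators],
    )
    pred_sets = [
        (set(o.id for o in tu.orfs), tu.tu_class) for tu in result.assembly.tus
    ]
    jaccards, class_ok = [], 0
    coding = truth_tus[~truth_tus.ncrna]
    for _, row in coding.iterrows():
        t = set(str(row["orfs"]).split(","))
        best_j, best_cls = 0.0, None
        for p, cls in pred_sets:
            if t & p:
                j = len(t & p) / len(t | p)
                if j > best_j:
                    best_j, best_cls = j, cls
        jaccards.append(best_j)
        class_ok += int(best_cls == row["class"])
    summary = {
        "n_tus_assembled": result.summary["n_tus"],
        "class_counts": result.summary["class_counts"],
        "strand_percent": result.summary["strand_percent"],
        "promoter_sensitivity": round(prom.sensitivity, 3),
        "promoter_precision": round(prom.precision, 3),
        "terminator_sensitivity": round(term.sensitivity, 3),
        "terminator_precision": round(term.precision, 3),
        "tu_orf_jaccard": round(sum(jaccards) / len(jaccards), 3),
        "tu_class_accuracy": round(class_ok / len(coding), 3),
    }
    (out / "recovery.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(json.dumps(summary, indent=2))
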