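#!/usr/bin/env python
"""Generate the reference synthetic phage transcriptome experiment.

A 50 kb AT-rich genome carries 12 planted transcription units (early/late/
dual in roughly a 26:4:5 ratio) plus two highly expressed non-coding
regions; strand-specific coverage is simulated at 5, 15 and 30 min with NB
noise and 5'-degradation of early transcripts, and an ORF x (timepoint,
replicate) count table is drawn on top. Everything downstream
(analysis/02 .. 06) consumes the files written here; the planted truth
tables let the final script score recovery.
"""

from pathlib import Path

from click.testing import CliRunner

from phagetu.cli import main

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 11

if __name__ == "__main__":
    runner = CliRunner()
    res = runner.invoke(
        main,
        [
            "synth", "--n-tus", "12", "--genome-length", "50000",
            "--seed", str(SEED), "--out-dir", str(OUT),
        ],
        catch_exceptions=False,
    )
    if res.exit_code != 0:
        raise SystemExit(res.output)
    print(res.output.strip())
    print(f"truth tables and coverage written under {OUT}")
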