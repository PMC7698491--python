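# Methods

This note documents the models, the defaults and the design choices behind
`phagetu`, and states explicitly what the synthetic experiments do and do
not show about real data.

## Coordinate conventions

All internal coordinates are 0-based half-open on the plus-strand axis;
GFF3 converts at the I/O boundary, bedGraph is native. A promoter is
located by its TSS base; the coverage boundary it creates is the TSS itself
on the plus strand and TSS+1 on the minus strand (half-open bookkeeping). A
terminator is located by its down-step boundary, the first coordinate past
the polyT tract in transcription direction. Coverage is real-valued so that
normalised tracks survive a round-trip.

## Step detection

Mean depths over `[p-w, p)` and `[p, p+w)` give a per-boundary fold
`(hi+ε)/(lo+ε)`. Defaults: `w` = 50 bp, `min_fold` = 3, `min_high_depth` =
10 reads/base, `ε` = 1, `merge_distance` = 25 bp. A candidate is reported
only where its fold is the maximum over ±`merge_distance` for its direction
(windowed non-maximum suppression). This formalises what is otherwise a
manual, genome-browser judgement of "sharp"; the thresholds are ours and
exposed in `StepParams`. Two consequences are worth knowing:

* two genuine steps closer than `merge_distance` collapse to the sharper
  one — promoters stacked within ~25 bp are not resolvable;
* the slope ends of decaying readthrough coverage can pass the fold test
  and appear as down-steps. They carry no hairpin and are discarded by the
  terminator caller, which is the intended division of labour.

Timing: steps present at either of the first two timepoints are *early*
(the two early samples are pooled; they show no systematic differences in
either the motivating data or the simulator), steps present only at the
last timepoint are *late*. A strong step seen only at 30 min at a position
that already carries a weak (fold ≥ 1.5) step at 5/15 min is demoted to
early: 5′-degradation steepens early steps late in infection, and without
the demotion those positions masquerade as late promoters.

## Promoter models

**Early**: two boxes. The 11-column extended −10 block (`TRTGN`+`TATANT`)
and a −35 hexamer (`TTGACW`) at spacer 16/17/18 with penalties 1.5/0/1.5
bits (17 bp dominates; 16/18 are rare variants). The TSS is 6 bp downstream
of the −10 box 3′ end. Total score = score(−35) + score(ext/−10) −
spacer penalty, maximised over spacers. **Late**: a single 10-column core
(`TGTTATATTA`); its weaker `TWN`/`TT` flanks are descriptive only and are
not scored, as is the early up-element, whose consensus is too ambiguous to
score profitably.

PWMs use Laplace pseudocount 1.0 and the genome mononucleotide composition
as background (both exposed). The rescanning threshold is the minimum
training-site score, which makes "a scan retrieves 100% of its training
set" an exact property rather than a calibration; hits at a genome edge are
reported even when the projected TSS falls outside the sequence.

**Model fitting is TSS-anchored.** Upstream windows end immediately before
the TSS, so a genuine box sits at a near-constant offset from the window
end. The fit scans that offset for the maximum total information content
(for the early model, block IC plus the best −35 partner IC over the three
spacers) and then lets each site jitter ±3 bp to absorb step-position
noise. We originally fit the block with free ZOOPS EM; on a minority of
simulated datasets EM phase-shifted by 1–2 columns or locked onto the −35
box, which inflates the rescan hit list by orders of magnitude once the
retrieve-all threshold drops. The anchored scan is deterministic and cannot
phase-shift. Free ZOOPS EM (20 restarts, convergence at log-likelihood gain
< 1e-6) remains available as `discover_motif` for windows without a TSS
anchor and is what the consensus-recovery checks exercise on random-offset
sites. With fewer than four late windows the IC scan is statistically
meaningless and the canonical anchor (core 3′ end 6 bp upstream of the TSS)
is used directly.

**Activity.** Each coverage step is one promoter: a strong step adopts the
best-scoring PWM hit within 25 bp (the step's timing decides the class), or
becomes a step-only call if no model exists or no hit is near. A weak step
(fold ≥ 1.5, high side ≥ 5×) may rescue one PWM hit without overriding the
hit's class. PWM hits with no coverage support at all are retained in the
output, flagged inactive, and excluded from TU assembly — they correspond
to sequence-plausible promoters that do not shape the landscape. Recovery
metrics score active calls only.

## Terminators

Exhaustive stem-loop enumeration replaces thermodynamic folding: the
defining criterion is structural (GC-rich hairpin + polyT), not an energy
threshold, and enumeration is exact, dependency-free and testable against a
brute-force oracle. Defaults: stem 5–15 bp, loop 3–9 nt, ≤1 mismatch, G·T
counted as a weak pair (the structure acts at RNA level; toggleable), score
`2·GC + 1·weak − 3·mismatch − 0.1·loop` ≥ 8, then a run of ≥4 T's (one
interruption allowed) starting ≤3 nt after the stem. Readthrough =
downstream/upstream mean depth over 100 bp flanks, clamped to [0, 1];
undefined (None) when upstream depth < 5, so a dead terminator is never
assigned a number.

## Expression

TMM follows the published algorithm exactly — M/A on library-scaled counts,
zeros removed, 30%/5% double trim with average ranks, 1/variance weights,
factors rescaled to geometric mean 1, reference chosen by the
75th-percentile rule — and one test drives the same matrix through edgeR's
`calcNormFactors` via Rscript, agreeing to ~1e-10. GeTMM computes TMM on
reads-per-kilobase so length is corrected before composition. The
differential test conditions on per-gene group totals after equalising
effective library sizes: under a common method-of-moments NB dispersion the
group sums are NB, and the two-sided exact p-value sums all conditional
outcomes no likelier than the observed one. This is deliberately simpler
than a full empirical-Bayes pipeline — the load-bearing parts here are the
normalisation and the FDR ≤ 0.01 flag, and the exact test is fast enough to
calibrate on 500 null simulations (empirical false-positive rate ≈ 0.002 at
nominal 0.01; power 1.0 for four-fold induction at n = 3, dispersion 0.05).
Temporal classes: *late-expressed* = significantly up at 30 min starting
below the 25th-percentile floor of first-timepoint expression;
*early-expressed* = at least 5 GeTMM units at 5 min; else *flat*. The rule
order matters: degradation-driven late increases of already-expressed genes
must not be called late.

## TU assembly

Per strand, 5′→3′: promoter opens (or joins) a unit; ORFs starting
downstream of the TSS join; a terminator with late-phase readthrough < 0.5
(configurable) closes after ≥1 ORF. Leaky terminators (readthrough ≥ 0.5)
are absorbed and transcription continues into the next gene block.
Promoters with no ORF before the next closing terminator are orphans and
form no unit (the two simulated non-coding regions surface this way); ORFs
upstream of every promoter are listed unassigned rather than forced into a
unit. Strands are treated fully independently, and unit spans are reported
TSS → terminator. The 5′-degradation signal is never used as assembly
evidence — positional promoter/terminator logic only.

## The synthetic generator

The generator is the package's instrument for making every stage falsifiable;
its defaults are fixed once and describe one concrete experiment:

| parameter | default | rationale |
| --- | --- | --- |
| genome | 50 kb, GC 0.33 | AT-rich myophage-like composition at desk scale |
| TUs | 12 coding + 2 non-coding, class mix 26:4:5 /35 | early/late/dual proportions of the motivating system |
| ORFs per TU | 1–6, 200–1200 bp, 15–40 bp gaps | tightly packed co-oriented blocks |
| early plateau | U(80, 350) reads/base | moderate host-RNAP-driven expression |
| late plateau | U(400, 1000) | late structural units dominate late-phase reads |
| internal promoters | upstream sum × U(0.8, 2.0) (early), × U(2.5, 5.0) (late) | an internal start is only *observable* if it changes coverage; the reference system's internal and dual-TU late promoters were, by the nature of their discovery, step-visible |
| tandem dual promoters | 45–80 bp apart | beyond the detector's ±25 bp resolution (see limitation above) |
| spacer | 17 bp w.p. 0.9; 16/18 w.p. 0.05 each | dominant sigma-70 spacing with rare variants |
| site mutation rate | 0.02/position | near-consensus planted sites |
| terminators | stem 7–12, loop 3–8, GC 0.75–0.95, polyT 5–8, readthrough U(0, 0.3) | strong intrinsic terminators with partial readthrough; a 100 bp readthrough plateau then a linear taper to zero over 200 bp (an abrupt end would plant an artificial down-step) |
| coverage noise | per-base NB, dispersion 0.1 | overdispersed depth |
| degradation | 0.1/kb × (0, 0.5, 1) across timepoints, early contributions only | 5′-exonucleolytic depletion of aged transcripts; late transcripts at 30 min are fresh |
| counts | NB, dispersion 0.05, mean = depth × length / 100 | featureCounts-like endpoint at 100 bp read scale |

Absolute depths are not constrained by any published value and are exposed
as configuration. Late-promoter TT-extension letters are drawn at 0.75
fidelity so the flank is visibly less conserved than the core.

**What passing recovery does and does not show.** The simulator plants
near-consensus sites, independent per-base noise, rectangular plateaus and
a single contiguous replicon; real libraries have correlated coverage
(fragment length, mappability, rRNA depletion artefacts), promoters of
widely varying information content, overlapping antisense transcription
and manual-curation judgement calls. Recovery of planted architecture
demonstrates internal correctness of the inference chain — not that the
default thresholds are optimal for any particular real dataset. Promoters
closer than ~25 bp, late promoters whose contribution is small relative to
ongoing early transcription, and non-intrinsic (factor-dependent)
terminators are out of reach by design. The simulated non-coding regions
are constitutively early-driven, so their fold changes across timepoints
are modest; the generator does not emulate late-boosted non-coding
transcription.

## Numerical and degenerate-input choices

* ε = 1 pseudocount in step folds and readthrough ratios; readthrough
  undefined below 5× upstream depth.
* PWM pseudocount 1.0; pseudocount 0 allowed (log-odds −inf on unseen
  bases) for exactness checks.
* Hit merging: same-strand PWM hits within 5 bp collapse to the best score,
  ties leftmost; strands are never merged (palindromic sites appear twice).
* Step ties at equal fold keep the leftmost boundary.
* BH adjustment via statsmodels; an independent hand implementation is the
  test oracle.
* All randomness flows through explicit integer seeds; the EM and the
  anchored fits are deterministic given their inputs.

## Problem sizes

The test suite and the acceptance script run the full pipeline on the 50 kb
/ 12-TU experiment (about a second per run), 500 null datasets of 100 genes
and 200 power datasets of 51 genes for the differential-test calibration,
and brute-force oracle comparisons on instances of 80–200 genes, 120–150 nt
windows and 2–5 kb genomes. These sizes were chosen so that the whole
verification cycle completes in well under a minute while every check stays
statistically meaningful.
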