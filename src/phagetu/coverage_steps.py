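"""TSS/TTS candidate detection from sharp steps in stranded coverage.

A step at boundary ``p`` compares mean depth over ``[p-w, p)`` against
``[p, p+w)``; positions where the fold (high/low, pseudocount-stabilised)
exceeds a threshold and is a local maximum are reported, then merged within a
small distance. "Up" means the high side is downstream in transcription
direction: the right side on the plus strand, the left side on the minus
strand. Steps found at the first two timepoints are "early"; steps appearing
only at the last timepoint are "late" (a position already early stays early).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from scipy.ndimage import maximum_filter1d

from .genome_io import CoverageTrack, GenomeRecord, reverse_complement


@dataclass(frozen=True)
class StepParams:
    window: int = 50
    min_fold: float = 3.0
    min_high_depth: float = 10.0
    merge_distance: int = 25
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_fold <= 1:
            raise ValueError("min_fold must be > 1")


@dataclass(frozen=True)
class CoverageStep:
    """A candidate TSS (up) or TTS (down) boundary."""

    position: int
    direction: str  # "up" | "down"
    strand: str
    fold: float
    high_side_depth: float
    timepoint: str | None = None
    timing: str | None = None  # filled by classify_step_timing
    timepoints: frozenset = field(default_factory=frozenset)


def detect_steps(track: CoverageTrack, params: StepParams) -> list[CoverageStep]:
    """Find coverage steps in one track; returns steps sorted by position."""
    d = track.depth
    L = d.size
    w = params.window
    if 2 * w > L:
        raise ValueError(f"window {w} too long for genome of {L} bp")
    c = np.concatenate([[0.0], np.cumsum(d)])
    p = np.arange(w, L - w + 1)
    left = (c[p] - c[p - w]) / w
    right = (c[p + w] - c[p]) / w
    hi = np.maximum(left, right)
    lo = np.minimum(left, right)
    fold = (hi + params.epsilon) / (lo + params.epsilon)
    cand = (fold >= params.min_fold) & (hi >= params.min_high_depth)
    # a reported step must be the fold maximum over +-merge_distance, so
    # noise jitter on the shoulders of a strong step cannot spawn extra
    # calls and nearby candidates collapse onto the sharpest boundary
    m = params.merge_distance
    right_high = right > left
    accepted: list[int] = []
    for updir in (True, False):
        dir_fold = np.where(right_high == updir, fold, 1.0)
        maxf = maximum_filter1d(dir_fold, size=2 * m + 1, mode="nearest")
        idx = np.flatnonzero(cand & (right_high == updir) & (dir_fold >= maxf))
        # greedy suppression settles plateaus (ties keep the leftmost position)
        chosen: list[int] = []
        for i in sorted(idx, key=lambda i: (-fold[i], i)):
            if all(abs(i - j) > m for j in chosen):
                chosen.append(i)
        accepted.extend(chosen)

    steps: list[CoverageStep] = []
    for i in sorted(accepted):
        pos = int(p[i])
        up = right_high[i] if track.strand == "+" else not right_high[i]
        steps.append(
            CoverageStep(
                position=pos,
                direction="up" if up else "down",
                strand=track.strand,
                fold=float(fold[i]),
                high_side_depth=float(hi[i]),
                timepoint=track.timepoint,
            )
        )
    return steps


def classify_step_timing(
    steps_by_timepoint: Mapping[str, Iterable[CoverageStep]],
    merge_distance: int = 25,
    early_timepoints: tuple[str, ...] = ("t5", "t15"),
) -> list[CoverageStep]:
    """Match steps across timepoints and assign early/late timing.

    Positions within ``merge_distance`` (same strand and direction) are one
    step. A step seen at any of ``early_timepoints`` is early; one seen only
    at the last timepoint is late. The reported position/fold come from the
    max-fold member of the cluster.
    """
    flat: list[CoverageStep] = []
    for tp, steps in steps_by_timepoint.items():
        for s in steps:
            flat.append(s if s.timepoint == tp else replace(s, timepoint=tp))
    out: list[CoverageStep] = []
    for key in {(s.strand, s.direction) for s in flat}:
        group = sorted(
            (s for s in flat if (s.strand, s.direction) == key),
            key=lambda s: s.position,
        )
        cluster: list[CoverageStep] = []

        def flush(cluster: list[CoverageStep]) -> None:
            best = max(cluster, key=lambda x: (x.fold, -x.position))
            tps = frozenset(s.timepoint for s in cluster)
            timing = "early" if tps & set(early_timepoints) else "late"
            out.append(replace(best, timing=timing, timepoints=tps))

        for s in group:
            if cluster and s.position - cluster[-1].position >= merge_distance:
                flush(cluster)
                cluster = []
            cluster.append(s)
        if cluster:
            flush(cluster)
    return sorted(out, key=lambda s: s.position)


@dataclass(frozen=True)
class StepWindow:
    step: CoverageStep
    sequence: str
    truncated: bool


def extract_upstream_windows(
    genome: GenomeRecord,
    steps: Iterable[CoverageStep],
    length: int = 100,
) -> list[StepWindow]:
    """Transcription-oriented windows immediately upstream of up-steps.

    Plus strand: plus-strand bases ``[pos-length, pos)``; minus strand: the
    reverse complement of ``[pos, pos+length)``. Windows clipped at a genome
    edge are flagged truncated.
    """
    out = []
    for s in steps:
        if s.direction != "up":
            raise ValueError("extract_upstream_windows expects up-steps")
        if s.strand == "+":
            a, b = max(0, s.position - length), s.position
            seq = genome.sequence[a:b]
        else:
            a, b = s.position, min(genome.length, s.position + length)
            seq = reverse_complement(genome.sequence[a:b])
        out.append(StepWindow(step=s, sequence=seq, truncated=len(seq) < length))
    return out


def extract_downstep_windows(
    genome: GenomeRecord,
    steps: Iterable[CoverageStep],
    halfwidth: int = 50,
) -> list[StepWindow]:
    """Transcription-oriented windows centered on down-steps ([pos-hw, pos+hw),
    reverse-complemented on the minus strand)."""
    out = []
    for s in steps:
        if s.direction != "down":
            raise ValueError("extract_downstep_windows expects down-steps")
        a = max(0, s.position - halfwidth)
        b = min(genome.length, s.position + halfwidth)
        seq = genome.sequence[a:b]
        if s.strand == "-":
            seq = reverse_complement(seq)
        out.append(StepWindow(step=s, sequence=seq, truncated=(b - a) < 2 * halfwidth))
    return out


def steps_to_bed(steps: Iterable[CoverageStep], chrom: str = "genome") -> list[tuple]:
    """BED6 rows: name = up|down + timing class, score = fold*100 capped at 1000."""
    rows = []
    for s in steps:
        name = s.direction + ("_" + s.timing if s.timing else "")
        score = min(1000.0, s.fold * 100.0)
        rows.append((chrom, s.position, s.position + 1, name, score, s.strand))
    return rows
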