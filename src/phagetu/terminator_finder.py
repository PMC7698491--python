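"""Rho-independent terminator calling at coverage down-steps.

A terminator is a GC-rich stem-loop immediately followed by a polyT tract
(polyU in the transcript). Instead of thermodynamic folding, stems are found
by exhaustive enumeration of all (start, stem length, loop length) triples
with an additive pairing score:

    score = 2*(#GC pairs) + 1*(#AT or GU pairs) - 3*(#mismatches) - 0.1*loop

G.T pairs in the DNA text count as weak (G.U in RNA) when enabled. A call
additionally requires a run of >= ``min_t`` T's (one interruption allowed)
beginning within ``max_gap`` nt of the stem's 3' side. Readthrough is the
downstream/upstream mean-coverage ratio at the down-step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import CoverageTrack
from .coverage_steps import CoverageStep

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class TerminatorParams:
    min_stem: int = 5
    max_stem: int = 15
    loop_min: int = 3
    loop_max: int = 9
    max_mismatch: int = 1
    min_score: float = 8.0
    min_t: int = 4
    max_gap: int = 3
    allow_gu: bool = True


@dataclass(frozen=True)
class Hairpin:
    start: int  # offset of the 5' stem arm within the window
    stem_len: int
    loop_len: int
    n_gc: int
    n_weak: int  # AT + GU pairs
    n_mismatch: int
    score: float

    @property
    def end(self) -> int:
        """Offset just past the 3' stem arm."""
        return self.start + 2 * self.stem_len + self.loop_len

    @property
    def gc_fraction(self) -> float:
        return self.n_gc / self.stem_len


@dataclass
class TerminatorCall:
    position: int  # genomic down-step boundary
    strand: str
    hairpin: Hairpin
    polyt_len: int
    readthrough: dict[str, float | None] = field(default_factory=dict)

    @property
    def stem_len(self) -> int:
        return self.hairpin.stem_len

    @property
    def loop_len(self) -> int:
        return self.hairpin.loop_len

    @property
    def gc_fraction(self) -> float:
        return self.hairpin.gc_fraction

    @property
    def score(self) -> float:
        return self.hairpin.score


def _pair_kind(a: str, b: str, allow_gu: bool) -> str:
    """'gc', 'weak' or 'mm' for one stem pair (a 5' arm base vs its partner)."""
    if _COMP.get(a) == b:
        return "gc" if a in "GC" else "weak"
    if allow_gu and {a, b} == {"G", "T"}:
        return "weak"
    return "mm"


def find_hairpins(window_seq: str, params: TerminatorParams) -> list[Hairpin]:
    """Enumerate every stem-loop candidate in a window.

    All (start, stem, loop) triples with stem in [min_stem, max_stem] and
    loop in [loop_min, loop_max] are tested; arm1 must pair with the reversed
    arm2 allowing up to ``max_mismatch`` mismatches. Windows too short for
    any candidate yield an empty list.
    """
    seq = window_seq.upper()
    n = len(seq)
    out: list[Hairpin] = []
    for stem in range(params.min_stem, params.max_stem + 1):
        for loop in range(params.loop_min, params.loop_max + 1):
            total = 2 * stem + loop
            if total > n:
                continue
            for i in range(n - total + 1):
                n_gc = n_weak = n_mm = 0
                ok = True
                for k in range(stem):
                    a = seq[i + k]
                    b = seq[i + total - 1 - k]
                    if a not in _COMP or b not in _COMP:
                        ok = False
                        break
                    kind = _pair_kind(a, b, params.allow_gu)
                    if kind == "gc":
                        n_gc += 1
                    elif kind == "weak":
                        n_weak += 1
                    else:
                        n_mm += 1
                        if n_mm > params.max_mismatch:
                            ok = False
                            break
                if not ok:
                    continue
                score = 2.0 * n_gc + 1.0 * n_weak - 3.0 * n_mm - 0.1 * loop
                out.append(
                    Hairpin(
                        start=i, stem_len=stem, loop_len=loop,
                        n_gc=n_gc, n_weak=n_weak, n_mismatch=n_mm, score=score,
                    )
                )
    return out


def _polyt_run(seq: str, start: int, min_t: int) -> int | None:
    """Length (T count) of a polyT run starting at ``start``, allowing one
    internal non-T; None when fewer than ``min_t`` T's."""
    if start >= len(seq) or seq[start] != "T":
        return None
    n_t = 0
    skips = 0
    i = start
    while i < len(seq):
        if seq[i] == "T":
            n_t += 1
        elif skips == 0 and n_t and i + 1 < len(seq) and seq[i + 1] == "T":
            skips = 1
        else:
            break
        i += 1
    return n_t if n_t >= min_t else None


def call_terminator(
    window,
    params: TerminatorParams | None = None,
) -> TerminatorCall | None:
    """Call a terminator in a down-step window, or None.

    The best-scoring hairpin with score >= ``min_score`` AND a downstream
    polyT run starting within ``max_gap`` nt of its 3' side is required; a
    hairpin without polyT, or polyT without a hairpin, is not a terminator.
    ``window`` is a ``StepWindow`` from ``extract_downstep_windows``.
    """
    params = params or TerminatorParams()
    seq = window.sequence.upper()
    best: tuple[Hairpin, int] | None = None
    for hp in find_hairpins(seq, params):
        if hp.score < params.min_score:
            continue
        for gap in range(params.max_gap + 1):
            run = _polyt_run(seq, hp.end + gap, params.min_t)
            if run is not None:
                if best is None or hp.score > best[0].score:
                    best = (hp, run)
                break
    if best is None:
        return None
    hp, polyt = best
    step = window.step
    return TerminatorCall(
        position=step.position,
        strand=step.strand,
        hairpin=hp,
        polyt_len=polyt,
        readthrough={},
    )


def readthrough_fraction(
    track: CoverageTrack,
    position: int,
    strand: str,
    flank: int = 100,
    epsilon: float = 1.0,
    min_upstream: float = 5.0,
) -> float | None:
    """Downstream/upstream mean coverage around a terminator boundary.

    Up- and downstream follow transcription direction on ``strand``; the
    ratio is epsilon-stabilised and clamped to [0, 1]. When the upstream side
    carries less than ``min_upstream`` mean depth the fraction is undefined
    and None is returned.
    """
    d = track.depth
    a = max(0, position - flank)
    b = min(d.size, position + flank)
    left = d[a:position].mean() if position > a else 0.0
    right = d[position:b].mean() if b > position else 0.0
    up, down = (left, right) if strand == "+" else (right, left)
    if up < min_upstream:
        return None
    return float(min(1.0, max(0.0, (down + epsilon) / (up + epsilon))))


def annotate_readthrough(
    call: TerminatorCall,
    tracks_by_timepoint: dict[str, CoverageTrack],
    flank: int = 100,
) -> TerminatorCall:
    call.readthrough = {
        tp: readthrough_fraction(tr, call.position, call.strand, flank=flank)
        for tp, tr in tracks_by_timepoint.items()
    }
    return call


def closure_readthrough(call: TerminatorCall, late_timepoint: str) -> float | None:
    """Readthrough used for TU-closure decisions: the late-timepoint value,
    falling back to the largest defined value at any timepoint."""
    rt = call.readthrough.get(late_timepoint)
    if rt is not None:
        return rt
    defined = [v for v in call.readthrough.values() if v is not None]
    return max(defined) if defined else None
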