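"""End-to-end transcriptional-landscape inference.

From a genome, an ORF annotation and stranded per-timepoint coverage:

1. call coverage steps per strand and timepoint, and classify their timing
   (early = seen in the first two timepoints, late = last timepoint only);
2. extract 100 bp upstream windows of early/late up-steps, fit the early
   two-box model and the late core PWM, and rescan the whole genome at the
   retrieve-the-training-set threshold;
3. mark promoter calls as active when coverage supports them: a strong step
   nearby assigns its timing; a weak step (lower fold threshold) rescues a
   PWM hit without flipping its class; PWM hits without any coverage support
   are kept but flagged inactive and excluded from the landscape;
4. call intrinsic terminators in windows around down-steps and estimate
   per-timepoint readthrough;
5. assemble active promoters, terminators and ORFs into transcription units
   and classify each unit early/late/both.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .genome_io import CoverageTrack, GenomeRecord, OrfFeature
from .coverage_steps import (
    CoverageStep,
    StepParams,
    classify_step_timing,
    detect_steps,
    extract_downstep_windows,
    extract_upstream_windows,
)
from .motif_model import (
    EarlyPromoterModel,
    PromoterCall,
    PwmModel,
    fit_early_model,
    fit_late_pwm,
    genome_background,
    scan_genome,
)
from .terminator_finder import (
    TerminatorCall,
    TerminatorParams,
    annotate_readthrough,
)
from .tu_assembly import AssemblyResult, assemble_tus, landscape_report


@dataclass
class LandscapeConfig:
    step: StepParams = field(default_factory=StepParams)
    weak_min_fold: float = 1.5
    weak_min_high_depth: float = 5.0
    early_timepoints: tuple[str, ...] = ("t5", "t15")
    late_timepoint: str = "t30"
    window_length: int = 100
    down_halfwidth: int = 50
    min_model_windows: int = 2  # below this, promoters are step-only calls
    pseudocount: float = 1.0
    hit_merge_within: int = 5
    terminator: TerminatorParams = field(default_factory=TerminatorParams)
    readthrough_flank: int = 100
    closure_threshold: float = 0.5
    seed: int = 0


@dataclass
class LandscapeResult:
    steps: list[CoverageStep]  # timed strong steps, up and down
    weak_steps: list[CoverageStep]
    early_model: EarlyPromoterModel | None
    late_pwm: PwmModel | None
    promoters: list[PromoterCall]  # all calls, active and inactive
    terminators: list[TerminatorCall]
    assembly: AssemblyResult
    summary: dict

    @property
    def active_promoters(self) -> list[PromoterCall]:
        return [p for p in self.promoters if p.active]


def _steps_by_timepoint(
    tracks: list[CoverageTrack], params: StepParams
) -> dict[str, list[CoverageStep]]:
    out: dict[str, list[CoverageStep]] = {}
    for tr in tracks:
        out.setdefault(tr.timepoint, []).extend(detect_steps(tr, params))
    return out


def _match_step(
    steps: list[CoverageStep], strand: str, pos: int, within: int,
    direction: str = "up",
) -> CoverageStep | None:
    best = None
    for s in steps:
        if s.strand != strand or s.direction != direction:
            continue
        d = abs(s.position - pos)
        if d <= within and (best is None or d < best[0]):
            best = (d, s)
    return best[1] if best else None


def _step_tss(step: CoverageStep) -> int:
    """TSS base coordinate corresponding to an up-step boundary."""
    return step.position if step.strand == "+" else step.position - 1


def run_landscape(
    genome: GenomeRecord,
    orfs: list[OrfFeature],
    tracks: list[CoverageTrack],
    config: LandscapeConfig | None = None,
) -> LandscapeResult:
    config = config or LandscapeConfig()
    bg = genome_background(genome)

    strong_by_tp = _steps_by_timepoint(tracks, config.step)
    weak_params = replace(
        config.step,
        min_fold=config.weak_min_fold,
        min_high_depth=config.weak_min_high_depth,
    )
    weak_by_tp = _steps_by_timepoint(tracks, weak_params)
    timed = classify_step_timing(
        strong_by_tp, config.step.merge_distance, config.early_timepoints
    )
    weak_timed = classify_step_timing(
        weak_by_tp, config.step.merge_distance, config.early_timepoints
    )
    # A strong step seen only at the last timepoint but already weakly
    # present earlier is ongoing early transcription (5'-degradation steepens
    # early steps late in infection), not late activation: demote to early.
    demoted = []
    for s in timed:
        if s.timing == "late" and _match_step(
            [w for w in weak_timed if w.timing == "early" and w.direction == s.direction],
            s.strand, s.position, config.step.merge_distance,
            direction=s.direction,
        ):
            s = replace(s, timing="early")
        demoted.append(s)
    timed = demoted
    up_steps = [s for s in timed if s.direction == "up"]
    down_steps = [s for s in timed if s.direction == "down"]

    # --- promoter models ---------------------------------------------------
    early_steps = [s for s in up_steps if s.timing == "early"]
    late_steps = [s for s in up_steps if s.timing == "late"]
    early_windows = [
        w for w in extract_upstream_windows(genome, early_steps, config.window_length)
        if not w.truncated
    ]
    late_windows = [
        w for w in extract_upstream_windows(genome, late_steps, config.window_length)
        if not w.truncated
    ]
    early_model = None
    if len(early_windows) >= config.min_model_windows:
        early_model = fit_early_model(
            [w.sequence for w in early_windows],
            seed=config.seed,
            pseudocount=config.pseudocount,
            background=bg,
        )
    late_pwm = None
    if len(late_windows) >= config.min_model_windows:
        late_pwm, _ = fit_late_pwm(
            [w.sequence for w in late_windows],
            seed=config.seed + 1,
            pseudocount=config.pseudocount,
            background=bg,
        )

    # --- scan + activity ---------------------------------------------------
    calls: list[PromoterCall] = []
    if early_model is not None:
        calls.extend(
            scan_genome(early_model, genome, promoter_class="early",
                        merge_within=config.hit_merge_within)
        )
    if late_pwm is not None:
        calls.extend(
            scan_genome(late_pwm, genome, promoter_class="late",
                        merge_within=config.hit_merge_within)
        )

    # Activity is step-centric: each coverage step is one promoter. A strong
    # step takes the best-scoring PWM call near it (assigning its timing as
    # the class) or, lacking one, becomes a step-only call. A weak step may
    # rescue the best PWM call near it without flipping the call's class.
    within = config.step.merge_distance
    weak_up = [
        s for s in weak_timed
        if s.direction == "up"
        and _match_step(up_steps, s.strand, s.position, within) is None
    ]

    def call_step_pos(c: PromoterCall) -> int:
        return c.tss if c.strand == "+" else c.tss + 1

    def best_call_near(step: CoverageStep, pool: list[int]) -> int | None:
        best_i = None
        for i in pool:
            c = calls[i]
            if c.strand != step.strand:
                continue
            if abs(call_step_pos(c) - step.position) > within:
                continue
            if best_i is None or c.score > calls[best_i].score:
                best_i = i
        return best_i

    unclaimed = list(range(len(calls)))
    final: list[PromoterCall] = []
    for s in up_steps:
        i = best_call_near(s, unclaimed)
        if i is not None:
            unclaimed.remove(i)
            final.append(replace(
                calls[i], cls=s.timing, active=True, source="pwm",
                matched_step=s.position,
            ))
        else:
            final.append(
                PromoterCall(
                    cls=s.timing, tss=_step_tss(s), strand=s.strand,
                    score=float("nan"), source="step", active=True,
                    matched_step=s.position,
                )
            )
    for s in weak_up:
        i = best_call_near(s, unclaimed)
        if i is not None:
            unclaimed.remove(i)
            final.append(replace(
                calls[i], active=True, source="pwm_rescue",
                matched_step=s.position,
            ))
    final.extend(replace(calls[i], active=False) for i in unclaimed)

    # --- terminators -------------------------------------------------------
    tracks_by_tp: dict[str, dict[str, CoverageTrack]] = {}
    for tr in tracks:
        tracks_by_tp.setdefault(tr.strand, {})[tr.timepoint] = tr
    terminators: list[TerminatorCall] = []
    from .terminator_finder import call_terminator

    for w in extract_downstep_windows(genome, down_steps, config.down_halfwidth):
        call = call_terminator(w, config.terminator)
        if call is None:
            continue
        annotate_readthrough(
            call, tracks_by_tp[call.strand], flank=config.readthrough_flank
        )
        terminators.append(call)

    # --- assembly ----------------------------------------------------------
    active = [c for c in final if c.active]
    assembly = assemble_tus(
        orfs, active, terminators, genome.length,
        closure_threshold=config.closure_threshold,
        late_timepoint=config.late_timepoint,
    )
    summary = landscape_report(assembly)
    summary["n_promoters_active"] = len(active)
    summary["n_promoters_inactive"] = len(final) - len(active)
    summary["n_terminators"] = len(terminators)
    return LandscapeResult(
        steps=timed,
        weak_steps=weak_timed,
        early_model=early_model,
        late_pwm=late_pwm,
        promoters=sorted(final, key=lambda c: c.tss),
        terminators=sorted(terminators, key=lambda t: t.position),
        assembly=assembly,
        summary=summary,
    )
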