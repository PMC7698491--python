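"""Assembly of promoters, terminators and ORFs into transcription units.

Each strand is walked 5'->3' in transcription direction. The first promoter
outside an open TU opens one; co-oriented ORFs starting downstream of the
TSS extend it; promoters met inside an open TU become internal promoters;
the TU closes at the first terminator whose late-phase readthrough falls
below the closure threshold after at least one ORF. A terminator with high
readthrough is absorbed (transcription continues); a promoter immediately
after a closing terminator opens the next TU. Promoters with no ORF before
the next closing terminator are orphans and form no unit.

A TU's temporal class is set-based: early iff all its promoters are early,
late iff all late, both when it carries at least one of each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import OrfFeature
from .motif_model import PromoterCall
from .terminator_finder import TerminatorCall, closure_readthrough


@dataclass
class TranscriptionUnit:
    id: str
    strand: str
    orfs: list[OrfFeature]
    promoters: list[PromoterCall]
    terminators: list[TerminatorCall]
    tu_class: str = ""
    open_ended: bool = False

    @property
    def span(self) -> tuple[int, int]:
        """First-promoter TSS to last-terminator boundary, as a plus-strand
        interval."""
        coords = [p.tss for p in self.promoters]
        coords += [t.position for t in self.terminators]
        if self.orfs:
            coords += [o.start for o in self.orfs] + [o.end - 1 for o in self.orfs]
        return (min(coords), max(coords) + 1)


@dataclass
class AssemblyResult:
    tus: list[TranscriptionUnit]
    orphan_promoters: list[PromoterCall]
    unassigned_orfs: list[OrfFeature]


def classify_tu(tu: TranscriptionUnit) -> str:
    if not tu.promoters:
        raise ValueError(f"TU {tu.id} has no promoters")
    classes = {p.cls for p in tu.promoters}
    if classes == {"early"}:
        return "early"
    if classes == {"late"}:
        return "late"
    return "both"


def assemble_tus(
    orfs: list[OrfFeature],
    promoters: list[PromoterCall],
    terminators: list[TerminatorCall],
    genome_length: int,
    closure_threshold: float = 0.5,
    late_timepoint: str = "t30",
) -> AssemblyResult:
    """Walk each strand and build transcription units (see module docstring).

    ``promoters`` should be the coverage-supported (active) calls; pass
    inactive PWM-only calls at your own risk, they will open units.
    """
    tus: list[TranscriptionUnit] = []
    orphans: list[PromoterCall] = []
    unassigned: list[OrfFeature] = []
    counter = 0

    for strand in "+-":
        events: list[tuple[float, int, str, object]] = []
        for p in promoters:
            if p.strand == strand:
                events.append((p.tss, 1, "promoter", p))
        for o in orfs:
            if o.strand == strand:
                events.append((o.tx_start(), 2, "orf", o))
        for t in terminators:
            if t.strand == strand:
                events.append((t.position, 0, "terminator", t))
        sign = 1 if strand == "+" else -1
        events.sort(key=lambda e: (sign * e[0], e[1]))

        open_tu: TranscriptionUnit | None = None
        for _pos, _rank, kind, obj in events:
            if kind == "promoter":
                if open_tu is None:
                    counter += 1
                    open_tu = TranscriptionUnit(
                        id=f"TU{counter:02d}", strand=strand,
                        orfs=[], promoters=[obj], terminators=[],
                    )
                else:
                    open_tu.promoters.append(obj)
            elif kind == "orf":
                if open_tu is not None:
                    open_tu.orfs.append(obj)
                else:
                    unassigned.append(obj)
            else:  # terminator
                if open_tu is None:
                    continue
                rt = closure_readthrough(obj, late_timepoint)
                open_tu.terminators.append(obj)
                closes = rt is None or rt < closure_threshold
                if not closes:
                    continue  # transcription mostly continues: absorb
                if open_tu.orfs:
                    tus.append(open_tu)
                else:
                    orphans.extend(open_tu.promoters)
                    counter -= 1
                open_tu = None
        if open_tu is not None:
            if open_tu.orfs:
                open_tu.open_ended = True
                tus.append(open_tu)
            else:
                orphans.extend(open_tu.promoters)
                counter -= 1

    for tu in tus:
        tu.tu_class = classify_tu(tu)
    # stable ids in genomic order
    tus.sort(key=lambda t: t.span[0])
    for i, tu in enumerate(tus, start=1):
        tu.id = f"TU{i:02d}"
    return AssemblyResult(
        tus=tus, orphan_promoters=orphans, unassigned_orfs=unassigned
    )


def landscape_report(result: AssemblyResult) -> dict:
    """Summary counts for an assembled landscape.

    Percentages are reported as round(100*k/n, 1).
    """
    tus = result.tus
    n = len(tus)

    def pct(k: int) -> float:
        return round(100.0 * k / n, 1) if n else 0.0

    by_class = {c: sum(1 for t in tus if t.tu_class == c)
                for c in ("early", "late", "both")}
    n_plus = sum(1 for t in tus if t.strand == "+")
    per_tu = [
        {
            "tu": t.id,
            "strand": t.strand,
            "class": t.tu_class,
            "n_orfs": len(t.orfs),
            "n_promoters": len(t.promoters),
            "n_terminators": len(t.terminators),
            "span_start": t.span[0],
            "span_end": t.span[1],
            "orfs": ",".join(o.id for o in t.orfs),
        }
        for t in tus
    ]
    return {
        "n_tus": n,
        "n_orfs_in_tus": sum(len(t.orfs) for t in tus),
        "class_counts": by_class,
        "class_percent": {c: pct(k) for c, k in by_class.items()},
        "strand_counts": {"+": n_plus, "-": n - n_plus},
        "strand_percent": {"+": pct(n_plus), "-": pct(n - n_plus)},
        "n_orphan_promoters": len(result.orphan_promoters),
        "n_unassigned_orfs": len(result.unassigned_orfs),
        "per_tu": per_tu,
    }


def tus_to_gff(result: AssemblyResult, seqid: str = "genome") -> list[tuple]:
    """GFF3 rows for TUs (with Parent-linked ORFs), promoters and terminators."""
    rows: list[tuple] = []
    for tu in result.tus:
        a, b = tu.span
        rows.append(
            (seqid, "phagetu", "transcription_unit", a, b, None, tu.strand,
             {"ID": tu.id, "class": tu.tu_class, "n_orfs": len(tu.orfs)})
        )
        for o in tu.orfs:
            rows.append(
                (seqid, "phagetu", "CDS", o.start, o.end, None, o.strand,
                 {"ID": o.id, "Parent": tu.id})
            )
        for p in tu.promoters:
            rows.append(
                (seqid, "phagetu", "promoter", p.tss, p.tss + 1, p.score,
                 p.strand,
                 {"Parent": tu.id, "class": p.cls, "source_kind": p.source,
                  **({"spacer": p.spacer} if p.spacer is not None else {})})
            )
        for t in tu.terminators:
            rt = {k: (f"{v:.3f}" if v is not None else "NA")
                  for k, v in t.readthrough.items()}
            rows.append(
                (seqid, "phagetu", "terminator", t.position, t.position + 1,
                 t.score, t.strand,
                 {"Parent": tu.id, "stem": t.stem_len, "loop": t.loop_len,
                  "polyT": t.polyt_len,
                  "readthrough": "|".join(f"{k}:{v}" for k, v in rt.items())})
            )
    return rows
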