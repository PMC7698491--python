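"""Synthetic phage genomes with planted transcriptional architecture.

The generator emulates the data a lytic, AT-rich Staphylococcus myophage
produces in a three-timepoint strand-specific RNA-seq experiment:

* tightly packed co-oriented ORF blocks on both strands, organised into
  transcription units (TUs), each driven by 1-4 promoters and closed by an
  intrinsic terminator with partial readthrough;
* two promoter classes: "early" sigma-70-like promoters (-35 TTGACW,
  extended -10 TRTGN, -10 TATANT, ~17 bp spacer, TSS 6 bp after the -10 box)
  active at every timepoint, and "late" promoters (long -10 TGTTATATTA with
  TWN upstream and TT downstream extensions) active only at the last
  timepoint;
* Rho-independent terminators planted as an exactly pairing GC-rich stem-loop
  followed by a polyT tract, with a configurable fraction of transcription
  reading through;
* 5'-sided depletion of early-TU coverage at later timepoints (exponential in
  distance from the TU 3' end), so late-vs-early differences grow toward TU
  3' ends;
* two highly transcribed non-coding regions quantified as pseudo-genes.

Every element's true coordinates are recorded so downstream detection can be
scored by recovery. All randomness flows from explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome_io import CoverageTrack, GenomeRecord, OrfFeature, reverse_complement

# Consensus element patterns (IUPAC)
EARLY_M35 = "TTGACW"
EARLY_EXT = "TRTGN"
EARLY_M10 = "TATANT"
LATE_UP = "TWN"
LATE_CORE = "TGTTATATTA"
LATE_DOWN = "TT"
TSS_OFFSET = 6  # initiating nucleotide is 6 bp after the -10 box 3' end

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PromoterSpec:
    """A planted promoter: class, TSS coordinate and expression strength."""

    id: str
    cls: str  # "early" | "late"
    position: int  # TSS base, 0-based genomic
    strand: str
    strength: float  # expected plateau depth, reads/base
    tu_id: str
    spacer: int | None = None  # -35..-10 spacer, early promoters only
    cassette_start: int = 0  # genomic interval holding the planted elements
    cassette_end: int = 0

    @property
    def step_position(self) -> int:
        """Boundary coordinate of the coverage up-step this promoter creates."""
        return self.position if self.strand == "+" else self.position + 1

    def active_strength(self, t_index: int, n_timepoints: int) -> float:
        if self.cls == "late":
            return self.strength if t_index == n_timepoints - 1 else 0.0
        return self.strength


@dataclass(frozen=True)
class TerminatorSpec:
    """A planted intrinsic terminator; ``position`` is the coverage down-step
    boundary (the first base past the polyT tract in transcription direction)."""

    id: str
    position: int
    strand: str
    stem_len: int
    loop_len: int
    gc_frac: float
    polyt_len: int
    readthrough: float
    tu_id: str
    cassette_start: int = 0
    cassette_end: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.readthrough <= 1.0:
            raise ValueError("readthrough must lie in [0,1]")


@dataclass
class SimParams:
    """Study conditions for the simulator.

    ``dispersion`` is the per-base negative-binomial dispersion of coverage;
    ``degradation_rate`` the per-kb 5'-depletion coefficient for early-TU
    transcripts, scaled by ``degradation_schedule`` across timepoints.
    """

    genome_length: int = 50_000
    timepoints: tuple[str, ...] = ("t5", "t15", "t30")
    dispersion: float = 0.1
    degradation_rate: float = 0.1
    degradation_schedule: tuple[float, ...] = (0.0, 0.5, 1.0)
    count_dispersion: float = 0.05
    read_scale: float = 100.0
    gc_content: float = 0.33
    mutation_rate: float = 0.02
    readthrough_extension: int = 300
    readthrough_flat: int = 100  # plateau length before the linear taper
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion < 0 or self.count_dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if len(self.degradation_schedule) != len(self.timepoints):
            raise ValueError("degradation_schedule must match timepoints")


@dataclass
class PlannedTu:
    id: str
    strand: str
    cls: str  # "early" | "late" | "both"
    promoter_ids: list[str]
    terminator_ids: list[str]
    orf_ids: list[str]
    start: int  # genomic span of the TU block (incl. readthrough extension)
    end: int
    is_ncrna: bool = False
    region: tuple[int, int] | None = None  # transcribed ncRNA interval


@dataclass
class Architecture:
    genome_length: int
    tus: list[PlannedTu]
    promoters: dict[str, PromoterSpec]
    terminators: dict[str, TerminatorSpec]
    orfs: list[OrfFeature]

    @property
    def coding_tus(self) -> list[PlannedTu]:
        return [tu for tu in self.tus if not tu.is_ncrna]

    def promoter_truth(self) -> list[tuple[str, int]]:
        return [(p.strand, p.position) for p in self.promoters.values()]

    def terminator_truth(self) -> list[tuple[str, int]]:
        return [(t.strand, t.position) for t in self.terminators.values()]


def sample_iupac(pattern: str, rng: np.random.Generator) -> str:
    """Draw one sequence from an IUPAC pattern, uniform over each code's set."""
    return "".join(rng.choice(list(IUPAC[c])) for c in pattern)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i, b in enumerate(out):
        if rng.random() < rate:
            out[i] = rng.choice([x for x in "ACGT" if x != b])
    return "".join(out)


def _random_bases(n: int, rng: np.random.Generator, gc: float = 0.33) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(BASES, size=n, p=p))


def early_cassette(
    spacer: int, rng: np.random.Generator, mutation_rate: float = 0.0, gc: float = 0.33
) -> str:
    """Early promoter cassette ending at the TSS base.

    Layout: [-35 (6)] [spacer-5 random] [ext (5)] [-10 (6)] [5 random] [+1].
    The ext element occupies the 5 spacer positions adjacent to the -10 box,
    so the -35 to -10 distance equals ``spacer``.
    """
    m35 = _mutate(sample_iupac(EARLY_M35, rng), mutation_rate, rng)
    ext = _mutate(sample_iupac(EARLY_EXT, rng), mutation_rate, rng)
    m10 = _mutate(sample_iupac(EARLY_M10, rng), mutation_rate, rng)
    fill = _random_bases(spacer - 5, rng, gc)
    gap5 = _random_bases(5, rng, gc)
    init = "T" if rng.random() < 0.7 else rng.choice(BASES)
    return m35 + fill + ext + m10 + gap5 + init


def late_cassette(
    rng: np.random.Generator, mutation_rate: float = 0.0, gc: float = 0.33
) -> str:
    """Late promoter cassette ending at the TSS base: TWN + TGTTATATTA + TT,
    then 3 random bases, then the (G-enriched) initiating nucleotide.

    The flanking extensions are only partially conserved (the TT letters are
    drawn with 0.75 fidelity), as befits "a sort of extension element" next
    to a strongly conserved core."""
    up = sample_iupac(LATE_UP, rng)
    core = _mutate(sample_iupac(LATE_CORE, rng), mutation_rate, rng)
    tt = "".join(
        c if rng.random() < 0.75 else str(rng.choice(BASES)) for c in LATE_DOWN
    )
    gap3 = _random_bases(3, rng, gc)
    init = "G" if rng.random() < 0.7 else rng.choice(BASES)
    return up + core + tt + gap3 + init


def terminator_cassette(
    stem_len: int, loop_len: int, gc_frac: float, polyt_len: int,
    rng: np.random.Generator,
) -> str:
    """Exactly pairing GC-rich hairpin followed by a polyT tract."""
    arm1 = "".join(
        rng.choice(list("GC")) if rng.random() < gc_frac else rng.choice(list("AT"))
        for _ in range(stem_len)
    )
    loop = _random_bases(loop_len, rng, gc=0.3)
    return arm1 + loop + reverse_complement(arm1) + "T" * polyt_len


# ---------------------------------------------------------------------------
# architecture generation


def _class_counts(n_tus: int, fractions: tuple[float, float, float]) -> list[str]:
    """Deterministic largest-remainder allocation of TU classes."""
    raw = np.array(fractions, dtype=float) * n_tus
    counts = np.floor(raw).astype(int)
    order = np.argsort(-(raw - counts))
    for i in range(n_tus - counts.sum()):
        counts[order[i % 3]] += 1
    labels = ["early", "late", "both"]
    out: list[str] = []
    for lbl, c in zip(labels, counts):
        out.extend([lbl] * c)
    return out


@dataclass
class _LocalPromoter:
    cls: str
    strength: float
    spacer: int | None
    cassette_start: int
    cassette_len: int

    @property
    def tss(self) -> int:
        return self.cassette_start + self.cassette_len - 1


def _draw_spacer(rng: np.random.Generator) -> int:
    return int(rng.choice([17, 16, 18], p=[0.9, 0.05, 0.05]))


def _plan_tu(
    cls: str,
    rng: np.random.Generator,
    extension: int,
    is_ncrna: bool = False,
):
    """Lay one TU out in local transcription coordinates (0 = block start)."""
    promoters: list[_LocalPromoter] = []
    orfs: list[tuple[int, int]] = []
    cursor = 0

    def place_promoter(pcls: str, strength: float) -> None:
        nonlocal cursor
        if pcls == "early":
            sp = _draw_spacer(rng)
            clen = sp + 18
        else:
            sp, clen = None, 19
        promoters.append(_LocalPromoter(pcls, strength, sp, cursor, clen))
        cursor += clen

    if is_ncrna:
        place_promoter("early", float(rng.uniform(800, 1500)))
        region_len = int(rng.integers(400, 601))
        region = (cursor, cursor + region_len)
        cursor += region_len
        n_orfs = 0
        internal: dict[int, str] = {}
    else:
        region = None
        n_orfs = int(rng.integers(1, 7))
        primary_cls = "late" if cls == "late" else "early"
        strength = (
            float(rng.uniform(400, 1000))
            if primary_cls == "late"
            else float(rng.uniform(80, 350))
        )
        place_promoter(primary_cls, strength)
        # internal promoters: class-dependent plan
        internal = {}
        if cls == "early":
            n_prom = int(rng.choice([1, 2, 3], p=[0.6, 0.3, 0.1]))
            n_prom = min(n_prom, n_orfs)  # internals go before ORFs 2..n
            for k in sorted(rng.choice(np.arange(1, n_orfs), size=n_prom - 1,
                                       replace=False)) if n_prom > 1 else []:
                internal[int(k)] = "early"
        elif cls == "both":
            if n_orfs >= 2:
                internal[int(rng.integers(1, n_orfs))] = "late"
            else:
                # single-ORF dual TU: tandem late promoter upstream of the
                # ORF, spaced past the step detector's window resolution
                cursor += int(rng.integers(45, 81))
                upstream = sum(p.strength for p in promoters)
                place_promoter("late", upstream * float(rng.uniform(2.5, 5.0)))

    for k in range(n_orfs):
        if k in internal:
            cursor += int(rng.integers(10, 31))
            upstream = sum(p.strength for p in promoters)
            mult = (
                float(rng.uniform(2.5, 5.0))
                if internal[k] == "late"
                else float(rng.uniform(0.8, 2.0))
            )
            place_promoter(internal[k], upstream * mult)
        gap = int(rng.integers(20, 61)) if k == 0 else int(rng.integers(15, 41))
        cursor += gap
        olen = int(rng.integers(200, 1201))
        orfs.append((cursor, cursor + olen))
        cursor += olen

    cursor += int(rng.integers(10, 31))
    stem = int(rng.integers(7, 13))
    loop = int(rng.integers(3, 9))
    gcf = float(rng.uniform(0.75, 0.95))
    polyt = int(rng.integers(5, 9))
    term_len = 2 * stem + loop + polyt
    term_start = cursor
    cursor += term_len
    boundary = cursor
    tu_len = boundary + extension
    term = dict(
        cassette_start=term_start, stem_len=stem, loop_len=loop,
        gc_frac=gcf, polyt_len=polyt, boundary=boundary,
        readthrough=float(rng.uniform(0.0, 0.3)),
    )
    return promoters, orfs, term, tu_len, region


def generate_architecture(
    n_tus: int,
    params: SimParams,
    seed: int | None = None,
    class_fractions: tuple[float, float, float] = (26 / 35, 4 / 35, 5 / 35),
    n_ncrna: int = 2,
) -> Architecture:
    """Place ``n_tus`` coding TUs (plus ``n_ncrna`` non-coding regions) on a
    genome of ``params.genome_length``, both strands, non-overlapping.

    ``class_fractions`` are the (early-only, late-only, dual) TU proportions;
    the default reproduces a 26/4/5-of-35 mix in expectation. Raises
    ``ValueError`` when the genome is too short to hold the layout.
    """
    if n_tus < 1:
        raise ValueError("n_tus must be >= 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    classes = _class_counts(n_tus, class_fractions)
    rng.shuffle(classes)
    kinds = [("tu", c) for c in classes] + [("ncrna", "early")] * n_ncrna
    rng.shuffle(kinds)

    tus: list[PlannedTu] = []
    promoters: dict[str, PromoterSpec] = {}
    terminators: dict[str, TerminatorSpec] = {}
    orf_records: list[tuple[int, int, str, str]] = []  # start, end, strand, tu_id
    offset = int(rng.integers(150, 401))
    p_i = t_i = 0
    for i, (kind, cls) in enumerate(kinds):
        strand = str(rng.choice(["+", "-"]))
        local_proms, local_orfs, term, tu_len, region = _plan_tu(
            cls, rng, params.readthrough_extension, is_ncrna=(kind == "ncrna")
        )
        if offset + tu_len > params.genome_length:
            raise ValueError(
                f"genome of {params.genome_length} bp too short for "
                f"{n_tus} TUs (+{n_ncrna} non-coding regions)"
            )
        tu_id = f"TU{i + 1:02d}" if kind == "tu" else f"ncRNA{i + 1:02d}"

        def to_genomic_base(u: int) -> int:
            return offset + u if strand == "+" else offset + tu_len - 1 - u

        def to_genomic_interval(a: int, b: int) -> tuple[int, int]:
            if strand == "+":
                return offset + a, offset + b
            return offset + tu_len - b, offset + tu_len - a

        prom_ids = []
        for lp in local_proms:
            p_i += 1
            pid = f"p{p_i:03d}" if lp.cls == "early" else f"pL{p_i:03d}"
            cs, ce = to_genomic_interval(lp.cassette_start,
                                         lp.cassette_start + lp.cassette_len)
            promoters[pid] = PromoterSpec(
                id=pid, cls=lp.cls, position=to_genomic_base(lp.tss),
                strand=strand, strength=lp.strength, tu_id=tu_id,
                spacer=lp.spacer, cassette_start=cs, cassette_end=ce,
            )
            prom_ids.append(pid)

        t_i += 1
        tid = f"t{t_i:03d}"
        cs, ce = to_genomic_interval(term["cassette_start"], term["boundary"])
        boundary = (
            offset + term["boundary"] if strand == "+"
            else offset + tu_len - term["boundary"]
        )
        terminators[tid] = TerminatorSpec(
            id=tid, position=boundary, strand=strand,
            stem_len=term["stem_len"], loop_len=term["loop_len"],
            gc_frac=term["gc_frac"], polyt_len=term["polyt_len"],
            readthrough=term["readthrough"], tu_id=tu_id,
            cassette_start=cs, cassette_end=ce,
        )

        tu_orf_ids: list[str] = []
        for a, b in local_orfs:
            ga, gb = to_genomic_interval(a, b)
            orf_records.append((ga, gb, strand, tu_id))
        g_region = to_genomic_interval(*region) if region else None
        tus.append(
            PlannedTu(
                id=tu_id, strand=strand, cls=cls, promoter_ids=prom_ids,
                terminator_ids=[tid], orf_ids=tu_orf_ids,
                start=offset, end=offset + tu_len,
                is_ncrna=(kind == "ncrna"), region=g_region,
            )
        )
        offset += tu_len + int(rng.integers(150, 401))

    # name ORFs in genomic order and attach them to their TUs
    orf_records.sort(key=lambda r: r[0])
    orfs: list[OrfFeature] = []
    by_tu = {tu.id: tu for tu in tus}
    for j, (a, b, strand, tu_id) in enumerate(orf_records, start=1):
        oid = f"orf{j:05d}"
        orfs.append(OrfFeature(id=oid, start=a, end=b, strand=strand))
        by_tu[tu_id].orf_ids.append(oid)
    for tu in tus:
        if tu.strand == "-":
            tu.orf_ids = tu.orf_ids[::-1]  # 5'->3' in transcription direction

    return Architecture(
        genome_length=params.genome_length, tus=tus,
        promoters=promoters, terminators=terminators, orfs=orfs,
    )


# ---------------------------------------------------------------------------
# sequence planting


def plant_sequence(
    architecture: Architecture,
    params: SimParams,
    seed: int | None = None,
    genome_id: str = "synthetic_phage",
) -> GenomeRecord:
    """Write every planted element's literal sequence into a random background.

    With ``params.mutation_rate == 0`` each promoter box is an exact draw from
    its consensus pattern. Minus-strand cassettes appear reverse-complemented
    in the plus-strand text. Overlapping planted elements raise ``ValueError``.
    """
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    gc = params.gc_content
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    genome = rng.choice(BASES, size=architecture.genome_length, p=p)
    planted = np.zeros(architecture.genome_length, dtype=bool)

    def place(cassette: str, start: int, end: int, strand: str, what: str) -> None:
        if end - start != len(cassette):
            raise ValueError(f"cassette length mismatch for {what}")
        if planted[start:end].any():
            raise ValueError(f"overlapping planted elements at {what}")
        text = cassette if strand == "+" else reverse_complement(cassette)
        genome[start:end] = list(text)
        planted[start:end] = True

    for prom in architecture.promoters.values():
        if prom.cls == "early":
            cassette = early_cassette(prom.spacer, rng, params.mutation_rate, gc)
        else:
            cassette = late_cassette(rng, params.mutation_rate, gc)
        place(cassette, prom.cassette_start, prom.cassette_end, prom.strand, prom.id)

    for term in architecture.terminators.values():
        cassette = terminator_cassette(
            term.stem_len, term.loop_len, term.gc_frac, term.polyt_len, rng
        )
        place(cassette, term.cassette_start, term.cassette_end, term.strand, term.id)

    return GenomeRecord(id=genome_id, sequence="".join(genome))


# ---------------------------------------------------------------------------
# coverage and count simulation


def expected_depth(
    architecture: Architecture, params: SimParams
) -> dict[tuple[str, str], np.ndarray]:
    """Noiseless expected coverage for every (strand, timepoint).

    Over a TU, the expectation at each base is the sum of the strengths of its
    active promoters 5' of that base, times terminator readthrough past the
    terminator, times the 5'-degradation factor for early contributions at
    later timepoints.
    """
    L = architecture.genome_length
    n_t = len(params.timepoints)
    out = {
        (s, tp): np.zeros(L) for s in "+-" for tp in params.timepoints
    }
    for tu in architecture.tus:
        tu_len = tu.end - tu.start
        term = architecture.terminators[tu.terminator_ids[0]]
        if tu.strand == "+":
            boundary_local = term.position - tu.start
        else:
            boundary_local = tu.end - term.position
        ext_end = min(boundary_local + params.readthrough_extension, tu_len)
        u = np.arange(tu_len)
        for ti, tp in enumerate(params.timepoints):
            total = np.zeros(tu_len)
            for pid in tu.promoter_ids:
                prom = architecture.promoters[pid]
                s = prom.active_strength(ti, n_t)
                if s <= 0:
                    continue
                tss_local = (
                    prom.position - tu.start if tu.strand == "+"
                    else tu.end - 1 - prom.position
                )
                contrib = np.zeros(tu_len)
                contrib[tss_local:boundary_local] = s
                # readthrough: flat plateau, then a linear taper to zero (an
                # abrupt end would plant an artificial sharp down-step)
                flat_end = min(boundary_local + params.readthrough_flat, ext_end)
                contrib[boundary_local:flat_end] = s * term.readthrough
                n_taper = ext_end - flat_end
                if n_taper > 0:
                    contrib[flat_end:ext_end] = (
                        s * term.readthrough
                        * (1.0 - (np.arange(n_taper) + 1) / (n_taper + 1))
                    )
                if prom.cls == "early" and params.degradation_rate > 0:
                    rate = params.degradation_rate * params.degradation_schedule[ti]
                    if rate > 0:
                        dist_kb = np.clip(boundary_local - u, 0, None) / 1000.0
                        contrib *= np.exp(-rate * dist_kb)
                total += contrib
            track = out[(tu.strand, tp)]
            if tu.strand == "+":
                track[tu.start : tu.end] += total
            else:
                track[tu.start : tu.end] += total[::-1]
    return out


def simulate_coverage(
    architecture: Architecture,
    params: SimParams,
    seed: int | None = None,
) -> list[CoverageTrack]:
    """Draw per-base NB coverage around the noiseless expectation.

    ``params.dispersion == 0`` returns the expectation itself (the noiseless
    limit used by exactness tests).
    """
    mu = expected_depth(architecture, params)
    rng = np.random.default_rng(params.seed + 2 if seed is None else seed)
    tracks = []
    for strand in "+-":
        for tp in params.timepoints:
            m = mu[(strand, tp)]
            if params.dispersion <= 0:
                depth = m.copy()
            else:
                n = 1.0 / params.dispersion
                depth = np.zeros_like(m)
                pos = m > 0
                pvals = n / (n + m[pos])
                depth[pos] = rng.negative_binomial(n, pvals).astype(float)
            tracks.append(CoverageTrack(strand=strand, timepoint=tp, depth=depth))
    return tracks


def _gene_intervals(architecture: Architecture) -> list[tuple[str, int, int, str]]:
    genes = [(o.id, o.start, o.end, o.strand) for o in architecture.orfs]
    for tu in architecture.tus:
        if tu.is_ncrna and tu.region is not None:
            genes.append((tu.id, tu.region[0], tu.region[1], tu.strand))
    return genes


def simulate_counts(
    architecture: Architecture,
    params: SimParams,
    n_replicates: int = 3,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """NB read counts per gene (ORFs + non-coding regions) per timepoint and
    replicate; mean = expected depth x length / read_scale.

    Returns ``(counts, lengths)`` with MultiIndex columns (timepoint, rep).
    ``params.count_dispersion == 0`` gives rounded means exactly.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    mu = expected_depth(architecture, params)
    rng = np.random.default_rng(params.seed + 3 if seed is None else seed)
    genes = _gene_intervals(architecture)
    ids = [g[0] for g in genes]
    lengths = pd.Series([g[2] - g[1] for g in genes], index=ids, name="length")
    cols = pd.MultiIndex.from_product(
        [params.timepoints, [f"rep{r + 1}" for r in range(n_replicates)]],
        names=["timepoint", "replicate"],
    )
    counts = pd.DataFrame(0, index=ids, columns=cols, dtype=int)
    for tp in params.timepoints:
        for gid, a, b, strand in genes:
            depth_mean = mu[(strand, tp)][a:b].mean()
            mean_count = depth_mean * (b - a) / params.read_scale
            if params.count_dispersion <= 0:
                draws = np.full(n_replicates, round(mean_count), dtype=int)
            elif mean_count <= 0:
                draws = np.zeros(n_replicates, dtype=int)
            else:
                n = 1.0 / params.count_dispersion
                draws = rng.negative_binomial(n, n / (n + mean_count), n_replicates)
            for r, d in enumerate(draws):
                counts.loc[gid, (tp, f"rep{r + 1}")] = int(d)
    return counts, lengths


def make_dataset(
    n_tus: int = 12,
    params: SimParams | None = None,
    seed: int = 0,
    n_replicates: int = 3,
    n_ncrna: int = 2,
):
    """Convenience wrapper: architecture + genome + coverage + counts, all
    deterministically derived from one seed."""
    params = params if params is not None else SimParams()
    ss = np.random.SeedSequence(seed)
    s_arch, s_plant, s_cov, s_cnt = [int(s) for s in ss.generate_state(4) % (2**31)]
    arch = generate_architecture(n_tus, params, seed=s_arch, n_ncrna=n_ncrna)
    genome = plant_sequence(arch, params, seed=s_plant)
    tracks = simulate_coverage(arch, params, seed=s_cov)
    counts, lengths = simulate_counts(arch, params, n_replicates, seed=s_cnt)
    return arch, genome, tracks, counts, lengths


def noiseless(params: SimParams) -> SimParams:
    """A copy of ``params`` with all stochastic noise switched off."""
    return replace(params, dispersion=0.0, count_dispersion=0.0)
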