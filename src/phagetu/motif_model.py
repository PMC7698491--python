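"""Promoter motif discovery, PWM scoring and genome rescanning.

PWMs are log-odds (base 2) against a background mononucleotide composition,
with Laplace-style pseudocounts. The rescanning threshold follows the
retrieve-the-training-set rule: the minimum PWM score over the sites the
matrix was built from, so a scan at that threshold recovers every training
site by construction.

Early promoters are modelled as two boxes — a -35 hexamer and an 11-column
extended-10 block (ext TRTGN + -10 TATANT) — joined by a 16-18 bp spacer with
per-spacer penalties; the TSS sits 6 bp after the -10 box 3' end. Late
promoters use a single 10-column core (TGTTATATTA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import GenomeRecord, reverse_complement

BASE_ORDER = "ACGT"
_ENCODE = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate(BASE_ORDER):
    _ENCODE[ord(_b)] = _i

PAIR_IUPAC = {
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
}

TSS_OFFSET = 6  # TSS is 6 bp downstream of the -10 box 3' end


def encode(seq: str) -> np.ndarray:
    """Map ACGT to 0..3; N (or any other base) becomes -1."""
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class PwmModel:
    """Count-based PWM with pseudocount smoothing and log-odds scoring."""

    counts: np.ndarray  # (4, width)
    pseudocount: float = 1.0
    background: np.ndarray | None = None
    threshold: float | None = None
    em_iterations: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must have shape (4, width)")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def probs(self) -> np.ndarray:
        col = self.counts.sum(axis=0)
        return (self.counts + self.pseudocount) / (col + 4 * self.pseudocount)

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.probs / self.background[:, None])

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits (uniform-background form)."""
        p = self.probs
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(p > 0, p * np.log2(p), 0.0).sum(axis=0)
        return 2.0 + h

    def score(self, seq: str) -> float:
        if len(seq) != self.width:
            raise ValueError(f"site length {len(seq)} != PWM width {self.width}")
        enc = encode(seq)
        if np.any(enc < 0):
            return float("-inf")
        return float(self.log_odds[enc, np.arange(self.width)].sum())

    def score_all(self, enc: np.ndarray) -> np.ndarray:
        """Score every start position of an encoded sequence; positions whose
        window contains a non-ACGT base score -inf."""
        w = self.width
        if enc.size < w:
            return np.empty(0)
        win = np.lib.stride_tricks.sliding_window_view(enc, w)
        valid = (win >= 0).all(axis=1)
        scores = np.full(win.shape[0], -np.inf)
        lo = self.log_odds
        safe = np.where(win >= 0, win, 0)
        scores_all = lo[safe, np.arange(w)].sum(axis=1)
        scores[valid] = scores_all[valid]
        return scores


def build_pwm(
    sites: list[str],
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> PwmModel:
    """Build a PWM from aligned equal-length sites."""
    if not sites:
        raise ValueError("need at least one site")
    w = len(sites[0])
    if any(len(s) != w for s in sites):
        raise ValueError("sites must have equal lengths")
    counts = np.zeros((4, w))
    for s in sites:
        enc = encode(s.upper())
        if np.any(enc < 0):
            raise ValueError(f"site contains non-ACGT base: {s}")
        counts[enc, np.arange(w)] += 1
    return PwmModel(counts=counts, pseudocount=pseudocount, background=background)


def training_threshold(pwm: PwmModel, sites: list[str]) -> float:
    """Minimum PWM score over the training sites (the retrieve-all rule)."""
    if not sites:
        raise ValueError("empty training set")
    return min(pwm.score(s) for s in sites)


def genome_background(genome: GenomeRecord) -> np.ndarray:
    enc = encode(genome.sequence)
    counts = np.bincount(enc[enc >= 0], minlength=4).astype(float)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# ZOOPS EM motif discovery


def discover_motif(
    windows: list[str],
    width: int,
    n_restarts: int = 20,
    seed: int = 0,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> PwmModel:
    """ZOOPS (zero-or-one-occurrence-per-sequence) EM motif discovery.

    Runs ``n_restarts`` random initialisations and keeps the highest
    log-likelihood model; deterministic given ``seed``. Requires at least 5
    windows and ``width`` no longer than the shortest window.
    """
    if len(windows) < 5:
        raise ValueError("discover_motif requires >= 5 windows")
    if width > min(len(w) for w in windows):
        raise ValueError("width exceeds the shortest window")
    encs = [encode(w.upper()) for w in windows]
    if background is None:
        allc = np.concatenate(encs)
        bc = np.bincount(allc[allc >= 0], minlength=4).astype(float)
        background = bc / bc.sum() if bc.sum() else np.full(4, 0.25)
    rng = np.random.default_rng(seed)

    # precompute per-window site matrices (n_pos, width)
    wins = []
    for enc in encs:
        view = np.lib.stride_tricks.sliding_window_view(enc, width)
        wins.append(np.where(view >= 0, view, rng.integers(0, 4, view.shape)))

    best_ll, best = -np.inf, None
    for _ in range(n_restarts):
        # initialise from one random site, heavily weighted
        i = rng.integers(len(wins))
        j = rng.integers(wins[i].shape[0])
        probs = np.full((4, width), 0.1)
        probs[wins[i][j], np.arange(width)] = 0.7
        gamma = 0.7
        prev_ll = -np.inf
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            log_ratio = np.log(probs / background[:, None])
            ll = 0.0
            soft = np.zeros((4, width))
            z_sum = 0.0
            for win in wins:
                m = win.shape[0]
                r = log_ratio[win, np.arange(width)].sum(axis=1)
                r = np.exp(np.clip(r, -700, 700))
                site_mass = gamma / m * r
                denom = (1.0 - gamma) + site_mass.sum()
                z = site_mass / denom
                ll += np.log(denom)
                # accumulate soft counts
                for b in range(4):
                    soft[b] += np.add.reduce(z[:, None] * (win == b), axis=0)
                z_sum += z.sum()
            gamma = min(max(z_sum / len(wins), 0.02), 0.98)
            probs = (soft + 0.25) / (soft.sum(axis=0) + 1.0)
            if abs(ll - prev_ll) < tol:
                break
            prev_ll = ll
        if ll > best_ll:
            best_ll = ll
            best = (soft, n_iter)

    soft_counts, iters = best
    model = PwmModel(
        counts=soft_counts,
        pseudocount=pseudocount,
        background=background,
        em_iterations=iters,
    )
    return model


def align_sites(model: PwmModel, windows: list[str]) -> list[str]:
    """Best-scoring site of ``model``'s width in each window (MAP alignment)."""
    sites = []
    for w in windows:
        enc = encode(w.upper())
        scores = model.score_all(enc)
        j = int(np.argmax(scores))
        sites.append(w[j : j + model.width].upper())
    return sites


def consensus_iupac(
    pwm: PwmModel, major_threshold: float = 0.5, pair_threshold: float = 0.75
) -> str:
    """IUPAC consensus: a single base where one dominates (prob >= major and
    >= 2x the runner-up), a two-base code where the top two cover
    ``pair_threshold``, else N."""
    out = []
    for col in pwm.probs.T:
        order = np.argsort(col)[::-1]
        top, second = col[order[0]], col[order[1]]
        if top >= major_threshold and top >= 2 * second:
            out.append(BASE_ORDER[order[0]])
        elif top + second >= pair_threshold:
            pair = frozenset(BASE_ORDER[order[0]] + BASE_ORDER[order[1]])
            out.append(PAIR_IUPAC[pair])
        else:
            out.append("N")
    return "".join(out)


# ---------------------------------------------------------------------------
# promoter models and genome scanning


@dataclass
class EarlyPromoterModel:
    """Two-box sigma-70-style early promoter model.

    Total score at an extended-10 block position is
    ``score_10ext + max_spacer(score_35(spacer) - penalty(spacer))``.
    """

    pwm_35: PwmModel
    pwm_10ext: PwmModel
    spacer_penalties: dict[int, float] = field(
        default_factory=lambda: {16: 1.5, 17: 0.0, 18: 1.5}
    )
    threshold: float | None = None
    training_sites: list[tuple[str, str, int]] = field(default_factory=list)

    def score_at(self, enc: np.ndarray, b: int) -> tuple[float, int] | None:
        """Score the promoter whose ext-10 block starts at ``b``; returns
        (score, spacer) or None if the -35 box would fall off the sequence."""
        w10 = self.pwm_10ext.width
        if b + w10 > enc.size:
            return None
        site10 = enc[b : b + w10]
        if np.any(site10 < 0):
            return None
        s10 = float(self.pwm_10ext.log_odds[site10, np.arange(w10)].sum())
        best = None
        for sp, pen in self.spacer_penalties.items():
            a = b - sp - 1
            if a < 0:
                continue
            site35 = enc[a : a + 6]
            if np.any(site35 < 0):
                continue
            s35 = float(self.pwm_35.log_odds[site35, np.arange(6)].sum())
            total = s10 + s35 - pen
            if best is None or total > best[0]:
                best = (total, sp)
        return best

    def score_site(self, site35: str, site10ext: str, spacer: int) -> float:
        return (
            self.pwm_35.score(site35)
            + self.pwm_10ext.score(site10ext)
            - self.spacer_penalties[spacer]
        )


@dataclass
class PromoterCall:
    cls: str  # "early" | "late"
    tss: int  # genomic coordinate of the initiating base
    strand: str
    score: float
    source: str = "pwm"  # "pwm" | "pwm_rescue" | "step"
    spacer: int | None = None
    box10: tuple[int, int] | None = None  # genomic interval of the -10 box/core
    box35: tuple[int, int] | None = None
    active: bool | None = None
    matched_step: int | None = None


def _merge_hits(hits: list[PromoterCall], within: int = 5) -> list[PromoterCall]:
    """Collapse same-strand hits with TSS within ``within`` bp, keeping the
    best score (tie: leftmost). Strands are never merged together."""
    out: list[PromoterCall] = []
    for strand in "+-":
        group = sorted(
            (h for h in hits if h.strand == strand), key=lambda h: h.tss
        )
        cluster: list[PromoterCall] = []
        for h in group:
            if cluster and h.tss - cluster[-1].tss > within:
                out.append(max(cluster, key=lambda x: (x.score, -x.tss)))
                cluster = []
            cluster.append(h)
        if cluster:
            out.append(max(cluster, key=lambda x: (x.score, -x.tss)))
    return sorted(out, key=lambda h: h.tss)


def scan_genome(
    model: PwmModel | EarlyPromoterModel,
    genome: GenomeRecord,
    threshold: float | None = None,
    promoter_class: str | None = None,
    merge_within: int = 5,
) -> list[PromoterCall]:
    """Scan both strands and report every position scoring >= threshold.

    For a plain ``PwmModel`` the matrix is taken to be the -10 box/core whose
    3' end sits 6 bp upstream of the TSS. For an ``EarlyPromoterModel`` the
    spacer maximisation is part of the score. Same-strand hits within
    ``merge_within`` bp of each other collapse to the best one; opposite
    strands are reported independently.
    """
    if threshold is None:
        threshold = model.threshold
    if threshold is None:
        raise ValueError("no threshold given and the model carries none")
    L = genome.length
    seqs = {"+": genome.sequence, "-": reverse_complement(genome.sequence)}
    hits: list[PromoterCall] = []

    def to_plus(pos_local: int, strand: str) -> int:
        return pos_local if strand == "+" else L - 1 - pos_local

    for strand, seq in seqs.items():
        enc = encode(seq)
        if isinstance(model, EarlyPromoterModel):
            w10 = model.pwm_10ext.width
            s10 = model.pwm_10ext.score_all(enc)
            s35 = model.pwm_35.score_all(enc)
            best_total = np.full(s10.shape, -np.inf)
            best_sp = np.zeros(s10.shape, dtype=int)
            for sp, pen in model.spacer_penalties.items():
                shift = sp + 1  # -35 box starts at b - sp - 1
                tot = np.full(s10.shape, -np.inf)
                tot[shift:] = s10[shift:] + s35[: s10.size - shift] - pen
                better = tot > best_total
                best_total[better] = tot[better]
                best_sp[better] = sp
            idx = np.flatnonzero(best_total >= threshold)
            for b in idx:
                # the projected TSS may fall just past a genome edge for a
                # hit at the boundary; it is reported with the hit regardless
                # so that threshold-rule retrieval stays exact
                tss_local = b + w10 + 5
                sp = int(best_sp[b])
                a35 = b - sp - 1
                hits.append(
                    PromoterCall(
                        cls=promoter_class or "early",
                        tss=to_plus(tss_local, strand),
                        strand=strand,
                        score=float(best_total[b]),
                        spacer=sp,
                        box10=_interval(b + 5, b + 11, strand, L),
                        box35=_interval(a35, a35 + 6, strand, L),
                    )
                )
        else:
            w = model.width
            scores = model.score_all(enc)
            idx = np.flatnonzero(scores >= threshold)
            for b in idx:
                tss_local = b + w - 1 + TSS_OFFSET
                hits.append(
                    PromoterCall(
                        cls=promoter_class or "late",
                        tss=to_plus(tss_local, strand),
                        strand=strand,
                        score=float(scores[b]),
                        box10=_interval(b, b + w, strand, L),
                    )
                )
    return _merge_hits(hits, merge_within)


def _interval(a: int, b: int, strand: str, L: int) -> tuple[int, int]:
    """Map a local [a,b) interval on the given strand's forward reading to a
    plus-strand genomic interval."""
    if strand == "+":
        return (a, b)
    return (L - b, L - a)


# ---------------------------------------------------------------------------
# promoter-model fitting from TSS-anchored upstream windows
#
# Upstream windows end immediately before the TSS base, so a genuine promoter
# box sits at a near-constant distance from the window end across windows.
# Model fitting exploits that anchor: scan the offset-from-end that maximises
# total information content (for the early model, jointly with the best
# -35 partner IC at spacers 16-18), then let each site jitter a few bases to
# absorb step-position noise. This is deterministic and, unlike free EM,
# cannot phase-shift onto a flank or lock onto the -35 box alone.


def _anchored_sites(
    windows: list[str], width: int, d_end: int, upstream_needed: int = 0
) -> tuple[list[str], list[int]] | None:
    """Sites of ``width`` whose 3' end lies ``d_end`` bases before each
    window's end; None when any window lacks room (incl. upstream slack)."""
    sites, offsets = [], []
    for w in windows:
        b = len(w) - d_end - width
        if b < upstream_needed:
            return None
        sites.append(w[b : b + width].upper())
        offsets.append(b)
    return sites, offsets


def _refine_sites(
    windows: list[str],
    offsets: list[int],
    width: int,
    pseudocount: float,
    background: np.ndarray | None,
    jitter: int = 3,
    min_offset: int = 0,
    rounds: int = 2,
) -> tuple[PwmModel, list[str], list[int]]:
    """Let each site shift by up to ``jitter`` to its best-scoring position,
    rebuilding the PWM between rounds."""
    sites = [w[b : b + width].upper() for w, b in zip(windows, offsets)]
    pwm = build_pwm(sites, pseudocount, background)
    for _ in range(rounds):
        new_offsets = []
        for w, b in zip(windows, offsets):
            best_b, best_s = b, -np.inf
            for delta in range(-jitter, jitter + 1):
                bb = b + delta
                if bb < min_offset or bb + width > len(w):
                    continue
                s = pwm.score(w[bb : bb + width].upper())
                if s > best_s:
                    best_b, best_s = bb, s
            new_offsets.append(best_b)
        if new_offsets == offsets:
            break
        offsets = new_offsets
        sites = [w[b : b + width].upper() for w, b in zip(windows, offsets)]
        pwm = build_pwm(sites, pseudocount, background)
    return pwm, sites, offsets


def fit_early_model(
    windows: list[str],
    seed: int = 0,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    d_end_range: tuple[int, int] = (0, 26),
) -> EarlyPromoterModel:
    """Fit the two-box early model from TSS-upstream windows.

    The 11-column ext-10 block offset is chosen by the anchored scan (block
    IC plus the best -35 IC over spacers 16-18), sites are jitter-refined,
    and -35 hexamers are assigned their penalised-best spacer per site over
    a few rounds. The rescanning threshold is the minimum total training-site
    score. ``seed`` is accepted for interface symmetry; the fit is
    deterministic.
    """
    penalties = {16: 1.5, 17: 0.0, 18: 1.5}
    upstream_needed = max(penalties) + 1  # room for the -35 box
    windows = [w.upper() for w in windows if len(w) >= upstream_needed + 11]
    if len(windows) < 2:
        raise ValueError("too few windows with room for the -35 box")

    best_d, best_obj = None, -np.inf
    for d in range(*d_end_range):
        res = _anchored_sites(windows, 11, d, upstream_needed)
        if res is None:
            continue
        sites10, offsets = res
        ic10 = build_pwm(sites10, pseudocount, background).information_content().sum()
        ic35 = -np.inf
        for sp in penalties:
            sites35 = [w[b - sp - 1 : b - sp + 5] for w, b in zip(windows, offsets)]
            ic35 = max(
                ic35,
                build_pwm(sites35, pseudocount, background)
                .information_content()
                .sum(),
            )
        obj = ic10 + ic35
        if obj > best_obj:
            best_obj, best_d = obj, d
    if best_d is None:
        raise ValueError("windows too short for the early model")

    _, offsets = _anchored_sites(windows, 11, best_d, upstream_needed)
    pwm_10ext, sites10, offsets = _refine_sites(
        windows, offsets, 11, pseudocount, background,
        min_offset=upstream_needed,
    )
    kept_windows = windows

    def candidates(w: str, b: int) -> dict[int, str]:
        return {sp: w[b - sp - 1 : b - sp + 5] for sp in penalties if b - sp - 1 >= 0}

    spacers = [17 if 17 in candidates(w, b) else max(candidates(w, b))
               for w, b in zip(kept_windows, offsets)]
    for _ in range(3):
        sites35 = [candidates(w, b)[sp]
                   for w, b, sp in zip(kept_windows, offsets, spacers)]
        pwm_35 = build_pwm(sites35, pseudocount, background)
        new_spacers = []
        for w, b in zip(kept_windows, offsets):
            cand = candidates(w, b)
            new_spacers.append(
                max(cand, key=lambda sp: pwm_35.score(cand[sp]) - penalties[sp])
            )
        if new_spacers == spacers:
            spacers = new_spacers
            break
        spacers = new_spacers
    sites35 = [candidates(w, b)[sp]
               for w, b, sp in zip(kept_windows, offsets, spacers)]
    pwm_35 = build_pwm(sites35, pseudocount, background)

    model = EarlyPromoterModel(
        pwm_35=pwm_35, pwm_10ext=pwm_10ext, spacer_penalties=penalties
    )
    model.training_sites = list(zip(sites35, sites10, spacers))
    model.threshold = min(
        model.score_site(s35, s10, sp) for s35, s10, sp in model.training_sites
    )
    return model


def fit_late_pwm(
    windows: list[str],
    seed: int = 0,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    core_width: int = 10,
    d_end_range: tuple[int, int] = (0, 26),
) -> tuple[PwmModel, list[str]]:
    """Fit the late-promoter core PWM from TSS-upstream windows.

    The core offset from the window end is chosen by the anchored IC scan
    (late up-steps are few, so the anchor carries the alignment) and sites
    are jitter-refined. Returns the PWM (threshold set by the retrieve-all
    rule) and the aligned training sites. Deterministic; ``seed`` kept for
    interface symmetry.
    """
    windows = [w.upper() for w in windows if len(w) >= core_width]
    if not windows:
        raise ValueError("no windows")
    canonical_d = TSS_OFFSET - 1  # core 3' end 6 bp upstream of the TSS base
    if len(windows) >= 4:
        best_d, best_ic = None, -np.inf
        for d in range(*d_end_range):
            res = _anchored_sites(windows, core_width, d)
            if res is None:
                continue
            sites, _ = res
            ic = build_pwm(sites, pseudocount, background).information_content().sum()
            if ic > best_ic:
                best_ic, best_d = ic, d
        if best_d is None:
            raise ValueError("windows too short for the late core")
    else:
        # too few sites for the IC scan to be meaningful: take the canonical
        # TSS-anchored offset and let jitter refinement absorb step noise
        best_d = canonical_d
    _, offsets = _anchored_sites(windows, core_width, best_d)
    pwm, sites, _ = _refine_sites(
        windows, offsets, core_width, pseudocount, background
    )
    pwm.threshold = training_threshold(pwm, sites)
    return pwm, sites


def write_meme(
    models: dict[str, PwmModel], path, background: np.ndarray | None = None
) -> None:
    """Write PWMs in MEME minimal motif format."""
    bg = background if background is not None else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.4f}" for b, f in zip(BASE_ORDER, bg)) + "\n\n")
        for name, pwm in models.items():
            n = int(round(pwm.counts.sum(axis=0).max()))
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= {n} E= 0\n"
            )
            for col in pwm.probs.T:
                fh.write(" ".join(f"{x:.6f}" for x in col) + "\n")
            fh.write("\n")
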