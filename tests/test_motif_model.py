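import numpy as np
import pytest

from phagetu.genome_io import GenomeRecord, reverse_complement
from phagetu.motif_model import (
    build_pwm,
    consensus_iupac,
    discover_motif,
    encode,
    fit_early_model,
    fit_late_pwm,
    scan_genome,
    training_threshold,
    write_meme,
)
from phagetu.synthetic_data import (
    _draw_spacer,
    _random_bases,
    early_cassette,
    late_cassette,
)

BASES = np.array(list("ACGT"))


def random_seq(n, rng):
    return "".join(rng.choice(BASES, n))


# ---------------------------------------------------------------------- PWMs


def test_build_pwm_hand_scores():
    pwm = build_pwm(["TATAAT"] * 4, pseudocount=1.0)
    assert pwm.score("TATAAT") == pytest.approx(6 * np.log2((5 / 8) / 0.25))
    single = build_pwm(["ACGT"], pseudocount=0.0)
    assert single.score("ACGT") == pytest.approx(8.0)


def test_log_odds_vanish_when_background_equals_columns():
    pwm = build_pwm(["AAAA", "CCCC", "GGGG", "TTTT"], pseudocount=0.0)
    pwm.background = np.full(4, 0.25)  # columns are uniform too
    assert np.allclose(pwm.log_odds, 0.0)


def test_build_pwm_rejects_unequal_lengths():
    with pytest.raises(ValueError):
        build_pwm(["ACGT", "ACG"])


def test_information_content_bounds():
    pwm = build_pwm(["TGTTATATTA"] * 5, pseudocount=0.0)
    ic = pwm.information_content()
    assert np.all(ic >= 0)
    assert ic.sum() == pytest.approx(2 * pwm.width)


def test_training_threshold_is_the_minimum_site_score():
    sites = ["TATAAT", "TATACT", "TAAAAT"]
    pwm = build_pwm(sites)
    thr = training_threshold(pwm, sites)
    assert thr == pytest.approx(min(pwm.score(s) for s in sites))
    with pytest.raises(ValueError):
        training_threshold(pwm, [])


def test_threshold_rule_retrieves_every_training_site(rng):
    """Scanning at the retrieve-all threshold finds 100% of training sites."""
    sites = [
        "".join(c if rng.random() > 0.1 else rng.choice(BASES) for c in "TGTTATATTA")
        for _ in range(12)
    ]
    positions, parts, cursor = [], [], 0
    for s in sites:
        gap = random_seq(80, rng)
        parts += [gap, s]
        cursor += len(gap)
        positions.append(cursor)
        cursor += len(s)
    genome = GenomeRecord(id="g", sequence="".join(parts) + random_seq(60, rng))
    pwm = build_pwm(sites)
    pwm.threshold = training_threshold(pwm, sites)
    hits = scan_genome(pwm, genome, promoter_class="late")
    hit_starts = {h.box10[0] for h in hits if h.strand == "+"}
    assert set(positions) <= hit_starts


# ---------------------------------------------------------------------- scan


def brute_scan(pwm, genome):
    """Independent all-positions scorer over both strands."""
    out = {}
    for strand, seq in (("+", genome.sequence), ("-", reverse_complement(genome.sequence))):
        scores = []
        for i in range(genome.length - pwm.width + 1):
            s = 0.0
            ok = True
            for j, b in enumerate(seq[i : i + pwm.width]):
                if b not in "ACGT":
                    ok = False
                    break
                s += pwm.log_odds["ACGT".index(b), j]
            scores.append(s if ok else -np.inf)
        out[strand] = np.array(scores)
    return out


def test_score_all_matches_brute_force_scorer(rng):
    genome = GenomeRecord(id="g", sequence=random_seq(2000, rng))
    sites = [random_seq(8, rng) for _ in range(6)]
    pwm = build_pwm(sites)
    brute = brute_scan(pwm, genome)
    assert np.allclose(pwm.score_all(encode(genome.sequence)), brute["+"], atol=1e-10)
    assert np.allclose(
        pwm.score_all(encode(reverse_complement(genome.sequence))),
        brute["-"],
        atol=1e-10,
    )


def test_scan_reports_every_above_threshold_cluster(rng):
    genome = GenomeRecord(id="g", sequence=random_seq(3000, rng))
    pwm = build_pwm([random_seq(7, rng) for _ in range(5)])
    thr = 6.0
    hits = scan_genome(pwm, genome, threshold=thr, promoter_class="late")
    brute = brute_scan(pwm, genome)
    for strand in "+-":
        above = np.flatnonzero(brute[strand] >= thr)
        got = {
            (h.box10[0] if strand == "+" else genome.length - h.box10[1])
            for h in hits
            if h.strand == strand
        }
        # every above-threshold position is represented within the merge radius
        for p in above:
            assert any(abs(p - g) <= 5 for g in got)
        # and no hit lacks an above-threshold witness
        for g in got:
            assert np.any(np.abs(above - g) <= 5)


def test_scan_with_infinite_threshold_is_empty(rng):
    genome = GenomeRecord(id="g", sequence=random_seq(500, rng))
    pwm = build_pwm(["ACGTAC"])
    assert scan_genome(pwm, genome, threshold=np.inf) == []


def test_palindromic_site_is_reported_on_both_strands():
    site = "GCATATGC"  # reverse complement of itself
    genome = GenomeRecord(id="g", sequence="A" * 40 + site + "A" * 40)
    pwm = build_pwm([site], pseudocount=1.0)
    hits = scan_genome(pwm, genome, threshold=pwm.score(site) - 1e-9)
    assert {h.strand for h in hits} == {"+", "-"}


def test_planted_single_consensus_yields_exactly_one_plus_hit():
    site = "TGTTATATTA"
    genome = GenomeRecord(id="g", sequence="A" * 50 + site + "A" * 50)
    pwm = build_pwm([site] * 3)
    pwm.threshold = training_threshold(pwm, [site])
    hits = [h for h in scan_genome(pwm, genome) if h.strand == "+"]
    assert len(hits) == 1 and hits[0].box10 == (50, 60)
    # TSS sits 6 bp after the core 3' end
    assert hits[0].tss == 60 - 1 + 6


# ----------------------------------------------------------------- consensus


def test_consensus_iupac_column_rules():
    pwm = build_pwm(["AT", "TA"], pseudocount=0.0)
    assert consensus_iupac(pwm) == "WW"
    uniform = build_pwm(["A", "C", "G", "T"], pseudocount=0.0)
    assert consensus_iupac(uniform) == "N"
    major = build_pwm(["AA"] * 9 + ["AC"], pseudocount=0.0)
    assert consensus_iupac(major)[0] == "A"


def test_consensus_recovers_planted_w_pattern(rng):
    sites = ["TTGAC" + rng.choice(list("AT")) for _ in range(40)]
    pwm = build_pwm(sites)
    assert consensus_iupac(pwm) == "TTGACW"


# ----------------------------------------------------------------- discovery


def test_zoops_em_recovers_planted_late_core(rng):
    wins = []
    for _ in range(20):
        bg = random_seq(60, rng)
        off = rng.integers(0, 50)
        wins.append(bg[:off] + "TGTTATATTA" + bg[off:])
    model = discover_motif(wins, width=10, seed=0)
    assert consensus_iupac(model) == "TGTTATATTA"


def test_zoops_em_on_uniform_noise_finds_no_motif(rng):
    wins = [random_seq(60, rng) for _ in range(20)]
    model = discover_motif(wins, width=10, seed=0)
    assert model.information_content().mean() < 0.5


def test_zoops_em_degenerate_identical_windows_converges_fast():
    wins = ["ACGTACGTTGCATGCA"] * 8
    model = discover_motif(wins, width=8, seed=0)
    assert model.em_iterations <= 5
    # all windows identical: the consensus is a literal substring of them
    assert consensus_iupac(model) in wins[0]


def test_discover_motif_preconditions():
    with pytest.raises(ValueError):
        discover_motif(["ACGTACGT"] * 4, width=4)  # fewer than 5 windows
    with pytest.raises(ValueError):
        discover_motif(["ACGTACGT"] * 6, width=20)  # width > window


# --------------------------------------------------------------- full models


def synth_early_windows(n, rng, mutation_rate=0.0):
    wins = []
    for _ in range(n):
        cas = early_cassette(_draw_spacer(rng), rng, mutation_rate)
        wins.append(_random_bases(100 - len(cas) + 1, rng) + cas[:-1])
    return wins


def test_early_model_recovers_boxes_and_spacers(rng):
    model = fit_early_model(synth_early_windows(36, rng), seed=0)
    assert consensus_iupac(model.pwm_10ext) == "TRTGNTATANT"
    assert consensus_iupac(model.pwm_35) == "TTGACW"
    spacers = {sp for _, _, sp in model.training_sites}
    assert spacers <= {16, 17, 18} and 17 in spacers
    # total score decomposition honours the spacer penalty
    s35, s10, sp = model.training_sites[0]
    assert model.score_site(s35, s10, sp) == pytest.approx(
        model.pwm_35.score(s35)
        + model.pwm_10ext.score(s10)
        - model.spacer_penalties[sp]
    )


def test_early_scan_recovers_planted_promoter_with_correct_tss(rng):
    model = fit_early_model(synth_early_windows(20, rng), seed=0)
    cas = early_cassette(17, rng, 0.0)
    tss = 200 + len(cas) - 1
    genome = GenomeRecord(
        id="g", sequence=_random_bases(200, rng) + cas + _random_bases(200, rng)
    )
    hits = [h for h in scan_genome(model, genome, threshold=0.0) if h.strand == "+"]
    best = max(hits, key=lambda h: h.score)
    assert best.tss == tss
    assert best.spacer == 17


def test_late_pwm_fit_uses_canonical_anchor_for_tiny_training_sets(rng):
    wins = []
    for _ in range(2):
        cas = late_cassette(rng, 0.0)
        wins.append(_random_bases(100 - len(cas) + 1, rng) + cas[:-1])
    pwm, sites = fit_late_pwm(wins, seed=0)
    assert all(s == "TGTTATATTA" for s in sites)


def test_write_meme_minimal_format(tmp_path):
    pwm = build_pwm(["TGTTATATTA"] * 4)
    out = tmp_path / "m.meme"
    write_meme({"late": pwm}, out)
    text = out.read_text()
    assert "MEME version 4" in text and "MOTIF late" in text
    assert "w= 10" in text
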