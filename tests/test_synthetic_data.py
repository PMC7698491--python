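import numpy as np
import pytest

from phagetu.genome_io import reverse_complement
from phagetu.synthetic_data import (
    LATE_CORE,
    SimParams,
    expected_depth,
    generate_architecture,
    make_dataset,
    noiseless,
    plant_sequence,
    simulate_counts,
    simulate_coverage,
)


def test_single_early_tu_architecture():
    params = SimParams(genome_length=8000)
    arch = generate_architecture(
        1, params, seed=0, class_fractions=(1.0, 0.0, 0.0), n_ncrna=0
    )
    proms = list(arch.promoters.values())
    assert len(arch.terminators) == 1
    assert all(p.cls == "early" for p in proms)
    assert len(arch.coding_tus) == 1


def test_class_fractions_reproduce_expected_mix():
    params = SimParams(genome_length=200_000)
    arch = generate_architecture(35, params, seed=1, n_ncrna=0)
    counts = {c: 0 for c in ("early", "late", "both")}
    for tu in arch.coding_tus:
        counts[tu.cls] += 1
    # largest-remainder allocation of (26,4,5)/35 is exact at n=35
    assert counts == {"early": 26, "late": 4, "both": 5}


def test_architecture_is_seed_deterministic():
    params = SimParams()
    a = generate_architecture(8, params, seed=5)
    b = generate_architecture(8, params, seed=5)
    assert [(t.id, t.strand, t.cls, tuple(t.orf_ids)) for t in a.tus] == [
        (t.id, t.strand, t.cls, tuple(t.orf_ids)) for t in b.tus
    ]
    assert a.promoter_truth() == b.promoter_truth()


def test_genome_too_short_raises():
    with pytest.raises(ValueError, match="too short"):
        generate_architecture(50, SimParams(genome_length=10_000), seed=0)


def test_planted_late_core_sits_six_bases_before_tss():
    """With mutation rate 0 the literal TGTTATATTA must end 6 bp upstream of
    each late TSS (strand-aware)."""
    params = SimParams(mutation_rate=0.0, genome_length=60_000)
    arch = generate_architecture(12, params, seed=3)
    genome = plant_sequence(arch, params, seed=4)
    lates = [p for p in arch.promoters.values() if p.cls == "late"]
    assert lates, "architecture should contain late promoters"
    for p in lates:
        if p.strand == "+":
            core = genome.sequence[p.position - 15 : p.position - 5]
        else:
            core = reverse_complement(
                genome.sequence[p.position + 6 : p.position + 16]
            )
        assert core == LATE_CORE


def test_planted_terminator_hairpin_pairs_exactly():
    params = SimParams(mutation_rate=0.0)
    arch = generate_architecture(6, params, seed=2)
    genome = plant_sequence(arch, params, seed=2)
    for t in arch.terminators.values():
        seg = genome.sequence[t.cassette_start : t.cassette_end]
        if t.strand == "-":
            seg = reverse_complement(seg)
        arm1 = seg[: t.stem_len]
        arm2 = seg[t.stem_len + t.loop_len : 2 * t.stem_len + t.loop_len]
        assert arm2 == reverse_complement(arm1)
        assert seg.endswith("T" * t.polyt_len)


def test_minus_strand_cassette_appears_reverse_complemented():
    params = SimParams(mutation_rate=0.0, genome_length=60_000)
    arch = generate_architecture(12, params, seed=3)
    genome = plant_sequence(arch, params, seed=4)
    minus_lates = [
        p for p in arch.promoters.values() if p.cls == "late" and p.strand == "-"
    ]
    assert minus_lates, "need a minus-strand late promoter for this check"
    p = minus_lates[0]
    plus_text = genome.sequence[p.cassette_start : p.cassette_end]
    assert reverse_complement(LATE_CORE) in plus_text


def test_noiseless_coverage_matches_closed_form_plateaus():
    params = noiseless(SimParams())
    arch = generate_architecture(4, params, seed=7)
    tracks = simulate_coverage(arch, params, seed=7)
    mu = expected_depth(arch, params)
    for tr in tracks:
        assert np.allclose(tr.depth, mu[(tr.strand, tr.timepoint)])


def test_noiseless_single_promoter_plateau_and_readthrough():
    # a late-only TU always carries exactly one promoter
    params = noiseless(SimParams())
    arch = generate_architecture(
        1, params, seed=9, class_fractions=(0.0, 1.0, 0.0), n_ncrna=0
    )
    (prom,) = arch.promoters.values()
    (term,) = arch.terminators.values()
    mu = expected_depth(arch, params)[(prom.strand, "t30")]
    inside = (
        mu[prom.position + 10 : term.position - 10]
        if prom.strand == "+"
        else mu[term.position + 10 : prom.position - 10]
    )
    assert np.allclose(inside, prom.strength)
    # plateau immediately past the terminator is strength x readthrough
    if prom.strand == "+":
        past = mu[term.position : term.position + params.readthrough_flat]
    else:
        past = mu[term.position - params.readthrough_flat : term.position]
    assert np.allclose(past, prom.strength * term.readthrough)


def test_late_promoters_silent_at_early_timepoints():
    params = noiseless(SimParams())
    arch = generate_architecture(
        1, params, seed=13, class_fractions=(0.0, 1.0, 0.0), n_ncrna=0
    )
    (prom,) = arch.promoters.values()
    assert prom.cls == "late"
    mu = expected_depth(arch, params)
    for tp in ("t5", "t15"):
        assert np.all(mu[(prom.strand, tp)] == 0)
    assert mu[(prom.strand, "t30")].max() > 0


def test_degradation_depletes_early_tu_five_prime_end_late():
    params = noiseless(SimParams(degradation_rate=0.2))
    arch = generate_architecture(
        1, params, seed=9, class_fractions=(1.0, 0.0, 0.0), n_ncrna=0
    )
    proms = list(arch.promoters.values())
    # the 5'-most promoter of the unit in transcription direction
    prom = min(proms, key=lambda p: p.position if p.strand == "+" else -p.position)
    (term,) = arch.terminators.values()
    mu = expected_depth(arch, params)
    tss_side = prom.position + 5 if prom.strand == "+" else prom.position - 5
    end_side = term.position - 5 if prom.strand == "+" else term.position + 5
    t5, t30 = mu[(prom.strand, "t5")], mu[(prom.strand, "t30")]
    # the 5' end loses more coverage at t30 than the 3' end
    assert t30[tss_side] < t5[tss_side]
    drop_5p = t5[tss_side] - t30[tss_side]
    drop_3p = t5[end_side] - t30[end_side]
    assert drop_5p > drop_3p


def test_counts_zero_dispersion_equals_rounded_means():
    params = noiseless(SimParams())
    arch = generate_architecture(3, params, seed=21)
    counts, lengths = simulate_counts(arch, params, n_replicates=2, seed=21)
    reps = counts.T.groupby(level=0).nunique().T
    assert (reps <= 1).all().all()  # replicates identical without noise


def test_count_length_proportionality_and_mc_mean(rng):
    """Expected count scales with ORF length; the NB empirical mean over many
    replicates stays within 2% of the analytic mean."""
    params = noiseless(SimParams())
    arch = generate_architecture(
        1, params, seed=33, class_fractions=(1.0, 0.0, 0.0), n_ncrna=0
    )
    counts, lengths = simulate_counts(arch, params, n_replicates=1, seed=33)
    mu = expected_depth(arch, params)
    tu = arch.coding_tus[0]
    # analytic check of the mean for the first ORF
    orf = next(o for o in arch.orfs if o.id == tu.orf_ids[0])
    mean_depth = mu[(orf.strand, "t5")][orf.start : orf.end].mean()
    expect = mean_depth * orf.length / params.read_scale
    assert counts.loc[orf.id, ("t5", "rep1")] == round(expect)
    # doubling length doubles the expected count at fixed depth
    assert np.isclose(
        (mean_depth * 2 * orf.length / params.read_scale) / expect, 2.0
    )
    # Monte-Carlo: NB draws around that mean
    noisy = SimParams(count_dispersion=0.05)
    n = 1 / noisy.count_dispersion
    draws = rng.negative_binomial(n, n / (n + expect), size=10_000)
    assert abs(draws.mean() - expect) / expect < 0.02


def test_same_seed_gives_bit_identical_dataset():
    a = make_dataset(6, SimParams(), seed=17)
    b = make_dataset(6, SimParams(), seed=17)
    assert a[1].sequence == b[1].sequence
    for ta, tb in zip(a[2], b[2]):
        assert np.array_equal(ta.depth, tb.depth)
    assert a[3].equals(b[3])
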