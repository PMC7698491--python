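import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from phagetu.expression import (
    benjamini_hochberg,
    differential,
    getmm,
    region_fraction,
    temporal_classes,
    temporal_profile,
    tmm_factor,
    tmm_norm_factors,
)


# ------------------------------------------------------------------- oracles


def tmm_oracle(obs, ref, trim_m=0.30, trim_a=0.05):
    """Step-by-step reimplementation of the trimmed-mean-of-M-values factor,
    written independently of the library code."""
    No, Nr = sum(obs), sum(ref)
    rows = []
    for o, r in zip(obs, ref):
        if o > 0 and r > 0:
            m = math.log2((o / No) / (r / Nr))
            a = 0.5 * math.log2((o / No) * (r / Nr))
            w = (No - o) / (No * o) + (Nr - r) / (Nr * r)
            rows.append((m, a, w))
    if max(abs(r[0]) for r in rows) < 1e-6:
        return 1.0
    n = len(rows)

    def ranks(vals):
        order = sorted(range(n), key=lambda i: vals[i])
        rk = [0.0] * n
        i = 0
        while i < n:
            j = i
            while j + 1 < n and vals[order[j + 1]] == vals[order[i]]:
                j += 1
            for k in range(i, j + 1):
                rk[order[k]] = (i + j) / 2 + 1
            i = j + 1
        return rk

    rm = ranks([r[0] for r in rows])
    ra = ranks([r[1] for r in rows])
    lo_m, hi_m = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
    lo_a, hi_a = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)
    num = den = 0.0
    for (m, a, w), km, ka in zip(rows, rm, ra):
        if lo_m <= km <= hi_m and lo_a <= ka <= hi_a:
            num += m / w
            den += 1 / w
    return 2 ** (num / den)


def bh_oracle(pvals):
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running = min(running, pvals[i] * m / (rank_from_top + 1))
        adj[i] = running
    return adj


def getmm_oracle(counts, lengths):
    rpk = counts.div(lengths / 1000.0, axis=0)
    factors = tmm_norm_factors(rpk)
    return rpk.div(rpk.sum(axis=0) * factors, axis=1) * 1e6


# ----------------------------------------------------------------------- TMM


def test_tmm_factor_trivial_cases(rng):
    ref = rng.integers(10, 1000, 100).astype(float)
    assert tmm_factor(ref, ref) == pytest.approx(1.0)
    assert tmm_factor(2 * ref, ref) == pytest.approx(1.0)  # scale invariance


def test_tmm_factor_matches_independent_oracle(rng):
    ref = rng.integers(10, 1000, 20).astype(float)
    obs = ref.copy()
    obs[3] *= 10  # one inflated gene
    assert tmm_factor(obs, ref) == pytest.approx(tmm_oracle(obs, ref), abs=1e-10)
    for _ in range(5):
        a = rng.negative_binomial(5, 0.02, 150).astype(float) + 1
        b = rng.negative_binomial(5, 0.02, 150).astype(float) + 1
        assert tmm_factor(a, b) == pytest.approx(tmm_oracle(a, b), abs=1e-10)


def test_tmm_reciprocity_after_rescaling(rng):
    a = rng.negative_binomial(5, 0.01, 300).astype(float) + 1
    b = rng.negative_binomial(5, 0.01, 300).astype(float) + 1
    assert tmm_factor(a, b) == pytest.approx(1 / tmm_factor(b, a), rel=0.02)


def test_tmm_norm_factors_have_unit_geometric_mean(rng):
    x = rng.negative_binomial(5, 0.02, (200, 5)).astype(float)
    f = tmm_norm_factors(pd.DataFrame(x))
    assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)
    assert (f > 0).all()


def test_tmm_matches_edger_calcnormfactors(rng, tmp_path):
    """Cross-check against the reference implementation through Rscript."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript not available for the edgeR cross-check")
    x = rng.negative_binomial(5, 0.02, size=(200, 4)).astype(float)
    x[rng.random((200, 4)) < 0.05] = 0
    df = pd.DataFrame(x, columns=list("ABCD"))
    df.to_csv(tmp_path / "m.csv")
    r = subprocess.run(
        [
            "Rscript", "-e",
            'suppressMessages(library(edgeR));'
            f'm<-as.matrix(read.csv("{tmp_path}/m.csv",row.names=1));'
            'cat(sprintf("%.12f ", calcNormFactors(m)))',
        ],
        capture_output=True, text=True, timeout=300,
    )
    assert r.returncode == 0, r.stderr
    theirs = np.array([float(v) for v in r.stdout.split()])
    assert np.allclose(tmm_norm_factors(df).to_numpy(), theirs, atol=1e-8)


# --------------------------------------------------------------------- GeTMM


def test_getmm_length_correction_arithmetic():
    counts = pd.DataFrame({"s1": [100, 100]}, index=["g1", "g2"])
    lengths = pd.Series([1000, 2000], index=["g1", "g2"])
    vals = getmm(counts, lengths).values["s1"]
    assert vals["g1"] / vals["g2"] == pytest.approx(2.0)


def test_getmm_equal_lengths_is_tmm_cpm(rng):
    x = rng.integers(1, 500, (50, 3)).astype(float)
    counts = pd.DataFrame(x, columns=list("abc"))
    lengths = pd.Series(500, index=counts.index)
    vals = getmm(counts, lengths).values
    factors = tmm_norm_factors(counts)
    cpm = counts.div(counts.sum(axis=0) * factors, axis=1) * 1e6
    assert np.allclose(vals, cpm)


def test_getmm_matches_oracle_to_1e10(rng):
    x = rng.negative_binomial(4, 0.01, (120, 4)).astype(float) + 1
    counts = pd.DataFrame(x)
    lengths = pd.Series(rng.integers(200, 3000, 120), index=counts.index)
    assert np.allclose(
        getmm(counts, lengths).values, getmm_oracle(counts, lengths), atol=1e-10
    )


def test_getmm_rejects_zero_length():
    counts = pd.DataFrame({"s": [1, 2]}, index=["a", "b"])
    with pytest.raises(ValueError):
        getmm(counts, pd.Series([0, 100], index=["a", "b"]))


# ------------------------------------------------------------------- regions


def test_region_fraction_arithmetic():
    vals = pd.DataFrame({"s": [22.0, 84.0, 894.0]}, index=["lnc1", "lnc2", "rest"])
    assert region_fraction(vals, ["lnc1", "lnc2"]) == pytest.approx(10.6)
    assert region_fraction(vals, ["lnc1"]) == pytest.approx(2.2)
    zero = pd.DataFrame({"s": [0.0, 100.0]}, index=["r", "g"])
    assert region_fraction(zero, ["r"]) == 0.0
    total = pd.DataFrame({"s": [50.0, 0.0]}, index=["r", "g"])
    assert region_fraction(total, ["r"]) == pytest.approx(100.0)
    with pytest.raises(KeyError):
        region_fraction(vals, ["missing"])


# ---------------------------------------------------------------------- BH


def test_bh_hand_case_and_oracle(rng):
    assert np.allclose(benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    for _ in range(5):
        p = rng.random(37)
        assert np.allclose(benjamini_hochberg(p), bh_oracle(list(p)), atol=1e-10)


def test_bh_is_monotone_in_raw_p_order(rng):
    p = np.sort(rng.random(50))
    adj = benjamini_hochberg(p)
    assert np.all(np.diff(adj) >= -1e-12)


# -------------------------------------------------------------- differential


def test_differential_identical_groups_is_null(rng):
    x = rng.negative_binomial(20, 0.1, (40, 3))
    df = pd.DataFrame(np.hstack([x, x]), columns=[f"s{i}" for i in range(6)])
    de = differential(df, [f"s{i}" for i in range(3)], [f"s{i}" for i in range(3, 6)])
    assert np.allclose(de["logFC"], 0.0)
    assert (de["fdr"] > 0.9).all()
    assert not de["significant"].any()


def test_differential_flags_strong_induction(rng):
    mu = np.exp(rng.uniform(np.log(50), np.log(300), 30))
    n = 1 / 0.05
    xa = rng.negative_binomial(n, n / (n + mu[:, None]), (30, 3)).astype(float)
    mu_b = mu.copy()
    mu_b[0] *= 4
    xb = rng.negative_binomial(n, n / (n + mu_b[:, None]), (30, 3)).astype(float)
    df = pd.DataFrame(np.hstack([xa, xb]), columns=[f"s{i}" for i in range(6)])
    de = differential(df, [f"s{i}" for i in range(3)], [f"s{i}" for i in range(3, 6)])
    assert de["significant"].iloc[0]
    assert de["logFC"].iloc[0] == pytest.approx(2.0, abs=0.6)


def test_differential_rejects_empty_group():
    df = pd.DataFrame({"a": [1], "b": [2]})
    with pytest.raises(ValueError):
        differential(df, [], ["a", "b"])


# ------------------------------------------------------------ temporal class


def test_temporal_profile_rules():
    assert temporal_profile((100, 100, 120), False, late_floor=5.0) == "early-expressed"
    assert temporal_profile((1, 2, 400), True, late_floor=5.0) == "late-expressed"
    assert temporal_profile((0, 0, 0), False, late_floor=5.0) == "flat"


def test_temporal_classes_on_synthetic_counts(noisy_dataset):
    arch, genome, tracks, counts, lengths = noisy_dataset
    table = temporal_classes(counts, lengths)
    by_tu = {tu.id: tu for tu in arch.tus}
    late_orfs = [
        oid
        for tu in arch.coding_tus
        if tu.cls == "late"
        for oid in tu.orf_ids
    ]
    early_orfs = [
        oid
        for tu in arch.coding_tus
        if tu.cls == "early"
        for oid in tu.orf_ids
    ]
    assert late_orfs and early_orfs
    late_called = table.loc[late_orfs, "temporal_class"]
    assert (late_called == "late-expressed").mean() >= 0.9
    early_called = table.loc[early_orfs, "temporal_class"]
    assert (early_called == "early-expressed").mean() >= 0.9
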