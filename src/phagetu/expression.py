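"""Count normalisation (TMM/GeTMM), differential expression and temporal
classification.

TMM follows the trimmed-mean-of-M-values algorithm: per-gene log-ratios (M)
and abundances (A) on library-size-scaled counts, genes with a zero in
either sample excluded, double trimming (30% on M, 5% on A), and an
inverse-asymptotic-variance weighted mean of M; factors are rescaled to
geometric mean 1. GeTMM applies TMM to reads-per-kilobase values so gene
length is corrected before the library composition.

The differential test is a conditional negative-binomial exact test on
library-size-equalised counts with a common method-of-moments dispersion,
followed by Benjamini-Hochberg adjustment; genes are flagged at FDR <= 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests


@dataclass
class NormalizedExpression:
    """GeTMM expression values plus the factors that produced them."""

    values: pd.DataFrame  # genes x samples, CPM scale on RPK
    tmm_factors: pd.Series
    library_sizes: pd.Series  # RPK library sizes


def tmm_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float | None = None,
    lib_ref: float | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> float:
    """TMM normalisation factor of ``obs`` against ``ref``.

    Genes with a zero in either sample are excluded; the M values are doubly
    trimmed (``trim_m`` of each M tail, ``trim_a`` of each A tail) and
    averaged with weights 1/v, v the delta-method binomial variance. Raises
    when trimming leaves nothing.
    """
    from scipy.stats import rankdata

    obs = np.asarray(obs, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if obs.shape != ref.shape:
        raise ValueError("samples must share the gene set")
    n_obs = obs.sum() if lib_obs is None else float(lib_obs)
    n_ref = ref.sum() if lib_ref is None else float(lib_ref)
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep], ref[keep]
    if o.size == 0:
        raise ValueError("no genes left after removing zeros")
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not np.any(sel):
        raise ValueError("all genes trimmed")
    f = np.sum(m[sel] / v[sel]) / np.sum(1.0 / v[sel])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_norm_factors(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Per-sample TMM factors, geometric mean 1.

    The reference sample is the one whose 75th-percentile-over-library-size
    is closest to the mean of that statistic, as in the standard algorithm.
    Genes that are zero in every sample are dropped first.
    """
    x = counts.loc[counts.sum(axis=1) > 0].to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("sample with zero library size")
    f75 = np.quantile(x, 0.75, axis=0) / lib
    ref_i = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            tmm_factor(x[:, j], x[:, ref_i], lib[j], lib[ref_i], trim_m, trim_a)
            for j in range(x.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def getmm(counts: pd.DataFrame, lengths: pd.Series) -> NormalizedExpression:
    """Gene-length-corrected TMM expression.

    RPK = count / (length in kb); TMM factors are computed on the RPK matrix
    and values are CPM-scaled: RPK / (RPK library size x factor) x 1e6.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("missing gene lengths")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rpk = counts.div(lengths / 1000.0, axis=0)
    factors = tmm_norm_factors(rpk)
    lib = rpk.sum(axis=0)
    values = rpk.div(lib * factors, axis=1) * 1e6
    return NormalizedExpression(values=values, tmm_factors=factors, library_sizes=lib)


def region_fraction(values: pd.DataFrame, region_ids: list[str]) -> float:
    """Percent of total normalised expression attributed to ``region_ids``."""
    missing = [r for r in region_ids if r not in values.index]
    if missing:
        raise KeyError(f"unknown region ids: {missing}")
    return float(100.0 * values.loc[region_ids].to_numpy().sum()
                 / values.to_numpy().sum())


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (via statsmodels)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def _mom_common_dispersion(adj: np.ndarray, groups: list[np.ndarray]) -> float:
    """Method-of-moments common NB dispersion on library-equalised counts."""
    phis = []
    for idx in groups:
        if idx.size < 2:
            continue
        sub = adj[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        phis.append(((v[ok] - m[ok]) / m[ok] ** 2))
    if not phis:
        return 1e-8
    allphi = np.concatenate(phis)
    allphi = allphi[np.isfinite(allphi)]
    if allphi.size == 0:
        return 1e-8
    return float(max(np.median(allphi), 1e-8))


def _nb_exact_pvalue(sa: float, sb: float, na: int, nb: int, phi: float) -> float:
    """Two-sided conditional NB exact test for group sums ``sa`` vs ``sb``.

    Conditions on the total s = sa + sb: under the null each group sum is NB
    with size n_g/phi and a common mean per sample, so P(Ya = y | s) is the
    normalised product of the two NB kernels. The p-value sums probabilities
    no larger than the observed one (edgeR-exact-test style).
    """
    s = int(round(sa + sb))
    ya = int(round(sa))
    if s == 0:
        return 1.0
    ra, rb = na / phi, nb / phi
    y = np.arange(s + 1)
    logp = (
        gammaln(y + ra) - gammaln(y + 1)
        + gammaln(s - y + rb) - gammaln(s - y + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return float(min(1.0, p[p <= p[ya] * (1 + 1e-12)].sum()))


def differential(
    counts: pd.DataFrame,
    group_a: list,
    group_b: list,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Two-group NB differential expression with BH adjustment.

    Counts are TMM-normalised and scaled to a common effective library size;
    a common method-of-moments dispersion feeds a conditional NB exact test
    per gene (Poisson-limit fallback when no group has replicates). Returns a
    frame with log2 fold change (b vs a), p-value, BH FDR and a significance
    flag at ``fdr_threshold``.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    cols = list(group_a) + list(group_b)
    sub = counts[cols]
    expressed = sub.sum(axis=1) > 0
    x = sub.loc[expressed].to_numpy(dtype=float)
    factors = tmm_norm_factors(sub.loc[expressed]).to_numpy()
    eff_lib = x.sum(axis=0) * factors
    target = np.exp(np.mean(np.log(eff_lib)))
    adj = x * (target / eff_lib)[None, :]
    ia = np.arange(len(group_a))
    ib = np.arange(len(group_a), len(cols))
    phi = _mom_common_dispersion(adj, [ia, ib])
    mean_a = adj[:, ia].mean(axis=1)
    mean_b = adj[:, ib].mean(axis=1)
    logfc = np.log2((mean_b + 0.5) / (mean_a + 0.5))
    pvals = np.array(
        [
            _nb_exact_pvalue(
                adj[g, ia].sum(), adj[g, ib].sum(), ia.size, ib.size, phi
            )
            for g in range(adj.shape[0])
        ]
    )
    fdr = benjamini_hochberg(pvals)
    out = pd.DataFrame(
        {
            "logFC": pd.Series(logfc, index=sub.index[expressed]),
            "pvalue": pd.Series(pvals, index=sub.index[expressed]),
            "fdr": pd.Series(fdr, index=sub.index[expressed]),
        }
    ).reindex(counts.index)
    out["pvalue"] = out["pvalue"].fillna(1.0)
    out["fdr"] = out["fdr"].fillna(1.0)
    out["logFC"] = out["logFC"].fillna(0.0)
    out["significant"] = out["fdr"] <= fdr_threshold
    out.attrs["common_dispersion"] = phi
    return out


def temporal_profile(
    values: tuple[float, float, float],
    significant_up: bool,
    late_floor: float,
    expr_floor: float = 5.0,
) -> str:
    """Temporal class of one gene from its per-timepoint mean expression.

    Late-expressed when significantly up at the last timepoint starting from
    below ``late_floor``; otherwise early-expressed when already expressed at
    the first timepoint (at or above ``expr_floor``); flat otherwise.
    """
    t1 = values[0]
    if significant_up and t1 < late_floor:
        return "late-expressed"
    if t1 >= expr_floor:
        return "early-expressed"
    return "flat"


def temporal_classes(
    counts: pd.DataFrame,
    lengths: pd.Series,
    early_timepoints: tuple[str, ...] = ("t5", "t15"),
    late_timepoint: str = "t30",
    min_expr: float = 5.0,
    floor_quantile: float = 0.25,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Classify every gene as early-expressed / late-expressed / flat.

    Counts carry MultiIndex columns (timepoint, replicate). Late-vs-pooled-
    early differential expression supplies the significance; the first-
    timepoint expression floor is the larger of ``min_expr`` and the
    ``floor_quantile`` quantile of first-timepoint means.
    """
    norm = getmm(counts, lengths)
    tp_means = norm.values.T.groupby(level=0).mean().T
    t1 = early_timepoints[0]
    late_floor = max(min_expr, float(tp_means[t1].quantile(floor_quantile)))
    early_cols = [c for c in counts.columns if c[0] in early_timepoints]
    late_cols = [c for c in counts.columns if c[0] == late_timepoint]
    de = differential(counts, early_cols, late_cols, fdr_threshold)
    sig_up = de["significant"] & (de["logFC"] > 0)
    classes = [
        temporal_profile(
            tuple(tp_means.loc[g]), bool(sig_up.loc[g]), late_floor, min_expr
        )
        for g in counts.index
    ]
    out = pd.DataFrame(
        {
            "temporal_class": classes,
            "logFC_late_vs_early": de["logFC"],
            "fdr": de["fdr"],
        },
        index=counts.index,
    )
    out = out.join(tp_means)
    return out
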