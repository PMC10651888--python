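"""Negative-binomial differential enrichment and transcript classification.

The proximity-labeling design supports three contrasts per condition:

1. post- vs pre-streptavidin enrichment (bait-fused line, +PA);
2. +PA vs omit-probe (bait-fused line, post-enrichment);
3. bait-fused vs untargeted photocatalyst (+PA, post-enrichment).

A transcript is called SG/G3BP1-proximal when it is significantly enriched
(log2FC > fc_threshold, BH-adjusted p < alpha, strict inequalities) in all
three contrasts, and SG-excluded when significantly depleted
(log2FC < -fc_threshold, padj < alpha) in contrasts 1 and 3.

The per-contrast test is a documented NB Wald approximation: median-of-ratios
size factors, method-of-moments dispersions shrunk toward a mean-dispersion
trend, group means on the normalized scale, and a Wald statistic whose
standard error comes from the observed Fisher information of the NB log-link
model.  No independent filtering, fold-change shrinkage or outlier handling
is applied; externally produced contrast tables can be supplied instead via
`read_contrast_table`.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import (
    CountMatrix,
    DesignError,
    FormatError,
    NormalizationError,
    RunConfig,
)

logger = logging.getLogger("sgcap")

#: the three canonical contrasts as (group_A predicate, group_B predicate)
STANDARD_CONTRASTS: dict[str, tuple[dict[str, str], dict[str, str]]] = {
    "post_vs_pre": (
        {"bait": "targeted", "probe": "PA", "fraction": "post"},
        {"bait": "targeted", "probe": "PA", "fraction": "pre"},
    ),
    "pa_vs_nopa": (
        {"bait": "targeted", "probe": "PA", "fraction": "post"},
        {"bait": "targeted", "probe": "noPA", "fraction": "post"},
    ),
    "targeted_vs_untargeted": (
        {"bait": "targeted", "probe": "PA", "fraction": "post"},
        {"bait": "untargeted", "probe": "PA", "fraction": "post"},
    ),
}

MIN_DISPERSION = 1e-8


# ---------------------------------------------------------------------------
# Normalization and dispersion
# ---------------------------------------------------------------------------

def estimate_size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample, the factor is the median over reference genes of
    count / geometric-mean, where the reference excludes genes with any zero
    count (their geometric mean is zero).
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = mat.to_numpy(dtype=float)
    nonzero = (arr > 0).all(axis=1)
    if not nonzero.any():
        raise NormalizationError(
            "no gene has nonzero counts in every sample; cannot normalize")
    log_ref = np.log(arr[nonzero])
    log_geo = log_ref.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_ref - log_geo, axis=0))
    return pd.Series(factors, index=mat.columns, name="size_factor")


def estimate_dispersions(counts: CountMatrix | pd.DataFrame,
                         factors: pd.Series,
                         groups: Sequence | None = None) -> pd.Series:
    """Per-gene dispersion: moment estimate shrunk toward a fitted trend.

    The raw moment estimate on normalized counts is (s^2 - m) / m^2; with a
    grouping factor, s^2 is the pooled within-group variance so condition
    effects do not inflate it.  A trend a0/m + a1 is fitted across the genes
    with positive raw estimates by least squares, and the final value is the
    geometric mean of the raw estimate and the trend.  A gene whose raw
    estimate is non-positive (sub-Poisson sample variance) carries no
    information about a positive dispersion and falls back to the trend;
    this keeps the Wald test near-nominal at small replicate numbers.  The
    result is floored at 1e-8.  With fewer than 2 replicates in every group
    the trend alone is used (logged).
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    norm = mat.to_numpy(dtype=float) / factors.loc[mat.columns].to_numpy()

    m = norm.mean(axis=1)
    if groups is None:
        groups = np.zeros(norm.shape[1], dtype=int)
    groups = np.asarray(groups)
    ss = np.zeros(norm.shape[0])
    dof = 0
    for g in np.unique(groups):
        sub = norm[:, groups == g]
        if sub.shape[1] >= 2:
            ss += sub.shape[1] * sub.var(axis=1, ddof=0)
            dof += sub.shape[1] - 1
    if dof < 1:
        logger.warning("single replicate per group: using trend-only dispersions")
        s2 = None
    else:
        s2 = ss / dof

    with np.errstate(divide="ignore", invalid="ignore"):
        if s2 is None:
            d_raw = np.full_like(m, np.nan)
        else:
            d_raw = (s2 - m) / np.where(m > 0, m, np.nan) ** 2
    d_raw = np.where(np.isfinite(d_raw), d_raw, np.nan)

    # trend d ~ a0/m + a1 over genes with informative (positive) moments
    ok = np.isfinite(d_raw) & (d_raw > 0) & (m > 0)
    if ok.sum() >= 2 and s2 is not None:
        X = np.column_stack([1.0 / m[ok], np.ones(int(ok.sum()))])
        coef, *_ = np.linalg.lstsq(X, d_raw[ok], rcond=None)
        a0, a1 = coef
    else:
        med = np.nanmedian(d_raw)
        a0, a1 = 0.0, med if np.isfinite(med) and med > 0 else 0.1
    with np.errstate(divide="ignore"):
        trend = np.where(m > 0, a0 / np.where(m > 0, m, np.nan) + a1, np.nan)
    trend = np.maximum(np.where(np.isfinite(trend), trend, MIN_DISPERSION),
                       MIN_DISPERSION)

    if s2 is None:
        final = trend
    else:
        shrunk = np.exp(0.5 * np.log(np.where(ok, d_raw, 1.0))
                        + 0.5 * np.log(trend))
        final = np.where(ok, shrunk, trend)
        final = np.where(np.isfinite(final), final, trend)
    return pd.Series(np.maximum(final, MIN_DISPERSION), index=mat.index,
                     name="dispersion")


# ---------------------------------------------------------------------------
# Contrast testing
# ---------------------------------------------------------------------------

def _match(samples: pd.DataFrame, predicate: Mapping[str, str]) -> np.ndarray:
    mask = np.ones(len(samples), dtype=bool)
    for col, val in predicate.items():
        mask &= (samples[col] == val).to_numpy()
    return mask


def test_contrast(counts: CountMatrix,
                  contrast: str | tuple[Mapping[str, str], Mapping[str, str]],
                  factors: pd.Series | None = None,
                  dispersions: pd.Series | None = None) -> pd.DataFrame:
    """Two-group NB Wald test for one contrast.

    contrast : a key of STANDARD_CONTRASTS or a (predicate_A, predicate_B)
        pair of metadata filters; group A is the numerator.

    Returns a contrast table indexed by gene with columns baseMean, log2fc,
    se, pvalue, padj, tested.  Genes with zero counts in every sample of both
    groups are marked untested (pvalue/padj NaN).  The fold change is the
    ratio of size-factor-weighted group means of normalized counts, with a
    0.5 pseudo-offset applied only when a group mean is exactly zero (never
    inside the likelihood).
    """
    if isinstance(contrast, str):
        try:
            pred_a, pred_b = STANDARD_CONTRASTS[contrast]
        except KeyError as exc:
            raise DesignError(f"unknown contrast '{contrast}'; expected one of "
                              f"{sorted(STANDARD_CONTRASTS)}") from exc
    else:
        pred_a, pred_b = contrast

    mask_a = _match(counts.samples, pred_a)
    mask_b = _match(counts.samples, pred_b)
    if not mask_a.any() or not mask_b.any():
        raise DesignError("contrast group is empty under the given predicates")
    if (mask_a & mask_b).any():
        raise DesignError("contrast groups overlap")

    sub = counts.subset_samples(mask_a | mask_b)
    in_a = _match(sub.samples, pred_a)

    if factors is None:
        factors = estimate_size_factors(sub)
    factors = factors.loc[sub.counts.columns]
    if dispersions is None:
        dispersions = estimate_dispersions(sub, factors, groups=in_a.astype(int))
    dispersions = dispersions.loc[sub.counts.index]

    k = sub.counts.to_numpy(dtype=float)
    sf = factors.to_numpy()
    d = dispersions.to_numpy()

    ka, kb = k[:, in_a], k[:, ~in_a]
    sfa, sfb = sf[in_a], sf[~in_a]

    # weighted group means on the normalized scale (MLE under Poisson, the
    # standard plug-in for the NB mean)
    qa = ka.sum(axis=1) / sfa.sum()
    qb = kb.sum(axis=1) / sfb.sum()
    base_mean = (k / sf).mean(axis=1)

    tested = (ka.sum(axis=1) + kb.sum(axis=1)) > 0

    qa_fc = np.where(qa > 0, qa, 0.5 / sfa.sum())
    qb_fc = np.where(qb > 0, qb, 0.5 / sfb.sum())
    log2fc = np.log2(qa_fc / qb_fc)

    # observed Fisher information of beta = log q under NB with fixed d:
    # I = sum_s mu_s / (1 + d mu_s), mu_s = sf_s * q
    def info(q: np.ndarray, sf_g: np.ndarray) -> np.ndarray:
        mu = q[:, None] * sf_g[None, :]
        return (mu / (1.0 + d[:, None] * mu)).sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        ia = info(qa, sfa)
        ib = info(qb, sfb)
        var_log = np.where(ia > 0, 1.0 / ia, np.inf) + \
            np.where(ib > 0, 1.0 / ib, np.inf)
    se = np.sqrt(var_log) / np.log(2.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(np.isfinite(se) & (se > 0), log2fc / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    pvalue = np.where(tested, pvalue, np.nan)
    log2fc = np.where(tested, log2fc, np.nan)

    table = pd.DataFrame({
        "baseMean": base_mean,
        "log2fc": log2fc,
        "se": np.where(tested, se, np.nan),
        "pvalue": pvalue,
        "tested": tested,
    }, index=sub.counts.index)
    table["padj"] = np.nan
    table.loc[tested, "padj"] = bh_adjust(table.loc[tested, "pvalue"].to_numpy())
    return table


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment over the tested genes.

    NaN entries are excluded from the family size m and returned as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise FormatError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def read_contrast_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read an externally produced contrast table (e.g. a DESeq2 export).

    Requires columns gene_id (or first column as index), log2fc and padj;
    tolerates DESeq2-style column names.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    rename = {"log2FoldChange": "log2fc", "pvalue": "pvalue", "pval": "pvalue",
              "p_adj": "padj", "FDR": "padj"}
    df = df.rename(columns=rename)
    first = df.columns[0]
    if first.lower() in ("gene_id", "gene", "id", "row", "unnamed: 0"):
        df = df.set_index(first)
        df.index.name = "gene_id"
    missing = {"log2fc", "padj"} - set(df.columns)
    if missing:
        raise FormatError(f"contrast table {path} lacks columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class ClassifiedTranscriptome:
    """Result of the three-contrast proximal/excluded classification."""

    proximal: frozenset[str]
    excluded: frozenset[str]
    enriched: dict[str, frozenset[str]]
    depleted: dict[str, frozenset[str]]
    fc_threshold: float
    alpha: float

    def __post_init__(self) -> None:
        assert not (self.proximal & self.excluded)


def significant_sets(table: pd.DataFrame, fc_threshold: float,
                     alpha: float) -> tuple[frozenset[str], frozenset[str]]:
    """(enriched, depleted) gene sets at strict thresholds.

    Missing padj never passes.
    """
    fc = table["log2fc"]
    padj = table["padj"]
    sig = padj.notna() & (padj < alpha)
    enriched = frozenset(table.index[sig & (fc > fc_threshold)])
    depleted = frozenset(table.index[sig & (fc < -fc_threshold)])
    return enriched, depleted


def classify_transcriptome(c1: pd.DataFrame, c2: pd.DataFrame | None,
                           c3: pd.DataFrame,
                           config: RunConfig | None = None,
                           allow_two_contrasts: bool = False
                           ) -> ClassifiedTranscriptome:
    """Classify transcripts from the three contrast tables.

    c1 = post-vs-pre, c2 = +PA-vs-omit-probe, c3 = targeted-vs-untargeted.
    proximal = intersection of the three enriched sets; excluded =
    intersection of the depleted sets of c1 and c3.  A two-contrast mode
    (c2 None) must be requested explicitly.
    """
    if config is None:
        config = RunConfig()
    if c2 is None and not allow_two_contrasts:
        raise DesignError("three contrast tables are required for the proximal "
                          "call (pass allow_two_contrasts=True to override)")
    tau, alpha = config.fc_threshold, config.alpha
    e1, d1 = significant_sets(c1, tau, alpha)
    e3, d3 = significant_sets(c3, tau, alpha)
    enriched = {"post_vs_pre": e1, "targeted_vs_untargeted": e3}
    depleted = {"post_vs_pre": d1, "targeted_vs_untargeted": d3}
    if c2 is not None:
        e2, d2 = significant_sets(c2, tau, alpha)
        enriched["pa_vs_nopa"] = e2
        depleted["pa_vs_nopa"] = d2
        proximal = e1 & e2 & e3
    else:
        proximal = e1 & e3
    excluded = d1 & d3
    return ClassifiedTranscriptome(
        proximal=frozenset(proximal), excluded=frozenset(excluded),
        enriched=enriched, depleted=depleted,
        fc_threshold=tau, alpha=alpha)
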