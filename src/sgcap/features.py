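"""Per-gene RNA features and between-set statistical comparisons.

For each gene the representative (longest) isoform contributes region lengths
(5'UTR / CDS / 3'UTR and total spliced length), AU content per region, m6A
site count and density (sites per kilobase of transcript), and translation
efficiency (log2 RPF/RNA, from an external table).  Sets of genes are
compared feature-by-feature with the unpaired two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import AnnotationError, GeneSetTable, SgcapError, TranscriptModel

logger = logging.getLogger("sgcap")


class EmptyGroupError(SgcapError):
    """A comparison group is empty after missing-value removal."""


# ---------------------------------------------------------------------------
# Representative isoform and per-transcript metrics
# ---------------------------------------------------------------------------

def select_longest_isoform(models: Mapping[str, TranscriptModel]
                           ) -> dict[str, TranscriptModel]:
    """Pick each gene's longest isoform (total spliced length).

    Ties break to the lexicographically smallest transcript id.
    """
    best: dict[str, TranscriptModel] = {}
    for tid in sorted(models):
        tm = models[tid]
        cur = best.get(tm.gene_id)
        if cur is None or tm.len_total > cur.len_total:
            best[tm.gene_id] = tm
    return best


def au_fraction(seq: str) -> float:
    """AU fraction among unambiguous bases; NaN for empty/fully ambiguous."""
    seq = seq.upper().replace("T", "U")
    au = seq.count("A") + seq.count("U")
    gc = seq.count("G") + seq.count("C")
    if au + gc == 0:
        return float("nan")
    return au / (au + gc)


def region_metrics(model: TranscriptModel) -> dict[str, float]:
    """Lengths and AU fractions of the transcript and its three regions."""
    return {
        "len_total": model.len_total,
        "len_utr5": model.len_utr5,
        "len_cds": model.len_cds,
        "len_utr3": model.len_utr3,
        "au_total": au_fraction(model.seq_full),
        "au_utr5": au_fraction(model.seq_utr5),
        "au_cds": au_fraction(model.seq_cds),
        "au_utr3": au_fraction(model.seq_utr3),
    }


def m6a_metrics(gene_id: str, sites: Mapping[str, Sequence[int]],
                len_total: int) -> dict[str, float]:
    """m6A site count and density (per kilobase of transcript)."""
    count = len(sites.get(gene_id, ()))
    if len_total <= 0:
        if count > 0:
            raise AnnotationError(
                f"gene {gene_id}: {count} m6A sites but zero transcript length")
        return {"m6a_count": 0, "m6a_density": float("nan")}
    return {"m6a_count": count, "m6a_density": 1000.0 * count / len_total}


def compute_feature_table(models: Mapping[str, TranscriptModel],
                          m6a_sites: Mapping[str, Sequence[int]] | None = None,
                          te: Mapping[str, float] | None = None
                          ) -> pd.DataFrame:
    """Build the per-gene feature table from the representative isoforms."""
    reps = select_longest_isoform(models)
    rows = []
    for gid, tm in sorted(reps.items()):
        row: dict[str, object] = {"gene_id": gid, "transcript_id": tm.transcript_id}
        row.update(region_metrics(tm))
        row.update(m6a_metrics(gid, m6a_sites or {}, tm.len_total))
        rows.append(row)
    table = pd.DataFrame(rows).set_index("gene_id")
    return attach_te(table, te or {})


def attach_te(features: pd.DataFrame, te_table: Mapping[str, float]
              ) -> pd.DataFrame:
    """Attach translation efficiency; genes absent from the table stay NaN."""
    features = features.copy()
    features["te"] = [te_table.get(g, np.nan) for g in features.index]
    return features


# ---------------------------------------------------------------------------
# Mann-Whitney comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Two-group Mann-Whitney comparison summary."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    u_statistic: float
    pvalue: float
    method: str  # "exact" | "normal-approx"

    @property
    def stars(self) -> str:
        p = self.pvalue
        if p < 1e-4:
            return "****"
        if p < 1e-3:
            return "***"
        if p < 1e-2:
            return "**"
        if p < 0.05:
            return "*"
        return "ns"


def compare_feature(set_a: Sequence[float], set_b: Sequence[float],
                    label_a: str = "A", label_b: str = "B"
                    ) -> ComparisonResult:
    """Unpaired two-sided Mann-Whitney U test between two value sets.

    U counts pairs with a > b plus half-ties.  The exact null distribution is
    used when min(n_a, n_b) <= 8 and there are no ties; otherwise the normal
    approximation with tie and continuity correction.  Missing values are
    dropped first.
    """
    a = np.asarray(set_a, dtype=float)
    b = np.asarray(set_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise EmptyGroupError("empty group after missing-value removal")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    exact = min(len(a), len(b)) <= 8 and not has_ties
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=True)
    return ComparisonResult(
        label_a=label_a, label_b=label_b, n_a=len(a), n_b=len(b),
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        u_statistic=float(res.statistic), pvalue=float(min(res.pvalue, 1.0)),
        method="exact" if exact else "normal-approx")


def compare_sets_features(features: pd.DataFrame,
                          sets: Mapping[str, GeneSetTable],
                          columns: Sequence[str] | None = None
                          ) -> pd.DataFrame:
    """All pairwise Mann-Whitney comparisons of feature columns between sets."""
    if columns is None:
        columns = [c for c in features.columns
                   if features[c].dtype.kind in "if"]
    names = list(sets)
    rows = []
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            ga = features.index.intersection(list(sets[na].members))
            gb = features.index.intersection(list(sets[nb].members))
            for col in columns:
                va = features.loc[ga, col].to_numpy(dtype=float)
                vb = features.loc[gb, col].to_numpy(dtype=float)
                try:
                    r = compare_feature(va, vb, na, nb)
                except EmptyGroupError:
                    logger.warning("comparison %s vs %s on %s skipped: empty group",
                                   na, nb, col)
                    continue
                rows.append({"feature": col, "set_a": na, "set_b": nb,
                             "n_a": r.n_a, "n_b": r.n_b,
                             "median_a": r.median_a, "median_b": r.median_b,
                             "U": r.u_statistic, "pvalue": r.pvalue,
                             "stars": r.stars, "method": r.method})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# m6A proportion table
# ---------------------------------------------------------------------------

DEFAULT_M6A_BINS: tuple[tuple[int, float], ...] = (
    (0, 0), (1, 2), (3, 5), (6, float("inf")))


def m6a_proportion_table(sets: Mapping[str, GeneSetTable],
                         features: pd.DataFrame,
                         bins: Sequence[tuple[int, float]] = DEFAULT_M6A_BINS
                         ) -> pd.DataFrame:
    """Per-set proportions of genes in m6A-count bins plus mean sites per RNA.

    bins : inclusive (lo, hi) count ranges covering [0, inf).  Set members
    absent from the feature table are excluded (logged).
    """
    rows = []
    for name, gs in sets.items():
        present = features.index.intersection(list(gs.members))
        absent = len(gs.members) - len(present)
        if absent:
            logger.warning("set '%s': %d members absent from feature table",
                           name, absent)
        counts = features.loc[present, "m6a_count"].to_numpy(dtype=float)
        row: dict[str, object] = {"set": name, "n": len(counts)}
        for lo, hi in bins:
            label = f"{lo}" if lo == hi else (
                f">={lo}" if np.isinf(hi) else f"{lo}-{int(hi)}")
            row[label] = float(np.mean((counts >= lo) & (counts <= hi))) \
                if len(counts) else np.nan
        row["mean_sites_per_rna"] = float(np.mean(counts)) if len(counts) else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("set")
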