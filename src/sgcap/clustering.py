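"""Kinetic clustering of log2FC trajectories across SG-disassembly timepoints.

Genes proximal to the bait at any of T0 (stress endpoint), T1 (1 h recovery)
or T3 (3 h recovery) form the trajectory matrix, holding each timepoint's
targeted-vs-untargeted log2 fold change.  Rows are z-scored, clustered by
complete-linkage agglomeration on Euclidean distances, and the tree is cut
into k clusters (k = 4 for the study's four kinetic classes), renumbered by
descending mean T0 value so cluster 1 is the most stress-enriched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io_core import EmptyInputError, GeneSetTable, SgcapError
from .features import compare_sets_features

logger = logging.getLogger("sgcap")

TIMEPOINTS = ("T0", "T1", "T3")


@dataclass
class TrajectoryMatrix:
    """genes x (T0, T1, T3) log2FC values with membership/imputation flags."""

    values: pd.DataFrame
    membership: pd.DataFrame  # gene x timepoint bool: in that timepoint's list
    imputed: pd.DataFrame     # gene x timepoint bool: untested, set to 0
    scaled: bool = False


@dataclass
class ClusterAssignment:
    """gene -> 1..k cluster labels plus the agglomeration tree."""

    labels: pd.Series
    linkage: np.ndarray
    k: int

    def members(self, cluster: int) -> frozenset[str]:
        return frozenset(self.labels.index[self.labels == cluster])

    def sets(self) -> dict[str, GeneSetTable]:
        return {f"cluster{c}": GeneSetTable(f"cluster{c}", self.members(c))
                for c in range(1, self.k + 1)}


def build_fc_matrix(tables: Mapping[str, pd.DataFrame],
                    membership: Mapping[str, GeneSetTable]
                    ) -> TrajectoryMatrix:
    """Assemble the trajectory matrix over the union of per-timepoint lists.

    Each cell holds that timepoint's log2fc from its contrast table; genes
    untested (absent or NaN) at a timepoint are imputed as 0 and flagged.
    """
    missing_tp = [tp for tp in TIMEPOINTS if tp not in tables]
    if missing_tp:
        raise SgcapError(f"missing contrast tables for timepoints {missing_tp}")
    union: set[str] = set()
    for tp in TIMEPOINTS:
        union |= set(membership[tp].members)
    if not union:
        raise EmptyInputError("union of timepoint membership lists is empty")
    genes = sorted(union)

    vals = pd.DataFrame(0.0, index=genes, columns=list(TIMEPOINTS))
    member = pd.DataFrame(False, index=genes, columns=list(TIMEPOINTS))
    imputed = pd.DataFrame(False, index=genes, columns=list(TIMEPOINTS))
    for tp in TIMEPOINTS:
        tab = tables[tp]
        fc = tab["log2fc"]
        present = fc.reindex(genes)
        ok = present.notna()
        vals.loc[ok, tp] = present[ok]
        imputed[tp] = ~ok.to_numpy()
        member[tp] = [g in membership[tp].members for g in genes]
    n_imputed = int(imputed.to_numpy().sum())
    if n_imputed:
        logger.info("trajectory matrix: %d gene-timepoint cells imputed as 0",
                    n_imputed)
    return TrajectoryMatrix(vals, member, imputed)


def _zscore_rows(mat: np.ndarray) -> np.ndarray:
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    out = np.where(sd > 0, (mat - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return out


def cluster_rows(matrix: TrajectoryMatrix, k: int = 4) -> ClusterAssignment:
    """Complete-linkage clustering of z-scored trajectories into k clusters.

    Rows are z-scored (sample SD; constant rows become all-zero), distances
    are Euclidean, and the tree is cut after exactly n-k merges so exactly k
    clusters result even under tied merge heights.  Clusters are renumbered
    1..k by descending mean (unscaled) T0 value.
    """
    n = len(matrix.values)
    if n < k:
        raise SgcapError(f"cannot form {k} clusters from {n} rows")
    z = _zscore_rows(matrix.values.to_numpy(dtype=float))
    link = hierarchy.linkage(z, method="complete", metric="euclidean")
    # cut after exactly n-k merges: robust to tied merge heights
    raw = hierarchy.cut_tree(link, n_clusters=k).ravel()
    labels = pd.Series(raw, index=matrix.values.index)
    order = (matrix.values["T0"].groupby(labels).mean()
             .sort_values(ascending=False).index)
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = labels.map(remap)
    return ClusterAssignment(labels=labels, linkage=link, k=k)


def summarize_clusters(assignment: ClusterAssignment,
                       features: pd.DataFrame,
                       columns: Sequence[str] | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster medians of the feature columns plus pairwise U tests."""
    if columns is None:
        columns = [c for c in ("te", "au_utr5", "au_cds", "au_utr3", "au_total",
                               "len_utr5", "len_cds", "len_utr3", "len_total",
                               "m6a_count", "m6a_density")
                   if c in features.columns]
    sets = assignment.sets()
    rows = []
    for name, gs in sets.items():
        present = features.index.intersection(list(gs.members))
        row: dict[str, object] = {"cluster": name, "n_genes": len(gs),
                                  "n_annotated": len(present)}
        if len(present) == 0:
            logger.warning("cluster %s has no feature-annotated member", name)
            row.update({c: np.nan for c in columns})
        else:
            for c in columns:
                row[c] = float(features.loc[present, c].median())
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("cluster")
    pairwise = compare_sets_features(features, sets, columns=columns)
    return summary, pairwise
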