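"""Gene-set algebra, condition categories, and hypergeometric overlap tests.

The study's comparative analyses are all set-level: stress-specific vs
stress-independent SG transcripts (two-condition comparison), basal-specific
vs pre-existing vs de novo G3BP1-proximal transcripts (basal vs a collection
of stress sets), cell-type sharing, and overlap significance by the
hypergeometric upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io_core import EmptyInputError, GeneSetTable, UniverseError


@dataclass
class VennReport:
    """Region cardinalities of a set comparison plus overlap significance."""

    regions: dict[str, int]
    percentages: dict[str, float]
    universe_size: int | None = None
    hypergeom_p: float | None = None

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())


@dataclass
class CategoryAssignment:
    """gene -> category label; labels partition the union of the inputs."""

    labels: dict[str, str]
    categories: tuple[str, ...]
    extras: dict[str, int] = field(default_factory=dict)

    def members(self, category: str) -> frozenset[str]:
        return frozenset(g for g, c in self.labels.items() if c == category)

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in self.categories}
        for c in self.labels.values():
            out[c] += 1
        return out


def set_algebra(a: GeneSetTable, b: GeneSetTable, op: str) -> GeneSetTable:
    """Exact set semantics; result members are a frozenset (render sorted)."""
    ops = {
        "intersect": a.members & b.members,
        "union": a.members | b.members,
        "diff": a.members - b.members,
        "symdiff": a.members ^ b.members,
    }
    if op not in ops:
        raise ValueError(f"unknown op '{op}'; expected one of {sorted(ops)}")
    return GeneSetTable(f"{a.name}_{op}_{b.name}", frozenset(ops[op]))


def compare_two_conditions(a: GeneSetTable, b: GeneSetTable,
                           universe: frozenset[str] | None = None
                           ) -> tuple[CategoryAssignment, VennReport]:
    """Partition A union B into {A-specific, shared, B-specific}.

    Percentages are relative to |A union B|, reported to one decimal.  When a
    universe is given the shared count is tested with the hypergeometric
    upper tail.
    """
    if not a.members and not b.members:
        raise EmptyInputError("both gene sets are empty")
    shared = a.members & b.members
    only_a = a.members - b.members
    only_b = b.members - a.members
    union = len(shared) + len(only_a) + len(only_b)
    labels: dict[str, str] = {}
    for g in only_a:
        labels[g] = f"{a.name}-specific"
    for g in shared:
        labels[g] = "shared"
    for g in only_b:
        labels[g] = f"{b.name}-specific"
    regions = {f"{a.name}-specific": len(only_a), "shared": len(shared),
               f"{b.name}-specific": len(only_b)}
    pct = {k: round(100.0 * v / union, 1) for k, v in regions.items()}
    p = None
    if universe is not None:
        p = hypergeom_overlap_test(a, b, universe)
    assignment = CategoryAssignment(
        labels, (f"{a.name}-specific", "shared", f"{b.name}-specific"))
    report = VennReport(regions, pct,
                        universe_size=len(universe) if universe else None,
                        hypergeom_p=p)
    return assignment, report


def categorize_basal_stress(basal: GeneSetTable,
                            stress_sets: Sequence[GeneSetTable]
                            ) -> CategoryAssignment:
    """Split basal vs stressed G3BP1-proximal transcripts into three classes.

    basal-specific = basal minus every stress set (proximal only without
    stress); pre-existing = basal that stays SG-proximal under at least one
    stress; de novo = stress-only.  The sub-counts present in ALL stress sets
    are reported for the pre-existing and de novo classes.
    """
    if not stress_sets:
        raise ValueError("need at least one stress set")
    stress_union: frozenset[str] = frozenset().union(
        *(s.members for s in stress_sets))
    stress_common: frozenset[str] = frozenset(stress_sets[0].members)
    for s in stress_sets[1:]:
        stress_common &= s.members

    basal_specific = basal.members - stress_union
    pre_existing = basal.members & stress_union
    de_novo = stress_union - basal.members
    labels: dict[str, str] = {}
    for g in basal_specific:
        labels[g] = "basal-specific"
    for g in pre_existing:
        labels[g] = "pre-existing"
    for g in de_novo:
        labels[g] = "de-novo"
    extras = {
        "pre_existing_all_stresses": len(pre_existing & stress_common),
        "de_novo_all_stresses": len(de_novo & stress_common),
    }
    return CategoryAssignment(labels, ("basal-specific", "pre-existing",
                                       "de-novo"), extras=extras)


def hypergeom_overlap_test(a: GeneSetTable, b: GeneSetTable,
                           universe: Iterable[str]) -> float:
    """Upper-tail hypergeometric p of the observed overlap.

    P(X >= |A & B|) with X ~ Hypergeom(N=|universe|, K=|A|, n=|B|), exact
    tail.  Both sets must be contained in the universe.
    """
    uni = frozenset(universe)
    stray = (a.members | b.members) - uni
    if stray:
        raise UniverseError(f"members outside universe: {sorted(stray)[:5]}")
    overlap = len(a.members & b.members)
    # sf(k-1) = P(X >= k), exact in scipy's hypergeom
    p = float(stats.hypergeom.sf(overlap - 1, len(uni), len(a.members),
                                 len(b.members)))
    return min(max(p, np.nextafter(0, 1)), 1.0)
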