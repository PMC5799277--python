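"""Correlation-based cluster classification of descriptor profiles.

Each query profile is compared with every labelled reference profile by the
Pearson correlation of their descriptor 4-vectors (loop %, external-loop %,
stem GC %, loop GC %); the query is assigned to the cluster of the
highest-r reference. Significance of a single comparison is declared at a
configurable correlation threshold (default r >= 0.95); p-values are
reported from the t-transform at df = 2 and can be adjusted across the run
by Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ConstantInputError, InputError
from .stats import bh_adjust, pearson_one_tailed
from .structures import StructureProfile

#: Correlation at or above which a single profile comparison is called
#: significantly similar (decision rule of the classification scheme).
DEFAULT_R_THRESHOLD = 0.95
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    """One query-vs-reference profile comparison."""

    query_label: str
    reference_label: str
    reference_cluster: str
    r: float
    p_one_tailed: float
    p_adjusted: float | None = None
    significant: bool = False
    comparable: bool = True
    reason: str = ""


@dataclass(frozen=True)
class ClusterAssignment:
    """Nearest-reference cluster call for one query."""

    query_label: str
    assigned_cluster: str
    best_reference_label: str
    best_r: float
    tied_references: tuple[str, ...] = ()
    per_cluster: dict = field(default_factory=dict)
    comparisons: tuple[ComparisonResult, ...] = ()
    reason: str = ""

    @property
    def assigned(self) -> bool:
        return self.assigned_cluster != "none"


def compare_profiles(query: StructureProfile, reference: StructureProfile,
                     *, alpha: float = DEFAULT_ALPHA,
                     r_threshold: float = DEFAULT_R_THRESHOLD
                     ) -> ComparisonResult:
    """Pearson r of the two descriptor 4-vectors with an upper-tail p at
    df = 2. Zero-variance vectors yield a flagged non-comparable result."""
    x = np.asarray(query.vector(), dtype=float)
    y = np.asarray(reference.vector(), dtype=float)
    try:
        r, p = pearson_one_tailed(x, y)
    except ConstantInputError:
        return ComparisonResult(
            query.label, reference.label, reference.cluster,
            float("nan"), float("nan"), comparable=False,
            reason="zero variance in a descriptor vector",
        )
    return ComparisonResult(
        query.label, reference.label, reference.cluster, r, p,
        significant=r >= r_threshold,
    )


def classify_structure(query: StructureProfile,
                       references: Sequence[StructureProfile],
                       *, alpha: float = DEFAULT_ALPHA,
                       r_threshold: float = DEFAULT_R_THRESHOLD
                       ) -> ClusterAssignment:
    """Assign a query to the cluster of its maximal-r reference.

    Ties in best r are broken by smaller p, then by reference order; all
    tied references are reported. If every comparison is non-comparable the
    result is unassigned with a reason.
    """
    if not references:
        raise InputError("reference set is empty")
    if any(ref.cluster in ("", "none") for ref in references):
        raise InputError("every reference needs a cluster label")
    comps = tuple(
        compare_profiles(query, ref, alpha=alpha, r_threshold=r_threshold)
        for ref in references
    )
    usable = [c for c in comps if c.comparable]
    per_cluster = _per_cluster_tally(usable, alpha)
    if not usable:
        return ClusterAssignment(
            query.label, "none", "", float("nan"), per_cluster=per_cluster,
            comparisons=comps, reason="all comparisons non-comparable",
        )
    best = min(usable, key=lambda c: (-c.r, c.p_one_tailed))
    ties = tuple(c.reference_label for c in usable if c.r == best.r)
    return ClusterAssignment(
        query.label, best.reference_cluster, best.reference_label, best.r,
        tied_references=ties, per_cluster=per_cluster, comparisons=comps,
    )


def _per_cluster_tally(comps: Sequence[ComparisonResult], alpha: float) -> dict:
    tally: dict[str, dict] = {}
    for c in comps:
        d = tally.setdefault(
            c.reference_cluster, {"comparisons": 0, "significant": 0}
        )
        d["comparisons"] += 1
        d["significant"] += int(c.p_one_tailed < alpha)
    for d in tally.values():
        d["fraction"] = (
            d["significant"] / d["comparisons"] if d["comparisons"] else 0.0
        )
    return tally


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-cluster comparison bookkeeping."""

    table: pd.DataFrame
    non_comparable: tuple[tuple[str, str], ...] = ()


def cluster_enrichment(queries: Sequence[StructureProfile],
                       references: Sequence[StructureProfile],
                       alpha: float = DEFAULT_ALPHA) -> EnrichmentResult:
    """Tally, per reference cluster, how many query-vs-reference
    comparisons were made and how many reached p < alpha.

    With q queries, a cluster of m members accumulates q x m comparisons.
    Non-comparable (zero-variance) pairs are excluded from the denominators
    and listed separately.
    """
    clusters = sorted({ref.cluster for ref in references})
    counts = {c: [0, 0] for c in clusters}
    skipped: list[tuple[str, str]] = []
    for q in queries:
        for ref in references:
            comp = compare_profiles(q, ref, alpha=alpha)
            if not comp.comparable:
                skipped.append((q.label, ref.label))
                continue
            counts[ref.cluster][0] += 1
            counts[ref.cluster][1] += int(comp.p_one_tailed < alpha)
    table = pd.DataFrame(
        {
            "cluster": clusters,
            "comparisons": [counts[c][0] for c in clusters],
            "significant": [counts[c][1] for c in clusters],
        }
    )
    denom = table["comparisons"].replace(0, 1)
    table["fraction"] = np.where(
        table["comparisons"] > 0, table["significant"] / denom, 0.0
    )
    return EnrichmentResult(table, tuple(skipped))


def classify_all(queries: Sequence[StructureProfile],
                 references: Sequence[StructureProfile],
                 *, alpha: float = DEFAULT_ALPHA,
                 r_threshold: float = DEFAULT_R_THRESHOLD,
                 bh: str = "global") -> tuple[list[ClusterAssignment], pd.DataFrame]:
    """Classify every query and BH-adjust the comparison p-values.

    ``bh='global'`` adjusts across the full query x reference matrix of the
    run (the conservative default); ``bh='per-query'`` adjusts within each
    query's comparisons.
    """
    if bh not in ("global", "per-query"):
        raise ConfigError(f"unknown bh family {bh!r}")
    assignments = [
        classify_structure(q, references, alpha=alpha, r_threshold=r_threshold)
        for q in queries
    ]
    rows = []
    for a in assignments:
        for c in a.comparisons:
            rows.append({
                "query": c.query_label, "reference": c.reference_label,
                "cluster": c.reference_cluster, "r": c.r,
                "p_one_tailed": c.p_one_tailed, "significant": c.significant,
                "comparable": c.comparable,
            })
    matrix = pd.DataFrame(rows)
    if not matrix.empty:
        adj = np.full(len(matrix), np.nan)
        if bh == "global":
            ok = matrix["comparable"].to_numpy()
            if ok.any():
                adj[ok] = bh_adjust(matrix.loc[ok, "p_one_tailed"])
        else:
            for _, idx in matrix.groupby("query").groups.items():
                sub = matrix.loc[idx]
                ok = sub["comparable"].to_numpy()
                if ok.any():
                    adj_idx = np.asarray(idx)[ok]
                    adj[[matrix.index.get_loc(i) for i in adj_idx]] = bh_adjust(
                        sub.loc[ok, "p_one_tailed"]
                    )
        matrix["p_adjusted"] = adj
    return assignments, matrix
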