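"""E/M/D classification of RBPs and functional units, and group summaries.

From the landscape's significant calls, every tested entity is assigned to
exactly one group: E (enrichments only), M (both enrichments and
depletions), D (depletions only) or none (no significant result).  RBPs
failing the promiscuity permutation control are reported as none with a
reason code rather than dropped, so the tested denominator always remains
reconstructable.  The module also computes the group-level summary
statistics (counts, means, lower-medians, group-to-group link tallies),
the one-sided Mann-Whitney burden comparisons between groups, and the
network of units sharing enriching RBPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .enrichment_core import DEPLETED, ENRICHED, LandscapeTable

GROUP_E = "E"
GROUP_M = "M"
GROUP_D = "D"
GROUP_NONE = "none"

FLAG_OK = "ok"
FLAG_FAILED_CONTROL = "failed control"


@dataclass(frozen=True)
class GroupAssignment:
    entity_id: str
    entity_kind: str  # "rbp" | "fu"
    group: str
    n_enriched: int
    n_depleted: int
    control_flag: str = FLAG_OK


@dataclass
class SharedRbpNetwork:
    """Units linked by the RBPs that call both of them enriched."""

    nodes: dict  # unit_id -> tag (e.g. disease / non-disease), possibly None
    edges: dict  # frozenset({unit_i, unit_j}) -> weight (shared RBP count)

    def edge_weight(self, unit_i: str, unit_j: str) -> int:
        return self.edges.get(frozenset((unit_i, unit_j)), 0)


@dataclass
class LandscapeSummary:
    """Group-level tallies of a classified landscape."""

    group_counts: dict  # kind -> {group: count}
    group_stats: dict  # (kind, group) -> {mean/median of n_enriched, n_depleted}
    link_counts: dict  # (rbp_group, fu_group, direction) -> record count
    frac_significant: dict  # kind -> fraction of tested entities with >=1 call
    n_tested: dict  # kind -> tested entities
    n_significant: dict  # kind -> entities with >=1 significant result


def _group_of(n_enr: int, n_dep: int) -> str:
    if n_enr >= 1 and n_dep == 0:
        return GROUP_E
    if n_enr >= 1 and n_dep >= 1:
        return GROUP_M
    if n_enr == 0 and n_dep >= 1:
        return GROUP_D
    return GROUP_NONE


def classify(
    landscape: LandscapeTable,
    verdicts: dict | None = None,
    kind: str = "rbp",
) -> list:
    """Assign each tested entity of the given kind to E/M/D/none.

    For ``kind="rbp"`` with verdicts supplied, RBPs that failed the
    permutation control are assigned none with control_flag
    "failed control" (their raw significant counts are preserved).
    """
    if kind not in ("rbp", "fu"):
        raise ValueError("kind must be 'rbp' or 'fu'")
    counts = landscape.counts_by(kind)
    out = []
    for entity_id, row in counts.iterrows():
        n_enr, n_dep = int(row.n_enriched), int(row.n_depleted)
        flag = FLAG_OK
        group = _group_of(n_enr, n_dep)
        if kind == "rbp" and verdicts is not None and group != GROUP_NONE:
            v = verdicts.get(entity_id)
            if v is None or not v.kept:
                group, flag = GROUP_NONE, FLAG_FAILED_CONTROL
        out.append(GroupAssignment(entity_id, kind, group, n_enr, n_dep, flag))
    return out


def _lower_median(values) -> float:
    """Median with the lower-of-two convention on even counts."""
    v = sorted(values)
    if not v:
        return float("nan")
    return float(v[(len(v) - 1) // 2])


def summarize(
    landscape: LandscapeTable,
    rbp_assignments: list,
    fu_assignments: list,
) -> LandscapeSummary:
    """Counts, per-group burden statistics and group-to-group link tallies."""
    group_counts: dict = {}
    group_stats: dict = {}
    frac_significant: dict = {}
    n_tested: dict = {}
    n_significant: dict = {}
    for kind, assignments in (("rbp", rbp_assignments), ("fu", fu_assignments)):
        counts: dict = {g: 0 for g in (GROUP_E, GROUP_M, GROUP_D, GROUP_NONE)}
        for a in assignments:
            counts[a.group] += 1
        group_counts[kind] = counts
        n_tested[kind] = len(assignments)
        n_sig = sum(1 for a in assignments if a.n_enriched + a.n_depleted > 0)
        n_significant[kind] = n_sig
        frac_significant[kind] = n_sig / len(assignments) if assignments else 0.0
        for g in (GROUP_E, GROUP_M, GROUP_D):
            members = [a for a in assignments if a.group == g]
            group_stats[(kind, g)] = {
                "n": len(members),
                "mean_enriched": (
                    float(np.mean([a.n_enriched for a in members])) if members else float("nan")
                ),
                "median_enriched": _lower_median([a.n_enriched for a in members]),
                "mean_depleted": (
                    float(np.mean([a.n_depleted for a in members])) if members else float("nan")
                ),
                "median_depleted": _lower_median([a.n_depleted for a in members]),
            }

    rbp_group = {a.entity_id: a.group for a in rbp_assignments}
    fu_group = {a.entity_id: a.group for a in fu_assignments}
    link_counts: dict = {}
    for rec in landscape.significant().itertuples():
        key = (
            rbp_group.get(rec.rbp_id, GROUP_NONE),
            fu_group.get(rec.unit_id, GROUP_NONE),
            rec.direction,
        )
        link_counts[key] = link_counts.get(key, 0) + 1
    return LandscapeSummary(
        group_counts, group_stats, link_counts, frac_significant, n_tested, n_significant
    )


def group_percentages(counts: dict) -> dict:
    """Percentage share of each group among entities with a significant result.

    ``counts`` maps group label -> entity count; the none group, if
    present, is excluded from the denominator (entities without any
    significant call).
    """
    total = sum(v for g, v in counts.items() if g != GROUP_NONE)
    if total == 0:
        return {g: 0.0 for g in counts if g != GROUP_NONE}
    return {g: 100.0 * v / total for g, v in counts.items() if g != GROUP_NONE}


def compare_group_burden(
    assignments: list,
    groups: tuple,
    measure: str = "n_enriched",
    alternative: str = "greater",
):
    """One-sided Mann-Whitney comparison of significant-call burden.

    Tests whether the first group's ``measure`` (n_enriched or n_depleted)
    is stochastically greater (or less) than the second's.  Exact
    enumeration is used for combined sample sizes <= 20 without ties, the
    tie-corrected normal approximation otherwise.  Returns (U, p).
    """
    if measure not in ("n_enriched", "n_depleted"):
        raise ValueError("measure must be n_enriched or n_depleted")
    by_group: dict = {}
    for a in assignments:
        by_group.setdefault(a.group, []).append(getattr(a, measure))
    try:
        x = by_group[groups[0]]
        y = by_group[groups[1]]
    except KeyError as exc:
        raise ValueError(f"empty group {exc.args[0]!r}") from None
    return mann_whitney_one_sided(x, y, alternative)


def mann_whitney_one_sided(x, y, alternative: str = "greater"):
    """Mann-Whitney U with the exact null for small untied samples."""
    x = list(x)
    y = list(y)
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    pooled = x + y
    exact = len(pooled) <= 20 and len(set(pooled)) == len(pooled)
    res = mannwhitneyu(
        x, y, alternative=alternative, method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def shared_rbp_network(
    landscape: LandscapeTable, unit_tags: dict | None = None
) -> SharedRbpNetwork:
    """Weighted unit-unit network of shared enriching RBPs.

    Two units are linked iff at least one RBP has both called enriched;
    the edge weight is the number of such RBPs.  No self-edges.
    """
    enriched = landscape.table[landscape.table.direction == ENRICHED]
    rbps_by_unit: dict = {}
    for rec in enriched.itertuples():
        rbps_by_unit.setdefault(rec.unit_id, set()).add(rec.rbp_id)
    edges: dict = {}
    for u1, u2 in combinations(sorted(rbps_by_unit), 2):
        shared = rbps_by_unit[u1] & rbps_by_unit[u2]
        if shared:
            edges[frozenset((u1, u2))] = len(shared)
    tags = unit_tags or {}
    nodes = {u: tags.get(u) for u in rbps_by_unit}
    return SharedRbpNetwork(nodes, edges)


def write_assignments(assignments: list, path) -> None:
    pd.DataFrame(
        [
            {
                "entity_id": a.entity_id,
                "kind": a.entity_kind,
                "group": a.group,
                "n_enr": a.n_enriched,
                "n_dep": a.n_depleted,
                "control_flag": a.control_flag,
            }
            for a in assignments
        ]
    ).to_csv(path, sep="\t", index=False)


def write_shared_network(net: SharedRbpNetwork, path) -> None:
    rows = []
    for pair, weight in sorted(net.edges.items(), key=lambda kv: sorted(kv[0])):
        u1, u2 = sorted(pair)
        rows.append({"unit_i": u1, "unit_j": u2, "shared_rbps": weight})
    pd.DataFrame(rows, columns=["unit_i", "unit_j", "shared_rbps"]).to_csv(
        path, sep="\t", index=False
    )
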