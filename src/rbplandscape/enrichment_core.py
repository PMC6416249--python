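"""Per-(RBP, functional unit) over/under-representation statistics.

For every RBP and every testable functional unit the module builds the
2x2 contingency table over the statistical background

    a = unit genes interacting with the RBP
    b = unit genes not interacting
    c = background genes outside the unit that interact
    d = background genes outside the unit that do not interact

computes the log2 interaction ratio

    ratio = log2( (a / (a + b)) / (c / (c + d)) )

tests it with a two-sided Fisher exact test, corrects per family with
Benjamini-Hochberg, and calls each pair enriched (ratio > 0), depleted
(ratio < 0) or unclassified at the chosen significance level.  A per-RBP
permutation control relabels genes across the compendium to flag
promiscuous binders whose significant counts are explainable by chance.

The Fisher p-values are produced by a margin-cached hypergeometric routine
(identical to the conditional exact test: sum of the probabilities of all
tables with the observed margins whose probability does not exceed the
observed one, with the customary 1 + 1e-7 relative slack against floating
point ties).  Caching by (background size, unit size, target count) makes
whole-landscape and permutation passes cheap, since unit sizes and per-RBP
target counts are fixed across shuffles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data_io import BinaryInteractionNetwork, FunctionalUnitCompendium

logger = logging.getLogger("rbplandscape")

DEFAULT_ALPHA = 0.05
DEFAULT_N_SHUFFLES = 1000

#: Relative slack when comparing hypergeometric point probabilities,
#: guarding against floating-point ties (same rule scipy/R use).
_REL_SLACK = 1.0 + 1e-7

ENRICHED = "enriched"
DEPLETED = "depleted"
NONE = "none"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts over the background (see module docstring for a,b,c,d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentRecord:
    """Outcome of one (RBP, functional unit) test."""

    rbp_id: str
    unit_id: str
    table: ContingencyTable
    log2_ratio: float
    p_value: float
    p_adjusted: float
    direction: str


@dataclass(frozen=True)
class PermutationVerdict:
    """Per-RBP shuffle-control outcome.

    ``kept`` is True when the RBP shows significantly more enrichments or
    depletions than expected from random gene-to-unit assignment.
    ``testable`` is False when the RBP had no significant result at all,
    in which case no shuffles are run.
    """

    rbp_id: str
    observed_n_enriched: int
    observed_n_depleted: int
    null_enriched: tuple
    null_depleted: tuple
    empirical_p_enriched: float
    empirical_p_depleted: float
    testable: bool

    @property
    def kept(self) -> bool:
        if not self.testable:
            return False
        return (
            (self.observed_n_enriched > 0 and self.empirical_p_enriched < DEFAULT_ALPHA)
            or (self.observed_n_depleted > 0 and self.empirical_p_depleted < DEFAULT_ALPHA)
        )


@dataclass
class LandscapeTable:
    """All enrichment records plus per-RBP permutation verdicts.

    ``table`` is a DataFrame with one row per tested (RBP, unit) pair and
    columns rbp_id, unit_id, source, a, b, c, d, log2_ratio, p, p_adj,
    direction.
    """

    table: pd.DataFrame
    alpha: float
    family: str
    background: frozenset
    verdicts: dict = field(default_factory=dict)

    @property
    def records(self) -> list:
        return [
            EnrichmentRecord(
                r.rbp_id,
                r.unit_id,
                ContingencyTable(r.a, r.b, r.c, r.d),
                r.log2_ratio,
                r.p,
                r.p_adj,
                r.direction,
            )
            for r in self.table.itertuples()
        ]

    def significant(self) -> pd.DataFrame:
        return self.table[self.table.direction != NONE]

    def counts_by(self, kind: str) -> pd.DataFrame:
        """(n_enriched, n_depleted) per rbp or per fu over all tested entities."""
        key = "rbp_id" if kind == "rbp" else "unit_id"
        sig = self.table[self.table.direction != NONE]
        out = pd.DataFrame(index=sorted(self.table[key].unique()))
        for direction, col in ((ENRICHED, "n_enriched"), (DEPLETED, "n_depleted")):
            counts = sig[sig.direction == direction].groupby(key).size()
            out[col] = counts.reindex(out.index).fillna(0).astype(int)
        return out

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

@lru_cache(maxsize=100_000)
def _two_sided_pvalue_table(N: int, K: int, n: int):
    """Two-sided Fisher p for every feasible a at fixed margins.

    Returns (amin, p) where p[i] is the p-value of the table with
    a = amin + i, unit size K, target count n, background size N.
    """
    amin = max(0, n - (N - K))
    amax = min(K, n)
    a = np.arange(amin, amax + 1)
    pmf = hypergeom.pmf(a, N, K, n)
    order = np.argsort(pmf, kind="stable")
    csum = np.cumsum(pmf[order])
    # p(a) = total probability of tables no more likely than the observed
    idx = np.searchsorted(pmf[order], pmf * _REL_SLACK, side="right")
    p = np.minimum(csum[idx - 1], 1.0)
    return amin, p


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Exact two-sided Fisher p-value of a 2x2 table.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability is at most that of the observed table.
    """
    N = table.n
    if N == 0:
        return 1.0
    K = table.a + table.b
    n = table.a + table.c
    amin, p = _two_sided_pvalue_table(N, K, n)
    return float(p[table.a - amin])


def log2_interaction_ratio(table: ContingencyTable) -> float:
    """log2 of the in-unit vs out-of-unit interacting fractions.

    Zero cells give signed-infinity sentinels (no pseudocounts): a = 0
    with c > 0 is -inf, c = 0 with a > 0 is +inf, and a = c = 0 is NaN
    (undefined).  Empty margins (a+b = 0 or c+d = 0) are an error.
    """
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise ValueError("log2 ratio undefined: empty row margin")
    if table.a == 0 and table.c == 0:
        return float("nan")
    if table.a == 0:
        return float("-inf")
    if table.c == 0:
        return float("inf")
    p_in = table.a / (table.a + table.b)
    p_out = table.c / (table.c + table.d)
    return float(np.log2(p_in / p_out))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_contingency(
    rbp_id: str,
    unit,
    network: BinaryInteractionNetwork,
    background,
) -> ContingencyTable:
    """Contingency counts for one RBP against one unit over the background."""
    background = frozenset(background)
    members = unit.members & background
    if not members:
        raise ValueError(f"unit {unit.unit_id!r} has no members in the background")
    targets = network.targets_of(rbp_id) & background
    a = len(members & targets)
    b = len(members) - a
    c = len(targets) - a
    d = len(background) - a - b - c
    return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# Vectorised landscape internals
# ---------------------------------------------------------------------------

def _bh_matrix(p: np.ndarray) -> np.ndarray:
    """BH adjustment along axis 0 of a 2-D array (columns are families)."""
    m = p.shape[0]
    order = np.argsort(p, axis=0)
    ranked = np.take_along_axis(p, order, axis=0)
    adj = ranked * m / np.arange(1, m + 1)[:, None]
    adj = np.minimum.accumulate(adj[::-1], axis=0)[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    np.put_along_axis(out, order, adj, axis=0)
    return out


class _LandscapeEngine:
    """Shared machinery for the landscape and its permutation null.

    Precomputes the unit-membership indicator matrix U (units x background
    genes), the per-RBP target indicator T (background genes x RBPs) and,
    lazily, the Fisher p lookup tables keyed by (unit size, target count).
    """

    def __init__(self, network, compendium, background, min_unit_size=1):
        self.background = sorted(frozenset(background))
        self.gene_index = {g: i for i, g in enumerate(self.background)}
        self.N = len(self.background)
        if self.N == 0:
            raise ValueError("empty statistical background")

        units = []
        for u in compendium:
            members = u.members & frozenset(self.background)
            if len(members) < max(min_unit_size, 1):
                logger.warning(
                    "unit %s skipped: %d member(s) in background", u.unit_id, len(members)
                )
                continue
            units.append((u.unit_id, u.source, members))
        if not units:
            raise ValueError("no testable unit after background restriction")
        self.unit_ids = [u[0] for u in units]
        self.unit_sources = [u[1] for u in units]
        self.U = np.zeros((len(units), self.N), dtype=np.float64)
        for i, (_, _, members) in enumerate(units):
            for g in members:
                self.U[i, self.gene_index[g]] = 1.0
        self.K = self.U.sum(axis=1).astype(int)

        self.rbp_ids = sorted(network.rbps)
        targets = network.targets_by_rbp()
        self.T = np.zeros((self.N, len(self.rbp_ids)), dtype=np.float64)
        for j, r in enumerate(self.rbp_ids):
            for g in targets[r] & frozenset(self.background):
                self.T[self.gene_index[g], j] = 1.0
        self.n_targets = self.T.sum(axis=0).astype(int)

        # per-RBP p-value lookup: L[j][i, a] = two-sided p at unit i, count a
        self._lut: dict = {}

    def _rbp_lut(self, j: int) -> np.ndarray:
        lut = self._lut.get(j)
        if lut is None:
            n = int(self.n_targets[j])
            width = int(min(self.K.max(), n)) + 1
            lut = np.ones((len(self.K), width))
            for i, K in enumerate(self.K):
                amin, p = _two_sided_pvalue_table(self.N, int(K), n)
                hi = amin + len(p)
                lut[i, amin:hi] = p
            self._lut[j] = lut
        return lut

    def a_counts(self, perm: np.ndarray | None = None) -> np.ndarray:
        """Units x RBPs matrix of in-unit interacting counts.

        ``perm`` applies a global permutation of gene identities over the
        background to the unit memberships (the shuffle null).
        """
        U = self.U if perm is None else self.U[:, perm]
        return np.rint(U @ self.T).astype(int)

    def pvalues(self, A: np.ndarray, rbp_cols=None) -> np.ndarray:
        cols = range(A.shape[1]) if rbp_cols is None else rbp_cols
        P = np.ones(A.shape)
        rows = np.arange(A.shape[0])
        for jj, j in enumerate(cols):
            lut = self._rbp_lut(j)
            P[:, jj] = lut[rows, A[:, jj]]
        return P

    def directions(self, A: np.ndarray, rbp_cols=None) -> np.ndarray:
        """Sign of the log2 ratio: +1 enriched-side, -1 depleted-side, 0 even."""
        cols = np.arange(A.shape[1]) if rbp_cols is None else np.asarray(rbp_cols)
        n = self.n_targets[cols][None, :]
        return np.sign(A * self.N - n * self.K[:, None]).astype(int)


def compute_landscape(
    network: BinaryInteractionNetwork,
    compendium: FunctionalUnitCompendium,
    background,
    alpha: float = DEFAULT_ALPHA,
    family: str = "per_rbp",
    min_unit_size: int = 1,
) -> LandscapeTable:
    """Test every (RBP, testable unit) pair and call significant directions.

    ``family`` selects the Benjamini-Hochberg correction family: "per_rbp"
    (default; each RBP's unit tests form one family, matching the per-RBP
    framing of the shuffle control) or "global" (one family across all
    RBP x unit tests).
    """
    if not 0 <= alpha < 1:
        raise ValueError("alpha must lie in [0, 1)")
    if family not in ("per_rbp", "global"):
        raise ValueError(f"unknown BH family {family!r}")
    eng = _LandscapeEngine(network, compendium, background, min_unit_size)
    A = eng.a_counts()
    P = eng.pvalues(A)
    if family == "per_rbp":
        Padj = _bh_matrix(P)
    else:
        Padj = bh_adjust(P.ravel()).reshape(P.shape)

    n_units, n_rbps = A.shape
    rows = []
    for j in range(n_rbps):
        n = int(eng.n_targets[j])
        for i in range(n_units):
            a = int(A[i, j])
            K = int(eng.K[i])
            t = ContingencyTable(a, K - a, n - a, eng.N - K - n + a)
            ratio = log2_interaction_ratio(t)
            p = float(P[i, j])
            padj = float(Padj[i, j])
            if padj < alpha and ratio > 0:
                direction = ENRICHED
            elif padj < alpha and ratio < 0:
                direction = DEPLETED
            else:
                direction = NONE
            rows.append(
                (
                    eng.rbp_ids[j],
                    eng.unit_ids[i],
                    eng.unit_sources[i],
                    t.a,
                    t.b,
                    t.c,
                    t.d,
                    ratio,
                    p,
                    padj,
                    direction,
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "rbp_id",
            "unit_id",
            "source",
            "a",
            "b",
            "c",
            "d",
            "log2_ratio",
            "p",
            "p_adj",
            "direction",
        ],
    )
    return LandscapeTable(df, alpha=alpha, family=family, background=frozenset(eng.background))


def permutation_control(
    network: BinaryInteractionNetwork,
    compendium: FunctionalUnitCompendium,
    background,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    alpha: float = DEFAULT_ALPHA,
    seed: int | None = None,
    family: str = "per_rbp",
    landscape: LandscapeTable | None = None,
    per_unit_resampling: bool = False,
) -> dict:
    """Shuffle-null control for promiscuous binders.

    Each shuffle applies a random permutation of gene identities over the
    background to all unit memberships at once (preserving unit sizes and
    their overlap structure), recomputes the full BH-corrected landscape,
    and counts significant enrichments/depletions per RBP.  The empirical
    p-value per direction is (1 + #{null count >= observed}) / (1 + S).
    RBPs with no observed significant result are marked untestable and
    skipped.  ``per_unit_resampling=True`` instead redraws each unit's
    membership independently (sensitivity variant; overlaps not preserved).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    eng = _LandscapeEngine(network, compendium, background)
    if landscape is None:
        landscape = compute_landscape(network, compendium, background, alpha, family)
    observed = landscape.counts_by("rbp")

    testable = [
        j
        for j, r in enumerate(eng.rbp_ids)
        if observed.loc[r, "n_enriched"] + observed.loc[r, "n_depleted"] > 0
    ]
    null_enr = {j: np.zeros(n_shuffles, dtype=int) for j in testable}
    null_dep = {j: np.zeros(n_shuffles, dtype=int) for j in testable}

    if testable:
        T_sub = eng.T[:, testable]
        for s in range(n_shuffles):
            if per_unit_resampling:
                U = np.zeros_like(eng.U)
                for i, K in enumerate(eng.K):
                    U[i, rng.choice(eng.N, int(K), replace=False)] = 1.0
                A = np.rint(U @ T_sub).astype(int)
            else:
                perm = rng.permutation(eng.N)
                A = np.rint(eng.U[:, perm] @ T_sub).astype(int)
            P = eng.pvalues(A, rbp_cols=testable)
            if family == "per_rbp":
                Padj = _bh_matrix(P)
            else:
                # the global family spans all RBPs; approximate within the
                # testable subset (identical when all RBPs are testable)
                Padj = bh_adjust(P.ravel()).reshape(P.shape)
            D = eng.directions(A, rbp_cols=testable)
            sig = Padj < alpha
            for jj, j in enumerate(testable):
                null_enr[j][s] = int(np.sum(sig[:, jj] & (D[:, jj] > 0)))
                null_dep[j][s] = int(np.sum(sig[:, jj] & (D[:, jj] < 0)))

    verdicts = {}
    for j, r in enumerate(eng.rbp_ids):
        n_enr = int(observed.loc[r, "n_enriched"])
        n_dep = int(observed.loc[r, "n_depleted"])
        if j not in null_enr:
            verdicts[r] = PermutationVerdict(
                r, n_enr, n_dep, (), (), 1.0, 1.0, testable=False
            )
            continue
        k_enr = int(np.sum(null_enr[j] >= n_enr))
        k_dep = int(np.sum(null_dep[j] >= n_dep))
        verdicts[r] = PermutationVerdict(
            r,
            n_enr,
            n_dep,
            tuple(int(x) for x in null_enr[j]),
            tuple(int(x) for x in null_dep[j]),
            (1 + k_enr) / (1 + n_shuffles),
            (1 + k_dep) / (1 + n_shuffles),
            testable=True,
        )
    return verdicts


def write_verdicts(verdicts: dict, path) -> None:
    rows = [
        {
            "rbp_id": v.rbp_id,
            "n_enriched": v.observed_n_enriched,
            "n_depleted": v.observed_n_depleted,
            "emp_p_enr": v.empirical_p_enriched,
            "emp_p_dep": v.empirical_p_depleted,
            "kept": v.kept,
        }
        for v in verdicts.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Predicted vs experimental network comparison
# ---------------------------------------------------------------------------

def compare_networks(
    predicted: BinaryInteractionNetwork,
    experimental: BinaryInteractionNetwork,
    common_universe,
) -> pd.DataFrame:
    """Per-RBP association between predicted and experimental target status.

    For every RBP present in both networks, cross-tabulates predicted vs
    experimental interaction status over the common universe, applies a
    two-sided Fisher exact test and corrects with BH across RBPs.  Returns
    a DataFrame with columns rbp_id, odds_ratio, p, p_adj (odds ratio
    carries an infinity sentinel on a zero denominator, NaN on 0/0).
    """
    universe = frozenset(common_universe)
    if not universe:
        raise ValueError("empty common universe")
    shared = predicted.rbps & experimental.rbps
    skipped = (predicted.rbps | experimental.rbps) - shared
    if skipped:
        logger.info("compare_networks: %d RBP(s) absent from one network, skipped", len(skipped))
    rows = []
    for rbp in sorted(shared):
        pred = predicted.targets_of(rbp) & universe
        expr = experimental.targets_of(rbp) & universe
        a = len(pred & expr)
        b = len(pred - expr)
        c = len(expr - pred)
        d = len(universe) - a - b - c
        t = ContingencyTable(a, b, c, d)
        if b * c == 0:
            odds = float("nan") if a * d == 0 else float("inf")
        else:
            odds = (a * d) / (b * c)
        rows.append({"rbp_id": rbp, "odds_ratio": odds, "p": fisher_exact_two_sided(t)})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = bh_adjust(df["p"])
    else:
        df["p_adj"] = []
    return df
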