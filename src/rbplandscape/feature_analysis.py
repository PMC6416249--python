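"""Group-level molecular features of the classified RBPs and units.

Covers the downstream comparisons between the E/M/D groups: RBP category
over/under-representation (one-sided Fisher), post-translational
modification density, intrinsic-disorder and low-complexity fractions,
tissue expression breadth, and the nonparametric machinery used to compare
their distributions (Kruskal-Wallis, Dunn's post-hoc z with BH correction,
two-sample Kolmogorov-Smirnov, and via :mod:`.classification` the
Mann-Whitney U).

Disorder and low-complexity predictors are consumed, not reimplemented:
the module takes per-residue probability tracks (one value per amino acid)
or boolean masks as input, one track per predictor, summarised separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, kruskal, ks_2samp, norm, rankdata

from .enrichment_core import bh_adjust

PTM_TYPES = (
    "acetylation",
    "methylation",
    "O-GalNAc",
    "O-GlcNAc",
    "phosphorylation",
    "sumoylation",
    "ubiquitination",
)

DISORDER_THRESHOLD = 0.4
N_TISSUES = 58
EXPRESSED_LEVELS = frozenset({"low", "medium", "high"})
ACCEPTED_RELIABILITY = frozenset({"approved", "enhanced", "supported"})


@dataclass(frozen=True)
class RbpAnnotation:
    """Functional-category flags and sequence length for one RBP.

    Categories follow the RNA-interactome-capture classification:
    established RBPs (known role in RNA biology), RBPs with a recognised
    RNA-binding domain, enigmRBPs (neither), and RNA-binding enzymes.
    """

    rbp_id: str
    is_established: bool
    has_rbd: bool
    is_enigm: bool
    is_enzyme: bool
    seq_length_aa: int

    def __post_init__(self) -> None:
        if self.seq_length_aa <= 0:
            raise ValueError("seq_length_aa must be positive")
        if self.is_enigm and (self.has_rbd or self.is_established):
            raise ValueError("an enigmRBP has no RBD and no established role")


@dataclass(frozen=True)
class PtmProfile:
    """Modification-site counts and per-residue densities for one RBP."""

    rbp_id: str
    site_counts: dict  # ptm_type -> count
    seq_length_aa: int

    @property
    def total_sites(self) -> int:
        return sum(self.site_counts.values())

    @property
    def density_overall(self) -> float:
        return self.total_sites / self.seq_length_aa

    def density(self, ptm_type: str) -> float:
        return self.site_counts.get(ptm_type, 0) / self.seq_length_aa


@dataclass(frozen=True)
class ResidueTrack:
    """Per-residue disorder probabilities and/or low-complexity mask."""

    rbp_id: str
    disorder: tuple = ()
    low_complexity_mask: tuple = ()


@dataclass(frozen=True)
class ExpressionProfile:
    """Qualitative per-tissue expression calls for one gene."""

    gene_id: str
    levels: dict  # tissue -> level in {not detected, low, medium, high}
    reliability: dict  # tissue -> reliability label


# ---------------------------------------------------------------------------
# Feature computations
# ---------------------------------------------------------------------------

def category_enrichment(
    assignments: list,
    annotations: dict,
    category: str,
    group: str,
    side: str = "greater",
):
    """One-sided Fisher test of a category within a classified group.

    Builds the 2x2 table of (in group) x (in category) over all classified
    RBPs with annotations and returns (odds_ratio, p) for the requested
    tail.  The odds ratio is ad/bc with an infinity sentinel on a zero
    denominator and NaN on 0/0.
    """
    if side not in ("greater", "less"):
        raise ValueError("side must be 'greater' or 'less'")
    flag = {
        "established": "is_established",
        "rbd": "has_rbd",
        "enigm": "is_enigm",
        "enzyme": "is_enzyme",
    }.get(category, category)
    a = b = c = d = 0
    for asg in assignments:
        ann = annotations.get(asg.entity_id)
        if ann is None:
            continue
        in_cat = bool(getattr(ann, flag))
        in_grp = asg.group == group
        if in_grp and in_cat:
            a += 1
        elif in_grp:
            b += 1
        elif in_cat:
            c += 1
        else:
            d += 1
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("degenerate margins: group or category empty (or universal)")
    p = float(fisher_exact([[a, b], [c, d]], alternative=side).pvalue)
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    return odds, p


def ptm_density(ptm_table: pd.DataFrame, annotations: dict) -> dict:
    """Per-RBP modification-site counts and densities.

    ``ptm_table`` has columns rbp_id, ptm_type, position (1-based).  Sites
    past the recorded sequence length are kept with a warning (database /
    sequence-version drift is tolerated).  Returns rbp_id -> PtmProfile
    for every annotated RBP (zero counts when no site is recorded).
    """
    import logging

    logger = logging.getLogger("rbplandscape")
    counts: dict = {r: {t: 0 for t in PTM_TYPES} for r in annotations}
    n_beyond = 0
    for row in ptm_table.itertuples():
        ann = annotations.get(row.rbp_id)
        if ann is None:
            continue
        if row.position > ann.seq_length_aa:
            n_beyond += 1
        counts[row.rbp_id].setdefault(row.ptm_type, 0)
        counts[row.rbp_id][row.ptm_type] += 1
    if n_beyond:
        logger.warning("ptm_density: %d site(s) beyond sequence length (kept)", n_beyond)
    return {
        r: PtmProfile(r, counts[r], annotations[r].seq_length_aa) for r in annotations
    }


def disorder_fraction(track, threshold: float = DISORDER_THRESHOLD) -> float:
    """Fraction of residues with disorder probability strictly above threshold."""
    values = np.asarray(track.disorder if isinstance(track, ResidueTrack) else track, dtype=float)
    if values.size == 0:
        raise ValueError("empty residue track")
    return float(np.mean(values > threshold))


def low_complexity_fraction(track, seq_length: int | None = None) -> float:
    """Fraction of residues flagged low-complexity by the mask."""
    mask = np.asarray(
        track.low_complexity_mask if isinstance(track, ResidueTrack) else track, dtype=bool
    )
    if mask.size == 0:
        raise ValueError("empty low-complexity mask")
    if seq_length is not None and mask.size != seq_length:
        raise ValueError(f"mask length {mask.size} != sequence length {seq_length}")
    return float(np.mean(mask))


def masked_fasta_fraction(sequence: str) -> float:
    """Low-complexity fraction from a soft-masked sequence (lowercase = masked)."""
    if not sequence:
        raise ValueError("empty sequence")
    return sum(1 for ch in sequence if ch.islower()) / len(sequence)


def expression_breadth(
    profile: ExpressionProfile,
    n_tissues: int = N_TISSUES,
    accepted_reliability=ACCEPTED_RELIABILITY,
) -> float:
    """Fraction of tissues where the gene is reliably expressed.

    A tissue counts when the qualitative level is at least "low" and the
    reliability is in the accepted set.
    """
    if n_tissues < 1:
        raise ValueError("n_tissues must be >= 1")
    accepted = frozenset(accepted_reliability)
    n_expressed = sum(
        1
        for tissue, level in profile.levels.items()
        if level in EXPRESSED_LEVELS and profile.reliability.get(tissue) in accepted
    )
    return n_expressed / n_tissues


# ---------------------------------------------------------------------------
# Nonparametric comparisons
# ---------------------------------------------------------------------------

def kruskal_wallis(*groups):
    """Tie-corrected Kruskal-Wallis H with chi-square reference.

    Accepts either separate sample arguments or a single iterable of
    samples.  All-identical data give (0, 1) rather than an error.
    """
    if len(groups) == 1 and hasattr(groups[0], "__iter__") and not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("each group needs at least one value")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    res = kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def dunn_posthoc(groups: dict, correction: str = "bh") -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons after Kruskal-Wallis.

    For groups i, j with mean pooled ranks Rbar_i, Rbar_j,

        z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))

    with pooled-tie term T = sum(t^3 - t) / (12 (N - 1)).  Two-sided p
    from the standard normal, BH-corrected across the pairs.  Runs
    regardless of whether the omnibus test rejected (caller's call).
    Returns a DataFrame with columns group_i, group_j, z, p, p_adj.
    """
    names = list(groups)
    if any(len(groups[g]) == 0 for g in names):
        raise ValueError("each group needs at least one value")
    sizes = {g: len(groups[g]) for g in names}
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    N = pooled.size
    ranks = rankdata(pooled)
    mean_rank = {}
    offset = 0
    for g in names:
        n = sizes[g]
        mean_rank[g] = float(ranks[offset : offset + n].mean())
        offset += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    base_var = N * (N + 1) / 12.0 - tie_term
    rows = []
    for gi, gj in combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
        z = (mean_rank[gi] - mean_rank[gj]) / se if se > 0 else 0.0
        p = 2.0 * norm.sf(abs(z)) if se > 0 else 1.0
        rows.append({"group_i": gi, "group_j": gj, "z": float(z), "p": float(min(p, 1.0))})
    df = pd.DataFrame(rows)
    if correction == "bh":
        df["p_adj"] = bh_adjust(df["p"])
    elif correction in (None, "none"):
        df["p_adj"] = df["p"]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return df


def ks_two_sample(sample_a, sample_b):
    """Two-sample Kolmogorov-Smirnov: D = sup|ECDF difference|, asymptotic p."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def read_annotations(path) -> dict:
    """Annotation TSV: rbp_id, is_established, has_rbd, is_enigm, is_enzyme, seq_length_aa."""
    df = pd.read_csv(path, sep="\t")
    return {
        row.rbp_id: RbpAnnotation(
            row.rbp_id,
            bool(row.is_established),
            bool(row.has_rbd),
            bool(row.is_enigm),
            bool(row.is_enzyme),
            int(row.seq_length_aa),
        )
        for row in df.itertuples()
    }


def write_annotations(annotations: dict, path) -> None:
    pd.DataFrame(
        [
            {
                "rbp_id": a.rbp_id,
                "is_established": a.is_established,
                "has_rbd": a.has_rbd,
                "is_enigm": a.is_enigm,
                "is_enzyme": a.is_enzyme,
                "seq_length_aa": a.seq_length_aa,
            }
            for a in annotations.values()
        ]
    ).to_csv(path, sep="\t", index=False)


def read_expression_table(path) -> dict:
    """Expression TSV (gene_id, tissue, level, reliability) -> profiles."""
    df = pd.read_csv(path, sep="\t")
    profiles: dict = {}
    for row in df.itertuples():
        levels, reliab = profiles.setdefault(row.gene_id, ({}, {}))
        levels[row.tissue] = row.level
        reliab[row.tissue] = row.reliability
    return {g: ExpressionProfile(g, lv, rb) for g, (lv, rb) in profiles.items()}
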