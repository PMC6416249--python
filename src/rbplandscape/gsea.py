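"""Threshold-free confirmation by gene-set enrichment analysis.

Instead of binarising interaction propensities at a cutoff, each RBP's
genes are ranked by score (descending) and every functional unit is tested
with a weighted Kolmogorov-Smirnov running-sum statistic: walking down the
ranking, hitting a unit member increments the sum by |score|^w / sum of
hit weights and missing decrements by 1/(N - n_hits); the enrichment score
(ES) is the extremum of largest magnitude.  A positive ES means members
concentrate among high-propensity genes (enrichment), negative among
low-propensity genes (depletion/avoidance).

Significance uses gene-set permutations: member sets of identical size are
resampled without replacement from the background, the normalised score
NES = ES / mean(|permuted ES| of the matching sign), and the FDR is the
standard signed ratio-of-tails estimate over the pooled permutation NES,
clipped to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import FunctionalUnitCompendium, ScoredInteractionMatrix
from .enrichment_core import DEPLETED, ENRICHED, NONE, LandscapeTable

logger = logging.getLogger("rbplandscape")

DEFAULT_WEIGHT_EXPONENT = 1.0
DEFAULT_N_PERMUTATIONS = 1000


@dataclass(frozen=True)
class RankedList:
    """One RBP's genes ordered by interaction propensity.

    Strictly ordered by (score descending, gene id ascending); genes are
    unique and drawn from the statistical background.
    """

    rbp_id: str
    genes: tuple
    scores: tuple

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must align")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked genes must be unique")
        keys = list(zip([-s for s in self.scores], self.genes))
        if keys != sorted(keys):
            raise ValueError("ranking must be ordered by (score desc, gene asc)")


@dataclass(frozen=True)
class GseaRecord:
    """Signed enrichment outcome of one (RBP, unit) pair."""

    rbp_id: str
    unit_id: str
    es: float
    nes: float
    fdr: float
    n_permutations: int
    direction: str


def make_ranked_list(
    matrix: ScoredInteractionMatrix, rbp_id: str, background
) -> RankedList:
    """Rank an RBP's background genes by score desc, ties by gene id asc."""
    background = sorted(frozenset(background) & matrix.genes)
    row = matrix.scores.loc[rbp_id, background]
    order = sorted(background, key=lambda g: (-row[g], g))
    return RankedList(rbp_id, tuple(order), tuple(float(row[g]) for g in order))


def _es_from_positions(
    weights: np.ndarray, positions: np.ndarray, N: int
) -> np.ndarray:
    """Vectorised extremum of the GSEA running sum.

    ``positions`` is an (n_sets, k) array of 0-based hit ranks, sorted
    ascending along axis 1; ``weights`` the matching |score|^w values.
    The running sum is piecewise linear between hits, so its extrema occur
    immediately after a hit (candidate maxima) or immediately before one
    (candidate minima); both are evaluated in closed form.
    """
    k = positions.shape[1]
    if k >= N:
        raise ValueError("gene set covers the whole ranking: no misses")
    W = weights.sum(axis=1, keepdims=True)
    if np.any(W == 0):
        # degenerate all-zero hit weights: fall back to unweighted steps
        weights = np.where(W == 0, 1.0, weights)
        W = weights.sum(axis=1, keepdims=True)
    cum = np.cumsum(weights, axis=1) / W
    miss = 1.0 / (N - k)
    j = np.arange(k)[None, :]
    after = cum - (positions - j) * miss
    before = np.concatenate([np.zeros((cum.shape[0], 1)), cum[:, :-1]], axis=1)
    before = before - (positions - j) * miss
    hi = after.max(axis=1)
    lo = np.minimum(before.min(axis=1), 0.0)
    return np.where(np.abs(hi) >= np.abs(lo), hi, lo)


def enrichment_score(
    ranked: RankedList,
    members,
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
):
    """Weighted-KS enrichment score and full running sum for one gene set.

    Returns (es, running_sum) where running_sum has one value per ranked
    gene.  Raises ``ValueError`` when no member is in the ranking or when
    the set covers it entirely (no misses).
    """
    members = frozenset(members)
    genes = ranked.genes
    N = len(genes)
    hit = np.fromiter((g in members for g in genes), dtype=bool, count=N)
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ValueError("no gene-set member present in the ranked list")
    if n_hits == N:
        raise ValueError("gene set covers the whole ranking: no misses")
    w = np.abs(np.asarray(ranked.scores)) ** weight_exponent
    w_hit = np.where(hit, w, 0.0)
    total = w_hit.sum()
    if total == 0:
        w_hit = hit.astype(float)
        total = float(n_hits)
    steps = w_hit / total - (~hit) / (N - n_hits)
    running = np.cumsum(steps)
    positions = np.nonzero(hit)[0][None, :]
    es = float(_es_from_positions(w[positions[0]][None, :], positions, N)[0])
    return es, running


def gsea_landscape(
    matrix: ScoredInteractionMatrix,
    compendium: FunctionalUnitCompendium,
    background,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | None = None,
    alpha: float = 0.05,
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
) -> pd.DataFrame:
    """Run the full ranked-list analysis for every (RBP, unit) pair.

    Permutation member sets are shared across units of identical size
    within an RBP (the null depends only on the ranking and the set size).
    Returns a DataFrame with columns rbp_id, unit_id, es, nes, fdr,
    direction; ``direction`` is enriched/depleted when fdr < alpha with
    the matching NES sign, else none.
    """
    rng = np.random.default_rng(seed)
    background = sorted(frozenset(background) & matrix.genes)
    N = len(background)
    if N == 0:
        raise ValueError("empty background")

    unit_members = []
    for u in compendium:
        members = u.members & frozenset(background)
        if not members:
            logger.warning("gsea: unit %s has no member in background, skipped", u.unit_id)
            continue
        if len(members) == N:
            logger.warning("gsea: unit %s covers the whole background, skipped", u.unit_id)
            continue
        unit_members.append((u.unit_id, members))
    if not unit_members:
        raise ValueError("no testable unit")

    sizes = sorted({len(m) for _, m in unit_members})
    rows = []
    all_nes = []
    all_perm_nes = []
    for rbp_id in sorted(matrix.rbps):
        ranked = make_ranked_list(matrix, rbp_id, background)
        w = np.abs(np.asarray(ranked.scores)) ** weight_exponent
        gene_pos = {g: i for i, g in enumerate(ranked.genes)}

        perm_es_by_size = {}
        for k in sizes:
            pos = np.empty((n_permutations, k), dtype=np.intp)
            for s in range(n_permutations):
                pos[s] = rng.choice(N, k, replace=False)
            pos.sort(axis=1)
            perm_es_by_size[k] = _es_from_positions(w[pos], pos, N)

        for unit_id, members in unit_members:
            pos = np.sort(np.fromiter((gene_pos[g] for g in members), dtype=np.intp))
            es = float(_es_from_positions(w[pos][None, :], pos[None, :], N)[0])
            perm = perm_es_by_size[len(members)]
            nes, perm_nes = _normalize_signed(es, perm)
            rows.append([rbp_id, unit_id, es, nes])
            all_nes.append(nes)
            all_perm_nes.append(perm_nes)

    df = pd.DataFrame(rows, columns=["rbp_id", "unit_id", "es", "nes"])
    perm_pool = np.concatenate(all_perm_nes)
    obs_pool = np.asarray(all_nes, dtype=float)
    df["fdr"] = [
        _signed_tail_fdr(nes, obs_pool, perm_pool) for nes in obs_pool
    ]
    df["n_permutations"] = n_permutations
    df["direction"] = np.where(
        (df.fdr < alpha) & (df.nes > 0),
        ENRICHED,
        np.where((df.fdr < alpha) & (df.nes < 0), DEPLETED, NONE),
    )
    df.loc[df.nes.isna(), "direction"] = NONE
    return df


def _normalize_signed(es: float, perm: np.ndarray):
    """NES for one observed ES given its size-matched permutation scores.

    The normaliser is the mean |permuted ES| of the matching sign.  When no
    permutation landed on the observed side — which happens precisely when
    the observed score is more extreme than every permutation, e.g. strong
    depletions under all-positive hit weights — the opposite side's mean
    magnitude is used instead, so the record keeps its sign rather than
    becoming undefined.  Returns (nes, permutation NES array); NES is NaN
    only when every permuted score is exactly zero.
    """
    pos_mean = np.abs(perm[perm > 0]).mean() if np.any(perm > 0) else np.nan
    neg_mean = np.abs(perm[perm < 0]).mean() if np.any(perm < 0) else np.nan
    pos_norm = pos_mean if np.isfinite(pos_mean) else neg_mean
    neg_norm = neg_mean if np.isfinite(neg_mean) else pos_mean
    if es > 0:
        nes = es / pos_norm if np.isfinite(pos_norm) else np.nan
    elif es < 0:
        nes = -abs(es) / neg_norm if np.isfinite(neg_norm) else np.nan
    else:
        nes = 0.0
    perm_nes = np.where(
        perm > 0,
        perm / (pos_mean if np.isfinite(pos_mean) else np.inf),
        perm / (neg_mean if np.isfinite(neg_mean) else np.inf),
    )
    return nes, perm_nes


def _signed_tail_fdr(nes: float, obs: np.ndarray, perm: np.ndarray) -> float:
    """Ratio-of-tails FDR estimate on the matching sign side."""
    if not np.isfinite(nes):
        return 1.0
    if nes == 0.0:
        return 1.0
    if nes > 0:
        perm_side = perm[perm >= 0]
        obs_side = obs[obs >= 0]
        num = np.mean(perm_side >= nes) if perm_side.size else 0.0
        den = np.mean(obs_side >= nes) if obs_side.size else 1.0
    else:
        perm_side = perm[perm <= 0]
        obs_side = obs[obs <= 0]
        num = np.mean(perm_side <= nes) if perm_side.size else 0.0
        den = np.mean(obs_side <= nes) if obs_side.size else 1.0
    if den == 0:
        return 0.0 if num == 0 else 1.0
    return float(min(1.0, num / den))


def normalize_and_fdr(
    es_table: dict,
    permutation_es: dict,
    n_permutations: int,
    alpha: float = 0.05,
) -> list:
    """Normalise observed scores and estimate FDR from given permutations.

    ``es_table`` maps (rbp_id, unit_id) -> es; ``permutation_es`` maps the
    same keys to arrays of permuted enrichment scores.  Exposed for use
    with externally computed permutations; :func:`gsea_landscape` is the
    usual entry point.
    """
    keys = sorted(es_table)
    nes_map = {}
    perm_nes_all = []
    for key in keys:
        perm = np.asarray(permutation_es[key], dtype=float)
        nes, perm_nes = _normalize_signed(float(es_table[key]), perm)
        nes_map[key] = nes
        perm_nes_all.append(perm_nes)
    obs_pool = np.asarray([nes_map[k] for k in keys], dtype=float)
    perm_pool = np.concatenate(perm_nes_all) if perm_nes_all else np.array([])
    records = []
    for key in keys:
        nes = nes_map[key]
        fdr = _signed_tail_fdr(nes, obs_pool, perm_pool)
        if not np.isfinite(nes):
            direction = NONE
        elif fdr < alpha and nes > 0:
            direction = ENRICHED
        elif fdr < alpha and nes < 0:
            direction = DEPLETED
        else:
            direction = NONE
        records.append(
            GseaRecord(key[0], key[1], float(es_table[key]), float(nes), float(fdr),
                       n_permutations, direction)
        )
    return records


def concordance(gsea_results: pd.DataFrame, landscape: LandscapeTable):
    """Direction agreement between the two analyses on shared pairs.

    Returns (crosstab, agreement) where ``crosstab`` counts
    threshold-based direction (rows) against ranked-list direction
    (columns) over the shared (RBP, unit) pairs and ``agreement`` is the
    fraction of shared pairs with identical calls.  Empty inputs give an
    empty table and NaN agreement.
    """
    left = landscape.table[["rbp_id", "unit_id", "direction"]].rename(
        columns={"direction": "threshold_call"}
    )
    right = gsea_results[["rbp_id", "unit_id", "direction"]].rename(
        columns={"direction": "gsea_call"}
    )
    merged = left.merge(right, on=["rbp_id", "unit_id"])
    if merged.empty:
        return pd.DataFrame(), float("nan")
    tab = pd.crosstab(merged.threshold_call, merged.gsea_call)
    agreement = float((merged.threshold_call == merged.gsea_call).mean())
    return tab, agreement
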