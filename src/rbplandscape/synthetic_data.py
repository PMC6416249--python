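"""Self-contained synthetic inputs with known planted structure.

Generates everything the pipeline consumes — a functional-unit compendium,
a scored RBP x gene interaction matrix with planted regulons (enrichment),
planted avoidance units (depletion) and promiscuous binders, group-biased
molecular-feature tables, and a toy peak/transcript fixture — together
with a ground-truth ledger, so that every stage is testable without any
external download.

Score model.  Scores sit on the interaction-propensity scale used by the
binarisation step: for a pair with target post-threshold probability p,

    score = threshold + sd * (Z + Phi^-1(p)),   Z ~ N(0, 1)

so that P(score >= threshold) = p exactly and scores are Gaussian with
spread ``score_sd``.  The background probability ``p_background`` applies
everywhere except planted unit memberships (``p_enrich`` / ``p_deplete``)
and promiscuous RBP rows (``promiscuous_rate``).

Planted sizes.  Enrichment-planted units have ``unit_size`` genes
(default 30).  Avoidance-planted units default to ``avoidance_unit_size``
= 100 genes: a depletion signal is bounded by the unit size (the in-unit
count cannot fall below zero), and a 30-gene unit cannot reach
multiple-testing-corrected significance at these rates, whereas avoided
units in real compendia are typically large pathways.

All randomness flows from ``SimulationConfig.seed`` through per-operation
derived streams, so each artefact is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_io import (
    BinaryInteractionNetwork,
    FunctionalUnit,
    FunctionalUnitCompendium,
    GenomicInterval,
    ScoredInteractionMatrix,
    TranscriptModel,
    write_edge_list,
    write_gene_sets,
    write_score_matrix,
    write_transcript_table,
)
from .feature_analysis import PTM_TYPES, ExpressionProfile, RbpAnnotation, ResidueTrack

ENRICH = "enrich"
DEPLETE = "deplete"

# per-operation stream tags, so artefacts are independently reproducible
_STREAM_COMPENDIUM = 1
_STREAM_SCORES = 2
_STREAM_FEATURES = 3
_STREAM_PEAKS = 4


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic instance.

    Defaults are the strong-effect benchmark: 2000 genes, 40 units, 50
    RBPs of which 6 are enrichment-only regulators (intended class E), 6
    mixed (M), 6 avoidance-only (D), 3 promiscuous and the rest
    unstructured; background binding probability 0.2 against 0.8 inside
    enrichment-planted units and 0.02 inside avoidance-planted units.
    """

    n_rbps: int = 50
    n_genes: int = 2000
    n_units: int = 36
    unit_size: int = 30
    avoidance_unit_size: int = 100
    overlap_fraction: float = 0.0
    p_background: float = 0.2
    p_enrich: float = 0.8
    p_deplete: float = 0.02
    promiscuous_rate: float = 0.6
    n_enrich_rbps: int = 6
    n_mixed_rbps: int = 6
    n_deplete_rbps: int = 6
    n_promiscuous: int = 3
    units_per_mode: int = 1
    score_sd: float = 10.0
    threshold: float = 50.0
    # feature model
    ptm_rate: dict = field(
        default_factory=lambda: {"E": 0.01, "M": 0.03, "D": 0.03, "none": 0.02}
    )
    established_prior: dict = field(
        default_factory=lambda: {"E": 0.25, "M": 0.6, "D": 0.5, "none": 0.5}
    )
    rbd_prior: dict = field(
        default_factory=lambda: {"E": 0.3, "M": 0.65, "D": 0.5, "none": 0.5}
    )
    enzyme_prior: float = 0.15
    expressed_prior: dict = field(
        default_factory=lambda: {"E": 0.8, "M": 0.8, "D": 0.8, "none": 0.8}
    )
    disorder_mean: float = 0.35
    low_complexity_rate: float = 0.1
    seq_len_range: tuple = (100, 700)
    n_tissues: int = 58
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.p_background,
            self.p_enrich,
            self.p_deplete,
            self.promiscuous_rate,
            self.overlap_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if max(self.unit_size, self.avoidance_unit_size) > self.n_genes:
            raise ValueError("unit sizes exceed the gene pool")
        n_structured = (
            self.n_enrich_rbps + self.n_mixed_rbps + self.n_deplete_rbps + self.n_promiscuous
        )
        if n_structured > self.n_rbps:
            raise ValueError("more structured RBPs than n_rbps")
        if self.n_planted_units > self.n_units:
            raise ValueError("more planted units than n_units")

    @property
    def n_enrich_units(self) -> int:
        return (self.n_enrich_rbps + self.n_mixed_rbps) * self.units_per_mode

    @property
    def n_deplete_units(self) -> int:
        return (self.n_mixed_rbps + self.n_deplete_rbps) * self.units_per_mode

    @property
    def n_planted_units(self) -> int:
        return self.n_enrich_units + self.n_deplete_units

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


@dataclass
class GroundTruthLedger:
    """What was planted, for oracle comparisons downstream."""

    planted: list  # of (rbp_id, unit_id, mode)
    intended_class: dict  # rbp_id -> E | M | D | none; promiscuous flagged below
    promiscuous: list
    unit_members: dict  # unit_id -> sorted member list
    params: dict

    def to_json(self, path) -> None:
        payload = {
            "planted": [list(t) for t in self.planted],
            "intended_class": self.intended_class,
            "promiscuous": self.promiscuous,
            "unit_members": self.unit_members,
            "params": self.params,
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=str))


def _gene_ids(n: int) -> list:
    return [f"g{i:05d}" for i in range(n)]


def _rbp_names(cfg: SimulationConfig) -> dict:
    """Ordered rbp_id -> intended class ('promiscuous' kept separate)."""
    names: dict = {}
    i = 0
    for _ in range(cfg.n_enrich_rbps):
        names[f"RBP_E{i:03d}"] = "E"
        i += 1
    for _ in range(cfg.n_mixed_rbps):
        names[f"RBP_M{i:03d}"] = "M"
        i += 1
    for _ in range(cfg.n_deplete_rbps):
        names[f"RBP_D{i:03d}"] = "D"
        i += 1
    for _ in range(cfg.n_promiscuous):
        names[f"RBP_P{i:03d}"] = "promiscuous"
        i += 1
    while i < cfg.n_rbps:
        names[f"RBP_N{i:03d}"] = "none"
        i += 1
    return names


def generate_compendium(cfg: SimulationConfig, rng=None) -> FunctionalUnitCompendium:
    """Sample the unit compendium: planted-size units first, then filler.

    Units are carved from a single global shuffle of the gene pool, so
    with ``overlap_fraction`` = 0 they are pairwise disjoint; with a
    positive fraction, each unit at an odd position reuses that fraction
    of the previous unit's members.  Unit ids encode their role (U_enr*,
    U_dep*, U_bg*) purely for readability; nothing downstream reads the
    names.  Raises when the total (non-shared) demand exceeds the pool.
    """
    rng = cfg.rng(_STREAM_COMPENDIUM) if rng is None else rng
    genes = _gene_ids(cfg.n_genes)
    pool = [genes[i] for i in rng.permutation(cfg.n_genes)]

    sizes = (
        [("U_enr", "complex", cfg.unit_size)] * cfg.n_enrich_units
        + [("U_dep", "pathway-A", cfg.avoidance_unit_size)] * cfg.n_deplete_units
        + [("U_bg", "module", cfg.unit_size)] * (cfg.n_units - cfg.n_planted_units)
    )
    units = []
    counters: dict = {}
    offset = 0
    prev: list = []
    for pos, (prefix, source, size) in enumerate(sizes):
        shared: list = []
        if cfg.overlap_fraction > 0 and pos % 2 == 1:
            shared = prev[: int(round(cfg.overlap_fraction * size))]
        n_fresh = size - len(shared)
        if offset + n_fresh > cfg.n_genes:
            raise ValueError(
                f"requested unit sizes need {offset + n_fresh} genes, pool has {cfg.n_genes}"
            )
        members = shared + pool[offset : offset + n_fresh]
        offset += n_fresh
        i = counters.get(prefix, 0)
        counters[prefix] = i + 1
        units.append(FunctionalUnit(f"{prefix}{i:03d}", source, frozenset(members)))
        prev = members
    return FunctionalUnitCompendium(units)


def _plant_assignments(cfg: SimulationConfig) -> list:
    """Deterministic (rbp_id, unit_id, mode) plants."""
    names = _rbp_names(cfg)
    plants = []
    enr_i = dep_i = 0
    for rbp, cls in names.items():
        if cls in ("E", "M"):
            for _ in range(cfg.units_per_mode):
                plants.append((rbp, f"U_enr{enr_i:03d}", ENRICH))
                enr_i += 1
        if cls in ("M", "D"):
            for _ in range(cfg.units_per_mode):
                plants.append((rbp, f"U_dep{dep_i:03d}", DEPLETE))
                dep_i += 1
    return plants


def generate_score_matrix(
    cfg: SimulationConfig, compendium: FunctionalUnitCompendium, rng=None
):
    """Scored matrix with planted structure, plus the ground-truth ledger.

    When a gene belongs to both an enrichment- and an avoidance-planted
    unit of the same RBP (possible when units overlap), the enrichment
    probability wins; the rule is deterministic and logged in the ledger
    params.
    """
    rng = cfg.rng(_STREAM_SCORES) if rng is None else rng
    genes = _gene_ids(cfg.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    names = _rbp_names(cfg)
    rbps = list(names)

    P = np.full((len(rbps), cfg.n_genes), cfg.p_background)
    for j, rbp in enumerate(rbps):
        if names[rbp] == "promiscuous":
            P[j, :] = cfg.promiscuous_rate

    plants = _plant_assignments(cfg)
    members_of = {u.unit_id: u.members for u in compendium}
    for rbp, unit_id, mode in plants:
        j = rbps.index(rbp)
        cols = [gene_index[g] for g in members_of[unit_id]]
        P[j, cols] = cfg.p_deplete if mode == DEPLETE else cfg.p_enrich
    for rbp, unit_id, mode in plants:  # enrichment overrides on shared genes
        if mode == ENRICH:
            j = rbps.index(rbp)
            cols = [gene_index[g] for g in members_of[unit_id]]
            P[j, cols] = cfg.p_enrich

    Z = rng.standard_normal(P.shape)
    scores = cfg.threshold + cfg.score_sd * (Z + norm.ppf(P))
    matrix = ScoredInteractionMatrix(pd.DataFrame(scores, index=rbps, columns=genes))

    ledger = GroundTruthLedger(
        planted=plants,
        intended_class={
            r: (cls if cls in ("E", "M", "D") else "none") for r, cls in names.items()
        },
        promiscuous=[r for r, cls in names.items() if cls == "promiscuous"],
        unit_members={u.unit_id: sorted(u.members) for u in compendium},
        params={**asdict(cfg), "plant_conflict_rule": "enrich overrides deplete"},
    )
    return matrix, ledger


def generate_features(cfg: SimulationConfig, intended_classes: dict, rng=None):
    """Group-biased molecular feature tables for the given RBPs.

    Returns (annotations, ptm_table, tracks, expression):
      * annotations: rbp_id -> RbpAnnotation with group-specific category
        priors and uniform sequence lengths,
      * ptm_table: DataFrame (rbp_id, ptm_type, position); site counts are
        Poisson(group rate x length), positions uniform,
      * tracks: rbp_id -> ResidueTrack (disorder probabilities Beta with
        the configured mean; low-complexity mask Bernoulli),
      * expression: rbp_id -> ExpressionProfile over ``n_tissues`` tissues.
    """
    rng = cfg.rng(_STREAM_FEATURES) if rng is None else rng
    annotations: dict = {}
    ptm_rows = []
    tracks: dict = {}
    expression: dict = {}
    lo, hi = cfg.seq_len_range
    ptm_type_weights = np.array([0.08, 0.06, 0.01, 0.01, 0.64, 0.04, 0.16])

    for rbp, cls in intended_classes.items():
        grp = cls if cls in ("E", "M", "D") else "none"
        length = int(rng.integers(lo, hi + 1))
        established = bool(rng.random() < cfg.established_prior[grp])
        has_rbd = bool(rng.random() < cfg.rbd_prior[grp])
        is_enigm = not established and not has_rbd
        is_enzyme = bool(rng.random() < cfg.enzyme_prior)
        annotations[rbp] = RbpAnnotation(rbp, established, has_rbd, is_enigm, is_enzyme, length)

        n_sites = int(rng.poisson(cfg.ptm_rate[grp] * length))
        if n_sites:
            types = rng.choice(len(PTM_TYPES), size=n_sites, p=ptm_type_weights)
            positions = rng.integers(1, length + 1, size=n_sites)
            for t, pos in zip(types, positions):
                ptm_rows.append({"rbp_id": rbp, "ptm_type": PTM_TYPES[t], "position": int(pos)})

        mean = cfg.disorder_mean
        a = mean * 8.0
        b = (1.0 - mean) * 8.0
        disorder = tuple(float(x) for x in rng.beta(a, b, size=length))
        mask = tuple(bool(x) for x in rng.random(length) < cfg.low_complexity_rate)
        tracks[rbp] = ResidueTrack(rbp, disorder, mask)

        levels: dict = {}
        reliability: dict = {}
        p_expr = cfg.expressed_prior[grp]
        for t in range(cfg.n_tissues):
            tissue = f"tissue{t:02d}"
            if rng.random() < p_expr:
                levels[tissue] = ("low", "medium", "high")[int(rng.integers(3))]
            else:
                levels[tissue] = "not detected"
            reliability[tissue] = "approved" if rng.random() < 0.9 else "uncertain"
        expression[rbp] = ExpressionProfile(rbp, levels, reliability)

    ptm_table = pd.DataFrame(ptm_rows, columns=["rbp_id", "ptm_type", "position"])
    return annotations, ptm_table, tracks, expression


def generate_peak_fixture(cfg: SimulationConfig, rng=None):
    """Toy genome with known peak-transcript overlaps.

    Returns (peaks, transcripts, expected_network) where ``expected_network``
    is derived directly from the construction (not by interval search), so
    it can serve as an oracle for the peak-mapping code.  Includes two
    isoforms of one gene hit by separate peaks (must collapse to one edge)
    and one peak on a chromosome absent from the transcript table (must be
    logged, not mapped).
    """
    rng = cfg.rng(_STREAM_PEAKS) if rng is None else rng
    transcripts = []
    n_genes = 8
    for i in range(n_genes):
        chrom = "chr1" if i < n_genes // 2 else "chr2"
        start = 1000 + 2000 * i
        transcripts.append(
            TranscriptModel(
                f"tx{i:02d}a",
                f"gene{i:02d}",
                GenomicInterval(chrom, start, start + 900, "+"),
                900,
            )
        )
    # a second isoform of gene00, downstream of the first
    transcripts.append(
        TranscriptModel("tx00b", "gene00", GenomicInterval("chr1", 2100, 2600, "+"), 500)
    )

    peaks = []
    expected_edges = set()
    rbps = ["RBPa", "RBPb", "RBPc"]
    for rbp in rbps:
        hit = rng.choice(n_genes, size=3, replace=False)
        for i in hit:
            t = transcripts[i]
            mid = (t.interval.start + t.interval.end) // 2
            peaks.append((rbp, GenomicInterval(t.interval.chrom, mid - 50, mid + 50, "+")))
            expected_edges.add((rbp, t.gene_id))
    # both isoforms of gene00 hit by RBPa: still a single edge
    peaks.append(("RBPa", GenomicInterval("chr1", 1050, 1150, "+")))
    peaks.append(("RBPa", GenomicInterval("chr1", 2150, 2250, "+")))
    expected_edges.add(("RBPa", "gene00"))
    # unmapped peak: chromosome absent from the transcript table
    peaks.append(("RBPb", GenomicInterval("chrM", 10, 110, "+")))

    expected = BinaryInteractionNetwork(
        frozenset(rbps),
        frozenset(t.gene_id for t in transcripts),
        frozenset(expected_edges),
    )
    return peaks, transcripts, expected


def simulate_to_dir(cfg: SimulationConfig, outdir) -> GroundTruthLedger:
    """Generate a full instance and write every artefact as text files.

    Writes scores.tsv, fu.gmt, net.tsv (binarised edges), annotations.tsv,
    ptm.tsv, expr.tsv, tracks.tsv, peaks.bed, transcripts.tsv and
    ledger.json into ``outdir``.
    """
    from .data_io import binarize

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    compendium = generate_compendium(cfg)
    matrix, ledger = generate_score_matrix(cfg, compendium)
    annotations, ptm_table, tracks, expression = generate_features(
        cfg, ledger.intended_class
    )
    peaks, transcripts, _ = generate_peak_fixture(cfg)

    write_score_matrix(matrix, outdir / "scores.tsv")
    write_gene_sets(compendium, outdir / "fu.gmt")
    write_edge_list(binarize(matrix, cfg.threshold), outdir / "net.tsv")
    from .feature_analysis import write_annotations

    write_annotations(annotations, outdir / "annotations.tsv")
    ptm_table.to_csv(outdir / "ptm.tsv", sep="\t", index=False)
    rows = []
    for rbp, prof in expression.items():
        for tissue, level in prof.levels.items():
            rows.append(
                {
                    "gene_id": rbp,
                    "tissue": tissue,
                    "level": level,
                    "reliability": prof.reliability[tissue],
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "expr.tsv", sep="\t", index=False)
    track_rows = [
        {
            "rbp_id": r,
            "disorder": ",".join(f"{x:.4f}" for x in t.disorder),
            "low_complexity": "".join("1" if m else "0" for m in t.low_complexity_mask),
        }
        for r, t in tracks.items()
    ]
    pd.DataFrame(track_rows).to_csv(outdir / "tracks.tsv", sep="\t", index=False)
    with open(outdir / "peaks.bed", "w") as fh:
        for rbp, iv in peaks:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rbp}\t0\t{iv.strand}\n")
    write_transcript_table(transcripts, outdir / "transcripts.tsv")
    ledger.to_json(outdir / "ledger.json")
    return ledger
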