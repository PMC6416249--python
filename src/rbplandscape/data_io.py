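"""Input/output and network construction.

Reads the external formats the pipeline consumes (BED6 peaks, transcript
tables, GMT-like gene-set compendia, scored interaction matrices, edge
lists), builds gene-level RBP-mRNA interaction networks from genomic peaks
or score matrices, applies the sequence-selection filters, and defines the
statistical background over which all enrichment tests are run.

Coordinate convention is BED throughout: 0-based, half-open intervals.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger("rbplandscape")

#: Functional-unit size bounds applied before testing.
DEFAULT_MIN_UNIT_SIZE = 5
DEFAULT_MAX_UNIT_SIZE = 500

#: Interaction-propensity cutoff separating interacting from
#: non-interacting protein-mRNA pairs.
DEFAULT_SCORE_THRESHOLD = 50.0

#: Transcript length window (nucleotides) for representative-sequence
#: selection.
DEFAULT_LEN_MIN_NT = 50
DEFAULT_LEN_MAX_NT = 1200

#: Protein length window (amino acids).
DEFAULT_AA_MIN = 50
DEFAULT_AA_MAX = 750


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): start must be < end"
            )

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        """True if the two intervals share at least one base."""
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with its gene assignment and spliced length."""

    transcript_id: str
    gene_id: str
    interval: GenomicInterval
    length_nt: int

    def __post_init__(self) -> None:
        if self.length_nt < 1:
            raise ValueError("length_nt must be >= 1")
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")


@dataclass
class BinaryInteractionNetwork:
    """Gene-level RBP-mRNA network: unweighted edges over a tested universe.

    ``genes`` is the tested universe (all genes that *could* have been
    called interacting), which may be larger than the set of genes with at
    least one edge.
    """

    rbps: frozenset
    genes: frozenset
    edges: frozenset  # of (rbp_id, gene_id)

    def __post_init__(self) -> None:
        self.rbps = frozenset(self.rbps)
        self.genes = frozenset(self.genes)
        self.edges = frozenset(self.edges)
        for rbp, gene in self.edges:
            if rbp not in self.rbps or gene not in self.genes:
                raise ValueError(f"edge ({rbp}, {gene}) has endpoint outside universe")

    def targets_of(self, rbp_id: str) -> frozenset:
        return frozenset(g for r, g in self.edges if r == rbp_id)

    def targets_by_rbp(self) -> dict:
        out: dict = {r: set() for r in self.rbps}
        for r, g in self.edges:
            out[r].add(g)
        return {r: frozenset(gs) for r, gs in out.items()}


@dataclass
class ScoredInteractionMatrix:
    """Dense RBP x gene interaction-propensity matrix (catRAPID scale).

    Backed by a pandas DataFrame with RBP ids as the index and gene ids as
    columns; every cell must be finite.
    """

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        import numpy as np

        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValueError("interaction scores must all be finite")

    @property
    def rbps(self) -> frozenset:
        return frozenset(self.scores.index)

    @property
    def genes(self) -> frozenset:
        return frozenset(self.scores.columns)

    def score(self, rbp_id: str, gene_id: str) -> float:
        return float(self.scores.at[rbp_id, gene_id])


@dataclass(frozen=True)
class FunctionalUnit:
    """A named gene set: protein complex, interactome module, or pathway."""

    unit_id: str
    source: str
    members: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValueError(f"unit {self.unit_id!r} has no members")


@dataclass
class FunctionalUnitCompendium:
    """An ordered collection of functional units with size bounds."""

    units: list
    size_min: int = DEFAULT_MIN_UNIT_SIZE
    size_max: int = DEFAULT_MAX_UNIT_SIZE

    def __post_init__(self) -> None:
        seen = set()
        for u in self.units:
            if u.unit_id in seen:
                raise ValueError(f"duplicate unit_id {u.unit_id!r}")
            seen.add(u.unit_id)

    def __len__(self) -> int:
        return len(self.units)

    def __iter__(self):
        return iter(self.units)

    def unit(self, unit_id: str) -> FunctionalUnit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    @property
    def all_members(self) -> frozenset:
        out: set = set()
        for u in self.units:
            out |= u.members
        return frozenset(out)


# ---------------------------------------------------------------------------
# Gene-set (GMT-like) I/O
# ---------------------------------------------------------------------------

def read_gene_sets(path) -> FunctionalUnitCompendium:
    """Parse a GMT-like file: unit_id, source tag, then member ids, tab-separated.

    Duplicate member ids within a unit are collapsed; unit order is
    preserved. Raises ``ValueError`` (naming the line) on malformed lines
    or duplicate unit ids.
    """
    units = []
    seen = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected unit_id, source and >=1 member, "
                    f"got {len(fields)} field(s)"
                )
            unit_id, source, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: unit {unit_id!r} has no members")
            if unit_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate unit_id {unit_id!r}")
            seen.add(unit_id)
            units.append(FunctionalUnit(unit_id, source, frozenset(members)))
    return FunctionalUnitCompendium(units)


def write_gene_sets(compendium: FunctionalUnitCompendium, path) -> None:
    """Write a compendium in the GMT-like format read by :func:`read_gene_sets`."""
    with open(path, "w") as fh:
        for u in compendium:
            fh.write("\t".join([u.unit_id, u.source, *sorted(u.members)]) + "\n")


def filter_compendium(
    compendium: FunctionalUnitCompendium,
    universe: Iterable,
    min_size: int = DEFAULT_MIN_UNIT_SIZE,
    max_size: int = DEFAULT_MAX_UNIT_SIZE,
) -> FunctionalUnitCompendium:
    """Restrict units to a gene universe and apply the size window.

    Each retained unit's member set is replaced by its intersection with
    ``universe``; units whose intersection falls outside
    ``[min_size, max_size]`` are dropped. Idempotent.
    """
    if min_size < 1 or max_size < min_size:
        raise ValueError("require 1 <= min_size <= max_size")
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty gene universe")
    kept = []
    for u in compendium:
        members = u.members & universe
        if min_size <= len(members) <= max_size:
            kept.append(FunctionalUnit(u.unit_id, u.source, members))
    return FunctionalUnitCompendium(kept, size_min=min_size, size_max=max_size)


# ---------------------------------------------------------------------------
# Peak-to-gene mapping
# ---------------------------------------------------------------------------

def read_bed_peaks(path) -> list:
    """Read BED6 peaks as (rbp_id, GenomicInterval); the name column is the RBP id."""
    peaks = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED line needs >=4 columns")
            chrom, start, end, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 else "."
            peaks.append((name, GenomicInterval(chrom, int(start), int(end), strand)))
    return peaks


def read_transcript_table(path) -> list:
    """Read the tab-separated transcript table.

    Columns: transcript_id, gene_id, chrom, start, end, strand, length_nt.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=0,
        dtype={"transcript_id": str, "gene_id": str, "chrom": str, "strand": str},
    )
    required = {"transcript_id", "gene_id", "chrom", "start", "end", "strand", "length_nt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        TranscriptModel(
            row.transcript_id,
            row.gene_id,
            GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
            int(row.length_nt),
        )
        for row in df.itertuples()
    ]


def write_transcript_table(transcripts: Sequence[TranscriptModel], path) -> None:
    rows = [
        {
            "transcript_id": t.transcript_id,
            "gene_id": t.gene_id,
            "chrom": t.interval.chrom,
            "start": t.interval.start,
            "end": t.interval.end,
            "strand": t.interval.strand,
            "length_nt": t.length_nt,
        }
        for t in transcripts
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def map_peaks_to_genes(
    peaks: Iterable,
    transcripts: Sequence[TranscriptModel],
    stranded: bool = False,
) -> BinaryInteractionNetwork:
    """Collapse peak-transcript overlaps into a gene-level binary network.

    An edge (rbp, gene) exists iff at least one peak of the RBP overlaps at
    least one transcript of the gene by >= 1 base; replicate peaks and
    isoforms collapse to a single edge. The gene universe is every gene in
    the transcript table, so genes without any peak remain available as
    non-interactors for downstream contingency tables. Peaks on
    chromosomes absent from the transcript table are skipped and counted
    in a logged summary, never fatal.
    """
    trees: dict = defaultdict(IntervalTree)
    for t in transcripts:
        key = (t.interval.chrom, t.interval.strand) if stranded else t.interval.chrom
        trees[key].addi(t.interval.start, t.interval.end, t.gene_id)

    rbps: set = set()
    edges: set = set()
    n_unmapped = 0
    for rbp_id, iv in peaks:
        rbps.add(rbp_id)
        key = (iv.chrom, iv.strand) if stranded else iv.chrom
        tree = trees.get(key)
        if tree is None:
            n_unmapped += 1
            continue
        hits = tree.overlap(iv.start, iv.end)
        if not hits:
            n_unmapped += 1
            continue
        for hit in hits:
            edges.add((rbp_id, hit.data))
    if n_unmapped:
        logger.info("map_peaks_to_genes: %d peak(s) unmapped to any transcript", n_unmapped)
    genes = frozenset(t.gene_id for t in transcripts)
    return BinaryInteractionNetwork(frozenset(rbps), genes, frozenset(edges))


def select_representative_transcripts(
    transcripts: Sequence[TranscriptModel],
    len_min_nt: int = DEFAULT_LEN_MIN_NT,
    len_max_nt: int = DEFAULT_LEN_MAX_NT,
) -> dict:
    """Pick one representative transcript per gene.

    Transcripts outside ``[len_min_nt, len_max_nt]`` (inclusive) are
    discarded first; among the survivors the longest is chosen, ties broken
    by lexicographically smallest transcript id. Genes with no surviving
    transcript are absent from the returned mapping.
    """
    best: dict = {}
    for t in transcripts:
        if not (len_min_nt <= t.length_nt <= len_max_nt):
            continue
        cur = best.get(t.gene_id)
        if cur is None or (t.length_nt, _neg_id(t.transcript_id)) > (
            cur.length_nt,
            _neg_id(cur.transcript_id),
        ):
            best[t.gene_id] = t
    return {gene: t.transcript_id for gene, t in best.items()}


class _neg_id:
    """Orders string ids descending so max() picks the lexicographically smallest."""

    __slots__ = ("s",)

    def __init__(self, s: str) -> None:
        self.s = s

    def __lt__(self, other: "_neg_id") -> bool:
        return self.s > other.s

    def __gt__(self, other: "_neg_id") -> bool:
        return self.s < other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _neg_id) and self.s == other.s


def filter_proteins_by_length(
    lengths: Mapping,
    aa_min: int = DEFAULT_AA_MIN,
    aa_max: int = DEFAULT_AA_MAX,
) -> frozenset:
    """Keep RBPs whose sequence length lies in [aa_min, aa_max], inclusive."""
    for rbp, n in lengths.items():
        if n <= 0:
            raise ValueError(f"non-positive sequence length for {rbp!r}")
    return frozenset(r for r, n in lengths.items() if aa_min <= n <= aa_max)


# ---------------------------------------------------------------------------
# Score matrix handling
# ---------------------------------------------------------------------------

def read_score_matrix(path) -> ScoredInteractionMatrix:
    """Read a TSV score matrix: first column RBP ids, header row gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ScoredInteractionMatrix(df.astype(float))


def write_score_matrix(matrix: ScoredInteractionMatrix, path) -> None:
    matrix.scores.to_csv(path, sep="\t", index_label="rbp_id")


def binarize(
    matrix: ScoredInteractionMatrix,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> BinaryInteractionNetwork:
    """Call pairs with score >= threshold interacting; universe unchanged."""
    import math

    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    df = matrix.scores
    mask = df.to_numpy() >= threshold
    rbp_ids = list(df.index)
    gene_ids = list(df.columns)
    edges = frozenset(
        (rbp_ids[i], gene_ids[j]) for i, j in zip(*mask.nonzero())
    )
    return BinaryInteractionNetwork(frozenset(rbp_ids), frozenset(gene_ids), edges)


# ---------------------------------------------------------------------------
# Edge-list I/O
# ---------------------------------------------------------------------------

def read_edge_list(path) -> BinaryInteractionNetwork:
    """Read a network as edge-list TSV with header rbp_id, gene_id.

    Optional header lines beginning ``#universe`` enumerate universe genes
    without edges so that round-trips preserve the tested space.
    """
    edges: set = set()
    rbps: set = set()
    genes: set = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#universe\t"):
                genes.update(line.split("\t")[1:])
                continue
            if line.startswith("rbp_id"):
                continue
            rbp, gene = line.split("\t")[:2]
            edges.add((rbp, gene))
            rbps.add(rbp)
            genes.add(gene)
    return BinaryInteractionNetwork(frozenset(rbps), frozenset(genes), frozenset(edges))


def write_edge_list(network: BinaryInteractionNetwork, path) -> None:
    with open(path, "w") as fh:
        bare = sorted(network.genes - {g for _, g in network.edges})
        if bare:
            fh.write("#universe\t" + "\t".join(bare) + "\n")
        fh.write("rbp_id\tgene_id\n")
        for rbp, gene in sorted(network.edges):
            fh.write(f"{rbp}\t{gene}\n")


# ---------------------------------------------------------------------------
# Statistical background
# ---------------------------------------------------------------------------

def define_background(
    network,
    compendium: FunctionalUnitCompendium,
    use_full_universe: bool = False,
) -> frozenset:
    """Genes of the tested universe annotated in at least one functional unit.

    This is the statistical background over which every contingency table
    is built. With ``use_full_universe=True`` the whole tested universe is
    returned instead (sensitivity analysis).
    """
    universe = frozenset(network.genes) if hasattr(network, "genes") else frozenset(network)
    if use_full_universe:
        return universe
    background = universe & compendium.all_members
    if not background:
        raise ValueError("no tested gene is annotated in any functional unit")
    return background
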