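"""Seeded generators for synthetic inputs with known ground truth.

Three generators mirror the statistical regimes the analysis assumes, so the
whole pipeline is exercisable without any downloads:

* AT-rich centromere-like DNA with planted inverted repeats whose expected
  count falls linearly with GC content (the negative GC–dyad-density regime);
* protein alignments with a conserved C-terminal block, a divergent
  N-terminal block and a lineage-restricted N-terminal insertion realized as
  a gap block in the non-carrier rows;
* presence/absence matrices produced by planting irreversible loss events on
  branches of a species tree.

Every generator is bit-reproducible under its seed and returns a
:class:`SimTruth` sufficient to score the downstream stage that consumes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import AMINO_ACIDS, GAP, Category, Msa, PresenceMatrix, SequenceRecord, SpeciesTree
from .dyad_analysis import Dyad, reverse_complement

import pandas as pd

__all__ = [
    "CentromereSimSpec",
    "SequenceTruth",
    "MsaTruth",
    "MatrixTruth",
    "SimTruth",
    "simulate_centromeres",
    "simulate_msa",
    "simulate_presence_matrix",
    "simulate_naumovozyma_panel",
    "NAUMOVOZYMA_GC_RANGES",
    "NAUMOVOZYMA_GROUP_SIZES",
]

# Reported GC-percent summaries (mean, min, max) of the old (syntenic,
# S. cerevisiae-like) and new (relocated) centromere regions in the two
# Naumovozyma species.  The panel generator draws per-sequence GC from a
# normal centred on the group mean, truncated to the reported extremes, with
# the spread implied by the range (range ~ 3.1-3.3 sd for samples of 10-12).
NAUMOVOZYMA_GC_RANGES: dict[tuple[str, str], tuple[float, float, float]] = {
    ("Naumovozyma_castellii", "new_centromere"): (21.36, 18.18, 24.55),
    ("Naumovozyma_castellii", "old_centromere"): (30.15, 21.82, 36.47),
    ("Naumovozyma_dairenensis", "new_centromere"): (25.80, 20.00, 35.16),
    ("Naumovozyma_dairenensis", "old_centromere"): (31.58, 22.03, 37.32),
}

NAUMOVOZYMA_GROUP_SIZES = {
    "Naumovozyma_castellii": 10,
    "Naumovozyma_dairenensis": 12,
}

_RANGE_TO_SD = 3.2  # expected (max - min)/sd for a normal sample of n ~= 10-12


@dataclass(frozen=True)
class CentromereSimSpec:
    """Study conditions for the centromere-like sequence generator.

    The expected planted-dyad count is proportional to sequence length:
    ``lambda = max(0, dyad_rate_intercept − dyad_rate_slope · gc_percent)``
    dyads per 500 bp.  Modest planting on top of the intrinsic dyad-richness
    of AT-biased i.i.d. sequence produces the monotone negative GC–dyad
    trend without saturating short sequences.
    """

    n_sequences: int = 200
    length_range: tuple[int, int] = (100, 500)
    gc_range: tuple[float, float] = (15.0, 45.0)
    dyad_rate_intercept: float = 2.5
    dyad_rate_slope: float = 0.05
    arm_range: tuple[int, int] = (5, 12)
    spacer_range: tuple[int, int] = (0, 20)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        for lo, hi, name in (
            (*self.length_range, "length_range"),
            (*self.gc_range, "gc_range"),
            (*self.arm_range, "arm_range"),
            (*self.spacer_range, "spacer_range"),
        ):
            if lo > hi:
                raise ValueError(f"degenerate {name}: ({lo}, {hi})")
        if self.length_range[0] < 2 * self.arm_range[1] + self.spacer_range[1]:
            raise ValueError("shortest sequence cannot host the largest dyad")


@dataclass
class SequenceTruth:
    """Ground truth for one simulated sequence."""

    id: str
    gc_drawn: float
    planted_dyads: list[Dyad]
    planted_coverage: float  # fraction of positions inside planted arms


@dataclass
class MsaTruth:
    column_rates: np.ndarray  # per alignment column; NaN at insertion columns
    insertion_columns: tuple[int, int] | None  # half-open range
    insertion_lineages: list[str]


@dataclass
class MatrixTruth:
    loss_branches: dict[str, frozenset[str]]  # gene -> planted branch ids


@dataclass
class SimTruth:
    """Container bundling whichever ground-truth sections a generator filled."""

    sequences: list[SequenceTruth] = field(default_factory=list)
    msa: MsaTruth | None = None
    matrix: MatrixTruth | None = None


_MAX_PLACEMENT_ATTEMPTS = 100


def _feasible_starts(
    length: int, span: int, occupied: list[tuple[int, int]]
) -> list[int]:
    """Left positions where a span fits without touching any occupied interval."""
    if span > length:
        return []
    free = []
    cursor = 0
    for s, e in sorted(occupied):
        if s - cursor >= span:
            free.extend(range(cursor, s - span + 1))
        cursor = max(cursor, e)
    if length - cursor >= span:
        free.extend(range(cursor, length - span + 1))
    return free


def _draw_bases(rng: np.random.Generator, n: int, gc_percent: float) -> np.ndarray:
    p_gc = gc_percent / 100.0
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]  # A C G T
    return rng.choice(np.array(list("ACGT")), size=n, p=probs)


def simulate_centromeres(
    spec: CentromereSimSpec,
) -> tuple[list[SequenceRecord], SimTruth]:
    """Generate centromere-like sequences with planted, non-overlapping dyads.

    Each sequence draws its GC uniformly from ``gc_range``, emits i.i.d.
    bases at that composition and plants ``Poisson(lambda)`` dyads (arm and
    spacer uniform in their ranges; left-arm content at the sequence
    composition, right arm its reverse complement).  Each planting attempt
    draws arm and spacer and places uniformly among the positions that do not
    overlap an already-planted dyad; a sequence that cannot host another dyad
    after 100 attempts is saturated, and planting stops there for that
    sequence (the truth table records exactly what was planted).
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SequenceRecord] = []
    truths: list[SequenceTruth] = []
    for idx in range(spec.n_sequences):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        gc = float(rng.uniform(*spec.gc_range))
        bases = _draw_bases(rng, length, gc)
        lam = max(0.0, spec.dyad_rate_intercept - spec.dyad_rate_slope * gc) * (
            length / 500.0
        )
        n_dyads = int(rng.poisson(lam))
        planted: list[Dyad] = []
        occupied: list[tuple[int, int]] = []
        for _ in range(n_dyads):
            placed = False
            for _attempt in range(_MAX_PLACEMENT_ATTEMPTS):
                arm = int(rng.integers(spec.arm_range[0], spec.arm_range[1] + 1))
                spacer = int(rng.integers(spec.spacer_range[0], spec.spacer_range[1] + 1))
                span = 2 * arm + spacer
                feasible = _feasible_starts(length, span, occupied)
                if not feasible:
                    continue
                left = int(rng.choice(feasible))
                left_arm = _draw_bases(rng, arm, gc)
                right_arm = np.array(list(reverse_complement("".join(left_arm))))
                bases[left : left + arm] = left_arm
                bases[left + arm + spacer : left + span] = right_arm
                planted.append(Dyad(left, arm, spacer))
                occupied.append((left, left + span))
                placed = True
                break
            if not placed:
                # saturated: no feasible slot in 100 draws; plant no more here
                break
        planted.sort(key=lambda d: d.left_start)
        covered = sum(2 * d.arm_length for d in planted)
        rec = SequenceRecord(
            id=f"sim_cen_{idx:04d}",
            sequence="".join(bases),
            category=Category.CENTROMERE,
        )
        records.append(rec)
        truths.append(
            SequenceTruth(
                id=rec.id,
                gc_drawn=gc,
                planted_dyads=planted,
                planted_coverage=covered / length,
            )
        )
    return records, SimTruth(sequences=truths)


def simulate_naumovozyma_panel(
    seed: int = 0, length_range: tuple[int, int] = (120, 300)
) -> tuple[list[SequenceRecord], SimTruth]:
    """Old/new centromere-like panels for the two Naumovozyma species.

    One sequence group per (species, category), sized like a chromosome
    complement, with per-sequence GC drawn from the group's reported
    composition summary (:data:`NAUMOVOZYMA_GC_RANGES`).  Returns records
    tagged with species and category, ready for GC profiling and
    within-species group comparison.
    """
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    truths: list[SequenceTruth] = []
    for (species, category), (mean, lo, hi) in sorted(NAUMOVOZYMA_GC_RANGES.items()):
        sd = (hi - lo) / _RANGE_TO_SD
        tag = species.split("_")[1][:4]
        for i in range(NAUMOVOZYMA_GROUP_SIZES[species]):
            gc = float(rng.normal(mean, sd))
            while not lo <= gc <= hi:
                gc = float(rng.normal(mean, sd))
            spec = CentromereSimSpec(
                n_sequences=1,
                length_range=length_range,
                gc_range=(gc, gc),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            (rec,), group_truth = simulate_centromeres(spec)
            rec.id = f"{tag}_{category.split('_')[0]}_{i:02d}"
            rec.species = species
            rec.category = Category(category)
            truth = group_truth.sequences[0]
            truth.id = rec.id
            records.append(rec)
            truths.append(truth)
    return records, SimTruth(sequences=truths)


def simulate_msa(
    n_seqs: int = 20,
    length: int = 120,
    conserved_block: tuple[int, int] = (70, 120),
    divergent_block: tuple[int, int] = (0, 40),
    insertion: tuple[list[str], int] | None = None,
    sub_rate_profile: np.ndarray | None = None,
    conserved_rate: float = 0.01,
    divergent_rate: float = 0.5,
    baseline_rate: float = 0.1,
    seed: int = 0,
) -> tuple[Msa, SimTruth]:
    """Simulate a protein alignment with block-structured per-column divergence.

    An ancestral sequence is mutated independently per column at the column's
    substitution rate (``sub_rate_profile`` overrides the block structure).
    ``insertion=(lineage_ids, block_len)`` prepends an N-terminal block
    carried only by the named lineages; all other rows show gaps there —
    the post-alignment view of a lineage-restricted insertion.
    """
    rng = np.random.default_rng(seed)
    ids = [f"taxon_{i:02d}" for i in range(n_seqs)]
    if sub_rate_profile is not None:
        rates = np.asarray(sub_rate_profile, dtype=float)
        if rates.shape != (length,):
            raise ValueError("sub_rate_profile must have one rate per core column")
    else:
        c0, c1 = conserved_block
        d0, d1 = divergent_block
        for lo, hi in (conserved_block, divergent_block):
            if not (0 <= lo <= hi <= length):
                raise ValueError("block outside sequence length")
        if max(c0, d0) < min(c1, d1):
            raise ValueError("conserved and divergent blocks overlap")
        rates = np.full(length, baseline_rate)
        rates[c0:c1] = conserved_rate
        rates[d0:d1] = divergent_rate
    if np.any(rates < 0) or np.any(rates > 1):
        raise ValueError("substitution rates must lie in [0, 1]")

    aa = np.array(list(AMINO_ACIDS))
    ancestor = rng.choice(aa, size=length)
    rows = []
    for _ in ids:
        mutate = rng.random(length) < rates
        row = ancestor.copy()
        if mutate.any():
            row[mutate] = rng.choice(aa, size=int(mutate.sum()))
        rows.append(row)

    insertion_cols: tuple[int, int] | None = None
    carriers: list[str] = []
    if insertion is not None:
        carriers, block_len = insertion
        unknown = set(carriers) - set(ids)
        if unknown:
            raise ValueError(f"insertion lineages not in alignment: {sorted(unknown)}")
        if block_len < 1:
            raise ValueError("insertion block length must be >= 1")
        insertion_cols = (0, block_len)
        for k, sid in enumerate(ids):
            block = (
                rng.choice(aa, size=block_len)
                if sid in carriers
                else np.full(block_len, GAP)
            )
            rows[k] = np.concatenate([block, rows[k]])
        rates = np.concatenate([np.full(block_len, np.nan), rates])

    records = [
        SequenceRecord(id=sid, sequence="".join(row)) for sid, row in zip(ids, rows)
    ]
    msa = Msa(records)
    truth = SimTruth(
        msa=MsaTruth(
            column_rates=rates,
            insertion_columns=insertion_cols,
            insertion_lineages=list(carriers),
        )
    )
    return msa, truth


def simulate_presence_matrix(
    tree: SpeciesTree,
    n_genes: int = 100,
    loss_prob_per_branch: float = 0.02,
    wgd_labels: dict[str, str] | None = None,
    seed: int = 0,
) -> tuple[PresenceMatrix, SimTruth]:
    """Plant irreversible loss events on tree branches for each gene.

    Every branch independently hosts a loss with probability
    ``loss_prob_per_branch``; all leaves below any loss branch get copy count
    0, the rest 1 (pre-WGD) or 2 (post-WGD).  ``wgd_labels`` maps species to
    PRE_WGD/POST_WGD (default: all POST_WGD).
    """
    if not 0 <= loss_prob_per_branch <= 1:
        raise ValueError("loss probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    leaves = tree.leaf_labels
    if wgd_labels is None:
        wgd_labels = {sp: "POST_WGD" for sp in leaves}
    nodes = [n for n in tree.tree.preorder_node_iter() if n is not tree.tree.seed_node]
    genes = [f"gene_{i:03d}" for i in range(n_genes)]
    counts = {}
    planted: dict[str, frozenset[str]] = {}
    for gene in genes:
        hit = rng.random(len(nodes)) < loss_prob_per_branch
        loss_nodes = [n for n, h in zip(nodes, hit) if h]
        absent: set[str] = set()
        for node in loss_nodes:
            absent |= node.leafset
        planted[gene] = frozenset(SpeciesTree.branch_id(n) for n in loss_nodes)
        counts[gene] = [
            0 if sp in absent else (1 if wgd_labels[sp] == "PRE_WGD" else 2)
            for sp in leaves
        ]
    frame = pd.DataFrame.from_dict(counts, orient="index", columns=leaves)
    frame = frame.loc[genes, leaves]
    matrix = PresenceMatrix(
        genes=genes, species=list(leaves), wgd_status=dict(wgd_labels), counts=frame
    )
    return matrix, SimTruth(matrix=MatrixTruth(loss_branches=planted))
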