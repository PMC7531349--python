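"""Kinetochore gene presence/absence analysis.

Loss calls from a gene-by-species copy matrix, Dollo-parsimony mapping of
loss events onto a species tree (presence is ancestral and can be lost on a
branch but never regained — the minimal explanation of an absence pattern is
the set of maximal all-absent clades), and open-reading-frame scanning of
intergenic regions used to confirm that a "lost" locus really carries no
unannotated gene.

For post-WGD species a gene counts as lost only when *both* ohnolog copies
are gone (copy count 0); single-ohnolog retention is presence.  The
alternative reading (count < 2 as loss) is available via a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .dyad_analysis import reverse_complement
from .io_formats import PresenceMatrix, SequenceRecord, SpeciesTree

__all__ = [
    "LossReport",
    "OrfRecord",
    "genes_lost_anywhere",
    "shared_pre_post_losses",
    "species_retaining_all",
    "dollo_loss_events",
    "find_orfs",
    "screen_intergenic",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"


def _loss_mask(matrix: PresenceMatrix, single_copy_post_is_loss: bool) -> pd.DataFrame:
    """Boolean gene × species frame marking loss calls."""
    if not single_copy_post_is_loss:
        return matrix.counts == 0
    mask = matrix.counts == 0
    for sp in matrix.post_wgd_species:
        mask[sp] = matrix.counts[sp] < 2
    return mask


def genes_lost_anywhere(
    matrix: PresenceMatrix, single_copy_post_is_loss: bool = False
) -> list[str]:
    """Genes lost (copy count 0) in at least one species, in input gene order."""
    mask = _loss_mask(matrix, single_copy_post_is_loss)
    return [g for g in matrix.genes if mask.loc[g].any()]


def shared_pre_post_losses(
    matrix: PresenceMatrix, single_copy_post_is_loss: bool = False
) -> list[str]:
    """Genes lost in ≥1 post-WGD species AND ≥1 pre-WGD species."""
    mask = _loss_mask(matrix, single_copy_post_is_loss)
    pre, post = matrix.pre_wgd_species, matrix.post_wgd_species
    return [
        g
        for g in matrix.genes
        if mask.loc[g, pre].any() and mask.loc[g, post].any()
    ]


def species_retaining_all(matrix: PresenceMatrix, genes: list[str]) -> int:
    """Number of species keeping ≥1 copy of every listed gene."""
    for g in genes:
        if g not in matrix.counts.index:
            raise ValueError(f"unknown gene {g!r}")
    if not genes:
        return len(matrix.species)
    present = (matrix.counts.loc[genes] >= 1).all(axis=0)
    return int(present.sum())


@dataclass
class LossReport:
    """Dollo reconstruction of one gene's absence pattern."""

    gene: str
    species_lost: frozenset[str]
    loss_branches: frozenset[str]
    lost_in_pre: bool
    lost_in_post: bool

    @property
    def n_events(self) -> int:
        return len(self.loss_branches)


def dollo_loss_events(
    matrix: PresenceMatrix, tree: SpeciesTree, gene: str
) -> LossReport:
    """Map a gene's absences onto the tree as irreversible loss events.

    The unique minimum-event Dollo reconstruction places one loss on the stem
    of each *maximal* subtree whose leaves all lack the gene.  When the gene
    is absent from every species the root's children carry the events (the
    root itself has no stem branch).
    """
    if gene not in matrix.counts.index:
        raise ValueError(f"unknown gene {gene!r}")
    tree_leaves = set(tree.leaf_labels)
    matrix_species = set(matrix.species)
    if matrix_species != tree_leaves:
        raise ValueError(
            "matrix species and tree leaves differ: "
            f"only-in-matrix={sorted(matrix_species - tree_leaves)}, "
            f"only-in-tree={sorted(tree_leaves - matrix_species)}"
        )
    absent = frozenset(
        sp for sp in matrix.species if int(matrix.counts.at[gene, sp]) == 0
    )
    root = tree.tree.seed_node
    branches: set[str] = set()
    if absent:
        for node in tree.tree.preorder_node_iter():
            if node is root:
                continue
            parent = node.parent_node
            if node.leafset <= absent and (
                parent is root or not parent.leafset <= absent
            ):
                branches.add(SpeciesTree.branch_id(node))
    pre = set(matrix.pre_wgd_species)
    return LossReport(
        gene=gene,
        species_lost=absent,
        loss_branches=frozenset(branches),
        lost_in_pre=bool(absent & pre),
        lost_in_post=bool(absent - pre),
    )


@dataclass(frozen=True)
class OrfRecord:
    """One open reading frame, forward-strand 0-based half-open coordinates.

    ``length_nt`` includes the stop codon (when terminated); ``protein``
    excludes it.  ``frame`` is the start offset modulo 3 on the ORF's own
    strand.
    """

    start: int
    end: int
    strand: str
    frame: int
    length_nt: int
    protein: str
    terminated: bool = True


def _scan_strand(seq: str, min_len: int, include_unterminated: bool) -> list[tuple]:
    """ORFs on one strand: (start, end, frame, protein, terminated) in local coords."""
    n = len(seq)
    out = []
    for frame in range(3):
        seg_start = frame
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                out.extend(
                    _orf_from_segment(seq, seg_start, i + 3, frame, True, min_len)
                )
                seg_start = i + 3
            i += 3
        if include_unterminated:
            # trailing segment runs to the last complete codon
            end = frame + 3 * ((n - frame) // 3)
            if end > seg_start:
                out.extend(
                    _orf_from_segment(seq, seg_start, end, frame, False, min_len)
                )
    return out


def _orf_from_segment(
    seq: str, seg_start: int, seg_end: int, frame: int, terminated: bool, min_len: int
) -> list[tuple]:
    # 5'-most ATG per (strand, frame, stop): only the longest ORF is kept
    for pos in range(seg_start, seg_end - (3 if terminated else 0), 3):
        if seq[pos : pos + 3] == START_CODON:
            length = seg_end - pos
            if length >= max(min_len, 3 + (3 if terminated else 0)):
                coding = seq[pos : seg_end - 3] if terminated else seq[pos:seg_end]
                protein = str(Seq(coding).translate())
                return [(pos, seg_end, frame, protein, terminated)]
            return []
    return []


def find_orfs(
    seq: str,
    min_len: int = 75,
    both_strands: bool = True,
    include_unterminated: bool = False,
) -> list[OrfRecord]:
    """All maximal ATG→stop ORFs of length ≥ ``min_len`` nt.

    Per (strand, frame, stop codon) only the 5'-most ATG (longest ORF) is
    reported.  ORFs running off the sequence end are included only with
    ``include_unterminated``.  Sorted by length descending, then by
    forward-strand coordinate.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    n = len(s)
    records: list[OrfRecord] = []
    for start, end, frame, protein, terminated in _scan_strand(
        s, min_len, include_unterminated
    ):
        records.append(
            OrfRecord(
                start=start,
                end=end,
                strand="+",
                frame=frame,
                length_nt=end - start,
                protein=protein,
                terminated=terminated,
            )
        )
    if both_strands:
        rc = reverse_complement(s)
        for start, end, frame, protein, terminated in _scan_strand(
            rc, min_len, include_unterminated
        ):
            records.append(
                OrfRecord(
                    start=n - end,
                    end=n - start,
                    strand="-",
                    frame=frame,
                    length_nt=end - start,
                    protein=protein,
                    terminated=terminated,
                )
            )
    records.sort(key=lambda r: (-r.length_nt, r.start, r.strand))
    return records


def screen_intergenic(
    records: list[SequenceRecord], min_len: int = 75
) -> pd.DataFrame:
    """One summary row per intergenic record: ORF count and the longest ORF.

    Records with no qualifying ORF are flagged ``no ORF`` — the evidence the
    loss screen uses to rule out an unannotated gene at a syntenic locus.
    """
    rows = []
    for rec in records:
        rec.validate_dna()
        orfs = find_orfs(rec.sequence, min_len=min_len)
        rows.append(
            {
                "id": rec.id,
                "n_orfs": len(orfs),
                "longest_orf_length": orfs[0].length_nt if orfs else 0,
                "longest_orf_protein": orfs[0].protein if orfs else "",
                "note": "" if orfs else "no ORF",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["id", "n_orfs", "longest_orf_length", "longest_orf_protein", "note"],
    )
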