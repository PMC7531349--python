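"""Readers, writers and shared record types for the pipeline's external formats.

Formats handled: FASTA (DNA and protein), aligned FASTA, the copy-count TSV
dialect for gene-by-species matrices, Newick species trees, and tab-separated
result tables.  All parsers validate eagerly and raise :class:`FormatError`
naming the offending record rather than silently coercing.

FASTA metadata dialect
----------------------
Headers may carry ``key=value`` tokens after the record id, e.g.::

    >CEN7 species=Naumovozyma_castellii category=new_centromere

``species`` and ``category`` are recognised; other tokens are ignored.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Category",
    "FormatError",
    "SequenceRecord",
    "Msa",
    "PresenceMatrix",
    "SpeciesTree",
    "read_fasta",
    "write_fasta",
    "read_msa",
    "write_msa",
    "read_copy_matrix",
    "write_copy_matrix",
    "read_species_tree",
    "write_table",
]

# IUPAC nucleotide codes (ambiguity codes are accepted but never treated as
# complementary to anything downstream).
DNA_ALPHABET = frozenset("ACGTNRYSWKMBDHV")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS)
GAP = "-"


class FormatError(ValueError):
    """Raised when an input file violates a format invariant."""


class Category(str, enum.Enum):
    """Functional category of a sequence region."""

    OLD_CENTROMERE = "old_centromere"
    NEW_CENTROMERE = "new_centromere"
    CENTROMERE = "centromere"
    INTERGENIC = "intergenic"
    OTHER = "other"


@dataclass
class SequenceRecord:
    """A named DNA or protein sequence with optional species/category metadata.

    Sequences are uppercased on construction; lowercase input is equivalent.
    DNA records must not contain gap characters.
    """

    id: str
    sequence: str
    species: str | None = None
    category: Category = Category.OTHER

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record has an empty id")
        self.sequence = self.sequence.upper()
        if len(self.sequence) == 0:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        if isinstance(self.category, str) and not isinstance(self.category, Category):
            self.category = Category(self.category)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate_dna(self) -> "SequenceRecord":
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r} contains non-DNA characters: {sorted(bad)}"
            )
        return self

    def validate_protein(self, allow_gaps: bool = True) -> "SequenceRecord":
        allowed = PROTEIN_ALPHABET | ({GAP} if allow_gaps else set())
        bad = set(self.sequence) - allowed
        if bad:
            raise FormatError(
                f"record {self.id!r} contains non-protein characters: {sorted(bad)}"
            )
        return self


@dataclass
class Msa:
    """A protein multiple sequence alignment (gapped, equal-length rows)."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise FormatError("an alignment needs at least 2 sequences")
        lengths = {r.length for r in self.records}
        if len(lengths) != 1:
            raise FormatError(
                f"alignment rows have unequal lengths: {sorted(lengths)}"
            )
        for r in self.records:
            r.validate_protein(allow_gaps=True)
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise FormatError("alignment contains duplicate sequence ids")

    @property
    def n_columns(self) -> int:
        return self.records[0].length

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    def column(self, i: int) -> str:
        return "".join(r.sequence[i] for r in self.records)


WGD_STATUSES = ("PRE_WGD", "POST_WGD")


@dataclass
class PresenceMatrix:
    """Gene-by-species retained-copy counts with pre/post-WGD annotation.

    Pre-WGD species carry a single gene slot (counts 0/1); post-WGD species
    carry two ohnolog slots (counts 0/1/2).  Copy counts rather than booleans
    are kept because "both copies lost in a post-WGD species" is distinct from
    single-ohnolog loss.
    """

    genes: list[str]
    species: list[str]
    wgd_status: dict[str, str]
    counts: pd.DataFrame  # index = genes, columns = species

    def __post_init__(self) -> None:
        if list(self.counts.index) != list(self.genes) or list(
            self.counts.columns
        ) != list(self.species):
            raise FormatError("counts frame does not match gene/species lists")
        if self.counts.isna().any().any():
            missing = self.counts.isna().stack()
            gene, sp = missing[missing].index[0]
            raise FormatError(f"missing copy count for gene {gene!r}, species {sp!r}")
        for sp in self.species:
            status = self.wgd_status.get(sp)
            if status not in WGD_STATUSES:
                raise FormatError(f"species {sp!r} lacks a PRE_WGD/POST_WGD annotation")
            col = self.counts[sp]
            if (col < 0).any():
                raise FormatError(f"negative copy count for species {sp!r}")
            cap = 1 if status == "PRE_WGD" else 2
            if (col > cap).any():
                gene = col.index[col > cap][0]
                raise FormatError(
                    f"copy count {int(col[gene])} exceeds {cap} for "
                    f"{status} species {sp!r}, gene {gene!r}"
                )

    @property
    def pre_wgd_species(self) -> list[str]:
        return [s for s in self.species if self.wgd_status[s] == "PRE_WGD"]

    @property
    def post_wgd_species(self) -> list[str]:
        return [s for s in self.species if self.wgd_status[s] == "POST_WGD"]


class SpeciesTree:
    """A rooted species tree with stable branch identifiers.

    Branch ids: a leaf's branch is named after the leaf; an internal branch is
    the ``|``-joined sorted list of the leaves below it.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise FormatError("species tree has duplicate leaf labels")
        self._leaves = labels
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                node.leafset = frozenset([node.taxon.label])
            else:
                node.leafset = frozenset().union(*(c.leafset for c in node.child_nodes()))

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(tree)

    @property
    def leaf_labels(self) -> list[str]:
        return list(self._leaves)

    @staticmethod
    def branch_id(node: dendropy.Node) -> str:
        return "|".join(sorted(node.leafset))

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# FASTA


def _parse_header_metadata(description: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    for token in description.split()[1:]:
        if "=" in token:
            key, _, value = token.partition("=")
            meta[key] = value
    return meta


def read_fasta(
    path: str | Path,
    category_map: Mapping[str, Category | str] | None = None,
    alphabet: str = "dna",
) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    ``alphabet`` is ``"dna"``, ``"protein"`` or ``None`` (skip validation).
    Categories come from ``category_map`` (keyed by id), else from
    ``category=`` header tokens, else default to ``other``.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise FormatError(f"{path}: duplicate record id {entry.id!r}")
        seen.add(entry.id)
        meta = _parse_header_metadata(entry.description)
        category: Category | str = Category.OTHER
        if category_map and entry.id in category_map:
            category = category_map[entry.id]
        elif "category" in meta:
            try:
                category = Category(meta["category"])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: record {entry.id!r} has unknown category "
                    f"{meta['category']!r}"
                ) from exc
        rec = SequenceRecord(
            id=entry.id,
            sequence=str(entry.seq),
            species=meta.get("species"),
            category=category,
        )
        if alphabet == "dna":
            rec.validate_dna()
        elif alphabet == "protein":
            rec.validate_protein()
        records.append(rec)
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    records: Iterable[SequenceRecord],
    path: str | Path,
    line_width: int = 60,
    include_metadata: bool = True,
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if include_metadata:
                if rec.species:
                    header += f" species={rec.species}"
                if rec.category is not Category.OTHER:
                    header += f" category={rec.category.value}"
            fh.write(f">{header}\n")
            for i in range(0, rec.length, line_width):
                fh.write(rec.sequence[i : i + line_width] + "\n")


def read_msa(path: str | Path) -> Msa:
    """Read an aligned (equal-length, gapped) protein FASTA into an :class:`Msa`."""
    path = Path(path)
    entries = list(SeqIO.parse(str(path), "fasta"))
    if not entries:
        raise FormatError(f"{path}: empty alignment")
    records = []
    for entry in entries:
        meta = _parse_header_metadata(entry.description)
        records.append(
            SequenceRecord(id=entry.id, sequence=str(entry.seq), species=meta.get("species"))
        )
    try:
        return Msa(records)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_msa(msa: Msa, path: str | Path) -> None:
    write_fasta(msa.records, path, include_metadata=False)


# ---------------------------------------------------------------------------
# Copy-count matrix TSV
#
# Dialect: first column "gene"; every other header cell is
# "<species>:<PRE_WGD|POST_WGD>"; cells are integer retained-copy counts.


def read_copy_matrix(path: str | Path) -> PresenceMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: matrix needs a gene column and ≥1 species column")
    gene_col = df.columns[0]
    species, status = [], {}
    for col in df.columns[1:]:
        name, sep, wgd = col.partition(":")
        if not sep or wgd not in WGD_STATUSES:
            raise FormatError(
                f"{path}: species column {col!r} lacks a ':PRE_WGD' or "
                f"':POST_WGD' annotation"
            )
        species.append(name)
        status[name] = wgd
    genes = df[gene_col].tolist()
    if len(set(genes)) != len(genes):
        raise FormatError(f"{path}: duplicate gene names")
    counts = df.iloc[:, 1:].copy()
    counts.columns = species
    counts.index = genes
    for sp in species:
        try:
            counts[sp] = counts[sp].astype("Int64").astype(int)
        except (ValueError, TypeError) as exc:
            raise FormatError(
                f"{path}: non-integer or missing copy count in column {sp!r}"
            ) from exc
    try:
        return PresenceMatrix(genes=genes, species=species, wgd_status=status, counts=counts)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_copy_matrix(matrix: PresenceMatrix, path: str | Path) -> None:
    header = ["gene"] + [f"{s}:{matrix.wgd_status[s]}" for s in matrix.species]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for gene in matrix.genes:
            row = [gene] + [str(int(matrix.counts.at[gene, s])) for s in matrix.species]
            fh.write("\t".join(row) + "\n")


def read_species_tree(path: str | Path) -> SpeciesTree:
    text = Path(path).read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty tree file")
    return SpeciesTree.from_newick(text)


# ---------------------------------------------------------------------------
# Result tables


def _fmt(value: object) -> str:
    if isinstance(value, float):
        return format(value, ".6g")
    return str(value)


def write_table(
    rows: Sequence[Mapping[str, object]], path: str | Path, columns: Sequence[str]
) -> None:
    """Write result rows as UTF-8 TSV, floats to 6 significant digits."""
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row[c]) for c in columns) + "\n")
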