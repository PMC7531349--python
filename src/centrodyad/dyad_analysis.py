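"""Dyad-symmetry (inverted repeat) detection and per-sequence composition stats.

A *dyad* is a pair of exactly reverse-complementary DNA arms separated by a
bounded spacer; such sites can extrude cruciform/non-B-form structures and are
enriched at budding-yeast point centromeres.  ``find_dyads`` reports every
*maximal* dyad whose arm length and spacer fall inside the configured bounds;
``dyad_density`` is the fraction of sequence positions covered by at least one
dyad arm, the statistic contrasted against GC content downstream.

Maximality is defined explicitly: a reported dyad can be extended neither
outward by one base (next flanking pair still complementary, in bounds, arm
within ``max_arm``) nor inward by one base (spacer shrinks by two, the two
absorbed spacer flanks complementary, arm within ``max_arm``).  Coordinates
are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import Category, SequenceRecord

__all__ = [
    "Dyad",
    "DyadParams",
    "SequenceStats",
    "find_dyads",
    "dyad_density",
    "gc_content",
    "profile_sequences",
    "reverse_complement",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_RC_TABLE = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv", "TGCANYRSWMKVHDBtgcanyrswmkvhdb"
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes mapped to their partners)."""
    return seq.translate(_RC_TABLE)[::-1]


def _complementary(b1: str, b2: str) -> bool:
    # Ambiguity codes (incl. N) never count as matching any base.
    return _COMPLEMENT.get(b1) == b2


@dataclass(frozen=True, order=True)
class DyadParams:
    """Detection bounds: arm length in [min_arm, max_arm], spacer ≤ max_spacer."""

    min_arm: int = 5
    max_arm: int = 100
    max_spacer: int = 20
    allow_overlap: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.min_arm <= self.max_arm):
            raise ValueError("require 1 <= min_arm <= max_arm")
        if self.max_spacer < 0:
            raise ValueError("max_spacer must be >= 0")


@dataclass(frozen=True)
class Dyad:
    """One inverted repeat: left arm start, arm length, spacer length."""

    left_start: int
    arm_length: int
    spacer_length: int

    def __post_init__(self) -> None:
        if self.arm_length < 1 or self.spacer_length < 0 or self.left_start < 0:
            raise ValueError(f"invalid dyad geometry: {self}")

    @property
    def right_start(self) -> int:
        return self.left_start + self.arm_length + self.spacer_length

    @property
    def span_end(self) -> int:
        """End (exclusive) of the full dyad span including the spacer."""
        return self.right_start + self.arm_length

    @property
    def span(self) -> tuple[int, int]:
        return (self.left_start, self.span_end)

    def covered_positions(self, include_spacer: bool = False) -> list[int]:
        if include_spacer:
            return list(range(self.left_start, self.span_end))
        left = range(self.left_start, self.left_start + self.arm_length)
        right = range(self.right_start, self.span_end)
        return list(left) + list(right)


@dataclass
class SequenceStats:
    """Per-sequence summary row: GC percent, dyad density and dyad count."""

    id: str
    length: int
    gc_percent: float
    dyad_density: float
    n_dyads: int
    category: Category = Category.OTHER
    species: str | None = None


def find_dyads(seq: str, params: DyadParams | None = None) -> list[Dyad]:
    """Return every maximal dyad of ``seq`` within the parameter bounds.

    Dyads are enumerated by their innermost complementary base pair: a dyad
    with left arm ``[l, l+a)`` and spacer ``g`` has innermost pair
    ``(l+a-1, l+a+g)``, and the maximal arm is the longest contiguous run of
    complementary pairs radiating outward from it (capped at ``max_arm``).
    A candidate is suppressed when an inward one-base extension (absorbing the
    two spacer flanks) is possible, since the extended dyad subsumes it.

    Output is sorted by ``(left_start, arm_length descending)``.  When
    ``allow_overlap`` is false, dyads are greedily retained by decreasing arm
    length (ties: smaller ``left_start``) discarding any whose full span
    overlaps an already-retained span.
    """
    if params is None:
        params = DyadParams()
    s = seq.upper()
    n = len(s)
    if n < 2 * params.min_arm:
        return []
    dyads: list[Dyad] = []
    for p0 in range(n - 1):
        for g in range(params.max_spacer + 1):
            q0 = p0 + g + 1
            if q0 >= n:
                break
            if not _complementary(s[p0], s[q0]):
                continue
            # extend outward while pairs stay complementary and in bounds
            a = 1
            while (
                a < params.max_arm
                and p0 - a >= 0
                and q0 + a < n
                and _complementary(s[p0 - a], s[q0 + a])
            ):
                a += 1
            if a < params.min_arm:
                continue
            # inward extension absorbs the two innermost spacer flanks
            if (
                g >= 2
                and a + 1 <= params.max_arm
                and _complementary(s[p0 + 1], s[q0 - 1])
            ):
                continue
            dyads.append(Dyad(left_start=p0 - a + 1, arm_length=a, spacer_length=g))
    if not params.allow_overlap:
        dyads = _drop_overlaps(dyads)
    dyads.sort(key=lambda d: (d.left_start, -d.arm_length, d.spacer_length))
    return dyads


def _drop_overlaps(dyads: list[Dyad]) -> list[Dyad]:
    kept: list[Dyad] = []
    for d in sorted(dyads, key=lambda d: (-d.arm_length, d.left_start, d.spacer_length)):
        if all(d.span_end <= k.left_start or k.span_end <= d.left_start for k in kept):
            kept.append(d)
    return kept


def dyad_density(
    seq_length: int, dyads: list[Dyad], include_spacer: bool = False
) -> float:
    """Fraction of positions covered by ≥1 dyad arm (optionally incl. spacers)."""
    if seq_length <= 0:
        raise ValueError("seq_length must be positive")
    mask = np.zeros(seq_length, dtype=bool)
    for d in dyads:
        if d.left_start < 0 or d.span_end > seq_length:
            raise ValueError(f"dyad {d} outside sequence of length {seq_length}")
        if include_spacer:
            mask[d.left_start : d.span_end] = True
        else:
            mask[d.left_start : d.left_start + d.arm_length] = True
            mask[d.right_start : d.span_end] = True
    return float(mask.sum()) / seq_length


def gc_content(seq: str) -> float:
    """GC percent: 100·(#G+#C)/length; ambiguity codes count in the denominator only."""
    if len(seq) == 0:
        raise ValueError("empty sequence")
    s = seq.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def profile_sequences(
    records: list[SequenceRecord],
    params: DyadParams | None = None,
    include_spacer: bool = False,
) -> list[SequenceStats]:
    """GC percent and dyad density for each DNA record (one stats row each)."""
    if params is None:
        params = DyadParams()
    out = []
    for rec in records:
        rec.validate_dna()
        dyads = find_dyads(rec.sequence, params)
        out.append(
            SequenceStats(
                id=rec.id,
                length=rec.length,
                gc_percent=gc_content(rec.sequence),
                dyad_density=dyad_density(rec.length, dyads, include_spacer),
                n_dyads=len(dyads),
                category=rec.category,
                species=rec.species,
            )
        )
    return out
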