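"""Per-column conservation scoring of protein alignments.

Implements the entropy, variance and sum-of-pairs column statistics, each
available unweighted or with Henikoff-Henikoff position-based sequence
weights — six measures in total.  The headline measure for centromeric
histone (CENPA/CSE4) profiles is the unweighted entropy score
``C(i) = Σ_a f_a ln f_a``, which is 0 at a perfectly conserved column and
−ln 20 at a uniform one, so *higher means more conserved*.

Gaps are excluded from frequency denominators; columns whose gap fraction
reaches ``gap_threshold`` (default 0.5) are masked and carry no scores.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .io_formats import AMINO_ACIDS, GAP, Msa

__all__ = [
    "Statistic",
    "Weighting",
    "Measure",
    "ConservationProfile",
    "column_frequencies",
    "entropy_score",
    "variance_score",
    "sum_of_pairs_score",
    "henikoff_weights",
    "overall_frequencies",
    "conservation_profile",
    "blosum62_matrix",
]

MIN_ENTROPY = -math.log(20.0)

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


class Statistic(str, enum.Enum):
    ENTROPY = "entropy"
    VARIANCE = "variance"
    SUM_OF_PAIRS = "sum_of_pairs"


class Weighting(str, enum.Enum):
    UNWEIGHTED = "unweighted"
    HENIKOFF = "henikoff"


Measure = tuple[Statistic, Weighting]

DEFAULT_MEASURES: list[Measure] = [(Statistic.ENTROPY, Weighting.UNWEIGHTED)]


def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 as a 20×20 array in alphabetical amino-acid order."""
    blosum = substitution_matrices.load("BLOSUM62")
    mat = np.empty((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            mat[i, j] = blosum[a, b]
    return mat


def _column_chars(msa: Msa, column: int) -> str:
    if not 0 <= column < msa.n_columns:
        raise IndexError(f"column {column} out of range")
    return msa.column(column)


def column_frequencies(
    msa: Msa, column: int, weights: np.ndarray | None = None
) -> np.ndarray:
    """Weighted residue frequencies of one column, gaps excluded.

    f_a = Σ_k w_k·[residue_k == a] / Σ_{k: residue_k ≠ gap} w_k.  Raises
    ``ValueError`` on an all-gap column (such columns are masked by
    :func:`conservation_profile` before this is called).
    """
    chars = _column_chars(msa, column)
    if weights is None:
        weights = np.ones(msa.n_sequences)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (msa.n_sequences,) or np.any(weights < 0) or weights.sum() == 0:
        raise ValueError("weights must be non-negative, one per sequence, not all zero")
    freqs = np.zeros(20)
    denom = 0.0
    for ch, w in zip(chars, weights):
        if ch == GAP:
            continue
        freqs[_AA_INDEX[ch]] += w
        denom += w
    if denom == 0:
        raise ValueError(f"column {column} is all-gap; frequencies undefined")
    return freqs / denom


def entropy_score(freqs: np.ndarray) -> float:
    """Shannon-entropy conservation score Σ f ln f (0·ln 0 ≡ 0), in [−ln 20, 0]."""
    f = np.asarray(freqs, dtype=float)
    nz = f[f > 0]
    return float(np.sum(nz * np.log(nz)))


def variance_score(freqs: np.ndarray, background: np.ndarray) -> float:
    """Root-sum-square deviation of column frequencies from the background."""
    f = np.asarray(freqs, dtype=float)
    b = np.asarray(background, dtype=float)
    return float(np.sqrt(np.sum((f - b) ** 2)))


def sum_of_pairs_score(freqs: np.ndarray, matrix: np.ndarray | None = None) -> float:
    """Σ_a Σ_b f_a f_b S(a,b) with a symmetric substitution matrix (BLOSUM62)."""
    if matrix is None:
        matrix = blosum62_matrix()
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (20, 20):
        raise ValueError("substitution matrix must be 20×20")
    if not np.allclose(matrix, matrix.T):
        raise ValueError("substitution matrix must be symmetric")
    f = np.asarray(freqs, dtype=float)
    return float(f @ matrix @ f)


def henikoff_weights(msa: Msa) -> np.ndarray:
    """Henikoff-Henikoff position-based sequence weights, normalized to mean 1.

    w_k = (1/L') Σ_i 1/(r_i · s_{i,k}) over usable (not all-gap) columns i,
    where r_i is the number of distinct non-gap residues in column i and
    s_{i,k} the count of sequence k's residue there; gap positions
    contribute 0.
    """
    n = msa.n_sequences
    if n == 1:
        return np.ones(1)
    raw = np.zeros(n)
    usable = 0
    for i in range(msa.n_columns):
        chars = _column_chars(msa, i)
        counts: dict[str, int] = {}
        for ch in chars:
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            continue
        usable += 1
        r = len(counts)
        for k, ch in enumerate(chars):
            if ch != GAP:
                raw[k] += 1.0 / (r * counts[ch])
    if usable == 0:
        raise ValueError("alignment has no usable (non-all-gap) columns")
    raw /= usable
    return raw / raw.mean()


def overall_frequencies(msa: Msa) -> np.ndarray:
    """Unweighted residue frequencies over the whole alignment (gaps excluded)."""
    freqs = np.zeros(20)
    for rec in msa.records:
        for ch in rec.sequence:
            if ch != GAP:
                freqs[_AA_INDEX[ch]] += 1
    total = freqs.sum()
    if total == 0:
        raise ValueError("alignment contains only gaps")
    return freqs / total


@dataclass
class ConservationProfile:
    """Per-column conservation scores with a gap mask.

    ``scores[measure]`` is an array of length ``n_columns`` holding NaN at
    masked columns.
    """

    n_columns: int
    gap_fraction: np.ndarray
    masked: np.ndarray
    scores: dict[Measure, np.ndarray]
    gap_threshold: float

    def unmasked_columns(self) -> np.ndarray:
        return np.flatnonzero(~self.masked)


def _coerce_measure(measure: Measure | tuple[str, str] | str) -> Measure:
    if isinstance(measure, str):
        stat, _, weighting = measure.partition(":")
        return (Statistic(stat), Weighting(weighting or "unweighted"))
    stat, weighting = measure
    return (Statistic(stat), Weighting(weighting))


def conservation_profile(
    msa: Msa,
    measures: list[Measure | tuple[str, str] | str] | None = None,
    gap_threshold: float = 0.5,
    normalize: bool = False,
    substitution_matrix: np.ndarray | None = None,
) -> ConservationProfile:
    """Score every column of ``msa`` with the requested measures.

    Columns with gap fraction ≥ ``gap_threshold`` are masked (NaN scores).
    With ``normalize=True`` each measure is z-scored over unmasked columns,
    matching the usual plotting convention for conservation profiles.
    """
    if not 0 < gap_threshold <= 1:
        raise ValueError("gap_threshold must be in (0, 1]")
    requested = [_coerce_measure(m) for m in (measures or DEFAULT_MEASURES)]
    n_cols = msa.n_columns
    gap_fraction = np.array(
        [msa.column(i).count(GAP) / msa.n_sequences for i in range(n_cols)]
    )
    masked = gap_fraction >= gap_threshold
    if masked.all():
        raise ValueError("every column is gap-masked; nothing to score")

    weights_cache: dict[Weighting, np.ndarray] = {
        Weighting.UNWEIGHTED: np.ones(msa.n_sequences)
    }
    if any(w is Weighting.HENIKOFF for _, w in requested):
        weights_cache[Weighting.HENIKOFF] = henikoff_weights(msa)
    background = None
    if any(s is Statistic.VARIANCE for s, _ in requested):
        background = overall_frequencies(msa)
    submat = None
    if any(s is Statistic.SUM_OF_PAIRS for s, _ in requested):
        submat = (
            np.asarray(substitution_matrix, dtype=float)
            if substitution_matrix is not None
            else blosum62_matrix()
        )

    scores: dict[Measure, np.ndarray] = {
        m: np.full(n_cols, np.nan) for m in requested
    }
    for i in range(n_cols):
        if masked[i]:
            continue
        freq_cache: dict[Weighting, np.ndarray] = {}
        for stat, weighting in requested:
            if weighting not in freq_cache:
                freq_cache[weighting] = column_frequencies(
                    msa, i, weights_cache[weighting]
                )
            f = freq_cache[weighting]
            if stat is Statistic.ENTROPY:
                val = entropy_score(f)
            elif stat is Statistic.VARIANCE:
                val = variance_score(f, background)
            else:
                val = sum_of_pairs_score(f, submat)
            scores[(stat, weighting)][i] = val

    if normalize:
        keep = ~masked
        for m, arr in scores.items():
            vals = arr[keep]
            sd = vals.std()
            scores[m][keep] = (vals - vals.mean()) / (sd if sd > 0 else 1.0)

    return ConservationProfile(
        n_columns=n_cols,
        gap_fraction=gap_fraction,
        masked=masked,
        scores=scores,
        gap_threshold=gap_threshold,
    )
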