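from __future__ import annotations

import numpy as np
import pytest

from centrodyad.io_formats import Msa, PresenceMatrix, SequenceRecord, SpeciesTree

import pandas as pd


def make_msa(rows: list[str], ids: list[str] | None = None) -> Msa:
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return Msa([SequenceRecord(id=i, sequence=r) for i, r in zip(ids, rows)])


def make_matrix(
    genes: list[str],
    species: list[str],
    wgd: dict[str, str],
    cells: dict[tuple[str, str], int],
    default_pre: int = 1,
    default_post: int = 1,
) -> PresenceMatrix:
    data = {
        sp: [
            cells.get(
                (g, sp), default_pre if wgd[sp] == "PRE_WGD" else default_post
            )
            for g in genes
        ]
        for sp in species
    }
    frame = pd.DataFrame(data, index=genes)[species]
    return PresenceMatrix(genes=genes, species=species, wgd_status=wgd, counts=frame)


@pytest.fixture
def quartet_tree() -> SpeciesTree:
    return SpeciesTree.from_newick("((A,B),(C,D));")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))
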