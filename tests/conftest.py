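"""Shared fixtures: tiny handcrafted datasets and generator shortcuts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from haplogeo.popdata import (
    Alignment,
    DistanceMatrix,
    HaplotypeSet,
    PopulationTable,
    collapse_haplotypes,
    pairwise_differences,
    recode_mutations,
)


def make_haplotype_set(counts: pd.DataFrame, vectors: np.ndarray | None = None,
                       alignment_length: int = 100) -> HaplotypeSet:
    """HaplotypeSet from a population x haplotype count table."""
    labels = tuple(counts.columns)
    if vectors is None:
        # distinct dummy vectors, one column per haplotype
        vectors = np.array(
            [["T" if i == j else "A" for j in range(len(labels))] for i in range(len(labels))],
            dtype="<U1",
        )
    return HaplotypeSet(labels, vectors, {}, counts, (), alignment_length)


def make_population_table(coords: dict[str, tuple[float, float]]) -> PopulationTable:
    """One individual per population, coordinates as (lat, lon)."""
    rows = [
        (pop, lat, lon, f"{pop}_s") for pop, (lat, lon) in coords.items()
    ]
    return PopulationTable(
        pd.DataFrame(rows, columns=["population", "latitude", "longitude", "sample_id"])
    )


@pytest.fixture
def two_pop_alignment(tmp_path):
    """4 samples, 2 populations, 1 segregating site over 10 bp."""
    fasta = tmp_path / "aln.fasta"
    fasta.write_text(
        ">s1\nAAAAAAAAAA\n>s2\nAAAAAAAAAA\n>s3\nAAAAATAAAA\n>s4\nAAAAATAAAA\n"
    )
    csv = tmp_path / "pops.csv"
    csv.write_text(
        "population,latitude,longitude,sample_id\n"
        "P1,25.0,110.0,s1\nP1,25.0,110.0,s2\nP2,27.0,112.0,s3\nP2,27.0,112.0,s4\n"
    )
    return fasta, csv


def haplotypes_from_sequences(seqs: list[str], pops: PopulationTable | None = None,
                              prefix: str = "H"):
    """(HaplotypeSet, DistanceMatrix) from raw aligned sequences."""
    ids = (
        tuple(pops.table["sample_id"]) if pops is not None
        else tuple(f"s{i}" for i in range(len(seqs)))
    )
    a = Alignment(ids, tuple(seqs), ((0, len(seqs[0])),))
    m = recode_mutations(a)
    h = collapse_haplotypes(m, pops, label_prefix=prefix)
    return h, pairwise_differences(h)
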