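"""Alignment input, mutation recoding, haplotype collapsing and distances.

The unit of every downstream statistic is the :class:`HaplotypeSet`: distinct
chloroplast sequence variants after each indel and each declared inversion has
been collapsed to a single mutational event.  Distances between haplotypes
count recoded columns, so a 5-bp deletion separates two haplotypes by one
step, the convention used throughout cpDNA phylogeography.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "Alignment",
    "PopulationTable",
    "MutationColumn",
    "MutationMatrix",
    "HaplotypeSet",
    "DistanceMatrix",
    "AlignmentError",
    "read_alignment",
    "read_population_table",
    "recode_mutations",
    "collapse_haplotypes",
    "pairwise_differences",
]

_VALID_CHARS = frozenset("ACGTN-")

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


class AlignmentError(ValueError):
    """Raised for malformed alignments, tables or recoding specifications."""


@dataclass(frozen=True)
class Alignment:
    """An aligned set of equal-length sequences over {A,C,G,T,N,-}.

    ``locus_bounds`` are half-open 0-based column ranges, one per concatenated
    spacer; they must partition ``[0, L)``.
    """

    sample_ids: tuple[str, ...]
    sequences: tuple[str, ...]
    locus_bounds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.sample_ids:
            raise AlignmentError("alignment has no records")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise AlignmentError("duplicate sample ids in alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        L = lengths.pop()
        bad = set("".join(self.sequences)) - _VALID_CHARS
        if bad:
            raise AlignmentError(f"illegal characters in alignment: {sorted(bad)}")
        covered = sorted(self.locus_bounds)
        pos = 0
        for start, end in covered:
            if start != pos or end <= start:
                raise AlignmentError("locus_bounds must partition [0, L)")
            pos = end
        if pos != L:
            raise AlignmentError("locus_bounds must partition [0, L)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def subset(self, sample_ids: Iterable[str]) -> "Alignment":
        wanted = list(sample_ids)
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return Alignment(
            tuple(wanted),
            tuple(self.sequences[index[s]] for s in wanted),
            self.locus_bounds,
        )


@dataclass(frozen=True)
class PopulationTable:
    """Populations with WGS84 decimal-degree coordinates and their members."""

    table: pd.DataFrame  # columns: population, latitude, longitude, sample_id

    def __post_init__(self) -> None:
        required = {"population", "latitude", "longitude", "sample_id"}
        missing = required - set(self.table.columns)
        if missing:
            raise AlignmentError(f"population table missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise AlignmentError(f"sample ids in more than one row: {list(dups)[:5]}")
        lat = self.table["latitude"].astype(float)
        lon = self.table["longitude"].astype(float)
        if (lat.abs() > 90).any():
            raise AlignmentError("latitude outside [-90, 90]")
        if (lon.abs() > 180).any():
            raise AlignmentError("longitude outside [-180, 180]")
        per_pop = self.table.groupby("population")[["latitude", "longitude"]].nunique()
        if (per_pop > 1).any().any():
            raise AlignmentError("inconsistent coordinates within a population")

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.table["population"]))

    @property
    def coordinates(self) -> pd.DataFrame:
        """One row per population: latitude, longitude."""
        return (
            self.table.groupby("population", sort=False)[["latitude", "longitude"]]
            .first()
            .astype(float)
        )

    def members(self, population: str) -> list[str]:
        rows = self.table[self.table["population"] == population]
        return list(rows["sample_id"])

    def population_of(self) -> dict[str, str]:
        return dict(zip(self.table["sample_id"], self.table["population"]))


@dataclass(frozen=True)
class MutationColumn:
    """Metadata for one recoded column.

    kind is 'substitution' (span = (site, site+1)), 'indel' or 'inversion'
    (span = the collapsed alignment-column range).
    """

    kind: str
    span: tuple[int, int]


@dataclass(frozen=True)
class MutationMatrix:
    """Samples x recoded variable columns after event collapsing."""

    sample_ids: tuple[str, ...]
    columns: tuple[MutationColumn, ...]
    data: np.ndarray  # dtype '<U1'; '-' acts as a wildcard in comparisons
    alignment_length: int

    @property
    def n_sites(self) -> int:
        return len(self.columns)


@dataclass(frozen=True)
class HaplotypeSet:
    """Distinct haplotypes, sample membership and per-population counts."""

    labels: tuple[str, ...]
    vectors: np.ndarray  # n_haplotypes x n_columns, '<U1'
    membership: dict[str, str]  # sample_id -> haplotype label
    counts: pd.DataFrame  # populations x haplotype labels
    columns: tuple[MutationColumn, ...]
    alignment_length: int

    @property
    def n_haplotypes(self) -> int:
        return len(self.labels)

    @property
    def monomorphic(self) -> bool:
        return self.n_haplotypes == 1

    @property
    def n_individuals(self) -> int:
        return int(self.counts.to_numpy().sum())

    def frequencies(self) -> pd.Series:
        tot = self.counts.sum(axis=0)
        return tot / tot.sum()


@dataclass(frozen=True)
class DistanceMatrix:
    """Integer mutational steps between haplotypes; symmetric, zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.array_equal(v, v.T) or np.diag(v).any():
            raise ValueError("distance matrix must be symmetric with zero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def read_alignment(path: str | Path, locus_bounds: Sequence[tuple[int, int]] | None = None) -> Alignment:
    """Read a multi-record aligned FASTA.

    ``locus_bounds`` defaults to a single range spanning the whole alignment
    (one concatenated region).  Lowercase bases are normalised to uppercase.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    ids = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper() for r in records)
    if locus_bounds is None:
        locus_bounds = [(0, len(seqs[0]))]
    return Alignment(ids, seqs, tuple((int(a), int(b)) for a, b in locus_bounds))


def read_population_table(path: str | Path) -> PopulationTable:
    """Read the population CSV (population, latitude, longitude, sample_id)."""
    return PopulationTable(pd.read_csv(path))


def _gap_spans(seq: str) -> list[tuple[int, int]]:
    spans = []
    start = None
    for i, c in enumerate(seq):
        if c == "-" and start is None:
            start = i
        elif c != "-" and start is not None:
            spans.append((start, i))
            start = None
    if start is not None:
        spans.append((start, len(seq)))
    return spans


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def recode_mutations(
    a: Alignment, inversions: Sequence[tuple[int, int]] | None = None
) -> MutationMatrix:
    """Collapse indels and declared inversions to single mutation columns.

    Substitution columns outside gap/inversion regions are kept per site.
    Every maximal gap run observed in any sample becomes one presence/absence
    column (distinct spans get distinct columns).  Each declared inversion
    range becomes one binary orientation column; sites inside it are not
    scanned for substitutions.  Columns containing N in any sample are dropped
    (complete-column deletion).
    """
    inversions = [tuple(map(int, r)) for r in (inversions or [])]
    L = a.length
    for s, e in inversions:
        if not (0 <= s < e <= L):
            raise AlignmentError(f"inversion range ({s},{e}) outside [0,{L})")
    for (s1, e1), (s2, e2) in zip(sorted(inversions), sorted(inversions)[1:]):
        if s2 < e1:
            raise AlignmentError("overlapping inversion ranges")

    in_inversion = np.zeros(L, dtype=bool)
    for s, e in inversions:
        in_inversion[s:e] = True

    # distinct maximal gap spans across samples, outside inversions
    span_set: dict[tuple[int, int], None] = {}
    for seq in a.sequences:
        for sp in _gap_spans(seq):
            if not in_inversion[sp[0]]:
                span_set[sp] = None
    gap_spans = sorted(span_set)

    arr = np.array([list(s) for s in a.sequences], dtype="<U1")
    has_n = (arr == "N").any(axis=0)

    columns: list[MutationColumn] = []
    data_cols: list[np.ndarray] = []

    # substitution columns: outside inversions, no N, >=2 distinct non-gap states
    for site in range(L):
        if in_inversion[site] or has_n[site]:
            continue
        col = arr[:, site]
        states = set(col) - {"-"}
        if len(states) >= 2:
            columns.append(MutationColumn("substitution", (site, site + 1)))
            data_cols.append(col.copy())

    for s, e in gap_spans:
        present = np.array(
            ["1" if seq[s:e] == "-" * (e - s) else "0" for seq in a.sequences],
            dtype="<U1",
        )
        if len(set(present)) >= 2:
            columns.append(MutationColumn("indel", (s, e)))
            data_cols.append(present)

    for s, e in sorted(inversions):
        ref = a.sequences[0][s:e]
        ref_rc = _revcomp(ref)
        orient = []
        for seq in a.sequences:
            sub = seq[s:e]
            fwd = sum(x == y for x, y in zip(sub, ref))
            rev = sum(x == y for x, y in zip(sub, ref_rc))
            orient.append("1" if rev > fwd else "0")
        orient_arr = np.array(orient, dtype="<U1")
        if len(set(orient)) >= 2:
            columns.append(MutationColumn("inversion", (s, e)))
            data_cols.append(orient_arr)

    data = (
        np.stack(data_cols, axis=1)
        if data_cols
        else np.empty((a.n_samples, 0), dtype="<U1")
    )
    return MutationMatrix(a.sample_ids, tuple(columns), data, L)


def collapse_haplotypes(
    m: MutationMatrix,
    pops: PopulationTable | None = None,
    label_prefix: str = "H",
) -> HaplotypeSet:
    """Group identical recoded vectors into haplotypes.

    Labels are ``prefix + 1-based rank of first appearance`` in file order
    (the CH1.../MH1.../SH1... convention).  When ``pops`` is given, a
    population x haplotype count table is built; otherwise all samples are
    pooled into a single nominal population.
    """
    if len(m.sample_ids) == 0:
        raise AlignmentError("no samples to collapse")
    keys = ["".join(row) for row in m.data]
    seen: dict[str, str] = {}
    labels: list[str] = []
    reps: list[int] = []
    membership: dict[str, str] = {}
    for i, (sid, key) in enumerate(zip(m.sample_ids, keys)):
        if key not in seen:
            label = f"{label_prefix}{len(seen) + 1}"
            seen[key] = label
            labels.append(label)
            reps.append(i)
        membership[sid] = seen[key]

    vectors = m.data[reps].copy() if m.data.size else np.empty((len(labels), 0), "<U1")

    if pops is not None:
        pop_of = pops.population_of()
        missing = [s for s in m.sample_ids if s not in pop_of]
        if missing:
            raise AlignmentError(f"samples missing from population table: {missing[:5]}")
        pop_list = pops.populations
    else:
        pop_of = {s: "all" for s in m.sample_ids}
        pop_list = ["all"]

    counts = pd.DataFrame(0, index=pop_list, columns=labels, dtype=int)
    for sid in m.sample_ids:
        counts.loc[pop_of[sid], membership[sid]] += 1

    return HaplotypeSet(
        tuple(labels), vectors, membership, counts, m.columns, m.alignment_length
    )


def pairwise_differences(h: HaplotypeSet) -> DistanceMatrix:
    """Mutational steps between haplotypes over recoded columns.

    A '-' state (sample gapped at a substitution site) is a wildcard: it never
    counts as a difference, since the corresponding indel column already
    carries that event.
    """
    K = h.n_haplotypes
    if K == 1:
        warnings.warn("single haplotype: degenerate 1x1 distance matrix")
        return DistanceMatrix(h.labels, np.zeros((1, 1), dtype=int))
    v = h.vectors
    d = np.zeros((K, K), dtype=int)
    for i in range(K):
        for j in range(i + 1, K):
            diff = (v[i] != v[j]) & (v[i] != "-") & (v[j] != "-")
            d[i, j] = d[j, i] = int(diff.sum())
    return DistanceMatrix(h.labels, d)
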