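"""Codons, labels, probabilistic code matrices and code partitions.

A *code matrix* models an ambiguous genetic code: a 64x21 row-stochastic
matrix ``p`` where ``p[c, l]`` is the probability that codon ``c`` is
translated as label ``l`` (20 amino acids plus the stop signal).  A *code
partition* is the unambiguous limit: every codon belongs to exactly one of
21 disjoint, non-empty codon groups.

Conventions
-----------
* Codons are indexed 0-63 by lexicographic rank over the DNA alphabet with
  A < C < G < T, so AAA=0 and TTT=63.
* Labels are indexed 0-20: the 20 amino-acid one-letter codes in
  alphabetical order followed by ``*`` (stop) as label 20.  Nothing in the
  model distinguishes labels beyond identity, so the ordering is pure
  convention.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

BASES = "ACGT"
N_CODONS = 64
N_LABELS = 21
#: Amino-acid one-letter codes (alphabetical) then stop.
LABEL_SYMBOLS = tuple("ACDEFGHIKLMNPQRSTVWY") + ("*",)
ROW_SUM_TOL = 1e-9

_BASE_RANK = {b: i for i, b in enumerate(BASES)}


class InvalidCodonError(ValueError):
    """A codon string is not a triplet over {A, C, G, T}."""


class CodeMatrixFormatError(ValueError):
    """A code-matrix file violates the 64x21 row-stochastic contract."""


def codon_index(bases: str) -> int:
    """Lexicographic rank of a codon triplet (A<C<G<T; AAA=0 ... TTT=63)."""
    if len(bases) != 3 or any(b not in _BASE_RANK for b in bases):
        raise InvalidCodonError(f"not a codon over ACGT: {bases!r}")
    b0, b1, b2 = bases
    return 16 * _BASE_RANK[b0] + 4 * _BASE_RANK[b1] + _BASE_RANK[b2]


def codon_string(index: int) -> str:
    """Inverse of :func:`codon_index`."""
    if not 0 <= index < N_CODONS:
        raise InvalidCodonError(f"codon index out of range: {index}")
    return BASES[index // 16] + BASES[(index // 4) % 4] + BASES[index % 4]


#: All 64 codon strings in index order.
ALL_CODONS = tuple(codon_string(i) for i in range(N_CODONS))


def label_index(symbol: str) -> int:
    try:
        return LABEL_SYMBOLS.index(symbol)
    except ValueError:
        raise ValueError(f"unknown label symbol: {symbol!r}") from None


def _as_codon_index(c) -> int:
    return c if isinstance(c, (int, np.integer)) else codon_index(c)


@dataclass(frozen=True)
class CodeMatrix:
    """64x21 row-stochastic matrix of codon -> label probabilities."""

    p: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if p.shape != (N_CODONS, N_LABELS):
            raise CodeMatrixFormatError(
                f"expected shape (64, 21), got {p.shape}"
            )
        if (p < 0).any():
            bad = ALL_CODONS[int(np.argwhere(p < 0)[0, 0])]
            raise CodeMatrixFormatError(f"negative probability in row {bad}")
        sums = p.sum(axis=1)
        off = np.abs(sums - 1.0) > ROW_SUM_TOL
        if off.any():
            bad = ALL_CODONS[int(np.argmax(off))]
            raise CodeMatrixFormatError(
                f"row {bad} sums to {sums[np.argmax(off)]:.6g}, not 1"
            )
        object.__setattr__(self, "p", p)

    def row(self, codon) -> np.ndarray:
        return self.p[_as_codon_index(codon)]


@dataclass(frozen=True)
class CodePartition:
    """Partition of the 64 codons into 21 disjoint non-empty groups.

    ``groups[l]`` is the frozenset of codon indices assigned to label ``l``.
    """

    groups: tuple

    def __post_init__(self):
        groups = tuple(frozenset(_as_codon_index(c) for c in g)
                       for g in self.groups)
        if len(groups) != N_LABELS:
            raise ValueError(f"expected 21 groups, got {len(groups)}")
        if any(len(g) == 0 for g in groups):
            empty = [i for i, g in enumerate(groups) if not g]
            raise ValueError(f"empty codon group(s) for labels {empty}")
        union = frozenset().union(*groups)
        if union != frozenset(range(N_CODONS)) or sum(map(len, groups)) != N_CODONS:
            raise ValueError("groups must partition all 64 codons exactly once")
        object.__setattr__(self, "groups", groups)

    @classmethod
    def from_mapping(cls, codon_to_label: Mapping) -> "CodePartition":
        """Build from a codon -> label mapping (strings or indices)."""
        groups = [set() for _ in range(N_LABELS)]
        for codon, label in codon_to_label.items():
            l = label if isinstance(label, (int, np.integer)) else label_index(label)
            groups[l].add(_as_codon_index(codon))
        return cls(tuple(groups))

    def label_of(self) -> np.ndarray:
        """Array of length 64 mapping codon index -> label index."""
        out = np.empty(N_CODONS, dtype=int)
        for l, g in enumerate(self.groups):
            for c in g:
                out[c] = l
        return out

    def group_codons(self, label) -> frozenset:
        l = label if isinstance(label, (int, np.integer)) else label_index(label)
        return self.groups[l]

    def group_sizes(self) -> list:
        return [len(g) for g in self.groups]


def random_code(rng: np.random.Generator) -> CodeMatrix:
    """Random ambiguous code: each row is 21 iid Uniform(0,1) draws
    divided by their sum.

    This initialization yields a mean per-row Shannon entropy of about
    2.85 nats, i.e. a whole-matrix entropy of roughly 182 nats -- a highly
    ambiguous starting code.
    """
    u = rng.random((N_CODONS, N_LABELS))
    return CodeMatrix(u / u.sum(axis=1, keepdims=True))


def random_population(n: int, rng: np.random.Generator) -> np.ndarray:
    """Stack of ``n`` random code matrices as an (n, 64, 21) array."""
    u = rng.random((n, N_CODONS, N_LABELS))
    return u / u.sum(axis=2, keepdims=True)


def partition_to_matrix(part: CodePartition) -> CodeMatrix:
    """Degenerate (0/1) code matrix of an unambiguous code partition."""
    p = np.zeros((N_CODONS, N_LABELS))
    p[np.arange(N_CODONS), part.label_of()] = 1.0
    return CodeMatrix(p)


def _data_path(name: str):
    return importlib.resources.files("ambicode.data").joinpath(name)


def sgc_partition() -> CodePartition:
    """The standard genetic code as a 21-group partition (NCBI table 1)."""
    return read_partition(_data_path("sgc_partition.tsv"))


def read_partition(path) -> CodePartition:
    """Read a two-column ``codon<TAB>label`` TSV into a partition."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["codon", "label"]:
        raise ValueError(f"expected columns ['codon', 'label'], got {list(df.columns)}")
    return CodePartition.from_mapping(dict(zip(df["codon"], df["label"])))


def write_partition(path, part: CodePartition) -> None:
    label_of = part.label_of()
    df = pd.DataFrame({
        "codon": ALL_CODONS,
        "label": [LABEL_SYMBOLS[label_of[c]] for c in range(N_CODONS)],
    })
    df.to_csv(path, sep="\t", index=False)


def read_code_matrix(path) -> CodeMatrix:
    """Read a code matrix TSV (``codon`` column + 21 label columns).

    Rows within the row-sum tolerance are renormalized exactly to 1;
    anything else raises :class:`CodeMatrixFormatError` naming the row.
    """
    df = pd.read_csv(path, sep="\t", dtype={"codon": str},
                     float_precision="round_trip")
    if "codon" not in df.columns:
        raise CodeMatrixFormatError("missing 'codon' column")
    if list(df.columns[1:]) != list(LABEL_SYMBOLS):
        raise CodeMatrixFormatError(
            f"expected label columns {list(LABEL_SYMBOLS)}, got {list(df.columns[1:])}"
        )
    seen = set(df["codon"])
    missing = [c for c in ALL_CODONS if c not in seen]
    if missing:
        raise CodeMatrixFormatError(f"missing codon row(s): {missing}")
    if len(df) != N_CODONS:
        raise CodeMatrixFormatError(f"expected 64 rows, got {len(df)}")
    p = np.empty((N_CODONS, N_LABELS))
    for codon, *vals in df.itertuples(index=False):
        row = np.asarray(vals, dtype=float)
        if (row < 0).any():
            raise CodeMatrixFormatError(f"negative probability in row {codon}")
        s = row.sum()
        if abs(s - 1.0) > ROW_SUM_TOL:
            raise CodeMatrixFormatError(f"row {codon} sums to {s:.6g}, not 1")
        # renormalize only measurable drift; keeps write/read bit-exact
        p[codon_index(codon)] = row if abs(s - 1.0) < 1e-12 else row / s
    return CodeMatrix(p)


def write_code_matrix(path, m: CodeMatrix) -> None:
    df = pd.DataFrame(m.p, columns=list(LABEL_SYMBOLS))
    df.insert(0, "codon", ALL_CODONS)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def hamming(a, b) -> int:
    """Number of differing positions between two codons."""
    sa, sb = codon_string(_as_codon_index(a)), codon_string(_as_codon_index(b))
    return sum(x != y for x, y in zip(sa, sb))
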