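"""Codon mutation graph and conductance measures.

The codon graph G has the 64 codons as vertices and an edge between every
pair of codons differing at exactly one position (a point mutation).  It is
9-regular (3 positions x 3 alternative bases) with 288 edges.

For a codon group S, the conductance

    phi(S) = E(S, S-bar) / vol(S),    vol(S) = 9 |S|

is the fraction of point mutations hitting S's codons that leave the group
(non-synonymous changes).  Low conductance means robust coding.  phi_k(G)
is the minimum over all size-k groups, and the average code conductance
Phi(C) is the mean of the 21 group conductances of a code partition.

All conductances are exact rationals (:class:`fractions.Fraction`);
4-decimal rendering is left to callers.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

import networkx as nx
import numpy as np

from .code_space import CodePartition, N_CODONS, codon_string, hamming

DEGREE = 9
EXHAUSTIVE_MAX_K = 4

_GRAPH = None
_ADJ_BITS = None


def build_codon_graph() -> nx.Graph:
    """The 64-node point-mutation graph (vertices are codon indices)."""
    global _GRAPH
    if _GRAPH is None:
        g = nx.Graph()
        g.add_nodes_from(range(N_CODONS))
        g.add_edges_from(
            (a, b) for a, b in combinations(range(N_CODONS), 2)
            if hamming(a, b) == 1
        )
        _GRAPH = g
    return _GRAPH


def _adjacency_bits() -> list:
    """Per-vertex adjacency encoded as a 64-bit mask (fast subset scans)."""
    global _ADJ_BITS
    if _ADJ_BITS is None:
        g = build_codon_graph()
        _ADJ_BITS = [
            sum(1 << nb for nb in g.neighbors(v)) for v in range(N_CODONS)
        ]
    return _ADJ_BITS


def _as_indices(S) -> list:
    from .code_space import _as_codon_index
    return [int(_as_codon_index(c)) for c in S]


def internal_edge_count(S) -> int:
    """Number of graph edges with both endpoints in S."""
    idx = _as_indices(S)
    adj = _adjacency_bits()
    mask = sum(1 << v for v in idx)
    return sum((adj[v] & mask).bit_count() for v in idx) // 2


def set_conductance(S) -> Fraction:
    """phi(S) = crossing edges / (9 |S|), exact.

    ``S`` is a non-empty proper subset of the codons (strings or indices).
    """
    idx = _as_indices(S)
    n = len(idx)
    if n == 0 or n >= N_CODONS:
        raise ValueError("conductance requires a non-empty proper codon subset")
    if len(set(idx)) != n:
        raise ValueError("duplicate codons in set")
    crossing = DEGREE * n - 2 * internal_edge_count(idx)
    return Fraction(crossing, DEGREE * n)


def average_code_conductance(part: CodePartition) -> Fraction:
    """Phi(C): the mean of the 21 group conductances, exact."""
    return sum(set_conductance(g) for g in part.groups) / 21


@dataclass(frozen=True)
class KSizeConductance:
    """Result of a k-size conductance search.

    ``exact`` is True only for the exhaustive search; the candidate search
    reports the best structured set found, an upper bound on phi_k(G).
    """

    k: int
    value: Fraction
    witness: frozenset  # codon indices attaining the value
    exact: bool


def k_size_conductance(k: int, mode: str = "auto") -> KSizeConductance:
    """min (or best-found) conductance over all codon sets of size k.

    ``mode='exhaustive'`` enumerates all C(64, k) subsets and is allowed
    for k <= 4 (C(64,4) = 635,376 subsets); ``mode='candidate'`` runs a
    greedy max-internal-edge search from every seed vertex and returns an
    upper bound.  ``'auto'`` picks exhaustive when permitted.
    """
    if not 1 <= k <= N_CODONS - 1:
        raise ValueError(f"k must be in 1..63, got {k}")
    if mode == "auto":
        mode = "exhaustive" if k <= EXHAUSTIVE_MAX_K else "candidate"
    if mode == "exhaustive":
        if k > EXHAUSTIVE_MAX_K:
            raise ValueError(
                f"exhaustive search over C(64,{k}) subsets refused; "
                f"use mode='candidate' for k > {EXHAUSTIVE_MAX_K}"
            )
        best_set, best_internal = _exhaustive_max_internal(k)
        exact = True
    elif mode == "candidate":
        best_set, best_internal = _greedy_max_internal(k)
        exact = False
    else:
        raise ValueError(f"unknown mode {mode!r}")
    value = Fraction(DEGREE * k - 2 * best_internal, DEGREE * k)
    return KSizeConductance(k=k, value=value, witness=frozenset(best_set), exact=exact)


def _exhaustive_max_internal(k: int):
    """Scan all k-subsets for the maximum internal edge count
    (equivalently the minimum conductance)."""
    adj = _adjacency_bits()
    best, best_set = -1, None
    # Upper bound on internal edges of a k-set in this graph: a single-
    # position block gives C(k,2) for k<=4; stop early if attained.
    cap = k * (k - 1) // 2
    for combo in combinations(range(N_CODONS), k):
        mask = 0
        for v in combo:
            mask |= 1 << v
        e = sum((adj[v] & mask).bit_count() for v in combo) // 2
        if e > best:
            best, best_set = e, combo
            if best == cap:
                break
    return best_set, best


def _greedy_max_internal(k: int):
    """Greedy growth from each seed vertex, maximizing internal edges;
    ties go to the lowest codon index.  Deterministic."""
    adj = _adjacency_bits()
    best, best_set = -1, None
    for seed in range(N_CODONS):
        members = [seed]
        mask = 1 << seed
        internal = 0
        for _ in range(k - 1):
            gain_best, v_best = -1, None
            for v in range(N_CODONS):
                if mask >> v & 1:
                    continue
                gain = (adj[v] & mask).bit_count()
                if gain > gain_best:
                    gain_best, v_best = gain, v
            members.append(v_best)
            mask |= 1 << v_best
            internal += gain_best
        if internal > best:
            best, best_set = internal, tuple(members)
    return best_set, best


def non_optimal_groups(part: CodePartition) -> list:
    """Labels whose group conductance strictly exceeds the k-size minimum
    for its size (exhaustive minima for k <= 4, greedy bounds beyond)."""
    minima: dict = {}
    out = []
    for l, group in enumerate(part.groups):
        k = len(group)
        if k not in minima:
            minima[k] = k_size_conductance(k).value
        if set_conductance(group) > minima[k]:
            out.append(l)
    return out


def render_fraction(f: Fraction, decimals: int = 4) -> str:
    return f"{float(f):.{decimals}f}"
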