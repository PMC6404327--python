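"""Mistranslation neighbourhoods and the stochastic code fitness.

A codon's *neighbourhood* ``N(c)`` is the set of codons the translational
machinery may confuse with ``c``: ``c`` itself plus every codon differing
from it by one nucleotide at one of the model's varied positions.

* ``M1`` varies only the third position (wobble-like reading), |N| = 4;
* ``M2`` varies the first or second position, |N| = 7;
* ``M3`` varies any single position, |N| = 10.

The fitness of a code matrix is the total probability -- up to the constant
``64**21`` -- that the code produces all 21 labels when each label's
representative codon is misread anywhere inside its neighbourhood:

    F = sum over (c'_1..c'_21), c'_i in N(c_i), of  prod_i P(l_i | c'_i)

with the representative codons ``c_i`` drawn per label from the code's
posterior P(c | l).  Because the coordinates of the tuple sum are
independent, F factorizes into a product of per-label neighbourhood sums;
a forward dynamic-programming recursion computes the same value in
O(n_labels * |N|^2) operations instead of |N|^21.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .code_space import (
    N_CODONS,
    N_LABELS,
    CodeMatrix,
    codon_index,
    codon_string,
)

_BASES = "ACGT"


class DegenerateLabelError(ValueError):
    """A label's matrix column is all zeros; no codon can represent it."""


@dataclass(frozen=True)
class NeighbourhoodModel:
    """A misreading rule: which codon positions may be misread.

    ``varied_positions`` holds 0-based codon positions.  The neighbourhood
    size is ``1 + 3 * len(varied_positions)``.
    """

    name: str
    varied_positions: tuple

    def __post_init__(self):
        vp = tuple(sorted(set(self.varied_positions)))
        if not vp or any(p not in (0, 1, 2) for p in vp):
            raise ValueError(f"varied positions must be within 0..2, got {vp}")
        object.__setattr__(self, "varied_positions", vp)

    @property
    def size(self) -> int:
        return 1 + 3 * len(self.varied_positions)

    @classmethod
    def from_name(cls, name: str) -> "NeighbourhoodModel":
        try:
            return _STANDARD_MODELS[name.upper()]
        except KeyError:
            raise ValueError(
                f"unknown model {name!r}; expected one of M1, M2, M3"
            ) from None

    def table(self) -> np.ndarray:
        """(64, size) array: row c lists the codon indices of N(c)."""
        return _neighbour_table(self.varied_positions)


#: Default scenarios.  M1 fixes positions 1-2 and varies position 3 (the
#: wobble position); M2 fixes position 3 and varies positions 1-2; M3
#: varies all three.
M1 = NeighbourhoodModel("M1", (2,))
M2 = NeighbourhoodModel("M2", (0, 1))
M3 = NeighbourhoodModel("M3", (0, 1, 2))
_STANDARD_MODELS = {"M1": M1, "M2": M2, "M3": M3}

_TABLE_CACHE: dict = {}


def _neighbour_table(varied_positions: tuple) -> np.ndarray:
    if varied_positions in _TABLE_CACHE:
        return _TABLE_CACHE[varied_positions]
    rows = []
    for c in range(N_CODONS):
        s = codon_string(c)
        nb = [c]
        for pos in varied_positions:
            for b in _BASES:
                if b != s[pos]:
                    nb.append(codon_index(s[:pos] + b + s[pos + 1:]))
        rows.append(sorted(nb))
    table = np.asarray(rows, dtype=np.intp)
    _TABLE_CACHE[varied_positions] = table
    return table


def neighbourhood(codon, model: NeighbourhoodModel) -> set:
    """The misreading neighbourhood N(c), including c itself.

    Returns codon strings if given a string, codon indices if given an int.
    """
    as_string = isinstance(codon, str)
    c = codon_index(codon) if as_string else int(codon)
    members = model.table()[c]
    return {codon_string(int(i)) for i in members} if as_string else set(map(int, members))


def draw_codon_for_label(m: CodeMatrix, label: int, rng: np.random.Generator) -> int:
    """Sample a representative codon for ``label``: P(c|l) = p[c,l] / col sum."""
    col = m.p[:, label]
    s = col.sum()
    if s <= 0.0:
        raise DegenerateLabelError(f"label {label} has an all-zero column")
    return int(rng.choice(N_CODONS, p=col / s))


def draw_label_codons(m: CodeMatrix, rng: np.random.Generator) -> np.ndarray:
    """One representative codon per label (length-21 array of codon indices)."""
    return np.array([draw_codon_for_label(m, l, rng) for l in range(N_LABELS)])


def _factors(m: CodeMatrix, draw, model: NeighbourhoodModel) -> np.ndarray:
    draw = np.asarray(draw, dtype=np.intp)
    labels = np.arange(len(draw))
    nb = model.table()[draw]                    # (k, size)
    return m.p[nb, labels[:, None]].sum(axis=1)  # (k,)


def fitness_forward(m: CodeMatrix, draw, model: NeighbourhoodModel) -> float:
    """Fitness F for a draw of per-label representative codons.

    Computed via the factorized closed form (the tuple sum over independent
    neighbourhood coordinates is a product of per-label sums), which equals
    the forward recursion :func:`fitness_alpha` to machine precision.
    """
    return float(np.prod(_factors(m, draw, model)))


def fitness_alpha(m: CodeMatrix, draw, model: NeighbourhoodModel,
                  count_ops: bool = False):
    """Fitness F via the literal forward dynamic-programming recursion.

    alpha_1(c) = P(l_1|c) on N(c_1); alpha_k(c) = P(l_k|c) *
    sum of alpha_{k-1} over N(c_{k-1}); F = sum of alpha_last over N(c_last).

    With ``count_ops=True`` also returns the number of multiply-accumulate
    steps, which is bounded by ``n_labels * |N|**2`` (2100 for |N| = 10 and
    21 labels).
    """
    draw = np.asarray(draw, dtype=np.intp)
    table = model.table()
    ops = 0
    alpha = {int(c): m.p[int(c), 0] for c in table[draw[0]]}
    ops += len(alpha)
    for k in range(1, len(draw)):
        prev = alpha
        alpha = {}
        for c in table[draw[k]]:
            acc = 0.0
            for c_prev, a in prev.items():
                acc += a * m.p[int(c), k]  # alpha_{k-1}(c') * P(l_k|c)
                ops += 1
            alpha[int(c)] = acc
    f = 0.0
    for a in alpha.values():
        f += a
        ops += 1
    return (f, ops) if count_ops else f


def fitness_direct(m: CodeMatrix, draw, model: NeighbourhoodModel,
                   max_labels: int = 6) -> float:
    """Brute-force fitness: exact sum over all |N|^k misreading tuples.

    Exponential in the number of labels; refuses beyond ``max_labels``.
    Serves as the independent oracle for the forward computation.
    """
    draw = np.asarray(draw, dtype=np.intp)
    if len(draw) > max_labels:
        raise ValueError(
            f"direct enumeration over {model.size}^{len(draw)} tuples refused; "
            f"raise max_labels explicitly or use fitness_forward"
        )
    table = model.table()
    neighbourhoods = [table[c] for c in draw]
    total = 0.0
    for tup in itertools.product(*neighbourhoods):
        prod = 1.0
        for label, c in enumerate(tup):
            prod *= m.p[int(c), label]
        total += prod
    return total


def forward_cost(model: NeighbourhoodModel, n_labels: int = N_LABELS) -> int:
    """Nominal multiply-accumulate cost of the forward recursion,
    ``n_labels * |N|**2`` (e.g. 2100 for M3 with 21 labels), versus
    ``|N|**n_labels`` for direct enumeration."""
    return n_labels * model.size ** 2


def population_fitness(pop: np.ndarray, model: NeighbourhoodModel,
                       rng: np.random.Generator) -> np.ndarray:
    """One stochastic fitness evaluation per individual, vectorized.

    For each individual a fresh per-label codon draw is sampled via the
    posterior P(c|l) (inverse-CDF on the column-normalized matrix), then
    the factorized F is evaluated.  Equivalent to calling
    :func:`draw_label_codons` + :func:`fitness_forward` per individual.
    """
    n = pop.shape[0]
    colsum = pop.sum(axis=1, keepdims=True)              # (n, 1, 21)
    if (colsum <= 0).any():
        raise DegenerateLabelError("an individual has an all-zero label column")
    cdf = np.cumsum(pop / colsum, axis=1)                # (n, 64, 21)
    u = rng.random((n, 1, N_LABELS))
    draws = (cdf < u).sum(axis=1)                        # (n, 21)
    np.clip(draws, 0, N_CODONS - 1, out=draws)
    nb = model.table()[draws]                            # (n, 21, size)
    pt = np.swapaxes(pop, 1, 2)                          # (n, 21, 64)
    vals = np.take_along_axis(pt, nb, axis=2)            # (n, 21, size)
    return vals.sum(axis=2).prod(axis=1)
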