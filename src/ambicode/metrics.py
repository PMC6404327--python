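"""Ambiguity measures for probabilistic genetic codes.

* **Code entropy** H(P): the sum of the Shannon entropies (natural log) of
  the 64 codon rows.  0 for an unambiguous code; at most 64*ln(21) ~ 194.9
  for uniformly ambiguous rows; ~182 for freshly initialized random codes.
* **Maximum-likelihood graph partition (MLGP)**: each codon is assigned to
  its highest-probability label, provided every label is attained.
* **Coding strength** psi(S_l): the mean probability, over a group's
  codons, of encoding the group's label; Psi is the 21-group mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .code_space import N_LABELS, CodeMatrix, CodePartition


class EmptyGroupError(ValueError):
    """MLGP existence condition violated: some label attains no codon."""

    def __init__(self, missing_labels):
        self.missing_labels = list(missing_labels)
        super().__init__(
            f"no codon attains its row maximum at label(s) {self.missing_labels}"
        )


def code_entropy(m: CodeMatrix) -> float:
    """H(P) = -sum_{c,l} p_cl * ln(p_cl), with 0*ln(0) := 0."""
    return float(-xlogy(m.p, m.p).sum())


def population_entropy(pop: np.ndarray) -> np.ndarray:
    """Per-individual code entropy for an (n, 64, 21) population array."""
    return -xlogy(pop, pop).sum(axis=(1, 2))


def average_entropy(population) -> float:
    """H_av: arithmetic mean of the code entropy over the population."""
    if isinstance(population, np.ndarray) and population.ndim == 3:
        if population.shape[0] == 0:
            raise ValueError("empty population")
        return float(population_entropy(population).mean())
    matrices = list(population)
    if not matrices:
        raise ValueError("empty population")
    return float(np.mean([code_entropy(m) for m in matrices]))


def mlgp(m: CodeMatrix) -> CodePartition:
    """Maximum-likelihood graph partition: codon -> argmax label.

    Ties are broken toward the lowest label id (np.argmax convention).
    Raises :class:`EmptyGroupError` if any label ends up with no codon.
    """
    part, missing = mlgp_lenient(m)
    if missing:
        raise EmptyGroupError(missing)
    return CodePartition(part)


def mlgp_lenient(m: CodeMatrix):
    """Argmax assignment without the existence check.

    Returns ``(groups, missing_labels)`` where ``groups`` is a 21-tuple of
    codon-index sets (possibly empty) and ``missing_labels`` lists labels
    with no codon.  Intended for diagnostics of codes mid-evolution.
    """
    assign = np.argmax(m.p, axis=1)
    groups = tuple(set(np.flatnonzero(assign == l)) for l in range(N_LABELS))
    missing = [l for l, g in enumerate(groups) if not g]
    return groups, missing


@dataclass(frozen=True)
class StrengthReport:
    """Per-group coding strengths psi(S_l) and their mean Psi."""

    psi: tuple  # length 21, in label order
    average: float


def coding_strength(m: CodeMatrix, part: CodePartition) -> StrengthReport:
    """psi(S_l) = mean over c in S_l of p[c, l]; Psi = mean of the 21 psi."""
    psi = tuple(
        float(np.mean([m.p[c, l] for c in group]))
        for l, group in enumerate(part.groups)
    )
    return StrengthReport(psi=psi, average=float(np.mean(psi)))


def average_strength_of_values(psi_values) -> float:
    """Psi from an explicit list of 21 per-group psi values."""
    psi_values = list(psi_values)
    if len(psi_values) != N_LABELS:
        raise ValueError(f"expected 21 psi values, got {len(psi_values)}")
    return float(np.mean(psi_values))
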