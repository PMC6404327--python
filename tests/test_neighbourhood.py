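"""Misreading neighbourhoods, label-conditioned codon sampling, and the
fitness function (forward recursion vs brute force vs closed form)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ambicode import (
    M1,
    M2,
    M3,
    CodeMatrix,
    NeighbourhoodModel,
    draw_codon_for_label,
    fitness_alpha,
    fitness_direct,
    fitness_forward,
    forward_cost,
    neighbourhood,
    random_code,
)
from ambicode.code_space import codon_index
from ambicode.neighbourhood import DegenerateLabelError

MODELS = [M1, M2, M3]


class TestNeighbourhoods:
    def test_ggg_m1_wobble(self):
        assert neighbourhood("GGG", M1) == {"GGG", "GGA", "GGC", "GGT"}

    def test_ggg_m2_first_two_positions(self):
        assert neighbourhood("GGG", M2) == {
            "GGG", "AGG", "CGG", "TGG", "GAG", "GCG", "GTG"}

    def test_ggg_m3_any_position(self):
        assert neighbourhood("GGG", M3) == {
            "GGG", "AGG", "CGG", "TGG", "GAG", "GCG", "GTG",
            "GGA", "GGC", "GGT"}

    @pytest.mark.parametrize("model,size", [(M1, 4), (M2, 7), (M3, 10)])
    def test_constant_size_and_self_membership(self, model, size):
        assert model.size == size
        for c in range(64):
            nb = neighbourhood(c, model)
            assert len(nb) == size
            assert c in nb

    def test_size_law_for_custom_positions(self):
        for positions in [(0,), (1,), (0, 2), (1, 2)]:
            model = NeighbourhoodModel("custom", positions)
            assert model.size == 1 + 3 * len(positions)
            assert len(neighbourhood(0, model)) == model.size

    @given(st.integers(0, 63), st.integers(0, 63))
    def test_m3_symmetry(self, a, b):
        assert (a in neighbourhood(b, M3)) == (b in neighbourhood(a, M3))

    def test_unknown_model_name(self):
        with pytest.raises(ValueError, match="M1, M2, M3"):
            NeighbourhoodModel.from_name("M4")


class TestCodonSampling:
    def test_uniform_matrix_samples_uniformly(self, uniform_matrix, rng):
        draws = [draw_codon_for_label(uniform_matrix, 0, rng)
                 for _ in range(6400)]
        freq = np.bincount(draws, minlength=64) / len(draws)
        # each codon has probability 1/64; 4 sigma binomial band
        se = np.sqrt((1 / 64) * (63 / 64) / len(draws))
        assert np.abs(freq - 1 / 64).max() < 4 * se

    def test_degenerate_column_is_certain(self, rng):
        p = np.full((64, 21), 1 / 21)
        p[:, 0] = 0.0
        p[5, 0] = 1 / 21
        p /= p.sum(axis=1, keepdims=True)
        m = CodeMatrix(p)
        assert all(draw_codon_for_label(m, 0, rng) == 5 for _ in range(50))

    def test_column_probabilities_recovered(self, rng):
        # column mass (0.2, 0.6, 0.2) over codons 0..2, rows kept stochastic
        p = np.zeros((64, 21))
        p[:, [l for l in range(21) if l != 3]] = 1 / 20
        for codon, mass in [(0, 0.2), (1, 0.6), (2, 0.2)]:
            p[codon, 3] = mass
            p[codon, [l for l in range(21) if l != 3]] = (1 - mass) / 20
        m = CodeMatrix(p)
        n = 30_000
        draws = np.array([draw_codon_for_label(m, 3, rng) for _ in range(n)])
        for codon, prob in [(0, 0.2), (1, 0.6), (2, 0.2)]:
            se = np.sqrt(prob * (1 - prob) / n)
            assert abs((draws == codon).mean() - prob) < 3 * se

    def test_all_zero_column_rejected(self, rng):
        p = np.full((64, 21), 1 / 21)
        p[:, 7] = 0.0
        p /= p.sum(axis=1, keepdims=True)
        with pytest.raises(DegenerateLabelError, match="7"):
            draw_codon_for_label(CodeMatrix(p), 7, rng)


class TestFitness:
    def test_uniform_matrix_closed_form(self, uniform_matrix):
        draw = np.zeros(21, dtype=int)
        for model in MODELS:
            expected = (model.size / 21) ** 21
            assert fitness_forward(uniform_matrix, draw, model) == \
                pytest.approx(expected, rel=1e-12)

    def test_single_label_is_neighbourhood_sum(self, random_matrix):
        c = codon_index("GGG")
        f = fitness_direct(random_matrix, [c], M1)
        expected = sum(random_matrix.p[codon_index(n), 0]
                       for n in neighbourhood("GGG", M1))
        assert f == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("model,n_labels", [(M1, 3), (M1, 5), (M2, 4), (M3, 3)])
    def test_forward_equals_direct_and_alpha(self, rng, model, n_labels):
        for _ in range(10):
            m = random_code(rng)
            draw = rng.integers(0, 64, n_labels)
            f_fwd = fitness_forward(m, draw, model)
            f_dir = fitness_direct(m, draw, model)
            f_alp = fitness_alpha(m, draw, model)
            assert f_dir == pytest.approx(f_fwd, rel=1e-12)
            assert f_alp == pytest.approx(f_fwd, rel=1e-12)

    def test_direct_refuses_exponential_blowup(self, random_matrix):
        with pytest.raises(ValueError, match="refused"):
            fitness_direct(random_matrix, list(range(10)), M3)

    def test_monotone_in_neighbourhood_probability(self, rng):
        # raising p[c', l] for c' inside N(c_l), before renormalization,
        # never decreases F
        m = random_code(rng)
        draw = rng.integers(0, 64, 21)
        f0 = _factors_raw(m.p, draw, M3)
        for label in (0, 4, 20):
            p = m.p.copy()
            c_prime = sorted(neighbourhood(int(draw[label]), M3))[1]
            p[c_prime, label] += 0.3
            assert _factors_raw(p, draw, M3) >= f0

    def test_fitness_bounds(self, rng):
        for _ in range(20):
            m = random_code(rng)
            draw = rng.integers(0, 64, 21)
            f = fitness_forward(m, draw, M3)
            assert 0.0 <= f <= M3.size ** 21

    def test_operation_count(self, random_matrix, rng):
        draw = rng.integers(0, 64, 21)
        _, ops = fitness_alpha(random_matrix, draw, M3, count_ops=True)
        assert forward_cost(M3) == 21 * 10 ** 2 == 2100
        assert ops <= forward_cost(M3)
        assert ops >= 20 * 10 ** 2  # the label-transition MACs dominate


def _factors_raw(p, draw, model):
    import numpy as _np
    labels = _np.arange(len(draw))
    nb = model.table()[_np.asarray(draw)]
    return float(_np.prod(p[nb, labels[:, None]].sum(axis=1)))
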