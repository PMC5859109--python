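import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from izhifit.evolve import (DEFAULT_BOUNDS, EAConfig, Gene, GenomeLayout,
                            chain_layout, crossover_two_point, init_population,
                            mutate, run_trial, select_parent,
                            single_compartment_layout, step_generation,
                            symmetric_pair_layout)
from izhifit.model import SimConfig
from izhifit.objective import ErrorBreakdown


@pytest.fixture(scope="module")
def layout():
    return single_compartment_layout([156.0])


class TestLayouts:
    def test_single_compartment_length(self):
        assert single_compartment_layout([100.0]).length == 9 + 1
        assert single_compartment_layout([100.0, 200.0, None]).length == 9 + 3

    def test_chain_length_formula(self):
        # 8c + 1 shared Vr + 2(c-1) coupling genes + n_I currents
        lay = chain_layout(["SO", "SP", "SR", "SLM"], "SP", [401.0])
        assert lay.length == 8 * 4 + 1 + 2 * 3 + 1

    def test_known_current_narrow_window(self, layout):
        g = layout.genes[layout.index("I_0")]
        assert (g.lo, g.hi) == (146.0, 166.0)
        unknown = single_compartment_layout([None])
        g = unknown.genes[unknown.index("I_0")]
        assert (g.lo, g.hi) == (50.0, 800.0)

    def test_decode_round_trip(self, layout):
        rng = np.random.default_rng(0)
        for _ in range(20):
            genome = init_population(layout, 1, rng)[0]
            try:
                model, currents = layout.decode(genome)
            except Exception:
                continue  # invalid orderings are rejected, not silently fixed
            p = model.params("soma")
            assert p.Vr < p.Vt and p.Vmin < p.Vpeak
            assert 146.0 <= currents[0] <= 166.0

    def test_symmetric_pair_decodes_identical_compartments(self):
        lay = symmetric_pair_layout([300.0])
        rng = np.random.default_rng(3)
        genome = init_population(lay, 1, rng)[0]
        try:
            model, _ = lay.decode(genome)
        except Exception:
            pytest.skip("random draw violated ordering invariants")
        assert model.params("c1") == model.params("c2")
        assert model.links[0].P == 0.5


class TestInitPopulation:
    def test_degenerate_bounds_identical_population(self):
        genes = tuple(Gene(f"g{i}", 2.0, 2.0) for i in range(5))
        lay = GenomeLayout(genes, ("soma",), "soma", 0, "single")
        pop = init_population(lay, 20, np.random.default_rng(0))
        assert np.all(pop == 2.0)

    def test_identical_seed_identical_population(self, layout):
        p1 = init_population(layout, 30, np.random.default_rng(42))
        p2 = init_population(layout, 30, np.random.default_rng(42))
        np.testing.assert_array_equal(p1, p2)

    def test_samples_fill_bounds(self, layout):
        pop = init_population(layout, 10_000, np.random.default_rng(7))
        b = layout.bounds
        assert np.all(pop >= b[:, 0]) and np.all(pop <= b[:, 1])
        # empirical extrema approach the bounds for the continuous genes
        for i, gene in enumerate(layout.genes):
            if gene.integer_walk:
                continue
            width = gene.hi - gene.lo
            assert pop[:, i].min() < gene.lo + 0.01 * width
            assert pop[:, i].max() > gene.hi - 0.01 * width

    def test_integer_genes_integral(self, layout):
        pop = init_population(layout, 100, np.random.default_rng(1))
        for i, gene in enumerate(layout.genes):
            if gene.integer_walk:
                np.testing.assert_array_equal(pop[:, i], np.round(pop[:, i]))


class TestSelection:
    def test_single_genome_population(self):
        pop = np.tile([1.0, 2.0], (4, 1))
        out = select_parent(pop, np.array([5.0, 5.0, 5.0, 5.0]),
                            np.random.default_rng(0))
        np.testing.assert_array_equal(out, [1.0, 2.0])

    def test_best_selected_with_tournament_probability(self):
        """Binary tournament without replacement picks the best of N with
        probability 2/N (both orderings of {best, other} / all pairs)."""
        N = 4
        pop = np.arange(N, dtype=float).reshape(-1, 1)
        errors = np.arange(N, dtype=float)  # genome 0 is best
        rng = np.random.default_rng(123)
        wins = sum(select_parent(pop, errors, rng)[0] == 0.0
                   for _ in range(20_000))
        assert wins / 20_000 == pytest.approx(2.0 / N, abs=0.01)

    def test_unique_worst_never_selected(self):
        """Without replacement and without ties, the strictly worst
        individual always loses its tournament."""
        pop = np.arange(3, dtype=float).reshape(-1, 1)
        errors = np.array([0.0, 1.0, 2.0])
        rng = np.random.default_rng(5)
        wins = sum(select_parent(pop, errors, rng)[0] == 2.0 for _ in range(5000))
        assert wins == 0


class TestCrossover:
    def test_identical_parents_identical_child(self):
        a = np.arange(10.0)
        child = crossover_two_point(a, a.copy(), np.random.default_rng(0))
        np.testing.assert_array_equal(child, a)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_positional_inheritance(self, seed):
        rng = np.random.default_rng(seed)
        a = np.zeros(12)
        b = np.ones(12)
        child = crossover_two_point(a, b, rng)
        assert set(np.unique(child)) <= {0.0, 1.0}
        # the segment from parent b is contiguous
        ones = np.nonzero(child == 1.0)[0]
        if ones.size:
            assert np.all(np.diff(ones) == 1)

    def test_layout_mismatch_rejected(self):
        with pytest.raises(ValueError):
            crossover_two_point(np.zeros(3), np.zeros(4),
                                np.random.default_rng(0))


class TestMutation:
    def test_zero_probability_no_change(self, layout):
        g = init_population(layout, 1, np.random.default_rng(0))[0]
        out = mutate(g, layout, 0.0, np.random.default_rng(1))
        np.testing.assert_array_equal(out, g)

    def test_integer_walk_clamped_at_bounds(self):
        genes = (Gene("d", 0.0, 5.0, integer_walk=True),)
        lay = GenomeLayout(genes, ("soma",), "soma", 0, "single")
        rng = np.random.default_rng(2)
        at_top = np.array([5.0])
        for _ in range(50):
            out = mutate(at_top, lay, 1.0, rng)
            assert out[0] in (4.0, 5.0)

    def test_reset_mutation_uniform_in_bounds(self):
        from scipy import stats
        genes = (Gene("k", 1.0, 3.0),)
        lay = GenomeLayout(genes, ("soma",), "soma", 0, "single")
        rng = np.random.default_rng(11)
        vals = np.array([mutate(np.array([2.0]), lay, 1.0, rng)[0]
                         for _ in range(5000)])
        assert stats.kstest(vals, "uniform", args=(1.0, 2.0)).pvalue > 0.01


def _sphere_evaluate(genome):
    bd = ErrorBreakdown(accepted=True)
    bd.trace_terms.append({"sphere": float(np.sum((genome - 1.0) ** 2))})
    return bd


class TestGenerationLoop:
    """EA mechanics on a cheap analytic objective (no simulations)."""

    def _layout(self, n=6):
        return GenomeLayout(tuple(Gene(f"g{i}", -5.0, 5.0) for i in range(n)),
                            ("soma",), "soma", 0, "single")

    def _config(self, **kw):
        kw.setdefault("population", 24)
        kw.setdefault("generations", 40)
        kw.setdefault("final_sim", None)
        return EAConfig(**kw)

    def test_elitism_best_error_never_increases(self):
        lay = self._layout()
        rec = run_trial(None, lay, self._config(), seed=3,
                        evaluate=_sphere_evaluate)
        assert all(b <= a + 1e-15 for a, b in
                   zip(rec.best_error, rec.best_error[1:]))
        assert rec.final_error < rec.best_error[0]

    def test_population_respects_bounds_every_generation(self):
        lay = self._layout()
        cfg = self._config()
        rng = np.random.default_rng(9)
        pop = init_population(lay, cfg.population, rng)
        for _ in range(15):
            errors = np.array([_sphere_evaluate(g).total for g in pop])
            pop = step_generation(pop, errors, lay, cfg, rng)
            assert pop.shape == (cfg.population, lay.length)
            assert np.all(pop >= -5.0) and np.all(pop <= 5.0)

    def test_converged_population_closed_under_zero_mutation(self):
        lay = self._layout()
        cfg = self._config(p_mutation=0.0)
        pop = np.tile(np.linspace(-1, 1, lay.length), (cfg.population, 1))
        errors = np.array([_sphere_evaluate(g).total for g in pop])
        nxt = step_generation(pop, errors, lay, cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(nxt, pop)

    def test_seeded_runs_bitwise_identical(self):
        lay = self._layout()
        r1 = run_trial(None, lay, self._config(), seed=77,
                       evaluate=_sphere_evaluate)
        r2 = run_trial(None, lay, self._config(), seed=77,
                       evaluate=_sphere_evaluate)
        assert r1.best_error == r2.best_error
        np.testing.assert_array_equal(r1.best_genome, r2.best_genome)
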