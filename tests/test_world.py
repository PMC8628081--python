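"""Grid dynamics: competition, reproduction, the step schedule, engine
consistency with the reference operators, and determinism."""

import numpy as np
import pytest

from tecoevo import _engine as eng
from tecoevo.config import SimulationConfig
from tecoevo.genome import Genome, essential, transposon
from tecoevo.mutation import MutationRates, mutate_genome
from tecoevo.world import (Cell, CompetitionParams, World, compete, crossover,
                           reproduce_asexual, reproduce_sexual)

NO_MUT = MutationRates.disabled()


def _cell(fitness):
    c = Cell(Genome.initial(10, 0))
    c.fitness = fitness
    return c


class TestCompete:
    def test_no_living_neighbours(self, rng):
        dead = _cell(1.0)
        dead.alive = False
        assert compete([dead], CompetitionParams(), rng) is None

    def test_lone_fit_neighbour_with_zero_epsilon_always_wins(self, rng):
        c = _cell(1.0)
        params = CompetitionParams(epsilon=0.0)
        assert all(compete([c], params, rng) is c for _ in range(100))

    def test_two_equal_neighbours_unit_epsilon_is_one_third_each(self, rng):
        """f = {1, 1}, eps = 1: each wins w.p. 1/3, empty w.p. 1/3."""
        a, b = _cell(1.0), _cell(1.0)
        params = CompetitionParams(epsilon=1.0)
        n = 100_000
        wins = {id(a): 0, id(b): 0, None: 0}
        for _ in range(n):
            w = compete([a, b], params, rng)
            wins[None if w is None else id(w)] += 1
        for count in wins.values():
            assert count / n == pytest.approx(1 / 3, abs=0.01)

    def test_win_probability_proportional_to_fitness(self, rng):
        a, b = _cell(0.9), _cell(0.3)
        params = CompetitionParams(epsilon=0.5)
        n = 50_000
        wins_a = sum(compete([a, b], params, rng) is a for _ in range(n))
        assert wins_a / n == pytest.approx(0.9 / 1.7, abs=0.01)


class TestReproduction:
    def test_asexual_without_mutation_is_clone(self, rng, founder_genome):
        parent = Cell.from_genome(founder_genome)
        child = reproduce_asexual(parent, NO_MUT, parent_fp(), rng)
        assert child.genome == founder_genome
        assert child.fitness == 1.0

    def test_daughter_missing_essential_gene_is_unfit(self, rng, minimal_genome):
        rates = MutationRates(single_dup=0, single_del=1.0, inactivation=0,
                              large_scale=0, phi_mut=0)
        parent = Cell.from_genome(minimal_genome)
        child = reproduce_asexual(parent, rates, parent_fp(), rng)
        assert child.fitness == 0.0

    def test_crossover_split_lengths(self):
        p1 = Genome.initial(10, 0)           # length 10 -> left 5
        p2 = Genome.initial(10, 2)           # length 12 -> right 6
        child = crossover(p1, p2)
        assert len(child) == 5 + 6

    def test_identical_even_parents_reproduce_exactly(self, rng, founder_genome):
        child = crossover(founder_genome, founder_genome)
        assert child == founder_genome

    def test_tes_cross_in_without_transposition(self, rng):
        """TEs in the right half of parent 2 reach the child with no
        transposition event (recombination bypasses insertion damage)."""
        p1 = Cell.from_genome(Genome.initial(10, 10))
        right_te = Genome.from_elements(
            [essential(c) for c in "abcdefghij"] + [transposon(0.9)] * 4
        )
        p2 = Cell.from_genome(right_te)
        params = CompetitionParams(epsilon=0.0, reproduction="sexual")
        children_with_tes = 0
        for _ in range(200):
            child = reproduce_sexual([p1, p2], params, NO_MUT, parent_fp(), rng)
            assert child is not None
            if child.genome.te_count > 0:
                children_with_tes += 1
        assert children_with_tes > 0

    def test_single_parent_falls_back_to_clonal(self, rng, founder_genome):
        p1 = Cell.from_genome(founder_genome)
        params = CompetitionParams(epsilon=0.0, reproduction="sexual")
        child = reproduce_sexual([p1], params, NO_MUT, parent_fp(), rng)
        assert child.genome == founder_genome


def parent_fp():
    from tecoevo.genome import FitnessParams

    return FitnessParams()


def tiny_config(**kw):
    base = dict(width=12, height=12, steps=10, seed=3, write_png=False,
                snapshot_every=10**9, sample_every=5)
    base.update(kw)
    return SimulationConfig(**base)


class TestStepWorld:
    def test_empty_world_stays_empty(self):
        w = World(8, 8, seed=1)
        for _ in range(5):
            w.step()
        assert w.n_cells == 0
        assert w.n_fragments == 0

    def test_absorbing_state_without_death_or_mutation(self):
        """d=0, no TEs, no mutation, full grid: nothing can change."""
        cfg = tiny_config(d=0.0, single_dup=0, single_del=0, inactivation=0,
                          large_scale=0, phi_mut=0, inoculation="none")
        w, _ = cfg.build_world()
        before = w.codes.copy(), w.glen.copy()
        for _ in range(10):
            w.step()
        assert w.n_cells == w.n_sites
        assert np.array_equal(w.codes, before[0])
        assert np.array_equal(w.glen, before[1])

    def test_occupancy_never_exceeds_one_cell_per_site(self):
        cfg = tiny_config(steps=0)
        w, _ = cfg.build_world()
        for _ in range(30):
            w.step()
            assert np.count_nonzero(w.occ) == w.n_cells
            assert np.all(w.glen[~w.occ] == 0)

    def test_death_rate_matches_d(self):
        cfg = tiny_config(width=40, height=40, d=0.1, inoculation="none",
                          single_dup=0, single_del=0, inactivation=0,
                          large_scale=0, phi_mut=0)
        w, _ = cfg.build_world()
        events = w.step()
        frac = len(events.death_lineage) / w.n_sites
        assert frac == pytest.approx(0.1, abs=0.03)

    def test_dead_cells_lyse_into_local_fragments(self):
        cfg = tiny_config(d=1.0, q=0.0, inoculation="none")
        w, _ = cfg.build_world()
        w.step()
        assert w.n_cells == 0
        # 144 cells x 40 elements, fragments of mean ~5.5
        assert w.n_fragments > 144 * 40 / 8
        total_elements = int(w.f_len[:w.n_fragments].astype(int).sum())
        assert total_elements == 144 * 40

    def test_engine_scan_matches_reference_on_forced_rates(self):
        """The engine's mutation scan and the reference mutate_genome agree
        exactly on deterministic (rate 0/1) settings."""
        g = Genome.initial(10, 10)
        for rates in (
            MutationRates(1.0, 0.0, 0.0, 0.0, 0.0),
            MutationRates(0.0, 1.0, 0.0, 0.0, 0.0),
            MutationRates(0.0, 0.0, 1.0, 0.0, 0.0),
        ):
            ref = mutate_genome(g, rates, np.random.default_rng(0))
            P = np.zeros(eng.NPARAMS)
            P[eng.P_SDUP] = rates.single_dup
            P[eng.P_SDEL] = rates.single_del
            P[eng.P_INACT] = rates.inactivation
            P[eng.P_LARGE] = rates.large_scale
            P[eng.P_PHIMUT] = rates.phi_mut
            P[eng.P_PHISTEP] = rates.phi_step
            wcodes = np.zeros(256, dtype=np.int8)
            wphis = np.zeros(256, dtype=np.float32)
            wfresh = np.zeros(256, dtype=np.uint8)
            wcodes[: len(g)] = g.codes
            wphis[: len(g)] = g.phis
            eng.seed_rng(0)
            L = eng._scan_mutate(wcodes, wphis, wfresh, len(g), P)
            assert L == len(ref)
            assert np.array_equal(wcodes[:L], ref.codes)

    def test_same_seed_reproduces_exactly(self, tmp_path):
        from tecoevo.scenarios import run_single

        outs = []
        for rep in range(2):
            cfg = tiny_config(steps=40, seed=11, inoculation="block",
                              inoculation_block=3)
            res = run_single(cfg, str(tmp_path / f"rep{rep}"))
            outs.append((tmp_path / f"rep{rep}" / "timeseries.csv").read_bytes())
        assert outs[0] == outs[1]

    def test_different_seeds_diverge(self):
        from tecoevo.scenarios import run_single

        finals = set()
        for seed in (1, 2, 3):
            cfg = tiny_config(steps=30, seed=seed, inoculation="block",
                              inoculation_block=3)
            res = run_single(cfg)
            finals.add((res.final_n_cells, res.final_te_total))
        assert len(finals) > 1

    def test_mixed_cells_mode_preserves_population(self):
        cfg = tiny_config(mode="mixed_cells", inoculation="none", d=0.0,
                          single_dup=0, single_del=0, inactivation=0,
                          large_scale=0, phi_mut=0)
        w, _ = cfg.build_world()
        w.step()
        assert w.n_cells == w.n_sites  # shuffling must not lose cells

    def test_mixed_edna_mode_scatters_fragments_only(self):
        cfg = tiny_config(mode="mixed_edna", d=1.0, q=0.0, diffusion=0.0,
                          inoculation="none")
        w, _ = cfg.build_world()
        w.step()  # everyone lyses at their own site, then the pool scatters
        n = w.n_fragments
        assert n > 100
        # fragments land at uniformly random sites, not only at dead cells'
        sites = w.f_site[:n]
        assert len(np.unique(sites)) > w.n_sites // 2

    def test_checkpoint_round_trip(self, tmp_path):
        cfg = tiny_config(steps=0, inoculation="block", inoculation_block=3)
        w, _ = cfg.build_world()
        for _ in range(10):
            w.step()
        path = str(tmp_path / "ckpt.npz")
        w.save(path)
        w2 = World.load(path)
        assert w2.t == w.t
        assert w2.n_cells == w.n_cells
        assert np.array_equal(w2.occ, w.occ)
        assert np.array_equal(w2.glen, w.glen)
        assert w2.te_total == w.te_total
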