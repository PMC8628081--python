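"""Mutation operators: the replication scan and its building blocks."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tecoevo.genome import Genome, essential, noncoding, transposon
from tecoevo.mutation import (MutationRates, apply_inactivation, apply_large_scale,
                              apply_single_deletion, apply_single_duplication,
                              draw_segment_length, mutate_genome, mutate_phi)

from conftest import random_genome


class TestSingleOps:
    def test_duplication_is_tandem(self):
        g = Genome.from_elements([essential("a"), essential("b"), essential("c")])
        out = apply_single_duplication(g, 1)
        assert out.to_text() == "a,b,b,c"

    def test_duplicating_te_copies_phi(self):
        g = Genome.from_elements([transposon(0.7)])
        out = apply_single_duplication(g, 0)
        assert out.te_count == 2
        assert np.allclose(out.te_phis, [0.7, 0.7])

    def test_dup_then_delete_restores(self):
        g = Genome.from_elements([essential("a"), transposon(0.3), noncoding()])
        assert apply_single_deletion(apply_single_duplication(g, 1), 2) == g

    def test_inactivation_of_each_kind(self):
        g = Genome.from_elements([essential("a"), transposon(0.9), noncoding()])
        for pos in range(3):
            out = apply_inactivation(g, pos)
            assert out[pos].kind == "noncoding"
            assert len(out) == len(g)
        # phi is discarded with the TE
        assert apply_inactivation(g, 1).te_count == 0

    def test_out_of_range_raises(self):
        g = Genome.from_elements([essential("a")])
        for op in (apply_single_duplication, apply_single_deletion, apply_inactivation):
            with pytest.raises(IndexError):
                op(g, 5)


class TestLargeScale:
    def test_full_inversion_reverses(self, rng):
        g = Genome.from_elements([essential(c) for c in "abcd"])
        out = apply_large_scale(g, 0, "inversion", rng, length=4)
        assert out.to_text() == "d,c,b,a"

    def test_deletion_arithmetic(self, rng):
        g = Genome.initial(10, 30)
        out = apply_large_scale(g, 5, "deletion", rng, length=10)
        assert len(out) == 30

    def test_duplication_is_tandem_segment(self, rng):
        g = Genome.from_elements([essential(c) for c in "abcd"])
        out = apply_large_scale(g, 1, "duplication", rng, length=2)
        assert out.to_text() == "a,b,c,b,c,d"

    def test_truncation_at_genome_end(self, rng):
        g = Genome.from_elements([essential(c) for c in "abc"])
        out = apply_large_scale(g, 2, "deletion", rng, length=10)
        assert out.to_text() == "a,b"

    @given(st.integers(0, 2**31 - 1))
    def test_inversion_conserves_length_and_multiset(self, seed):
        rng = np.random.default_rng(seed)
        g = random_genome(rng, length=30)
        pos = int(rng.integers(0, 30))
        out = apply_large_scale(g, pos, "inversion", rng)
        assert len(out) == len(g)
        assert sorted(out.codes.tolist()) == sorted(g.codes.tolist())
        assert sorted(out.phis.tolist()) == pytest.approx(sorted(g.phis.tolist()))

    def test_segment_length_mean_is_quarter_genome(self, rng):
        """Large-scale events affect on average 25% of the genome."""
        draws = [draw_segment_length(40, rng) for _ in range(10_000)]
        assert np.mean(draws) / 40 == pytest.approx(0.25, abs=0.01)
        assert min(draws) >= 1
        assert max(draws) <= 19


class TestPhiMutation:
    def test_step_is_plus_or_minus_point_one(self, rng):
        rates = MutationRates(phi_mut=1.0)
        seen = set()
        for _ in range(200):
            out = mutate_phi(transposon(0.5), rates, rng)
            seen.add(round(out.phi, 3))
        assert seen == {0.4, 0.6}

    def test_clamped_at_zero(self, rng):
        rates = MutationRates(phi_mut=1.0)
        outs = {round(mutate_phi(transposon(0.05), rates, rng).phi, 3)
                for _ in range(200)}
        assert outs == {0.0, 0.15}

    def test_symmetry_of_fired_steps(self, rng):
        rates = MutationRates(phi_mut=1.0)
        vals = [mutate_phi(transposon(0.5), rates, rng).phi for _ in range(10_000)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.005)

    def test_requires_te(self, rng):
        with pytest.raises(ValueError):
            mutate_phi(essential("a"), MutationRates(), rng)

    @given(st.integers(0, 2**31 - 1))
    def test_phi_stays_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        rates = MutationRates(phi_mut=1.0)
        te = transposon(float(rng.random()))
        for _ in range(50):
            te = mutate_phi(te, rates, rng)
            assert 0.0 <= te.phi <= 1.0


class TestScan:
    def test_zero_rates_is_identity(self, rng, founder_genome):
        out = mutate_genome(founder_genome, MutationRates.disabled(), rng)
        assert out.to_text() == founder_genome.to_text()

    def test_forced_deletion_erases_genome(self, rng):
        rates = MutationRates(single_dup=0, single_del=1.0, inactivation=0,
                              large_scale=0, phi_mut=0)
        g = Genome.initial(5, 0)
        assert len(mutate_genome(g, rates, rng)) == 0

    def test_forced_duplication_doubles_adjacently(self, rng):
        rates = MutationRates(single_dup=1.0, single_del=0, inactivation=0,
                              large_scale=0, phi_mut=0)
        g = Genome.from_elements([essential(c) for c in "abcde"])
        out = mutate_genome(g, rates, rng)
        assert out.to_text() == "a,a,b,b,c,c,d,d,e,e"

    def test_forced_inactivation_blanks_everything(self, rng):
        rates = MutationRates(single_dup=0, single_del=0, inactivation=1.0,
                              large_scale=0, phi_mut=0)
        g = Genome.initial(10, 0)
        out = mutate_genome(g, rates, rng)
        assert len(out) == 10
        assert np.all(out.codes == 0)

    @given(st.integers(0, 2**31 - 1))
    def test_scan_at_default_rates_keeps_genome_reasonable(self, seed):
        rng = np.random.default_rng(seed)
        g = random_genome(rng, length=40)
        out = mutate_genome(g, MutationRates(), rng)
        # a single pass at the default (0.1%) rates cannot reshape the
        # genome drastically: rare events each add/remove at most ~G/2
        assert 0 < len(out) < 3 * len(g)
        assert np.all((out.te_phis >= 0) & (out.te_phis <= 1))
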