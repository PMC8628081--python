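"""Time-series sampling, lineage accounting and snapshot export."""

import numpy as np
import pytest

from tecoevo.config import SimulationConfig
from tecoevo.observers import (LineageTracker, TimeSeriesObserver,
                               export_snapshot, record_timeseries)
from tecoevo.world import World


def small_config(**kw):
    base = dict(width=15, height=15, steps=0, seed=7, write_png=False,
                snapshot_every=10**9)
    base.update(kw)
    return SimulationConfig(**base)


class TestTimeSeries:
    def test_uniform_founder_population_means(self):
        w, _ = small_config(inoculation="none").build_world()
        rec = record_timeseries(w)
        assert rec.n_cells == 225
        assert rec.mean_essential == pytest.approx(10.0)
        assert rec.mean_te == pytest.approx(0.0)
        assert rec.mean_noncoding == pytest.approx(30.0)
        assert rec.mean_length == pytest.approx(40.0)
        assert rec.mean_fitness == pytest.approx(1.0)
        assert np.isnan(rec.mean_phi)  # no TEs anywhere

    def test_single_cell_metrics(self):
        from tecoevo.genome import Genome

        w = World(8, 8, seed=0)
        w.place_cell(2, 2, Genome.initial(10, 0))
        rec = record_timeseries(w)
        assert rec.n_cells == 1
        assert rec.mean_length == pytest.approx(10.0)
        assert rec.mean_fitness == pytest.approx(1.0)

    def test_empty_world_record(self):
        rec = record_timeseries(World(8, 8, seed=0))
        assert rec.n_cells == 0
        assert np.isnan(rec.mean_length)

    def test_length_identity_holds_at_every_sample(self):
        cfg = small_config(inoculation="block", inoculation_block=3)
        w, _ = cfg.build_world()
        ts = TimeSeriesObserver(sample_every=5)
        w.run(40, observers=[ts])
        df = ts.to_frame()
        assert len(df) >= 3
        total = df.mean_essential + df.mean_te + df.mean_noncoding
        assert np.allclose(total, df.mean_length)

    def test_n_cells_matches_independent_scan(self):
        cfg = small_config(inoculation="block", inoculation_block=3)
        w, _ = cfg.build_world()
        for _ in range(20):
            w.step()
        rec = record_timeseries(w)
        by_scan = sum(
            w.genome_at(x, y) is not None
            for x in range(w.width) for y in range(w.height)
        )
        assert rec.n_cells == by_scan


class TestLineages:
    def _run(self, steps=120, **kw):
        cfg = small_config(inoculation="block", inoculation_block=5, **kw)
        w, seeded = cfg.build_world()
        lt = LineageTracker()
        lt.register_infections(seeded, t=0)
        w.run(steps, observers=[lt])
        return w, lt

    def test_infected_lineages_are_tracked(self):
        w, lt = self._run()
        assert len(lt.records) >= 25  # at least the inoculated block

    def test_te_ledger_conservation(self):
        """TEs attributed to lineages at lysis equal all TEs ever lysed
        from infected cells (open + closed records)."""
        cfg = small_config(inoculation="block", inoculation_block=5)
        w, seeded = cfg.build_world()
        lt = LineageTracker()
        lt.register_infections(seeded, t=0)
        total_lysed_infected = 0
        for _ in range(150):
            ev = w.step()
            mask = ev.death_lineage >= 0
            total_lysed_infected += int(ev.death_te[mask].sum())
            lt.observe(w, ev)
        assert lt.total_te_produced == total_lysed_infected

    def test_closed_records_are_consistent(self):
        w, lt = self._run(steps=300)
        for rec in lt.closed_records:
            assert rec.t_extinct >= rec.t_infected
            assert rec.te_produced >= 0
            assert rec.generations_survived >= 0

    def test_never_infected_lineages_have_no_record(self):
        cfg = small_config(inoculation="none")
        w, seeded = cfg.build_world()
        assert seeded == []
        lt = LineageTracker()
        w.run(50, observers=[lt])
        assert lt.records == {}

    def test_explicit_te_sum(self):
        """A lineage whose members lyse 2, 1 and 4 TEs reports 7."""
        lt = LineageTracker()
        lt.register_infections([0], t=100)
        from tecoevo.world import StepEvents

        def ev(t, deaths=(), births=0):
            lam = np.array([d[0] for d in deaths], dtype=np.int64)
            te = np.array([d[1] for d in deaths], dtype=np.int32)
            dep = np.array([d[2] for d in deaths], dtype=np.int32)
            return StepEvents(lam, te, dep,
                              np.zeros(births, dtype=np.int64),
                              np.zeros(0, dtype=np.int64), t=t)

        lt.observe(None, ev(101, births=2))
        lt.observe(None, ev(102, deaths=[(0, 2, 1)]))
        lt.observe(None, ev(103, deaths=[(0, 1, 2)]))
        lt.observe(None, ev(104, deaths=[(0, 4, 2)]))
        rec = lt.records[0]
        assert rec.closed
        assert rec.te_produced == 7
        assert rec.t_extinct == 104
        assert rec.generations_survived == 2


class TestSnapshots:
    def test_matrix_dimensions_match_grid(self):
        w, _ = small_config(inoculation="none").build_world()
        mat = export_snapshot(w, "occupancy")
        assert mat.shape == (w.height, w.width)

    def test_empty_world_all_empty(self):
        mat = export_snapshot(World(6, 9, seed=0), "te_count")
        assert mat.shape == (9, 6)
        assert np.all(mat == -1)

    def test_checkerboard_round_trips_exactly(self, tmp_path):
        from tecoevo.genome import Genome

        w = World(8, 8, seed=0)
        for y in range(8):
            for x in range(8):
                if (x + y) % 2 == 0:
                    w.place_cell(x, y, Genome.initial(10, 0))
        txt = str(tmp_path / "snap.txt")
        mat = export_snapshot(w, "occupancy", txt_path=txt)
        back = np.loadtxt(txt, dtype=int)
        assert np.array_equal(back, mat)
        expected = np.fromfunction(lambda y, x: (x + y) % 2 == 0, (8, 8))
        assert np.array_equal(mat == 1, expected)

    def test_genome_length_channel(self):
        w, _ = small_config(inoculation="none").build_world()
        mat = export_snapshot(w, "genome_length")
        assert np.all(mat == 40)

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError):
            export_snapshot(World(5, 5, seed=0), "colour")

    def test_edna_channels_census_the_pool(self):
        cfg = small_config(d=1.0, q=0.0, inoculation="none")
        w, _ = cfg.build_world()
        w.step()  # everyone lyses in place
        frag = export_snapshot(w, "edna_fragments")
        te = export_snapshot(w, "edna_te")
        assert frag.sum() == w.n_fragments
        assert te.sum() == w.edna_te_total
        assert frag.min() >= 1  # every site hosted a lysis

    def test_genome_dump_round_trips(self, tmp_path):
        from tecoevo.genome import Genome

        w = World(6, 6, seed=0)
        w.place_cell(1, 1, Genome.initial(10, 3))
        w.place_cell(4, 2, Genome.from_text("a,T:0.900,."))
        path = tmp_path / "genomes.txt"
        w.write_genomes(str(path))
        lines = path.read_text().splitlines()
        assert len(lines) == 2
        assert sorted(len(Genome.from_text(l)) for l in lines) == [3, 13]

    def test_png_written(self, tmp_path):
        w, _ = small_config(inoculation="block", inoculation_block=3).build_world()
        png = tmp_path / "snap.png"
        export_snapshot(w, "te_count", png_path=str(png))
        assert png.stat().st_size > 0
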