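"""Observers: time series, lineage tracking, and grid snapshot export.

``TimeSeriesObserver`` samples population-level means every
``sample_every`` steps (genome composition, fitness, transposition rate,
eDNA pool size).  ``LineageTracker`` follows infected lineages: a lineage
is founded the first time a cell of an uninfected line of descent
acquires a TE, all descendants share the record (including branches that
later lose their TEs), and the record closes when the last member dies.
Per closed lineage it reports the time of infection, the extinction time,
the generations survived (longest chain of reproduction events since
infection) and the cumulative number of TE copies the lineage released
into the eDNA pool by lysis.  ``export_snapshot`` rasterises one grid
channel (TE load, occupancy or genome length) to a numeric matrix and
optionally a PNG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .world import StepEvents, World

__all__ = [
    "TimeSeriesRecord",
    "TimeSeriesObserver",
    "record_timeseries",
    "LineageRecord",
    "LineageTracker",
    "export_snapshot",
    "SNAPSHOT_CHANNELS",
]


@dataclass
class TimeSeriesRecord:
    """Population means at one timestep (NaN where the population is empty)."""

    t: int
    n_cells: int
    mean_essential: float
    mean_te: float
    mean_noncoding: float
    mean_length: float
    mean_phi: float
    mean_fitness: float
    edna_fragments: int
    edna_te: int


def record_timeseries(world: World) -> TimeSeriesRecord:
    """Sample the population-level state of ``world``.

    All means are over living cells; ``mean_phi`` is over all TE copies in
    living cells.  An empty population yields NaN means and n_cells = 0.
    """
    occ = world.occ
    n = int(np.count_nonzero(occ))
    if n == 0:
        return TimeSeriesRecord(world.t, 0, np.nan, np.nan, np.nan, np.nan,
                                np.nan, np.nan, world.n_fragments,
                                world.edna_te_total)
    te = world.te_cnt[occ]
    te_total = int(te.sum())
    mean_phi = float(world.phi_sum[occ].sum() / te_total) if te_total else np.nan
    return TimeSeriesRecord(
        t=world.t,
        n_cells=n,
        mean_essential=float(world.ess_cnt[occ].mean()),
        mean_te=float(te.mean()),
        mean_noncoding=float(world.nc_cnt[occ].mean()),
        mean_length=float(world.glen[occ].mean()),
        mean_phi=mean_phi,
        mean_fitness=float(world.fitness[occ].mean()),
        edna_fragments=world.n_fragments,
        edna_te=world.edna_te_total,
    )


class TimeSeriesObserver:
    """Collects a `TimeSeriesRecord` every ``sample_every`` steps."""

    def __init__(self, sample_every: int = 50):
        self.sample_every = int(sample_every)
        self.records: list[TimeSeriesRecord] = []

    def observe(self, world: World, events: StepEvents) -> None:
        if world.t % self.sample_every == 0:
            self.records.append(record_timeseries(world))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class LineageRecord:
    """Fate of one infected lineage, closed at collective extinction."""

    lineage_id: int
    t_infected: int
    t_extinct: int = -1
    generations_survived: int = 0
    births: int = 0
    te_produced: int = 0
    closed: bool = False

    @property
    def lifetime_steps(self) -> int:
        return self.t_extinct - self.t_infected if self.closed else -1


class LineageTracker:
    """Aggregates the engine's per-step lineage events into records.

    ``generations_survived`` is the maximum reproduction depth reached by
    any member (number of birth events along the deepest chain of descent
    since infection); the number of timesteps survived is also available
    as ``lifetime_steps``.
    """

    def __init__(self):
        self.records: dict[int, LineageRecord] = {}
        self._alive: dict[int, int] = {}

    def register_infections(self, lineage_ids: list[int], t: int) -> None:
        """Register lineages founded outside the step loop (inoculation)."""
        for lid in lineage_ids:
            self.records[lid] = LineageRecord(lid, t)
            self._alive[lid] = 1

    def observe(self, world: World, events: StepEvents) -> None:
        for lid in events.new_infections:
            lid = int(lid)
            self.records[lid] = LineageRecord(lid, events.t)
            self._alive[lid] = 1
        for lid in events.birth_lineage:
            lid = int(lid)
            if lid in self.records:
                self.records[lid].births += 1
                self._alive[lid] = self._alive.get(lid, 0) + 1
        for lid, te, depth in zip(events.death_lineage, events.death_te,
                                  events.death_depth):
            lid = int(lid)
            if lid < 0 or lid not in self.records:
                continue
            rec = self.records[lid]
            rec.te_produced += int(te)
            if int(depth) > rec.generations_survived:
                rec.generations_survived = int(depth)
            self._alive[lid] -= 1
            if self._alive[lid] <= 0:
                rec.t_extinct = events.t
                rec.closed = True

    @property
    def closed_records(self) -> list[LineageRecord]:
        return [r for r in self.records.values() if r.closed]

    @property
    def total_te_produced(self) -> int:
        return sum(r.te_produced for r in self.records.values())

    def to_frame(self, closed_only: bool = True) -> pd.DataFrame:
        recs = self.closed_records if closed_only else list(self.records.values())
        cols = ["lineage_id", "t_infected", "t_extinct", "generations_survived",
                "births", "te_produced"]
        return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in recs],
                            columns=cols)

    def to_csv(self, path: str, closed_only: bool = True) -> None:
        self.to_frame(closed_only).to_csv(path, index=False)


SNAPSHOT_CHANNELS = ("te_count", "occupancy", "genome_length",
                     "edna_fragments", "edna_te")

#: matrix value encoding an empty site (rendered black in PNGs)
EMPTY_SITE = -1


def export_snapshot(
    world: World,
    channel: str = "te_count",
    png_path: str | None = None,
    txt_path: str | None = None,
) -> np.ndarray:
    """Rasterise one channel of the grid to a (height, width) matrix.

    Empty sites are encoded as -1 (black in the PNG) for the cell
    channels; the eDNA-pool channels (``edna_fragments``/``edna_te``,
    per-site pool censuses) have no empty encoding.  The ``te_count``
    colour map is log-scaled (log1p) to resolve low TE loads.  Returns
    the raw (un-logged) matrix; optionally writes a PNG and/or a
    plain-text matrix.
    """
    if channel not in SNAPSHOT_CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; choose from {SNAPSHOT_CHANNELS}")
    occ = world.occ.reshape(world.height, world.width)
    if channel == "occupancy":
        mat = np.where(occ, 1, EMPTY_SITE).astype(np.int32)
    elif channel == "te_count":
        vals = world.te_cnt.reshape(world.height, world.width)
        mat = np.where(occ, vals, EMPTY_SITE).astype(np.int32)
    elif channel == "genome_length":
        vals = world.glen.reshape(world.height, world.width)
        mat = np.where(occ, vals, EMPTY_SITE).astype(np.int32)
    else:
        n = world.n_fragments
        weights = None if channel == "edna_fragments" else world.f_te[:n]
        counts = np.bincount(world.f_site[:n], weights=weights,
                             minlength=world.n_sites)
        mat = counts.reshape(world.height, world.width).astype(np.int32)
    if txt_path is not None:
        np.savetxt(txt_path, mat, fmt="%d")
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib import colormaps

        display = mat.astype(float)
        if channel == "te_count":
            display = np.where(mat >= 0, np.log1p(np.maximum(mat, 0)), np.nan)
        else:
            display = np.where(mat >= 0, display, np.nan)
        cmap = colormaps["viridis"].copy()
        cmap.set_bad("black")
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.imshow(display, cmap=cmap, interpolation="nearest")
        ax.set_axis_off()
        fig.savefig(png_path, bbox_inches="tight", dpi=120)
        plt.close(fig)
    return mat


class SnapshotObserver:
    """Writes snapshot matrices (and PNGs) every ``every`` steps."""

    def __init__(self, outdir: str, channel: str = "te_count", every: int = 1000,
                 png: bool = True):
        self.outdir = outdir
        self.channel = channel
        self.every = int(every)
        self.png = png

    def observe(self, world: World, events: StepEvents) -> None:
        if events.t % self.every != 0:
            return
        base = f"{self.outdir}/snapshot_{self.channel}_t{events.t:07d}"
        export_snapshot(world, self.channel,
                        png_path=base + ".png" if self.png else None,
                        txt_path=base + ".txt")
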