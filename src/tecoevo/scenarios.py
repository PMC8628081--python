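"""Canned scenario runners mirroring the model's headline experiments.

Each scenario builds one or more configured worlds, runs them with
observers attached, writes a reproducible run directory (config copy,
time-series CSV, lineage CSV, snapshots, summary JSON) and classifies
the ecological outcome.  Desk-scale defaults (a smaller grid and fewer
steps than the full 150x150 x 50 000+ scale) keep a scenario within
minutes on one CPU while preserving the qualitative regimes; pass
``full_scale=True`` for the full scale.

Scenarios
---------
``ecology_sweep``  fixed genomes, mutations off: phase structure of
                   TE/host coexistence over transposition rate and
                   genome streamlining, spatial or well-mixed.
``evolve``         the de novo genome-streamlining experiment (10
                   essential + 30 non-coding founders, local TE
                   inoculation, all mutations on).
``evolve_mixed``   as ``evolve`` but cells shuffled every step.
``sexual_compare`` sexual vs asexual-HGT vs strictly clonal populations.
``b_sweep``        the insertion-damage control (b = 0 .. 1).
``no_hgt``         DNA uptake disabled (TE extinction control).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .observers import (LineageTracker, SnapshotObserver, TimeSeriesObserver,
                        record_timeseries)

__all__ = ["SCENARIOS", "run_scenario", "run_single", "classify_outcome", "RunResult"]

OUTCOMES = ("hosts_extinct", "tes_extinct", "coexistence", "undecided")


@dataclass
class RunResult:
    """Everything produced by one simulation run."""

    config: SimulationConfig
    timeseries: pd.DataFrame
    lineages: pd.DataFrame
    final_n_cells: int
    final_te_total: int
    outcome: str


def classify_outcome(timeseries: pd.DataFrame) -> str:
    """Classify a completed run from its time series.

    ``hosts_extinct`` if the population died out; ``tes_extinct`` if
    hosts live but no TE remains anywhere (genomes or eDNA pool);
    ``coexistence`` if both persist and the total TE abundance is not
    strongly trending over the final quartile of samples; otherwise
    ``undecided`` (apparent coexistence that has not reached steady
    state).  The trend test compares the fitted linear change over the
    final quartile against half its mean level.
    """
    if len(timeseries) == 0:
        raise ValueError("empty time series")
    last = timeseries.iloc[-1]
    if last.n_cells == 0:
        return "hosts_extinct"
    te_total = timeseries.mean_te.fillna(0.0) * timeseries.n_cells + timeseries.edna_te
    if te_total.iloc[-1] == 0:
        return "tes_extinct"
    tail = te_total.iloc[-max(2, len(te_total) // 4):]
    if len(tail) < 3:
        return "coexistence"  # too few samples to assess a trend
    t = np.arange(len(tail), dtype=float)
    slope = float(np.polyfit(t, tail.to_numpy(dtype=float), 1)[0])
    change = abs(slope) * (len(tail) - 1)
    if change > 0.5 * max(tail.mean(), 1.0):
        return "undecided"
    return "coexistence"


def run_single(
    config: SimulationConfig,
    outdir: str | None = None,
    progress: bool = False,
) -> RunResult:
    """Run one configured simulation and (optionally) write its directory.

    The run is fully reproducible from the embedded config + seed; with
    the same seed the CSV outputs are byte-identical.
    """
    world, seeded_lineages = config.build_world()
    ts = TimeSeriesObserver(config.sample_every)
    lt = LineageTracker()
    lt.register_infections(seeded_lineages, t=0)
    observers = [ts, lt]
    snap = None
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        config.with_overrides(outdir=outdir).to_yaml(os.path.join(outdir, "config.yaml"))
        snap = SnapshotObserver(outdir, "te_count", config.snapshot_every,
                                png=config.write_png)
        observers.append(snap)
    world.run(config.steps, observers=observers)
    if not ts.records or ts.records[-1].t != world.t:
        ts.records.append(record_timeseries(world))
    result = RunResult(
        config=config,
        timeseries=ts.to_frame(),
        lineages=lt.to_frame(closed_only=True),
        final_n_cells=world.n_cells,
        final_te_total=world.te_total,
        outcome=classify_outcome(ts.to_frame()),
    )
    if outdir is not None:
        result.timeseries.to_csv(os.path.join(outdir, "timeseries.csv"), index=False)
        result.lineages.to_csv(os.path.join(outdir, "lineages.csv"), index=False)
        with open(os.path.join(outdir, "summary.json"), "w") as fh:
            json.dump({
                "outcome": result.outcome,
                "final_n_cells": result.final_n_cells,
                "final_te_total": result.final_te_total,
                "steps": config.steps,
                "seed": config.seed,
            }, fh, indent=2)
    return result


# -- scenario definitions ------------------------------------------------

#: desk-scale defaults; the full scale is 150x150 and 50 000+ steps.
#: Ecological (fixed-genome) runs settle their outcome within 5000 steps;
#: evolutionary runs need ~15 000 steps for the full expansion ->
#: streamlining arc, including the reproduction-mode comparison (each
#: population type is compared at its final extant state; see
#: docs/methods.md).
DESK_ECO = dict(width=75, height=75, steps=5000)
DESK_EVO = dict(width=75, height=75, steps=15_000)
DESK_SEX = dict(width=75, height=75, steps=15_000)
FULL_ECO = dict(width=150, height=150, steps=50_000)
FULL_EVO = dict(width=150, height=150, steps=80_000)


def _base(full_scale: bool, scale_desk=None, scale_full=None, **kw) -> SimulationConfig:
    scale = (scale_full or FULL_EVO) if full_scale else (scale_desk or DESK_EVO)
    return SimulationConfig(**{**scale, **kw})


def _ecology_config(full_scale: bool, **kw) -> SimulationConfig:
    """Fixed-genome ecology: mutations disabled, TEs inoculated into a
    central block of cells (insertion without damage at t = 0).  Local
    seeding is essential: the coexistence regime lives on travelling
    infection waves with an uninfected bulk to recolonise behind them."""
    defaults = dict(
        single_dup=0.0, single_del=0.0, inactivation=0.0, large_scale=0.0,
        phi_mut=0.0, inoculation="block", inoculation_block=5,
        write_png=False, snapshot_every=10**9,
    )
    defaults.update(kw)
    return _base(full_scale, scale_desk=DESK_ECO, scale_full=FULL_ECO, **defaults)


def scenario_ecology_sweep(outdir, seed=1, full_scale=False, overrides=None,
                           phis=(0.3, 0.9), noncoding=(0, 30, 240)):
    """Phase structure over transposition rate x genome streamlining."""
    results = {}
    for phi in phis:
        for nc in noncoding:
            cfg = _ecology_config(full_scale, phi_init=phi, initial_noncoding=nc,
                                  seed=seed, **(overrides or {}))
            sub = os.path.join(outdir, f"phi{phi}_nc{nc}")
            results[(phi, nc)] = run_single(cfg, sub)
    table = pd.DataFrame(
        [{"phi": k[0], "noncoding": k[1], "outcome": r.outcome,
          "final_n_cells": r.final_n_cells, "final_te_total": r.final_te_total}
         for k, r in results.items()]
    )
    table.to_csv(os.path.join(outdir, "sweep_outcomes.csv"), index=False)
    return results


def scenario_evolve(outdir, seed=1, full_scale=False, overrides=None):
    """De novo genome streamlining: evolving 10+30 founders, local
    TE inoculation at the grid centre."""
    cfg = _base(full_scale, seed=seed, inoculation="block",
                initial_noncoding=30, **(overrides or {}))
    return {"evolve": run_single(cfg, outdir)}


def scenario_evolve_mixed(outdir, seed=1, full_scale=False, overrides=None):
    """The well-mixed control of the evolutionary run: cells scattered to
    random sites every step, starting from an ecologically viable
    composition."""
    cfg = _base(full_scale, seed=seed, inoculation="block", mode="mixed_cells",
                initial_noncoding=30, **(overrides or {}))
    return {"evolve_mixed": run_single(cfg, outdir)}


def scenario_sexual_compare(outdir, seed=1, full_scale=False, overrides=None):
    """Sexual vs asexual-HGT vs strictly clonal populations."""
    results = {}
    for name, repro in (("sexual", "sexual"), ("asexual", "asexual_hgt"),
                        ("clonal", "clonal")):
        cfg = _base(full_scale, scale_desk=DESK_SEX, seed=seed,
                    inoculation="block", reproduction=repro,
                    initial_noncoding=30, **(overrides or {}))
        results[name] = run_single(cfg, os.path.join(outdir, name))
    return results


def scenario_b_sweep(outdir, seed=1, full_scale=False, overrides=None,
                     b_values=(0.0, 0.5, 1.0)):
    """Insertion-damage control: evolutionary runs over b."""
    results = {}
    for b in b_values:
        cfg = _base(full_scale, seed=seed, inoculation="block", b=b,
                    initial_noncoding=30, **(overrides or {}))
        results[f"b{b}"] = run_single(cfg, os.path.join(outdir, f"b{b}"))
    return results


def scenario_no_hgt(outdir, seed=1, full_scale=False, overrides=None):
    """DNA uptake disabled: TEs lose their route to new lineages."""
    cfg = _base(full_scale, seed=seed, inoculation="block", u=0.0,
                initial_noncoding=30, **(overrides or {}))
    return {"no_hgt": run_single(cfg, outdir)}


SCENARIOS = {
    "ecology_sweep": scenario_ecology_sweep,
    "evolve": scenario_evolve,
    "evolve_mixed": scenario_evolve_mixed,
    "sexual_compare": scenario_sexual_compare,
    "b_sweep": scenario_b_sweep,
    "no_hgt": scenario_no_hgt,
}


def run_scenario(name: str, outdir: str, seed: int = 1, full_scale: bool = False,
                 overrides: dict | None = None) -> dict[str, RunResult]:
    """Run a named scenario; returns its RunResults keyed by sub-run.

    ``overrides`` are SimulationConfig fields applied on top of the
    scenario's defaults.  Every run directory written is reproducible
    from its embedded ``config.yaml`` (which includes the seed).
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    os.makedirs(outdir, exist_ok=True)
    results = SCENARIOS[name](outdir, seed=seed, full_scale=full_scale,
                              overrides=overrides)
    with open(os.path.join(outdir, "scenario_summary.json"), "w") as fh:
        json.dump({k: v.outcome for k, v in results.items()}, fh, indent=2)
    return results
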