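"""Why streamlining does not evolve in sexually reproducing populations.

Three population types are evolved from identical founders: sexual
(mid-genome cross-over, no DNA uptake), asexual with HGT (the
bacteria-like baseline), and strictly clonal (no uptake, no sex).
Recombination lets TEs enter new lineages without the lethal-insertion
gamble, so streamlining gives no protection and genomes grow large and
TE-loaded until the population collapses; clonal populations starve TEs
of new hosts entirely.  Each population is reported at its final extant
state (15 000-step runs, ~1 minute in total).
"""

from tecoevo import SimulationConfig, run_single

for label, repro in (("sexual", "sexual"), ("asexual+HGT", "asexual_hgt"),
                     ("clonal", "clonal")):
    cfg = SimulationConfig(
        width=75, height=75, steps=15_000, seed=1,
        initial_noncoding=30, inoculation="block", reproduction=repro,
        write_png=False, snapshot_every=10**9, sample_every=100,
    )
    res = run_single(cfg)
    ts = res.timeseries
    end = ts[ts.n_cells > 0].iloc[-1]
    print(f"{label:12} (t={int(end.t):6d}): genome length {end.mean_length:6.1f}  "
          f"TEs/cell {end.mean_te:6.2f}  fitness {end.mean_fitness:.3f}  "
          f"cells {int(end.n_cells)}")

print("\nThe sexual population ends with the largest, most TE-loaded genomes")
print("and the lowest fitness (and finally collapses under the load); the")
print("asexual+HGT population streamlines and thrives; the clonal population")
print("has purged its TEs completely.")
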