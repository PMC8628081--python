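"""The replication mutation scan and the large-scale events.

Shows forced single-element events, a large-scale inversion, and checks
by simulation that large-scale segments cover on average a quarter of
the genome.
"""

import numpy as np

from tecoevo import (Genome, MutationRates, apply_large_scale,
                     apply_single_duplication, draw_segment_length,
                     mutate_genome)

rng = np.random.default_rng(42)
g = Genome.from_text("a,b,c,d,e")
print("genome:            ", g.to_text())
print("duplicate pos 1:   ", apply_single_duplication(g, 1).to_text())
print("invert [1,4):      ", apply_large_scale(g, 1, "inversion", rng, length=3).to_text())
print("delete  [1,4):     ", apply_large_scale(g, 1, "deletion", rng, length=3).to_text())

# the scan applies each point event at 0.1% per position per replication
founder = Genome.initial(10, 30)
daughter = mutate_genome(founder, MutationRates(), rng)
print(f"\nfounder length {len(founder)} -> daughter length {len(daughter)} "
      "(one replication pass, default rates: usually identical)")

draws = [draw_segment_length(40, rng) for _ in range(10_000)]
print(f"mean large-scale segment on a 40-element genome: "
      f"{np.mean(draws)/40:.1%} of the genome (calibrated to 25%)")
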