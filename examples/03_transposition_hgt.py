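"""TE replication within genomes and horizontal transfer via eDNA.

A TE-carrying genome replicates its TEs at rate phi*j; a dead neighbour's
fragments can reinfect a naive cell after uptake.  Prints the measured
per-step replication rate and one uptake-infection event.
"""

import numpy as np

from tecoevo import (EdnaParams, Genome, MutationRates, insert_te,
                     lifetime_transposition, lyse, uptake_and_integrate)
from tecoevo.genome import transposon
from tecoevo.transposition import TranspositionParams

rng = np.random.default_rng(7)
no_phi_mut = MutationRates(phi_mut=0.0)

carrier = Genome.from_elements(
    list(Genome.initial(10, 10)) + [transposon(0.9)]
)
params = TranspositionParams(j=0.01, b=0.0)  # b=0: count copies cleanly
gains = sum(
    lifetime_transposition(carrier, params, no_phi_mut, rng).te_count > 1
    for _ in range(100_000)
)
print(f"per-step replication rate of one phi=0.9 TE at j=0.01: "
      f"{gains/100_000:.4f} (expected phi*j = 0.009)")

# insertion damage: a TE landing on the sole copy of a gene is lethal
victim = Genome.initial(10, 0)
damaged, report = insert_te(victim, 0.9, 2, b=1.0, rng=rng)
print(f"insertion into gene 'c': damaged={report.damaged}, "
      f"essential hit={report.essential_inactivated} -> genome {damaged.to_text()}")

# horizontal transfer: lyse the carrier, feed its fragments to a naive cell
fragments = lyse(damaged, site=(0, 0), rng=rng)
naive = Genome.initial(10, 30)
infected, consumed = uptake_and_integrate(
    naive, fragments, EdnaParams(u=1.0), b=1.0, rates=no_phi_mut, rng=rng)
print(f"lysis gave {len(fragments)} fragments; naive cell consumed "
      f"{len(consumed)} and now carries {infected.te_count} TE(s)")
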