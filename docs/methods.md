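# Methods

`tecoevo` is an individual-based, spatially explicit model of the
coevolution of transposable elements (TEs) and the architecture of the
host genomes that carry them.  This note describes the model and its
assumptions, the parameters that matter, the numerical choices made in
the implementation, and what the shipped scaled-down scenarios do and do
not demonstrate.

## The model

**Genomes and fitness.**  A genome is a linear, ordered sequence of
elements of three kinds: essential genes (one of `n_functions = 10`
types, `a`–`j`), TEs (each carrying a heritable transposition propensity
`phi` in [0, 1]) and non-coding elements.  A cell is viable iff every
essential function is encoded at least once; fitness is

    f = 0                  if any essential function is missing,
    f = max(0, 1 - c*T)    otherwise,

with `T` the TE count and `c = 0.005` the per-TE cost.  Non-coding DNA
and redundant gene copies are deliberately free: there is no cost on
genome size, so any streamlining that evolves is attributable to TE
dynamics rather than replication economics.  The linear TE penalty is
clamped at zero in this implementation because
fitness is used as a competition weight and must be non-negative (the
clamp only matters beyond `T = 1/c = 200`, where the cell is
reproductively dead either way).

**Space and competition.**  Cells live at most one per site on a
toroidal `W x H` grid.  Each timestep, every empty site is contested by
its up-to-eight Moore neighbours; neighbour `i` wins with probability
`f_i / (f_TOTAL + epsilon)`.  The regulariser `epsilon` leaves the site
empty with the complementary probability, so a lone unfit cell does not
colonise by default.  Competition is synchronous: all empty sites are
filled from the same post-death occupancy snapshot, so a daughter never
reproduces in the step of its own birth.

`epsilon` is the one constant of the model's reference parameterisation
that is left unstated, and it matters enormously: it sets the recolonisation timescale
of vacant space.  The package's default is `epsilon = 50`, calibrated
once on the model's own design conditions — TE–host coexistence
requires local extinctions whose vacated space healthy lineages can
re-invade, i.e. a regime with persistent empty "niche space" visible
on the grid.  With small `epsilon` (tested 1–20 at grids up to 100 x 100),
eight fit neighbours refill an empty site almost immediately, burned-out
patches are recolonised long before their eDNA pool (mean fragment
lifetime `1/q = 50` steps) has decayed, every recoloniser is promptly
reinfected, the epidemic sweeps the grid and the population either
collapses or freezes in a fully infected state — no wave structure, no
refugia, no streamlining.  With `epsilon` of about 50–100, refilling an
empty site takes ~5–15 steps, vacated patches outlive their infectious
fragments, and the model's characteristic phenomenology (travelling
infection waves, majority-uninfected populations, de novo
streamlining) emerges robustly at desk scale.  50 was chosen from inside that band: it keeps
populations larger and, unlike 100, leaves the evolved mean
transposition rate at or above its inoculated value.  At the full
150 x 150 scale a smaller `epsilon` may well suffice, because system
size itself can keep infection waves and recolonisation fronts apart;
`epsilon` is an ordinary config field for anyone exploring that
trade-off.

**Death, lysis and the eDNA pool.**  Each step, non-viable cells die
deterministically and viable cells die with probability `d = 0.02`.
Dead cells lyse: the genome is cut left-to-right into fragments of
iid-uniform length 3–8 (a terminal remainder shorter than 3 is kept, so
fragments partition the genome exactly), deposited at the cell's site.
Fragments independently degrade with probability `q = 0.02` per step
(mean lifetime 50 steps) and otherwise hop to a random Moore neighbour
with probability `D = 0.01`.

**Transposition and horizontal transfer.**  Within a living cell, each
TE present at the start of the step replicates copy-and-paste with
probability `phi * j` (`j = 0.01`); the copy inserts at a uniformly
random genome position.  Copies made in a step do not replicate again in
that step.  Living cells take up each co-located fragment with
probability `u = 0.01`; of a consumed fragment's content only TEs can
cross into the genome — each integrates with probability equal to its
own `phi`, at a uniform position.  There is no homologous recombination:
essential-gene and non-coding fragment content is inert and lost.
Insertion damage is controlled by `b` (default 1): with probability `b`
a coding element (essential gene or TE) at the insertion site is
inactivated, i.e. converted to a non-coding position that stays in the
genome; non-coding targets are never damaged; with `b = 0` TEs insert
cleanly between elements.  Losing the last active copy of an essential
gene is lethal at the next death phase.

**Mutation at replication.**  A daughter genome is produced by scanning
the parental genome left to right; each position is offered, in fixed
order, a large-scale event, a single duplication, a single deletion and
an inactivation (each at 0.001 per position), and at most one fires.
Copies created during the pass are not re-scanned.  A large-scale event
duplicates (in tandem), deletes or inverts — each kind equally likely —
a contiguous segment starting at the scanned position, truncated at the
genome end.  The segment length is uniform on `[1, max(1, G//2 - 1)]`,
calibrated so the mean segment covers exactly a quarter of the genome
(for even `G`), matching the model's stated 25% average exactly
(`scripts/acceptance.py` recomputes this).  Every TE replication — both
transposition and host-genome replication — offers the copy a
`phi`-mutation: with probability 0.01 the propensity steps by ±0.1
(equal odds), clamped to [0, 1].  The per-replication offer during the
scan is implemented as a single post-scan pass over the daughter's TEs,
which is distributionally equivalent.

**Reproduction modes.**  `asexual_hgt` (the bacteria-like baseline)
copies the winner's genome through the mutation scan and keeps DNA
uptake on.  `sexual` first lets a parent win the empty site under the
epsilon rule, then draws a mate purely fitness-proportionally from the
remaining living neighbours — epsilon regulates colonisation of space,
not mate choice; applying the epsilon slack to the mate draw as well
would, at the calibrated epsilon, silently turn the vast majority of
sexual births into clonal copies.  The child is the left half of
parent 1 (split at `floor(len/2)`) concatenated with the right half of
parent 2, then mutated as usual; uptake is disabled.  A winner with no
living mate is copied clonally.  `clonal` is asexual reproduction with
uptake disabled (no HGT, no sex).  Well-mixed controls destroy spatial
structure by scattering all cells (`mixed_cells`) or only the fragments
(`mixed_edna`) to random sites every step.

**Update schedule.**  The per-step ordering is not uniquely determined
by the model definition; this implementation fixes it as: (1) death and lysis, (2) eDNA degradation/diffusion, (3)
synchronous competition/reproduction, (4) uptake and integration, (5)
lifetime transposition, (6) cache/viability refresh (continuous), (7)
well-mixed shuffling.  Viability lost to transposition in step 5 is
collected at the next step's death phase — a cell rendered non-viable
after the reproductive phase dies in the next time step — and lysis
products are available to the following generation.

**Lineages.**  A lineage (for the extinction-time statistics) begins at
an infection event: the first time a cell on a never-infected line of
descent acquires a TE it founds a lineage, all descendants share it —
including branches that later lose their TEs — and the record closes
when the last member dies.  Recorded per lineage: infection and
extinction times, generations survived (deepest chain of reproduction
events since infection; timestep lifetime is also kept), and the
cumulative TE copies released to the eDNA pool by lysis of members.

## Implementation notes

The per-operation API (`genome`, `mutation`, `transposition`, `edna`
modules) is plain NumPy and takes an explicit `numpy.random.Generator`.
Whole-world stepping is a numba-compiled engine over flat arrays
(`_engine`), seeded once per world; a run is fully deterministic given
its seed, and identical seeds yield byte-identical CSV outputs.  The
two layers implement the same semantics; the test suite pins them
together on forced-rate (0/1) settings where the scan is deterministic.
Use one active world at a time: the engine RNG state is global, so
stepping two worlds interleaved breaks per-world reproducibility
(sequential runs are fine — each world seeds the stream at
construction).

Numerical bounds: genomes are capped at 1024 elements and the fragment
pool at 512 per site on average; growth events beyond a cap are
skipped and fragments beyond capacity dropped.  The caps matter: an
earlier 512-element cap was reachable by heavily infected genomes, and
a capped genome stops accumulating TEs *and* stops suffering insertion
damage, freezing populations in an artificial equilibrium just below
the fitness-zero TE load.  With the present caps, the relevant regimes
(TE loads up to ~200, genome lengths up to ~500) sit well inside the
bounds; states pinned at the cap should not be interpreted.

Uptake and pool turnover are sampled by geometric skips (one RNG draw
per event rather than per fragment), which is exactly equivalent to
the per-fragment Bernoulli draws and keeps large-pool steps cheap.

## Scenario scale and what the scaled runs show

At full scale the model's experiments run on a 150 x 150 torus for
50 000–80 000 steps; the package reproduces their qualitative
contrasts at desk
scale, chosen so each scenario completes in seconds to a couple of
minutes on one CPU: 75 x 75 with 5000 steps for fixed-genome ecology
and 15 000 steps for the evolutionary runs (the expansion →
streamlining → steady-state arc completes by then at this scale).
TE inoculation is local (a 5 x 5
central block) in all scenarios — seeding infection uniformly at random
leaves no uninfected refugia and the wave structure cannot form.

At 75 x 75, `epsilon = 50` and `phi = 0.9`, the measured ecological
phase structure is: compositions up to ~10 essential + 15 non-coding
purge their TEs; around 10+30, TEs and hosts coexist through the full
run (the shipped "intermediate" composition); by 10+240 the hosts are
driven extinct; and scattering cells to random positions every step
(well-mixed control) collapses the 10+30 coexistence to host
extinction.  Two desk-scale outcomes are more extreme than their
full-scale counterparts and are read accordingly by the tests.  First,
with insertion damage disabled (`b = 0`) nothing checks TE
amplification, mean fitness decays with the growing TE load and the
population collapses — at full scale this manifests as absence of
streamlining rather than extinction; either way the streamlining
decline does not occur.  Second, sexually reproducing populations
accumulate TEs without bound (recombination bypasses the
lethal-insertion defence) and, because colonisation requires absolute
fitness to compete against `epsilon`, the population eventually
collapses (~8000–10 000 steps at this scale).  The reproduction-mode
comparison therefore reads each population at its final extant
time-series sample: the sexual population's terminal state is the
bloated, TE-loaded, low-fitness composition that causes its collapse
(genome length ~300–400 vs ~18 in the streamlined asexual population),
and the strictly clonal population has lost every TE.

The scaled scenarios demonstrate the model's qualitative mechanisms —
phase structure, the necessity of spatial structure and of insertion
damage, the sexual/asexual contrast, lineage-level selection — not
full-scale quantitative trajectories; means, peak sizes and timescales
at desk scale differ from the full 150 x 150 scale.  A caveat on the
lineage statistics: extinct-lineage records are dominated in every era
by single-cell dead-end infections, whose TE output is just the dose
of the infecting fragment, so medians sit close to that floor (the
strong contrast lives in the upper tail — during the expansion era the
90th percentile of per-lineage TE output is several-fold the
post-streamlining one).  The shipped epoch comparison draws its early
lineages from the expansion era (the ~2000 steps up to the non-coding
peak) and its late ones from the final quartile of the run; with these
epochs both the median extinction time and the median TE output fall
after streamlining.

## Known limitations

* The update-schedule ordering and the epsilon value are this package's
  own choices where the model definition is silent; both are
  configurable or documented above.
* The transposition snapshot is of TE propensities, not positions: a TE
  inactivated by another TE's insertion within the same step retains
  its already-granted replication opportunity.  At `j = 0.01` this is a
  sub-percent effect.
* `generations_survived` counts the deepest descent chain; other
  countings of "generations since infection" are possible (timestep
  lifetimes are logged alongside).
* Checkpoint resume reseeds the engine RNG from (seed, t); a resumed
  run is reproducible but does not continue the original run's exact
  random stream.
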