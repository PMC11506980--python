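# Methods

## The model

`evochase` simulates Darwinian evolution of predator agents whose entire
behaviour is a fixed-length block of Intel i8080 machine code — the genome.
The setting is the simplest possible predator–prey arena:

* a toroidal grid (default 256×256; coordinates are bytes, so wrap-around
  matches the 8-bit arithmetic of the agent brains);
* exactly one prey at a time; a caught prey respawns on a uniformly random
  cell distinct from the agent;
* the prey jumps randomly each step, each axis an independent uniform
  integer in [−l, l] (default l = 3), or, alternatively, moves along a
  circle in a fixed angular direction;
* the agent jumps by the vector its program wrote to the actuator cells,
  clipped per axis to [−L, L] (default L = 5);
* a catch occurs when the toroidal Chebyshev distance between agent and
  prey is at most `catch_radius` (default 1).

Astronomical time `t` is counted in agent jumps, grouped into epochs of
`T` jumps (default 1000).  Developmental time per epoch is proxied by the
number of catches, which is proportional to the energy the agent acquires
and dissipates; the normalised ensemble catch rate `K(t)` (catches per
epoch divided by the run maximum) is therefore the rate at which
developmental time advances per unit of astronomical time.

## The agent CPU

Each agent owns a 64 KiB address space holding, in disjoint regions, its
genome (Ψ bytes, default 100, mapped read-only at 0x0100), four read-only
sensor bytes (agent x/y and prey x/y at 0x0004–0x0007), two writable
actuator bytes (dx, dy at 0x0000–0x0001, read back as two's-complement),
and 2 KiB of scratch RAM (0x0800–0x0FFF) whose top hosts the stack.

Every world step the agent runs one *thought slice*: registers and flags
are cleared, PC returns to the genome base, SP to the scratch top, and up
to `4·Ψ` instructions execute (the factor 4 admits loops while bounding
every slice).  A slice also ends at `HLT` or when PC leaves the genome
region.  Scratch RAM and the actuator cells persist across slices within a
lifetime and are cleared only at birth: this carried state is the agent's
only memory of the past, and is what makes behaviours such as
discriminating clockwise from counter-clockwise prey representable even
though the sensors expose only current coordinates.

Emulator totality is a hard requirement — any random byte string must run:
undocumented opcodes, `IN`/`OUT`, `EI`/`DI` and `RST` execute with no
architectural effect (PC advances by the documented instruction length),
and writes from executing code to the sensor cells or the genome region
are silently dropped.  The latter sandboxes the agent (no self-modification,
no sensory self-deception); self-modifying genomes are an interesting
variant deliberately left out.

The memory-map defaults place the actuators at the very bottom of page
zero.  Because register pairs start each slice at zero, single-byte motifs
(`DCR A; STAX B` and relatives) already produce movement; this gives blind
evolution a findable first foothold, which matters because fitness
gradients below the level of "moves at all" do not exist in this model.

## Evolution

A population of `population_size` agents (default 100), each with an
initially uniform-random genome, hunts independently — one private world
per agent, no interference.  After each epoch agents are ranked by catches
(ties broken by the selection stream):

* bottom third: destroyed;
* top third (elite): survive and reproduce;
* middle third: survive childless.

The vacated slots are filled by mutated copies of elites, with offspring
counts drawn from a multinomial with probabilities proportional to elite
catches (uniform if no elite caught anything).  Mutation resamples each
byte independently with probability δ (default 0.05) from the uniform byte
distribution; genome length never changes.  Survivors keep their scratch
RAM and actuator state; offspring start blank.  The thirds split and the
catch-proportional offspring rule are this package's concrete choice for
the ranking scheme, which the source material describes only qualitatively;
both fractions are configurable.

Reproducibility is bit-exact: hunting streams are derived per
(master seed, epoch, agent) and selection streams per (master seed, epoch)
with a splitmix64-based derivation, so a replicate never depends on
execution order and a checkpointed run resumes identically.  The hunt loop
itself uses a deterministic splitmix64 generator implemented identically in
the compiled kernel and the pure-Python reference pipeline (a test asserts
bit-identical trajectories between the two).

## Analysis

`normalize_series` maps raw per-epoch ensemble totals to K = raw / max(raw)
(error if nothing was ever caught; K is idempotent and scale-invariant).

`detect_jumps` locates jump-like transitions by binary segmentation on a
centred moving-median smoothing of K (window 101 epochs): each interval is
split at the point minimising the piecewise-constant SSE, and a split is
accepted only when both segments hold at least `min_seg = 200` epochs and
their means differ by at least θ = 0.1.  Defaults were chosen on the
synthetic fixtures and are configurable; on the noiseless ideal step the
detector is exact, and on the noisy two-step benchmark (σ = 0.02) it
recovers both jumps with zero location error in 100/100 seeded series.
Jump magnitude is reported as post-segment mean minus pre-segment mean.

`fit_model` fits four growth laws to K(t) windows: logarithmic
a·ln t + b, linear m·t + q (both closed-form least squares; the log model
is ordinary regression on ln t), power (c·t)^d (seeded by a log-log
regression when all K > 0, polished by nonlinear least squares), and
hyperbolic a·t/(t + b) (multi-start nonlinear least squares over a grid of
half-saturation starts).  R² is always computed on the original K scale;
standard errors come from the OLS formulas or the NLS covariance.  Constant
windows are rejected (R² undefined), and non-convergence after all starts
raises with diagnostics.

`compare_models` ranks all four by R² and attaches the qualitative screens
used to argue for the logarithmic law: a catch *rate* is meaningless at
t = 0, so models with a definite value there (power, linear, hyperbolic)
carry a `defined_at_zero` flag, and models that saturate carry
`horizontal_asymptote` (hyperbolic) — growth in this system keeps rising
without bound, as the near-flat pre-jump segments with reliably positive
slope show.  Per-model squared-residual traces are returned because R²
alone rarely separates the candidates.

`jump_histograms` pools jump events from replicate runs into
relative-frequency histograms (heights sum to one) of location and
magnitude.

## Synthetic data

`synth.make_synthetic_series` builds K(t) from contiguous constant, linear
or logarithmic segments plus optional i.i.d. Gaussian noise.  The presets
mirror the shapes real runs produce — a long near-flat stretch (slope
~2.6·10⁻⁶ per epoch) ending in one or two jump-like increases followed by
logarithmic growth.  What the generator deliberately does not emulate:
binomial counting noise (real K noise scales with the catch total),
serial correlation across epochs, and selection-driven drift within
segments.  Tests passing on these fixtures therefore validate the
analysis machinery, not the biology of real trajectories.

## Problem sizes used in the tests

The test suite and the acceptance script run the evolutionary study at a
scaled size chosen to keep a full pipeline run on one CPU in minutes: 30
agents on a 64×64 field, T = 200 steps, 1500 epochs, δ = 0.05, Ψ = 100.
At this scale selection reliably lifts the late-epoch catch rate above the
initial-population baseline (8/10 seeded replicates), and the
hand-assembled chaser genome out-catches random genomes by roughly two
orders of magnitude.

The scale matters for what can be observed.  On a small field a sizeable
share of catches comes from prey wandering into an agent, so the dynamic
range of K is compressed; and the de-novo discovery of genuine pursuit
code — a multi-byte read-sensors/compute-difference/store motif with no
intermediate fitness gradient above "moves at all" — is a rare event at
any scale (see limitations).  The ensemble tests therefore separate the
two halves of the jump phenomenology that are reproducible in minutes:

* *spread*: injecting a single skilled ancestor into a random population
  and letting catch-proportional selection amplify it produces exactly one
  jump-like step in K per run, magnitude ≈ 0.2–0.45, early in the run —
  the positive-feedback avalanche that makes favourable mutations visible
  as discrete jumps in ensemble statistics;
* *retention*: a clonal skilled population under the default mutation load
  (δ·Ψ = 5 expected byte changes per offspring) keeps its catch rate —
  selection is strongly purifying, so an acquired skill persists.

The full-scale experiment (100 agents, 256×256, T = 1000, 10⁴ epochs —
hours of compute) is a single `evochase evolve` invocation with the
default configuration.

## Known limitations

* The i8080 core is instruction-accurate, not cycle-accurate; interrupts
  and peripherals are out of scope.
* Uniform-modulo random draws carry a bias of order n/2⁶⁴ — negligible
  here but formally present.
* The strategy classifier is a heuristic over approach segments; it labels
  clean trajectories and returns `none` on ambiguous ones rather than
  guessing.
* Selection fractions, slice budget, memory-map addresses and the boundary
  topology are modelling choices (all configurable); different choices can
  shift the speed of evolution considerably.
* Spontaneous discovery of pursuit behaviour is the model's hard step.
  Blind movement is reachable by one- or two-byte mutations and is mildly
  favoured, but the shortest sensor-coupled pursuit program is ~11 bytes
  per axis with no smooth fitness path leading to it, so runs dominated by
  the discovery phase show only modest gains in K rather than the large
  jump transitions that follow a discovery.  The spread and retention
  studies above characterise what selection does once such code exists;
  how a particular memory-map design changes the discovery rate is an open
  experimental question this package is built to explore.
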