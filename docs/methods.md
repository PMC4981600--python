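# Methods

`erbbsim` is a particle-based stochastic reaction–diffusion simulator of
ErbB2 and ErbB3 receptors on a two-dimensional membrane patch.  Its
purpose is to ask how two properties of membrane micro-organisation —
the overlap between the confinement domains of the two receptor species,
and the strength of retention in those domains — shape dimerization and
phosphorylation.

## Model

**Geometry.**  The membrane patch is a square periodic box of area
0.1995 µm² (side ≈ 0.4466 µm) containing 5 ErbB2-specific and 9
ErbB3-specific confinement domains with total areas 0.0502 µm² and
0.0274 µm².  Domains of the same species are disjoint; cross-species
overlap is the controlled variable.  Published domain maps are irregular
shapes derived from single-particle tracking that are not available as
coordinates, so the generator emulates them with axis-aligned rectangles.
Rectangles keep reflective-boundary geometry exact, and the quantities the
conclusions rest on — areas and overlap fraction, not shape — are
honoured: per-species totals are met within 1% and the achieved
ErbB3-into-ErbB2 overlap fraction is exact for targets 0 and 1 and within
0.02 otherwise (intermediate overlaps are built by straddling each ErbB3
rectangle across the edge of a host ErbB2 rectangle with exactly the
target fraction of its area inside).  Landscape geometry is a
deterministic function of the generator seed.

**Receptors.**  31 ErbB2 and 31 ErbB3 receptors (159/µm² of each species,
the density of 50,000 receptors on a 314.16 µm² cell) are placed uniformly
over their own species' domains plus the free area, never inside only the
other species' domains.  A configurable fraction of ErbB3 carries ligand;
occupancy is fixed for a run (no ligand on/off kinetics).  ErbB2 is
constitutively dimerization-competent ("open").  Liganded ErbB3 is open;
unliganded ErbB3 is open in any timestep with probability 1e-4 — a flat
per-step probability, deliberately not a rate conversion, so the open
*fraction* (1e-4) is independent of the timestep.  ErbB2 carries one
representative phosphorylation site, ErbB3 two (PY1197, PY1289).

**Diffusion and boundaries.**  Each mobile unit (monomer or dimer) takes
independent Gaussian axis displacements with variance 2·D·dt per step,
with D from the published single-particle-tracking values (and reduced
dimer coefficients once any member site is phosphorylated).  The outer box
is periodic: the distance past an edge is continued from the opposite
edge.  Domain edges are one-way barriers: entry is free; each outbound
edge crossing is gated by a per-encounter escape probability (Table-2
values, optionally scaled by 1/2 or 1/4), and a failed draw mirror-reflects
the remaining displacement back inside.  Multiple crossings within one
step are resolved sequentially along the path.  A particle is confined
only by domains of its own species; heterodimers are confined by domains
of either species.  In equilibrium this gating enriches a species inside
its domains by a factor ≈ 1/p_escape, independent of dt (entry and exit
encounter frequencies scale identically with step size); only the
exchange timescale depends on dt.

**Dimerization.**  At the end of each step, any pair of open monomers
closer than the binding radius r_b forms a dimer; conflicts are resolved
closest-pair-first (ties by lower particle id), each monomer joining at
most one dimer per step.  r_b is calibrated per pair kind so that this
capture rule reproduces the mass-action association rate at the pair's
mutual diffusion coefficient (the sum of the two units' coefficients) and
the timestep in use.  The tabulated on-rate is a 3D quantity
(9e-5 µm³/s); a two-dimensional simulation needs an areal rate, so the
value is divided by the thickness of the membrane-proximal reaction layer
(default 10 nm), giving k_on_2d = 9e-3 µm²/s.  This conversion is the
choice that makes the model's published kinetics come out: at 9e-3 µm²/s
the initial heterodimer formation rate is ≈ 43/s, so dimers are present
by the first 0.05 s observation and phosphorylation events become visible
within ~0.5 s, and roughly a third of receptors are dimerized at steady
state (ErbB2 monomers visibly depleted); reading the printed number as an
areal rate directly (9e-5 µm²/s) yields steady-state dimer counts of
order one, with dimerization undetectable at 0.05 s and all
domain-organisation effects buried in replicate noise.  The calibration
solves the steady-state radial pair-distribution function under
step-kernel convolution with absorption inside r_b and root-finds r_b; a
brute-force well-mixed simulation verifies the round trip within 5%.  At
the rates and timesteps used here r_b stays well below the rms step
(capture is close to activation-limited, r_b ≈ sqrt(k·dt/π)), which also
makes steady-state dimer counts insensitive to dt once r_b is
recalibrated.  A dimer occupies a single point (the pair midpoint at
formation); on formation one member is drawn as "activator" and the other
as "receiver" with equal probability, fixed for the dimer's lifetime.
ErbB2 homo-interactions are doubly disfavoured, reflecting the
electrostatic repulsion of the ErbB2 dimerization arm: dissociation is
10× faster than for the other pairings (tabulated) and the association
step carries a low success probability
(``erbb2_homodimer_on_multiplier``, default 0.1).  Without the
association penalty, ErbB2/ErbB2 dimers accumulate precisely under the
strong-retention conditions the study varies and pin ErbB2
phosphorylation at a level insensitive to heterodimer loss, contrary to
the behaviour the model is built to express; 0.1 keeps homodimerization
possible but rare (≈100× disfavoured at equilibrium).

**Dissociation.**  Each dimer dissociates per step with probability
1 − exp(−k_off·dt), with k_off depending on composition and ligand count.
The released monomers are placed diametrically opposite at the unbinding
radius 5·r_b (2.5·r_b each side, uniform random direction) to suppress
immediate rebinding.  Phosphorylation states persist; roles are cleared;
a released unliganded ErbB3 starts closed.

**Phosphorylation.**  Only the activator member of a dimer is
phosphorylated, by the receiver's kinase: each unphosphorylated activator
site gains phosphate per step with probability 1 − exp(−k·dt), where k is
the full phosphorylation rate if the receiver is kinase-competent (ErbB2
always; ErbB3 only while it carries at least one phosphate) and the basal
rate otherwise.  Every phosphorylated site, in dimers or monomers, loses
phosphate with its site-specific dephosphorylation probability.  A
dephosphorylated ErbB3 immediately loses receiver competence.

**Sub-step order.**  Conformation update → diffusion with boundary
resolution (domain edges, then the periodic wrap) → dissociation →
dimerization → phosphorylation/dephosphorylation → observation.  The
order is not dictated by the underlying description; it is fixed and
documented here, and the timestep is small enough that ordering effects
are below sampling noise (checked by the dt-robustness test).  Dissociated
monomers are placed without re-gating the tiny 2.5·r_b offset against
domain edges (the offset is ~100× smaller than a domain side).

## Observables

Observations are recorded every 0.05 s: monomer counts per species,
ErbB2/3, ErbB3/3 and ErbB2/2 dimer counts, phosphorylated-receptor counts
(ErbB2 with its site phosphorylated; ErbB3 with ≥ 1 phosphorylated site —
a per-site ErbB3 tally is also emitted so a site-level reading is
recoverable), per-species in-domain counts, and the number of open ErbB3
monomers.  Species conservation (monomers + dimer members = 31) is
asserted on every row.  Steady-state values are time-averages over a
terminal window, summarised as mean ± sample (n−1) SD across replicate
runs; replicate r of a condition uses seed base_seed + r.

## Parameters

All defaults reproduce the published parameterisation: diffusion
coefficients (ErbB2 0.0272, ErbB3 0.013 µm²/s; dimers 0.015/0.0185 µm²/s,
reduced to 0.0046/0.0028 µm²/s when phosphorylated; ErbB2/2 0.015),
on-rate 9e-5 µm³/s for all pairings (2D: 9e-3 µm²/s through the 10-nm
reaction depth), dissociation rates 0.436/0.408 (1/s,
ErbB2/3 by ligand count), 0.436/0.234/0.13 (ErbB3/3), 4.36 (ErbB2/2),
phosphorylation rates 0.146/0.078 (1/s), basal rates 0.073/7e-5,
dephosphorylation 0.2 (ErbB2), 0.013/0.06 (ErbB3 PY1197/PY1289), escape
probabilities 0.5128 (ErbB2 monomer and ErbB2/2 dimer), 0.2401 (ErbB3
monomer and ErbB3/3 dimer), 0.3764 (ErbB2/3 dimer), timestep 1e-6 s.
Scaled escape rows are exact multiples (×1/2, ×1/4) of the nominal row;
the printed scaled table is rounded to four decimals.

## Study protocols and problem sizes

The reference protocol is dt = 1e-6 s and 240 s of simulated time with 4
replicate runs — about 10^10 particle-steps per condition, which is a
long-running computation.  The package therefore defines a scaled protocol
used by the test suite, the presets and the acceptance script: dt = 1e-5 s
with recalibrated binding radii, 60–120 s of simulated time, 4 replicates,
and steady-state windows covering the final 30–60 s.  Dimer turnover
(1/k_off ≈ 2.5 s) and spatial redistribution (seconds) equilibrate well
within this horizon; ErbB3 phosphorylation is the slowest observable
(dephosphorylation timescales up to ~77 s), so its absolute steady-state
level retains a small downward bias at this duration — percent-change
comparisons between conditions, which share the bias, are much less
affected.  Escape probabilities are per-encounter quantities; at a 10×
coarser timestep boundary encounters are ~√10 less frequent, so absolute
exchange kinetics are slower than at the reference timestep while the
equilibrium in-domain enrichment (≈ 1/p) is unchanged.

## What the generator does and does not emulate

The fixture landscapes reproduce the domain counts, areas and overlap
fraction of the mapped membrane, with a "CHO-like" preset at 42.4%
overlap.  They do not reproduce the irregular domain shapes, domain-size
correlations, or any remodelling of domains over time (domains are
static).  The printed per-species areas, free area and overlap of the
original map are mutually inconsistent at face value (0.0502 + 0.0274 +
0.1219 equals the full box area, leaving no room for double-counted
overlap); the generator enforces the per-species totals and derives the
free area from the geometry, so fixture free area is smaller than the
printed value whenever overlap is nonzero.  Conclusions drawn from
passing tests therefore concern the rectangle-domain idealisation, not
the exact mapped geometry.

## Numerical choices

Random numbers come from an explicit xorshift128+ stream (seeded via
splitmix64) with a 128-layer ziggurat normal sampler, so runs are exactly
reproducible from the seed and independent of global library state.
Boundary crossings use half-open rectangle membership (closed low edges)
with an epsilon nudge (1e-12 µm, five orders below r_b) across or inside
an edge after each gating event to keep membership unambiguous; the event
loop is bounded at 64 crossings per step.  The pair search bins open
monomers by x (bins wider than r_b) and scans same/adjacent bins.  The
radial-distribution solver for r_b uses a grid refined to r_b/12 near the
absorbing boundary, kernel-resolved (≤ σ/4) further out, truncated at
r_b + 12σ; Brent root-finding stops at a relative xtol of 1e-6.
Degenerate inputs (k_on = 0, D = 0, zero-length steps) short-circuit to
exact results.

## Known limitations

No ligand binding/unbinding kinetics, receptor internalisation or
synthesis, directed motion, or downstream adaptor recruitment; domains are
static rectangles; dimers are point particles; the ErbB2/ErbB3 system is
closed (no other ErbB species).  Steady-state counts at physiological
density are small (order 1–10), so percent-change comparisons between
conditions carry replicate noise of a few percentage points even with the
full protocol.
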