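# Model and methods

## The model

`betalattice` implements a coarse-grained protein model on the simple cubic
lattice in which each residue *i* carries four degrees of freedom: a lattice
position **r**<sub>i</sub>, an amino-acid type a<sub>i</sub> (one of the 20
standard types), a unit side-chain direction **d**<sub>i</sub>, and a
secondary-structure state s<sub>i</sub> ∈ {coil, strand}.  Consecutive
residues occupy face-adjacent sites, chains are self-avoiding and mutually
excluding, and the side chain may point to any of the six neighbours except
along the backbone bond(s) at that residue — four admissible directions for
an internal residue, five for a terminal one.  Side chains occupy no volume.
Vacant sites are implicit solvent.

Two residues are *in contact* when they sit on face-adjacent sites and are
not sequential neighbours of the same chain.  Boxes are periodic in all
three axes by default (constant-volume, fixed-concentration multi-chain
simulations need no walls); positions are stored reduced into the box and
displacements use the minimum-image convention, which requires a box edge of
at least 3.

### Potential

The energy decomposes into independent terms

    E = E_hb + E_aa + E_state + E_sol + E_steric

| term | rule | default scale |
|------|------|---------------|
| E_hb | ε_hb per pair in contact, both strand, identical **d**, contact vector ⊥ **d** | ε_hb = −50 |
| E_aa | M(a_i, a_j) per contact whose side chains face each other, or are parallel (same **d**) and ⊥ the contact | matrix entries ≈ −65…+8 |
| E_state | ε_state per strand residue | ε_state = 0 |
| E_sol | M(SOL, a_i) per residue whose side chain points at a vacant site | ≈ −10…+10 |
| E_steric | ε_steric per chain bond whose two side chains are parallel | ε_steric = +55 |

Units are reduced throughout with k_B = 1.  The strand state costs no
explicit energy; it pays entropy (strand residues are conformationally
frozen, see below) and earns the hydrogen-bond reward.

The perpendicularity requirement on hydrogen bonds (the lateral in-register
beta geometry) is a deliberate sharpening of the bare
contact+strand+same-direction rule: it prevents a bond "through" a side
chain and caps the hydrogen-bond valence of an internal strand residue at
two — its straight backbone occupies two of the four perpendicular contact
sites — reproducing beta-sheet valence.  It is switchable
(`EnergyParams.hb_strict_perpendicular`).

### The bundled interaction matrix

Published knowledge-based contact matrices (with an explicit solvent row)
are treated as input data: any 21×21 whitespace table (20 codes + `SOL`,
exactly symmetric, M(SOL,SOL)=0) can be loaded.  The package ships a documented stand-in built
from the Kyte–Doolittle hydropathy scale q ∈ [0,1]:

    M(a,b)   = −60 q_a q_b + R_ab,    R symmetric, frozen, |R| ≤ 6
    M(SOL,a) = 10 (2 q_a − 1)

The product term reproduces the dominant hydrophobicity structure of
statistical contact potentials; the small frozen roughness term R breaks the
degeneracy of a purely multiplicative potential so designed sequences have a
well-defined ground state.  All entries are quantised to multiples of 1/4:
every energy in the model is then a dyadic rational, partial sums are exact
in double precision, and the incremental bookkeeping of the samplers matches
full recomputation *bit for bit* (a tested invariant).

With this matrix the strongest side-chain attraction (I–I ≈ −65) is
comparable to the hydrogen bond (−50), making side-chain interactions the
dominant folding force, with hydrogen bonding decisive only when geometry
and sequence cooperate — the regime the model is meant to probe.  The
temperature scale follows the energy scale: the folding transition of
designed 18-mers sits near T ≈ 18 and seeded fibrils of hydrophobic
peptides dissolve above T ≈ 25.  (With contact energies O(10), temperatures
are numerically ~100× those of parameterisations whose entries are O(0.1).)

## Monte Carlo

Each canonical iteration attempts one **local move** — state flip,
side-chain redraw, or internal backbone move (end move, corner flip,
crankshaft), chosen uniformly at 1/3 each — and, with probability
`p_global` (default 0.2), one **rigid-body move** (whole-chain unit
translation or quarter rotation about a chain site).  Acceptance is the
Metropolis rule min(1, e^(−ΔE/k_BT)); an invalid proposal counts as a
rejected trial.

Strand residues are frozen: no backbone move may relocate them or change
their side chain, and no move may bend the backbone at an internal strand
residue or leave any residue's side chain along a backbone bond.  A coil
residue may enter the strand state only where the backbone runs straight
(terminal residues, having one bond, are defined non-collinear and can
never enter it) and only if strand sequential neighbours carry the opposite
side-chain direction.  Strand→coil is always proposable.

Every proposal distribution is exactly symmetric, so detailed balance holds
with the plain Metropolis factor.  Two choices matter for this and are easy
to get wrong:

* relocated residues *always* redraw their side chain uniformly from the
  admissible set — the set size (4 internal / 5 terminal) is independent of
  the conformation, so forward and reverse proposals match.  A
  keep-if-admissible policy is *not* symmetric (the reverse of a forced
  redraw can be a zero-probability keep) and is not used.
* crankshafts co-rotate positions *and* side chains rigidly about the
  anchor axis; admissibility is automatically preserved.

Correctness of the whole stack (energy, moves, acceptance) is tested by
exhaustive enumeration: on a 3-residue chain in a 4³ periodic box (~10⁵
microstates) the sampled means of energy, strand occupancy and end-to-end
contact match the exact Boltzmann averages within statistical error at two
temperatures.

### Parallel tempering

Replicas at an ascending temperature ladder advance independently; every
`swap_interval` iterations each adjacent rung pair attempts a temperature
swap, accepted with min(1, e^((1/T₁−1/T₂)(E₁−E₂)/k_B)).  Swaps exchange
temperatures, never configurations; samples are binned by the temperature a
replica holds when recorded, and per-rung ensemble averages are reported
(no cross-rung reweighting).  The default ladder spans 5–40 in 10 rungs,
bracketing both the fibril and folding regimes of the bundled matrix.

### Grand-canonical peptide exchange

For fibril growth the sampler adds whole-peptide insertions/deletions of a
single species.  Insertions propose a straight all-coil rod: uniform
position, uniform axis (6), uniform admissible side-chain directions.
Deletions pick one peptide of the species uniformly and are valid only if
it currently *is* such a rod.  Because the proposal measures coincide and
the direction-set sizes are conformation-independent, the pair satisfies
detailed balance with

    P_ins = min(1, aV/(N+1) · e^(−ΔE/k_BT)),   P_del = min(1, N/(aV) · e^(−ΔE/k_BT))

where `a` is the activity, V the box volume and N the current species
count.  In the non-interacting dilute limit the count is Poisson with mean
aV — the closed-form check used in the tests.  Strand-containing (bound)
peptides are automatically protected from deletion until they melt into
rods, which is the physically sensible behaviour for seeded growth.

## Sequence design

Design holds a target backbone rigid and Monte Carlo-samples (a) point
mutations to a uniform random type, (b) composition-neutral type swaps
between two positions, and (c) side-chain redraws (strand residues keep the
antiparallel-neighbour rule).  Moves pass a Metropolis stage on the full
potential at a design temperature (default 6, optional geometric
annealing); mutations additionally pass an independent composition stage
with probability min(1, e^(−k_bias·ΔD)), where

    D = Σ_a (f_a(seq) − f_a(ref))²

over the 20 types and f(ref) defaults to the residue frequencies of natural
proteins (Swiss-Prot composition statistics, bundled).  Reference fractions
are quantised to multiples of 1/2048 by largest-remainder apportionment, so
D is a ratio of integers and the O(1) update after a substitution equals
full recomputation exactly.  k_bias = 2000 keeps designed 12–36-mers within
D ≲ 0.02 of the natural distribution while the energy term buries
hydrophobic side chains and exposes polar ones.  The best-energy state seen
is returned (ties resolve to the most recent state).

Target structures come from `fixtures.compact_cuboid_structure`: a
boustrophedon space-filling walk on an nx×ny×nz block.  With
`strand_runs=True` the straight interior of each x-row is declared strand
with x-parity side chains, so the target itself carries a small in-register
sheet and backbone hydrogen bonds, as folded beta proteins do.

## Experiment recipes and problem sizes

The package's standard experiments (also exposed as CLI subcommands) are
run at sizes chosen so the full suite completes on a single CPU core in
minutes while preserving the phenomenology:

* **Folding specificity** — design an 18-mer for the 3×3×2 cuboid, then a
  parallel-tempering *melting* scan (8 rungs, 6–31; 2.5×10⁵ iterations per
  replica) starting from the native state, against a composition-matched
  shuffled control started from the same backbone.  The designed sequence
  holds a cold plateau at ~100% native contacts and melts in a sharp
  transition where the heat capacity peaks and the hydrogen bonds vanish;
  the shuffle shows no plateau and no coincident sharp peak.  Melting
  rather than refolding is measured because equilibrating a designed
  18-mer from the extended state requires orders of magnitude more
  sweeps than a desk-scale run; a melting scan probes the same equilibrium
  curves from an initial condition that low-temperature replicas can
  actually equilibrate.  The protocol's conclusions were checked to be
  stable across independent design/sampling/shuffle seeds.
* **Fibril stability** — 10-peptide in-register seeds of TFTFTFT and
  TTTTTTT in a 20³ box, independent canonical runs at T = 8…36.  Both stay
  intact cold and dissolve hot; near T ≈ 22 (the folding-relevant regime)
  only TFTFTFT, whose phenylalanines form a hydrophobic core, remains
  assembled.
* **Spontaneous formation** — 10 dispersed TFTFTFT peptides, 14³ box,
  1.5×10⁵ iterations: intermolecular hydrogen bonds appear at T = 8 and
  not at T = 40.
* **Seeded growth** — grand-canonical runs (activity ≈ 2/V) grow a
  4-peptide seed, measured as a rising intermolecular hydrogen-bond count.

## Numerical choices and degenerate inputs

* Exactness: with the bundled (dyadic) matrix, running energy deltas equal
  full recomputation bit-exactly over arbitrary trajectories; with a
  user-supplied non-dyadic matrix agreement is to float rounding only.
* Trajectory ensemble averages discard a burn-in fraction (default 50%,
  logged in the summary).
* Statistical test tolerances use batch-means standard errors (10–20
  batches) at 3σ.
* `validate()` checks structural invariants (bonds, exclusion, side-chain
  admissibility, occupancy-index consistency) but deliberately not
  state-machine reachability: hand-built states such as ideal fibril seeds
  legitimately place terminal residues in the strand state, which dynamics
  can leave but never re-enter.
* Empty systems (grand-canonical starts) skip canonical moves; insertion
  into a full box is a rejected proposal, not an error.
* Boxes must be ≥ 3 per periodic axis; single-residue chains have 6
  admissible side-chain directions and no internal moves.

## What the generators do and do not emulate

The synthetic fixtures (compact cuboids, ideal in-register seeds, dispersed
rods) are geometric idealisations: real seeds formed in long unbiased runs
may differ in register and contain defects, and designed cuboid natives are
maximally compact in a way real folds are not.  Passing tests therefore
demonstrate the model's internal thermodynamic consistency and its
qualitative sequence-dependent phenomenology — not quantitative agreement
with any experimental system.  Helical structure is outside the model by
construction (no lattice geometry supports it), so sequences with helical
propensity are not meaningfully represented.

## Known limitations

* Pure-Python sampling covers desk-scale systems (≤ ~100 residues,
  ~10⁶ iterations/minute); production-scale studies of the original kind
  (36-mer refolding, 30³ boxes over CPU-hours) need longer runs than the
  bundled recipes perform.
* The stand-in matrix preserves the hydrophobicity structure of
  knowledge-based potentials but not their pair-specific detail; supply the
  published matrix file to reproduce its exact behaviour (temperatures then
  rescale with the entry magnitudes).
* No cluster moves; dynamics near fully frozen aggregates are slow, which
  is physical for templated growth but makes very low temperatures
  expensive to equilibrate.
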