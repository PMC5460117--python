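# Methods

## Network model

Nodes are protein residues, each represented by the mass-weighted center
of mass (COM) of its side chain. The side chain of a residue is every
atom except the backbone names `N, CA, C, O, OXT` and the backbone
hydrogens `H, H1, H2, H3, HA, HA2, HA3`; this name-blacklist definition
is the universal structural-biology convention and is checkable against
any standard PDB naming. Hydrogens present in the input are included in
the COM (their mass weight makes the effect small); united-atom inputs
simply lack them, so both conventions work without special cases.
Glycine has no side chain and is excluded from the node set by default
(`excluded_resnames={"GLY"}`); non-standard residues are kept as nodes
whenever they have non-backbone atoms, and every exclusion is logged with
its reason. Residue identity is the (chain, resid, insertion-code)
triple, 1-based as in the PDB, never renumbered.

Masses default to standard element masses (C 12.011, N 14.007, O 15.999,
S 32.06, H 1.008, P 30.974, Se 78.971); a plain-text table
(`RESNAME ATOM MASS` or `ELEMENT MASS` lines) can override them per atom
when force-field-specific masses matter. The network-level observables
are insensitive to this choice at realistic mass differences.

For a frame *f* and nodes *i, j*, a contact is `d_ij(f) ≤ r_c`
(inclusive), plain Euclidean distance with no periodic-boundary
minimum-image handling — inputs are assumed whole-molecule. The edge
weight is the *persistence*: the fraction of frames in contact, stored
as a percentage. An edge is kept iff its persistence is `≥ p_crit`
(inclusive, default 20%). Both comparisons being inclusive is a
deliberate numerical choice: "at least 20% of frames" reads as stated,
and ties are kept. Anyone comparing bit-exactly against other PSN
software should check that software's convention at the boundary.
Sequence-adjacent pairs are *not* excluded by default; an optional
`min_seq_separation` drops same-chain pairs closer than a given sequence
distance for users who want an i,i+k exclusion.

## Hubs and components

Degree counts incident edges, ignoring weights. A hub is a node with
degree ≥ 3 (the fixed-threshold convention; a mode selecting nodes above
the network's mean degree is available but not the default). Connected
components include singletons, so the partition covers all nodes;
components are ranked by size, ties broken by the smallest member's
(chain, resid) so cluster IDs are reproducible across runs — which is
what makes rank-matched jackknife errors well defined. Reports list the
non-singleton count separately and the top-5 component sizes by default.

## Jackknife resampling

The trajectory's F frames are tiled into n contiguous blocks of
`B = floor(F/n)` frames (default n = 10); subset *i* removes block *i*
and keeps the remaining `F − B` frames in order (90% retention when
n | F). Remainder frames (`F mod n`, at the tail) belong to no block and
are retained in every subset — the simplest deterministic treatment,
preserving equal subset sizes. Observables with error bars are the hub
count at each degree (from the hub threshold up to the largest degree
observed in the full ensemble or any subset) and the size of the k-th
largest component (k = 1..5); component observables are matched across
subsets by rank, the only deterministic matching that needs no member
tracking. An observable absent in a subset contributes θ̂(i) = 0. The
standard error is the jackknife formula
`SE = {(n−1)/n · Σ(θ̂(i) − θ̂(.))²}^½`; it is computed exactly, with an
explicit zero when all θ̂(i) are equal. Set-valued residue-level
comparisons (which residues are hubs / share a cluster in each subset)
are available as per-subset tables, not SEs — a set has no standard
error under this formula. No autocorrelation or statistical-inefficiency
correction is applied; blocks are treated as exchangeable.

## Cutoff scan

The scan runs persistence → graph → hubs/components on the full ensemble
and on every jackknife subset at each cutoff of the grid (default 4.0,
4.5, 5.0, 5.5, 6.0 Å — a 0.5 Å step across the range where side-chain
COM networks go from fragmented to percolated). COM positions are
per-frame quantities, so they are computed once and frame-sliced for the
subsets. The analysis path contains no randomness; reports are
byte-identical across reruns. Per-cutoff failures abort with the cutoff
identified rather than silently skipping grid points.

## Synthetic ensembles

Two generators make every stage testable with exactly known answers; all
randomness in the package lives here, behind explicit seeds.

**Schedule-driven ensembles.** A contact schedule assigns each selected
node pair the exact set of frames in which it sits at distance `d_in`
(default 4 Å); in all other frames, and for all unscheduled pairs, the
distance is at least `d_out` (default 12 Å). Residues are single-atom
pseudo side chains (one CB carbon), so the COM is the atom itself and
downstream persistence equals the programmed fraction k/N with zero
floating error for any cutoff between `d_in` and `d_out`; keeping both
distances ≥ 1 Å away from scanned cutoffs also makes the values immune
to the PDB format's 3-decimal coordinate rounding. Schedules are
restricted to families with a guaranteed 3D embedding — node-disjoint
pairs (each pair in its own grid cell, cells 3·d_out apart), chains
(collinear, gaps d_in/d_out; realizable only when 2·d_in ≥ d_out), and
stars (leaves on tetrahedral/octahedral/Fibonacci directions) — and the
generated coordinates are verified against the schedule; an unrealizable
request raises an error instead of silently bending geometry.

**Compact chain.** The protein-like article for cutoff scans. A
self-avoiding random walk with step 3.8 Å (the Cα virtual bond length)
is confined to a sphere sized from a bead density of 0.0065 residues/Å³
— protein interior packing, a mean nearest-neighbor spacing near 5 Å.
Each residue emits one side-chain pseudo-atom displaced 1–3 Å from its
trace bead in a per-residue direction, with the emitted atoms keeping a
4.6 Å excluded-volume separation (side-chain COMs, unlike Cα traces,
rarely approach below ~4.5 Å); frames add isotropic Gaussian jitter of
sd 0.5 Å per atom. These three numbers (density, separation, jitter)
were calibrated together so the ensemble reproduces the qualitative
behavior of real side-chain COM networks across 4–6 Å: essentially no
hubs and a fragmented partition at 4.0 Å, a single dominant component at
6.0 Å, hub degrees within the steric 3–10 range near 5 Å. A bare 3.8 Å
walk cannot show this — consecutive beads would lie inside every cutoff
and the chain path alone would keep the graph connected — which is
precisely why the side-chain displacement is part of the model.

What the generators do *not* emulate: real side-chain rotamer dynamics,
correlated motions, secondary-structure geometry, residue-size
heterogeneity (all pseudo-residues are single atoms), and solvent
effects. Passing tests therefore demonstrate correctness of the
*pipeline* (exact persistence accounting, graph properties, resampling
algebra, monotone cutoff behavior) and the qualitative percolation
signature — not quantitative agreement with any particular protein's
hub/component distributions, which depend on microsecond-scale sampling
of real structures.

## Numerical choices and degenerate inputs

- Contact tests compare squared distances against the squared cutoff;
  fixtures keep ≥ 1 Å margins so round-off at the boundary is
  irrelevant, and a rigid rotation+translation of all frames changes no
  persistence entry beyond 1e-9.
- Persistence is an integer frame count divided once by the frame
  count — exact rational arithmetic up to a single IEEE division.
- Single-frame ensembles are legal; persistence is then a 0/1 indicator.
- Single-atom side chains bypass the mass-weighted sum (exact identity).
- An empty node set after selection is a fatal error, not an empty
  result; zero-frame inputs and frame/atom-count mismatches across
  models are rejected at load time.
- Jackknife requires at least 2 subsets and at least as many frames as
  subsets.

## Default problem sizes

The test suite and the reproduction script use 50-residue, 100-frame
compact chains and small schedule ensembles — sizes at which every
property being asserted (exactness, nesting of edge sets, percolation
within the 4–6 Å grid) is already fully expressed, and the complete
pipeline runs in seconds. The implementation is vectorized per frame and
handles proteins of ordinary size (hundreds of residues, thousands of
frames) without structural changes.

## Known limitations

- Only the side-chain COM contact definition is implemented; H-bond,
  hydrophobic, energy- and correlation-based networks are out of scope.
- No trajectory preprocessing: periodic-boundary artifacts must be
  removed upstream.
- Rank-matching of components across jackknife subsets can compare
  different member sets when two clusters swap size order; membership-
  overlap matching is not implemented.
- The persistence filter's inclusive boundary may differ from other PSN
  implementations at exactly p_crit.
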