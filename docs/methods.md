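# Methods

## Scope and data model

All computation is alpha-carbon based. A chain is an ordered list of
residues carrying a one-letter code, author numbering (plus insertion
code, preserved for reporting) and a Cα position; internal indices are
0-based and contiguous. On loading a PDB chain, only ATOM records are
read, the first-listed alternate location is kept, HETATM residues are
excluded, and residues without a Cα are skipped (counted and warned).
This is sufficient because every quantity in the pipeline — pairing
distances, elastic-network matrices, boundary distances — consumes Cα
positions only.

DSSP output is collapsed to three states: H/G/I → H, E/B → E, everything
else (turns, bends, blanks) → C. Manual overrides are (residue range,
label) pairs applied in order, later overrides winning; the shipped
reference protocol uses one such override (a three-residue helical
element inside the first grafted loop treated as coil, matching the
supersecondary definition used for that system).

## Superposition

The pairing step consumes coordinates in a common frame. Externally
superposed files (e.g. from CE, the aligner used for the reference
system) are accepted as-is with an identity transform, so an external
superposition can be injected bit-exactly. When no common frame is
given, an iterative least-squares procedure alternates a Kabsch fit on
the current pair set with greedy re-pairing until the pair set repeats
exactly (a discrete, deterministic criterion), capped at 20 iterations;
oscillation returns the best-RMSD iterate with a warning. The Kabsch
step itself is delegated to scipy's `Rotation.align_vectors` with a
proper-rotation guarantee.

## Geometric sequence pairing

Given the n_A × n_B matrix *D* of Cα–Cα distances:

1. **Greedy matching.** Repeatedly take the globally smallest unused
   entry with value ≤ *T* (default 1.9 Å); ties break by (smaller row,
   smaller column). The implementation ranks the candidate entries once
   and sweeps them in order — equivalent to repeated full-matrix scans
   but O(K log K); the equivalence is asserted against the naive scan
   oracle in the tests.
2. **Monotonicity repair.** The greedy matching need not respect
   sequence order. A maximum-cardinality subset with both index
   sequences strictly increasing is kept (weighted
   longest-increasing-subsequence, O(n²) dynamic program); among
   equal-cardinality optima the subset with smallest total distance is
   chosen, so the repair removes as few pairs as possible.
3. **Offset filter.** With signed offsets o = i − j over the surviving
   pairs, the mean and population SD are computed once; pairs with
   |o − μ| > 4σ (multiplier configurable) are removed. A zero-SD
   distribution removes nothing. Whether the original procedure centred
   offsets on the mean or on zero, and whether it filtered before or
   after the order repair, is not documented; mean-centred filtering
   after the repair is this package's choice, applied uniformly.

The pairing doubles as a gapped pairwise alignment: paired residues
share a column, and unpaired stretches between consecutive pairs are
written as mutually gapped blocks, first-chain block first.

## Elastic network models

GNM uses the Kirchhoff (graph Laplacian) matrix with a 10 Å contact
cutoff; ANM uses the standard 3N Hessian of super-elements
−γ·ddᵀ/|d|² with a 15 Å cutoff. Those cutoffs are the published
defaults of the implementation family this follows; both are exposed in
config. The spring constant and kT are set to 1: every downstream use
is min–max normalized, so only relative flexibility matters. B factors
use the Debye–Waller constant 8π²/3; the constant likewise cancels
under normalization.

Modes come from a dense symmetric eigendecomposition. Eigenvalues below
1e-8 × (largest eigenvalue) are discarded as rigid-body modes — exactly
1 expected for a connected GNM graph, 6 for a non-degenerate ANM
geometry; deviations warn (disconnected graph, collinear points). The
default mode count is N−1 for both models (for ANM that means the N−1
lowest non-zero modes out of 3N−6). Mean-square fluctuations are the
per-residue mode sums Σ u²/λ (summing the three coordinates per residue
for ANM); with the full spectrum they equal the pseudoinverse diagonal,
which serves as the independent oracle (agreement within 1e-8 in the
tests, with the oracle's rank cutoff set explicitly so the rigid-body
mode is not inverted). Cross-correlations are the covariance normalized
by its diagonal; region-level values are plain arithmetic means over
the residue block, including self-pairs when regions overlap.

## Loops and grafting

Maximal runs of identical labels form segments; every
(regular, coil, regular) triple is a loop, numbered in sequence order,
with consecutive loops sharing a flank. Chain-terminal coils are not
loops — they lack the two recombination flanks.

Boundary candidates are explored per flank from the residue most distal
to the coil inward. An aligned position yields a candidate directly; a
gapped position (on either chain) resolves to the gap-flanking residue
of the other chain at the smaller Euclidean distance, ties toward the
anterior residue, flagged `from_gap`. Candidates whose partner falls
outside the partner flank are dropped; a flank with no candidates makes
the loop ungraftable (warning).

Boundary semantics: the boundary residue pair itself stays scaffold;
the replaced material is the open interval between the N- and C-boundary
scaffold residues, substituted by the matching open interval of the
insert. This keeps the geometrically anchored recombination points on
the scaffold side of the seam; an inclusive mode (boundary residues
taken from the insert) is available behind a flag. Designs are the N×C
cross product of candidates, accepted only if the chimera differs, as
an exact string, from the scaffold and all previously accepted designs;
enumeration order is deterministic, so design lists are reproducible.
Multi-loop sets are combined as cross products with the novelty filter
re-applied; overlapping windows across loops are an error.

For modelling input, one excised-scaffold PDB is written per design
(all replaced spans omitted; author numbering preserved so chain breaks
are implied), one insert fragment per window, and a PIR alignment whose
columns follow the chimera: each chimera position aligns to its
provenance reference, so the scaffold row restricted to scaffold
provenance reproduces the retained scaffold residues.

## Scoring and selection

Score tables are TSV with a `design_id` column and `dope` and/or
`fastrelax` columns, both "lower is more stable", carried verbatim in
their own units (AU, REU) with no cross-metric combination. Ranking is
ascending with deterministic id tie-break. Sequential grafting picks
the metric-best single-loop design and enumerates the second loop on
that fixed background, returning the set for external scoring.
Flexibility comparison between a chimera and its template subtracts
min–max-normalized profiles at paired positions; unpaired positions are
reported missing (NaN).

## Synthetic data generator

The generator emulates the study conditions: a scaffold and a
homologous insert differing by isotropic Cα noise and one divergent
(replaced) loop of different length and letters, with the ground-truth
correspondence known by construction. Helices use textbook Cα
parameters (radius 2.3 Å, rise 1.5 Å/residue, 100°/residue); coils are
self-avoiding random walks with a fixed 3.8 Å step and a 3 Å exclusion
over a 5-residue window. The default blueprint
(H10–C6–H12–C6–H10, 44 residues) gives two loops sharing a flank; the
default noise is σ = 0.3 Å, the level at which pairing recovery is
required to stay ≥ 95%. All randomness flows through a single seeded
generator, so every fixture is reproducible.

What the toys do not model: side chains, realistic packing densities,
beta sheets, crystallographic disorder, or genuinely homologous (rather
than perturbed-copy) geometry. Passing tests therefore demonstrate
algorithmic correctness under controlled conditions, not performance on
real superpositions, where the choice of superposition engine
measurably shifts the pairing and hence the design counts.

## Problem sizes

Tests and the acceptance script use 44-residue toys for ENM oracles
(20 seeds), up to 100×100 random matrices for the greedy-pairing oracle
(1,000 in the test suite), a 250-residue synthetic mimic of the
reference protocol (loops pinned at author ranges 135–166, with the
151–153 coil override, and 210–244), and 20 seeds for noise-recovery
statistics. The full-scale run on the published crystal structures
requires user-supplied coordinate and DSSP files
(`data/reference_structures/README.md`); its design enumeration is
sensitive to the superposition used — the published counts were derived
from a CE superposition.

## Known limitations

- No backbone closure or rebuilding of the chimera: partial structures
  and alignments are emitted for an external comparative-modelling
  step.
- The offset filter and gap tie-breaks implement one defensible reading
  of an under-specified procedure (see above).
- Loop numbering reproduces published loop indices only under the same
  secondary-structure definitions; the override mechanism exists for
  exactly that reason.
- DSSP is consumed, never computed: structures without DSSP output need
  user-provided labels.
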