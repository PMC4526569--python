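# Methods

This note documents the models, conventions and numerical choices behind
`hullprot`, in the order the pipeline applies them, and states what the
synthetic test bed does and does not demonstrate.

## Structure model

PDB files are parsed with gemmi and reduced to a minimal atom/residue
hierarchy.  Hydrogens and deuterium are always dropped: DPX is defined on
heavy atoms, and for consistency every other descriptor uses the same atom
set.  Waters are always removed; other HETATM groups only on request.  For
alternate locations the highest-occupancy conformer is kept, ties breaking
toward the first occurrence in the file.  Van der Waals radii come from a
fixed element table (C 1.70, N 1.55, O 1.52, S/P 1.80 Å; anything else
1.70 Å), chosen to match the NACCESS defaults so RSA values remain comparable
with that program's output.  Modified residues with a clear parent (MSE, SEP,
PTR, …) map to the parent type; anything else becomes 'X', is carried through
the geometry, and is excluded from composition statistics and RSA
normalisation (no reference area exists for it).

Epitope labels are an input, not something the package derives: benchmark
datasets define epitopes from antibody contacts under cut-offs that vary
between studies, so the label file (`chain resnum[icode] label`) is the
interface and unlisted residues default to non-epitope.

## Solvent accessibility

Per-atom ASA uses Shrake–Rupley-style sampling with a deterministic
golden-section spiral lattice instead of random points: the same inputs give
bit-identical output on any platform.  Defaults: probe 1.4 Å (water),
960 points per atom.  At 960 points the isolated-sphere error is below 0.5%
and doubling the density changes fixture totals by under 1%.  A point on the
expanded sphere (radius r_vdw + probe) is accessible iff it lies outside
every other atom's expanded sphere; ASA is the sphere area times the
accessible fraction.

RSA is a **percentage**: 100 × residue ASA / reference ASA of that residue
type in an extended Gly-X-Gly tripeptide (Hubbard & Thornton values, the
NACCESS reference).  Exposure uses the literal RSA > 0 rule rather than the
common 5% cut-off — a few genuine epitope residues have RSA barely above
zero, and a 5% threshold would discard them.  A reader for NACCESS `.rsa`
files lets users substitute that program's numbers column-for-column.

## Depth functions

**Chakravarty-style depth.**  The classical definition measures distance to
the nearest surface water of an explicitly solvated model.  Here the retained
accessible sample points of the ASA step serve as the solvent-surface proxy:
atom depth is the distance to the nearest such point, residue depth the mean
over the residue's atoms.  This approximation can shift absolute depths by a
fraction of an Å (the proxy surface sits at r_vdw + probe from atom centres,
water oxygens sit where the solvation shell puts them), which is why a reader
for `depth-1.0` output is provided for exact parity.  Relative ordering —
the quantity the layer analysis uses — is unaffected on all fixtures.

**DPX.**  An atom is solvent-accessible iff its sampled ASA > 0 (the original
program's contact criterion is not published; ASA > 0 is the natural reading
and is documented here as the adopted convention).  DPX is 0 for accessible
atoms and the distance to the nearest accessible atom centre otherwise;
residue DPX is the mean over atoms.

**Half-sphere exposure.**  Neighbours are all other residues' Cα atoms within
13 Å (Cα-to-Cα in both modes), across chains.  The up half-sphere is oriented
by the side-chain direction: mode A uses the pseudo-Cβ vector
(Cα_i − Cα_{i−1}) + (Cα_i − Cα_{i+1}), mode B the actual Cα→Cβ vector,
falling back to the mode-A vector for Gly or a missing Cβ.  Terminal residues
use their single available chain neighbour; an isolated residue has no
orientation and counts everything as "down" with a warning.  Neighbours
exactly on the dividing plane (zero dot product) count as "down" — the
original definition leaves this open, so the tie side is fixed and tested.

**Half-space (Tukey) depth.**  Computed exactly on the empirical Cα point
set.  The minimal closed half-space can be rotated until its boundary plane
passes through the query point and two others, so all pair cross-product
normals (plus single difference vectors for collinear cases) are enumerated.
The subtle part is the boundary: points lying exactly on a candidate plane
can usually be tilted out of the half-space by an infinitesimal rotation
about a line through the query point, so they must *not* simply be counted on
both sides.  For the generating pair of a non-degenerate plane the tilt
always exists; when more points are coplanar the minimal number that must
stay inside is itself a 2-D half-plane problem, solved exactly by an angular
sweep over the on-plane points (breakpoints at their angles ± 90°).  Points
coincident with the query point can never be excluded, giving the 1/N floor
and making every hull vertex score exactly 1/N.  The residue's own point is
included in the count (the half-space contains it by definition).  Numerical
tolerance for "on the plane" is 1e-9 relative to the coordinate scale.
Cost is O(N³) per residue; for large inputs a flagged approximate mode
minimises over a 2000-direction quasi-uniform grid instead, which upper-bounds
the exact value.

## Convex-hull peeling

X is the set of *all* atoms of *all* exposed residues, pooled across the
selected chains (multi-chain complexes peel as one body).  Each iteration
computes the 3-D hull of the remaining points (scipy/Qhull) and removes every
point on the hull surface — vertices and points lying on facets within a
1e-9 relative tolerance — as the current layer; coplanar patches would
otherwise stall the peel.  Degenerate remainders (≤ 4 points, coplanar or
collinear sets, Qhull failures) are assigned wholesale to the current layer,
which guarantees termination and the partition invariant Σ|CHₖ| = |X|.
Duplicate coordinates collapse to one point for the hull and share its level.
Hulls are computed on atom centres without vdW inflation.  A residue's level
is the minimum of its atoms' levels; K₀ is the maximum level over epitope
residues (equivalently, the smallest k whose cumulate hull contains them
all).

## Layer statistics and comparisons

Per protein and layer k: CREPIₖ = epitopes at level k / all epitopes,
CREXPₖ = exposed residues at level k / all exposed residues, PROPₖ =
epitopes at level k / residues at level k; cumulate versions use level ≤ k.
Cross-protein curves are **unweighted means over proteins** — pooling
residues would let a 600-residue antigen dominate a 90-residue one.  Layers
beyond a protein's own depth contribute 0 to its per-layer values; cumulate
values stay at their exhausted-hull value (1 for the coverage ratios), so
curves over k = 1..k_max are well-defined for every cohort.  Proteins with
zero epitopes are excluded from CREPI/PROP averages (undefined ratios).

Group comparisons use the Wilcoxon rank-sum (Mann–Whitney U) test via scipy:
exact enumeration for untied samples up to n = 50 per group, normal
approximation with tie correction beyond; two identical constant samples
return p = 1 with a warning.  p-values are reported raw, with no
multiple-testing correction.  Depth–RSA association is summarised as the
unweighted mean ± SD of within-protein Pearson correlations; proteins with
fewer than 3 paired residues or zero variance are skipped and counted.

For residue-table verification (XLSX/CSV), pooled-residue means and SDs are
reported per class, since that is how a flat per-residue table aggregates;
per-protein averaging is used only where a protein grouping exists.

## Conservation and secondary structure

Conservation is 1 − H(p)/log₂20 with p the WOP row divided by 100, 0·log 0
:= 0, and **no renormalisation** — renormalising rows that do not sum to 100
would change scores, so the values are used as printed.  An all-zero row (no
alignment information) scores 1 by convention.  Scores are guaranteed in
[0, 1] for rows summing to at most 100, which is the domain PSI-BLAST emits.
DSSP files are parsed (never executed, via Biopython's DSSP-file reader) and
the 8-state codes group as H/G/I → helix, E/B → strand, everything else
(T, S, blank, unknown) → coil.

## Synthetic test bed

The fixtures module generates everything the tests and the acceptance script
consume; geometry is RNG-free (spiral lattices), randomness is confined to
labels and globule packing under a seed.

* **Shell clouds** — concentric quasi-uniform spherical shells whose true
  peel level is the shell index; shell separations must exceed the lattice
  spacing or the generator refuses, keeping the ground truth provable.
  Per-shell epitope fractions emulate surface-enriched labelling.
* **Globules** — rejection-packed points in a ball at ~3.8 Å minimum
  separation, modelled as residue-sized spheres (3 Å) so the core is
  genuinely solvent-excluded; outer-half residues draw epitope labels at
  25%, inner at 3%, giving cohorts whose epitopes prefer outer hull layers
  the way real conformational epitopes do.  The coarse one-sphere-per-residue
  model keeps surface depth nearly constant for accessible residues, so
  continuous depth–RSA correlations are demonstrated on layered shell
  structures instead, where a real depth gradient exists.
* **Mini-PDBs, WOP matrices, DSSP records** — schematic but format-valid
  text for parser and pipeline tests.

None of these reproduce protein chemistry: no bonded backbone for the
globules, no rotamers, no physical solvation.  Passing tests therefore
demonstrate the correctness of the geometry and statistics algorithms and the
direction of the epitope-location signal under surface-biased labelling — not
biological performance on real antigen–antibody complexes, which requires
real structures and labels supplied by the user.

## Command-line design

The CLI is a thin layer over the library: `features` (one structure →
per-residue table + JSON summary), `cohort` (tables → cross-protein curves,
K₀ histogram, comparisons, optional train/test split with the benchmark's
seven held-out chains as a preset), `fixtures` (synthetic inputs) and
`verify-s1` (summary statistics from a flat residue table).  All options are
plain flags rather than a config file — every run records its full parameter
set in a `provenance` block of the JSON it writes, so a run is reproducible
from its own output and a separate config layer would duplicate that record.
Re-running with identical inputs produces byte-identical output files.

## Problem sizes

Default analysis settings (960 SASA points, exact HSD) process a 150-residue
input in about a second.  The acceptance script uses a cohort of 8 synthetic
antigens of 130 residues, 50 random 20–40-point clouds for the depth oracle,
and 4-shell clouds of 1200 points — sizes chosen so the whole recomputation
finishes in well under a minute while exercising every code path; all of its
statistics are stable across seeds at these sizes.

## Known limitations

* Chakravarty depth is a surface-sample approximation (see above); absolute
  values differ slightly from the solvated-water original.
* Exact HSD is O(N³) per residue — fine for single chains (N ≲ 600), use the
  approximate mode for whole complexes.
* The sampled SASA counts interior cavity surfaces as accessible, like other
  Shrake–Rupley implementations; no solvent-exclusion cavity detection is
  attempted.
* mmCIF input is not supported; convert to PDB first.
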