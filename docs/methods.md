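# Methods

## Structural model and residue identity

Coordinates are read with gemmi (PDB and mmCIF); only the first model of a
multi-model file is used, waters are dropped, and alternate locations
resolve to the highest-occupancy conformer (ties broken by first label in
file order). Hydrogens are ignored by default because cryo-EM depositions
rarely contain them; they can be kept, in which case they carry a 1.20 Å
radius. Every residue is identified throughout the package by
`(chain_id, auth_number, insertion_code)` in author numbering, so intervals
quoted in the structural literature (domain boundaries, gap positions) map
onto model residues without renumbering. Common modified residues (MSE,
SEP, PTR, …) are mapped to their parent standard type; residues that cannot
be mapped are kept in the model but excluded from composition and
hydropathy statistics, with a warning.

Coverage accounting treats a *gap* as any maximal run of author numbers in
a declared region absent from the chain, terminal runs included. Residues
differing only by insertion code contribute one author number, which keeps
the invariant `n_solved + Σ gap lengths = region length` exact; the
coverage fraction divides by the computed region span (end − start + 1),
even when an external source quotes a different count for the same
interval.

## Solvent accessibility

SASA uses the Shrake–Rupley construction. Each atom's solvent-extended
sphere (van der Waals radius + probe radius) carries a deterministic
Fibonacci golden-angle lattice of test points; a point is accessible when
it lies inside no other atom's extended sphere, and the atom's area is the
accessible fraction times the extended-sphere area. Neighbour lookup uses a
k-d tree with search radius `r_i + max_j r_j`. Defaults: probe 1.4 Å
(water), 960 points per atom. The lattice is deterministic, so repeated
runs are bit-identical without a seed; at 960 points the isolated-sphere
case is exact to well under 1% and two-sphere configurations agree with the
spherical-cap closed form to a few parts in 10⁴ (both asserted in the
tests, along with a Monte-Carlo oracle on random configurations and a
cross-check against an independent implementation).

Radii: C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, Se 1.90, H 1.20 Å; unknown
elements are a configuration error unless an override radius is supplied.

When a complex is analyzed, all chains occlude but only the target chain is
reported (`occluder_scope="complex"`), because the surface of interest is
the one the deposited complex actually exposes — a bound partner buries its
interface. `chain_only` exists for sensitivity analysis. Adding an occluder
chain can only decrease any residue's SASA (asserted as a property test).

RSA divides residue SASA by the type's maximal accessible area. The default
normalization is the Rost & Sander (1994) table, the convention under which
the RSA ≥ 20% surface definition is customary; the Tien et al. (2013)
theoretical table is selectable by config. RSA values above 1 occur for
extended termini and are kept (logged, not clamped). The surface is
`{r : RSA(r) ≥ threshold}` with the threshold included on ties, default
0.20. The reported surface area is the sum of member SASA; the pipeline
report also carries the total chain SASA, since the two are easy to
conflate when only one number is quoted.

## Hydropathy smoothing

Each surface residue takes the Kyte–Doolittle index of its type (−4.5 Arg
… +4.5 Ile). The smoothed value is the unweighted arithmetic mean of the
raw values of all *surface* residues whose Cα lies within the smoothing
radius (6 Å default) of the residue's own Cα, itself included. Cα-based
membership was chosen over all-atom membership for determinism and for
consistency with the patch definition, which is also Cα-based; no distance
kernel is applied because the quantity is a plain neighborhood average.
Consequences asserted as properties: as the radius → 0 the smoothed field
equals the raw field; as it → ∞ it becomes the constant surface mean; the
smoothed range is always contained in the raw range. The summary reports
both raw and smoothed extremes, since for an isolated residue they
coincide and a quoted extreme may be either.

## Composition

Counts and fractions are computed over any residue-key set. The default
polarity partition is the textbook one — charged {Asp, Glu, Lys, Arg, His},
polar-uncharged {Ser, Thr, Asn, Gln, Tyr, Cys}, non-polar the remaining
nine — with an alternative scheme treating His as neutral-polar, because
published polar/charged percentages rarely state where His was counted.
Ranking is by count descending with alphabetical tie-break.

## Site tracks, patches, neighborhoods

Interaction-site and ion-site predictions are inputs (TSV tracks), never
computed: re-implementing the upstream predictors is out of scope by
design. Site tracks are validated against the model; unresolvable keys are
an error listing every offender, type mismatches only warn. Patches are
connected components of the graph joining site residues with Cα–Cα distance
*strictly below* the cutoff (6 Å default, matching the usual "lower than"
phrasing); singletons are patches. Ion neighborhoods use *inclusive* ≤ at
3.5 Å over all heavy atoms — a coordination-shell distance unreachable from
most Cα positions, which is why the Cα-only mode is offered only as a
config switch. Patch count is non-increasing in the cutoff; neighborhoods
are monotone in the radius (both asserted).

Domain assignment counts residues into named author-numbering intervals
with first-match semantics and an explicit unassigned bucket. No default
domain map ships: solenoid domain boundaries (N-HEAT/BRIDGE/C-HEAT) vary by
publication and must be supplied by the user.

## Synthetic generator

`build_helix_bundle` builds each chain as an ideal α-helix from internal
coordinates (φ = −57°, ψ = −47°, ω = 180°; N–Cα 1.458, Cα–C 1.525, C–N
1.329, C=O 1.231 Å; standard angles), which yields the textbook ≈1.5 Å
rise and ≈3.8 Å consecutive Cα spacing without hand-tuning. Side chains are
a single ideal-geometry Cβ pseudo-atom (absent for Gly) — sufficient for
SASA, contact and neighborhood testing without rotamer machinery. Helix
axes are aligned with z and spaced along x; inter-chain clashes below 2 Å
abort generation. Randomness enters only through sequence sampling from a
composition, ion-direction search and track scores, all driven by one
documented NumPy generator per call; coordinates for a fixed sequence are
fully deterministic.

`plant_sites` plants patches as runs of consecutive residues (consecutive
Cα ≈ 3.8 Å < cutoff), separated by a residue gap that is grown until the
realized minimum inter-run Cα distance exceeds the cutoff; runs broken by a
chain discontinuity are rejected, so each run is exactly one patch by
construction. `plant_ions` places one ion per target at exactly the
requested offset from a chosen atom (Cβ preferred), choosing among 256
seeded random directions the one maximizing clearance to non-target
residues and requiring ≥ 5 Å; infeasible placements are an error naming the
residue. With offset 3.0 Å and radius 3.5 Å the neighborhood equals the
target set exactly; with offset 4.0 Å it is empty.

What the generator does *not* emulate: real packing density (a Cβ-only
helix is much less occluded than a rotamer-packed core, so nearly every
residue of a thin bundle is "surface"), loops and turns, crystallographic
disorder, and realistic sequence correlation. Passing the planted-truth
suite therefore demonstrates the correctness of the geometry, clustering
and accounting machinery — not that any particular biological surface
composition will be reproduced. Checks against deposited structures exist
separately in the acceptance suite and require the coordinate files (local
cache `scratch/structures`/`data/structures`, else an RCSB download).

## Pipeline and numerical choices

The pipeline executes load → gaps → SASA → RSA → surface → smoothed KD →
composition → patches → ions → overlap → domains, writing one table per
stage plus a single `report.json`; stages with missing optional inputs are
skipped and listed in the report. The default chain is the longest polymer
chain, which selects the main protein over short bound partners without
naming chain letters. Re-running a config reproduces the report exactly
except for its timestamp. Degenerate inputs are defined rather than
accidental: an empty composition input yields a zero summary; an empty
surface is an error for smoothing; a zero-site track yields zero patches;
B-factor annotation values outside the fixed-width PDB column are an error
before writing, and undefined residues write 0.0.

Problem sizes used by the automated runs — a 3 × 60-residue bundle for
planted-truth work, ≤ 20-atom toys for the Monte-Carlo oracle, 10,000-point
lattices for convergence checks — were chosen as the smallest instances
that exercise every code path with unambiguous ground truth.

## Known limitations

- The SASA integrator is a fixed-lattice estimator: per-atom error at 960
  points is a few tenths of a percent, so residue counts near the RSA
  threshold can differ from other implementations' by a handful.
- No secondary-structure assignment, superposition or rendering; annotated
  PDBs delegate display to external viewers.
- Insertion-code ordering assumes the deposited file lists inserted
  residues in order; exotic icode schemes are untested.
- The generator's clash test bounds inter-chain contacts only; it trusts
  ideal internal geometry within a chain.
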