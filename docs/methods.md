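# Methods

## Model overview

The package treats the hydrophobicity arrangement of a structural unit
as a probability distribution over its residues and asks how close that
arrangement is to the idealized product of aqueous folding: a centric
hydrophobic core with a polar shell.  Three distributions are built on
the unit's *effective atoms* (one pseudo-atom per residue at the
unweighted mean of its heavy-atom positions):

* the **theoretical** profile T — a 3D Gaussian spanning the oriented
  molecule, evaluated at each effective atom and normalized;
* the **observed** profile O — per-residue sums of pairwise
  hydrophobic interactions within a cutoff, normalized;
* the **uniform** reference R = 1/N.

The relative distance `RD = D_KL(O|T)/(D_KL(O|T)+D_KL(O|R))` locates O
between the two references; the modified field `M ∝ T + K(T_max − T)`
with fitted K quantifies the non-aqueous contribution; `RD_FR` applies
RD to a renormalized contiguous fragment.  Pair screening orders the
two `RD_FR` values of each structure pair as (higher, lower),
correlates the scatter and prunes outliers stepwise.

## Effective atoms and structure input

All heavy atoms (backbone and side chain) enter the centroid; this is
the least-qualified reading of "the atoms comprising the residue", and
it is the main convention a user would revisit when comparing against
numbers produced with Cα-only or side-chain-only conventions.  PDB
parsing keeps the first model of multi-model files and resolves
alternate locations to the highest-occupancy conformer (file order on
ties), so any input yields one deterministic conformer.  Residue ranges
in unit selectors are author-numbered and inclusive on both ends (the
CATH convention).  Non-standard residues stay in the unit with sequence
letter `X` and hydrophobicity equal to the scale's configurable default
(0.0); a mapping like `{"MSE": "M"}` can override this per call.

## Orientation and sigmas

The canonical frame is built from the effective atoms only: (1)
translate the geometric center to the origin; (2) find the
maximal-distance residue pair and rotate its connecting line parallel
to the X axis; (3) rotate about X so the longest YZ-projected pair runs
along Y.  Because the centroid stays at the origin, the maximal pair's
line is made parallel to X rather than coincident with it; the two
constraints are incompatible whenever the line misses the centroid, and
centering is the constraint kept.  Sign conventions (difference vector
of the first-in-chain member aligned to +X, likewise +Y for the
projected pair; ties broken by lexicographic residue order) make the
output frame reproducible; RD and K are invariant to them since the
Gaussian is even.

The three-sigma rule is implemented as `sigma_a = max_i |a_i| / 3` about
the geometric center.  The alternative reading `(max − min)/6`
coincides only for clouds symmetric about their center; the direct
max-based form was chosen and is isolated in one function should the
other convention be needed.  A zero-extent axis (perfectly planar or
collinear input) gets a 1 Å sigma floor with a warning rather than an
error, so degenerate toy inputs remain analyzable.

## Profiles

The observed profile uses Levitt's fall-off
`g(x) = 1 − ½(7x² − 9x⁴ + 5x⁶ − x⁸)` on `x = r/c`, `c = 9 Å` by
default; `g(0) = 1`, `g(1) = 0`, zero beyond the cutoff, so the
open/closed boundary is immaterial.  The self-term `j = i` is excluded:
the interaction sum is over residue pairs.  Distances are between
effective-atom centroids.  Normalization makes O invariant to uniform
rescaling of the hydrophobicity scale, which is why an arbitrary scale
is usable; the packaged default is Kyte–Doolittle min–max rescaled to
[0, 1] (any two-column TSV replaces it).  A unit in which no residue
pair falls inside the cutoff, or whose scale values are all zero, has a
zero observed sum and raises a degenerate-profile error rather than
returning NaNs.

## Divergences, RD, K

Divergence entropy is computed base 2 (bits) with the `0·log 0 = 0`
convention; `p_i > 0` where `q_i = 0` is rejected as unsupported
support.  RD is base-invariant, as is the location of the D_KL(O|M)
minimum, so only the printed divergence magnitudes depend on the base
choice.  The degenerate case O = T = R (all references identical)
defines RD = 0.5 with a warning: such a unit carries no information
either way.

K is fitted by grid search on [0, 5] in steps of 0.01, ties to the
smallest K, with a warning when the minimum sits at the upper bound
(both bounds configurable).  A grid rather than a continuous optimizer
keeps the estimate deterministic and reproducible to the printed
precision; 0.01 matches the two-decimal reporting convention for K.
Because K = 0 is always in the grid, `D_KL(O|M) ≤ D_KL(O|T)` holds by
construction.

For fragments, the O and T slices are renormalized to sum 1 and
compared against a uniform reference of the fragment length; the
complement field plays no role in `RD_FR`.  `T_max` in the M field is
taken over the whole unit's T profile.

## Pair screening

Pairs are categorized by unit-level RD (1: both < 0.5; 2: both > 0.5;
3: mixed, with exactly 0.5 counting as not-greater).  Ordered points
take (max, min) of the two `RD_FR` values so the comparison is blind to
which member carries the helix and which the strand.  Outlier pruning
removes one point at a time — the point whose removal maximizes the
recomputed Pearson r — until r exceeds the target (default 0.9) or
fewer than three points would remain, with ties broken by the larger
absolute residual to the current least-squares line and then by input
order.  The greedy max-gain selection is this package's concrete
choice for a step that is often done by eye; the stopping rule is the
part that is externally fixed.  The removal sequence is deterministic
for a fixed input order, and r never decreases across removals.

## Synthetic fixtures

The generator emulates exactly one thing: the geometric relation
between residue position and intrinsic hydrophobicity in a compact
globule.  Residues are single pseudo-atoms (so the centroid step is an
identity and profile math is isolated from averaging), positions are
drawn from an isotropic Gaussian cloud (scale = radius/2.5, default
radius 12 Å, n = 60) whose central density mimics a globular protein,
and letters are assigned by radial rank through the hydrophobicity
scale — descending for `micelle`, ascending for `inverted`, constant
for `uniform`.  The radial rank is pushed through a sigmoid toward the
scale's extremes so that the core/shell contrast dominates the
quantization noise of a 20-letter alphabet.

The `gaussian_exact` mode constructs per-residue hydrophobicities (not
letters) such that O reproduces T: the observed raw profile is linear
in H, `O_raw = (diag(s) + G) H` with G the Levitt kernel matrix and s
its row sums, and H ≥ 0 is obtained by minimizing `D_KL(O|T)` from a
non-negative-least-squares start under the side constraint
`Σ_i O_i/T_i ≤ N`.  That sum equals N exactly at O = T, and its excess
is precisely what makes the derivative of `D_KL(O|M(k))` negative at
k = 0; the constraint therefore pins the fitted K of the finished
fixture at zero instead of leaving it to rounding luck.  Points for
this mode are drawn from a uniform ball (radius 12 Å) so the kernel
graph stays connected.

What the fixtures do **not** emulate: backbone connectivity and
realistic bond geometry, side-chain packing, sequence correlations,
secondary structure, and crystallographic artifacts.  Tests passing on
fixtures therefore validate the statistics and their implementation —
core detection responds to hydrophobicity placement with the correct
sign, planted parameters are recovered — not the biological claims one
would make about real proteins.

## Study sizes and determinism

Default problem sizes: 60-residue fixtures, 20 seeds per fixture class,
planted K ∈ {0.2, 0.7, 1.5} on 60-bin profiles, and a 50-point
screening scatter (35 near-collinear, 15 planted outliers displaced an
order of magnitude beyond the inlier noise).  These sizes give stable
statistics while keeping a full run in seconds.  All randomness flows
through explicit integer seeds; identical seeds give byte-identical
fixtures and identical results.

## Known limitations

* Reproducing published RD/K values for real PDB entries depends on
  the exact hydrophobicity scale and on conventions (centroid atom
  set, unit boundaries) that published tables rarely pin down; the
  scale and the centroid convention are the designated knobs, and
  agreement should be validated per scale before cross-study
  comparison.
* Unit boundaries are user input; the package does not look up domain
  definitions.
* Secondary-structure labels in pair manifests are metadata; no
  assignment is computed.
* The K grid upper bound (5 by default) truncates genuinely extreme
  environments; the fit warns when it hits the bound.
* mmCIF input is not supported; structures must be PDB-format text.
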