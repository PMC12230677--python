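# Methods

This note documents the model implemented by `qdrcharges`, the numerical
choices behind it, what the synthetic fixtures do and do not emulate, and
the package's known limitations.

## Inputs and conventions

A stockholder partition supplies, per atom A: the net atomic charge `q_A`
(e), the atom-in-material dipole `mu_A` (e bohr), the traceless
atom-in-material quadrupole `Theta_A` (e bohr^2), the assigned electron
count `N_A`, and pairwise overlap populations `OP_Ab >= 0` between atom A
and atom images b (images are periodic translations indexed by an integer
triple; nonperiodic systems have only the zero translation).  All internal
arithmetic is in atomic units; file I/O uses angstrom for coordinates
(1 bohr = 0.529177210903 angstrom).

Quadrupole tensors are stored in the detraced-second-moment convention
`Theta_ij = integral rho(r) (x_i x_j - r^2 delta_ij / 3) d^3r`.  The
Buckingham convention is a uniform factor 3/2 larger; `to_buckingham` /
`from_buckingham` convert.  Mixing the two conventions is a classic
pitfall, so every tensor entering or leaving the package is in the first
convention and tracelessness is validated at 1e-10 (inputs) and preserved
to 1e-12 (updates).

Pair lists store both directed orientations of every pair so per-atom
blocks assemble without lookups; the mirror of `(A, b)` is `(B, a)` with
negated translation and identical overlap population.  A pair enters the
sums when its distance is within the cutoff-radius sum (10 angstrom with
the default 5 angstrom per-atom radii) or its overlap population is at
least the threshold (default 1e-4).  Results are insensitive to the
threshold because a transfer's magnitude scales as `w_Ab^2` with
`w_Ab = 2 tanh(2 OP_Ab)`, which vanishes quadratically in `OP_Ab`.

## Dipole resorption (DR)

For each directed pair, an unknown charge `q_Ab` flows from image b to
atom A.  The shift changes the point-charge dipole by `-q_Ab R_Ab
Rhat_Ab`; the balancing shift dipole `+q_Ab R_Ab Rhat_Ab` is split half
onto atom A and half onto image b.  This half/half split is the unique
per-pair assignment that preserves the total traceless quadrupole about
*any* origin (placing the whole shift dipole on one atom preserves only
the dipole).  Atomic quadrupoles are untouched.

The transfers minimize the convex loss

    L_DR = sum_pairs (q_Ab R_Ab / w_Ab)^2
         + sum_A || mu_A + sum_b q_Ab R_Ab Rhat_Ab ||^2 .

Each atom's residual dipole in the loss is modeled with that atom's own
outgoing transfers; the mirrored transfers are the neighbor's unknowns and
appear in the neighbor's block.  That choice makes the normal equations
exactly block diagonal per atom; in the scaled unknowns
`X_Ab = q_Ab R_Ab / w_Ab` the block is `M^(A) = I + G G^T` with rows
`G_b = w_Ab Rhat_Ab` (diagonal `1 + w^2`, off-diagonal
`w_b w_d Rhat_b.Rhat_d`) and right-hand side `-w_Ab (mu_A . Rhat_Ab)`.
The apply step then uses the exactly conservative half/half split with
both mirrored solutions; for symmetric configurations the two views
coincide, and the conservation triple holds identically in all cases (it
is enforced at 1e-10 in the test suite, and holds to ~1e-15 in practice).

For a heterodiatomic with both dipoles along the bond this machinery
reduces to the closed form: resorbed fraction `f = w^2/(1+w^2)`, giving
0.699 at OP = 0.5, 0.788 at OP = 1, 0.135 at OP = 0.1, 0.0016 at
OP = 0.01, and 1.6e-5 at OP = 0.001.  `f` is independent of the bond
length and of the dipole magnitude (homogeneity of the quadratic loss),
strictly increasing in OP, and bounded by 1 — all asserted as properties.

## Quadrupole resorption (QR)

QR moves charge the same way but compensates entirely on the self atom: a
compensating dipole `+q_Ab R_Ab Rhat_Ab` is placed on atom A (cancelling
the point-charge dipole change), and the quadrupole generated by the
shift, `q_Ab R_Ab^2 (Rhat Rhat^T - I/3)` about atom A's center, is added
to `Theta_A`.  Dipole and quadrupole changes are therefore confined to
self atoms; only the charges reach first neighbors.  The loss mirrors
DR's with an extra `R_Ab^2` in the first term for dimensional consistency
and the Frobenius norm of the residual quadrupole in the second.  In the
unknowns `S_Ab = q_Ab R_Ab^2 / w_Ab` the block is `C^(A) = I + W W^T`
with `W_b = w_Ab vec(Rhat_b Rhat_b^T - I/3)` (diagonal `1 + (2/3) w^2`,
off-diagonal `w_b w_d ((Rhat_b.Rhat_d)^2 - 1/3)`) and right-hand side
`-w_Ab (Rhat . Theta_A . Rhat)`; the trace term drops because `Theta_A`
is traceless.  Degenerate geometries (two slots with the same direction)
need no special-casing: the identity keeps the block positive definite.

## Block solver

Both blocks are `identity + low-rank Gram`: rank <= 3 (DR, directions
live in R^3) and rank <= 5 (QR, symmetric traceless tensors live in a
5-dimensional space), hence at most 4 and 8 distinct eigenvalues, every
eigenvalue >= 1, and `lambda_max <= 1 + (sum_b w_b)^2 <= 1 + 16 SOP_A^2`
(QR carries the extra 2/3 from `||Rhat Rhat^T - I/3||^2`); the
diagnostics routine also checks a Gershgorin radius.  Matrix-vector
products never materialize the matrix: DR accumulates one 3-vector, QR
one 3x3 tensor plus a scalar, so a product costs O(block dimension).

Conjugate gradients with a zero initial guess and relative residual
tolerance 1e-10 terminates, in exact arithmetic, in at most
(number of distinct eigenvalues) iterations — hence at most 4 / 8
matrix-vector products per block, which the acceptance suite verifies on
200 random blocks against dense-inverse oracles.  The tight tolerance is
free: CG's finite-termination property means loosening it would not save
iterations.  Blocks are independent and side-effect free, so solves may
run in any order or concurrently with bitwise-identical results; the cost
of a full pass is linear in the number of pairs (verified as exact 8x
scaling of pair counts, matvec counts, and pair-array bytes over 1x/8x/64x
rocksalt supercells).

## Multi-pass driver

One QDR pass is QR then DR — QR first, because QR converts quadrupole
information into self-atom dipoles that the following DR can partly
resorb, whereas DR first would do nothing on a zero-dipole input
(implemented behind an explicit `dr_first` flag purely to make that
thought experiment testable).  Each pass propagates charge changes about
one bonded-neighbor shell.  The default is 2 passes: enough to involve
first and second neighbors (whose geometry — bond lengths and angles — is
nearly conformation-independent) while excluding third neighbors (whose
geometry varies with rotatable dihedrals), which is the
accuracy/transferability sweet spot for forcefield charges.  Overlap
populations are held constant across passes; resorption moves charge, not
density overlap.  Trace snapshots are deep copies — auditability is worth
more than memory at desk scale.

## Electrostatic-potential evaluation

Model potential terms per atom (hartree/e at off-nucleus points):
`q_A / r`; `mu_A . rvec / r^3`; and a cloud-penetration correction
`N_cloud exp(-b r)(1/r + b/2)` — the closed-form potential of the neutral
pair {point `+N_cloud`, diffuse exponential cloud `rho = a exp(-b r)`,
`N_cloud = 8 pi a / b^3`}, validated against numerical radial integration.
For 3D-periodic cells the charge term is an Ewald sum in the tinfoil
gauge (validated against the rocksalt Madelung constant 1.7475646 to
1e-5 relative); dipole and cloud terms are real-space sums with a 25
angstrom default cutoff.  Periodic potentials carry an arbitrary
constant, so metric evaluation offers mean-offset alignment (on by
default for periodic grids, off otherwise).

Metrics are computed over valid grid points only: electron density below
1e-4 e/bohr^3, farther than 2 angstrom from every atom, and within 5
angstrom of at least one atom.  RMSE is the rms model-reference
difference over the mask; RRMSE divides by the RMSE of the null model
(every atomic charge zero, i.e. zero predicted potential), so the null
model scores exactly 1; `R^2 = 1 - RRMSE^2` (0.91 at RRMSE 0.3).  RMSE is
reported in kcal mol^-1 e^-1 (1 hartree/e = 627.5094740631).

## Ensemble figures of merit

From per-(method, conformation, atom) charges: the rms charge transfer
`sigma_method` is the population rms of conformation-averaged charges
about the method's overall mean (the mean is kept because training sets
may contain charged molecules); conformational sensitivity is the pooled
rms of per-conformation deviations from each atom's conformation average,
over all atoms and conformations jointly — this pooling satisfies the
homogeneity (scaling all charges scales the sensitivity, not its
normalized form) and law-of-total-variance identities checked in the
tests; normalized sensitivity divides by `sigma_method`.  Covariance and
Pearson correlation matrices between methods are computed on
conformation-averaged charges; `S_alpha` sums a method's correlation row
(self included), and the strong-correlation count uses the inclusive
threshold `Omega >= 0.9` excluding self.  All denominators are population
(1/N): these are rms statistics, not sample standard deviations.

## Synthetic fixtures

The generators emulate the *structure* of stockholder output — charge
sums matching the net charge, symmetric pair lists, exactly traceless
quadrupoles, overlap populations decaying with distance — with controlled
special cases: `rocksalt` (3D-periodic, every atom on an inversion center
so all moments vanish and QDR provably returns the input charges),
`ring_tube` (alternating charges with coherent radial dipoles, producing
an inside/outside potential offset that no atom-centered point-charge
model can reproduce), `chain` (overlap only between bonded neighbors, for
locality tests), `homodiatomic` (exchange symmetry forces zero charge
transfer), and `water_like` (published starting magnitudes for a water
molecule; dipole and quadrupole *orientations* are generator-defined
C2v-symmetric choices, so downstream numbers depend on them and only
structural patterns — conservation, frozen quadrupoles under DR, exact
dipole reproduction by the charges+dipoles model — are meaningful).
Oracle grids take the package's own multipole model as ground truth, so
closure tests (model reproduces its own grid to rounding) validate
bookkeeping, not chemistry.  The default density cloud (`a = 2.2`,
`b = 2.0` bohr^-1) puts the 1e-4 e/bohr^3 isosurface at ~2.65 angstrom,
between the mask's inner and outer cutoffs, so all three selection rules
are exercised.  None of the fixtures emulate real DDEC6/MBIS statistics
beyond magnitude ranges; passing tests demonstrate the re-expansion
machinery and metrics, not agreement with quantum-mechanical references.

Problem sizes in the test and acceptance suites are desk scale by design
(2-512 atoms, grids of a few tens of thousands of points, 100-fixture
statistical batches, supercells to 64x), chosen so the full suite
completes in well under a minute while still exercising multi-image
periodic enumeration and the linear-scaling property.

## Numerical choices

* CG: zero initial guess, relative tolerance 1e-10, matvec cap 4x block
  dimension (non-convergence signals corrupted inputs and raises with the
  solve report attached).
* Eigenvalue clustering tolerance 1e-8 relative, matching the
  floating-point spread of the analytically 4/8 eigenvalue families.
* Conservation asserted at 1e-10 a.u. — pure linear algebra on O(1)
  quantities; observed drift is ~1e-15.
* Zero-overlap pairs inside the distance cutoff stay in the pair list
  with zero weight: they contribute nothing to solves but keep the
  enumeration rule simple and the block dimensions geometry-determined.
* Statistical design goals ("more often than not" the rms atomic moments
  shrink) are asserted as majorities/medians over 100 seeded random
  fixtures, never per instance.

## Limitations

* Overlap populations are inputs; the package never recomputes them from
  electron densities, and no importer for third-party population-analysis
  output formats is provided (the versioned qdr-json/qdr-csv schema is the
  interface).
* Ewald evaluation supports 3D-periodic cells; 1D/2D-periodic ESP
  evaluation raises.  System multipoles are defined for nonperiodic
  systems only.
* Hard dipole/quadrupole constraints (Lagrange-multiplier style) are
  deliberately out of scope: they break size consistency and condition
  badly on linear molecules; the resorption losses are soft by design.
* Octupole resorption and off-site charges are not implemented.
* The per-atom trace columns in `trace_report` are emitted for systems of
  up to 12 atoms; larger systems get summary statistics only.
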