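# Methods

## The model

The package implements a static-structure route to protein-ligand binding
affinity: experimentally measured inhibition constants, expressed as
log10(K_i/nM), are regressed on energy descriptors computed for a
"QM cluster" — the ligand plus every active-site residue in direct contact
with it — excised from a single crystal structure. No dynamics, docking or
geometry optimization enters anywhere; the claim under test is that the
electronic structure of the bound complex alone carries enough information
to rank and predict affinities within a congeneric series.

The pipeline has three stages.

### 1. Active-site cluster extraction (`structure`)

A residue is *active* when any of its atoms lies within a Euclidean cutoff
(default 3.5 Å, boundary inclusive) of any ligand atom. Active residues are
kept whole — backbone and sidechain, no peptide capping — and everything
else is discarded. Operational choices:

- Only the 20 standard amino acids are eligible; waters, ions, glycans and
  other het groups never enter the protein fragment. Crystallographic
  waters bridging ligand and protein are excluded.
- Plain Euclidean distance on the atoms present in the file: hydrogens are
  used if present and never added; no element-specific radii.
- Alternate locations resolve to the highest-occupancy conformer (ties keep
  the first listed); only the first MODEL of a multi-model file is read.
- The contact search uses a k-d tree; an O(n²) all-pairs scan is kept in the
  test suite as an independent oracle, and the two agree on every generated
  structure.

The cluster is emitted as XYZ or as a two-fragment coupled-cluster/LED
input deck (fragment 1 = residues, fragment 2 = ligand). Total charge and
multiplicity must be supplied explicitly: a crystal structure does not
determine protonation, so the writer refuses to guess silently (the CLI
defaults to a neutral singlet with a prominent warning).

### 2. LED descriptor assembly (`led`)

The quantum-chemistry calculation itself is out of scope; the package only
writes input decks and parses output text. From a two-fragment local energy
decomposition it extracts, in Hartree: the total and intra-fragment
energies, the inter-fragment sum, reference-level electrostatics and
exchange, both charge-transfer directions, and strong- plus weak-pair
dispersion. Five descriptors result, all in kcal/mol with stabilizing
contributions positive (conversion 627.509474 kcal/mol per Hartree,
configurable; conversion negates the sign):

- binding energy = −(inter-fragment sum) — the energy of the cluster minus
  its fragments at fixed geometry,
- E_elstat, E_exch,
- E_ct = −(CT 1→2 + CT 2→1),
- E_disp = −(strong + weak dispersion).

Charge transfer and dispersion are grouped by their intermolecular distance
dependence, which is what makes them informative about the binding process
beyond a single interaction-strength number. The five descriptors do *not*
sum to the binding energy (preparation/residual LED terms are parsed over,
not modelled) and no such identity is asserted. A bookkeeping check
verifies |inter − (total − Σ intra)| ≤ 1e−6 Eh on every parse; the
tolerance is configurable and a failure is reported, never raised.

### 3. Regression suite (`regression`)

Three nested OLS models, all with intercept, relate log(K_i/nM) to the
descriptors: M1 = binding energy only; M2 = the four LED components;
M3 = all five. Statistics follow the conventions of the reference analysis:

- SSQ_data — total sum of squares of log(K_i) about its mean,
- %SSQ recovered = 100·(1 − SSQ_residual/SSQ_data) (R² in percent),
- MSE = SSQ_residual / N (population convention, not N − p),
- residual = observed − predicted,
- coefficient p-values — two-sided t tests with N − p − 1 residual dof
  (via statsmodels).

Leave-one-out cross-validation refits the model on each (n−1)-subset by
explicit refit (square training systems are permitted when n−1 equals the
coefficient count), PRESS is the sum of squared held-out errors and
Q² = 1 − PRESS/SSQ_data with SSQ_data over all n points. The
"outlier-removed" Q² variant drops the designated fold's squared error from
PRESS and recomputes the denominator over the remaining points about their
own mean; the folds are not refitted, because refitting leave-one-out on
n−1 points with n−1 coefficients would be exactly determined and carry no
information.

Supporting procedures:

- *Variable selection*: stepwise on coefficient p-values, forward (add the
  smallest p while < α) and backward (drop the largest p while ≥ α).
  On the reference dataset backward selection retains all five descriptors
  with p < 0.05, while forward selection legally terminates empty — no
  single descriptor is individually significant at α = 0.05. Both outcomes
  are frozen in the tests.
- *Single-variable exclusion scan*: refit the full model without each
  predictor; on the reference data the smallest loss is ≈28 percentage
  points of recovered SSQ, i.e. every descriptor is load-bearing.
- *Commensurability screen*: n sub-fits, each excluding one point; a point
  is flagged when the fit without it beats the median sub-fit's %SSQ by
  more than a margin (default 10 percentage points — the reference analysis
  gives only a qualitative criterion, so the margin is configurable). This
  is the mechanism that justifies excluding the pH-anomalous GNT complex,
  whose energetics are not part of the packaged table; the screen is
  therefore validated on synthetic data with planted outliers.
- *LED fraction table*: E_x/binding energy per complex plus max−min ranges.
  The ordering E_ct ≤ E_exch < E_disp < E_elstat is checked on fractions
  rounded to two decimals, the precision at which it is stated; at full
  precision one complex (5NAP/DZ7) has E_ct marginally above E_exch.

## The packaged dataset

`data/tcache_led_table.csv` carries the seven Torpedo californica
acetylcholinesterase complexes (3ZV7/NHG, 5NAU/DZ0, 1U65/CP0, 5NAP/DZ7,
1H23/E12, 1H22/E10, 1E66/HUX): measured log(K_i/nM) and the five
descriptors from DLPNO-CCSD(T)/def2-SVP (NormalPNO) LED calculations on the
3.5 Å clusters, as printed in the reference tabulation at three decimals.

### Input-precision sensitivity of the full model

M3 fits six coefficients to seven points, leaving one residual degree of
freedom. The residual vector is then confined to a one-dimensional
subspace fixed by the design matrix: its *direction* is robust, but its
*magnitude* — and everything downstream of near-singular six-point
training fits in the leave-one-out loop — reacts strongly to rounding in
the inputs. From the three-decimal table the package obtains M3 residuals
of (0.022, 0.045, −0.025, −0.052, −0.033, 0.031, 0.012), max |residual|
0.052, SSQ_residual 8.07e−3, Q²_LOO 0.913 and outlier-removed Q² 0.926.
The reference analysis, run at full spreadsheet precision, reports the
same residual pattern at a ≈1.15× larger magnitude (max 0.06,
SSQ_residual 1.08e−2) and Q² = 0.78 / 0.91. The discrepancy is provably a
rounding effect: perturbing the printed response values within their
half-ulp bounds can move the residual scale by at most ≈9% of the gap, and
no sub-rounding reading of any single table entry reproduces Q² = 0.78.
These comparisons are reported as annotated deviations in the reproduction
report and asserted at the published values in the acceptance tests, where
they fail visibly rather than being loosened. All statistics with ≥2
residual dof (M1, M2, SSQ_data, the fraction table, the exclusion scan)
reproduce the published values exactly at printed precision, which was
verified against an exact rational-arithmetic solve of the normal
equations.

## Synthetic data

The generators produce every input class the pipeline consumes, so all
stages are testable without downloads.

- `make_toy_structure` plants exact residue-ligand minimum distances:
  ligand atoms are sampled on the 0.001 Å grid (the PDB coordinate
  precision), and each residue is laid out along a coordinate axis from the
  ligand atom extreme in that direction. Every other ligand atom then has a
  non-negative projection onto the axis, which makes the residue's contact
  atom provably its nearest atom to the ligand and the planted distance
  exact (to ~1e−12, well inside the 1e−6 contract). Up to six residues per
  complex (one per axis direction); atom placements closer than 1.0 Å are
  resampled and eventually raise a placement error. The toys emulate
  contact *geometry* only — no realistic stereochemistry, B-factors,
  occupancies or symmetry, so passing tests say nothing about such features
  of real files.
- `make_led_fixture` emits the LED dialect with the total energy set to
  Σ(intra) + inter, so the consistency check passes by construction; an
  `inconsistency` offset plants a defect. Values are printed at 17
  significant digits so parsing recovers them bit-exactly.
- `make_linear_dataset` draws descriptors uniformly from the spans of the
  reference table (binding energy ≈ 19.6–243.6 kcal/mol, etc.) and builds
  log(K_i) = β₀ + Σ βx + N(0, σ²), returning the ground truth. Gaussian
  noise is the conventional choice consistent with the t-test machinery;
  an optional planted outlier (+5 log units by default) exercises the
  commensurability screen. Real descriptor sets are strongly collinear
  (the reference set has pairwise correlations above 0.9), which uniform
  independent draws do not emulate; coefficient-recovery results on
  synthetic data are therefore optimistic about identifiability.

All generators are pure functions of their spec and seed; identical inputs
give byte-identical text.

## Numerical choices and limitations

- OLS is solved by statsmodels (QR-based); the tests cross-check against a
  direct normal-equation solve at 1e−10 relative and, for the reference
  dataset, against exact rational arithmetic.
- Rank deficiency is detected via `numpy.linalg.matrix_rank` with its
  default tolerance and raises a singular-design error; leave-one-out folds
  report the offending fold by name.
- Degenerate inputs: a zero contact cutoff yields an empty-cluster error;
  fraction tables refuse zero binding energies naming the complex; fits
  require strictly more points than coefficients.
- The models are explanatory instruments for this seven-complex series;
  nothing here supports extrapolation to other targets or chemotypes, and
  no regularized or robust variants are provided by design.
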