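# Methods

## Scope and model

`cyp51var` post-processes trajectory-level output for the CYP51A1 variant
problem. It does not run molecular dynamics or docking: coordinates, energy
series and candidate poses are inputs (real or synthetic), and the package
implements the statistics computed *on* them.

### Hydrogen-bond occupancy

A hydrogen bond between the lanosterol hydroxyl and a candidate partner atom
is declared by distance alone: partner–hydroxyl distance ≤ `cutoff_angstrom`
(default 2.4 Å, inclusive). No angular criterion is applied. The default
`donor_acceptor` mode measures the hydroxyl's heavy (oxygen) atom; a 2.4 Å
heavy-atom cutoff is unusually short by general hydrogen-bond conventions
(heavy-atom cutoffs are typically ~3.5 Å), so the alternative
`hydrogen_acceptor` mode — where 2.4 Å is a natural H···acceptor cutoff — is
shipped as a configuration option; the default implements the distance
criterion literally as stated for this analysis. Candidate partners default
to the backbone amide N and carbonyl O of the twenty standard residues, with
an `extra_spec` hook for side-chain donors/acceptors.

Per residue, the relative occupation time is
τ_HB/τ_0 = 100 × (#frames in window with ≥ 1 bonded partner atom of the
residue) / (#frames in window). τ_0 is the full analysis window (so values
are bounded by 100); multiple bonded atoms of one residue in one frame count
once; a frame may contribute to several residues or to none, so occupancies
do not sum to 100. The window defaults to the second half of the trajectory,
the usual production-window convention (equilibration discarded). Reports
round to one decimal; full precision is kept internally.

### Fe–C30 distance

Per-frame Euclidean distance between two single-atom selections (heme FE,
ligand C30), computed over the full trajectory; windowed summaries use the
sample (n−1) standard deviation. Smoothed traces use a trailing running mean
with a configurable window (default 100 frames). Frames are assumed unwrapped
(no periodic-boundary imaging).

### Binding enthalpy

E_b = ⟨U_cmplx⟩ − ⟨U_m1⟩ − ⟨U_m2⟩, each average over its own series; the
three series come from separate simulations and may differ in length. Sign
convention: more negative is more favorable. Energy units are metadata
(default kcal/mol); all operations are unit-agnostic.

Uncertainty: each term's standard error is estimated by block averaging —
split the series into `n_blocks` contiguous, near-equal blocks (default 10, a
standard heuristic for correlated MD series), then SE = sd(block means,
ddof=1)/√n_blocks — and the three SEs combine in quadrature. Series shorter
than `n_blocks` fall back to one block per frame; a length-1 series
contributes zero uncertainty. E_b is invariant to frame permutation (it uses
means only); the block SE is not, which is documented behavior rather than a
defect — block averaging exists precisely to respect serial correlation.
`compare_variants` sorts labels by E_b ascending (deterministic tie-break on
the label), propagates pairwise SEs in quadrature (independent simulations),
and flags |E_b| < 2 SE as "indistinguishable from zero".

### Pose ranking

For each cross-chain pair of key interface residues, the score records the
minimum heavy-atom distance (hydrogens excluded by element or H-prefixed atom
name); a pair is a contact at ≤ 5.0 Å, a common interface-contact convention
adopted here as a design choice. Poses sort by contact count (descending),
then summed minimum distances (ascending), then label — fully deterministic.
The CYP51A1 key set is K127, A172, K175, K364, K442, R452, N459; the POR set
is residues 92 (expected Glu), 93 and 142. The identities of POR 93 and 142
are deliberately wildcards: a mismatch between an expected residue name and
the pose warns but does not fail, since pose selection is positional.

### Variant tables

Printed SIFT/PolyPhen-2 labels are stored verbatim and never overwritten;
threshold classes are recomputed from the printed scores with the tools'
standard conventions (SIFT damaging at ≤ 0.05; PolyPhen-2 HumDiv bins:
probably ≥ 0.957, possibly ≥ 0.453, else benign). The curated tables contain
internally inconsistent labels (e.g. R258H printed "Benign" at 0.93 while
M384I is printed "Probably damaging" at 0.930, and the bin source —
HumDiv vs HumVar — is not recorded), so `consistency_check` reports
label/class disagreements instead of resolving them. Termination (`*`/`Ter`)
and deletion (`del…`) variants carry class `unknown` for both tools. The
damaging-by-both filter requires a SIFT class of damaging and a PolyPhen-2
class of probably- or possibly-damaging, excluding records lacking either
score. Residue numbering follows the NP_000777.1 reference protein;
population-frequency and in-vitro-mutant tables are stored as fixtures with
no computation on them.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical* structure the analysis layer
consumes — never physics (no force field, no sterics, no solvent):

- **Hydrogen-bond trajectories.** Each target residue's backbone N hops
  between a bonded distance (2.2 Å, inside the 2.4 Å cutoff) and an unbonded
  distance (6.0 Å) from a hydroxyl fixed at the origin, driven by an
  independent two-state Markov chain whose stationary probability is the
  target occupancy. `persistence` ρ sets the chain's extra stay-probability
  (P(bond|bond) = ρ + (1−ρ)p), default 0 (i.i.d. frames), so the effect of
  autocorrelation on effective sample size is testable. Residues sit on
  golden-spiral directions so partners never interfere.
- **Energy and distance series.** Stationary AR(1): x_0 = mean,
  x_t = mean + φ(x_{t−1}−mean) + ε_t with Var(ε) = sd²(1−φ²), so the
  stationary mean and sd equal the scenario parameters exactly. The
  effective sample size n_eff = n(1−φ)/(1+φ) governs the recovery bounds
  used in tests.
- **Pose sets.** One planted pose with exactly k key pairs at 4.0 Å
  (within the 4.5 Å near-native definition) plus decoys whose partner chain
  is randomly rotated (uniform quaternion) and translated to ≥ 15 Å
  interface separation, with bounded retries.

Default study conditions: occupancy trajectories of 2000 frames with targets
mirroring the reported occupancy table (WT: I385 65.9 %, M384 24.5 %, I383
1.5 %, etc.); Fe–C30 series of 3000 frames, sd 0.3 Å and φ = 0.8 (the
reported traces are "stable", i.e. strongly autocorrelated with small
fluctuation) with WT at 5.0 Å — a typical catalytically competent Fe–C
distance, chosen once since no absolute value is printed — R277L at 5.4 Å
and the displaced variants R431H/D152G at 9.0 Å (+4 Å); energy series of
2000 frames, sd 2 kcal/mol, φ = 0.5, with binding-enthalpy means ordered
WT (−45) < R277L (−38) < R431H (−18) < D152G (−12) kcal/mol toward
lanosterol and WT (−60) < R431H (−40) < R277L (−20) < D152G (0) toward POR;
pose sets of 10 decoys + 1 planted pose with all 21 key pairs in contact.

Consequently, passing tests demonstrate that the *analysis* is correct and
recovers known ground truth at realistic sampling noise; they say nothing
about force fields, docking accuracy, conformational sampling, water-mediated
interactions, or whether real CYP51A1 variants behave as modelled.

## Numerical and design choices

- Coordinates in Å, times in ps, 1-based PDB residue numbering. Multi-model
  PDB is the canonical trajectory carrier (inspectable, fixed-column,
  3-decimal precision); XYZ and two-column CSV are lighter alternatives.
  Binary formats (DCD/XTC) are out of scope.
- The atom-selection grammar is equality tests joined by `and`/`or` with
  parentheses (`and` binds tighter); no ranges. Empty selections warn rather
  than fail; distance operations require exactly one atom per selection and
  raise on any other cardinality.
- Parsers never silently drop frames: every MODEL/frame either appears in
  the output or raises an error naming the offender.
- HB criterion boundary: inclusive by default (distance exactly at the
  cutoff is bonded); configurable.
- Occupancy entries sort by descending occupancy with (residue number, name)
  tie-breaks; zero-occupancy residues are omitted from entries but counted.
- Statistical test bounds: binomial 3σ for occupancy recovery, 3 SE for
  mean recovery, with coverage asserted at ≥ 95 % over seeded replicates
  (a correct sampler exceeds a 3σ band at a small nonzero rate, so hard
  per-draw assertions would be flaky by construction).
- All generators take explicit integer seeds and are byte-identical on
  rerun; derived seeds are drawn below 2³¹.

## Known limitations

- The 2.4 Å donor–acceptor criterion is applied literally by default; users
  analysing real trajectories should consider `hydrogen_acceptor` mode or a
  longer heavy-atom cutoff plus an angular term (not implemented).
- No PBC imaging, RMSD alignment or hydrogen inference; inputs are assumed
  unwrapped and complete.
- Pose scoring is positional only (contact counts), not energetic; it ranks
  candidate poses, it does not validate docking.
- The variant tables are static curated snapshots; the package does not
  query dbSNP/COSMIC or run SIFT/PolyPhen-2.
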