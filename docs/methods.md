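# Methods

This note documents the models, conventions, and numerical choices behind
`kinothread`, and what the synthetic-data generators do and do not emulate.

## Potts model and gauge

The Hamiltonian is `E(S) = Σ_{i<j} J^ij_{S_i S_j} + Σ_i h^i_{S_i}` over `L`
aligned columns and `q` states; the default alphabet is the 20 canonical
amino acids in one-letter alphabetical order followed by the gap symbol
(`ACDEFGHIKLMNPQRSTVWY-`). The gap is a full Potts state and participates in
energies and threading like any residue. Couplings are stored densely for
the `i < j` triangle only; the `(j, i)` view is the stored block's
transpose, so the swap symmetry `J^ij_ab = J^ji_ba` holds structurally
rather than by duplication.

Potts parameters are only defined up to a gauge. `to_zero_mean_gauge`
applies the standard zero-sum transform per pair block,
`J' = J − rowmean − colmean + mean`, pushes the row/column means into the
per-position fields, centres the fields, and returns the remaining shift as
a separate additive constant (the transform itself never hides energy: for
every sequence `E_before = E_after + constant`). After the transform every
block has zero row, column, and total means, which makes the operation
idempotent and lets an all-zero block be read as "uncoupled". Threading
(below) is not gauge invariant — it sums raw couplings over a subset of
pairs — so all threading entry points require a zero-mean model and raise
otherwise. Gauge invariants are checked to an absolute tolerance of 1e-8.

## Sampling

`sample_sequences` draws from `P(S) ∝ exp(−E(S))` with single-site
Metropolis updates: a uniformly random site, a uniformly random proposed
state, acceptance `min(1, exp(−ΔE))`. Defaults are `burn_in = 1000·L` and
`thinning = 10·L` elementary updates. For throughput the sampler advances
`n_chains` (default 64) independent chains in lockstep and pools their
thinned draws; every chain is burnt in independently, so pooling changes
nothing about the target distribution. A single seeded NumPy generator
drives everything; identical arguments reproduce identical samples
byte-for-byte. Correctness is verified against exhaustive enumeration of
the Boltzmann distribution for enumerable models (L=4, q=3; chi-square over
all 81 sequences).

## Contacts and Δc

Two residues are in contact when their nearest sidechain heavy-atom
distance is strictly below the cutoff (default 6.0 Å; the comparison is
`<`, so a pair at exactly 6.0 Å is not a contact). Sidechain atoms are all
heavy atoms except the backbone N, CA, C, O (and OXT). Glycine, which has
no sidechain heavy atom, uses CA as a configurable proxy; alanine uses its
CB naturally. Sequence-adjacent pairs are not excluded: their near-constant
contacts cancel in Δc, so excluding them would buy nothing and complicate
the bookkeeping.

Ensemble contact frequencies use per-pair denominators: a structure in
which either residue is unresolved is excluded from that pair's count, and
a pair never co-resolved in an ensemble is *absent*, not zero. Δc = c_A −
c_B is defined only where both basins have counts; one-sided pairs are
dropped and logged, and contribute nothing to ΔT. Structure files are read
through gemmi; altlocs resolve to the highest-occupancy conformer, and the
residue→MSA-column mapping is always an explicit user-supplied table
(chain, resseq, icode, column) — no internal alignment is ever attempted.

## Basin classification

Spatial DFG and dihedral-class labels are consumed as external annotations
(KinCoRe-style TSV); no Ramachandran classifier is implemented, because
inventing region boundaries would add error without adding capability.
Basin A requires DFG-in + BLAminus, basin B DFG-out + BBAminus. Both
additionally require, where coordinates allow (and configurable off):

- **αC-in**: β3-Lys NZ within 4.0 Å of either αC-Glu carboxylate oxygen.
  The 4.0 Å N–O bound is a standard salt-bridge convention; only the
  existence of the bridge is prescribed by the classification scheme.
- **Extended G-loop**: the first conserved G-loop Gly carbonyl O within
  3.5 Å of the β2 Val backbone N, *and* at least 6.5 Å from the amide N of
  the residue immediately before the conserved Phe/Tyr. The second
  criterion reads "minimum distance 6.5 Å" as a required lower bound and
  excludes kinked loops; the boundary is inclusive (≥).

Structures with unresolved motif residues are excluded as indeterminate
rather than guessed. Every input lands in exactly one of basin A, basin B,
or the rejection report with a machine-readable reason.

## ΔT, ΔΔT, and the mutation scan

`ΔT = T_B − T_A = −Σ J·Δc` with `Δc = c_A − c_B`; positive ΔT penalises the
inactive basin, and the per-pair terms `−J^ij·Δc^ij` are exposed as a
decomposition that sums exactly to ΔT (ties in the ranked decomposition
break deterministically by (i, j)). ΔΔT is defined as ΔT(mutant) −
ΔT(wildtype) computed under this sign convention, so that positive ΔΔT
means a shift toward the active conformation — the convention the
downstream ΔΔG_reorg comparison shares. Evaluation is sparse (only pairs
touching mutated columns), with the pair between two mutated columns
counted once; sparse and dense routes agree to 1e-10 and antisymmetry
ΔΔT(w→m) = −ΔΔT(m→w) holds exactly.

The scan excludes Gly, Pro, Trp, His, and Cys — and the gap — both as
wildtype and as mutation targets (the same modelling-complication rationale
applies in both directions), and restricts to columns with at least one
|Δc| strictly above 0.8. Double mutations pair eligible columns whose
mutual |Δc| passes the same gate; a configurable `all_eligible` rule crosses
every eligible pair instead, since the gating of pairs cannot be
adjudicated from counts alone. Tail selection takes the n most-negative
plus n most-positive ΔΔT rows (default 3+3), with ties broken by |ΔΔT| then
lexicographic mutation key, making selections byte-reproducible.

## Thermodynamic cycles

For a variant, `ΔΔG_reorg = ΔG_B − ΔG_A` over matching alchemical legs.
For a double {i, j} the three paths are (w→i)+(i→ij), (w→j)+(j→ij), and
the direct (w→ij), each summed per basin then differenced B−A. The three
single-mutant paths through the double-mutant cycle are our reconstruction
(only their existence is prescribed): direct (w→i); (w→ij)−(i→ij); and
(w→j)+(j→ij)−(i→ij), symmetrically for j. With legs generated from any
per-variant free-energy function all paths coincide to 1e-10, which the
tests enforce. Hysteresis is the population (ddof=0) standard deviation
over the available paths — the natural choice when the three paths are the
whole population — and is reported as absent when only one path exists.
The job planner emits, per double, the core legs w→i, w→j, w→ij in both
basins (6 per double; 3 kinases × 6 doubles → 108), plus optional closure
legs i→ij and j→ij per basin; both the full-closure and core-only modes are
supported because partial closure designs occur in practice.

The Potts↔FEP comparison is a Pearson correlation (two-sided p via the
t-transform, as implemented by scipy) plus an ordinary least-squares fit of
ΔΔG_reorg on ΔΔT; the slope is the statistical-energy → kcal/mol conversion
factor and its standard error is returned for confidence intervals.
Population conversion uses `f_inactive = e^(−ΔG/kT)/(1 + e^(−ΔG/kT))` with
k = 0.0019872 kcal/(mol·K) and T = 300 K by default; 1.3 kcal/mol gives
10.2 %, i.e. a 1:10 inactive:active ratio at the nearest percent. (At
310 K the value is 10.8 %, which rounds to 11 % — the 1:10 reading is a
300 K statement.)

## MSA weighting and clades

"Within 40 % identity" is implemented as the standard DCA down-weighting:
`w_s = 1 / #{t : identity(s,t) ≥ 0.6}`, neighbourhood including self, so
Meff = Σw never exceeds N. Identity counts gaps as a 21st symbol over all
columns (the gaps-included convention; the threshold is configurable
because the phrase is ambiguous). Weighted marginals normalise per site and
per pair. Alignment filtering drops sequences gapped at the DFG-Asp column,
sequences with gap fraction above 0.25 (a conventional bound for "many
gaps"), and exact duplicates. Clade labels come from ordered conjunctive
column constraints shipped as editable data, defaulting to the catalytic
motif contrasts (TK: catalytic-base Arg at HRD+4 and Pro at APE−5; STK:
catalytic-base Lys at HRD+2) at the reference MSA numbering — real analyses
should supply columns matching their own alignment.

## Synthetic data: what it does and does not show

The generators exist so every stage can be tested against ground truth
known by construction:

- **Toy models**: sparse random coupling blocks, each projected to the
  zero-sum gauge, zero fields. A `sparsity` fraction of pairs is coupled at
  a chosen scale.
- **Two-basin ensembles**: one pseudo-sidechain bead (CB) per residue on a
  20 Å-spaced line; a planted contact moves a bead to 4 Å from its partner.
  Planted contact sets must form a matching (no column in two planted pairs)
  — this guarantees the requested contact graph is realized *exactly*, and
  anything else raises as geometrically unrealizable. Optional per-structure
  contact flips (known binomial effect on Δc) and random missing residues
  (exercising the per-pair denominators) are seeded and reproducible.
- **Scenarios**: default study conditions are three toy kinases, L = 16,
  four planted |Δc| = 1 contact changes with strong couplings, a wildtype
  drawn over non-excluded residues, closed-form true ΔΔT for the whole
  library, and the 3+3 most extreme *double* mutations selected — matching
  a design in which all tail selections are doubles, giving 18 doubles + 36
  constituent singles = 54 compared mutations and 108 core legs.
- **Simulated legs**: per-variant ground-truth free energies are planted so
  that ΔΔG_reorg is exactly `slope × ΔΔT` (default slope 1.3 kcal/mol per
  statistical-energy unit), then every leg receives independent Gaussian
  noise (default σ = 0.5 kcal/mol).

These toys validate the algebra, the bookkeeping, the file formats, and the
statistics — contact detection, gauge handling, sparse scan correctness,
exact cycle closure, slope/correlation recovery under noise. They do not
emulate real kinase geometry, MD dynamics, force-field error, sampling
nonconvergence, or a Potts model inferred from a real alignment; passing
tests therefore demonstrate the pipeline's correctness, not the physical
accuracy of any particular kinase model supplied to it.

## Numerical and scale choices

Energy and threading oracles agree with naive double loops to 1e-12; gauge
and closure identities to 1e-10; end-to-end planted-ΔΔT recovery through
structure files on disk to 1e-8 (deterministic ensembles). The default test
and acceptance runs use deliberately small problem sizes — L = 14–16
scenarios, 4–10 structures per basin, 10⁵ sampler draws, 200 regression
replicates — chosen as the smallest sizes at which each statistical check
has clear resolution; the scan itself vectorises per column and handles
10⁴–10⁵ mutations in seconds. Degenerate inputs fail loudly and early:
empty ensembles, never-co-resolved pairs, stale mutation lists
(wildtype-state mismatches), missing basin legs, and zero-variance
regressions all raise with the offending item named.
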