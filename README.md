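# kinothread

Threading Potts statistical energies over kinase conformational ensembles.

Protein kinases interconvert between an active conformation (DFG-in,
activation loop extended) and an autoinhibited inactive one (DFG-out,
activation loop folded). How strongly a given sequence prefers one basin over
the other is encoded both in its co-evolutionary couplings and in the
residue–residue contacts that break and form between the two ensembles.
`kinothread` is a toolkit for researchers in structural bioinformatics and
molecular modelling who want to score that preference from sequence, scan
mutations for the largest shifts, and reconcile the sequence-based
predictions with alchemical free-energy results.

## The method

Given a Potts model with couplings `J^ij_ab` over `L` aligned columns and
`q = 21` states (20 amino acids + gap), the statistical energy of an aligned
sequence `S` is

    E(S) = Σ_{i<j} J^ij_{S_i S_j} + Σ_i h^i_{S_i},

with `P(S) ∝ exp(−E(S))`. Threading restricts the pair sum to the contacts of
a structure (nearest sidechain heavy-atom distance < 6 Å), or weights it by
the contact frequency `c^ij` of an ensemble. With `Δc^ij = c^ij_A − c^ij_B`
between the active (A) and inactive (B) basins, the conformational preference
of a sequence is

    ΔT(S) = T_B(S) − T_A(S) = −Σ_{i<j} J^ij_{S_i S_j} · Δc^ij,

computed in the zero-mean gauge (each coupling block averages to zero; fields
do not contribute). Positive ΔT penalises the inactive basin. The mutational
shift ΔΔT(w→m) = ΔT(m) − ΔT(w) is the sequence-space analogue of

    ΔΔG_reorg = ΔG_B(w→m) − ΔG_A(w→m),

the change, upon mutation, of the free-energy cost of reorganising from
active to inactive, measured by alchemical mutation legs run in both basins.
The package covers the full workflow:

- **potts**: Potts model containers and I/O, energy evaluation, zero-mean
  gauge transform, single-site Metropolis sampling from `P(S)`.
- **contacts**: contact maps and per-pair-denominator contact frequencies
  from PDB/mmCIF snapshots with explicit residue→MSA-column maps.
- **conformers**: active/inactive basin assignment from external spatial/
  dihedral labels (DFG-in/BLAminus vs DFG-out/BBAminus) plus geometric
  filters (β3-Lys–αC-Glu salt bridge; extended, non-kinked glycine-rich
  loop).
- **threader / scan**: ΔT with per-pair decompositions, sparse ΔΔT, library
  enumeration under the eligibility rules (no G/P/W/H/C wildtype or target,
  |Δc| > 0.8 gate), tail selection.
- **cycles**: FEP job planning, three-path double-mutant cycle closure with
  hysteresis estimates, ΔΔG_reorg vs ΔΔT regression (the slope converts
  statistical-energy units to kcal/mol), Boltzmann population conversion.
- **msa**: alignment filtering, 40 %-identity down-weighting (Meff),
  weighted marginals, TK/STK clade labelling from editable rules.
- **synthetic**: toy Potts models, two-basin bead ensembles with planted Δc,
  and simulated alchemical legs with known ground truth.

## Worked example

Everything below runs on synthetic data with known ground truth:

```python
from kinothread import (make_scenario, make_two_basin_ensembles,
                        contact_frequencies, delta_contacts, delta_T,
                        run_scan, make_fep_legs, close_cycles,
                        compare_potts_fep)
from kinothread.cycles import WT
from kinothread.threader import MutationSpec

scn = make_scenario(seed=1, kinase="SYNK0", L=16, n_planted=4)
ensA, ensB, _ = make_two_basin_ensembles(16, 5, scn.planted_contact_changes,
                                         seed=2)
dc = delta_contacts(contact_frequencies(ensA), contact_frequencies(ensB))

print(round(delta_T(scn.model, scn.wildtype, dc).delta_T, 3))   # 2.027
table = run_scan(scn.model, scn.wildtype, scn.mutations, dc)
print(len(table))                                               # 896

pairs = []
for dbl in scn.selected:                 # 3+3 extreme double mutations
    singles = str(dbl).split("+")
    legs = [l for l in make_fep_legs(scn) if l.end == str(dbl)
            or (l.start == WT and l.end in singles)]
    res = close_cycles(legs)
    print(f"{dbl}  ddG = {res['double'].mean:+.2f} "
          f"+/- {res['double'].path_std:.2f}")
    mi, mj = (MutationSpec((s,)) for s in dbl.substitutions)
    pairs += [(scn.true_ddTs[dbl], res["double"].mean),
              (scn.true_ddTs[mi], res["single_i"].mean),
              (scn.true_ddTs[mj], res["single_j"].mean)]

fit = compare_potts_fep(pairs)
print(round(fit["pearson_r"], 3), round(fit["slope"], 3))
```

Output:

```
2.027
896
E6Q+E9L  ddG = -5.24 +/- 1.25
E6M+E9Q  ddG = -5.06 +/- 1.09
E6N+E9K  ddG = -3.82 +/- 1.20
Q8Y+F11N  ddG = +5.27 +/- 0.50
Q8E+F11N  ddG = +2.99 +/- 0.67
Q8K+F11L  ddG = +3.63 +/- 0.60
0.969 1.187
```

The wildtype ΔT of 2.027 says this toy sequence pays about two
statistical-energy units to occupy the inactive basin. The scan scores 896
candidate mutations; for the six most extreme double mutations, simulated
noisy alchemical legs are closed over the three thermodynamically equivalent
paths, giving a ΔΔG_reorg estimate with a hysteresis error bar each. The
regression of the 18 ΔΔG_reorg values on their ΔΔT recovers the planted
conversion factor of 1.3 kcal/mol per statistical-energy unit (fitted 1.19,
r = 0.97) despite 0.5 kcal/mol of leg noise.

The same stages are scriptable via the `kinothread` console command
(`gen`, `contacts`, `classify`, `thread`, `scan`, `select`, `plan`,
`cycles`, `compare`, `msa-weights`); every output is accompanied by a
`.prov.json` provenance record.

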