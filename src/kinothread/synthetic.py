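"""Synthetic inputs with known ground truth for every pipeline stage.

Generators for (i) sparse zero-mean-gauge toy Potts models, (ii) two-basin
bead-model structure ensembles whose contact-frequency difference Δc is known
by construction, (iii) complete scan scenarios with closed-form true ΔΔT
values, and (iv) simulated alchemical legs whose ground-truth ΔΔG_reorg is
linear in ΔΔT with additive Gaussian noise.  All generators are pure
functions of (parameters, seed).

Toy structures place one pseudo-sidechain bead (CB) per residue on a widely
spaced line (20 Å apart); a planted contact moves one bead to 4 Å from its
partner.  Because positions per basin are laid out independently, a planted
contact set is geometrically realizable exactly when it is a matching (no
column in two planted contacts of the same basin); anything else raises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contacts import DeltaContacts, MappedStructure, Residue
from .potts import ALPHABET, GAP, GAUGE_ZERO_MEAN, AlignedSequence, PottsModel
from .scan import ScanConfig, eligible_positions, enumerate_mutations
from .threader import MutationSpec, Substitution

__all__ = [
    "SyntheticScenario",
    "make_toy_model",
    "make_two_basin_ensembles",
    "make_scenario",
    "make_fep_legs",
    "naive_ddt",
    "write_ensemble_pdb",
]

CONTACT_OFFSET = 4.0   # Å between beads of a planted contact (< 6 Å cutoff)
SITE_SPACING = 20.0    # Å between base sites (>> cutoff)


# ---------------------------------------------------------------------------
# Toy Potts models
# ---------------------------------------------------------------------------

def _zero_sum_block(block: np.ndarray) -> np.ndarray:
    row = block.mean(axis=1, keepdims=True)
    col = block.mean(axis=0, keepdims=True)
    return block - row - col + block.mean()


def make_toy_model(L: int, q: int = 21, sparsity: float = 0.2,
                   coupling_scale: float = 1.0, seed: int = 0,
                   alphabet: str | None = None) -> PottsModel:
    """Sparse random Potts model in zero-mean gauge, reproducible from seed.

    ``sparsity`` is the fraction of position pairs that receive a random
    coupling block (each projected to the zero-sum gauge); the rest stay
    exactly zero.  Fields are zero.
    """
    if L < 2 or q < 2:
        raise ValueError("need L >= 2 and q >= 2")
    if not 0 <= sparsity <= 1:
        raise ValueError("sparsity must be in [0, 1]")
    alphabet = alphabet if alphabet is not None else ALPHABET[:q - 1] + GAP
    rng = np.random.default_rng(seed)
    model = PottsModel(L=L, q=q, alphabet=alphabet, gauge_tag=GAUGE_ZERO_MEAN)
    n_pairs = L * (L - 1) // 2
    mask = rng.random(n_pairs) < sparsity
    for p in np.nonzero(mask)[0]:
        block = rng.normal(scale=coupling_scale, size=(q, q))
        model.couplings[p] = _zero_sum_block(block)
    return model


# ---------------------------------------------------------------------------
# Two-basin bead ensembles
# ---------------------------------------------------------------------------

def _basin_contact_set(planted: dict, basin: str) -> set:
    k = 0 if basin == "A" else 1
    return {pair for pair, flags in planted.items() if flags[k]}


def _check_matching(contacts: set, basin: str) -> None:
    used = set()
    for (i, j) in contacts:
        if i in used or j in used:
            raise ValueError(
                f"planted contact set for basin {basin} is not a matching "
                f"(column reused); request is geometrically unrealizable"
            )
        used.add(i)
        used.add(j)


def _bead_structure(identifier: str, L: int, contacts: set,
                    missing: set) -> MappedStructure:
    pos = {c: np.array([SITE_SPACING * c, 0.0, 0.0]) for c in range(1, L + 1)}
    for (i, j) in contacts:
        pos[j] = pos[i] + np.array([CONTACT_OFFSET, 0.0, 0.0])
    residues = {}
    for c in range(1, L + 1):
        if c in missing:
            continue
        residues[c] = Residue(name="ALA", atoms={
            "CA": pos[c] + np.array([0.0, 1.5, 0.0]),
            "CB": pos[c].copy(),
        })
    return MappedStructure(identifier=identifier, chain="A",
                           residues=residues,
                           missing_columns=set(missing))


def make_two_basin_ensembles(L: int, n_per_basin: int,
                             planted_contact_changes: dict, seed: int = 0,
                             flip_prob: float = 0.0,
                             missing_prob: float = 0.0):
    """Toy active/inactive ensembles realizing a requested contact pattern.

    ``planted_contact_changes`` maps 1-based column pairs (i, j), i<j, to a
    pair of booleans (in_contact_in_A, in_contact_in_B).  Unlisted pairs are
    never in contact.  With ``flip_prob`` each planted pair's contact state
    is inverted independently per structure; with ``missing_prob`` residues
    are dropped so frequency denominators are exercised.  Returns
    ``(ensembleA, ensembleB, true_dc)`` where ``true_dc`` is the expected
    contact-frequency difference implied by the request (exact when both
    probabilities are zero), defined for every column pair.
    """
    if n_per_basin < 1:
        raise ValueError("n_per_basin must be >= 1")
    for (i, j) in planted_contact_changes:
        if not 1 <= i < j <= L:
            raise ValueError(f"planted pair ({i}, {j}) invalid for L={L}")
    base = {b: _basin_contact_set(planted_contact_changes, b) for b in "AB"}
    # the union must be a matching so any per-structure flip combination
    # stays realizable
    _check_matching(set(planted_contact_changes), "A∪B")

    rng = np.random.default_rng(seed)
    ensembles = {"A": [], "B": []}
    for basin in "AB":
        for n in range(n_per_basin):
            contacts = set()
            for pair, flags in planted_contact_changes.items():
                state = pair in base[basin]
                if flip_prob and rng.random() < flip_prob:
                    state = not state
                if state:
                    contacts.add(pair)
            missing = {c for c in range(1, L + 1)
                       if missing_prob and rng.random() < missing_prob}
            ensembles[basin].append(
                _bead_structure(f"{basin}{n:04d}", L, contacts, missing)
            )

    dc = {}
    for i in range(1, L + 1):
        for j in range(i + 1, L + 1):
            flags = planted_contact_changes.get((i, j))
            if flags is None:
                dc[(i, j)] = 0.0
            else:
                pA = (1 - flip_prob) if flags[0] else flip_prob
                pB = (1 - flip_prob) if flags[1] else flip_prob
                dc[(i, j)] = pA - pB
    return ensembles["A"], ensembles["B"], DeltaContacts(dc=dc)


def write_ensemble_pdb(out_dir, structures: list) -> list:
    """Write each bead structure as a PDB file (via gemmi); returns the paths."""
    import os

    import gemmi

    paths = []
    for st in structures:
        g = gemmi.Structure()
        g.name = st.identifier
        model = gemmi.Model("1")
        chain = gemmi.Chain(st.chain or "A")
        for col in st.columns:
            res = st.residues[col]
            r = gemmi.Residue()
            r.name = res.name
            r.seqid = gemmi.SeqId(col, " ")
            for atom_name, xyz in res.atoms.items():
                a = gemmi.Atom()
                a.name = atom_name
                a.pos = gemmi.Position(*map(float, xyz))
                a.element = gemmi.Element(atom_name[:1])
                a.occ = 1.0
                r.add_atom(a)
            chain.add_residue(r)
        model.add_chain(chain)
        g.add_model(model)
        path = os.path.join(str(out_dir), f"{st.identifier}.pdb")
        g.write_minimal_pdb(path)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Oracles and full scenarios
# ---------------------------------------------------------------------------

def naive_ddt(model: PottsModel, wt: AlignedSequence | str, mut: MutationSpec,
              dc: DeltaContacts) -> float:
    """Dense two-sequence ΔΔT oracle: -Σ_{i<j} (J_m - J_w)·dc over all pairs."""
    symbols = wt.symbols if isinstance(wt, AlignedSequence) else wt
    m_symbols = mut.apply(symbols)
    s_w = model.encode(symbols)
    s_m = model.encode(m_symbols)
    total = 0.0
    for (i, j), d in dc.dc.items():
        blk = model.J(i - 1, j - 1)
        total += -(blk[s_m[i - 1], s_m[j - 1]] - blk[s_w[i - 1], s_w[j - 1]]) * d
    return float(total)


@dataclass
class SyntheticScenario:
    """One synthetic kinase with ground truth for scan + cycle analysis."""

    seed: int
    kinase: str
    model: PottsModel
    wildtype: AlignedSequence
    planted_dc: DeltaContacts
    planted_contact_changes: dict
    scan_cfg: ScanConfig
    mutations: list               # full enumerated library
    true_ddTs: dict               # MutationSpec -> closed-form ΔΔT
    selected: list                # 3+3 extreme double mutations
    fep_slope: float = 1.3
    fep_noise_sd: float = 0.5


def make_scenario(seed: int, kinase: str = "SYNK", L: int = 20, q: int = 21,
                  n_planted: int = 6, coupling_scale: float = 1.0,
                  background_sparsity: float = 0.15,
                  fep_slope: float = 1.3, fep_noise_sd: float = 0.5,
                  scan_cfg: ScanConfig | None = None) -> SyntheticScenario:
    """Build a complete synthetic study for one toy kinase.

    ``n_planted`` disjoint column pairs receive |Δc| = 1 contact changes
    (alternating contact-in-A-only / contact-in-B-only) and strong coupling
    blocks, guaranteeing eligible positions and large double-mutant effects;
    the wildtype is a random sequence over non-excluded residues.  True ΔΔT
    values for the whole mutation library come from the dense closed form,
    and the 3 most-negative plus 3 most-positive *double* mutations are
    selected for the simulated free-energy follow-up (matching the design in
    which all tail selections are doubles).
    """
    scan_cfg = scan_cfg or ScanConfig()
    if 2 * n_planted > L:
        raise ValueError("need L >= 2*n_planted disjoint planted columns")
    rng = np.random.default_rng(seed)
    model = make_toy_model(L, q, sparsity=background_sparsity,
                           coupling_scale=0.3 * coupling_scale, seed=seed)

    cols = rng.permutation(np.arange(1, L + 1))[:2 * n_planted]
    planted = {}
    for k in range(n_planted):
        i, j = sorted((int(cols[2 * k]), int(cols[2 * k + 1])))
        planted[(i, j)] = (k % 2 == 0, k % 2 == 1)
        block = rng.normal(scale=coupling_scale, size=(q, q))
        model.set_J(i - 1, j - 1, _zero_sum_block(block))

    dc = {}
    for i in range(1, L + 1):
        for j in range(i + 1, L + 1):
            flags = planted.get((i, j))
            dc[(i, j)] = 0.0 if flags is None else (
                (1.0 if flags[0] else 0.0) - (1.0 if flags[1] else 0.0)
            )
    planted_dc = DeltaContacts(dc=dc)

    allowed = [a for a in model.alphabet
               if a != GAP and a not in scan_cfg.excluded_residues]
    wt = AlignedSequence("".join(rng.choice(allowed, size=L)),
                         identifier=f"{kinase}_wt")

    eligible = eligible_positions(wt, planted_dc, scan_cfg)
    mutations = enumerate_mutations(wt, eligible, planted_dc, scan_cfg,
                                    model.alphabet)
    true_ddTs = {m: naive_ddt(model, wt, m, planted_dc) for m in mutations}

    doubles = [(m, v) for m, v in true_ddTs.items()
               if len(m.substitutions) == 2]
    doubles.sort(key=lambda r: (r[1], r[0].sort_key()))
    selected = ([m for m, _ in doubles[:3]]
                + [m for m, _ in sorted(doubles[-3:],
                                        key=lambda r: (-r[1], r[0].sort_key()))])

    return SyntheticScenario(
        seed=seed, kinase=kinase, model=model, wildtype=wt,
        planted_dc=planted_dc, planted_contact_changes=planted,
        scan_cfg=scan_cfg, mutations=mutations, true_ddTs=true_ddTs,
        selected=selected, fep_slope=fep_slope, fep_noise_sd=fep_noise_sd,
    )


def _single_specs(double: MutationSpec) -> tuple:
    si, sj = double.substitutions
    return MutationSpec((si,)), MutationSpec((sj,))


def make_fep_legs(scenario: SyntheticScenario, include_closure: bool = True,
                  noise_sd: float | None = None, seed: int | None = None) -> list:
    """Simulated alchemical legs whose true ΔΔG_reorg is slope × ΔΔT.

    Per selected double mutation, a per-variant ground-truth free energy is
    planted (basin A flat, basin B shifted by slope·ΔΔT of the variant), and
    every core leg (w→i, w→j, w→ij per basin) plus, optionally, closure legs
    (i→ij, j→ij per basin) is emitted with independent Gaussian noise of
    standard deviation ``noise_sd`` (default: the scenario's).  Seeded and
    reproducible.
    """
    from .cycles import WT, AlchemicalLeg

    sd = scenario.fep_noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(scenario.seed + 7919 if seed is None else seed)
    legs = []
    for double in scenario.selected:
        mi, mj = _single_specs(double)
        gtrue = {WT: 0.0}
        for spec, lab in ((mi, str(mi)), (mj, str(mj)), (double, str(double))):
            ddt = scenario.true_ddTs.get(spec)
            if ddt is None:
                ddt = naive_ddt(scenario.model, scenario.wildtype, spec,
                                scenario.planted_dc)
            gtrue[lab] = scenario.fep_slope * ddt
        pairs = [(WT, str(mi)), (WT, str(mj)), (WT, str(double))]
        if include_closure:
            pairs += [(str(mi), str(double)), (str(mj), str(double))]
        for basin in ("A", "B"):
            for start, end in pairs:
                truth = (gtrue[end] - gtrue[start]) if basin == "B" else 0.0
                noise = rng.normal(scale=sd) if sd > 0 else 0.0
                legs.append(AlchemicalLeg(
                    kinase=scenario.kinase, basin=basin, start=start, end=end,
                    dg=truth + noise, dg_err=sd,
                ))
    return legs
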