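"""Contact geometry, per-structure maps, and ensemble frequencies."""

import numpy as np
import pytest

from kinothread import (
    MappedStructure,
    Residue,
    contact_frequencies,
    contact_map,
    delta_contacts,
    sidechain_min_distance,
)
from kinothread.contacts import (
    ContactFrequencies,
    read_frequencies_tsv,
    write_frequencies_tsv,
)
from kinothread.synthetic import make_two_basin_ensembles


def bead(name="ALA", **atoms):
    return Residue(name=name, atoms={k: np.asarray(v, float)
                                     for k, v in atoms.items()})


def chain(positions, missing=()):
    """1-bead-per-residue structure; positions maps column -> CB coordinate."""
    residues = {c: bead(CB=p) for c, p in positions.items()}
    return MappedStructure(identifier="toy", chain="A", residues=residues,
                           missing_columns=set(missing))


class TestSidechainMinDistance:
    def test_two_single_atom_sidechains(self):
        a = bead(CB=[0, 0, 0])
        b = bead(CB=[5.0, 0, 0])
        assert sidechain_min_distance(a, b) == pytest.approx(5.0)

    def test_minimum_over_atom_pairs(self):
        a = bead(CB=[0, 0, 0], CG=[1.0, 0, 0])
        b = bead(CB=[10.0, 0, 0], CG1=[4.2, 0, 0])
        assert sidechain_min_distance(a, b) == pytest.approx(3.2)

    def test_backbone_atoms_excluded(self):
        a = bead(N=[0, 0, 0], CA=[1, 0, 0], C=[2, 0, 0], O=[3, 0, 0],
                 CB=[0, 10, 0])
        b = bead(CB=[0, 0, 0])
        # nearest backbone atom is 0 A away but only CB counts
        assert sidechain_min_distance(a, b) == pytest.approx(10.0)

    def test_glycine_uses_ca_proxy(self):
        gly = bead(name="GLY", N=[9, 0, 0], CA=[3.0, 0, 0], C=[9, 1, 0],
                   O=[9, 2, 0])
        other = bead(CB=[0, 0, 0])
        assert sidechain_min_distance(gly, other) == pytest.approx(3.0)

    def test_matches_brute_force_all_pairs(self, rng):
        for _ in range(50):
            na, nb = rng.integers(1, 6, size=2)
            a = Residue("X", {f"C{k}": rng.normal(size=3) * 10
                              for k in range(na)})
            b = Residue("Y", {f"S{k}": rng.normal(size=3) * 10
                              for k in range(nb)})
            brute = min(
                np.linalg.norm(p - q)
                for p in a.atoms.values() for q in b.atoms.values()
            )
            assert sidechain_min_distance(a, b) == pytest.approx(brute,
                                                                 abs=1e-12)


class TestContactMap:
    def test_strict_cutoff_boundary(self):
        st = chain({1: [0, 0, 0], 2: [5.999, 0, 0], 3: [12.0, 0, 0]})
        cmap = contact_map(st, cutoff=6.0)
        assert (1, 2) in cmap.pairs
        st2 = chain({1: [0, 0, 0], 2: [6.0, 0, 0]})
        assert contact_map(st2, cutoff=6.0).pairs == set()

    def test_planted_contacts_recovered(self):
        # 6 residues, exactly 3 close pairs by construction
        st = chain({1: [0, 0, 0], 2: [3, 0, 0], 3: [50, 0, 0],
                    4: [53, 0, 0], 5: [100, 0, 0], 6: [104, 0, 0]})
        assert contact_map(st).pairs == {(1, 2), (3, 4), (5, 6)}

    def test_missing_column_excluded(self):
        st = chain({1: [0, 0, 0], 2: [3, 0, 0]}, missing=(4,))
        assert all(4 not in p for p in contact_map(st).pairs)

    def test_symmetry_of_membership(self):
        st = chain({1: [0, 0, 0], 2: [3, 0, 0]})
        cmap = contact_map(st)
        assert (1, 2) in cmap and (2, 1) in cmap

    def test_cutoff_monotonicity(self, rng):
        st = chain({c: rng.normal(size=3) * 8 for c in range(1, 9)})
        small = contact_map(st, cutoff=4.0).pairs
        large = contact_map(st, cutoff=9.0).pairs
        assert small <= large

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError, match="no mapped residues"):
            contact_map(MappedStructure("e", "A", {}))


class TestContactFrequencies:
    def test_constant_ensemble_equals_indicator(self):
        st = chain({1: [0, 0, 0], 2: [3, 0, 0], 3: [30, 0, 0]})
        cf = contact_frequencies([st] * 10)
        assert cf.freq[(1, 2)] == 1.0
        assert cf.freq[(1, 3)] == 0.0
        assert all(c == 10 for c in cf.count.values())

    def test_per_pair_denominator_excludes_missing(self):
        near = chain({1: [0, 0, 0], 2: [3, 0, 0]})
        far = chain({1: [0, 0, 0], 2: [30, 0, 0]})
        absent = chain({1: [0, 0, 0]}, missing=(2,))
        ens = [near, near, near, far, far, absent, absent]
        cf = contact_frequencies(ens)
        assert cf.count[(1, 2)] == 5
        assert cf.freq[(1, 2)] == pytest.approx(3 / 5)

    def test_never_coresolved_pair_absent_not_zero(self):
        a = chain({1: [0, 0, 0]}, missing=(2,))
        b = chain({2: [0, 0, 0]}, missing=(1,))
        cf = contact_frequencies([a, b])
        assert (1, 2) not in cf.freq

    def test_matches_naive_recount(self, rng):
        ens = []
        for _ in range(20):
            cols = [c for c in range(1, 7) if rng.random() > 0.2]
            ens.append(chain({c: rng.normal(size=3) * 6 for c in cols}))
        cf = contact_frequencies(ens, cutoff=6.0)
        # independent recount
        for (i, j), f in cf.freq.items():
            hits = denom = 0
            for st in ens:
                if i in st.residues and j in st.residues:
                    denom += 1
                    d = np.linalg.norm(st.residues[i].atoms["CB"]
                                       - st.residues[j].atoms["CB"])
                    if d < 6.0:
                        hits += 1
            assert cf.count[(i, j)] == denom
            assert f == pytest.approx(hits / denom, abs=1e-15)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            contact_frequencies([])

    def test_tsv_roundtrip(self, tmp_path):
        cf = ContactFrequencies(freq={(1, 2): 0.6, (2, 3): 0.0},
                                count={(1, 2): 5, (2, 3): 7},
                                n_structures=7, L=3)
        p = tmp_path / "cf.tsv"
        write_frequencies_tsv(p, cf)
        back = read_frequencies_tsv(p)
        assert back.freq == cf.freq and back.count == cf.count
        assert back.n_structures == 7 and back.L == 3


class TestDeltaContacts:
    def test_identical_basins_give_zero(self):
        cf = ContactFrequencies(freq={(1, 2): 0.4}, count={(1, 2): 5},
                                n_structures=5)
        dc = delta_contacts(cf, cf)
        assert dc.dc == {(1, 2): 0.0}

    def test_planted_one_sided_contact(self):
        ensA, ensB, true_dc = make_two_basin_ensembles(
            L=6, n_per_basin=4, planted_contact_changes={(2, 5): (True, False)},
            seed=0)
        dc = delta_contacts(contact_frequencies(ensA),
                            contact_frequencies(ensB))
        assert dc.get(2, 5) == pytest.approx(1.0)
        assert dc.get(5, 2) == pytest.approx(1.0)  # unordered access

    def test_elementwise_subtraction_oracle(self, rng):
        pairs = [(i, j) for i in range(1, 6) for j in range(i + 1, 6)]
        fa = {p: rng.random() for p in pairs}
        fb = {p: rng.random() for p in pairs}
        cfa = ContactFrequencies(freq=fa, count={p: 3 for p in pairs},
                                 n_structures=3)
        cfb = ContactFrequencies(freq=fb, count={p: 3 for p in pairs},
                                 n_structures=3)
        dc = delta_contacts(cfa, cfb)
        for p in pairs:
            assert dc.dc[p] == pytest.approx(fa[p] - fb[p], abs=1e-15)

    def test_one_sided_pairs_dropped(self):
        cfa = ContactFrequencies(freq={(1, 2): 1.0, (1, 3): 0.5},
                                 count={(1, 2): 2, (1, 3): 2}, n_structures=2)
        cfb = ContactFrequencies(freq={(1, 2): 0.0},
                                 count={(1, 2): 2}, n_structures=2)
        assert set(delta_contacts(cfa, cfb).dc) == {(1, 2)}

    def test_length_mismatch_rejected(self):
        cfa = ContactFrequencies(freq={}, count={}, n_structures=1, L=5)
        cfb = ContactFrequencies(freq={}, count={}, n_structures=1, L=6)
        with pytest.raises(ValueError, match="length mismatch"):
            delta_contacts(cfa, cfb)
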