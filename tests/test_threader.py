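"""Threading, ΔT sign convention, and sparse ΔΔT evaluation."""

import numpy as np
import pytest

from kinothread import (
    AlignedSequence,
    ContactFrequencies,
    ContactMap,
    DeltaContacts,
    MutationSpec,
    PottsModel,
    Substitution,
    contact_frequencies,
    delta_contacts,
    delta_delta_T,
    delta_T,
    pair_decomposition,
    thread_basins,
    thread_ensemble,
    thread_structure,
)
from kinothread.synthetic import make_toy_model, make_two_basin_ensembles, naive_ddt

from conftest import random_sequence


def random_dc(L, rng, density=0.6):
    dc = {}
    for i in range(1, L + 1):
        for j in range(i + 1, L + 1):
            if rng.random() < density:
                dc[(i, j)] = float(rng.uniform(-1, 1))
    return DeltaContacts(dc=dc)


class TestThreadStructure:
    def test_empty_contact_map(self, small_model):
        assert thread_structure(small_model, random_sequence(
            small_model, np.random.default_rng(0)), ContactMap(set())) == 0.0

    def test_single_contact_reads_coupling(self):
        m = make_toy_model(L=3, q=3, sparsity=0.0, seed=0)
        # zero-mean block with J[A,A] = -0.7
        m.set_J(0, 1, np.array([[-0.7, 0.35, 0.35],
                                [0.35, -0.175, -0.175],
                                [0.35, -0.175, -0.175]]))
        seq = m.alphabet[0] * 3
        t = thread_structure(m, seq, ContactMap({(1, 2)}))
        assert t == pytest.approx(-0.7)

    def test_matches_naive_loop(self, small_model, rng):
        cmap = ContactMap({(i, j) for i in range(1, 7) for j in range(i + 1, 7)
                           if rng.random() < 0.5})
        for _ in range(10):
            seq = random_sequence(small_model, rng)
            s = small_model.encode(seq.symbols)
            naive = sum(small_model.J(i - 1, j - 1)[s[i - 1], s[j - 1]]
                        for (i, j) in cmap.pairs)
            assert thread_structure(small_model, seq, cmap) == pytest.approx(
                naive, abs=1e-12)

    def test_non_zero_mean_model_rejected(self, rng):
        m = PottsModel(L=3, q=3, alphabet="AC-",
                       couplings=rng.normal(size=(3, 3, 3)) + 1.0)
        with pytest.raises(ValueError, match="zero-mean"):
            thread_structure(m, "AAA", ContactMap({(1, 2)}))


class TestThreadEnsemble:
    def test_zero_frequencies(self, small_model, rng):
        cf = ContactFrequencies(freq={(1, 2): 0.0}, count={(1, 2): 3},
                                n_structures=3)
        assert thread_ensemble(small_model, random_sequence(small_model, rng),
                               cf) == 0.0

    def test_single_structure_consistency(self, small_model, rng):
        cmap = ContactMap({(1, 3), (2, 5), (4, 6)})
        cf = ContactFrequencies(
            freq={p: (1.0 if p in cmap.pairs else 0.0)
                  for p in [(i, j) for i in range(1, 7)
                            for j in range(i + 1, 7)]},
            count={(i, j): 1 for i in range(1, 7) for j in range(i + 1, 7)},
            n_structures=1)
        seq = random_sequence(small_model, rng)
        assert thread_ensemble(small_model, seq, cf) == pytest.approx(
            thread_structure(small_model, seq, cmap), abs=1e-12)

    def test_linearity_over_ensemble(self, rng):
        """Frequency-threading equals the mean of per-structure energies."""
        L = 8
        m = make_toy_model(L=L, q=4, sparsity=0.7, seed=5)
        planted = {(1, 4): (True, False), (2, 6): (True, True),
                   (3, 7): (False, True)}
        ensA, _, _ = make_two_basin_ensembles(L, 15, planted, seed=3,
                                              flip_prob=0.3)
        cf = contact_frequencies(ensA)
        from kinothread.contacts import contact_map

        seq = random_sequence(m, rng)
        per_structure = [thread_structure(m, seq, contact_map(st))
                         for st in ensA]
        assert thread_ensemble(m, seq, cf) == pytest.approx(
            np.mean(per_structure), abs=1e-10)


class TestDeltaT:
    def test_zero_dc(self, small_model, rng):
        res = delta_T(small_model, random_sequence(small_model, rng),
                      DeltaContacts(dc={(1, 2): 0.0}))
        assert res.delta_T == 0.0

    def test_sign_convention_contact_only_in_active(self):
        """dc=+1 with favourable (negative) coupling penalises basin B."""
        m = make_toy_model(L=3, q=3, sparsity=0.0, seed=0)
        m.set_J(0, 1, np.array([[-0.5, 0.25, 0.25],
                                [0.25, -0.125, -0.125],
                                [0.25, -0.125, -0.125]]))
        res = delta_T(m, m.alphabet[0] * 3, DeltaContacts(dc={(1, 2): 1.0}))
        assert res.delta_T == pytest.approx(+0.5)

    def test_two_route_consistency(self, rng):
        """ΔT from dc equals T_B - T_A from the two frequency tables."""
        for trial in range(20):
            L = 7
            m = make_toy_model(L=L, q=4, sparsity=0.8, seed=100 + trial)
            pairs = [(i, j) for i in range(1, L + 1)
                     for j in range(i + 1, L + 1)]
            fa = {p: float(rng.random()) for p in pairs}
            fb = {p: float(rng.random()) for p in pairs}
            cfa = ContactFrequencies(freq=fa, count={p: 4 for p in pairs},
                                     n_structures=4)
            cfb = ContactFrequencies(freq=fb, count={p: 4 for p in pairs},
                                     n_structures=4)
            seq = random_sequence(m, rng)
            res = thread_basins(m, seq, cfa, cfb)
            assert res.delta_T == pytest.approx(res.T_B - res.T_A, abs=1e-10)

    def test_contributions_sum_to_delta_T(self, small_model, rng):
        dc = random_dc(6, rng)
        res = delta_T(small_model, random_sequence(small_model, rng), dc)
        assert sum(v for _, _, v in res.contributions) == pytest.approx(
            res.delta_T, abs=1e-12)


class TestDeltaDeltaT:
    def wt(self, model, rng):
        return random_sequence(model, rng)

    def spec_for(self, model, wt, col, rng, avoid=None):
        avoid = avoid or set()
        choices = [a for a in model.alphabet
                   if a != wt.symbols[col - 1] and a not in avoid]
        return Substitution(col, wt.symbols[col - 1],
                            str(rng.choice(choices)))

    def test_mutation_at_inert_column_is_zero(self, small_model, rng):
        dc = DeltaContacts(dc={(1, 2): 0.8, (2, 3): -0.4})
        wt = self.wt(small_model, rng)
        sub = self.spec_for(small_model, wt, 5, rng)  # column 5 not in dc
        assert delta_delta_T(small_model, wt, MutationSpec((sub,)),
                             dc) == 0.0

    def test_sparse_equals_dense_recompute(self, rng):
        for trial in range(30):
            L = 8
            m = make_toy_model(L=L, q=5, sparsity=0.7, seed=trial)
            dc = random_dc(L, rng)
            wt = random_sequence(m, rng)
            cols = rng.choice(np.arange(1, L + 1), size=2, replace=False)
            subs = tuple(self.spec_for(m, wt, int(c), rng) for c in cols)
            for spec in (MutationSpec(subs[:1]), MutationSpec(subs)):
                sparse = delta_delta_T(m, wt, spec, dc)
                dense = naive_ddt(m, wt, spec, dc)
                assert sparse == pytest.approx(dense, abs=1e-12)

    def test_antisymmetry(self, rng):
        m = make_toy_model(L=6, q=4, sparsity=0.8, seed=9)
        dc = random_dc(6, rng)
        wt = random_sequence(m, rng)
        sub = self.spec_for(m, wt, 2, rng)
        spec = MutationSpec((sub,))
        fwd = delta_delta_T(m, wt, spec, dc)
        mut_seq = AlignedSequence(spec.apply(wt.symbols))
        back = delta_delta_T(m, mut_seq, spec.reversed(), dc)
        assert fwd == pytest.approx(-back, abs=1e-12)

    def test_double_additivity_boundary(self, rng):
        """Doubles are non-additive in general, additive when J[i][j] = 0."""
        L = 5
        m = make_toy_model(L=L, q=4, sparsity=0.0, seed=1)
        # couple (0,1) strongly; dc on all pairs
        rngl = np.random.default_rng(3)
        blk = rngl.normal(size=(4, 4))
        blk = blk - blk.mean(axis=1, keepdims=True) \
            - blk.mean(axis=0, keepdims=True) + blk.mean()
        m.set_J(0, 1, blk)
        dc = DeltaContacts(dc={(i, j): 1.0 for i in range(1, L + 1)
                               for j in range(i + 1, L + 1)})
        wt = random_sequence(m, rng)
        s1 = self.spec_for(m, wt, 1, rng)
        s2 = self.spec_for(m, wt, 2, rng)
        both = delta_delta_T(m, wt, MutationSpec((s1, s2)), dc)
        sum_singles = (delta_delta_T(m, wt, MutationSpec((s1,)), dc)
                       + delta_delta_T(m, wt, MutationSpec((s2,)), dc))
        assert both != pytest.approx(sum_singles, abs=1e-9)
        # uncoupled columns: additivity holds
        s4 = self.spec_for(m, wt, 4, rng)
        both2 = delta_delta_T(m, wt, MutationSpec((s1, s4)), dc)
        sum2 = (delta_delta_T(m, wt, MutationSpec((s1,)), dc)
                + delta_delta_T(m, wt, MutationSpec((s4,)), dc))
        assert both2 == pytest.approx(sum2, abs=1e-12)

    def test_stale_wildtype_state_rejected(self, small_model, rng):
        wt = self.wt(small_model, rng)
        wrong_from = next(a for a in small_model.alphabet
                          if a != wt.symbols[0])
        spec = MutationSpec((Substitution(1, wrong_from,
                                          wt.symbols[0]),))
        with pytest.raises(ValueError, match="wildtype state"):
            delta_delta_T(small_model, wt, spec,
                          DeltaContacts(dc={(1, 2): 1.0}))


class TestPairDecomposition:
    def test_single_pair_ranked_first_and_conserved(self, small_model, rng):
        dc = DeltaContacts(dc={(1, 2): 1.0, (3, 4): 0.01})
        res = delta_T(small_model, random_sequence(small_model, rng), dc)
        ranked = pair_decomposition(res)
        assert abs(ranked[0][2]) >= abs(ranked[-1][2])
        assert sum(v for _, _, v in ranked) == pytest.approx(res.delta_T)

    def test_planted_dominant_coupling_rank_one(self, rng):
        m = make_toy_model(L=6, q=4, sparsity=0.3, coupling_scale=0.1, seed=4)
        big = np.zeros((4, 4))
        big[0, 0] = -8.0
        big = big - big.mean(axis=1, keepdims=True) \
            - big.mean(axis=0, keepdims=True) + big.mean()
        m.set_J(1, 4, big)
        seq = m.alphabet[0] * 6
        dc = DeltaContacts(dc={(i, j): 1.0 for i in range(1, 7)
                               for j in range(i + 1, 7)})
        ranked = pair_decomposition(delta_T(m, seq, dc), top_k=1)
        assert ranked[0][:2] == (2, 5)

    def test_deterministic_tie_break(self):
        res = delta_T(
            make_toy_model(L=4, q=3, sparsity=0.0, seed=0), "AAAA"[:4],
            DeltaContacts(dc={(1, 2): 1.0, (3, 4): 1.0}))
        ranked = pair_decomposition(res)
        assert ranked[0][:2] == (1, 2)  # equal (zero) values: (i, j) order
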