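"""DCA pipeline: weighting, Potts fitting, scoring, matching, SASA filter."""

import math

import numpy as np
import pytest

from chapdock.coevolution import (
    AVERAGE_RESIDUE_SASA,
    apc_correct,
    compute_sasa,
    empirical_interprotein_score,
    fit_plm,
    frobenius_scores,
    normalize_scores,
    random_match,
    sasa_filter,
    selection_frequencies,
    sequence_weights,
)
from chapdock.structures import ContactPrediction, FamilyMSA, PairedMSA

from conftest import make_fullatom_residue_pdb

Q = 21


def paired(seqs, boundary, orgs=None):
    seqs = np.asarray(seqs, dtype=np.int8)
    if orgs is None:
        orgs = np.array(["o"] * len(seqs))
    return PairedMSA(sequences=seqs, boundary=boundary, organism_ids=orgs)


class TestSequenceWeights:
    def test_all_distinct_rows_weigh_one(self):
        rng = np.random.default_rng(0)
        msa = paired(rng.integers(0, Q, size=(30, 20)), 10)
        w, neff = sequence_weights(msa)
        assert np.allclose(w, 1.0)
        assert neff == pytest.approx(30.0)

    def test_duplicated_row_shares_weight(self):
        rng = np.random.default_rng(1)
        base = rng.integers(0, Q, size=(6, 20))
        seqs = np.vstack([base, np.tile(base[0], (3, 1))])  # row 0 appears 4×
        msa = paired(seqs, 10)
        w, neff = sequence_weights(msa)
        assert w[0] == pytest.approx(0.25)
        assert np.allclose(w[-3:], 0.25)
        assert np.allclose(w[1:6], 1.0)
        assert neff == pytest.approx(6.0)

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(2)
        # low-cardinality alphabet so near-duplicates actually occur
        seqs = rng.integers(0, 3, size=(120, 12))
        msa = paired(seqs, 6)
        w, _ = sequence_weights(msa, identity_threshold=0.8)
        for i in range(120):
            count = sum(
                np.mean(seqs[i] == seqs[j]) >= 0.8 for j in range(120))
            assert w[i] == pytest.approx(1.0 / count)

    def test_row_duplication_leaves_neff_unchanged(self):
        rng = np.random.default_rng(3)
        seqs = rng.integers(0, Q, size=(25, 16))
        _, neff1 = sequence_weights(paired(seqs, 8))
        _, neff2 = sequence_weights(paired(np.vstack([seqs, seqs]), 8))
        assert neff2 == pytest.approx(neff1)


class TestFitPlm:
    def test_identical_rows_carry_no_covariation_signal(self):
        # fully conserved columns: whatever apparent coupling strength the
        # conditional fits absorb is uniform across pairs (pure positional
        # bias), so the APC-corrected scores vanish
        seqs = np.tile(np.arange(8) % Q, (40, 1))
        msa = paired(seqs, 4)
        model = fit_plm(msa)
        s_raw = frobenius_scores(model)
        off_diag = s_raw[~np.eye(8, dtype=bool)]
        assert off_diag.std() < 1e-6 * max(off_diag.mean(), 1e-12)
        s = apc_correct(s_raw, 4)
        assert np.abs(s[:4, 4:]).max() < 1e-6

    def test_independent_columns_below_permutation_null(self):
        rng = np.random.default_rng(7)
        m = 800
        seqs = rng.integers(0, Q, size=(m, 6))
        msa = paired(seqs.copy(), 3)
        s_obs = apc_correct(frobenius_scores(fit_plm(msa)), 3)[:3, 3:]
        null_max = []
        for k in range(5):
            perm = seqs.copy()
            perm[:, 3:] = perm[rng.permutation(m), 3:]
            s_null = apc_correct(
                frobenius_scores(fit_plm(paired(perm, 3))), 3)[:3, 3:]
            null_max.append(np.abs(s_null).max())
        thresh = np.mean(null_max) + 3 * np.std(null_max, ddof=1)
        assert np.abs(s_obs).max() < max(thresh, 0.05)

    def test_planted_coupling_tops_scores_and_matches_mf_oracle(
            self, planted_families):
        fam_a, fam_b, truth = planted_families
        msa = random_match(fam_a, fam_b, seed=0)
        sequence_weights(msa)
        model = fit_plm(msa)
        s = apc_correct(frobenius_scores(model), msa.boundary)
        inter = s[:msa.boundary, msa.boundary:]
        planted = {(i, j) for i, j in truth["planted_pairs"]}
        top = {tuple(map(int, np.unravel_index(k, inter.shape)))
               for k in np.argsort(inter.ravel())[::-1][:len(planted)]}
        assert top == planted

        # independent mean-field (covariance-inversion) oracle finds the
        # same planted pairs
        mf_inter = _mean_field_scores(msa)
        mf_top = {tuple(map(int, np.unravel_index(k, mf_inter.shape)))
                  for k in np.argsort(mf_inter.ravel())[::-1][:len(planted)]}
        assert mf_top == planted


def _mean_field_scores(msa: PairedMSA) -> np.ndarray:
    """Naive mean-field DCA (pseudocount + covariance inversion) as an
    independent cross-check; returns the APC-corrected inter block."""
    seqs = msa.sequences
    m, n = seqs.shape
    q = Q - 1                                   # drop one state for gauge
    x = np.zeros((m, n * q))
    for j in range(n):
        for a in range(q):
            x[:, j * q + a] = seqs[:, j] == a + 1
    pc = 0.5
    f = (x.sum(axis=0) + pc) / (m + pc * 2)
    c = (x.T @ x) / m - np.outer(x.mean(axis=0), x.mean(axis=0))
    c += np.eye(n * q) * 1e-2                    # ridge, keeps inversion stable
    jmat = -np.linalg.inv(c)
    s = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                block = jmat[i * q:(i + 1) * q, j * q:(j + 1) * q]
                s[i, j] = np.sqrt(np.sum(block ** 2))
    s = 0.5 * (s + s.T)
    return apc_correct(s, msa.boundary)[:msa.boundary, msa.boundary:]


class TestScores:
    def test_zero_couplings_zero_scores(self):
        from chapdock.coevolution import PottsModel
        model = PottsModel(J=np.zeros((5, 5, Q, Q)), h=np.zeros((5, Q)),
                           lambda_J=0.01, lambda_h=0.01)
        assert np.all(frobenius_scores(model) == 0.0)

    def test_frobenius_equals_direct_recomputation(self):
        from chapdock.coevolution import PottsModel, zero_sum_gauge
        rng = np.random.default_rng(9)
        j = rng.normal(size=(4, 4, Q, Q))
        j = 0.5 * (j + np.transpose(j, (1, 0, 3, 2)))
        for i in range(4):
            j[i, i] = 0.0
        model = PottsModel(J=j, h=np.zeros((4, Q)), lambda_J=0, lambda_h=0)
        s = frobenius_scores(model)
        for a in range(4):
            for b in range(4):
                if a == b:
                    assert s[a, b] == 0.0
                    continue
                expected = math.sqrt(np.sum(zero_sum_gauge(j[a, b]) ** 2))
                assert s[a, b] == pytest.approx(expected, rel=1e-12)

    def test_frobenius_invariant_under_gauge_shifts(self):
        from chapdock.coevolution import PottsModel
        rng = np.random.default_rng(10)
        j = rng.normal(size=(3, 3, Q, Q))
        j = 0.5 * (j + np.transpose(j, (1, 0, 3, 2)))
        for i in range(3):
            j[i, i] = 0.0
        s0 = frobenius_scores(PottsModel(j, np.zeros((3, Q)), 0, 0))
        # add row/column shifts, which the zero-sum gauge must remove
        shifted = j.copy()
        shifted[0, 1] += rng.normal(size=(Q, 1))    # row shift
        shifted[0, 1] += rng.normal(size=(1, Q))    # column shift
        shifted[1, 0] = shifted[0, 1].T
        s1 = frobenius_scores(PottsModel(shifted, np.zeros((3, Q)), 0, 0))
        assert s1[0, 1] == pytest.approx(s0[0, 1], rel=1e-9)

    def test_apc_uniform_inter_block_cancels_exactly(self):
        n_a, n_b = 4, 6
        s = np.zeros((n_a + n_b, n_a + n_b))
        s[:n_a, n_a:] = 0.7
        s[n_a:, :n_a] = 0.7
        corrected = apc_correct(s, n_a)
        assert np.allclose(corrected[:n_a, n_a:], 0.0, atol=1e-14)

    def test_apc_one_by_one_inter_block_zero(self):
        s = np.array([[0.0, 0.9], [0.9, 0.0]])
        corrected = apc_correct(s, 1)
        assert corrected[0, 1] == 0.0

    def test_apc_matches_direct_recomputation_6x8(self):
        rng = np.random.default_rng(11)
        n_a, n_b = 6, 8
        n = n_a + n_b
        s = np.abs(rng.normal(size=(n, n)))
        s = 0.5 * (s + s.T)
        np.fill_diagonal(s, 0.0)
        corrected = apc_correct(s, n_a)
        block = s[:n_a, n_a:]
        for i in range(n_a):
            for j in range(n_b):
                expected = (block[i, j]
                            - block[i, :].mean() * block[:, j].mean()
                            / block.mean())
                assert corrected[i, n_a + j] == pytest.approx(expected,
                                                              abs=1e-12)

    def test_normalization_plug_ins_and_rank_preservation(self):
        rng = np.random.default_rng(12)
        n_a, n_b = 5, 7
        n = n_a + n_b
        s = np.zeros((n, n))
        inter = rng.normal(size=(n_a, n_b))
        s[:n_a, n_a:] = inter
        s[n_a:, :n_a] = inter.T
        neff = 50.0
        st = normalize_scores(s, n_a, n, neff)
        # the minimum-score pair maps to −(1 + N/Neff)
        i, j = np.unravel_index(np.argmin(inter), inter.shape)
        assert st[i, j] == pytest.approx(-(1 + n / neff))
        # N == Neff gives multiplier 2
        st2 = normalize_scores(s, n_a, n, float(n))
        assert st2[i, j] == pytest.approx(-2.0)
        # ranking of inter pairs is preserved
        assert np.array_equal(np.argsort(st.ravel()),
                              np.argsort(inter.ravel()))
        # divide variant
        st3 = normalize_scores(s, n_a, n, neff, variant="divide")
        assert st3[i, j] == pytest.approx(-1.0 / (1 + n / neff))

    def test_empirical_score_top_four_mean(self):
        n_a, n_b = 2, 3
        s = np.zeros((5, 5))
        s[:2, 2:] = [[4.0, 3.0, 2.0], [1.0, 0.0, -1.0]]
        s[2:, :2] = s[:2, 2:].T
        assert empirical_interprotein_score(s, 2) == pytest.approx(2.5)
        s[:2, 2:] = 0.3
        s[2:, :2] = 0.3
        assert empirical_interprotein_score(s, 2) == pytest.approx(0.3)

    def test_column_permutation_equivariance(self, planted_families):
        fam_a, fam_b, _ = planted_families
        msa = random_match(fam_a, fam_b, seed=4)
        sequence_weights(msa)
        s1 = apc_correct(frobenius_scores(fit_plm(msa)), msa.boundary)

        perm = np.random.default_rng(5).permutation(fam_a.width)
        fam_a_perm = FamilyMSA(sequences=fam_a.sequences[:, perm],
                               organism_ids=fam_a.organism_ids,
                               labels=fam_a.labels)
        msa2 = random_match(fam_a_perm, fam_b, seed=4)
        sequence_weights(msa2)
        s2 = apc_correct(frobenius_scores(fit_plm(msa2)), msa2.boundary)
        inter1 = s1[:msa.boundary, msa.boundary:]
        inter2 = s2[:msa.boundary, msa.boundary:]
        assert np.allclose(inter2, inter1[perm, :], atol=1e-6)


class TestRandomMatch:
    @staticmethod
    def families(spec):
        """spec: dict organism -> (n_a, n_b); sequences encode their row."""
        rows_a, orgs_a, rows_b, orgs_b = [], [], [], []
        for org, (na, nb) in spec.items():
            for k in range(na):
                rows_a.append(np.full(4, (len(rows_a)) % Q))
                orgs_a.append(org)
            for k in range(nb):
                rows_b.append(np.full(4, (len(rows_b)) % Q))
                orgs_b.append(org)
        fa = FamilyMSA(np.array(rows_a, dtype=np.int8), np.array(orgs_a),
                       np.arange(len(rows_a)))
        fb = FamilyMSA(np.array(rows_b, dtype=np.int8), np.array(orgs_b),
                       np.arange(len(rows_b)))
        return fa, fb

    def test_single_copy_organism_always_paired(self):
        fa, fb = self.families({"x": (1, 1), "y": (2, 2)})
        for seed in range(20):
            msa = random_match(fa, fb, seed)
            pairs = set(zip(msa.labels_a.tolist(), msa.labels_b.tolist()))
            assert (0, 0) in pairs                # organism x row ids
            assert msa.n_rows == 3

    def test_exhaustion_rule_two_vs_one(self):
        fa, fb = self.families({"x": (2, 1)})
        for seed in range(10):
            msa = random_match(fa, fb, seed)
            assert msa.n_rows == 1

    def test_each_sequence_used_at_most_once(self):
        fa, fb = self.families({"x": (3, 3), "y": (4, 2)})
        msa = random_match(fa, fb, 7)
        assert len(set(msa.labels_a.tolist())) == msa.n_rows
        assert len(set(msa.labels_b.tolist())) == msa.n_rows

    def test_no_shared_organisms_rejected(self):
        fa, _ = self.families({"x": (1, 1)})
        _, fb = self.families({"z": (1, 1)})
        with pytest.raises(ValueError, match="organism"):
            random_match(fa, fb, 0)

    def test_three_by_three_matchings_roughly_uniform(self):
        # smaller-n twin of the fairness check: all 6 permutations appear
        from itertools import permutations
        from scipy.stats import chisquare
        fa, fb = self.families({"x": (3, 3)})
        perms = {p: 0 for p in permutations(range(3))}
        n_draws = 1200
        for seed in range(n_draws):
            msa = random_match(fa, fb, seed)
            order = tuple(int(msa.labels_b[msa.labels_a.tolist().index(i)])
                          for i in range(3))
            perms[order] += 1
        assert chisquare(list(perms.values())).pvalue > 0.01


class TestSelectionFrequencies:
    def test_planted_pairs_reach_frequency_one(self, planted_families):
        fam_a, fam_b, truth = planted_families
        preds = selection_frequencies(fam_a, fam_b, n_realizations=5,
                                      score_threshold=0.8, seed=77)
        planted = {tuple(p) for p in truth["planted_pairs"]}
        by_pair = {(p.column_a, p.column_b): p.frequency for p in preds}
        # single-copy organisms: matching is deterministic, so the strong
        # planted signal is selected in every realization
        for pair in planted:
            assert by_pair[pair] == pytest.approx(1.0)

    def test_single_realization_binary_frequencies(self, planted_families):
        fam_a, fam_b, _ = planted_families
        preds = selection_frequencies(fam_a, fam_b, n_realizations=1, seed=3)
        assert all(p.frequency == 1.0 for p in preds)

    def test_residue_mapping_applied(self, planted_families):
        fam_a, fam_b, _ = planted_families
        map_a = {i: 100 + i for i in range(fam_a.width)}
        map_b = {j: 1 + j for j in range(fam_b.width)}
        preds = selection_frequencies(fam_a, fam_b, n_realizations=1, seed=3,
                                      residue_map_a=map_a, residue_map_b=map_b)
        for p in preds:
            assert p.residue_a == 100 + p.column_a
            assert p.residue_b == 1 + p.column_b


def predictions_with_freqs(freqs):
    return [ContactPrediction(column_a=i, column_b=i, residue_a=i,
                              residue_b=i, frequency=f)
            for i, f in enumerate(freqs)]


class TestSasaFilter:
    def test_all_exposed_all_retained(self):
        preds = predictions_with_freqs([0.9, 0.8, 0.7])
        sasa = {i: 50.0 for i in range(3)}
        out = sasa_filter(preds, sasa, sasa)
        assert all(p.retained for p in out)

    def test_stop_at_first_buried_keeps_top_three(self):
        preds = predictions_with_freqs([0.996, 0.976, 0.587, 0.414, 0.334])
        sasa_a = {0: 102.7, 1: 41.6, 2: 17.3, 3: 0.6, 4: 89.5}
        sasa_b = {i: 100.0 for i in range(5)}
        out = sasa_filter(preds, sasa_a, sasa_b, mode="stop")
        assert [p.retained for p in out] == [True, True, True, False, False]

    def test_discard_mode_drops_only_buried(self):
        freqs = [0.9 - 0.05 * i for i in range(9)]
        preds = predictions_with_freqs(freqs)
        sasa_a = {i: 50.0 for i in range(9)}
        sasa_a[3] = 0.6
        sasa_a[7] = 0.7
        sasa_b = {i: 50.0 for i in range(9)}
        out = sasa_filter(preds, sasa_a, sasa_b, mode="discard")
        assert sum(p.retained for p in out) == 7
        assert not out[3].retained and not out[7].retained

    def test_missing_residue_is_named(self):
        preds = predictions_with_freqs([0.5])
        with pytest.raises(KeyError, match="0"):
            sasa_filter(preds, {}, {0: 10.0})


class TestComputeSasa:
    def test_isolated_residue_matches_mdtraj_oracle(self, tmp_path):
        pdb_text = make_fullatom_residue_pdb()
        sasa, norm = compute_sasa(pdb_text)
        assert set(sasa) == {1}
        import mdtraj as md
        path = tmp_path / "ala.pdb"
        path.write_text(pdb_text)
        traj = md.load(str(path))
        ref = float(md.shrake_rupley(traj, mode="residue")[0, 0]) * 100.0
        # different radii sets (ProtOr vs mdtraj defaults): agree within 15%
        assert sasa[1] == pytest.approx(ref, rel=0.15)
        assert norm[1] == pytest.approx(sasa[1] / AVERAGE_RESIDUE_SASA["A"])

    def test_buried_residue_below_one_angstrom_squared(self):
        pdb_text = make_fullatom_residue_pdb(extra_shell=True)
        sasa, _ = compute_sasa(pdb_text, residues=[1])
        assert sasa[1] < 1.0

    def test_ca_only_structure_rejected(self):
        from conftest import make_ca_pdb
        pdb = make_ca_pdb([(i, "ALA", (3.8 * i, 0.0, 0.0))
                           for i in range(1, 6)])
        with pytest.raises(ValueError, match="full atoms"):
            compute_sasa(pdb)
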