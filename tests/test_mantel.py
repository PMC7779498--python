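"""Mantel, categorical Mantel, restricted permutations and the quartile contrast."""

import itertools

import numpy as np
import pytest

from convergekit import (
    DyadicMatrix,
    PermutationScheme,
    build_structure,
    categorical_mantel,
    mantel_test,
    membership_matrix,
    quartile_contrast,
    restricted_permute,
)

try:
    from hypothesis import given, strategies as st

    HAVE_HYPOTHESIS = True
except ImportError:  # pragma: no cover
    HAVE_HYPOTHESIS = False


def sym_noise(n, rng):
    M = rng.normal(size=(n, n))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0)
    return M


class TestMembership:
    def test_total_and_within_gang_dyad_counts(self, study_structure):
        m = membership_matrix(study_structure, "gang")
        dyads = m.condensed()
        assert len(dyads) == 351
        assert int(dyads.sum()) == 169  # C(13,2) + C(14,2)

    def test_single_gang_all_ones(self):
        s = build_structure([[2, 3]])
        m = membership_matrix(s, "gang")
        assert np.all(m.condensed() == 1.0)

    def test_unknown_level_rejected(self, study_structure):
        with pytest.raises(ValueError):
            membership_matrix(study_structure, "unit")


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        ids = tuple("abcdef")
        A = DyadicMatrix(ids, sym_noise(6, rng))
        res = mantel_test(A, A, PermutationScheme("free", None, 49, seed=0))
        assert res.observed == pytest.approx(1.0)

    def test_exhaustive_p_matches_bruteforce(self, rng):
        n = 5
        ids = tuple("abcde")
        A = DyadicMatrix(ids, sym_noise(n, rng))
        B = DyadicMatrix(ids, sym_noise(n, rng))
        res = mantel_test(A, B, PermutationScheme("free", exhaustive=True), alternative="greater")
        iu = np.triu_indices(n, 1)
        va = A.values[iu]
        r_obs = np.corrcoef(va, B.values[iu])[0, 1]
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            P = np.array(perm)
            r = np.corrcoef(va, B.values[np.ix_(P, P)][iu])[0, 1]
            total += 1
            hits += r >= r_obs - 1e-12
        assert res.p_value == pytest.approx(hits / total)
        assert res.observed == pytest.approx(r_obs)

    def test_zero_variance_rejected(self, rng):
        ids = tuple("abcd")
        A = DyadicMatrix(ids, np.ones((4, 4)) - np.eye(4))
        B = DyadicMatrix(ids, sym_noise(4, rng))
        with pytest.raises(ValueError, match="variance"):
            mantel_test(A, B, PermutationScheme("free", None, 9, seed=1))

    def test_symmetric_in_arguments(self, rng):
        ids = tuple("abcdefg")
        A = DyadicMatrix(ids, sym_noise(7, rng))
        B = DyadicMatrix(ids, sym_noise(7, rng))
        sch = PermutationScheme("free", None, 99, seed=5)
        assert mantel_test(A, B, sch).observed == pytest.approx(mantel_test(B, A, sch).observed)


class TestCategoricalMantel:
    def test_constant_values_give_zero_difference(self, study_structure):
        n = study_structure.n
        V = np.ones((n, n))
        np.fill_diagonal(V, 0)
        mat = DyadicMatrix(tuple(study_structure.individuals), V)
        con = categorical_mantel(
            mat, study_structure, "gang", PermutationScheme("free", None, 99, seed=2)
        )
        assert con.mean_difference == pytest.approx(0.0)
        assert con.result.p_value > 0.9

    def test_exhaustive_p_matches_label_enumeration(self, rng):
        s = build_structure([[3], [3]])  # 6 individuals, 2 gangs of 3
        V = sym_noise(6, rng)
        mat = DyadicMatrix(tuple(s.individuals), V)
        con = categorical_mantel(
            mat, s, "gang", PermutationScheme("free", exhaustive=True), alternative="greater"
        )
        iu = np.triu_indices(6, 1)
        vals = V[iu]
        labels = s.gang_labels()

        def stat(lab):
            same = (lab[:, None] == lab[None, :])[iu]
            return vals[~same].mean() - vals[same].mean()

        obs = stat(labels)
        hits = total = 0
        for perm in itertools.permutations(range(6)):
            total += 1
            hits += stat(labels[np.array(perm)]) >= obs - 1e-12
        assert con.result.p_value == pytest.approx(hits / total)

    def test_party_universe_restricted_to_same_gang(self, study_structure):
        rng = np.random.default_rng(3)
        V = sym_noise(27, rng)
        mat = DyadicMatrix(tuple(study_structure.individuals), V)
        con = categorical_mantel(
            mat, study_structure, "party",
            PermutationScheme("within_blocks", dict(study_structure.gang_of), 99, seed=4),
        )
        assert con.n_a + con.n_b == 169  # same-gang dyad universe

    def test_detects_party_convergence(self, study_structure):
        # strong within-party similarity (low dissimilarity) must fire
        rng = np.random.default_rng(8)
        party = study_structure.party_labels()
        same = party[:, None] == party[None, :]
        V = np.where(same, 0.0, 1.0) + 0.01 * sym_noise(27, rng)
        V = (V + V.T) / 2
        np.fill_diagonal(V, 0)
        mat = DyadicMatrix(tuple(study_structure.individuals), V)
        con = categorical_mantel(
            mat, study_structure, "party",
            PermutationScheme("within_blocks", dict(study_structure.gang_of), 999, seed=5),
            alternative="greater",
        )
        assert con.result.p_value == pytest.approx(1 / 1000)


class TestRestrictedPermute:
    def test_single_block_is_plain_permutation(self, rng):
        labels = list("aabbcc")
        out = restricted_permute(labels, ["x"] * 6, rng)
        assert sorted(out) == sorted(labels)

    def test_labels_never_cross_blocks(self, rng):
        labels = np.array(["p1", "p1", "p2", "p2"], dtype=object)
        blocks = np.array(["A", "A", "B", "B"], dtype=object)
        for _ in range(200):
            out = restricted_permute(labels, blocks, rng)
            assert set(out[:2]) == {"p1"} and set(out[2:]) == {"p2"}

    def test_multiset_preserved_within_blocks(self, rng):
        labels = np.array(["p1", "p1", "p2", "q1", "q2", "q2"], dtype=object)
        blocks = np.array(["A", "A", "A", "B", "B", "B"], dtype=object)
        for _ in range(50):
            out = restricted_permute(labels, blocks, rng)
            assert sorted(out[:3]) == ["p1", "p1", "p2"]
            assert sorted(out[3:]) == ["q1", "q2", "q2"]

    if HAVE_HYPOTHESIS:

        @given(st.integers(0, 2**31 - 1))
        def test_within_gang_support_property(self, seed):
            rng = np.random.default_rng(seed)
            labels = np.array(["a", "b", "c", "d"], dtype=object)
            blocks = np.array(["A", "A", "B", "B"], dtype=object)
            out = restricted_permute(labels, blocks, rng)
            assert set(out[:2]) == {"a", "b"}
            assert set(out[2:]) == {"c", "d"}


class TestQuartileContrast:
    def _mats(self, rng, n=27, coupled=False):
        ids = tuple(f"i{k}" for k in range(n))
        w = sym_noise(n, rng)
        d = 0.5 * w + sym_noise(n, rng) if coupled else sym_noise(n, rng)
        return DyadicMatrix(ids, w, "relatedness_W"), DyadicMatrix(ids, d, "dissimilarity_lnF")

    def test_constant_w_rejected(self, rng):
        ids = tuple("abcd")
        W = DyadicMatrix(ids, np.ones((4, 4)) - np.eye(4), "relatedness_W")
        D = DyadicMatrix(ids, sym_noise(4, rng), "dissimilarity_lnF")
        with pytest.raises(ValueError, match="tie"):
            quartile_contrast(W, D, n_permutations=9, seed=1)

    def test_quartile_split_selects_about_half(self, rng):
        W, D = self._mats(rng)
        con = quartile_contrast(W, D, q=0.25, n_permutations=49, seed=2)
        assert 174 <= con.n_a + con.n_b <= 176  # of 351 dyads

    def test_null_p_values_roughly_uniform(self):
        reps, rej = 200, 0
        for k in range(reps):
            r = np.random.default_rng(3000 + k)
            W, D = self._mats(r, n=15)
            con = quartile_contrast(W, D, n_permutations=99, seed=k, alternative="less")
            rej += con.result.p_value <= 0.05
        assert abs(rej / reps - 0.05) < 0.05

    def test_detects_coupling(self):
        r = np.random.default_rng(77)
        W, D = self._mats(r, coupled=True)
        con = quartile_contrast(W, D, n_permutations=199, seed=6, alternative="greater")
        assert con.result.p_value < 0.05
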