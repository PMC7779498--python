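"""Locus screening and Wang relatedness against enumeration/simulation oracles."""

import itertools
import math

import numpy as np
import pytest

import convergekit.relatedness as rel
from convergekit import (
    GenotypeTable,
    PedigreeSimConfig,
    allele_frequencies,
    build_structure,
    filter_loci,
    hwe_exact_test,
    null_allele_screen,
    screen_loci,
    simulate_genotypes,
    wang_for_pairs,
    wang_pairwise,
)
from convergekit.relatedness import LocusReport, _locus_coefficients, _moments_from_frequencies


def table_from_genotypes(genos, loci=None):
    """genos: list per individual of list per locus of (a, b) tuples."""
    n, L = len(genos), len(genos[0])
    alleles = np.zeros((n, L, 2), dtype=int)
    for i, row in enumerate(genos):
        for j, g in enumerate(row):
            alleles[i, j] = sorted(g)
    return GenotypeTable(
        [f"i{k}" for k in range(n)], loci or [f"L{j + 1}" for j in range(L)], alleles
    )


class TestAlleleFrequencies:
    def test_direct_count(self):
        t = table_from_genotypes([[(1, 1)], [(1, 2)]])
        assert allele_frequencies(t, "L1") == {1: 0.75, 2: 0.25}

    def test_monomorphic(self):
        t = table_from_genotypes([[(3, 3)], [(3, 3)]])
        assert allele_frequencies(t, "L1") == {3: 1.0}

    def test_all_missing_locus_rejected(self):
        t = table_from_genotypes([[(0, 0)], [(0, 0)]])
        with pytest.raises(ValueError, match="L1"):
            allele_frequencies(t, "L1")

    def test_estimates_within_binomial_ci(self, rng):
        p = 0.3
        draws = rng.choice([1, 2], size=(1000, 2), p=[p, 1 - p])
        t = table_from_genotypes([[tuple(g)] for g in draws])
        f = allele_frequencies(t, "L1")[1]
        se = math.sqrt(p * (1 - p) / 2000)
        assert abs(f - p) < 4 * se


def _bruteforce_hwe_p(geno):
    """Independent exact-test oracle: enumerate pairings via permutations."""
    genes = [a for g in geno for a in g]
    n = len(geno)
    counts = {}
    for v in genes:
        counts[v] = counts.get(v, 0) + 1

    def logprob(pairs):
        from collections import Counter

        c = Counter(tuple(sorted(p)) for p in pairs)
        h = sum(v for k, v in c.items() if k[0] != k[1])
        lp = math.lgamma(n + 1) + h * math.log(2)
        lp += sum(math.lgamma(x + 1) for x in counts.values())
        lp -= math.lgamma(2 * n + 1)
        lp -= sum(math.lgamma(v + 1) for v in c.values())
        return lp

    obs = logprob([tuple(g) for g in geno])
    hits = total = 0
    for perm in itertools.permutations(genes):
        pairs = [perm[2 * i : 2 * i + 2] for i in range(n)]
        total += 1
        hits += logprob(pairs) <= obs + 1e-9
    return hits / total


class TestHWE:
    def test_matches_bruteforce_enumeration(self):
        geno = [(1, 1), (1, 2), (2, 2), (1, 2)]
        t = table_from_genotypes([[g] for g in geno])
        assert hwe_exact_test(t, "L1") == pytest.approx(_bruteforce_hwe_p(geno))

    def test_monomorphic_locus_p_one(self):
        t = table_from_genotypes([[(2, 2)]] * 6)
        assert hwe_exact_test(t, "L1") == 1.0

    def test_monte_carlo_agrees_with_enumeration(self, monkeypatch):
        geno = [(1, 1), (1, 2), (2, 2), (1, 1), (1, 2), (2, 2), (1, 2)]
        t = table_from_genotypes([[g] for g in geno])
        p_enum = hwe_exact_test(t, "L1")
        monkeypatch.setattr(rel, "HWE_ENUMERATION_MAX_GENES", 0)
        p_mc = hwe_exact_test(t, "L1", n_mc=50_000, seed=3)
        assert abs(p_mc - p_enum) < 0.02

    def test_heterozygote_deficit_detected(self):
        geno = [(1, 1)] * 20 + [(2, 2)] * 20 + [(1, 2)] * 2
        t = table_from_genotypes([[g] for g in geno])
        assert hwe_exact_test(t, "L1", n_mc=20_000, seed=1) < 0.001

    def test_type_one_error_not_anticonservative(self):
        # exact conditional test: rejection rate <= alpha (discrete support
        # makes it conservative at small n)
        reps, rej = 150, 0
        master = np.random.default_rng(99)
        fr = master.dirichlet(np.ones(6))
        for k in range(reps):
            r = np.random.default_rng(1000 + k)
            draws = r.choice(np.arange(1, 7), size=(40, 2), p=fr)
            t = table_from_genotypes([[tuple(g)] for g in draws])
            rej += hwe_exact_test(t, "L1", n_mc=1500, seed=k) < 0.05
        rate = rej / reps
        assert rate <= 0.05 + 2.6 * math.sqrt(0.05 * 0.95 / reps)
        assert rate > 0.0


class TestNullAlleleScreen:
    def test_no_deficit_gives_zero(self):
        geno = [(1, 2), (1, 2), (1, 1), (2, 2)]  # Ho = He = 0.5
        t = table_from_genotypes([[g] for g in geno])
        assert null_allele_screen(t, "L1") == pytest.approx(0.0)

    def test_closed_form_value(self):
        # He = 0.5, Ho = 0.25 -> r = 0.25 / 1.5
        geno = [(1, 1)] * 3 + [(2, 2)] * 3 + [(1, 2)] * 2
        t = table_from_genotypes([[g] for g in geno])
        assert null_allele_screen(t, "L1") == pytest.approx(0.25 / 1.5)

    def test_recovers_simulated_null_frequency(self, rng):
        # true null allele at freq 0.2: carriers look homozygous, double-null missing
        p_null = 0.2
        vis = np.array([0.4, 0.4])  # two visible alleles, equal share of 0.8
        probs = np.concatenate([vis, [p_null]])
        draws = rng.choice([1, 2, 0], size=(400, 2), p=probs)
        genos = []
        for a, b in draws:
            if a == 0 and b == 0:
                genos.append([(0, 0)])
            elif a == 0:
                genos.append([(b, b)])
            elif b == 0:
                genos.append([(a, a)])
            else:
                genos.append([(a, b)])
        t = table_from_genotypes(genos)
        assert abs(null_allele_screen(t, "L1") - p_null) < 0.1


class TestFilterLoci:
    @staticmethod
    def _report(name, excluded):
        return LocusReport(name, {1: 1.0}, 10, 0.5, 0.5, 0.5, 0.0, excluded,
                           "null alleles + HWE deviation" if excluded else None)

    def test_one_of_24_flagged_leaves_23(self):
        reports = [self._report(f"L{k}", k == 7) for k in range(24)]
        assert len(filter_loci(reports)) == 23

    def test_no_flags_identity(self):
        reports = [self._report(f"L{k}", False) for k in range(5)]
        assert filter_loci(reports) == [f"L{k}" for k in range(5)]

    def test_all_flagged_rejected(self):
        reports = [self._report(f"L{k}", True) for k in range(3)]
        with pytest.raises(ValueError):
            filter_loci(reports)

    def test_screen_flags_require_conjunction(self, rng):
        # strong heterozygote deficit -> both flags -> excluded
        bad = [[(1, 1)]] * 20 + [[(2, 2)]] * 20 + [[(1, 2)]] * 2
        good = rng.choice(np.arange(1, 7), size=(42, 2))
        genos = [b + [tuple(g)] for b, g in zip(bad, good)]
        t = table_from_genotypes(genos, loci=["bad", "good"])
        reports = screen_loci(t, hwe_mc=5000, seed=2)
        assert [r.excluded for r in reports] == [True, False]


class TestWang:
    def test_category_probabilities_match_enumeration(self, rng):
        # D0 coefficients b, d, f equal brute-force genotype-pair probabilities
        p = rng.dirichlet(np.ones(5))
        a2, a3, a4 = _moments_from_frequencies(p)
        b, c, d, e, f, g, u = _locus_coefficients(a2, a3, a4)
        genos = [(i, j) for i in range(5) for j in range(i, 5)]

        def gp(gt):
            i, j = gt
            return p[i] ** 2 if i == j else 2 * p[i] * p[j]

        def cat(A, B):
            if A == B:
                return 1
            ha, hb = A[0] == A[1], B[0] == B[1]
            share = len(set(A) & set(B)) > 0
            if share and (ha != hb):
                return 2
            if share and not ha and not hb:
                return 3
            return 4

        P = np.zeros(5)
        for A in genos:
            for B in genos:
                P[cat(A, B)] += gp(A) * gp(B)
        assert b == pytest.approx(P[1], abs=1e-12)
        assert d == pytest.approx(P[2], abs=1e-12)
        assert f == pytest.approx(P[3], abs=1e-12)

    def test_identical_multiallelic_genotypes_score_high(self):
        L, A = 30, 10
        freqs = {f"L{j + 1}": {a: 1.0 / A for a in range(1, A + 1)} for j in range(L)}
        genos = [[(j % A + 1, j % A + 1) for j in range(L)] for _ in range(2)]
        t = table_from_genotypes(genos)
        w = wang_for_pairs(t, [("i0", "i1")], freqs)[0]
        assert w > 0.7

    def test_sib_classes_rank_ordered(self):
        s = build_structure([[10] * 4, [10] * 4])
        cfg = PedigreeSimConfig(
            n_loci=100, within_party_fullsib_prop=0.4, within_party_halfsib_prop=0.4, seed=7
        )
        g, kin = simulate_genotypes(s, cfg)
        W = wang_pairwise(g)
        k = kin.condensed()
        w = W.condensed()
        m_fs = w[k == 0.5].mean()
        m_hs = w[k == 0.25].mean()
        m_ur = w[k == 0.0].mean()
        assert m_fs > m_hs > m_ur
        assert abs(m_ur) < 0.05

    def test_matrix_symmetric_and_in_range(self, study_structure):
        g, _ = simulate_genotypes(study_structure, PedigreeSimConfig(seed=3))
        W = wang_pairwise(g)
        assert np.allclose(W.values, W.values.T)
        off = W.condensed()
        assert np.all(off >= -1.0) and np.all(off <= 1.0)

    def test_variance_shrinks_with_more_loci(self, study_structure):
        sds = []
        for L in (20, 120):
            g, _ = simulate_genotypes(
                study_structure,
                PedigreeSimConfig(n_loci=L, within_party_fullsib_prop=0,
                                  within_party_halfsib_prop=0, seed=9),
            )
            sds.append(wang_pairwise(g).condensed().std())
        assert sds[1] < sds[0]

    def test_disjoint_loci_dyad_is_nan(self):
        genos = [
            [(1, 2), (0, 0)],
            [(0, 0), (3, 4)],
            [(1, 1), (3, 3)],
            [(1, 2), (3, 4)],
        ]
        t = table_from_genotypes(genos)
        w = wang_for_pairs(t, [("i0", "i1"), ("i2", "i3")])
        assert np.isnan(w[0]) and np.isfinite(w[1])
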