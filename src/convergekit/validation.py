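"""Study-scale validation experiments.

These routines re-derive the package's key guarantees from scratch at
realistic problem sizes: agreement of the pairwise F with the Hotelling T²
oracle, exactness of permutation p-values against complete enumeration,
recovery of pedigree relatedness by the Wang estimator, type-I error of the
permutation tests under their nulls, and the dissociation property — a
population with social convergence in calls and elevated within-party
relatedness, but no coupling between the two channels, should show
significant within-level acoustic contrasts while the acoustic–genetic
Mantel correlation stays null.

Everything is deterministic given the seed.  Problem sizes default to values
that keep each experiment in the seconds-to-minutes range.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .core import CallFeatureTable, DyadicMatrix
from .dfa import dissimilarity_from_f, fit_model, pairwise_f_matrix, stepwise_select
from .mantel import PermutationScheme, categorical_mantel, mantel_test
from .pdfa import PdfaConfig, pdfa_test
from .relatedness import wang_for_pairs, wang_pairwise
from .synthetic import (
    FeatureSimConfig,
    PedigreeSimConfig,
    build_structure,
    simulate_features,
    simulate_genotypes,
)

import pandas as pd

logger = logging.getLogger("convergekit")

__all__ = [
    "hotelling_relative_error",
    "exhaustive_p_difference",
    "wang_recovery",
    "type1_mantel_free",
    "type1_categorical",
    "type1_pdfa",
    "dissociation_success",
]


def _feature_table(X: np.ndarray, labels) -> CallFeatureTable:
    df = pd.DataFrame(X, columns=[f"f{j + 1}" for j in range(X.shape[1])])
    df.insert(0, "individual_id", list(labels))
    df.insert(0, "call_id", [f"c{i}" for i in range(len(df))])
    return CallFeatureTable(df)


def _sym_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    M = rng.normal(size=(n, n))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0)
    return M


def hotelling_relative_error(seed: int, n1: int = 14, n2: int = 17, p: int = 5) -> float:
    """|pairwise F - Hotelling T² F| / F for a two-group table."""
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n1, p)), rng.normal(0.7, 1, (n2, p))])
    table = _feature_table(X, ["a"] * n1 + ["b"] * n2)
    F = pairwise_f_matrix(fit_model(table)).values[0, 1]
    x, y = X[:n1], X[n1:]
    S = (np.cov(x.T) * (n1 - 1) + np.cov(y.T) * (n2 - 1)) / (n1 + n2 - 2)
    d = x.mean(0) - y.mean(0)
    T2 = n1 * n2 / (n1 + n2) * d @ np.linalg.solve(S, d)
    F_hot = (n1 + n2 - p - 1) / (p * (n1 + n2 - 2)) * T2
    return abs(F - F_hot) / F_hot


def exhaustive_p_difference(seed: int) -> dict[str, float]:
    """Exhaustive-scheme p-values vs independent enumeration oracles (<= 6 ids)."""
    rng = np.random.default_rng(seed)

    # Mantel on 5 individuals (120 permutations)
    n = 5
    ids = tuple(f"i{k}" for k in range(n))
    A = DyadicMatrix(ids, _sym_noise(n, rng))
    B = DyadicMatrix(ids, _sym_noise(n, rng))
    res = mantel_test(A, B, PermutationScheme("free", exhaustive=True), alternative="greater")
    iu = np.triu_indices(n, 1)
    va = A.values[iu]
    r_obs = float(np.corrcoef(va, B.values[iu])[0, 1])
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        P = np.array(perm)
        r = np.corrcoef(va, B.values[np.ix_(P, P)][iu])[0, 1]
        total += 1
        hits += r >= r_obs - 1e-12
    mantel_diff = abs(res.p_value - hits / total)

    # categorical Mantel on 6 individuals, 2 groups of 3 (720 label orders)
    s6 = build_structure([[3], [3]])
    V = _sym_noise(6, rng)
    mat = DyadicMatrix(tuple(s6.individuals), V)
    con = categorical_mantel(
        mat, s6, "gang", PermutationScheme("free", exhaustive=True), alternative="greater"
    )
    iu6 = np.triu_indices(6, 1)
    vals = V[iu6]
    labels = s6.gang_labels()

    def stat(lab):
        same = (lab[:, None] == lab[None, :])[iu6]
        return vals[~same].mean() - vals[same].mean()

    obs = stat(labels)
    hits = total = 0
    for perm in itertools.permutations(range(6)):
        total += 1
        hits += stat(labels[np.array(perm)]) >= obs - 1e-12
    cat_diff = abs(con.result.p_value - hits / total)
    return {"mantel": mantel_diff, "categorical": cat_diff}


def wang_recovery(seed: int, n_pairs: int = 500, n_loci: int = 200) -> dict[str, float]:
    """Mean Wang Ŵ for simulated full-sib and unrelated dyads.

    125 parties of 8 individuals, all paired into full sibs; unrelated dyads
    pair members of different parties.  Frequencies are estimated from the
    full sample (with the small-sample bias correction).
    """
    n_parties = (2 * n_pairs + 7) // 8
    sizes = [[8] * n_parties]
    structure = build_structure(sizes)
    cfg = PedigreeSimConfig(
        n_loci=n_loci,
        alleles_per_locus=8,
        within_party_fullsib_prop=1.0,
        within_party_halfsib_prop=0.0,
        seed=seed,
    )
    genotypes, kinship = simulate_genotypes(structure, cfg)
    kin = kinship.values
    pos = {v: k for k, v in enumerate(genotypes.individuals)}

    fs_pairs = []
    parties = structure.parties
    for party in parties:
        members = structure.party_members(party)
        for a, b in itertools.combinations(members, 2):
            if kin[pos[a], pos[b]] == 0.5:
                fs_pairs.append((a, b))
    fs_pairs = fs_pairs[:n_pairs]

    ur_pairs = []
    for pa, pb in zip(parties, parties[1:]):
        ma, mb = structure.party_members(pa), structure.party_members(pb)
        ur_pairs.extend(zip(ma, mb))
        if len(ur_pairs) >= n_pairs:
            break
    ur_pairs = ur_pairs[:n_pairs]

    w_fs = wang_for_pairs(genotypes, fs_pairs)
    w_ur = wang_for_pairs(genotypes, ur_pairs)
    return {
        "fullsib_mean": float(np.nanmean(w_fs)),
        "unrelated_mean": float(np.nanmean(w_ur)),
        "n_fullsib": len(fs_pairs),
        "n_unrelated": len(ur_pairs),
        "n_loci": n_loci,
    }


def type1_mantel_free(seed: int, reps: int = 500, n: int = 12, n_perm: int = 99) -> float:
    """Rejection rate at alpha = 0.05 for independent dyadic matrices."""
    rej = 0
    for k in range(reps):
        rng = np.random.default_rng((seed, 1, k))
        ids = tuple(f"i{j}" for j in range(n))
        A = DyadicMatrix(ids, _sym_noise(n, rng))
        B = DyadicMatrix(ids, _sym_noise(n, rng))
        p = mantel_test(
            A, B, PermutationScheme("free", None, n_perm, seed=int(rng.integers(2**31))),
            alternative="two-sided",
        ).p_value
        rej += p <= 0.05
    return rej / reps


def type1_categorical(seed: int, reps: int = 500, restricted: bool = False) -> float:
    """Type-I of the categorical Mantel test under its null.

    Free scheme: pure-noise dyadic values against gang membership.
    Restricted scheme: values carry a gang effect but no party signal; party
    labels are permuted within gangs — the regime the restriction exists for.
    """
    structure = build_structure([[6, 7], [5, 9]])
    gangs = structure.gang_labels()
    rej = 0
    for k in range(reps):
        rng = np.random.default_rng((seed, 2 + restricted, k))
        V = _sym_noise(27, rng)
        if restricted:
            eff = {g: rng.normal(0.0, 1.0) for g in structure.gangs}
            v = np.array([eff[g] for g in gangs])
            V = V + np.add.outer(v, v)
            np.fill_diagonal(V, 0)
            scheme = PermutationScheme(
                "within_blocks", dict(structure.gang_of), 199, seed=int(rng.integers(2**31))
            )
            con = categorical_mantel(
                DyadicMatrix(tuple(structure.individuals), V),
                structure, "party", scheme, alternative="greater",
            )
        else:
            scheme = PermutationScheme("free", None, 99, seed=int(rng.integers(2**31)))
            con = categorical_mantel(
                DyadicMatrix(tuple(structure.individuals), V),
                structure, "gang", scheme, alternative="greater",
            )
        rej += con.result.p_value <= 0.05
    return rej / reps


def type1_pdfa(seed: int, reps: int = 500) -> float:
    """Type-I of the permuted DFA on pure-noise tables.

    8 individuals × 8 calls, 3 noise features; one balanced subset for the
    observed statistic and per permutation (exactly exchangeable), 39
    permutations.
    """
    rej = 0
    for k in range(reps):
        rng = np.random.default_rng((seed, 4, k))
        labels = np.repeat([f"m{j}" for j in range(8)], 8)
        table = _feature_table(rng.normal(size=(64, 3)), labels)
        cfg = PdfaConfig(
            calls_per_class=6, n_subsets=1, n_permutations=39, n_subsets_null=1,
            seed=int(rng.integers(2**31)),
        )
        rej += pdfa_test(table, cfg).p_value <= 0.05
    return rej / reps


@dataclass
class DissociationOutcome:
    gang_p: float
    party_p: float
    mantel_r: float
    mantel_p: float

    @property
    def success(self) -> bool:
        return self.gang_p < 0.05 and self.party_p < 0.05 and self.mantel_p > 0.05


def dissociation_trial(seed: int, n_perm: int = 199, n_perm_party: int = 399) -> DissociationOutcome:
    """One run of the dissociation scenario at the generator defaults."""
    structure = build_structure([[6, 7], [5, 9]])
    features = simulate_features(structure, FeatureSimConfig(seed=seed))
    genotypes, _ = simulate_genotypes(structure, PedigreeSimConfig(seed=seed + 1))
    model = stepwise_select(features)
    if model.is_empty:  # no acoustic signal at all — cannot succeed
        return DissociationOutcome(1.0, 1.0, 0.0, 1.0)
    lnF = dissimilarity_from_f(pairwise_f_matrix(model)).reindex(structure.individuals)
    Wm = wang_pairwise(genotypes).reindex(structure.individuals)
    cg = categorical_mantel(
        lnF, structure, "gang",
        PermutationScheme("free", None, n_perm, seed=seed + 2), alternative="greater",
    )
    cp = categorical_mantel(
        lnF, structure, "party",
        PermutationScheme("within_blocks", dict(structure.gang_of), n_perm_party, seed=seed + 3),
        alternative="greater",
    )
    man = mantel_test(
        lnF, Wm, PermutationScheme("free", None, n_perm, seed=seed + 4), alternative="two-sided"
    )
    return DissociationOutcome(cg.result.p_value, cp.result.p_value, man.observed, man.p_value)


def dissociation_success(seed: int, n_seeds: int = 20) -> dict:
    """Fraction of seeds reproducing the dissociation pattern."""
    outcomes = [dissociation_trial(seed + 1000 * k) for k in range(n_seeds)]
    return {
        "success_rate": float(np.mean([o.success for o in outcomes])),
        "mean_abs_mantel_r": float(np.mean([abs(o.mantel_r) for o in outcomes])),
        "n_seeds": n_seeds,
        "outcomes": outcomes,
    }
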