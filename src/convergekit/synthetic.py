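"""Synthetic study generator: nested social structure, acoustic features, genotypes.

The generator emulates the statistical structure of a vocal-convergence field
study on a multi-level society: ~27 males in 2 gangs × 2 parties (party sizes
6, 7, 5, 9), a variable number of calls per male (uniform on a configured
integer range, 5–127 by default), 82 numeric acoustic features whose variance
decomposes into gang, party, individual and residual components, and 23
microsatellite loci whose within-party relatedness is elevated by simulated
full-sib / half-sib dyads sharing Mendelian parents.

Every output is a plain in-memory container from :mod:`convergekit.core` and
is byte-deterministic for a fixed config + seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import CallFeatureTable, DyadicMatrix, GenotypeTable, SocialStructure

import pandas as pd

logger = logging.getLogger("convergekit")

__all__ = [
    "FeatureSimConfig",
    "PedigreeSimConfig",
    "SimulatedStudy",
    "build_structure",
    "simulate_features",
    "simulate_genotypes",
    "simulate_study",
    "DEFAULT_GANG_PARTY_SIZES",
]

#: Party sizes per gang of the emulated study population (two gangs with
#: parties of 6+7 and 5+9 males → 27 individuals).
DEFAULT_GANG_PARTY_SIZES: list[list[int]] = [[6, 7], [5, 9]]


@dataclass(frozen=True)
class FeatureSimConfig:
    """Variance-component model for the acoustic feature table.

    Each call row is ``grand mean + gang + party + individual + residual``,
    with each effect drawn per feature from a zero-mean normal with the
    configured standard deviation (one sigma per level, shared across
    features).  Calls per individual are uniform on ``calls_range``.
    """

    n_features: int = 82
    calls_range: tuple[int, int] = (5, 127)
    sigma_gang: float = 0.2
    sigma_party: float = 0.35
    sigma_individual: float = 0.5
    sigma_resid: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        lo, hi = self.calls_range
        if lo < 1 or hi < lo:
            raise ValueError("calls_range must satisfy 1 <= min <= max")
        for name in ("sigma_gang", "sigma_party", "sigma_individual", "sigma_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class PedigreeSimConfig:
    """One-generation pedigree simulation for microsatellite genotypes.

    Founder allele frequencies are drawn per locus from a symmetric Dirichlet
    with concentration ``founder_freq_concentration`` (smaller → more skewed
    frequencies, as typical for microsatellites).  Within each party a
    proportion of individuals is paired into full-sib or half-sib dyads whose
    genotypes are Mendelian samples from shared simulated parents; everyone
    else is an unrelated founder.  Missing genotypes are inserted completely
    at random at ``missing_rate``.
    """

    n_loci: int = 23
    alleles_per_locus: int = 8
    founder_freq_concentration: float = 2.0
    within_party_fullsib_prop: float = 0.3
    within_party_halfsib_prop: float = 0.3
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.alleles_per_locus < 2:
            raise ValueError("alleles_per_locus must be >= 2")
        if self.founder_freq_concentration <= 0:
            raise ValueError("founder_freq_concentration must be > 0")
        for name in ("within_party_fullsib_prop", "within_party_halfsib_prop", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.within_party_fullsib_prop + self.within_party_halfsib_prop > 1.0 + 1e-12:
            raise ValueError("sib proportions must sum to <= 1")


@dataclass
class SimulatedStudy:
    """Bundle of all simulated inputs plus the pedigree's expected kinship.

    ``true_kinship`` holds the pedigree expectation of pairwise relatedness
    (0.5 full sibs, 0.25 half sibs, 0 founders) with a unit diagonal
    (self-relatedness convention r = 1 for non-inbred individuals).
    """

    structure: SocialStructure
    features: CallFeatureTable
    genotypes: GenotypeTable
    true_kinship: DyadicMatrix
    feature_config: FeatureSimConfig
    pedigree_config: PedigreeSimConfig


def build_structure(
    gang_party_sizes: Sequence[Sequence[int]],
    gang_names: Sequence[str] | None = None,
) -> SocialStructure:
    """Build a nested structure from per-gang lists of party sizes.

    ``[[6, 7], [5, 9]]`` yields 27 individuals in 4 parties and 2 gangs.
    Individual ids encode their position (e.g. ``G1P2-03``) so that tables
    remain human-readable.
    """
    if len(gang_party_sizes) == 0:
        raise ValueError("need at least one gang")
    if gang_names is None:
        gang_names = [f"G{k + 1}" for k in range(len(gang_party_sizes))]
    if len(gang_names) != len(gang_party_sizes):
        raise ValueError("gang_names length must match gang_party_sizes")
    individuals: list[str] = []
    party_of: dict[str, str] = {}
    gang_of: dict[str, str] = {}
    for gname, parties in zip(gang_names, gang_party_sizes):
        if len(parties) == 0:
            raise ValueError(f"gang {gname!r} has no parties")
        for p, size in enumerate(parties, start=1):
            if size < 1:
                raise ValueError(f"party size must be >= 1, got {size}")
            pname = f"{gname}P{p}"
            for i in range(1, size + 1):
                ind = f"{pname}-{i:02d}"
                individuals.append(ind)
                party_of[ind] = pname
                gang_of[ind] = gname
    return SocialStructure(tuple(individuals), party_of, gang_of)


def simulate_features(structure: SocialStructure, cfg: FeatureSimConfig) -> CallFeatureTable:
    """Draw the call-level acoustic feature table under the nested model."""
    rng = np.random.default_rng(cfg.seed)
    K = cfg.n_features
    gangs, parties = structure.gangs, structure.parties
    gang_eff = {g: rng.normal(0.0, cfg.sigma_gang, K) for g in gangs}
    party_eff = {p: rng.normal(0.0, cfg.sigma_party, K) for p in parties}
    ind_eff = {i: rng.normal(0.0, cfg.sigma_individual, K) for i in structure.individuals}
    lo, hi = cfg.calls_range
    n_calls = {i: int(rng.integers(lo, hi + 1)) for i in structure.individuals}

    rows = []
    call_ids = []
    labels = []
    for ind in structure.individuals:
        base = gang_eff[structure.gang_of[ind]] + party_eff[structure.party_of[ind]] + ind_eff[ind]
        resid = rng.normal(0.0, cfg.sigma_resid, (n_calls[ind], K))
        rows.append(base[None, :] + resid)
        call_ids.extend(f"{ind}_c{k + 1:03d}" for k in range(n_calls[ind]))
        labels.extend([ind] * n_calls[ind])
    X = np.vstack(rows)
    df = pd.DataFrame(X, columns=[f"f{j + 1:03d}" for j in range(K)])
    df.insert(0, "individual_id", labels)
    df.insert(0, "call_id", call_ids)
    return CallFeatureTable(df)


def _mendelian_child(parent_a: np.ndarray, parent_b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One allele from each parent at every locus; shape (L, 2)."""
    L = parent_a.shape[0]
    pick_a = rng.integers(0, 2, L)
    pick_b = rng.integers(0, 2, L)
    return np.stack([parent_a[np.arange(L), pick_a], parent_b[np.arange(L), pick_b]], axis=1)


def simulate_genotypes(
    structure: SocialStructure, cfg: PedigreeSimConfig
) -> tuple[GenotypeTable, DyadicMatrix]:
    """Simulate genotypes with designated within-party sib dyads.

    Returns the genotype table and the pedigree-expected kinship matrix.
    Sib pairing: within each party, ``round(prop * size / 2)`` disjoint
    full-sib pairs and likewise half-sib pairs are formed from a random
    shuffle of the party's members; a pairing that cannot be honoured (too
    few members) raises ``ValueError``.
    """
    rng = np.random.default_rng(cfg.seed)
    L, A = cfg.n_loci, cfg.alleles_per_locus
    freqs = rng.dirichlet(np.full(A, cfg.founder_freq_concentration), size=L)  # (L, A)

    def draw_founder() -> np.ndarray:
        out = np.empty((L, 2), dtype=int)
        for l in range(L):
            out[l] = rng.choice(np.arange(1, A + 1), size=2, p=freqs[l])
        return out

    inds = list(structure.individuals)
    pos = {v: k for k, v in enumerate(inds)}
    genotypes: dict[str, np.ndarray] = {}
    kin = np.zeros((len(inds), len(inds)))
    np.fill_diagonal(kin, 1.0)

    for party in structure.parties:
        members = list(structure.party_members(party))
        size = len(members)
        n_fs = int(round(cfg.within_party_fullsib_prop * size / 2))
        n_hs = int(round(cfg.within_party_halfsib_prop * size / 2))
        if 2 * (n_fs + n_hs) > size:
            raise ValueError(
                f"sib proportions incompatible with party {party!r} of size {size}"
            )
        order = list(rng.permutation(members))
        cursor = 0
        for _ in range(n_fs):
            a, b = order[cursor], order[cursor + 1]
            cursor += 2
            pa, pb = draw_founder(), draw_founder()
            genotypes[a] = _mendelian_child(pa, pb, rng)
            genotypes[b] = _mendelian_child(pa, pb, rng)
            kin[pos[a], pos[b]] = kin[pos[b], pos[a]] = 0.5
        for _ in range(n_hs):
            a, b = order[cursor], order[cursor + 1]
            cursor += 2
            shared, pa, pb = draw_founder(), draw_founder(), draw_founder()
            genotypes[a] = _mendelian_child(shared, pa, rng)
            genotypes[b] = _mendelian_child(shared, pb, rng)
            kin[pos[a], pos[b]] = kin[pos[b], pos[a]] = 0.25
        for ind in order[cursor:]:
            genotypes[ind] = draw_founder()

    alleles = np.stack([genotypes[i] for i in inds])  # (n, L, 2)
    alleles.sort(axis=2)
    if cfg.missing_rate > 0:
        drop = rng.random((len(inds), L)) < cfg.missing_rate
        alleles[drop] = 0
        n_drop = int(drop.sum())
        if n_drop:
            logger.info("inserted %d missing genotypes (rate %.3f)", n_drop, cfg.missing_rate)

    table = GenotypeTable(inds, [f"L{l + 1:02d}" for l in range(L)], alleles)
    kinship = DyadicMatrix(tuple(inds), kin, kind="relatedness_W")
    return table, kinship


def simulate_study(
    gang_party_sizes: Sequence[Sequence[int]] | None = None,
    feature_config: FeatureSimConfig | None = None,
    pedigree_config: PedigreeSimConfig | None = None,
    seed: int | None = None,
) -> SimulatedStudy:
    """Simulate a complete study (structure + calls + genotypes).

    If ``seed`` is given it deterministically re-seeds both component configs
    (feature seed = seed, pedigree seed = seed + 1), so a single integer
    reproduces the whole study.
    """
    sizes = DEFAULT_GANG_PARTY_SIZES if gang_party_sizes is None else gang_party_sizes
    structure = build_structure(sizes)
    fcfg = feature_config or FeatureSimConfig()
    pcfg = pedigree_config or PedigreeSimConfig()
    if seed is not None:
        fcfg = replace(fcfg, seed=int(seed))
        pcfg = replace(pcfg, seed=int(seed) + 1)
    features = simulate_features(structure, fcfg)
    genotypes, kinship = simulate_genotypes(structure, pcfg)
    return SimulatedStudy(structure, features, genotypes, kinship, fcfg, pcfg)
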