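"""Microsatellite locus screening and pairwise Wang relatedness.

Loci are screened with an exact Hardy–Weinberg test (complete enumeration of
allele pairings for small samples, seeded Monte-Carlo otherwise) and a
heterozygote-deficit null-allele estimate r = (He - Ho) / (1 + He); a locus is
excluded only when BOTH flags fire (null-allele estimate above threshold AND
HWE p below alpha), mirroring the conjunction used in practice.

Pairwise relatedness uses Wang's (2002) moment estimator.  For a dyad at one
locus the genotype pair falls into one of four similarity categories

    1: identical genotypes           3: two heterozygotes sharing one allele
    2: homozygote + heterozygote     4: no allele in common
       sharing an allele

whose probabilities are linear in phi (exactly one pair of alleles IBD) and
Delta (two pairs IBD).  With allele-frequency moments a_m = sum_i p_i^m and

    b = 2 a2² - a4                e = 2 (a2 - 3 a3 + 2 a4)
    c = a2 - 2 a2² + a4           f = 4 (a2 - a2² - 2 a3 + 2 a4)
    d = 4 (a3 - a4)               g = 1 - 7 a2 + 4 a2² + 10 a3 - 8 a4

the moment equations are

    P1 = b + c phi + (1 - b) Delta
    P2 = d + e phi - d Delta
    P3 = f + g phi - f Delta.

Loci are combined by averaging the observed category indicators and the
coefficients with weights 1/u, u = 2 a2 - a4 (more polymorphic loci weigh
more); the overdetermined 3×2 system is solved by least squares and

    r = phi / 2 + Delta.

When frequencies are estimated from the sample the moments a2, a3, a4 are
replaced by their unbiased factorial-moment estimators (Wang's small-sample
bias correction); frequencies passed in explicitly are treated as known.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DyadicMatrix, GenotypeTable

logger = logging.getLogger("convergekit")

__all__ = [
    "LocusReport",
    "allele_frequencies",
    "hwe_exact_test",
    "null_allele_screen",
    "screen_loci",
    "filter_loci",
    "wang_pairwise",
    "wang_for_pairs",
]

#: complete HWE enumeration is used when the locus has at most this many
#: typed gene copies (14 copies → 135135 pairings)
HWE_ENUMERATION_MAX_GENES = 14


# ---------------------------------------------------------------------------
# allele frequencies and locus screening


def _locus_genotypes(table: GenotypeTable, locus: str) -> np.ndarray:
    """Non-missing (n_typed, 2) allele array at the locus."""
    j = table.locus_index(locus)
    a = table.alleles[:, j, :]
    return a[a[:, 0] > 0]


def allele_frequencies(table: GenotypeTable, locus: str) -> dict[int, float]:
    """Observed allele frequencies at a locus (counts over 2 × typed)."""
    geno = _locus_genotypes(table, locus)
    if len(geno) == 0:
        raise ValueError(f"locus {locus!r} has no typed individuals")
    vals, counts = np.unique(geno.ravel(), return_counts=True)
    total = counts.sum()
    return {int(v): float(c) / total for v, c in zip(vals, counts)}


def _levene_log_prob(genotype_counts: dict[tuple[int, int], int], allele_counts: dict[int, int]) -> float:
    """Log conditional probability of a genotype array given allele counts.

    Levene (1949): P = n! 2^h prod_i x_i! / ((2n)! prod_{ij} n_ij!) with h the
    number of heterozygotes.
    """
    n = sum(genotype_counts.values())
    h = sum(c for (a, b), c in genotype_counts.items() if a != b)
    logp = math.lgamma(n + 1) + h * math.log(2.0)
    logp += sum(math.lgamma(x + 1) for x in allele_counts.values())
    logp -= math.lgamma(2 * n + 1)
    logp -= sum(math.lgamma(c + 1) for c in genotype_counts.values())
    return logp


def _geno_counts(geno: np.ndarray) -> dict[tuple[int, int], int]:
    out: dict[tuple[int, int], int] = {}
    for a, b in geno:
        key = (int(min(a, b)), int(max(a, b)))
        out[key] = out.get(key, 0) + 1
    return out


def _enumerate_pairings(genes: tuple[int, ...]):
    """Yield (genotype_counts, weight) over all perfect pairings of the gene list.

    Weight = number of distinct pairings mapping to that leaf path; pairings
    are enumerated by always pairing the first remaining gene.
    """
    def rec(remaining: list[int], acc: dict[tuple[int, int], int], weight: int):
        if not remaining:
            yield dict(acc), weight
            return
        first = remaining[0]
        rest = remaining[1:]
        # group identical partners to avoid redundant branches
        seen: dict[int, int] = {}
        for x in rest:
            seen[x] = seen.get(x, 0) + 1
        for partner, cnt in seen.items():
            nxt = list(rest)
            nxt.remove(partner)
            key = (min(first, partner), max(first, partner))
            acc[key] = acc.get(key, 0) + 1
            yield from rec(nxt, acc, weight * cnt)
            acc[key] -= 1
            if acc[key] == 0:
                del acc[key]
    yield from rec(list(genes), {}, 1)


def hwe_exact_test(
    table: GenotypeTable,
    locus: str,
    n_mc: int = 100_000,
    seed: int = 0,
) -> float:
    """Exact conditional Hardy–Weinberg test (probability ordering).

    Complete enumeration of allele pairings when the locus has at most
    ``HWE_ENUMERATION_MAX_GENES`` typed gene copies; otherwise seeded
    Monte-Carlo shuffling of the gene vector with the add-one correction.
    A monomorphic locus returns p = 1 by convention (logged).  Fewer than 5
    typed individuals is flagged low-power but still computed.
    """
    geno = _locus_genotypes(table, locus)
    if len(geno) == 0:
        raise ValueError(f"locus {locus!r} has no typed individuals")
    if len(geno) < 5:
        logger.warning("HWE test at %s: only %d typed individuals (low power)", locus, len(geno))
    genes = geno.ravel()
    allele_counts = {int(v): int(c) for v, c in zip(*np.unique(genes, return_counts=True))}
    if len(allele_counts) < 2:
        logger.info("HWE test at %s: monomorphic locus, p = 1 by convention", locus)
        return 1.0
    obs_logp = _levene_log_prob(_geno_counts(geno), allele_counts)
    tol = 1e-9

    if len(genes) <= HWE_ENUMERATION_MAX_GENES:
        hit = 0.0
        total = 0.0
        for counts, weight in _enumerate_pairings(tuple(int(x) for x in genes)):
            total += weight
            if _levene_log_prob(counts, allele_counts) <= obs_logp + tol:
                hit += weight
        return hit / total

    return _hwe_monte_carlo(np.asarray(genes, dtype=int), n_mc, seed, tol)


def _hwe_monte_carlo(genes: np.ndarray, n_mc: int, seed: int, tol: float) -> float:
    """Vectorized Monte-Carlo HWE p-value (probability ordering, add-one).

    Only the shuffle-dependent part of the Levene log-probability is used as
    the statistic: s = h log 2 - sum_ij lgamma(n_ij + 1).
    """
    from scipy.special import gammaln

    codes, coded = np.unique(genes, return_inverse=True)
    K = len(codes)
    n_pairs = len(genes) // 2

    def stat_batch(pairs: np.ndarray) -> np.ndarray:
        # pairs: (B, n_pairs, 2) of dense allele codes, sorted on last axis
        h = (pairs[:, :, 0] != pairs[:, :, 1]).sum(axis=1)
        code = pairs[:, :, 0] * K + pairs[:, :, 1]
        B = pairs.shape[0]
        flat = (np.arange(B)[:, None] * (K * K) + code).ravel()
        counts = np.bincount(flat, minlength=B * K * K).reshape(B, K * K)
        return h * math.log(2.0) - gammaln(counts + 1.0).sum(axis=1)

    obs_pairs = np.sort(coded.reshape(1, n_pairs, 2), axis=2)
    s_obs = stat_batch(obs_pairs)[0]

    rng = np.random.default_rng(seed)
    hit = 0
    chunk = 5000
    done = 0
    while done < n_mc:
        B = min(chunk, n_mc - done)
        keys = rng.random((B, 2 * n_pairs))
        order = np.argsort(keys, axis=1)
        shuffled = coded[order].reshape(B, n_pairs, 2)
        shuffled.sort(axis=2)
        hit += int((stat_batch(shuffled) <= s_obs + tol).sum())
        done += B
    return (hit + 1) / (n_mc + 1)


def _heterozygosities(geno: np.ndarray) -> tuple[float, float]:
    """(observed, expected) heterozygosity of a typed genotype array."""
    ho = float((geno[:, 0] != geno[:, 1]).mean())
    _, counts = np.unique(geno.ravel(), return_counts=True)
    p = counts / counts.sum()
    he = float(1.0 - (p ** 2).sum())
    return ho, he


def null_allele_screen(table: GenotypeTable, locus: str) -> float:
    """Chakraborty heterozygote-deficit null-allele estimate (He-Ho)/(1+He)."""
    geno = _locus_genotypes(table, locus)
    if len(geno) == 0:
        raise ValueError(f"locus {locus!r} has no typed individuals")
    ho, he = _heterozygosities(geno)
    if he == 0.0:
        return 0.0
    return max((he - ho) / (1.0 + he), 0.0)


@dataclass
class LocusReport:
    locus: str
    frequencies: dict[int, float]
    n_typed: int
    ho: float
    he: float
    hwe_p: float
    null_freq: float
    excluded: bool = False
    reason: str | None = None


def screen_loci(
    table: GenotypeTable,
    hwe_alpha: float = 0.05,
    null_threshold: float = 0.05,
    hwe_mc: int = 100_000,
    seed: int = 0,
) -> list[LocusReport]:
    """Per-locus report: frequencies, heterozygosities, HWE p, null estimate.

    A locus is flagged for exclusion only when the null-allele estimate
    exceeds ``null_threshold`` AND the HWE p-value falls below ``hwe_alpha``.
    """
    reports = []
    for k, locus in enumerate(table.loci):
        geno = _locus_genotypes(table, locus)
        if len(geno) == 0:
            reports.append(
                LocusReport(locus, {}, 0, np.nan, np.nan, np.nan, np.nan, True, "no typed individuals")
            )
            continue
        freqs = allele_frequencies(table, locus)
        ho, he = _heterozygosities(geno)
        hwe_p = hwe_exact_test(table, locus, n_mc=hwe_mc, seed=seed + k)
        null = null_allele_screen(table, locus)
        flagged = null > null_threshold and hwe_p < hwe_alpha
        reports.append(
            LocusReport(
                locus, freqs, len(geno), ho, he, hwe_p, null,
                excluded=flagged,
                reason="null alleles + HWE deviation" if flagged else None,
            )
        )
    return reports


def filter_loci(reports: list[LocusReport]) -> list[str]:
    """Names of retained loci; raises if every locus is excluded."""
    kept = [r.locus for r in reports if not r.excluded]
    dropped = [(r.locus, r.reason) for r in reports if r.excluded]
    for locus, reason in dropped:
        logger.info("excluding locus %s: %s", locus, reason)
    if not kept:
        raise ValueError("all loci excluded by the screening rules")
    return kept


def reports_frame(reports: list[LocusReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus": r.locus,
                "n_typed": r.n_typed,
                "n_alleles": len(r.frequencies),
                "Ho": r.ho,
                "He": r.he,
                "hwe_p": r.hwe_p,
                "null_freq": r.null_freq,
                "excluded": r.excluded,
                "reason": r.reason or "",
            }
            for r in reports
        ]
    )


# ---------------------------------------------------------------------------
# Wang pairwise relatedness


def _moments_from_frequencies(freqs: np.ndarray) -> tuple[float, float, float]:
    a2 = float((freqs ** 2).sum())
    a3 = float((freqs ** 3).sum())
    a4 = float((freqs ** 4).sum())
    return a2, a3, a4


def _unbiased_moments(counts: np.ndarray) -> tuple[float, float, float] | None:
    """Unbiased estimators of a2, a3, a4 from allele counts (factorial moments)."""
    S = counts.sum()
    if S < 4:
        return None
    x = counts.astype(float)
    a2 = float((x * (x - 1)).sum() / (S * (S - 1)))
    a3 = float((x * (x - 1) * (x - 2)).sum() / (S * (S - 1) * (S - 2)))
    a4 = float((x * (x - 1) * (x - 2) * (x - 3)).sum() / (S * (S - 1) * (S - 2) * (S - 3)))
    return a2, a3, a4


def _locus_coefficients(a2: float, a3: float, a4: float) -> tuple[float, ...]:
    b = 2 * a2 ** 2 - a4
    c = a2 - 2 * a2 ** 2 + a4
    d = 4 * (a3 - a4)
    e = 2 * (a2 - 3 * a3 + 2 * a4)
    f = 4 * (a2 - a2 ** 2 - 2 * a3 + 2 * a4)
    g = 1 - 7 * a2 + 4 * a2 ** 2 + 10 * a3 - 8 * a4
    u = 2 * a2 - a4
    return b, c, d, e, f, g, u


def _dyad_categories(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Similarity category (1..4) for genotype arrays A, B of shape (m, 2).

    Alleles are assumed sorted within the genotype.  Category 4 collects all
    no-shared-allele configurations (including distinct homozygotes).
    """
    a1, a2_ = A[:, 0], A[:, 1]
    b1, b2 = B[:, 0], B[:, 1]
    identical = (a1 == b1) & (a2_ == b2)
    homA = a1 == a2_
    homB = b1 == b2
    share = (
        (a1 == b1) | (a1 == b2) | (a2_ == b1) | (a2_ == b2)
    )
    cat = np.full(len(A), 4, dtype=int)
    cat[share & (homA ^ homB)] = 2
    cat[share & ~homA & ~homB] = 3
    cat[identical] = 1
    return cat


def _locus_tables(
    table: GenotypeTable,
    frequencies: dict[str, dict[int, float]] | None,
) -> tuple[list[int], list[tuple[float, ...]]]:
    """Usable locus indices and their (b..g, u) coefficient tuples."""
    usable: list[int] = []
    coeffs: list[tuple[float, ...]] = []
    for j, locus in enumerate(table.loci):
        a = table.alleles[:, j, :]
        typed = a[a[:, 0] > 0]
        if len(typed) == 0:
            logger.info("Wang: skipping all-missing locus %s", locus)
            continue
        vals, counts = np.unique(typed.ravel(), return_counts=True)
        if frequencies is not None and locus in frequencies:
            fr = frequencies[locus]
            p = np.array(list(fr.values()), dtype=float)
            if not math.isclose(p.sum(), 1.0, rel_tol=0, abs_tol=1e-6):
                raise ValueError(f"frequencies at {locus!r} do not sum to 1")
            if len(p) < 2:
                logger.info("Wang: skipping locus %s with < 2 alleles", locus)
                continue
            a2, a3, a4 = _moments_from_frequencies(p)
        else:
            if len(vals) < 2:
                logger.info("Wang: skipping locus %s with < 2 observed alleles", locus)
                continue
            mom = _unbiased_moments(counts)
            if mom is None:
                logger.info("Wang: skipping locus %s (too few gene copies)", locus)
                continue
            a2, a3, a4 = mom
        usable.append(j)
        coeffs.append(_locus_coefficients(a2, a3, a4))
    return usable, coeffs


def wang_for_pairs(
    table: GenotypeTable,
    pairs: list[tuple[str, str]],
    frequencies: dict[str, dict[int, float]] | None = None,
) -> np.ndarray:
    """Wang relatedness for an explicit list of dyads.

    ``frequencies`` maps locus → {allele: freq}; when omitted, frequencies are
    estimated from the full table with the small-sample bias correction.
    Dyads with no shared typed (usable) locus get NaN (logged).
    """
    usable, coeffs = _locus_tables(table, frequencies)
    if not usable:
        raise ValueError("no usable locus for the Wang estimator")
    pos = {v: k for k, v in enumerate(table.individuals)}
    ia = np.array([pos[a] for a, _ in pairs])
    ib = np.array([pos[b] for _, b in pairs])
    n_pairs = len(pairs)

    # per dyad, accumulate weighted indicators and weighted coefficients
    sumw = np.zeros(n_pairs)
    P = np.zeros((n_pairs, 3))
    C = np.zeros((n_pairs, 6))  # b, c, d, e, f, g averaged with the same weights
    for j, (b, c, d, e, f, g, u) in zip(usable, coeffs):
        A = table.alleles[ia, j, :]
        B = table.alleles[ib, j, :]
        ok = (A[:, 0] > 0) & (B[:, 0] > 0)
        if not ok.any():
            continue
        w = 1.0 / u
        cat = _dyad_categories(A[ok], B[ok])
        idx = np.flatnonzero(ok)
        sumw[idx] += w
        for k in (1, 2, 3):
            P[idx[cat == k], k - 1] += w
        C[idx] += w * np.array([b, c, d, e, f, g])

    out = np.full(n_pairs, np.nan)
    have = sumw > 0
    if not have.all():
        logger.info("Wang: %d dyads share no typed locus (NaN)", int((~have).sum()))
    Pn = P[have] / sumw[have, None]
    Cn = C[have] / sumw[have, None]
    vals = np.empty(Pn.shape[0])
    for r in range(Pn.shape[0]):
        b, c, d, e, f, g = Cn[r]
        M = np.array([[c, 1.0 - b], [e, -d], [g, -f]])
        y = Pn[r] - np.array([b, d, f])
        theta, *_ = np.linalg.lstsq(M, y, rcond=None)
        phi, delta = theta
        vals[r] = phi / 2.0 + delta
    out[have] = vals
    return out


def wang_pairwise(
    table: GenotypeTable,
    frequencies: dict[str, dict[int, float]] | None = None,
) -> DyadicMatrix:
    """Full symmetric Wang relatedness matrix (diagonal set to 1)."""
    ids = table.individuals
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    pairs = [(ids[i], ids[j]) for i, j in zip(*iu)]
    vals = wang_for_pairs(table, pairs, frequencies)
    W = np.zeros((n, n))
    W[iu] = vals
    W = W + W.T
    np.fill_diagonal(W, 1.0)
    return DyadicMatrix(tuple(ids), W, kind="relatedness_W")
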