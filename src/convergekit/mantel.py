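"""Mantel correlation and categorical Mantel tests over dyadic matrices.

Supports free permutation of individuals and restricted permutation within
blocks (e.g. party labels shuffled only among males of the same gang — the
scheme used to test party-level convergence while holding gang membership
fixed).  Also provides the relatedness-quartile contrast, which compares a
continuous dyadic outcome between the most- and least-related dyads.

Permutation p-values use the add-one correction p = (#{null >= obs} + 1) /
(n_perm + 1); with ``exhaustive=True`` the scheme enumerates every allowed
permutation (identity included) and the p-value is exact.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from .core import DyadicMatrix, PermutationResult, SocialStructure

logger = logging.getLogger("convergekit")

__all__ = [
    "PermutationScheme",
    "CategoricalContrast",
    "membership_matrix",
    "mantel_test",
    "categorical_mantel",
    "restricted_permute",
    "quartile_contrast",
]


@dataclass
class PermutationScheme:
    """How individuals are permuted to build the null distribution.

    ``kind='free'`` permutes all individuals; ``kind='within_blocks'``
    permutes only within the given block labels (every individual needs a
    block).  ``exhaustive=True`` replaces random sampling by complete
    enumeration of the allowed permutations.
    """

    kind: str = "free"
    blocks: Mapping[str, str] | None = None
    n_permutations: int = 1000
    seed: int | None = None
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("free", "within_blocks"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.kind == "within_blocks" and self.blocks is None:
            raise ValueError("within_blocks scheme requires block labels")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    def describe(self) -> str:
        return self.kind if not self.exhaustive else f"{self.kind}(exhaustive)"

    # -- permutation generation -----------------------------------------

    def _block_groups(self, ids: Sequence[str]) -> list[np.ndarray]:
        assert self.blocks is not None
        missing = [i for i in ids if i not in self.blocks]
        if missing:
            raise ValueError(f"individuals without a block: {missing}")
        groups: dict[str, list[int]] = {}
        for k, i in enumerate(ids):
            groups.setdefault(self.blocks[i], []).append(k)
        return [np.array(v) for v in groups.values()]

    def sample(self, ids: Sequence[str], rng: np.random.Generator) -> np.ndarray:
        n = len(ids)
        if self.kind == "free":
            return rng.permutation(n)
        perm = np.arange(n)
        for idx in self._block_groups(ids):
            perm[idx] = idx[rng.permutation(len(idx))]
        return perm

    def enumerate(self, ids: Sequence[str]) -> Iterator[np.ndarray]:
        n = len(ids)
        if self.kind == "free":
            for p in itertools.permutations(range(n)):
                yield np.array(p)
            return
        groups = self._block_groups(ids)
        pools = [list(itertools.permutations(idx)) for idx in groups]
        for combo in itertools.product(*pools):
            perm = np.arange(n)
            for idx, assigned in zip(groups, combo):
                perm[idx] = np.array(assigned)
            yield perm

    def count(self, ids: Sequence[str]) -> int:
        if self.kind == "free":
            return math.factorial(len(ids))
        return int(np.prod([math.factorial(len(idx)) for idx in self._block_groups(ids)]))


def membership_matrix(structure: SocialStructure, level: str) -> DyadicMatrix:
    """Binary same-membership matrix at ``level`` ('gang' or 'party')."""
    if level == "gang":
        labels = structure.gang_labels()
    elif level == "party":
        labels = structure.party_labels()
    else:
        raise ValueError(f"unknown level {level!r} (expected 'gang' or 'party')")
    same = (labels[:, None] == labels[None, :]).astype(float)
    return DyadicMatrix(tuple(structure.individuals), same, kind="membership")


def _p_value(null: np.ndarray, observed: float, alternative: str, exhaustive: bool) -> float:
    if alternative == "greater":
        hits = int((null >= observed - 1e-12).sum())
    elif alternative == "less":
        hits = int((null <= observed + 1e-12).sum())
    elif alternative == "two-sided":
        hits = int((np.abs(null) >= abs(observed) - 1e-12).sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    if exhaustive:
        # identity permutation is part of the enumerated null
        return hits / len(null)
    return (hits + 1) / (len(null) + 1)


def mantel_test(
    A: DyadicMatrix,
    B: DyadicMatrix,
    scheme: PermutationScheme | None = None,
    alternative: str = "two-sided",
) -> PermutationResult:
    """Mantel matrix correlation test.

    Observed statistic: Pearson correlation over the off-diagonal upper
    triangle.  Null: simultaneous row/column permutation of B's individuals
    under the scheme.  Dyads that are NaN in either matrix are dropped
    pairwise (per permutation).
    """
    scheme = scheme or PermutationScheme()
    if A.ids != B.ids:
        B = B.reindex(A.ids)
    n = A.n
    iu = np.triu_indices(n, k=1)
    va = A.values[iu]

    def corr(bmat: np.ndarray) -> float:
        vb = bmat[iu]
        ok = np.isfinite(va) & np.isfinite(vb)
        x, y = va[ok], vb[ok]
        if len(x) < 3 or x.std() == 0 or y.std() == 0:
            raise ValueError("Mantel correlation undefined (zero variance or too few dyads)")
        return float(np.corrcoef(x, y)[0, 1])

    observed = corr(B.values)
    rng = np.random.default_rng(scheme.seed)
    if scheme.exhaustive:
        null = np.array([corr(B.values[np.ix_(p, p)]) for p in scheme.enumerate(A.ids)])
    else:
        null = np.array(
            [corr(B.values[np.ix_(p, p)]) for p in (scheme.sample(A.ids, rng) for _ in range(scheme.n_permutations))]
        )
    return PermutationResult(
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if len(null) > 1 else 0.0,
        n_permutations=len(null),
        p_value=_p_value(null, observed, alternative, scheme.exhaustive),
        seed=scheme.seed,
        scheme=scheme.describe(),
        alternative=alternative,
        extra={"statistic": "pearson_r"},
    )


@dataclass
class CategoricalContrast:
    """Two-sided dyad contrast: values split by a categorical dyad label."""

    label_a: str
    label_b: str
    values_a: np.ndarray  # e.g. same-group dyads
    values_b: np.ndarray  # e.g. different-group dyads
    mean_difference: float  # mean(values_b) - mean(values_a)
    result: PermutationResult

    @property
    def n_a(self) -> int:
        return len(self.values_a)

    @property
    def n_b(self) -> int:
        return len(self.values_b)


def restricted_permute(
    labels: Sequence, blocks: Sequence, rng: np.random.Generator
) -> np.ndarray:
    """Shuffle ``labels`` within each block; labels never cross blocks."""
    labels = np.asarray(labels, dtype=object)
    blocks = np.asarray(blocks, dtype=object)
    if labels.shape != blocks.shape:
        raise ValueError("labels and blocks must have the same length")
    out = labels.copy()
    for b in np.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        out[idx] = labels[idx[rng.permutation(len(idx))]]
    return out


def categorical_mantel(
    values: DyadicMatrix,
    structure: SocialStructure,
    level: str,
    scheme: PermutationScheme | None = None,
    alternative: str = "greater",
) -> CategoricalContrast:
    """Categorical Mantel test of a dyadic outcome against group membership.

    Observed statistic: mean(different-group dyads) - mean(same-group dyads).
    For ``level='gang'`` the dyad universe is all dyads and the default
    scheme permutes individuals freely; for ``level='party'`` the universe is
    restricted to same-gang dyads and party labels are permuted within gangs.
    ``alternative='greater'`` is the convergence direction for dissimilarity
    matrices (same-group dyads less dissimilar); use ``'less'`` for
    relatedness (same-group dyads more related).
    """
    ids = list(values.ids)
    if set(ids) != set(structure.individuals):
        raise ValueError("matrix ids do not match the structure")
    gang = structure.gang_labels(ids)
    if level == "gang":
        labels = gang
        universe = np.ones((len(ids), len(ids)), dtype=bool)
        default_scheme = PermutationScheme(kind="free", n_permutations=1000)
        block_vec = None
    elif level == "party":
        labels = structure.party_labels(ids)
        universe = gang[:, None] == gang[None, :]
        default_scheme = PermutationScheme(
            kind="within_blocks",
            blocks=dict(structure.gang_of),
            n_permutations=10_000,
        )
        block_vec = gang
    else:
        raise ValueError(f"unknown level {level!r}")
    scheme = scheme or default_scheme

    n = len(ids)
    iu = np.triu_indices(n, k=1)
    V = values.values
    in_universe = universe[iu]
    vals = V[iu]
    finite = np.isfinite(vals)
    dropped = int((~finite & in_universe).sum())
    if dropped:
        logger.info("categorical Mantel: dropping %d dyads with missing values", dropped)
    use = in_universe & finite

    def statistic(lab: np.ndarray) -> tuple[float, np.ndarray]:
        same = (lab[:, None] == lab[None, :])[iu]
        a = vals[use & same]
        b = vals[use & ~same]
        if len(a) == 0 or len(b) == 0:
            raise ValueError("a side of the contrast has zero dyads")
        return float(b.mean() - a.mean()), same

    observed, same_mask = statistic(labels)
    rng = np.random.default_rng(scheme.seed)

    def permuted_labels() -> Iterator[np.ndarray]:
        if scheme.exhaustive:
            for p in scheme.enumerate(ids):
                yield labels[p]
        else:
            for _ in range(scheme.n_permutations):
                yield labels[scheme.sample(ids, rng)]

    null = np.array([statistic(lab)[0] for lab in permuted_labels()])
    if block_vec is not None and scheme.kind != "within_blocks":
        logger.warning("party-level contrast run with a %s scheme", scheme.kind)

    result = PermutationResult(
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if len(null) > 1 else 0.0,
        n_permutations=len(null),
        p_value=_p_value(null, observed, alternative, scheme.exhaustive),
        seed=scheme.seed,
        scheme=scheme.describe(),
        alternative=alternative,
        extra={"statistic": "mean_diff_minus_same", "level": level},
    )
    return CategoricalContrast(
        label_a=f"same_{level}",
        label_b=f"different_{level}",
        values_a=vals[use & same_mask],
        values_b=vals[use & ~same_mask],
        mean_difference=observed,
        result=result,
    )


def quartile_contrast(
    W: DyadicMatrix,
    D: DyadicMatrix,
    q: float = 0.25,
    n_permutations: int = 1000,
    seed: int | None = None,
    alternative: str = "less",
) -> CategoricalContrast:
    """Contrast of D between the most- and least-related dyads.

    Dyads are split by the empirical ``q`` and ``1-q`` quantiles of W with
    strict inequalities (ties fall in neither side).  The null permutes the
    high/low assignment across the selected dyads.  ``alternative='less'``
    is the direction "more-related dyads are less dissimilar".
    """
    if not 0.0 < q < 0.5:
        raise ValueError("q must be in (0, 0.5)")
    if W.ids != D.ids:
        D = D.reindex(W.ids)
    w = W.condensed()
    d = D.condensed()
    ok = np.isfinite(w) & np.isfinite(d)
    w, d = w[ok], d[ok]
    lo_thr = np.quantile(w, q)
    hi_thr = np.quantile(w, 1.0 - q)
    high = w > hi_thr
    low = w < lo_thr
    if not high.any() or not low.any():
        n_lo_ties = int((w == lo_thr).sum())
        n_hi_ties = int((w == hi_thr).sum())
        raise ValueError(
            "empty quartile side under strict thresholds "
            f"(ties at lower threshold: {n_lo_ties}, upper: {n_hi_ties})"
        )
    sel = high | low
    vals = d[sel]
    grp = high[sel]  # True = high relatedness
    observed = float(vals[grp].mean() - vals[~grp].mean())
    rng = np.random.default_rng(seed)
    n_high = int(grp.sum())
    null = np.empty(n_permutations)
    for k in range(n_permutations):
        perm = rng.permutation(len(vals))
        pg = np.zeros(len(vals), dtype=bool)
        pg[perm[:n_high]] = True
        null[k] = vals[pg].mean() - vals[~pg].mean()
    result = PermutationResult(
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if len(null) > 1 else 0.0,
        n_permutations=n_permutations,
        p_value=_p_value(null, observed, alternative, exhaustive=False),
        seed=seed,
        scheme="dyad_label_permutation",
        alternative=alternative,
        extra={
            "statistic": "mean_high_minus_low",
            "w_threshold_low": float(lo_thr),
            "w_threshold_high": float(hi_thr),
        },
    )
    return CategoricalContrast(
        label_a="low_W",
        label_b="high_W",
        values_a=vals[~grp],
        values_b=vals[grp],
        mean_difference=observed,
        result=result,
    )
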