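"""Core containers shared across the analysis pipeline.

Four tabular/matrix objects move between stages:

* :class:`SocialStructure` — the individual → party → gang nesting that defines
  dyadic membership and the permutation blocks of the restricted tests.
* :class:`CallFeatureTable` — one row per recorded call, numeric acoustic
  features plus the caller's identity; input to the discriminant analysis.
* :class:`GenotypeTable` — diploid codominant (microsatellite) genotypes,
  individual × locus, two integer alleles per locus with 0 marking missing.
* :class:`DyadicMatrix` — a symmetric individual × individual matrix: acoustic
  dissimilarity ln(1+F), pairwise relatedness W, or binary same-membership.

All containers round-trip through plain CSV so that every intermediate of a
study can be inspected with ordinary tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("convergekit")

__all__ = [
    "SocialStructure",
    "CallFeatureTable",
    "GenotypeTable",
    "DyadicMatrix",
    "PermutationResult",
]


@dataclass(frozen=True)
class SocialStructure:
    """Nested social structure: individuals within parties within gangs.

    Every individual belongs to exactly one party and one gang, and every
    party is nested in exactly one gang.  Violations raise ``ValueError`` at
    construction time.
    """

    individuals: tuple[str, ...]
    party_of: Mapping[str, str]
    gang_of: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.individuals) == 0:
            raise ValueError("structure has no individuals")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual ids")
        for ind in self.individuals:
            if ind not in self.party_of or ind not in self.gang_of:
                raise ValueError(f"individual {ind!r} lacks a party or gang")
        # nesting: a party never spans two gangs
        party_gang: dict[str, str] = {}
        for ind in self.individuals:
            p, g = self.party_of[ind], self.gang_of[ind]
            if party_gang.setdefault(p, g) != g:
                raise ValueError(f"party {p!r} appears in more than one gang")

    # -- derived views ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def parties(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(self.party_of[ind], None)
        return tuple(seen)

    @property
    def gangs(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(self.gang_of[ind], None)
        return tuple(seen)

    def party_members(self, party: str) -> tuple[str, ...]:
        return tuple(i for i in self.individuals if self.party_of[i] == party)

    def gang_members(self, gang: str) -> tuple[str, ...]:
        return tuple(i for i in self.individuals if self.gang_of[i] == gang)

    def party_labels(self, ids: Sequence[str] | None = None) -> np.ndarray:
        ids = self.individuals if ids is None else ids
        return np.array([self.party_of[i] for i in ids])

    def gang_labels(self, ids: Sequence[str] | None = None) -> np.ndarray:
        ids = self.individuals if ids is None else ids
        return np.array([self.gang_of[i] for i in ids])

    # -- IO ----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual": list(self.individuals),
                "party": [self.party_of[i] for i in self.individuals],
                "gang": [self.gang_of[i] for i in self.individuals],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SocialStructure":
        required = {"individual", "party", "gang"}
        if not required.issubset(df.columns):
            raise ValueError(f"structure table needs columns {sorted(required)}")
        inds = tuple(str(i) for i in df["individual"])
        return cls(
            individuals=inds,
            party_of=dict(zip(inds, (str(p) for p in df["party"]))),
            gang_of=dict(zip(inds, (str(g) for g in df["gang"]))),
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "SocialStructure":
        return cls.from_frame(pd.read_csv(path, dtype=str))


class CallFeatureTable:
    """Per-call acoustic features with the caller's identity.

    Wraps a DataFrame with columns ``call_id``, ``individual_id`` and one
    numeric column per acoustic feature.
    """

    META_COLS = ("call_id", "individual_id")

    def __init__(self, data: pd.DataFrame):
        for col in self.META_COLS:
            if col not in data.columns:
                raise ValueError(f"feature table needs a {col!r} column")
        feats = [c for c in data.columns if c not in self.META_COLS]
        if not feats:
            raise ValueError("feature table has no feature columns")
        X = data[feats].to_numpy(dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")
        if data["individual_id"].nunique() < 2:
            raise ValueError("feature table needs at least two individuals")
        if data["call_id"].duplicated().any():
            raise ValueError("duplicate call ids")
        self.data = data.reset_index(drop=True)
        self._features = feats

    @property
    def feature_names(self) -> list[str]:
        return list(self._features)

    @property
    def X(self) -> np.ndarray:
        return self.data[self._features].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.data["individual_id"].to_numpy(dtype=object)

    @property
    def individuals(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.data["individual_id"]:
            seen.setdefault(str(v), None)
        return list(seen)

    def counts(self) -> pd.Series:
        return self.data["individual_id"].value_counts()

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, row_idx: Iterable[int]) -> "CallFeatureTable":
        return CallFeatureTable(self.data.iloc[list(row_idx)].reset_index(drop=True))

    def select_features(self, names: Sequence[str]) -> np.ndarray:
        missing = [n for n in names if n not in self._features]
        if missing:
            raise KeyError(f"unknown features {missing}")
        return self.data[list(names)].to_numpy(dtype=float)

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "CallFeatureTable":
        return cls(pd.read_csv(path))


class GenotypeTable:
    """Diploid codominant genotypes: individual × locus, integer alleles.

    ``alleles`` has shape ``(n_individuals, n_loci, 2)``; allele codes are
    positive integers and 0 marks a missing genotype (both copies).
    """

    def __init__(self, individuals: Sequence[str], loci: Sequence[str], alleles: np.ndarray):
        alleles = np.asarray(alleles, dtype=int)
        if alleles.shape != (len(individuals), len(loci), 2):
            raise ValueError("alleles must have shape (n_individuals, n_loci, 2)")
        if (alleles < 0).any():
            raise ValueError("allele codes must be non-negative (0 = missing)")
        half = (alleles == 0).sum(axis=2) == 1
        if half.any():
            raise ValueError("half-missing genotypes are not allowed (both alleles or none)")
        if len(set(individuals)) != len(individuals):
            raise ValueError("duplicate individual ids")
        if len(set(loci)) != len(loci):
            raise ValueError("duplicate locus names")
        self.individuals = list(map(str, individuals))
        self.loci = list(map(str, loci))
        self.alleles = alleles

    @property
    def n(self) -> int:
        return len(self.individuals)

    def typed_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci): genotype present."""
        return self.alleles[:, :, 0] > 0

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def subset_loci(self, names: Sequence[str]) -> "GenotypeTable":
        idx = [self.locus_index(n) for n in names]
        return GenotypeTable(self.individuals, [self.loci[i] for i in idx], self.alleles[:, idx, :])

    def to_frame(self) -> pd.DataFrame:
        cols = {"individual": self.individuals}
        for j, locus in enumerate(self.loci):
            cols[f"{locus}_a1"] = self.alleles[:, j, 0]
            cols[f"{locus}_a2"] = self.alleles[:, j, 1]
        return pd.DataFrame(cols)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeTable":
        if "individual" not in df.columns:
            raise ValueError("genotype table needs an 'individual' column")
        loci = []
        for col in df.columns:
            if col.endswith("_a1"):
                name = col[:-3]
                if f"{name}_a2" not in df.columns:
                    raise ValueError(f"locus {name!r} lacks its _a2 column")
                loci.append(name)
        if not loci:
            raise ValueError("no locus columns (expected pairs like L1_a1,L1_a2)")
        n = len(df)
        alleles = np.zeros((n, len(loci), 2), dtype=int)
        for j, name in enumerate(loci):
            alleles[:, j, 0] = df[f"{name}_a1"].to_numpy(dtype=int)
            alleles[:, j, 1] = df[f"{name}_a2"].to_numpy(dtype=int)
        return cls([str(i) for i in df["individual"]], loci, alleles)

    @classmethod
    def read_csv(cls, path) -> "GenotypeTable":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class DyadicMatrix:
    """Symmetric individual × individual matrix with a semantic kind tag.

    ``kind`` is one of ``pairwise_F``, ``dissimilarity_lnF``, ``relatedness_W``
    or ``membership``.  The diagonal is 0 for F and ln(1+F) matrices, 1 for
    membership and self-relatedness.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        self.ids = tuple(map(str, self.ids))
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids")
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        finite = np.isfinite(self.values)
        sym_ok = np.allclose(
            np.where(finite, self.values, 0.0),
            np.where(finite.T, self.values.T, 0.0),
            atol=1e-10,
        ) and (finite == finite.T).all()
        if not sym_ok:
            raise ValueError("matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (off-diagonal) values, row-major — one per dyad."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def dyads(self) -> list[tuple[str, str]]:
        iu = np.triu_indices(self.n, k=1)
        return [(self.ids[i], self.ids[j]) for i, j in zip(*iu)]

    def reindex(self, ids: Sequence[str]) -> "DyadicMatrix":
        ids = tuple(map(str, ids))
        pos = {v: k for k, v in enumerate(self.ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise KeyError(f"ids not in matrix: {missing}")
        idx = np.array([pos[i] for i in ids])
        return DyadicMatrix(ids, self.values[np.ix_(idx, idx)], self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="id")

    @classmethod
    def read_csv(cls, path, kind: str = "generic") -> "DyadicMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if list(df.index) != list(df.columns):
            raise ValueError("square matrix CSV must have identical row/column ids")
        return cls(tuple(df.index), df.to_numpy(dtype=float), kind)


@dataclass
class PermutationResult:
    """Observed statistic, null summary and permutation p-value."""

    observed: float
    null_mean: float
    null_sd: float
    n_permutations: int
    p_value: float
    seed: int | None
    scheme: str
    alternative: str = "greater"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value outside (0, 1]")

    def to_dict(self) -> dict:
        d = {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "n_permutations": self.n_permutations,
            "p_value": self.p_value,
            "seed": self.seed,
            "scheme": self.scheme,
            "alternative": self.alternative,
        }
        d.update(self.extra)
        return d
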