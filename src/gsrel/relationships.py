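"""Candidate-reference relationship specifications.

A RelationshipSpec bundles the pedigree additive-relationship matrix A of the
candidate-plus-reference set (candidate row/column first) with the per-pair identity
moment coefficients needed by the closed-form expectations.  Note the two conventions
in play: the A matrix has unit diagonal for non-inbred individuals, while the pairwise
``a`` coefficients are coancestries with a_cc = 1/2 for a non-inbred self pair; the
off-diagonal conversion is A_ij = 2 a_ij.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .moments import PairCoefficients, UnsupportedRelationshipError, pair_coefficients
from .pedigree import Pedigree

_UNRELATED = pair_coefficients("unrelated")
_PARENT_OFFSPRING = pair_coefficients("parent_offspring")
_HALF_SIB = pair_coefficients("half_sibs")


@dataclass
class RelationshipSpec:
    """Relationship of one selection candidate to the n_r reference individuals."""

    preset: str
    n_r: int
    A: np.ndarray
    pair_coefs: List[PairCoefficients]

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        n = self.n_r + 1
        if self.A.shape != (n, n):
            raise ValueError("A must be (n_r+1) x (n_r+1) with the candidate first")
        if not np.allclose(self.A, self.A.T):
            raise ValueError("A must be symmetric")
        if len(self.pair_coefs) != self.n_r:
            raise ValueError("one PairCoefficients entry per reference individual")

    # pairwise coancestries candidate -> reference
    @property
    def a_c(self) -> np.ndarray:
        return np.array([c.a for c in self.pair_coefs])

    # means over reference individuals, as used by the closed-form expectations
    @property
    def abar2(self) -> float:
        return float(np.mean(self.a_c**2))

    @property
    def alpha22_bar(self) -> float:
        return float(np.mean([c.alpha22 for c in self.pair_coefs]))

    @property
    def gamma22_bar(self) -> float:
        return float(np.mean([c.gamma22 for c in self.pair_coefs]))

    # ------------------------------------------------------------------
    @classmethod
    def unrelated(cls, n_r: int) -> "RelationshipSpec":
        return cls(
            preset="unrelated",
            n_r=n_r,
            A=np.eye(n_r + 1),
            pair_coefs=[_UNRELATED] * n_r,
        )

    @classmethod
    def sire_in_reference(cls, n_r: int) -> "RelationshipSpec":
        """Candidate is the offspring of reference individual 1; everyone else unrelated."""
        A = np.eye(n_r + 1)
        A[0, 1] = A[1, 0] = 0.5
        return cls(
            preset="sire_in_reference",
            n_r=n_r,
            A=A,
            pair_coefs=[_PARENT_OFFSPRING] + [_UNRELATED] * (n_r - 1),
        )

    @classmethod
    def both_parents(cls, n_r: int) -> "RelationshipSpec":
        """Both parents of the candidate are reference individuals 1 and 2."""
        if n_r < 2:
            raise ValueError("need at least two reference individuals")
        A = np.eye(n_r + 1)
        A[0, 1] = A[1, 0] = 0.5
        A[0, 2] = A[2, 0] = 0.5
        return cls(
            preset="both_parents",
            n_r=n_r,
            A=A,
            pair_coefs=[_PARENT_OFFSPRING] * 2 + [_UNRELATED] * (n_r - 2),
        )

    @classmethod
    def half_sibs(cls, n_r: int, k: Optional[int] = None) -> "RelationshipSpec":
        """The first k reference individuals are paternal half-sibs of the candidate.

        Half-sibs share a sire who is not part of the reference set, so they are also
        half-sibs of each other (A = 0.25 within the whole half-sib block).  ``k``
        defaults to the whole reference population.
        """
        k = n_r if k is None else int(k)
        if not 1 <= k <= n_r:
            raise ValueError("k must be in 1..n_r")
        A = np.eye(n_r + 1)
        block = slice(0, k + 1)  # candidate + k half-sibs
        A[block, block] = np.where(np.eye(k + 1) == 1.0, 1.0, 0.25)
        return cls(
            preset=f"half_sibs({k})",
            n_r=n_r,
            A=A,
            pair_coefs=[_HALF_SIB] * k + [_UNRELATED] * (n_r - k),
        )

    @classmethod
    def custom(
        cls, A: np.ndarray, pair_coefs: Sequence[PairCoefficients]
    ) -> "RelationshipSpec":
        return cls(preset="custom", n_r=len(pair_coefs), A=A, pair_coefs=list(pair_coefs))

    @classmethod
    def from_pedigree(
        cls,
        pedigree: Pedigree,
        candidate: str,
        reference: Sequence[str],
        pair_coefs: Optional[Sequence[PairCoefficients]] = None,
    ) -> "RelationshipSpec":
        """Relationship spec from an explicit pedigree.

        The A matrix always comes from the tabular kinship recursion.  The per-pair
        identity coefficients cannot be recovered from kinship alone, so they must be
        supplied for any pair that is not unrelated, parent-offspring or half-sib at
        the exact canonical coancestry.
        """
        idx = [pedigree.index(candidate)] + [pedigree.index(r) for r in reference]
        A_full = pedigree.additive_relationship()
        A = A_full[np.ix_(idx, idx)]
        if pair_coefs is None:
            f = pedigree.kinship()
            coefs = []
            lookup = {0.0: _UNRELATED, 0.25: _PARENT_OFFSPRING, 0.125: _HALF_SIB}
            for r in reference:
                a = f[pedigree.index(candidate), pedigree.index(r)]
                match = lookup.get(round(float(a), 12))
                if match is None:
                    raise UnsupportedRelationshipError(
                        f"cannot infer identity coefficients for pair (candidate, {r}) "
                        f"with coancestry {a}; supply pair_coefs explicitly"
                    )
                coefs.append(match)
            pair_coefs = coefs
        return cls(
            preset="pedigree", n_r=len(reference), A=A, pair_coefs=list(pair_coefs)
        )

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Per-pair coefficient table (one reference individual per row)."""
        return pd.DataFrame(
            [
                {
                    "reference": i + 1,
                    "a": c.a,
                    "alpha11": c.alpha11,
                    "alpha13": c.alpha13,
                    "gamma13": c.gamma13,
                    "alpha22": c.alpha22,
                    "gamma22": c.gamma22,
                }
                for i, c in enumerate(self.pair_coefs)
            ]
        )


def preset_relationship(preset: str, n_r: int) -> RelationshipSpec:
    key = str(preset).lower().replace("-", "_")
    if key == "unrelated":
        return RelationshipSpec.unrelated(n_r)
    if key in {"sire_in_reference", "sire"}:
        return RelationshipSpec.sire_in_reference(n_r)
    if key == "both_parents":
        return RelationshipSpec.both_parents(n_r)
    if key.startswith("half_sibs"):
        k = None
        if "(" in key:
            k = int(key.split("(", 1)[1].rstrip(")"))
        return RelationshipSpec.half_sibs(n_r, k)
    raise UnsupportedRelationshipError(
        f"unknown preset {preset!r}; use unrelated / sire_in_reference / both_parents "
        "/ half_sibs(k) or RelationshipSpec.custom"
    )
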