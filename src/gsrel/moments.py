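"""Identity-by-descent states and single-locus genotype product moments.

The joint distribution of the coded genotypes of two individuals at one locus is
fully determined by the 15 detailed identity states of their four gametes.  Writing
delta_1..delta_15 for the state probabilities, every product moment up to order four
takes the form

    E[X_i^di X_j^dj] = p(1-p) * alpha - [p(1-p)]^2 * gamma,

with alpha and gamma linear forms of the deltas.  The state ordering used here:

    1        : all four gametes IBD
    2 - 5    : exactly three gametes IBD (i1i2j1, i1i2j2, j1j2i1, j1j2i2)
    6        : i1=i2 and j1=j2, no cross IBD
    7        : i1=i2 only
    8        : j1=j2 only
    9        : i1=j1 and i2=j2 (two cross pairs)
    10,11    : single cross pair i1=j1 / i1=j2
    12       : i1=j2 and i2=j1 (two cross pairs, swapped)
    13,14    : single cross pair i2=j1 / i2=j2
    15       : no gametes IBD

This ordering is the unique one consistent with the linear forms implemented below
(two-cross-pair states carry weight 2 in alpha_11, single-pair states weight 1, ...).
Only non-inbred canonical relationships are supported as presets; arbitrary inbred
pedigrees require user-supplied pair coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np

from .params import Codification, MonomorphicMarkerError
from .pedigree import CANONICAL_PAIR_PEDIGREES, Pedigree


class UnsupportedRelationshipError(ValueError):
    """Unknown relationship preset; supply identity-state or pair coefficients directly."""


#: delta vectors of the canonical non-inbred pair relationships.  The four
#: single-cross-pair states (10, 11, 13, 14) enter every moment with equal weight, so
#: their mass is split evenly where the split is ambiguous.
_PRESET_DELTAS = {
    "unrelated": {15: 1.0},
    "parent_offspring": {10: 0.25, 11: 0.25, 13: 0.25, 14: 0.25},
    "half_sibs": {10: 0.125, 11: 0.125, 13: 0.125, 14: 0.125, 15: 0.5},
    "full_sibs": {9: 0.25, 10: 0.25, 14: 0.25, 15: 0.25},
}


def identity_coefficients(preset: str) -> np.ndarray:
    """15-vector of detailed identity-state probabilities for a canonical preset."""
    key = str(preset).lower().replace("-", "_")
    if key not in _PRESET_DELTAS:
        raise UnsupportedRelationshipError(
            f"unknown relationship preset {preset!r}; supported presets are "
            f"{sorted(_PRESET_DELTAS)} -- for other relationships supply pair "
            "coefficients (PairCoefficients) directly"
        )
    out = np.zeros(15)
    for state, prob in _PRESET_DELTAS[key].items():
        out[state - 1] = prob
    return out


@dataclass(frozen=True)
class PairCoefficients:
    """Moment coefficients of a candidate-reference pair.

    ``a`` is the coancestry (kinship) coefficient; the alpha/gamma pairs are the linear
    forms of the identity-state probabilities entering the order-2/3/4 product moments.
    A pair of an individual with itself contracts the exponents, giving
    alpha22 = alpha4 = 2 and gamma22 = gamma4 = 0 with a = 1/2.
    """

    a: float
    alpha11: float
    alpha13: float
    gamma13: float
    alpha22: float
    gamma22: float

    @classmethod
    def self_pair(cls) -> "PairCoefficients":
        return cls(a=0.5, alpha11=2.0, alpha13=2.0, gamma13=0.0, alpha22=2.0, gamma22=0.0)


def moment_coefficients(deltas: np.ndarray) -> PairCoefficients:
    """Apply the identity-state linear forms to a 15-vector of state probabilities."""
    d = np.asarray(deltas, dtype=float)
    if d.shape != (15,):
        raise ValueError("deltas must be a 15-vector")
    if np.any(d < -1e-12) or abs(d.sum() - 1.0) > 1e-9:
        raise ValueError("deltas must be a probability vector")
    (d1, d2, d3, d4, d5, d6, d7, d8, d9, d10, d11, d12, d13, d14, d15) = d
    alpha11 = 4 * d1 + 2 * (d2 + d3 + d4 + d5 + d9 + d12) + d10 + d11 + d13 + d14
    alpha13 = (
        16 * d1
        + 2 * (d2 + d3)
        + 8 * (d4 + d5)
        + 2 * (d9 + d12)
        + d10
        + d11
        + d13
        + d14
    )
    gamma13 = 24 * d1 + 12 * (d4 + d5)
    alpha22 = (
        16 * d1 + 4 * (d2 + d3 + d4 + d5) + 2 * (d9 + d12) + d10 + d11 + d13 + d14
    )
    gamma22 = (
        48 * d1 + 8 * (d2 + d3 + d4 + d5) - 4 * d15 - 16 * d6 - 8 * (d7 + d8)
    )
    return PairCoefficients(
        a=alpha11 / 4.0,
        alpha11=alpha11,
        alpha13=alpha13,
        gamma13=gamma13,
        alpha22=alpha22,
        gamma22=gamma22,
    )


def pair_coefficients(preset: str) -> PairCoefficients:
    """Pair coefficients of a canonical preset (including the self pair)."""
    if str(preset).lower() == "self":
        return PairCoefficients.self_pair()
    return moment_coefficients(identity_coefficients(preset))


# ----------------------------------------------------------------------
def genotype_moment(
    coefs: PairCoefficients,
    p_m: float,
    exponents: Tuple[int, int],
    codification: Union[str, Codification] = Codification.CENTERED,
) -> float:
    """Expectation of a product of single-locus coded genotypes of a pair.

    ``exponents = (d_i, d_j)`` with d_i + d_j <= 4.  The centered coding returns the
    raw moment; the standardized coding divides by sigma_m^(d_i + d_j).
    """
    if not 0.0 < p_m < 1.0:
        raise MonomorphicMarkerError("p_m must be strictly in (0,1)")
    di, dj = exponents
    if di < 0 or dj < 0 or di + dj > 4:
        raise ValueError("exponents must be non-negative and sum to at most 4")
    pq = p_m * (1.0 - p_m)
    key = tuple(sorted((di, dj)))
    if key in {(0, 0)}:
        val = 1.0
    elif key in {(0, 1), (0, 3)}:
        val = 0.0  # odd single-individual moments vanish
    elif key == (0, 2):
        val = 2.0 * pq  # sigma_m^2
    elif key == (0, 4):
        val = 2.0 * pq  # alpha4 = 2, gamma4 = 0
    elif key == (1, 1):
        val = pq * coefs.alpha11
    elif key == (1, 3):
        val = 0.5 * coefs.alpha13 * (2.0 * pq) - 0.25 * coefs.gamma13 * (2.0 * pq) ** 2
    elif key == (2, 2):
        val = 0.5 * coefs.alpha22 * (2.0 * pq) - 0.25 * coefs.gamma22 * (2.0 * pq) ** 2
    else:
        raise ValueError(f"moment with exponents {exponents} is not tabulated")
    if Codification(codification) is Codification.STANDARDIZED:
        val /= (2.0 * pq) ** ((di + dj) / 2.0)
    return float(val)


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class OracleEstimate:
    mean: float
    se: float
    n_reps: int

    def within(self, value: float, n_se: float = 3.0) -> bool:
        return abs(self.mean - value) <= n_se * max(self.se, 1e-12)


def gene_drop_oracle(
    pedigree: Pedigree,
    p_m: float,
    individuals: Tuple[str, ...],
    exponents: Tuple[int, ...],
    n_reps: int = 10**6,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> OracleEstimate:
    """Monte-Carlo estimate of E[prod_k X_{individual_k}^{d_k}] at one locus.

    Each replicate is an independent locus dropped through the pedigree; the estimator
    is unbiased and its standard error is reported.
    """
    if len(individuals) != len(exponents):
        raise ValueError("individuals and exponents must have equal length")
    if n_reps < 10**3:
        warnings.warn("fewer than 1000 replicates: standard error is unreliable")
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = pedigree.gene_drop(float(p_m), rng, n_loci=n_reps).astype(float)
    x = counts - 2.0 * p_m
    prod = np.ones(n_reps)
    for ind, d in zip(individuals, exponents):
        prod *= x[pedigree.index(ind)] ** d
    return OracleEstimate(
        mean=float(prod.mean()),
        se=float(prod.std(ddof=1) / np.sqrt(n_reps)),
        n_reps=n_reps,
    )


def preset_oracle_pedigree(preset: str):
    """Canonical pair pedigree and the (candidate, reference) ids for a preset."""
    key = str(preset).lower().replace("-", "_")
    if key not in CANONICAL_PAIR_PEDIGREES:
        raise UnsupportedRelationshipError(f"no oracle pedigree for preset {preset!r}")
    return CANONICAL_PAIR_PEDIGREES[key]()
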