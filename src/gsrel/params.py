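"""Shared parameterization of the molecular-score model and of the marker panel.

The molecular score of an individual is the linear combination q = sum_m x_m beta_m of
its coded marker genotypes.  Its variance decomposes the total phenotypic variance
``sigma2`` into a part ``sigma_q2`` explained by the score (fraction ``nu2``) and a
residual ``sigma_e2``.  Marker effects are i.i.d. with variance
``sigma_beta2 = sigma_q2 / tau``, where ``tau = sum_m sigma_m^2`` is the summed
per-locus genotypic variance of the panel, so the ridge parameter of GBLUP is
``lambda_beta = sigma_e2 / sigma_beta2 = tau / gamma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd


class MonomorphicMarkerError(ValueError):
    """Raised when an allele frequency of exactly 0 or 1 is supplied."""


class Codification(str, Enum):
    """Genotype coding convention.

    ``CENTERED``      x = a - 2p       (per-locus variance sigma_m^2 = 2p(1-p))
    ``STANDARDIZED``  x = (a - 2p)/sigma_m   (per-locus variance 1; tau becomes n_M)
    """

    CENTERED = "centered"
    STANDARDIZED = "standardized"


@dataclass(frozen=True)
class VarianceSpec:
    """Variance components of the molecular-score model.

    Parameters
    ----------
    nu2 : float
        Fraction of the phenotypic variance explained by the molecular score, in (0,1).
    sigma2 : float
        Total phenotypic variance (trait units squared).  Default 1.
    tau : float, optional
        Summed per-locus genotypic variance of the marker panel.  Needed only for the
        quantities that depend on the panel (``sigma_beta2``, ``lambda_beta``).
    """

    nu2: float
    sigma2: float = 1.0
    tau: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.nu2 < 1.0:
            raise ValueError(f"nu2 must be in (0,1), got {self.nu2}")
        if self.sigma2 <= 0.0:
            raise ValueError("sigma2 must be positive")
        if self.tau is not None and self.tau <= 0.0:
            raise ValueError("tau must be positive")

    @property
    def sigma_q2(self) -> float:
        """Molecular-score variance."""
        return self.nu2 * self.sigma2

    @property
    def sigma_e2(self) -> float:
        """Residual variance."""
        return (1.0 - self.nu2) * self.sigma2

    @property
    def gamma(self) -> float:
        """Variance ratio sigma_q2 / sigma_e2 = nu2 / (1 - nu2)."""
        return self.nu2 / (1.0 - self.nu2)

    def _require_tau(self) -> float:
        if self.tau is None:
            raise ValueError("this quantity needs tau; use with_tau() first")
        return self.tau

    def with_tau(self, tau: float) -> "VarianceSpec":
        return VarianceSpec(self.nu2, self.sigma2, float(tau))

    @property
    def sigma_beta2(self) -> float:
        """Per-marker effect variance sigma_q2 / tau."""
        return self.sigma_q2 / self._require_tau()

    @property
    def lambda_beta(self) -> float:
        """GBLUP ridge parameter sigma_e2 / sigma_beta2 = tau / gamma."""
        return self._require_tau() / self.gamma


@dataclass
class MarkerPanel:
    """Allele frequencies and derived summaries of a marker panel.

    ``delta`` is an optional symmetric matrix of pairwise linkage-disequilibrium values
    Delta_ml = P(B_m B_l haplotype) - p_m p_l, with the convention that the diagonal
    holds sigma_m^2 / 2 = p_m (1 - p_m).
    """

    p: np.ndarray
    delta: Optional[np.ndarray] = None
    _sigma_m2: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.p = np.atleast_1d(np.asarray(self.p, dtype=float))
        if self.p.ndim != 1 or self.p.size == 0:
            raise ValueError("p must be a non-empty 1-D vector of frequencies")
        if np.any(self.p <= 0.0) or np.any(self.p >= 1.0):
            raise MonomorphicMarkerError("allele frequencies must lie strictly in (0,1)")
        self._sigma_m2 = 2.0 * self.p * (1.0 - self.p)
        if self.delta is not None:
            d = np.asarray(self.delta, dtype=float)
            if d.shape != (self.n_markers, self.n_markers):
                raise ValueError("delta must be n_M x n_M")
            if not np.allclose(d, d.T):
                raise ValueError("delta must be symmetric")
            sig = np.sqrt(self._sigma_m2)
            bound = np.outer(sig, sig)
            if np.any(np.abs(2.0 * d) > bound * (1.0 + 1e-12)):
                raise ValueError("|2 Delta_ml| must not exceed sigma_m sigma_l")
            self.delta = d

    @property
    def n_markers(self) -> int:
        return self.p.size

    @property
    def sigma_m2(self) -> np.ndarray:
        """Per-locus genotypic variances 2 p (1-p)."""
        return self._sigma_m2

    @property
    def tau(self) -> float:
        """Sum of per-locus variances."""
        return float(self._sigma_m2.sum())

    @property
    def tau2(self) -> float:
        """Sum of squared per-locus variances."""
        return float((self._sigma_m2**2).sum())

    @property
    def zeta(self) -> float:
        """Mean inverse per-locus variance (standardized-coding correction)."""
        return float(np.mean(1.0 / self._sigma_m2))

    def tau_for(self, codification: Codification) -> float:
        """Panel variance total under a coding convention (n_M when standardized)."""
        if Codification(codification) is Codification.STANDARDIZED:
            return float(self.n_markers)
        return self.tau

    @classmethod
    def from_csv(cls, path, delta_path=None) -> "MarkerPanel":
        """Read a one-column CSV of allele frequencies.

        An optional LD file has rows (locus_m, locus_l, delta) with 1-based locus
        indices.
        """
        p = pd.read_csv(path, header=None).to_numpy(dtype=float).ravel()
        delta = None
        if delta_path is not None:
            n = p.size
            tab = pd.read_csv(delta_path, header=None).to_numpy(dtype=float)
            delta = np.zeros((n, n))
            np.fill_diagonal(delta, p * (1.0 - p))
            for m, l, d in tab:
                i, j = int(m) - 1, int(l) - 1
                delta[i, j] = delta[j, i] = d
        return cls(p=p, delta=delta)
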