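"""Effective and equivalent numbers of independent loci under linkage disequilibrium.

Two different scalar summaries reduce an LD-correlated marker panel to an
"independent-locus" count:

* the effective number of segments M_e = tau^2 / tau_2, which matches the variance of
  realized genomic relationships;
* the equivalent number of independent loci n_Mi, which matches the GBLUP reliability
  achieved with the full correlated panel.  Unlike M_e, n_Mi depends on the reference
  population size and on heritability.

Under Sved's drift relation, the expected LD correlation between equidistant ordered
loci is R_ml = sqrt(n_M / (n_M + 4 Ne |l-m| L)) for a genome of length L Morgan, and
n_Mi has a closed form in the trace U = tr[(gamma n_R R + n_M I)^{-1}].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import integrate
from scipy import linalg as sla
from scipy.linalg import matmul_toeplitz
from scipy.sparse.linalg import LinearOperator, cg

DENSE_TRACE_LIMIT = 5000


@dataclass(frozen=True)
class LociEquivalence:
    Me: Optional[float] = None
    nMi: Optional[float] = None
    U: Optional[float] = None
    b: Optional[float] = None


def effective_segments(tau: float, tau2: float) -> float:
    """Effective number of independent segments M_e = tau^2 / tau_2."""
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    return tau**2 / tau2


def sved_correlation_row(n_M: int, Ne: float, L: float) -> np.ndarray:
    """First row of the Toeplitz Sved correlation matrix (entries by locus lag)."""
    lags = np.arange(n_M, dtype=float)
    return np.sqrt(n_M / (n_M + 4.0 * Ne * lags * L))


def sved_correlation_matrix(n_M: int, Ne: float, L: float) -> np.ndarray:
    row = sved_correlation_row(n_M, Ne, L)
    idx = np.abs(np.subtract.outer(np.arange(n_M), np.arange(n_M)))
    return row[idx]


def _toeplitz_inverse_trace(
    row: np.ndarray,
    scale: float,
    shift: float,
    n_probes: int = 24,
    seed: int = 0,
    tol: float = 1e-8,
) -> float:
    """Hutchinson trace estimate of (scale*R + shift*I)^{-1} for Toeplitz R.

    Matrix-vector products use FFT-based Toeplitz multiplication; each probe solve
    uses conjugate gradients (the matrix is SPD).  Stochastic: the estimate carries
    Monte-Carlo error of order tr/sqrt(n_probes).
    """
    n = row.size
    col = row * scale
    col0 = col.copy()
    col0[0] += shift

    def mv(v):
        return matmul_toeplitz((col0, col0), v)

    op = LinearOperator((n, n), matvec=mv, dtype=float)
    rng = np.random.default_rng(seed)
    acc = 0.0
    for _ in range(n_probes):
        z = rng.choice([-1.0, 1.0], size=n)
        x, info = cg(op, z, rtol=tol, maxiter=2000)
        if info != 0:
            raise RuntimeError("CG failed to converge in Toeplitz trace estimation")
        acc += float(z @ x)
    return acc / n_probes


def equivalent_loci_sved(
    n_M: int,
    n_R: int,
    Ne: float,
    L: float,
    gamma: float,
    dense_limit: int = DENSE_TRACE_LIMIT,
    seed: int = 0,
) -> LociEquivalence:
    """Equivalent number of independent loci under the Sved LD structure.

    U = tr[(gamma n_R R + n_M I)^{-1}];  n_Mi = n_M n_R gamma (1-U) /
    (n_R gamma - n_M (1-U)).  Dense Cholesky up to ``dense_limit`` loci; a
    matrix-free stochastic Toeplitz trace beyond.
    """
    if min(n_M, n_R) <= 0 or Ne <= 0 or L <= 0 or gamma <= 0:
        raise ValueError("all parameters must be positive")
    row = sved_correlation_row(n_M, Ne, L)
    if n_M <= dense_limit:
        M = gamma * n_R * sved_correlation_matrix(n_M, Ne, L)
        M[np.diag_indices_from(M)] += n_M
        cf = sla.cho_factor(M, check_finite=False)
        inv = sla.cho_solve(cf, np.eye(n_M), check_finite=False)
        U = float(np.trace(inv))
    else:
        U = _toeplitz_inverse_trace(row, scale=gamma * n_R, shift=float(n_M), seed=seed)
    den = n_R * gamma - n_M * (1.0 - U)
    if den <= 0:
        raise ValueError(
            "ill-posed regime: n_R gamma - n_M (1-U) <= 0; the equivalent-locus "
            "formula has no positive solution here"
        )
    nMi = n_M * n_R * gamma * (1.0 - U) / den
    return LociEquivalence(nMi=float(nMi), U=U)


def equivalent_loci_exact(
    EXtX: np.ndarray,
    gamma: float,
    lambda_beta: float,
    sigma_m2: np.ndarray,
) -> LociEquivalence:
    """Equivalent number of independent loci from an expected marker cross-product
    matrix E[X_r'X_r]:

        n_Mi = n_M (1+gamma)/gamma * (1 - tr[(E[X_r'X_r] + lambda_beta I)^{-1}]
                                          * (sum_m sigma_m^2 / n_M) / gamma).

    Note: unlike the Sved form, this expression does not reduce algebraically to n_M
    under linkage equilibrium; it is provided as printed and the two routes are
    reported side by side rather than reconciled.
    """
    EXtX = np.asarray(EXtX, dtype=float)
    n_M = EXtX.shape[0]
    M = EXtX.copy()
    M[np.diag_indices_from(M)] += lambda_beta
    try:
        cf = sla.cho_factor(M, check_finite=False)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("E[X'X] + lambda_beta I is not invertible") from exc
    tr = float(np.trace(sla.cho_solve(cf, np.eye(n_M), check_finite=False)))
    mean_s2 = float(np.mean(sigma_m2))
    nMi = n_M * (1.0 + gamma) / gamma * (1.0 - tr * mean_s2 / gamma)
    return LociEquivalence(nMi=float(nMi), U=tr)


def sved_expected_r2(Ne: float, c: float) -> float:
    """Sved's expected squared LD correlation at recombination distance c Morgan."""
    return 1.0 / (1.0 + 4.0 * Ne * c)


def variance_captured_fraction(n_M: int, Ne: float, L: float) -> float:
    """Fraction b of the genetic variance captured by the marker panel.

    Mean of Sved's expected r^2 over the QTL-to-nearest-marker distance, uniform on
    (0, L/(2 n_M)):  b = n_M/(2 Ne L) * ln(1 + 2 Ne L / n_M).
    """
    if min(n_M, Ne, L) <= 0:
        raise ValueError("all parameters must be positive")
    x = 2.0 * Ne * L / n_M
    return float(np.log1p(x) / x)


def variance_captured_fraction_quadrature(
    n_M: int, Ne: float, L: float, tol: float = 1e-10
) -> float:
    """Quadrature evaluation of b (independent route for validation)."""
    upper = L / (2.0 * n_M)
    val, _ = integrate.quad(
        lambda c: sved_expected_r2(Ne, c) / upper, 0.0, upper, epsabs=tol, epsrel=tol
    )
    return float(val)
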