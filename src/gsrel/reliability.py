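"""Exact GBLUP reliability and its two Taylor-series approximations.

For a single unphenotyped candidate with coded genotype row x_c and a reference
population with genotype matrix X_r, phenotypic variance matrix
V = G* sigma_q^2 / tau + I sigma_e^2 (G* = X X'), the exact conditional reliability is

    r^2 = v(qhat_c | X) / v(q_c | X)
        = x_c X_r' (X_r X_r' + I lambda_beta)^{-1} X_r x_c' / (x_c x_c').

Two Neumann-series approximations are implemented:

* the first factors V = sigma_e^2 (I + A gamma)(I + D gamma) with
  T = (I + A gamma)^{-1} and D = T (G*/tau - A), and truncates
  (I + D gamma)^{-1} = sum_t (-D gamma)^t;
* the second factors X_r'X_r + I lambda_beta = (I + B) C with
  C = I lambda_beta + n_r diag(sigma_m^2) and B = (X_r'X_r - n_r diag(sigma_m^2)) C^{-1},
  and truncates (I + B)^{-1}.

Both series converge only when the spectral radius of the perturbation is below one;
divergence is reported through the result object, never raised.  Closed-form
expectations of the approximations over the genotype distribution are provided for the
unrelated and sire-in-reference relationships.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import linalg as sla
from scipy.sparse.linalg import LinearOperator, eigsh

from .freqs import FreqDistributionModel, SpectrumExpectations, spectrum_expectations
from .moments import UnsupportedRelationshipError
from .params import Codification, MarkerPanel, VarianceSpec
from .relationships import RelationshipSpec

DENSE_EIG_LIMIT = 3000


class UndefinedReliabilityError(ValueError):
    """Candidate has zero coded genotypic variance; the reliability is undefined."""


@dataclass
class GenotypeData:
    """Coded genotypes of candidate (row 0) plus reference individuals."""

    X: np.ndarray
    panel: MarkerPanel
    codification: Codification = Codification.CENTERED

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] < 2:
            raise ValueError("X must be 2-D with at least two rows (candidate first)")
        if self.X.shape[1] != self.panel.n_markers:
            raise ValueError("X column count must match the marker panel")
        self.codification = Codification(self.codification)

    @property
    def n_r(self) -> int:
        return self.X.shape[0] - 1

    @property
    def n_markers(self) -> int:
        return self.X.shape[1]

    @property
    def x_c(self) -> np.ndarray:
        return self.X[0]

    @property
    def X_r(self) -> np.ndarray:
        return self.X[1:]

    @property
    def tau(self) -> float:
        return self.panel.tau_for(self.codification)

    def sigma_m2(self) -> np.ndarray:
        """Per-locus coded variances (ones under the standardized coding)."""
        if self.codification is Codification.STANDARDIZED:
            return np.ones(self.n_markers)
        return self.panel.sigma_m2


@dataclass
class ReliabilityResult:
    """A reliability estimate plus its provenance and convergence diagnostics."""

    estimate: float
    method: str
    order: Optional[int] = None
    spectral_radius: Optional[float] = None
    components: dict = field(default_factory=dict)

    @property
    def converged(self) -> Optional[bool]:
        if self.spectral_radius is None:
            return None
        return bool(self.spectral_radius < 1.0)

    @property
    def divergence_warning(self) -> bool:
        out_of_range = not (0.0 <= self.estimate <= 1.0)
        return out_of_range or self.converged is False


# ----------------------------------------------------------------------
def exact_reliability(geno: GenotypeData, vs: VarianceSpec) -> ReliabilityResult:
    """Exact conditional GBLUP reliability of the candidate given realized genotypes."""
    xc = geno.x_c
    Xr = geno.X_r
    xcxc = float(xc @ xc)
    if xcxc <= 0.0:
        raise UndefinedReliabilityError(
            "candidate coded genotypes are all zero; v(q_c|X) = 0"
        )
    lam = vs.with_tau(geno.tau).lambda_beta
    n_r, n_M = Xr.shape
    try:
        if n_r <= n_M:
            # individual-side system (X_r X_r' + I lambda)^{-1}
            b = Xr @ xc
            M = Xr @ Xr.T
            M[np.diag_indices_from(M)] += lam
            cf = sla.cho_factor(M, check_finite=False)
            v_qhat_over_sb2 = float(b @ sla.cho_solve(cf, b, check_finite=False))
        else:
            # marker-side identity: x_c Xr'(Xr Xr'+lam I)^-1 Xr x_c'
            #   = x_c x_c' - lam * x_c (Xr'Xr + lam I)^-1 x_c'
            M = Xr.T @ Xr
            M[np.diag_indices_from(M)] += lam
            cf = sla.cho_factor(M, check_finite=False)
            v_qhat_over_sb2 = xcxc - lam * float(
                xc @ sla.cho_solve(cf, xc, check_finite=False)
            )
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        cond = np.linalg.cond(M)
        raise np.linalg.LinAlgError(
            f"GBLUP system could not be factorized (condition number {cond:.3e})"
        ) from exc
    est = v_qhat_over_sb2 / xcxc
    sb2 = vs.with_tau(geno.tau).sigma_beta2
    return ReliabilityResult(
        estimate=float(est),
        method="exact",
        components={
            "v_qhat": sb2 * v_qhat_over_sb2,
            "v_q": sb2 * xcxc,
            "lambda_beta": lam,
        },
    )


# ----------------------------------------------------------------------
def matrix_T(A: np.ndarray, gamma: float) -> np.ndarray:
    """Numerical inverse T = (I + A gamma)^{-1} of the pedigree factor of V."""
    A = np.asarray(A, dtype=float)
    M = gamma * A
    M[np.diag_indices_from(M)] += 1.0
    try:
        cf = sla.cho_factor(M, check_finite=False)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "I + A*gamma is not positive definite; A must be a valid relationship matrix"
        ) from exc
    return sla.cho_solve(cf, np.eye(A.shape[0]), check_finite=False)


def spectral_radius(
    M: Union[np.ndarray, LinearOperator],
    symmetric: bool = False,
    n_iter: int = 200,
    seed: int = 0,
) -> float:
    """Largest absolute eigenvalue.

    Dense routines up to ``DENSE_EIG_LIMIT``; power iteration (or Lanczos for
    symmetric operators) beyond that or for matrix-free operators.
    """
    n = M.shape[0]
    if isinstance(M, np.ndarray) and n <= DENSE_EIG_LIMIT:
        if symmetric:
            ev = sla.eigvalsh(M, check_finite=False)
            return float(max(abs(ev[0]), abs(ev[-1])))
        return float(np.max(np.abs(sla.eigvals(M, check_finite=False))))
    if symmetric:
        ev = eigsh(M, k=1, which="LM", return_eigenvectors=False, tol=1e-8)
        return float(abs(ev[0]))
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(n)
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(n_iter):
        w = M @ v
        nrm = np.linalg.norm(w)
        if nrm == 0.0:
            return 0.0
        v = w / nrm
        lam = nrm
    return float(lam)


def taylor_series_inverse(
    perturbation: np.ndarray,
    order: int,
    base: Optional[np.ndarray] = None,
    compute_radius: bool = True,
) -> tuple:
    """Truncated Neumann series sum_{t=0..order} (-P)^t (optionally right-multiplied
    by a base factor) and the spectral radius of P."""
    if order < 0:
        raise ValueError("order must be non-negative")
    P = np.asarray(perturbation, dtype=float)
    n = P.shape[0]
    S = np.eye(n)
    term = np.eye(n)
    for _ in range(order):
        term = -term @ P
        S = S + term
    if base is not None:
        S = S @ base
    rho = spectral_radius(P) if compute_radius else None
    return S, rho


# ----------------------------------------------------------------------
# first approximation (pedigree-factor series), realized genotypes
def approx1_on_genotypes(
    geno: GenotypeData,
    rel: RelationshipSpec,
    vs: VarianceSpec,
    order: int = 2,
    T: Optional[np.ndarray] = None,
    compute_radius: bool = True,
) -> ReliabilityResult:
    """Order-truncated first approximation evaluated on realized genotypes.

    The candidate-block element of the truncated V^{-1} is accumulated by matrix-vector
    products, so only the G* product with vectors is formed.  The spectral radius of
    the perturbation D*gamma is computed (optionally) from the symmetrized similar
    matrix L' (G*/tau - A) L * gamma, with T = L L'.
    """
    xc = geno.x_c
    if float(xc @ xc) <= 0.0:
        raise UndefinedReliabilityError("candidate coded genotypes are all zero")
    gamma = vs.gamma
    X = geno.X
    n = X.shape[0]
    A = rel.A
    if T is None:
        T = matrix_T(A, gamma)
    tau = geno.tau

    def D_mat_vec(v: np.ndarray) -> np.ndarray:
        return T @ (X @ (X.T @ v) / tau - A @ v)

    e_c = np.zeros(n)
    e_c[0] = 1.0
    u = T @ e_c
    acc = u.copy()
    for _ in range(order):
        u = -gamma * D_mat_vec(u)
        acc = acc + u
    Lcc = float(acc[0])  # sigma_e^2 * Lambda_cc
    # estimate vs the expected denominator E[v(q_c)] = sigma_q^2
    est = 1.0 / vs.nu2 - 1.0 / (gamma * Lcc) if Lcc != 0.0 else np.inf
    rho = None
    if compute_radius:
        # D gamma is similar to the symmetric gamma * L'(G*/tau - A)L with T = LL'
        L = sla.cholesky(T, lower=True, check_finite=False)
        P = X.T @ L
        sym = gamma * ((P.T @ P) / tau - L.T @ A @ L)
        rho = spectral_radius(sym, symmetric=True)
    sb2 = vs.with_tau(tau).sigma_beta2
    v_qhat = vs.sigma2 - vs.sigma_e2 / Lcc if Lcc != 0.0 else np.nan
    return ReliabilityResult(
        estimate=float(est),
        method="approx1",
        order=order,
        spectral_radius=rho,
        components={
            "Lambda_cc_sigma_e2": Lcc,
            "v_qhat": v_qhat,
            "v_q_realized": sb2 * float(xc @ xc),
            "v_q_expected": vs.sigma_q2,
        },
    )


# second approximation (marker-factor series), realized genotypes
def approx2_on_genotypes(
    geno: GenotypeData,
    vs: VarianceSpec,
    order: int = 1,
    compute_radius: bool = False,
) -> ReliabilityResult:
    """Order-truncated second approximation on realized genotypes (matrix-free)."""
    xc = geno.x_c
    xcxc = float(xc @ xc)
    if xcxc <= 0.0:
        raise UndefinedReliabilityError("candidate coded genotypes are all zero")
    Xr = geno.X_r
    n_r = Xr.shape[0]
    sig2 = geno.sigma_m2()
    lam = vs.with_tau(geno.tau).lambda_beta
    c_diag = lam + n_r * sig2

    def B_mat_vec(v: np.ndarray) -> np.ndarray:
        w = v / c_diag
        return Xr.T @ (Xr @ w) - (n_r * sig2) * w

    u = xc.copy()
    acc = xc.copy()
    for _ in range(order):
        u = -B_mat_vec(u)
        acc = acc + u
    quad = float((xc / c_diag) @ acc)  # x_c C^{-1} sum_t (-B)^t x_c'
    est = 1.0 - lam * quad / xcxc
    rho = None
    if compute_radius:
        # B is similar to the symmetric C^{-1/2}(Xr'Xr - n_r diag)C^{-1/2}
        inv_sqrt = 1.0 / np.sqrt(c_diag)
        n_M = Xr.shape[1]
        if n_M <= DENSE_EIG_LIMIT:
            S = Xr * inv_sqrt  # Xr C^{-1/2}
            sym = S.T @ S - np.diag(n_r * sig2 * inv_sqrt**2)
            rho = spectral_radius(sym, symmetric=True)
        else:
            def sym_mv(v):
                w = inv_sqrt * v
                return inv_sqrt * (Xr.T @ (Xr @ w)) - (n_r * sig2 * inv_sqrt**2) * v

            op = LinearOperator((n_M, n_M), matvec=sym_mv, dtype=float)
            rho = spectral_radius(op, symmetric=True)
    sb2 = vs.with_tau(geno.tau).sigma_beta2
    return ReliabilityResult(
        estimate=float(est),
        method="approx2",
        order=order,
        spectral_radius=rho,
        components={
            "v_qhat": sb2 * (xcxc - lam * quad),
            "v_q_realized": sb2 * xcxc,
            "lambda_beta": lam,
        },
    )


# ----------------------------------------------------------------------
# closed-form expectations
def effective_segments_from(tau: float, tau2: float) -> float:
    return tau**2 / tau2


def approx1_expectation(
    rel: RelationshipSpec,
    vs: VarianceSpec,
    tau: float,
    tau2: float,
    n_r: Optional[int] = None,
) -> ReliabilityResult:
    """Expectation of the first (order-2) approximation over the genotype distribution.

    Supported relationships: unrelated (the n_r/M_e formula with M_e = tau^2/tau_2)
    and sire-in-reference (the three-constant formula with the 2x2 T block inverted
    numerically).
    """
    n_r = rel.n_r if n_r is None else n_r
    nu2, gamma = vs.nu2, vs.gamma
    Me = effective_segments_from(tau, tau2)
    preset = rel.preset
    if preset == "unrelated":
        ratio = nu2 * n_r / Me
        est = ratio / (1.0 + nu2**2 * n_r / Me)
        return ReliabilityResult(
            estimate=float(est), method="approx1_expect", order=2,
            components={"Me": Me},
        )
    if preset == "sire_in_reference":
        Tblock = np.linalg.inv(
            np.array([[1.0 + gamma, gamma / 2.0], [gamma / 2.0, 1.0 + gamma]])
        )
        a, b = Tblock[0, 0], Tblock[0, 1]
        c1 = (a + b) ** 3 + (a**2 + b**2) * a / 2.0
        c2 = a * (b**2 - a**2) / 4.0
        c3 = a**2 + b**2 + a * b / 2.0
        den = (
            gamma * a
            + gamma**3 * (tau - tau2) / tau**2 * c1
            + gamma**3 * tau2 / tau**2 * (c2 + (n_r - 1) / (1.0 + gamma) * c3)
        )
        est = 1.0 / nu2 - 1.0 / den
        return ReliabilityResult(
            estimate=float(est), method="approx1_expect", order=2,
            components={"a": a, "b": b, "c1": c1, "c2": c2, "c3": c3, "Me": Me},
        )
    raise UnsupportedRelationshipError(
        f"no closed-form first-approximation expectation for preset {preset!r} "
        "(quadruple identity coefficients unavailable)"
    )


def approx1_expectation_standardized(
    vs: VarianceSpec, zeta: float, n_M: int, n_r: int
) -> ReliabilityResult:
    """Unrelated-case expectation of the first approximation, standardized coding."""
    ratio = (zeta + n_r - 1.0) / n_M
    est = vs.nu2 * ratio / (1.0 + vs.nu2**2 * ratio)
    return ReliabilityResult(
        estimate=float(est), method="approx1_expect_standardized", order=2,
        components={"zeta": zeta},
    )


@dataclass(frozen=True)
class ShrinkageMoments:
    """Realized or expected values of the marker-shrinkage sums in the second
    approximation: sum_m rho_m, sum_m rho_m^2, sum_m rho_m^2/sigma_m^2, plus the
    value used for (sum_m rho_m)^2, tau and lambda_beta."""

    sum_rho: float
    sum_rho2: float
    sum_rho2_over_sigma2: float
    sum_rho_squared: float
    tau: float
    lambda_beta: float

    @classmethod
    def from_panel(
        cls, panel: MarkerPanel, vs: VarianceSpec, n_r: int
    ) -> "ShrinkageMoments":
        tau = panel.tau
        lam = tau / vs.gamma
        rho = n_r * panel.sigma_m2 / (lam + n_r * panel.sigma_m2)
        s = float(rho.sum())
        return cls(
            sum_rho=s,
            sum_rho2=float((rho**2).sum()),
            sum_rho2_over_sigma2=float((rho**2 / panel.sigma_m2).sum()),
            sum_rho_squared=s**2,
            tau=tau,
            lambda_beta=lam,
        )

    @classmethod
    def from_model(
        cls,
        model_or_table: Union[FreqDistributionModel, SpectrumExpectations],
        vs: VarianceSpec,
        n_r: int,
        n_M: int,
    ) -> "ShrinkageMoments":
        t3 = (
            model_or_table
            if isinstance(model_or_table, SpectrumExpectations)
            else spectrum_expectations(model_or_table, vs, n_r, n_M)
        )
        s = n_M * t3.E_rho
        return cls(
            sum_rho=s,
            sum_rho2=n_M * t3.E_rho2,
            sum_rho2_over_sigma2=n_M * t3.E_rho2_over_sigma2,
            sum_rho_squared=s**2,
            tau=t3.tau,
            lambda_beta=t3.lambda_beta,
        )


def approx2_expectation(
    rel: RelationshipSpec,
    vs: VarianceSpec,
    moments: ShrinkageMoments,
    n_r: Optional[int] = None,
) -> ReliabilityResult:
    """First-order second-approximation expectation for any relationship whose mean
    pair coefficients are available.

    The unrelated case collapses to 1 - lambda_beta sum(rho)/(n_r tau); the
    sire-in-reference case reproduces its printed closed form exactly.
    """
    n_r = rel.n_r if n_r is None else n_r
    try:
        abar2 = rel.abar2
        albar = rel.alpha22_bar
        gbar = rel.gamma22_bar
    except Exception as exc:  # pragma: no cover - defensive
        raise UnsupportedRelationshipError(
            "relationship must supply mean pair coefficients "
            "(abar2, alpha22_bar, gamma22_bar)"
        ) from exc
    braces = (
        moments.sum_rho
        + moments.sum_rho2 * (1.0 + 4.0 * abar2 + gbar / 4.0)
        - moments.sum_rho_squared * (4.0 * abar2)
        - moments.sum_rho2_over_sigma2 * (albar / 2.0)
    )
    est = 1.0 - moments.lambda_beta / (n_r * moments.tau) * braces
    return ReliabilityResult(
        estimate=float(est), method="approx2_expect", order=1,
        components={"braces": braces, "lambda_beta": moments.lambda_beta},
    )


def approx2_expectation_unrelated_closed(
    vs: VarianceSpec, n_r: int, n_M: int, Ne: Optional[float] = None
) -> ReliabilityResult:
    """Closed form of the unrelated-case expectation under the U-shaped spectrum:
    1 - n_M k theta / (gamma n_r omega), with Ne defaulting to n_r."""
    Ne = n_r if Ne is None else Ne
    from .freqs import UShapedModel, _h_omega_theta

    k = UShapedModel(Ne).k
    if n_M == 0:  # no markers: no shrinkage term, the formula's limit is 1
        return ReliabilityResult(estimate=1.0, method="approx2_expect", order=1)
    tau = n_M * k
    lam = tau / vs.gamma
    _, omega, theta = _h_omega_theta(lam, n_r)
    est = 1.0 - n_M * k * theta / (vs.gamma * n_r * omega)
    return ReliabilityResult(
        estimate=float(est), method="approx2_expect", order=1,
        components={"k": k, "omega": omega, "theta": theta},
    )


def approx2_expectation_sire_closed(
    vs: VarianceSpec, n_r: int, n_M: int, Ne: Optional[float] = None
) -> ReliabilityResult:
    """Closed form of the sire-in-reference expectation under the U-shaped spectrum."""
    Ne = n_r if Ne is None else Ne
    from .freqs import UShapedModel, _h_omega_theta

    k = UShapedModel(Ne).k
    tau = n_M * k
    lam = tau / vs.gamma
    h, omega, theta = _h_omega_theta(lam, n_r)
    gamma = vs.gamma
    est = (
        1.0
        - n_M * k * theta / (gamma * n_r * omega)
        - n_M
        * k
        / (4.0 * gamma * n_r**2 * omega**2)
        * (
            5.0 * theta * omega
            - (10.0 * h + 2.0) * theta / omega
            - 5.0
            - n_M * k * theta**2
            - 1.0 / h
        )
    )
    return ReliabilityResult(
        estimate=float(est), method="approx2_expect", order=1,
        components={"k": k, "omega": omega, "theta": theta, "h": h},
    )
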