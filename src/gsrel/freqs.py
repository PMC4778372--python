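"""Allele-frequency distribution models and their moment expectations.

Three models are supported for the distribution of marker allele frequencies p:

* uniform on (0,1);
* the U-shaped neutral-drift spectrum f(p) = k / [2p(1-p)] truncated to
  [1/(2Ne), 1 - 1/(2Ne)], with k = 1/ln(2 Ne);
* a symmetric Beta(phi, phi).

Each model provides the per-locus expectations entering the reliability formulas:
E[sigma_m^2], E[sigma_m^4], and the shrinkage-factor moments E[rho_m], E[rho_m^2],
E[rho_m^2 / sigma_m^2] with rho_m = n_r sigma_m^2 / (lambda_beta + n_r sigma_m^2).
The closed forms use h = lambda_beta / (2 n_r), omega = sqrt(1 + 4h) and
theta = ln|(1 + omega)/(1 - omega)|.  The Beta model evaluates the same integrals by
adaptive quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import integrate, optimize, stats

from .params import VarianceSpec


@dataclass(frozen=True)
class SpectrumExpectations:
    """Per-locus expectations of the quantities entering the precision formulas."""

    E_sigma2: float
    E_sigma4: float
    E_rho: float
    E_rho2: float
    E_rho2_over_sigma2: float
    h: float
    omega: float
    theta: float
    lambda_beta: float
    tau: float


def _h_omega_theta(lambda_beta: float, n_r: int):
    h = lambda_beta / (2.0 * n_r)
    if h <= 0.0:
        raise ZeroDivisionError("h = lambda_beta / (2 n_r) must be positive")
    omega = np.sqrt(1.0 + 4.0 * h)
    theta = np.log(abs((1.0 + omega) / (1.0 - omega)))
    return h, omega, theta


def ushape_constant(Ne: float) -> float:
    """Normalizing constant k = 1 / ln(2 Ne) of the U-shaped spectrum."""
    return 1.0 / np.log(2.0 * Ne)


class FreqDistributionModel:
    """Base class; subclasses define the density and per-locus expectations."""

    kind: str

    def pdf(self, p: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def support(self) -> tuple:
        return (0.0, 1.0)

    def E_sigma2(self) -> float:
        raise NotImplementedError

    def E_sigma4(self) -> float:
        raise NotImplementedError

    def zeta_expectation(self) -> float:
        raise NotImplementedError

    def rho_expectations(self, lambda_beta: float, n_r: int) -> tuple:
        """(E[rho], E[rho^2], E[rho^2/sigma^2]); overridden with closed forms."""
        return self._rho_quadrature(lambda_beta, n_r)

    def _rho_quadrature(self, lambda_beta: float, n_r: int, tol: float = 1e-10) -> tuple:
        # integrate over the full (0,1): the closed forms neglect the support
        # truncation (1/Ne effects), which is confined to the sampler
        lo, hi = 0.0, 1.0

        def rho(p):
            s2 = 2.0 * p * (1.0 - p)
            return n_r * s2 / (lambda_beta + n_r * s2)

        out = []
        for fn in (
            lambda p: rho(p),
            lambda p: rho(p) ** 2,
            lambda p: rho(p) ** 2 / (2.0 * p * (1.0 - p)),
        ):
            val, _ = integrate.quad(
                lambda p: fn(p) * self.pdf(p), lo, hi, epsabs=tol, epsrel=tol, limit=200
            )
            out.append(val)
        return tuple(out)


class UniformModel(FreqDistributionModel):
    kind = "uniform"

    def __init__(self, Ne: Optional[float] = None):
        self.Ne = Ne  # only used by the zeta expectation

    def pdf(self, p):
        return np.ones_like(np.asarray(p, dtype=float))

    def E_sigma2(self) -> float:
        return 1.0 / 3.0

    def E_sigma4(self) -> float:
        return 2.0 / 15.0

    def zeta_expectation(self) -> float:
        """E[1/sigma_m^2] for frequencies truncated to [1/Ne, 1 - 1/Ne]: ln(Ne - 1).

        The mean inverse locus variance is dominated by the truncation bound; the
        conventional bound for this quantity is 1/Ne.
        """
        if self.Ne is None or self.Ne <= 2:
            raise ValueError("zeta expectation needs Ne > 2")
        return float(np.log(self.Ne - 1.0))

    def rho_expectations(self, lambda_beta: float, n_r: int) -> tuple:
        h, w, th = _h_omega_theta(lambda_beta, n_r)
        E_rho = 1.0 - 2.0 * h * th / w
        # derived from the antiderivatives of 1/(h + p(1-p)) and its square;
        # validated against adaptive quadrature
        E_rho2 = 1.0 - 4.0 * h * th / w + 2.0 * h / w**2 + 4.0 * h**2 * th / w**3
        E_rho2_s2 = (th * (w - 2.0 * h / w) - 1.0) / w**2
        return E_rho, E_rho2, E_rho2_s2


class UShapedModel(FreqDistributionModel):
    kind = "u_shaped"

    def __init__(self, Ne: float):
        if Ne <= 2:
            raise ValueError("Ne must exceed 2")
        self.Ne = float(Ne)
        self.k = ushape_constant(self.Ne)

    def support(self) -> tuple:
        eps = 1.0 / (2.0 * self.Ne)
        return (eps, 1.0 - eps)

    def pdf(self, p):
        p = np.asarray(p, dtype=float)
        # closed forms ignore the support truncation (1/Ne negligible); the sampler
        # enforces it.  The density integrates to 1 - O(1/Ne) over the support.
        return self.k / (2.0 * p * (1.0 - p))

    def E_sigma2(self) -> float:
        return self.k

    def E_sigma4(self) -> float:
        return self.k / 3.0

    def zeta_expectation(self) -> float:
        """E[1/sigma_m^2] with frequencies truncated to [1/Ne, 1 - 1/Ne].

        Exact integral of 1/(2pq) against the U-shaped density:
        (k/4) [2 Ne (Ne-2)/(Ne-1) + 4 ln(Ne-1)].  The quantity diverges as the
        truncation bound shrinks, so the bound convention (1/Ne here) matters; the
        leading Ne term dominates the log term by a factor Ne/ln(Ne).
        """
        Ne = self.Ne
        return float(
            self.k / 4.0 * (4.0 * np.log(Ne - 1.0) + 2.0 * Ne * (Ne - 2.0) / (Ne - 1.0))
        )

    def rho_expectations(self, lambda_beta: float, n_r: int) -> tuple:
        h, w, th = _h_omega_theta(lambda_beta, n_r)
        k = self.k
        E_rho = k * th / w
        E_rho2 = k / w**2 * (th * (w - 2.0 * h / w) - 1.0)
        E_rho2_s2 = k / (2.0 * w**3) * (2.0 * th + w / h)
        return E_rho, E_rho2, E_rho2_s2


class BetaModel(FreqDistributionModel):
    """Symmetric Beta(phi, phi) allele-frequency model; expectations by quadrature."""

    kind = "beta"

    def __init__(self, phi: float):
        if phi <= 0:
            raise ValueError("phi must be positive")
        self.phi = float(phi)
        self._dist = stats.beta(self.phi, self.phi)

    def pdf(self, p):
        return self._dist.pdf(p)

    def E_sigma2(self) -> float:
        # 2 E[p(1-p)] = phi / (2 phi + 1), exact Beta moment
        return self.phi / (2.0 * self.phi + 1.0)

    def E_sigma4(self) -> float:
        val, _ = integrate.quad(
            lambda p: (2.0 * p * (1.0 - p)) ** 2 * self.pdf(p), 0, 1,
            epsabs=1e-10, epsrel=1e-10,
        )
        return val

    def zeta_expectation(self) -> float:
        if self.phi <= 0.5:
            raise ValueError("E[1/sigma^2] diverges for phi <= 1/2")
        val, _ = integrate.quad(
            lambda p: self.pdf(p) / (2.0 * p * (1.0 - p)), 0, 1,
            epsabs=1e-10, epsrel=1e-10,
        )
        return val


def make_model(kind: str, Ne: Optional[float] = None, phi: Optional[float] = None):
    kind = str(kind).lower().replace("-", "_").replace("ushaped", "u_shaped")
    if kind == "uniform":
        return UniformModel(Ne=Ne)
    if kind == "u_shaped":
        if Ne is None:
            raise ValueError("u-shaped model needs Ne")
        return UShapedModel(Ne)
    if kind == "beta":
        if phi is None:
            raise ValueError("beta model needs phi")
        return BetaModel(phi)
    raise ValueError(f"unknown frequency model {kind!r}")


# ----------------------------------------------------------------------
def sample_frequencies(
    n_M: int,
    n_r: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    model: str = "u_shaped",
) -> np.ndarray:
    """Draw marker allele frequencies.

    The U-shaped model uses the inverse-transform sampler
    p = (2 n_r - 1)^(2u - 1) / (1 + (2 n_r - 1)^(2u - 1)) with u ~ U(0,1), whose
    support is (1/(2 n_r), 1 - 1/(2 n_r)).  The uniform model samples uniformly on
    the same truncated support.
    """
    if n_r < 2:
        raise ValueError("n_r must be at least 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    u = rng.uniform(size=int(n_M))
    kind = str(model).lower().replace("-", "_").replace("ushaped", "u_shaped")
    if kind == "u_shaped":
        return ushape_quantile(u, n_r)
    if kind == "uniform":
        eps = 1.0 / (2.0 * n_r)
        return eps + (1.0 - 2.0 * eps) * u
    raise ValueError(f"no sampler for frequency model {model!r}")


def ushape_quantile(u: Union[float, np.ndarray], n_r: int) -> Union[float, np.ndarray]:
    """Quantile function of the truncated U-shaped spectrum (inverse transform)."""
    z = (2.0 * n_r - 1.0) ** (2.0 * np.asarray(u, dtype=float) - 1.0)
    out = z / (1.0 + z)
    return float(out) if np.ndim(u) == 0 else out


def spectrum_expectations(
    model: FreqDistributionModel, vs: VarianceSpec, n_r: int, n_M: int
) -> SpectrumExpectations:
    """All per-locus expectations needed by the reliability formulas.

    lambda_beta is evaluated on the expectation scale, tau = n_M * E[sigma_m^2],
    so h = lambda_beta / (2 n_r) is deterministic given the model.
    """
    E_s2 = model.E_sigma2()
    tau = n_M * E_s2
    lam = tau / vs.gamma
    h, omega, theta = _h_omega_theta(lam, n_r)
    E_rho, E_rho2, E_rho2_s2 = model.rho_expectations(lam, n_r)
    return SpectrumExpectations(
        E_sigma2=E_s2,
        E_sigma4=model.E_sigma4(),
        E_rho=E_rho,
        E_rho2=E_rho2,
        E_rho2_over_sigma2=E_rho2_s2,
        h=h,
        omega=omega,
        theta=theta,
        lambda_beta=lam,
        tau=tau,
    )


def zeta_expectation(model: FreqDistributionModel) -> float:
    """Expected mean inverse locus variance (standardized-coding correction)."""
    return model.zeta_expectation()


# ----------------------------------------------------------------------
def fit_beta_to_ushape(n_r: int, n_bins: int = 50) -> tuple:
    """Fit a symmetric Beta(phi, phi) to the U-shaped spectrum with Ne = n_r.

    The discrepancy is a chi-square-style statistic over ``n_bins`` equal-width bins
    of (0,1): sum over bins of (q_beta - q_u)^2 / q_u, with q_u the truncated U-shaped
    bin probabilities.  Returns (phi_hat, discrepancy_at_minimum).
    """
    if n_r < 10:
        raise ValueError("n_r must be at least 10")
    model = UShapedModel(n_r)
    lo, hi = model.support()
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    ce = np.clip(edges, lo, hi)
    # truncated U-shaped cdf: (k/2) ln[p(2Ne-1)/(1-p)] with k = 1/ln(2Ne-1)
    kq = 1.0 / np.log(2.0 * n_r - 1.0)
    cdf = 0.5 * kq * (np.log(ce / (1.0 - ce)) - np.log(lo / (1.0 - lo)))
    q_u = np.diff(cdf)
    q_u = q_u / q_u.sum()

    def discrepancy(phi: float) -> float:
        q_b = np.diff(stats.beta.cdf(edges, phi, phi))
        return float(np.sum((q_b - q_u) ** 2 / q_u))

    res = optimize.minimize_scalar(
        discrepancy, bounds=(1e-3, 50.0), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(f"Beta fit did not converge: {res}")
    return float(res.x), float(res.fun)


def beta_moment_integrals(
    phi: float, vs: VarianceSpec, n_r: int, n_M: int, tol: float = 1e-8
) -> dict:
    """Quadrature expectations under Beta(phi, phi) of the precision-formula elements.

    tau is evaluated on the expectation scale (n_M * E[sigma^2]) so that
    lambda_beta = tau / gamma, as in the closed-form models.
    """
    model = BetaModel(phi)
    E_s2 = model.E_sigma2()
    tau = n_M * E_s2
    lam = tau / vs.gamma

    def rho(p):
        s2 = 2.0 * p * (1.0 - p)
        return n_r * s2 / (lam + n_r * s2)

    def q(fn):
        val, _ = integrate.quad(
            lambda p: fn(p) * model.pdf(p), 0, 1, epsabs=tol, epsrel=tol, limit=200
        )
        return val

    return {
        "E_sigma2": E_s2,
        "E_sigma4": model.E_sigma4(),
        "E_rho": q(rho),
        "E_rho2": q(lambda p: rho(p) ** 2),
        "E_rho2_over_sigma2": q(lambda p: rho(p) ** 2 / (2.0 * p * (1.0 - p))),
        "E_tau": tau,
        "lambda_beta": lam,
    }
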