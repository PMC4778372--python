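"""Two-locus, two-individual genotype moments under linkage disequilibrium.

The first-order second approximation needs, for every ordered pair of loci (m, l) and
every reference individual i, the four-value expectation E[x_cm X_im x_cl X_il].
Decomposing each coded genotype into its two parental allelic values g = (0 or 1) - p,
these expectations are sums of sixteen terms classified by parental origin
(whether the two loci of each individual sit on the same gamete) and by the IBD state
of the candidate-reference allele pairs at the two loci (both loci IBD: S_ml; one
locus: S_m / S_l; none: S_0).

The closed conditional expectations implemented in :func:`conditional_product_moment` are validated
against exact enumeration over founder haplotypes (see :func:`enumerate_conditional`)
for the configurations whose printed conditions are reconstructible.  The aggregate
formulas of :func:`four_value_expectation` are implemented as printed; the weight
``r_ml`` attached to the joint-IBD configuration in the sire case is exposed as a
parameter (default one minus the recombination fraction), and gene dropping
(:func:`two_locus_gene_drop`) provides the independent empirical route.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .moments import UnsupportedRelationshipError
from .params import MarkerPanel, VarianceSpec
from .relationships import RelationshipSpec
from .reliability import ReliabilityResult


@dataclass(frozen=True)
class TwoLocusContext:
    """Frequencies, LD and relationship information for one locus pair."""

    p_m: float
    p_l: float
    delta: float
    relationship: str = "unrelated"  # 'unrelated' or 'sire'
    r_ml: Optional[float] = None  # joint-IBD weight; default 1 - c handled by callers

    def __post_init__(self) -> None:
        for p in (self.p_m, self.p_l):
            if not 0.0 < p < 1.0:
                raise ValueError("frequencies must lie in (0,1)")
        sm = np.sqrt(2.0 * self.p_m * (1.0 - self.p_m))
        sl = np.sqrt(2.0 * self.p_l * (1.0 - self.p_l))
        if abs(2.0 * self.delta) > sm * sl + 1e-12:
            raise ValueError("|2 delta| must not exceed sigma_m sigma_l")
        if self.r_ml is not None and not 0.0 <= self.r_ml <= 1.0:
            raise ValueError("r_ml must lie in [0,1]")


def haplotype_probs(p_m: float, p_l: float, delta: float) -> np.ndarray:
    """Probabilities of the four haplotypes (00, 01, 10, 11) at loci (m, l)."""
    pr = np.array(
        [
            (1 - p_m) * (1 - p_l) + delta,
            (1 - p_m) * p_l - delta,
            p_m * (1 - p_l) - delta,
            p_m * p_l + delta,
        ]
    )
    if np.any(pr < -1e-12):
        raise ValueError("delta incompatible with the allele frequencies")
    return np.clip(pr, 0.0, 1.0)


# ----------------------------------------------------------------------
def conditional_product_moment(state: str, origin: str, p_m: float, p_l: float, delta: float) -> float:
    """Conditional expectation E[g_cls g_cmt g_ilu g_imv | state & origin type].

    ``state`` in {'S_ml', 'S_m', 'S_l', 'S_0'}; ``origin`` in
    {'same_same', 'same_diff', 'diff_same', 'diff_diff'} (candidate / reference pair
    of loci on the same or on different gametes).  Values as printed; the S_0 row is
    reproduced as printed even though its condition could not be reconstructed (see
    the package methods note).
    """
    qm, ql = 1.0 - p_m, 1.0 - p_l
    base = qm * ql * p_m * p_l
    if state == "S_ml":
        if origin in {"same_same", "same_diff", "diff_same"}:
            return base + delta * (1.0 - 2.0 * p_l) * (1.0 - 2.0 * p_m)
        return base  # diff_diff: no within-gamete LD pairing survives
    if state == "S_m":
        if origin == "same_same":
            return delta**2 * (p_m**3 + qm**3) / (p_m * qm)
        return 0.0
    if state == "S_l":
        if origin == "same_same":
            return delta**2 * (p_l**3 + ql**3) / (p_l * ql)
        return 0.0
    if state == "S_0":
        if origin == "same_same":
            return delta**2 * (1.0 - 2.0 * p_m) * (1.0 - 2.0 * p_l)
        return 0.0
    raise ValueError(f"unknown IBD state {state!r}")


def pairwise_second_moment(ctx: TwoLocusContext) -> float:
    """Single-locus term E[x_cm^2 X_im^2] at locus m for the supported relationships."""
    pq = ctx.p_m * (1.0 - ctx.p_m)
    if ctx.relationship == "unrelated":
        return 4.0 * pq**2
    if ctx.relationship == "sire":
        return pq
    raise UnsupportedRelationshipError(
        "two-locus moments support only 'unrelated' and 'sire' pairs"
    )


def four_value_expectation(ctx: TwoLocusContext) -> float:
    """Cross-locus expectation E[x_cl x_cm X_il X_im] for one reference individual."""
    pm, pl, d = ctx.p_m, ctx.p_l, ctx.delta
    if ctx.relationship == "unrelated":
        return 4.0 * d**2 * (1.0 - 2.0 * pm) * (1.0 - 2.0 * pl)
    if ctx.relationship == "sire":
        r = 0.5 if ctx.r_ml is None else ctx.r_ml
        qm, ql = 1.0 - pm, 1.0 - pl
        t1 = qm * ql * pm * pl + d * (1.0 - 2.0 * pl) * (1.0 - 2.0 * pm)
        fm = (pm**3 + qm**3) / (pm * qm)
        fl = (pl**3 + ql**3) / (pl * ql)
        return t1 + 2.0 * d**2 * (
            r * (fm + fl) + (1.0 - r) * (1.0 - 2.0 * pm) * (1.0 - 2.0 * pl)
        )
    raise UnsupportedRelationshipError(
        "two-locus moments support only 'unrelated' and 'sire' pairs"
    )


# ----------------------------------------------------------------------
# oracles
def enumerate_conditional(
    state: str, origin: str, p_m: float, p_l: float, delta: float
) -> float:
    """Exact enumeration of E[g_cls g_cmt g_ilu g_imv | state & origin].

    Constructs the conditional configuration directly: shared (IBD) alleles are drawn
    once, non-shared values come from independent haplotypes, and 'same'-gamete locus
    pairs are drawn jointly from the haplotype table.  Returns the exact expectation
    by enumeration over haplotypes.  Only configurations with an unambiguous
    reconstruction are supported.
    """
    pr = haplotype_probs(p_m, p_l, delta)
    am = np.array([0, 0, 1, 1], dtype=float)
    al = np.array([0, 1, 0, 1], dtype=float)
    gm = am - p_m
    gl = al - p_l
    pm_marg = np.array([1.0 - p_m, p_m])
    gm_val = np.array([-p_m, 1.0 - p_m])

    def cond_gl_given_am(a: int) -> float:
        # E[g_l | a_m = a] on one haplotype
        mask = am == a
        w = pr[mask] / pr[mask].sum()
        return float(w @ gl[mask])

    def joint_sq() -> float:
        # E[g_m^2 g_l^2] on one haplotype
        return float(pr @ (gm**2 * gl**2))

    def joint() -> float:
        return float(pr @ (gm * gl))

    if state == "S_ml":
        if origin in {"same_same"}:
            return joint_sq()
        if origin in {"same_diff", "diff_same"}:
            # shared alleles at both loci; one individual's pair on one gamete
            return joint_sq()
        # diff_diff: shared m-allele and shared l-allele on different gametes
        return float((pm_marg @ gm_val**2) * ((1 - p_l) * p_l**2 + p_l * (1 - p_l) ** 2))
    if state in {"S_m", "S_l"}:
        if origin != "same_same":
            # at least one unshared allele sits alone on a gamete: mean zero
            return 0.0
        if state == "S_l":
            return enumerate_conditional("S_m", origin, p_l, p_m, delta)
        # shared allele at m; each individual's l-value conditional on it
        out = 0.0
        for a in (0, 1):
            out += pm_marg[a] * gm_val[a] ** 2 * cond_gl_given_am(a) ** 2
        return float(out)
    if state == "S_0":
        if origin == "same_same":
            # two independent within-gamete LD pairs
            return joint() ** 2
        return 0.0
    raise ValueError(f"unsupported configuration ({state}, {origin})")


def two_locus_gene_drop(
    p_m: float,
    p_l: float,
    delta: float,
    c: float,
    relationship: str = "sire",
    n_reps: int = 10**6,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple:
    """Monte-Carlo estimate of E[x_cl x_cm X_il X_im] by two-locus gene dropping.

    Founder haplotypes are drawn from the table implied by (p_m, p_l, delta);
    transmitted gametes recombine with fraction ``c``.  For ``relationship='sire'``
    the reference individual is the candidate's sire; for 'unrelated' it is an
    independent founder.  Returns (mean, standard error).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    pr = haplotype_probs(p_m, p_l, delta)
    n = int(n_reps)

    def founder():
        idx = rng.choice(4, size=n, p=pr)
        return (idx // 2).astype(float), (idx % 2).astype(float)

    def gamete(m1, l1, m2, l2):
        start = rng.integers(0, 2, size=n)
        rec = rng.random(n) < c
        g_m = np.where(start == 0, m1, m2)
        g_l = np.where(start == 0, np.where(rec, l2, l1), np.where(rec, l1, l2))
        return g_m, g_l

    s_m1, s_l1 = founder()
    s_m2, s_l2 = founder()
    d_m1, d_l1 = founder()
    d_m2, d_l2 = founder()
    cs_m, cs_l = gamete(s_m1, s_l1, s_m2, s_l2)
    cd_m, cd_l = gamete(d_m1, d_l1, d_m2, d_l2)
    x_cm = cs_m + cd_m - 2.0 * p_m
    x_cl = cs_l + cd_l - 2.0 * p_l
    if relationship == "sire":
        X_im = s_m1 + s_m2 - 2.0 * p_m
        X_il = s_l1 + s_l2 - 2.0 * p_l
    elif relationship == "unrelated":
        u_m1, u_l1 = founder()
        u_m2, u_l2 = founder()
        X_im = u_m1 + u_m2 - 2.0 * p_m
        X_il = u_l1 + u_l2 - 2.0 * p_l
    else:
        raise UnsupportedRelationshipError(
            "two-locus gene drop supports 'sire' and 'unrelated'"
        )
    prod = x_cm * x_cl * X_im * X_il
    return float(prod.mean()), float(prod.std(ddof=1) / np.sqrt(n))


# ----------------------------------------------------------------------
def approx2_expectation_ld(
    rel: RelationshipSpec,
    vs: VarianceSpec,
    panel: MarkerPanel,
    r_ml: Optional[np.ndarray] = None,
    L: Optional[float] = None,
) -> ReliabilityResult:
    """First-order second-approximation expectation with LD-aware cross moments.

    Evaluates the general first-order expectation with the double sum over locus
    pairs (m, l != m) supplied by :func:`four_value_expectation` and the single-locus
    terms by :func:`pairwise_second_moment`.  With ``panel.delta`` identically zero
    this reduces exactly to the independent-marker expectation.

    ``r_ml`` may be a full matrix of joint-IBD weights for the sire pair; when absent
    it defaults to 1 - c_ml with c_ml = min(|l - m| L / n_M, 1/2) if a genome length
    ``L`` is given, else to 1/2 everywhere.
    """
    if panel.delta is None:
        raise ValueError("panel must carry a delta (LD) matrix")
    if rel.preset not in {"unrelated", "sire_in_reference"}:
        raise UnsupportedRelationshipError(
            "LD-aware expectation supports only unrelated and sire_in_reference"
        )
    n_M = panel.n_markers
    n_r = rel.n_r
    p = panel.p
    sig2 = panel.sigma_m2
    tau = panel.tau
    lam = tau / vs.gamma
    denom = lam + n_r * sig2

    if r_ml is None:
        if L is not None:
            dist = np.abs(np.subtract.outer(np.arange(n_M), np.arange(n_M))) * L / n_M
            r_ml = 1.0 - np.minimum(dist, 0.5)
        else:
            r_ml = np.full((n_M, n_M), 0.5)

    one_minus_2p = 1.0 - 2.0 * p
    f = ((p**3 + (1.0 - p) ** 3) / (p * (1.0 - p)))  # per-locus heterozygosity factor
    d2 = panel.delta**2
    cross_unrel = 4.0 * d2 * np.outer(one_minus_2p, one_minus_2p)
    # sire-pair cross matrix (printed three-term formula, vectorized)
    t1 = (
        np.outer((1.0 - p) * p, (1.0 - p) * p)
        + panel.delta * np.outer(one_minus_2p, one_minus_2p)
    )
    cross_sire = t1 + 2.0 * d2 * (
        r_ml * np.add.outer(f, f)
        + (1.0 - r_ml) * np.outer(one_minus_2p, one_minus_2p)
    )
    np.fill_diagonal(cross_unrel, 0.0)
    np.fill_diagonal(cross_sire, 0.0)

    w = 1.0 / denom
    diag_terms = np.sum(sig2 / denom) + n_r * np.sum(sig2**2 / denom**2)

    def pair_sum(second_moments: np.ndarray, cross: np.ndarray) -> float:
        return float(np.sum(second_moments / denom**2) + w @ cross @ w)

    second_unrel = 4.0 * (p * (1.0 - p)) ** 2
    second_sire = p * (1.0 - p)
    if rel.preset == "unrelated":
        pair_total = n_r * pair_sum(second_unrel, cross_unrel)
    else:
        pair_total = pair_sum(second_sire, cross_sire) + (n_r - 1) * pair_sum(
            second_unrel, cross_unrel
        )
    braces = diag_terms - pair_total
    est = 1.0 - lam / tau * braces
    return ReliabilityResult(
        estimate=float(est), method="approx2_expect_ld", order=1,
        components={"lambda_beta": lam, "braces": braces},
    )
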