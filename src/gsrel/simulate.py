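"""Seeded genotype simulation and batch replication of the numerical experiments.

A scenario draws allele frequencies from the U-shaped spectrum (with effective size
equal to the reference size), generates coded genotypes for the reference population
plus one candidate by gene dropping with Hardy-Weinberg founders and free
recombination across loci, and evaluates the exact reliability together with the
Taylor approximations at the requested orders.  Means over replicates with their
Monte-Carlo standard errors reproduce the reference result tables; the closed-form
expectation columns are computed once per scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .freqs import UShapedModel, sample_frequencies, spectrum_expectations
from .params import Codification, MarkerPanel, VarianceSpec
from .relationships import RelationshipSpec, preset_relationship
from .reliability import (
    GenotypeData,
    ShrinkageMoments,
    approx1_expectation,
    approx1_on_genotypes,
    approx2_expectation,
    approx2_on_genotypes,
    exact_reliability,
    matrix_T,
)

#: scenario grids of the reference tables (marker counts x reference sizes)
UNRELATED_GRID: List[Tuple[int, int]] = [
    (nM, nr)
    for nM in (50, 100, 250, 1000, 1500, 2000, 2500)
    for nr in (500, 1000, 1500, 2000)
]
SIRE_GRID: List[Tuple[int, int]] = [
    (nM, nr) for nM in (1000, 1500, 2000, 2500) for nr in (500, 1000, 1500, 2000)
]
RATIO_GRID: List[Tuple[int, int]] = [
    (nM, nr) for nM in (1000, 1500, 2000, 2500) for nr in (500, 1000, 1500, 2000)
]


@dataclass
class ScenarioConfig:
    """One simulation scenario (or grid cell)."""

    n_r: int
    n_M: int
    nu2: float = 0.4
    preset: str = "unrelated"
    n_reps: int = 50
    seed: int = 0
    orders1: Tuple[int, ...] = (2, 10)  # first-approximation truncation orders
    orders2: Tuple[int, ...] = (1, 10)  # second-approximation truncation orders
    fix_freqs: bool = False

    def __post_init__(self) -> None:
        if self.n_reps < 1 or self.n_r < 2 or self.n_M < 1:
            raise ValueError("sizes and replicate counts must be positive")


# ----------------------------------------------------------------------
def generate_genotypes(
    preset: str,
    p: np.ndarray,
    n_r: int,
    rng: np.random.Generator,
    codification: Codification = Codification.CENTERED,
) -> GenotypeData:
    """Generate coded genotypes for a candidate (row 0) plus n_r reference individuals.

    Founders receive two independent Bernoulli(p) alleles per locus; non-founders one
    uniformly chosen allele from each parent, independently across loci.  Gametes of
    parents outside the modeled set (e.g. the candidate's dam) are population draws.
    """
    p = np.asarray(p, dtype=float)
    n_M = p.size
    key = str(preset).lower().replace("-", "_")

    def founder_counts(n: int) -> np.ndarray:
        return rng.binomial(2, p, size=(n, n_M)).astype(float)

    def pop_gamete(n: int = 1) -> np.ndarray:
        g = rng.random((n, n_M)) < p
        return g.astype(float)

    def transmitted(parent_counts: np.ndarray) -> np.ndarray:
        # one allele sampled from an individual's two (equivalent to picking a gamete
        # under free recombination): Bernoulli(count / 2) per locus
        return rng.binomial(1, parent_counts / 2.0).astype(float)

    refs = founder_counts(n_r)
    if key == "unrelated":
        cand = founder_counts(1)[0]
    elif key in {"sire_in_reference", "sire"}:
        cand = transmitted(refs[0]) + pop_gamete()[0]
    elif key == "both_parents":
        cand = transmitted(refs[0]) + transmitted(refs[1])
    elif key.startswith("half_sibs"):
        k = n_r
        if "(" in key:
            k = int(key.split("(", 1)[1].rstrip(")"))
        hidden_sire = founder_counts(1)[0]
        for i in range(k):
            refs[i] = transmitted(hidden_sire) + pop_gamete()[0]
        cand = transmitted(hidden_sire) + pop_gamete()[0]
    else:
        raise ValueError(f"unknown relationship preset {preset!r}")
    counts = np.vstack([cand, refs])
    X = counts - 2.0 * p
    panel = MarkerPanel(p=p)
    if Codification(codification) is Codification.STANDARDIZED:
        X = X / np.sqrt(panel.sigma_m2)
    return GenotypeData(X=X, panel=panel, codification=codification)


# ----------------------------------------------------------------------
def _mean_se(values: Sequence[float]) -> Tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(arr.size))


def replicate_cell(config: ScenarioConfig, compute_radius: bool = False) -> dict:
    """Replicate one scenario; returns per-column means and standard errors."""
    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(config.n_reps + 1)
    vs = VarianceSpec(nu2=config.nu2)
    rel = preset_relationship(config.preset, config.n_r)
    T = matrix_T(rel.A, vs.gamma)
    freq_rng = np.random.default_rng(child_seeds[0])
    p_fixed = (
        sample_frequencies(config.n_M, config.n_r, rng=freq_rng)
        if config.fix_freqs
        else None
    )
    cols: dict = {"exact": []}
    for o in config.orders1:
        cols[f"approx1_o{o}"] = []
    for o in config.orders2:
        cols[f"approx2_o{o}"] = []
    if config.orders1:
        cols["v_qhat_a1"] = []
        cols["v_q_realized"] = []
    radii1, radii2 = [], []
    for r in range(config.n_reps):
        rng = np.random.default_rng(child_seeds[r + 1])
        p = p_fixed if p_fixed is not None else sample_frequencies(
            config.n_M, config.n_r, rng=rng
        )
        geno = generate_genotypes(config.preset, p, config.n_r, rng)
        cols["exact"].append(exact_reliability(geno, vs).estimate)
        want_r1 = compute_radius and r < 5
        for j, o in enumerate(config.orders1):
            res = approx1_on_genotypes(
                geno, rel, vs, order=o, T=T, compute_radius=want_r1 and j == 0
            )
            cols[f"approx1_o{o}"].append(res.estimate)
            if j == 0:
                cols["v_qhat_a1"].append(res.components["v_qhat"])
                cols["v_q_realized"].append(res.components["v_q_realized"])
                if res.spectral_radius is not None:
                    radii1.append(res.spectral_radius)
        for j, o in enumerate(config.orders2):
            res = approx2_on_genotypes(
                geno, vs, order=o, compute_radius=want_r1 and j == 0
            )
            cols[f"approx2_o{o}"].append(res.estimate)
            if res.spectral_radius is not None and j == 0:
                radii2.append(res.spectral_radius)
    out: dict = {
        "n_M": config.n_M,
        "n_r": config.n_r,
        "nu2": config.nu2,
        "preset": config.preset,
        "n_reps": config.n_reps,
    }
    for name, vals in cols.items():
        m, se = _mean_se(vals)
        out[name] = m
        out[f"{name}_se"] = se
    out["_raw"] = cols
    if radii1:
        out["radius_approx1"] = float(np.mean(radii1))
    if radii2:
        out["radius_approx2"] = float(np.mean(radii2))
    return out


def expectation_columns(n_M: int, n_r: int, nu2: float, preset: str) -> dict:
    """Closed-form expectation columns of a scenario (U-shaped spectrum, Ne = n_r)."""
    vs = VarianceSpec(nu2=nu2)
    rel = preset_relationship(preset, n_r)
    model = UShapedModel(Ne=n_r)
    tau = n_M * model.E_sigma2()
    tau2 = n_M * model.E_sigma4()
    out = {}
    try:
        out["E_approx1"] = approx1_expectation(rel, vs, tau, tau2).estimate
    except Exception:
        out["E_approx1"] = np.nan
    t3 = spectrum_expectations(model, vs, n_r, n_M)
    moments = ShrinkageMoments.from_model(t3, vs, n_r, n_M)
    out["E_approx2"] = approx2_expectation(rel, vs, moments).estimate
    return out


def replicate_table(
    grid: Iterable[Tuple[int, int]],
    nu2: float = 0.4,
    preset: str = "unrelated",
    n_reps: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate a (n_M, n_r) scenario grid; mirrors the reference table layout."""
    grid = list(grid)
    seeds = np.random.SeedSequence(seed).spawn(len(grid))
    rows = []
    for (n_M, n_r), cell_seed in zip(grid, seeds):
        cfg_seed = int(np.random.default_rng(cell_seed).integers(0, 2**31 - 1))
        cfg = ScenarioConfig(
            n_r=n_r, n_M=n_M, nu2=nu2, preset=preset, n_reps=n_reps, seed=cfg_seed
        )
        cell = replicate_cell(cfg)
        cell.pop("_raw")
        cell.update(expectation_columns(n_M, n_r, nu2, preset))
        rows.append(cell)
    return pd.DataFrame(rows)


def ratio_bias_check(
    grid: Iterable[Tuple[int, int]],
    nu2: float = 0.4,
    n_reps: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean of per-replicate variance ratios vs ratio of mean variances.

    Pairs E[v(qhat)/v(q)] with E[v(qhat)]/E[v(q)] from the same replicate stream,
    where v(qhat) is the order-2 first-approximation prediction variance and v(q) the
    realized candidate molecular-score variance.
    """
    grid = list(grid)
    seeds = np.random.SeedSequence(seed).spawn(len(grid))
    rows = []
    for (n_M, n_r), cell_seed in zip(grid, seeds):
        cfg_seed = int(np.random.default_rng(cell_seed).integers(0, 2**31 - 1))
        cfg = ScenarioConfig(
            n_r=n_r, n_M=n_M, nu2=nu2, preset="unrelated", n_reps=n_reps,
            seed=cfg_seed, orders1=(2,), orders2=(),
        )
        cell = replicate_cell(cfg)
        raw = cell.pop("_raw")
        num = np.asarray(raw["v_qhat_a1"])
        den = np.asarray(raw["v_q_realized"])
        ratios = num / den
        mean_ratio, se_ratio = _mean_se(ratios)
        ratio_of_means = float(num.mean() / den.mean())
        rows.append(
            {
                "n_r": n_r,
                "n_M": n_M,
                "E_ratio": mean_ratio,
                "ratio_E": ratio_of_means,
                "difference": mean_ratio - ratio_of_means,
                "E_ratio_se": se_ratio,
                "n_reps": n_reps,
            }
        )
    return pd.DataFrame(rows)


def eigenvalue_sweep(
    n_r_values: Sequence[int],
    n_M_values: Sequence[int],
    nu2_values: Sequence[float],
    n_reps: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean spectral radius of both series' perturbation matrices over a grid."""
    combos = [
        (nr, nM, nu2)
        for nr in n_r_values
        for nM in n_M_values
        for nu2 in nu2_values
    ]
    seeds = np.random.SeedSequence(seed).spawn(len(combos))
    rows = []
    for (n_r, n_M, nu2), cell_seed in zip(combos, seeds):
        cfg_seed = int(np.random.default_rng(cell_seed).integers(0, 2**31 - 1))
        vs = VarianceSpec(nu2=nu2)
        rel = preset_relationship("unrelated", n_r)
        T = matrix_T(rel.A, vs.gamma)
        ss = np.random.SeedSequence(cfg_seed).spawn(n_reps)
        r1, r2 = [], []
        for child in ss:
            rng = np.random.default_rng(child)
            p = sample_frequencies(n_M, n_r, rng=rng)
            geno = generate_genotypes("unrelated", p, n_r, rng)
            res1 = approx1_on_genotypes(geno, rel, vs, order=0, T=T, compute_radius=True)
            res2 = approx2_on_genotypes(geno, vs, order=0, compute_radius=True)
            r1.append(res1.spectral_radius)
            r2.append(res2.spectral_radius)
        rows.append(
            {
                "n_r": n_r,
                "n_M": n_M,
                "nu2": nu2,
                "radius_approx1": float(np.mean(r1)),
                "radius_approx2": float(np.mean(r2)),
                "n_reps": n_reps,
            }
        )
    return pd.DataFrame(rows)
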