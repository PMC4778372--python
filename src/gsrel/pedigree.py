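"""Pedigrees, tabular kinship, and gene dropping.

A pedigree is a list of individuals with optional sire and dam.  Founders are assumed
unrelated and non-inbred.  Gene dropping simulates bi-allelic genotypes through the
pedigree: founder gametes are Bernoulli(p) draws (Hardy-Weinberg), and each non-founder
receives one uniformly chosen allele from each parent, independently across loci (free
recombination; within-genome linkage is handled analytically elsewhere).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

FOUNDER_TOKENS = {"0", "na", "nan", ".", "", "none"}


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Ordered pedigree; ``sire[i]``/``dam[i]`` are row indices or -1 for founders."""

    ids: List[str]
    sire: np.ndarray
    dam: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.sire = np.asarray(self.sire, dtype=int)
        self.dam = np.asarray(self.dam, dtype=int)
        if self.sire.shape != (n,) or self.dam.shape != (n,):
            raise PedigreeError("sire/dam must have one entry per individual")
        for i in range(n):
            for par in (self.sire[i], self.dam[i]):
                if par >= i:
                    raise PedigreeError(
                        "parents must precede offspring (cycle or unordered pedigree)"
                    )

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, individual: str) -> int:
        return self.ids.index(str(individual))

    @classmethod
    def from_records(
        cls, records: Sequence[tuple], reorder: bool = True
    ) -> "Pedigree":
        """Build from (id, sire, dam) triplets; 0/NA/None denote unknown parents."""

        def norm(tok) -> Optional[str]:
            s = str(tok).strip()
            return None if s.lower() in FOUNDER_TOKENS else s

        rec = [(str(i).strip(), norm(s), norm(d)) for i, s, d in records]
        ids = [r[0] for r in rec]
        if len(set(ids)) != len(ids):
            raise PedigreeError("duplicate individual ids")
        parents: Dict[str, tuple] = {i: (s, d) for i, s, d in rec}
        if reorder:
            ordered: List[str] = []
            mark: Dict[str, int] = {}

            def visit(node: str, stack: tuple) -> None:
                if node in stack:
                    raise PedigreeError(f"pedigree cycle involving {node!r}")
                if mark.get(node):
                    return
                for par in parents.get(node, (None, None)):
                    if par is not None:
                        if par not in parents:
                            parents[par] = (None, None)
                        visit(par, stack + (node,))
                mark[node] = 1
                ordered.append(node)

            for i in list(parents):
                visit(i, ())
            ids = ordered
        pos = {i: k for k, i in enumerate(ids)}
        sire = np.array(
            [pos[parents[i][0]] if parents[i][0] is not None else -1 for i in ids]
        )
        dam = np.array(
            [pos[parents[i][1]] if parents[i][1] is not None else -1 for i in ids]
        )
        return cls(ids=ids, sire=sire, dam=dam)

    @classmethod
    def from_file(cls, path) -> "Pedigree":
        """Read 3-column whitespace- or comma-delimited text (id, sire, dam)."""
        records = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.replace(",", " ").split()
                if len(parts) < 3:
                    raise PedigreeError(f"malformed pedigree line: {line!r}")
                records.append(tuple(parts[:3]))
        return cls.from_records(records)

    # ------------------------------------------------------------------
    def kinship(self) -> np.ndarray:
        """Tabular kinship recursion.

        Returns the matrix of coancestry coefficients a_ij (a_ii = 1/2 for a
        non-inbred individual).
        """
        n = self.n
        f = np.zeros((n, n))
        for i in range(n):
            s, d = self.sire[i], self.dam[i]
            fsd = f[s, d] if (s >= 0 and d >= 0) else 0.0
            f[i, i] = 0.5 * (1.0 + fsd)
            for j in range(i):
                val = 0.0
                if s >= 0:
                    val += 0.5 * f[j, s]
                if d >= 0:
                    val += 0.5 * f[j, d]
                f[i, j] = f[j, i] = val
        return f

    def additive_relationship(self) -> np.ndarray:
        """Numerator relationship matrix A = 2 * kinship (unit diagonal if non-inbred)."""
        return 2.0 * self.kinship()

    # ------------------------------------------------------------------
    def gene_drop(
        self, p: Union[float, np.ndarray], rng: np.random.Generator, n_loci: int = None
    ) -> np.ndarray:
        """Drop alleles through the pedigree at independent bi-allelic loci.

        Parameters
        ----------
        p : float or vector
            Allele frequency per locus (a scalar is broadcast over ``n_loci``).
        rng : numpy Generator
        n_loci : int, optional
            Number of loci when ``p`` is scalar.

        Returns
        -------
        counts : (n_individuals, n_loci) integer array of allele counts in {0,1,2}.
        """
        p = np.asarray(p, dtype=float)
        if p.ndim == 0:
            if n_loci is None:
                raise ValueError("n_loci required with scalar p")
            p = np.full(n_loci, float(p))
        nl = p.size
        pat = np.empty((self.n, nl), dtype=np.int8)
        mat = np.empty((self.n, nl), dtype=np.int8)
        for i in range(self.n):
            for gam, par in ((pat, self.sire[i]), (mat, self.dam[i])):
                if par < 0:
                    gam[i] = rng.random(nl) < p
                else:
                    pick = rng.integers(0, 2, size=nl)
                    gam[i] = np.where(pick == 0, pat[par], mat[par])
        return (pat + mat).astype(np.int16)


# ----------------------------------------------------------------------
# canonical two-individual pedigrees used by the moment oracles
def parent_offspring_pedigree() -> tuple:
    ped = Pedigree.from_records([("P", 0, 0), ("M", 0, 0), ("O", "P", "M")])
    return ped, ("P", "O")


def half_sib_pedigree() -> tuple:
    ped = Pedigree.from_records(
        [("S", 0, 0), ("D1", 0, 0), ("D2", 0, 0), ("H1", "S", "D1"), ("H2", "S", "D2")]
    )
    return ped, ("H1", "H2")


def full_sib_pedigree() -> tuple:
    ped = Pedigree.from_records(
        [("S", 0, 0), ("D", 0, 0), ("F1", "S", "D"), ("F2", "S", "D")]
    )
    return ped, ("F1", "F2")


def unrelated_pedigree() -> tuple:
    ped = Pedigree.from_records([("U1", 0, 0), ("U2", 0, 0)])
    return ped, ("U1", "U2")


CANONICAL_PAIR_PEDIGREES = {
    "unrelated": unrelated_pedigree,
    "parent_offspring": parent_offspring_pedigree,
    "half_sibs": half_sib_pedigree,
    "full_sibs": full_sib_pedigree,
}
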