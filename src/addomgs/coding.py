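"""Marker incidence coding and genomic/pedigree relationship matrices.

The additive code W and dominance code S map genotypes MM/Mm/mm at a locus
with allele frequency p (q = 1 - p) to

    W:  MM -> 2q,    Mm -> q - p,  mm -> -2p
    S:  MM -> -2q^2, Mm -> 2pq,    mm -> -2p^2

which matches the classical quantitative-genetics parameterization: W m_a
are breeding values (m_a the allele-substitution effects) and S m_d the
dominance deviations.  The genomic relationship matrices follow with the
variance identities sigma_a^2 = sum(2pq) * sigma_ma^2 and
sigma_d^2 = sum((2pq)^2) * sigma_md^2:

    G_a = W W' / sum_i 2 p_i q_i
    G_d = S S' / sum_i (2 p_i q_i)^2

Pedigree counterparts A (numerator relationship, tabular method) and D
(dominance relationship for non-inbred pedigrees) are provided for the
pedigree-BLUP baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MarkerCoding",
    "KinshipSet",
    "code_additive",
    "code_dominance",
    "build_coding",
    "build_Ga",
    "build_Gd",
    "build_A",
    "build_D",
    "build_kinships",
    "add_ridge",
]

#: diagonal jitter added before inverting a genomic relationship matrix
DEFAULT_RIDGE = 1e-8


def _check_freq(p, n_loci):
    p = np.asarray(p, dtype=float)
    if p.size != n_loci:
        raise ValueError("frequency vector does not match the marker count")
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError(
            "allele frequencies must lie strictly in (0, 1); "
            "filter monomorphic loci first"
        )
    return p


def code_additive(dosages: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Additive incidence W: dosage 2 -> 2q, 1 -> q - p, 0 -> -2p."""
    x = np.asarray(dosages, dtype=float)
    p = _check_freq(p, x.shape[-1])
    return x - 2.0 * p


def code_dominance(dosages: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Dominance incidence S: dosage 2 -> -2q^2, 1 -> 2pq, 0 -> -2p^2."""
    x = np.asarray(dosages, dtype=float)
    p = _check_freq(p, x.shape[-1])
    q = 1.0 - p
    out = np.empty_like(x)
    out[...] = np.where(x == 2, -2.0 * q * q, np.where(x == 1, 2.0 * p * q, -2.0 * p * p))
    return out


@dataclass
class MarkerCoding:
    """W/S incidence matrices with the frequencies that generated them."""

    W: np.ndarray
    S: np.ndarray
    p: np.ndarray

    @property
    def sum2pq(self) -> float:
        return float(np.sum(2.0 * self.p * (1.0 - self.p)))

    @property
    def sum2pq_sq(self) -> float:
        return float(np.sum((2.0 * self.p * (1.0 - self.p)) ** 2))


def build_coding(dosages: np.ndarray, p: np.ndarray | None = None) -> MarkerCoding:
    """Code a dosage matrix; p defaults to the observed cohort frequencies."""
    x = np.asarray(dosages, dtype=float)
    if p is None:
        p = x.mean(axis=0) / 2.0
    p = np.asarray(p, dtype=float)
    return MarkerCoding(code_additive(x, p), code_dominance(x, p), p)


def build_Ga(W: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Additive genomic relationship G_a = WW' / sum 2 p_i q_i."""
    p = np.asarray(p, dtype=float)
    denom = np.sum(2.0 * p * (1.0 - p))
    if denom <= 0:
        raise ValueError("sum of 2pq is zero; no polymorphic loci")
    return (W @ W.T) / denom


def build_Gd(S: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Dominance genomic relationship G_d = SS' / sum (2 p_i q_i)^2."""
    p = np.asarray(p, dtype=float)
    denom = np.sum((2.0 * p * (1.0 - p)) ** 2)
    if denom <= 0:
        raise ValueError("sum of (2pq)^2 is zero; no polymorphic loci")
    return (S @ S.T) / denom


def build_A(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Pedigree numerator relationship matrix by the tabular method.

    ``sire``/``dam`` are parent indices per individual, -1 for unknown
    (founder); parents must precede their offspring.
    """
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    n = sire.size
    idx = np.arange(n)
    for par in (sire, dam):
        known = par >= 0
        if np.any(par[known] >= idx[known]):
            raise ValueError("pedigree must be sorted: parents precede offspring")
    A = np.zeros((n, n))
    for j in range(n):
        s, d = sire[j], dam[j]
        a_sd = A[s, d] if (s != -1 and d != -1) else 0.0
        A[j, j] = 1.0 + 0.5 * a_sd
        if j:
            row = np.zeros(j)
            if s != -1:
                row += 0.5 * A[:j, s]
            if d != -1:
                row += 0.5 * A[:j, d]
            A[j, :j] = A[:j, j] = row
    return A


def build_D(sire: np.ndarray, dam: np.ndarray, A: np.ndarray | None = None) -> np.ndarray:
    """Pedigree dominance relationship for a non-inbred pedigree.

    D_jk = (A_{s(j)s(k)} A_{d(j)d(k)} + A_{s(j)d(k)} A_{d(j)s(k)}) / 4 with
    unit diagonal; terms involving unknown parents contribute zero.
    """
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    if A is None:
        A = build_A(sire, dam)
    n = sire.size

    # pad A with a zero row/col so index -1 (unknown parent) contributes 0
    Ap = np.zeros((n + 1, n + 1))
    Ap[:n, :n] = A
    s, d = sire.copy(), dam.copy()
    D = 0.25 * (Ap[np.ix_(s, s)] * Ap[np.ix_(d, d)] + Ap[np.ix_(s, d)] * Ap[np.ix_(d, s)])
    np.fill_diagonal(D, 1.0)
    return D


@dataclass
class KinshipSet:
    """Genomic (Ga, Gd) and pedigree (A, D) relationship matrices."""

    Ga: np.ndarray
    Gd: np.ndarray
    A: np.ndarray | None = None
    D: np.ndarray | None = None


def build_kinships(dosages, p=None, sire=None, dam=None) -> KinshipSet:
    coding = build_coding(dosages, p)
    Ga = build_Ga(coding.W, coding.p)
    Gd = build_Gd(coding.S, coding.p)
    A = D = None
    if sire is not None and dam is not None:
        A = build_A(sire, dam)
        D = build_D(sire, dam, A)
    return KinshipSet(Ga, Gd, A, D)


def add_ridge(G: np.ndarray, eps: float = DEFAULT_RIDGE) -> np.ndarray:
    """Numerical PSD repair: G + eps * mean(diag) * I."""
    return G + eps * float(np.mean(np.diag(G))) * np.eye(G.shape[0])
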