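"""Scaled LD matrix A and the per-locus iteration constants.

Row i of A carries the effect SNP, column j the tested SNP:

    a_ij = sqrt(N * H_i) * r_ij,

so the summary-statistic model reads z = A^T beta + e.  The fitter only ever
needs A through three precomputed objects: A1 = A z, the action of
A2 = -A A^T on a vector, and the exact row sums of squares sum_j a_ij^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import LDMatrix


@dataclass
class ScaledLD:
    """Scaled LD matrix with precomputed iteration constants.

    Attributes
    ----------
    a : ndarray, shape (M, M)
        Scaled LD matrix, rows indexed by effect SNP.
    a1 : ndarray, shape (M,)
        A z for the z-scores supplied at construction.
    col_sq : ndarray, shape (M,)
        Exact row sums of squares, sum_j a_ij^2 (used by the sigma_i^2
        gradient; never approximated).
    a2 : ndarray or None
        Dense A2 = -A A^T when precomputed; None when a low-rank factor
        stands in for it.
    lowrank : LowRankAAt or None
        Optional truncated eigenfactorization of A A^T (see
        :mod:`vbfinemap.lowrank`); when set, matrix-vector products with A2
        use it instead of the dense matrix.
    """

    a: np.ndarray
    a1: np.ndarray | None
    col_sq: np.ndarray
    a2: np.ndarray | None = None
    lowrank: "object | None" = field(default=None, repr=False)

    @property
    def m(self) -> int:
        return self.a.shape[0]

    def a2_mul(self, v: np.ndarray) -> np.ndarray:
        """A2 @ v = -(A (A^T v)); uses the dense or low-rank precomputation."""
        if self.lowrank is not None:
            from .lowrank import apply_a2mu

            return apply_a2mu(self.lowrank, v)
        if self.a2 is not None:
            return self.a2 @ v
        return -(self.a @ (self.a.T @ v))


def build_A(ld: LDMatrix, het: np.ndarray, n: int) -> np.ndarray:
    """Scale the LD matrix by per-SNP sqrt(N * H_i) along rows.

    A monomorphic SNP (H_i = 0) contributes a zero row: it carries no
    association signal.  Doubling N multiplies every entry by sqrt(2).
    """
    het = np.asarray(het, dtype=float)
    if het.shape != (ld.m,):
        raise ValueError(f"het has length {het.shape}, LD matrix is {ld.m}x{ld.m}")
    if np.any(het < 0):
        raise ValueError("negative heterozygosity")
    if n < 1:
        raise ValueError(f"sample size n={n} must be >= 1")
    scale = np.sqrt(float(n) * het)
    # r is symmetric, so row-scaling by sqrt(N H_i) realizes a_ij = sqrt(N H_i) r_ji
    return scale[:, None] * ld.r


def precompute(a: np.ndarray, z: np.ndarray, dense_a2: bool = True) -> ScaledLD:
    """Precompute A1 = A z and A2 = -A A^T once, before optimization.

    With ``dense_a2=False`` the M x M product is not formed; A2 v is then
    evaluated as two matrix-vector products per call (or through a low-rank
    factor attached afterwards).
    """
    a = np.asarray(a, dtype=float)
    z = np.asarray(z, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"A must be square, got {a.shape}")
    if z.shape != (a.shape[1],):
        raise ValueError(f"z has shape {z.shape}, A is {a.shape}")
    a1 = a @ z
    col_sq = np.einsum("ij,ij->i", a, a)
    a2 = -(a @ a.T) if dense_a2 else None
    return ScaledLD(a=a, a1=a1, col_sq=col_sq, a2=a2)


def a_from_genotypes(g: np.ndarray) -> tuple[LDMatrix, np.ndarray, int]:
    """Sample LD, heterozygosity and N from an allele-count genotype matrix.

    Parameters
    ----------
    g : ndarray, shape (N, M)
        Genotypes coded 0/1/2 (rows individuals, columns SNPs).

    Returns
    -------
    (LDMatrix, het, n)
        Sample Pearson correlation between columns, heterozygosity
        2 f (1 - f) from the sample allele frequency (folded to the minor
        allele), and the number of individuals.  Zero-variance columns get
        H = 0 and zero off-diagonal correlation, with a warning.
    """
    g = np.asarray(g)
    n, m = g.shape
    gc = g.astype(np.float32) - g.mean(axis=0, dtype=np.float64).astype(np.float32)
    ss = np.einsum("ij,ij->j", gc, gc, dtype=np.float64)
    zero_var = ss <= 0
    if np.any(zero_var):
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance genotype columns: "
            "het set to 0, LD row/column zeroed",
            stacklevel=2,
        )
    norm = np.sqrt(np.where(zero_var, 1.0, ss))
    gc /= norm.astype(np.float32)
    r = (gc.T @ gc).astype(np.float64)
    r[zero_var, :] = 0.0
    r[:, zero_var] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    r = 0.5 * (r + r.T)
    np.fill_diagonal(r, 1.0)
    freq = g.mean(axis=0, dtype=np.float64) / 2.0
    freq = np.minimum(freq, 1.0 - freq)
    het = 2.0 * freq * (1.0 - freq)
    het[zero_var] = 0.0
    return LDMatrix(r=r), het, n
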