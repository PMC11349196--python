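"""Low-rank acceleration of the A2 mu product.

The only O(M^2) term in the per-iteration gradient is A2 mu with
A2 = -A A^T.  A truncated eigendecomposition A A^T ~= U diag(lam) U^T with
p_c components turns it into an O(p_c M) product.  The factorization is
computed once before optimization; the row sums of squares sum_j a_ij^2
needed by the sigma_i^2 gradient are kept exact (they cost O(M^2) once and
O(M) per iteration, so approximating them buys nothing).

Two flavours are provided.  ``factorize`` truncates A A^T itself.
``factorize_hollow`` — the one the fitter uses — keeps the diagonal of
A A^T exact (it equals the already-exact col_sq, and it carries each SNP's
own-data curvature, the dominant shrinkage on a committed effect) and
truncates only the hollow remainder A A^T - diag(col_sq):

    A2 mu  ~=  -(col_sq * mu + U' diag(lam') U'^T mu),

still O(p_c M) per product.  Pure truncation keeps only the leading LD
subspace and loses most of the diagonal, which lets sparse fitted effects
grow unchecked in the dropped directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse.linalg


@dataclass
class LowRankAAt:
    """Top-p_c eigenpairs (of A A^T, or of its hollow part) plus the exact
    row sums of squares."""

    u: np.ndarray  # (M, p_c), orthonormal columns
    lam: np.ndarray  # (p_c,), non-increasing magnitude
    col_sq: np.ndarray  # (M,), exact sum_j a_ij^2
    p_c: int
    hollow: bool = False  # True when lam/u factor A A^T - diag(col_sq)

    @property
    def m(self) -> int:
        return self.u.shape[0]


def factorize(a: np.ndarray, p_c: int) -> LowRankAAt:
    """Truncated eigendecomposition of A A^T, computed once.

    Uses an implicitly restarted Lanczos iteration (through matrix-vector
    products v -> A (A^T v), never forming A A^T) when p_c is a small
    fraction of M, and a dense symmetric eigensolver otherwise.
    """
    a = np.asarray(a, dtype=float)
    m = a.shape[0]
    if not 1 <= p_c <= m:
        raise ValueError(f"p_c={p_c} out of range [1, {m}]")
    col_sq = np.einsum("ij,ij->i", a, a)
    if p_c >= m - 1 or m < 200:
        aat = a @ a.T
        lam, u = scipy.linalg.eigh(aat)
        lam, u = lam[::-1][:p_c], u[:, ::-1][:, :p_c]
    else:
        op = scipy.sparse.linalg.LinearOperator(
            (m, m), matvec=lambda v: a @ (a.T @ v), dtype=float
        )
        lam, u = scipy.sparse.linalg.eigsh(op, k=p_c, which="LM")
        order = np.argsort(lam)[::-1]
        lam, u = lam[order], u[:, order]
    lam = np.maximum(lam, 0.0)
    return LowRankAAt(u=np.ascontiguousarray(u), lam=lam, col_sq=col_sq, p_c=int(p_c))


def factorize_hollow(a: np.ndarray, p_c: int) -> LowRankAAt:
    """Truncated eigendecomposition of A A^T - diag(col_sq), computed once.

    Eigenvalues of the hollow matrix are signed; the p_c of largest
    magnitude are kept.
    """
    a = np.asarray(a, dtype=float)
    m = a.shape[0]
    if not 1 <= p_c <= m:
        raise ValueError(f"p_c={p_c} out of range [1, {m}]")
    col_sq = np.einsum("ij,ij->i", a, a)
    if p_c >= m - 1 or m < 200:
        h = a @ a.T
        np.fill_diagonal(h, 0.0)
        lam, u = scipy.linalg.eigh(h)
    else:
        op = scipy.sparse.linalg.LinearOperator(
            (m, m), matvec=lambda v: a @ (a.T @ v) - col_sq * v, dtype=float
        )
        lam, u = scipy.sparse.linalg.eigsh(op, k=min(p_c, m - 2), which="LM")
    order = np.argsort(-np.abs(lam))[:p_c]
    return LowRankAAt(
        u=np.ascontiguousarray(u[:, order]),
        lam=lam[order],
        col_sq=col_sq,
        p_c=int(p_c),
        hollow=True,
    )


def apply_a2mu(lr: LowRankAAt, mu: np.ndarray) -> np.ndarray:
    """A2 mu in O(p_c M) operations.

    -U (lam * (U^T mu)) for a plain factor; the hollow factor adds the
    exact diagonal term -col_sq * mu.
    """
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (lr.m,):
        raise ValueError(f"mu has shape {mu.shape}, expected ({lr.m},)")
    out = -(lr.u @ (lr.lam * (lr.u.T @ mu)))
    if lr.hollow:
        out -= lr.col_sq * mu
    return out


def attach_lowrank(sld, p_c: int, hollow: bool = True) -> None:
    """Replace the dense A2 action on a ScaledLD with a rank-p_c factor."""
    sld.lowrank = factorize_hollow(sld.a, p_c) if hollow else factorize(sld.a, p_c)
    sld.a2 = None
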