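"""Mean-field variational model for the spike-and-slab z-score likelihood.

Model
-----
z_j | beta ~ N(sum_i a_ij beta_i, sigma0^2)
beta_i | u_i = 0 ~ N(0, delta^2)        (spike; delta^2 fixed, tiny)
beta_i | u_i = 1 ~ N(0, sigma_beta^2)   (slab)
u_i ~ Bern(pi1)

Variational family:  q(beta, u) = prod_i Bern(u_i | q_i) N(beta_i | mu_i, sigma_i^2).

The evidence lower bound decomposes as L = T1 - T2 - T3 with
T1 the expected Gaussian log-likelihood, T2 the u-averaged Gaussian KL of
q(beta_i) against the spike/slab components, and T3 the Bernoulli KL.  All
six partial derivatives (mu_i, sigma_i^2, q_i, pi1, sigma_beta^2, sigma0^2)
are analytic; their correctness is pinned by finite-difference tests against
the ELBO implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

Q_CLIP = 1e-12  # q_i clipped into [Q_CLIP, 1-Q_CLIP] before log terms
SIGMA2_FLOOR = 1e-300
# Auto spike width: delta_i^2 = SPIKE_SCALE * sigma0^2 / sum_j a_ij^2, i.e. a
# spike-scale effect shifts the expected z-score of its own SNP by less than
# sqrt(SPIKE_SCALE) residual standard deviations.  Sizing the spike to the
# per-SNP information keeps it "sufficiently small" on any design: much wider
# and an LD block can absorb a real signal as many spike-scale effects without
# ever paying the Bernoulli cost of declaring a causal SNP; much narrower and
# the spike penalty freezes the optimization before signal SNPs can commit.
SPIKE_SCALE = 0.5


class NumericalDomainError(FloatingPointError):
    """A model quantity became non-finite; the message names the index."""


@dataclass
class VariationalState:
    """Mean-field parameters: per-SNP Bernoulli q_i and Gaussian (mu_i, sigma_i^2)."""

    q: np.ndarray
    mu: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.clip(np.asarray(self.q, dtype=float), Q_CLIP, 1.0 - Q_CLIP)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma2 = np.maximum(np.asarray(self.sigma2, dtype=float), SIGMA2_FLOOR)
        m = self.q.shape[0]
        if self.mu.shape != (m,) or self.sigma2.shape != (m,):
            raise ValueError("q, mu, sigma2 must share length")

    @property
    def m(self) -> int:
        return self.q.shape[0]


@dataclass
class Hyperparams:
    """Model hyperparameters theta = (pi1, sigma_beta2, sigma02) plus the
    fixed spike variance delta2.

    pi1 is the prior causal fraction, sigma_beta2 the slab (causal-effect)
    variance on the scale of the z-score model, sigma02 the residual
    z-score variance (1 under the null), and delta2 the spike variance —
    a scalar, a per-SNP array, or None for the auto rule
    delta_i^2 = SPIKE_SCALE * sigma0^2 / sum_j a_ij^2 resolved when a fit
    begins (the spike must be invisible at z-score scale, and what is
    invisible depends on each SNP's data precision).
    """

    pi1: float
    sigma_beta2: float
    sigma02: float = 1.0
    delta2: float | np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.pi1 < 1.0:
            raise ValueError(f"pi1={self.pi1} must lie in (0, 1)")
        if self.sigma_beta2 <= 0 or self.sigma02 <= 0:
            raise ValueError("variances must be positive")
        if self.delta2 is not None:
            d = np.asarray(self.delta2)
            if np.any(d <= 0):
                raise ValueError("spike variance delta2 must be positive")
            if np.any(d >= self.sigma_beta2):
                raise ValueError(
                    f"spike variance delta2 must be smaller than the slab "
                    f"variance sigma_beta2={self.sigma_beta2}"
                )

    def h2(self, het: np.ndarray) -> float:
        """Implied locus heritability h2 = sigma_beta2 * pi1 * sum_i H_i."""
        return float(self.sigma_beta2 * self.pi1 * np.sum(het))


@dataclass
class ELBOTerms:
    """ELBO decomposition; total = t1 - t2 - t3 with t2, t3 >= 0."""

    t1: float
    t2: float
    t3: float

    @property
    def total(self) -> float:
        return self.t1 - self.t2 - self.t3


def _gauss_kl(mu: np.ndarray, sigma2: np.ndarray, v: float) -> np.ndarray:
    """KL( N(mu, sigma2) || N(0, v) ) elementwise."""
    ratio = sigma2 / v
    return 0.5 * (ratio + mu * mu / v - 1.0 - np.log(ratio))


def expected_residual_ss(
    state: VariationalState, sld, z: np.ndarray, quad_mu: float | None = None
) -> float:
    """E_q || z - A^T beta ||^2 = ||z - A^T mu||^2 + sum_i sigma_i^2 sum_j a_ij^2.

    The quadratic part uses the precomputed A1 and the A2 action:
    ||z - A^T mu||^2 = z.z - 2 mu.A1 + mu.(A A^T mu); ``quad_mu`` may supply
    mu.(A A^T mu) externally (the optimizer passes an exactness-corrected
    value when a truncated A2 action is in use, since the truncation only
    ever underestimates this positive quadratic form).
    """
    if quad_mu is None:
        quad_mu = float(-(state.mu @ sld.a2_mul(state.mu)))
    resid2 = float(z @ z - 2.0 * (state.mu @ sld.a1)) + quad_mu
    return resid2 + float(state.sigma2 @ sld.col_sq)


def elbo(
    state: VariationalState,
    hyper: Hyperparams,
    sld,
    z: np.ndarray,
    quad_mu: float | None = None,
) -> ELBOTerms:
    """Evaluate the ELBO terms T1, T2, T3 in closed form."""
    m = state.m
    if z.shape != (m,) or sld.m != m:
        raise ValueError("dimension mismatch between state, A and z")
    if hyper.delta2 is None:
        raise ValueError("delta2 is unresolved; use optimize.resolve_spike first")
    s02 = hyper.sigma02
    t1 = -0.5 * m * np.log(2.0 * np.pi * s02) - expected_residual_ss(
        state, sld, z, quad_mu
    ) / (2.0 * s02)
    kl_spike = _gauss_kl(state.mu, state.sigma2, hyper.delta2)
    kl_slab = _gauss_kl(state.mu, state.sigma2, hyper.sigma_beta2)
    t2 = float(np.sum((1.0 - state.q) * kl_spike + state.q * kl_slab))
    q = state.q
    t3 = float(
        np.sum(q * np.log(q / hyper.pi1) + (1.0 - q) * np.log((1.0 - q) / (1.0 - hyper.pi1)))
    )
    terms = ELBOTerms(t1=float(t1), t2=t2, t3=t3)
    if not np.isfinite(terms.total):
        bad = _first_nonfinite(kl_spike + kl_slab)
        raise NumericalDomainError(f"non-finite ELBO (first offending SNP index: {bad})")
    return terms


def _first_nonfinite(x: np.ndarray) -> int | None:
    idx = np.flatnonzero(~np.isfinite(x))
    return int(idx[0]) if idx.size else None


def grad_state(
    state: VariationalState, hyper: Hyperparams, sld, z: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic ELBO gradients with respect to (mu, sigma2, q).

    dmu uses the compact precomputed form (A1 + A2 mu)/sigma0^2 minus the
    prior shrinkage terms; dsigma2 and dq are elementwise.
    """
    q, mu, s2 = state.q, state.mu, state.sigma2
    d2, sb2, s02 = hyper.delta2, hyper.sigma_beta2, hyper.sigma02
    dmu = (sld.a1 + sld.a2_mul(mu)) / s02 - (1.0 - q) * mu / d2 - q * mu / sb2
    dsigma2 = -sld.col_sq / (2.0 * s02) - 0.5 * ((1.0 - q) / d2 + q / sb2 - 1.0 / s2)
    second_moment = s2 + mu * mu
    dq = -(
        0.5 * np.log(sb2 / d2)
        - second_moment / (2.0 * d2)
        + second_moment / (2.0 * sb2)
        + np.log(q / hyper.pi1)
        - np.log((1.0 - q) / (1.0 - hyper.pi1))
    )
    for name, g in (("mu", dmu), ("sigma2", dsigma2), ("q", dq)):
        if not np.all(np.isfinite(g)):
            raise NumericalDomainError(
                f"non-finite gradient d{name} at SNP index {_first_nonfinite(g)}"
            )
    return dmu, dsigma2, dq


def grad_hyper(
    state: VariationalState, hyper: Hyperparams, sld, z: np.ndarray
) -> tuple[float, float, float]:
    """Analytic ELBO gradients with respect to (pi1, sigma_beta2, sigma02)."""
    q, mu, s2 = state.q, state.mu, state.sigma2
    pi1, sb2, s02 = hyper.pi1, hyper.sigma_beta2, hyper.sigma02
    dpi1 = float(np.sum(q - pi1) / (pi1 * (1.0 - pi1)))
    dsb2 = float(np.sum(q * (s2 + mu * mu - sb2)) / (2.0 * sb2 * sb2))
    e_resid = expected_residual_ss(state, sld, z)
    ds02 = (e_resid - state.m * s02) / (2.0 * s02 * s02)
    out = (dpi1, dsb2, float(ds02))
    if not all(np.isfinite(v) for v in out):
        raise NumericalDomainError("non-finite hyperparameter gradient")
    return out
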