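"""ADAM optimization of the ELBO over transformed variational parameters.

The constrained variational parameters are handled by smooth bijections
rather than projection: mu is unconstrained, sigma_i^2 = exp(s_i),
q_i = sigmoid(t_i); the analytic gradients are multiplied by the bijection
Jacobians and plain ADAM ascends the ELBO.

When hyperparameters are learned they are updated by exact coordinate
ascent rather than by ADAM: each update is the unique root of the
corresponding analytic derivative (pi1 <- mean(q), sigma_beta^2 <- the
q-weighted posterior second moment, sigma0^2 <- the expected residual sum
of squares over M), and the ELBO is unimodal in each hyperparameter
separately, so every update is a monotone ascent step.  Gradient steps on
log-scale hyperparameters proved unstable here: early in a fit the slab
gradient is dominated by the many null SNPs and scale-free steps can walk
sigma_beta^2 down onto the spike before the signal SNPs accumulate
evidence, collapsing the mixture.  pi1 is clipped to [1/(10 M), 0.5]
(the extremes degenerate the Bernoulli KL and the credible-set count
L = ceil(M pi1)) and sigma_beta^2 is floored at twice the spike variance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .model import (
    ELBOTerms,
    Hyperparams,
    NumericalDomainError,
    Q_CLIP,
    VariationalState,
    elbo,
    grad_hyper,
    grad_state,
)


@dataclass
class FitConfig:
    """Optimizer settings.

    learn_hyper toggles co-optimization of (pi1, sigma_beta2, sigma02);
    when on, hyperparameter updates start after ``hyper_warmup`` iterations
    so the variational state first adapts (and the signal SNPs commit) under
    the initial hyperparameters — updating the slab variance from a still
    uncommitted state lets the many null SNPs drag it onto the spike.
    The default warmup covers the commitment time of the sigmoid/log
    coordinates at the default learning rate (roughly 10 logit units at
    lr per iteration).  Convergence is declared when the relative ELBO
    change stays below ``tol`` for ``patience`` consecutive iterations.

    ``resid_refresh`` only matters with a truncated A2 action: the exact
    residual quadratic mu.(A A^T mu) is recomputed every that many
    iterations (O(M^2)) and the low-rank value is corrected in between, so
    the ELBO trace and the sigma0^2 update stay calibrated while the
    per-iteration gradient cost stays O(p_c M).
    """

    learn_hyper: bool = True
    lr: float = 0.05
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    max_iter: int = 2000
    tol: float = 1e-6
    patience: int = 10
    hyper_warmup: int = 250
    resid_refresh: int = 20
    exact_q: bool = True
    init: str = "null"
    min_iter: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("beta1, beta2 must lie in (0, 1)")


@dataclass
class FitResult:
    state: VariationalState
    hyper: Hyperparams
    elbo_trace: np.ndarray
    n_iter: int
    converged: bool
    terms: ELBOTerms = field(default=None)  # ELBO decomposition at the returned state


def resolve_spike(hyper: Hyperparams, col_sq: np.ndarray) -> Hyperparams:
    """Resolve ``delta2=None`` to the per-SNP auto spike width.

    delta_i^2 = SPIKE_SCALE * sigma0^2 / sum_j a_ij^2, capped at a quarter of
    the slab variance (rare or monomorphic SNPs carry little information, so
    their spike may otherwise grow arbitrarily wide).
    """
    if hyper.delta2 is not None:
        return hyper
    from .model import SPIKE_SCALE

    col_sq = np.maximum(np.asarray(col_sq, dtype=float), 1e-300)
    delta2 = np.minimum(SPIKE_SCALE * hyper.sigma02 / col_sq, hyper.sigma_beta2 / 4.0)
    return dataclasses.replace(hyper, delta2=delta2)


def init_state(m: int, hyper: Hyperparams) -> VariationalState:
    """Symmetric initialization: q_i = pi1, mu_i = 0, sigma_i^2 = sigma_beta^2.

    At this point the pi1- and sigma_beta2-gradients vanish identically.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    return VariationalState(
        q=np.full(m, hyper.pi1),
        mu=np.zeros(m),
        sigma2=np.full(m, hyper.sigma_beta2),
    )


def hyper_from_h2(
    h2: float, pi1: float, het: np.ndarray, n: int, sigma02: float = 1.0,
    delta2: float | np.ndarray | None = None
) -> Hyperparams:
    """Slab variance from a target locus heritability.

    Inverts h2 = sigma_beta2 * pi1 * sum_i H_i.  Because the sqrt(N H_i)
    weighting already lives inside A, the effect scale of the z-score model
    needs no extra N factor.  The residual z-score variance defaults to 1
    (its value under the null).
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError(f"h2={h2} must lie in (0, 1)")
    het_sum = float(np.sum(het))
    if het_sum <= 0:
        raise ValueError("sum of heterozygosities must be positive")
    sigma_beta2 = h2 / (pi1 * het_sum)
    return Hyperparams(pi1=pi1, sigma_beta2=sigma_beta2, sigma02=sigma02, delta2=delta2)


def posterior_closed_form_orthogonal(
    z: np.ndarray, a_diag: np.ndarray, hyper: Hyperparams
) -> np.ndarray:
    """Exact per-SNP posterior causal probability when A is diagonal.

    With a_i on the diagonal the likelihood factorizes and the marginal of
    z_i under each mixture component is Gaussian, giving posterior odds
    pi1/(1-pi1) * BF_i with

        BF_i = sqrt((s0^2 + a_i^2 d^2) / (s0^2 + a_i^2 sb^2))
               * exp( z_i^2 a_i^2 (sb^2 - d^2)
                      / (2 (s0^2 + a_i^2 sb^2)(s0^2 + a_i^2 d^2)) ).

    This is the independent oracle for the fitter on orthogonal designs.
    """
    z = np.asarray(z, dtype=float)
    a2 = np.asarray(a_diag, dtype=float) ** 2
    s0, sb, d = hyper.sigma02, hyper.sigma_beta2, hyper.delta2
    v1 = s0 + a2 * sb
    v0 = s0 + a2 * d
    log_bf = 0.5 * np.log(v0 / v1) + z * z * a2 * (sb - d) / (2.0 * v1 * v0)
    log_odds = np.log(hyper.pi1 / (1.0 - hyper.pi1)) + log_bf
    # odds/(1+odds) via the logistic for numerical stability
    return 1.0 / (1.0 + np.exp(-log_odds))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _logit(p):
    return np.log(p) - np.log1p(-p)


def fit(z: np.ndarray, sld, hyper0: Hyperparams, cfg: FitConfig | None = None) -> FitResult:
    """Maximize the ELBO by ADAM; returns the best state seen.

    Parameters
    ----------
    z : ndarray, shape (M,)
        GWAS z-scores.
    sld : ScaledLD
        Precomputed scaled LD (dense A2 or a low-rank factor).
    hyper0 : Hyperparams
        Initial (or fixed, if ``cfg.learn_hyper`` is False) hyperparameters.
    cfg : FitConfig, optional
    """
    cfg = cfg or FitConfig()
    z = np.asarray(z, dtype=float)
    m = z.shape[0]
    if sld.m != m:
        raise ValueError(f"A is {sld.m}x{sld.m} but z has length {m}")

    hyper0 = resolve_spike(hyper0, sld.col_sq)
    pi_lo, pi_hi = 1.0 / (10.0 * m), 0.5

    # unconstrained variational coordinates: [mu | log sigma2 | logit q]
    if cfg.init == "null":
        # spike-consistent start: sigma_i^2 at its coordinate optimum given
        # q = pi1, mu = 0 (the root of the sigma_i^2-derivative)
        prec = (
            sld.col_sq / hyper0.sigma02
            + (1.0 - hyper0.pi1) / np.asarray(hyper0.delta2)
            + hyper0.pi1 / hyper0.sigma_beta2
        )
        sigma2_init = 1.0 / prec
    elif cfg.init == "slab":
        sigma2_init = np.full(m, hyper0.sigma_beta2)
    else:
        raise ValueError(f"unknown init {cfg.init!r}")
    theta = np.concatenate(
        [np.zeros(m), np.log(sigma2_init), np.full(m, _logit(hyper0.pi1))]
    )
    hyper = hyper0

    def unpack(th: np.ndarray) -> VariationalState:
        return VariationalState(
            q=np.clip(_sigmoid(th[2 * m : 3 * m]), Q_CLIP, 1.0 - Q_CLIP),
            mu=th[:m],
            sigma2=np.exp(th[m : 2 * m]),
        )

    lowrank = getattr(sld, "lowrank", None) is not None

    def quad_exact(mu: np.ndarray) -> float:
        v = sld.a.T @ mu
        return float(v @ v)

    def quad_approx(mu: np.ndarray) -> float:
        return float(-(mu @ sld.a2_mul(mu)))

    quad_corr = 0.0  # exact-minus-approx correction, refreshed periodically

    def quad_mu(state: VariationalState, it: int) -> float | None:
        nonlocal quad_corr
        if not lowrank:
            return None  # dense A2 action is already exact
        approx = quad_approx(state.mu)
        if it % cfg.resid_refresh == 0:
            quad_corr = quad_exact(state.mu) - approx
        return max(approx + quad_corr, 0.0)

    def hyper_update(state: VariationalState, quad: float | None) -> Hyperparams:
        # exact coordinate-ascent roots of the analytic hyper derivatives
        pi1 = float(np.clip(np.mean(state.q), pi_lo, pi_hi))
        qsum = float(np.sum(state.q))
        second = float(np.sum(state.q * (state.sigma2 + state.mu**2)))
        sb2 = max(second / qsum, 2.0 * float(np.max(hyper0.delta2)))
        from .model import expected_residual_ss

        s02 = max(expected_residual_ss(state, sld, z, quad) / m, 1e-8)
        return Hyperparams(pi1=pi1, sigma_beta2=sb2, sigma02=s02, delta2=hyper0.delta2)

    adam_m = np.zeros_like(theta)
    adam_v = np.zeros_like(theta)
    trace = np.empty(cfg.max_iter + 1)
    state = unpack(theta)
    terms = elbo(state, hyper, sld, z)
    trace[0] = terms.total
    best = (terms.total, theta.copy(), hyper, terms)
    prev = terms.total
    quiet = 0
    converged = False
    n_iter = 0

    def exact_q_logits(th: np.ndarray, hyp: Hyperparams) -> np.ndarray:
        # unique root of the q_i-derivative given (mu_i, sigma_i^2): the
        # Bernoulli factor has a closed-form coordinate maximizer
        sm = np.exp(th[m : 2 * m]) + th[:m] ** 2
        d2 = np.asarray(hyp.delta2)
        t = (
            _logit(hyp.pi1)
            - 0.5 * np.log(hyp.sigma_beta2 / d2)
            + sm / (2.0 * d2)
            - sm / (2.0 * hyp.sigma_beta2)
        )
        return np.clip(t, -30.0, 30.0)

    if cfg.exact_q:
        theta[2 * m : 3 * m] = exact_q_logits(theta, hyper)
        state = unpack(theta)

    for it in range(1, cfg.max_iter + 1):
        dmu, dsigma2, dq = grad_state(state, hyper, sld, z)
        qv = state.q
        grad = np.concatenate(
            [
                dmu,
                dsigma2 * state.sigma2,  # d/ds, sigma2 = exp(s)
                np.zeros(m) if cfg.exact_q else dq * qv * (1.0 - qv),  # d/dt
            ]
        )
        adam_m = cfg.beta1 * adam_m + (1 - cfg.beta1) * grad
        adam_v = cfg.beta2 * adam_v + (1 - cfg.beta2) * grad * grad
        mhat = adam_m / (1 - cfg.beta1**it)
        vhat = adam_v / (1 - cfg.beta2**it)
        theta = theta + cfg.lr * mhat / (np.sqrt(vhat) + cfg.eps)

        if cfg.exact_q:
            theta[2 * m : 3 * m] = exact_q_logits(theta, hyper)
        state = unpack(theta)
        quad = quad_mu(state, it)
        if cfg.learn_hyper and it > cfg.hyper_warmup:
            hyper = hyper_update(state, quad)
        try:
            terms = elbo(state, hyper, sld, z, quad)
        except NumericalDomainError as exc:
            raise NumericalDomainError(
                f"non-finite ELBO at iteration {it} "
                f"(pi1={hyper.pi1:.3g}, sigma_beta2={hyper.sigma_beta2:.3g}, "
                f"sigma02={hyper.sigma02:.3g}): {exc}"
            ) from exc
        total = terms.total
        trace[it] = total
        n_iter = it
        if total > best[0]:
            best = (total, theta.copy(), hyper, terms)
        # convergence can only be declared after the transient (and, when
        # hyperparameters are learned, after they have had time to settle):
        # the ELBO trace has flat stretches mid-transient that would
        # otherwise trigger a premature stop
        can_stop = it >= cfg.min_iter and (
            not cfg.learn_hyper or it > cfg.hyper_warmup + cfg.patience
        )
        if can_stop and abs(total - prev) < cfg.tol * (1.0 + abs(prev)):
            quiet += 1
            if quiet >= cfg.patience:
                converged = True
                break
        else:
            quiet = 0
        prev = total

    return FitResult(
        state=unpack(best[1]),
        hyper=best[2],
        elbo_trace=trace[: n_iter + 1].copy(),
        n_iter=n_iter,
        converged=converged,
        terms=best[3],
    )
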