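"""Scoring of finemapping output against simulated truth, benchmark grids,
and the phenotype-prediction utilities used for real-data style evaluation.

AUC is the rank-based (Mann-Whitney) area under the ROC curve and AUPRC the
step-interpolated precision-recall area, both delegated to scikit-learn and
cross-checked in the tests against exhaustive threshold enumeration.
Credible-set coverage pools reported sets across replicates (the standard
estimator when a scenario is summarized by one number): coverage is the
fraction of pooled sets containing at least one causal SNP, power the
fraction of all causal SNPs captured by any set.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .credible import CredibleSet, build_credible_sets
from .ldmatrix import build_A, precompute
from .lowrank import attach_lowrank
from .model import NumericalDomainError
from .optimize import FitConfig, Hyperparams, fit, hyper_from_h2
from .simulate import SimConfig, simulate_locus

logger = logging.getLogger(__name__)


@dataclass
class EvalMetrics:
    auc: float
    auprc: float
    coverage: float | None
    power: float
    mean_set_size: float | None


def roc_auc(q: np.ndarray, truth: np.ndarray) -> float:
    """Mann-Whitney AUC of q against binary truth (ties averaged)."""
    truth = np.asarray(truth)
    if truth.sum() == 0 or truth.sum() == len(truth):
        raise ValueError("truth needs at least one positive and one negative")
    return float(roc_auc_score(truth, np.asarray(q, dtype=float)))


def pr_auc(q: np.ndarray, truth: np.ndarray) -> float:
    """Step-interpolated area under the precision-recall curve."""
    truth = np.asarray(truth)
    if truth.sum() == 0:
        raise ValueError("truth needs at least one positive")
    return float(average_precision_score(truth, np.asarray(q, dtype=float)))


def cs_metrics(
    sets: list[CredibleSet], truth: np.ndarray
) -> tuple[float | None, float, float | None]:
    """(coverage, power, mean set size) for one locus.

    With zero reported sets coverage and mean size are undefined (None) and
    power is 0.
    """
    truth = np.asarray(truth)
    causal = set(np.flatnonzero(truth).tolist())
    if not causal:
        raise ValueError("truth has no causal SNPs")
    if not sets:
        return None, 0.0, None
    hits = sum(1 for cs in sets if causal.intersection(cs.members))
    captured = causal.intersection(i for cs in sets for i in cs.members)
    coverage = hits / len(sets)
    power = len(captured) / len(causal)
    mean_size = float(np.mean([len(cs.members) for cs in sets]))
    return coverage, power, mean_size


def residualize_covariates(y: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Residual phenotype y - C (C^+ y) via least squares (no explicit inverse).

    Rank-deficient C is handled by the minimum-norm solution with a warning.
    """
    y = np.asarray(y, dtype=float)
    c = np.asarray(c, dtype=float)
    if c.shape[0] != y.shape[0]:
        raise ValueError("C and y disagree in length")
    if c.shape[0] <= c.shape[1]:
        raise ValueError("need more observations than covariates")
    bhat, _, rank, _ = np.linalg.lstsq(c, y, rcond=None)
    if rank < c.shape[1]:
        warnings.warn(
            f"covariate matrix rank {rank} < {c.shape[1]}; using minimum-norm solution",
            stacklevel=2,
        )
    return y - c @ bhat


def top_snp_r2(
    q: np.ndarray,
    g_train: np.ndarray,
    y_train: np.ndarray,
    g_test: np.ndarray,
    y_test: np.ndarray,
) -> float:
    """Out-of-sample R^2 of the single top-posterior SNP.

    Picks argmax q (ties -> lowest index), estimates its effect on the
    training data through the pseudoinverse of that single column, and
    returns corr(y_test, w * g_test_column)^2.
    """
    q = np.asarray(q, dtype=float)
    top = int(np.argmax(q))  # argmax returns the lowest index on ties
    col_tr = np.asarray(g_train[:, top], dtype=float)
    col_te = np.asarray(g_test[:, top], dtype=float)
    w = float(
        (np.linalg.pinv(col_tr[:, None]) @ np.asarray(y_train, dtype=float))[0]
    )
    pred = w * col_te
    if np.std(pred) == 0 or np.std(y_test) == 0:
        warnings.warn("zero-variance prediction or phenotype; R^2 = 0", stacklevel=2)
        return 0.0
    return float(np.corrcoef(y_test, pred)[0, 1] ** 2)


def build_sld(sim, backend: str = "auto", p_c: int | None = None):
    """Scaled-LD precomputation for one locus (everything except A1 = Az).

    The result depends only on the genotypes (through sample LD,
    heterozygosity and N), so the benchmark harness shares it across
    scenarios that reuse a genotype matrix.
    """
    from .ldmatrix import ScaledLD
    from .lowrank import factorize_hollow

    a = build_A(sim.ld, sim.het, sim.n)
    m = a.shape[0]
    if p_c is None:
        p_c = max(100, m // 20)
    if backend == "auto":
        backend = "pca" if m > 4 * p_c else "dense"
    col_sq = np.einsum("ij,ij->i", a, a)
    if backend == "pca":
        return ScaledLD(a=a, a1=None, col_sq=col_sq, a2=None,
                        lowrank=factorize_hollow(a, min(p_c, m)))
    if backend == "dense":
        return ScaledLD(a=a, a1=None, col_sq=col_sq, a2=-(a @ a.T))
    raise ValueError(f"unknown backend {backend!r}")


def finemap_locus(
    sim,
    backend: str = "auto",
    p_c: int | None = None,
    hyper0: Hyperparams | None = None,
    fit_cfg: FitConfig | None = None,
    eta: float = 0.5,
    q_thr: float = 0.95,
    sld=None,
):
    """Fit one simulated locus and build its credible sets.

    ``backend="auto"`` uses the low-rank path when M is large enough for
    the truncation to pay off (M > 4 p_c), the dense path otherwise.
    ``p_c=None`` resolves to max(100, M/20): the truncation must track the
    width of the LD spectrum, which grows with the number of LD blocks in
    the locus.  ``hyper0=None`` starts from a generic prior (pi1 = 0.01,
    locus h2 = 0.01) and lets hyperparameter optimization adapt; the truth
    is never consulted.
    """
    import dataclasses

    if sld is None:
        sld = build_sld(sim, backend=backend, p_c=p_c)
    sld = dataclasses.replace(sld, a1=sld.a @ np.asarray(sim.z, dtype=float))
    if hyper0 is None:
        hyper0 = hyper_from_h2(h2=0.01, pi1=0.01, het=sim.het, n=sim.n)
    res = fit(sim.z, sld, hyper0, fit_cfg or FitConfig())
    sets = build_credible_sets(res.state.q, sim.ld, eta=eta, q_thr=q_thr, pi1=res.hyper.pi1)
    return res, sets


def run_grid(
    grid: list[SimConfig],
    reps: int = 10,
    backend: str = "auto",
    p_c: int | None = None,
    eta: float = 0.5,
    q_thr: float = 0.95,
    fit_cfg: FitConfig | None = None,
) -> pd.DataFrame:
    """Run a benchmark grid; one tidy row per configuration.

    Per configuration, replicate r uses seed ``cfg.seed + r``.  AUC/AUPRC
    are averaged across replicates (with standard errors); coverage and
    power pool credible sets and causals across replicates.  Replicates
    whose fit fails numerically are excluded from AUC/coverage and counted
    as zero power, with a log record.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    acc = [
        dict(aucs=[], auprcs=[], pooled_sets=0, pooled_hits=0, captured=0,
             total_causal=0, sizes=[], failed=0)
        for _ in grid
    ]
    # replicate-major iteration so scenarios differing only in k, h2 or the
    # effect mode reuse one genotype matrix and sample-LD computation per
    # (locus-model, seed); the genotype and phenotype random streams are
    # independent, so results are identical to simulating per scenario
    for rep in range(reps):
        geno_cache: dict[tuple, tuple] = {}
        sld_cache: dict[tuple, object] = {}
        for cfg, a in zip(grid, acc):
            rcfg = SimConfig(**{**cfg.__dict__, "seed": cfg.seed + rep})
            key = (rcfg.n, rcfg.m, rcfg.ld_block_size, rcfg.ld_rho, rcfg.maf_range, rcfg.seed)
            if key not in geno_cache:
                from .ldmatrix import a_from_genotypes
                from .simulate import genotype_streams, simulate_genotypes

                rng_g, _ = genotype_streams(rcfg.seed)
                g = simulate_genotypes(rcfg, rng_g)
                ld, het, _ = a_from_genotypes(g)
                geno_cache[key] = (g, ld, het)
            sim = simulate_locus(rcfg, keep_genotypes=False, genotypes=geno_cache[key])
            if key not in sld_cache:
                # the scaled-LD precomputation (including the one-off
                # eigendecomposition of the pca backend) is z-independent
                sld_cache[key] = build_sld(sim, backend=backend, p_c=p_c)
            a["total_causal"] += rcfg.k
            try:
                res, sets = finemap_locus(
                    sim, eta=eta, q_thr=q_thr, fit_cfg=fit_cfg, sld=sld_cache[key]
                )
            except NumericalDomainError as exc:
                a["failed"] += 1
                logger.warning("fit failed for %s rep %d: %s", cfg, rep, exc)
                continue
            truth = sim.truth
            a["aucs"].append(roc_auc(res.state.q, truth))
            a["auprcs"].append(pr_auc(res.state.q, truth))
            causal = set(sim.causal_idx.tolist())
            a["pooled_sets"] += len(sets)
            a["pooled_hits"] += sum(1 for cs in sets if causal.intersection(cs.members))
            a["captured"] += len(causal.intersection(i for cs in sets for i in cs.members))
            a["sizes"].extend(len(cs.members) for cs in sets)

    rows = []
    for cfg, a in zip(grid, acc):
        aucs, auprcs = a["aucs"], a["auprcs"]
        pooled_sets, pooled_hits = a["pooled_sets"], a["pooled_hits"]
        captured, total_causal = a["captured"], a["total_causal"]
        sizes, failed = a["sizes"], a["failed"]
        rows.append(
            {
                "m": cfg.m,
                "k": cfg.k,
                "h2": cfg.h2,
                "effect_mode": cfg.effect_mode,
                "reps": reps,
                "failed": failed,
                "auc_mean": float(np.mean(aucs)) if aucs else math.nan,
                "auc_se": float(np.std(aucs, ddof=1) / np.sqrt(len(aucs))) if len(aucs) > 1 else math.nan,
                "auprc_mean": float(np.mean(auprcs)) if auprcs else math.nan,
                "auprc_se": float(np.std(auprcs, ddof=1) / np.sqrt(len(auprcs))) if len(auprcs) > 1 else math.nan,
                "coverage": pooled_hits / pooled_sets if pooled_sets else math.nan,
                "power": captured / total_causal if total_causal else math.nan,
                "n_sets": pooled_sets,
                "mean_set_size": float(np.mean(sizes)) if sizes else math.nan,
            }
        )
    return pd.DataFrame(rows)


def grid_preset(name: str, seed: int = 0, m_max: int | None = None) -> list[SimConfig]:
    """Named benchmark grids.

    - ``auc-beta-const`` / ``auc-beta-normal``: M in {200, 1000, 2000,
      4000, 8000} x k in {1, 5, 10} x h2 in {0.001, 0.005, 0.01} with
      constant or Gaussian causal effects (optionally truncated at
      ``m_max``).
    - ``credset-grid``: M = 4000, k in {1, 5, 10} x h2 in
      {0.005, 0.01, 0.02, 0.04}, Gaussian effects.
    """
    if name in ("auc-beta-const", "auc-beta-normal"):
        mode = "constant" if name.endswith("const") else "normal"
        ms = [m for m in (200, 1000, 2000, 4000, 8000) if m_max is None or m <= m_max]
        return [
            SimConfig(m=m, k=k, h2=h2, effect_mode=mode, seed=seed)
            for m in ms
            for k in (1, 5, 10)
            for h2 in (0.001, 0.005, 0.01)
        ]
    if name == "credset-grid":
        return [
            SimConfig(m=4000, k=k, h2=h2, effect_mode="normal", seed=seed)
            for k in (1, 5, 10)
            for h2 in (0.005, 0.01, 0.02, 0.04)
        ]
    raise ValueError(f"unknown grid preset {name!r}")
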