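"""Self-contained locus simulator: LD-structured genotypes, phenotypes at a
target locus heritability, and marginal-regression GWAS z-scores.

Genotypes follow a latent-Gaussian threshold model: per individual, two
independent latent vectors with block-AR(1) correlation (within a block of
``ld_block_size`` SNPs the latent correlation at lag d is ``ld_rho**d``;
blocks are independent) are thresholded at the allele-frequency quantile
and summed, giving allele counts in {0, 1, 2} with the desired expected
frequency and a realistic within-block LD decay.  Phenotypes follow the
additive model y = c1 G beta + c2 eps with c1 = sqrt(h2 / var(G beta)) and
c2 = sqrt(1 - h2), so Var(y) ~= 1 and Var(c1 G beta) = h2.  z-scores come
from per-SNP simple linear regression of y on each genotype column.

All randomness derives from ``SimConfig.seed`` through two independent
child streams (genotypes; phenotype and causal assignment), with no
hidden global state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .io import LDMatrix
from .ldmatrix import a_from_genotypes


@dataclass
class SimConfig:
    """Simulation scenario.

    Defaults mirror a typical single-locus benchmark: N = 10 000
    individuals, Gaussian causal effects, AR(1) LD blocks of 50 SNPs with
    within-block decay 0.9 per SNP, allele frequencies uniform on
    [0.05, 0.5].
    """

    n: int = 10_000
    m: int = 1000
    k: int = 5
    h2: float = 0.01
    effect_mode: str = "normal"  # "constant" (beta_i = 1) or "normal" (beta_i ~ N(0,1))
    ld_block_size: int = 50
    ld_rho: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.k <= self.m:
            raise ValueError(f"k={self.k} must lie in [1, m={self.m}]")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError(f"h2={self.h2} must lie in (0, 1)")
        if self.effect_mode not in ("constant", "normal"):
            raise ValueError(f"unknown effect_mode {self.effect_mode!r}")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError(f"ld_rho={self.ld_rho} must lie in [0, 1)")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError(f"maf_range={self.maf_range} must satisfy 0 < lo <= hi <= 0.5")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")


@dataclass
class SimResult:
    """One simulated locus: genotypes, truth, phenotype, GWAS output and
    the sample LD inputs the fitter consumes."""

    g: np.ndarray | None  # (N, M) allele counts, or None when dropped
    beta: np.ndarray  # (M,) true effects (0 off the causal set)
    causal_idx: np.ndarray  # (k,) causal indices
    y: np.ndarray  # (N,) phenotype
    z: np.ndarray  # (M,) GWAS z-scores
    ld: LDMatrix  # sample LD
    het: np.ndarray  # (M,) sample heterozygosity
    n: int
    c1: float
    c2: float

    @property
    def truth(self) -> np.ndarray:
        """Binary causal-status vector."""
        t = np.zeros(self.beta.shape[0], dtype=int)
        t[self.causal_idx] = 1
        return t


def _latent_block_ar1(rng: np.random.Generator, n: int, m: int, rho: float, block: int) -> np.ndarray:
    """(n, m) float32 latent Gaussians, block-AR(1) across columns."""
    x = rng.standard_normal((n, m), dtype=np.float32)
    if rho > 0:
        innov = np.float32(np.sqrt(1.0 - rho * rho))
        r32 = np.float32(rho)
        for j in range(1, m):
            if j % block:  # j starts a new block when j % block == 0
                x[:, j] = r32 * x[:, j - 1] + innov * x[:, j]
    return x


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw an (N, M) allele-count matrix with block-AR(1) latent LD."""
    rng = rng or np.random.default_rng(cfg.seed)
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.m)
    thr = norm.ppf(maf).astype(np.float32)
    g = np.zeros((cfg.n, cfg.m), dtype=np.uint8)
    for _ in range(2):  # two haplotype draws per individual
        x = _latent_block_ar1(rng, cfg.n, cfg.m, cfg.ld_rho, cfg.ld_block_size)
        g += (x < thr[None, :]).astype(np.uint8)
    return g


def simulate_phenotype(
    g: np.ndarray, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    """Additive phenotype with exact in-sample genetic variance h2.

    Returns (y, beta, causal_idx, c1, c2).  If every sampled causal SNP is
    monomorphic (var(G beta) = 0) the causal set is resampled with a
    warning.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n, m = g.shape
    gf = g.astype(np.float64)
    for attempt in range(100):
        causal_idx = np.sort(rng.choice(m, size=cfg.k, replace=False))
        if cfg.effect_mode == "constant":
            effects = np.ones(cfg.k)
        else:
            effects = rng.standard_normal(cfg.k)
        gb = gf[:, causal_idx] @ effects
        var_gb = float(np.var(gb))
        if var_gb > 0:
            break
        warnings.warn("var(G beta) = 0; resampling causal set", stacklevel=2)
    else:
        raise RuntimeError("could not sample a causal set with nonzero genetic variance")
    beta = np.zeros(m)
    beta[causal_idx] = effects
    c1 = float(np.sqrt(cfg.h2 / var_gb))
    c2 = float(np.sqrt(1.0 - cfg.h2))
    eps = rng.standard_normal(n)
    y = c1 * (gb - gb.mean()) + c2 * eps
    return y, beta, causal_idx, c1, c2


def gwas_zscores(g: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-SNP simple-regression z-scores, z_j = betahat_j / se(betahat_j).

    Zero-variance columns get z = 0 with a warning.
    """
    n, m = g.shape
    if n < 3:
        raise ValueError("need at least 3 individuals for marginal regression")
    y = np.asarray(y, dtype=np.float64)
    yc = y - y.mean()
    syy = float(yc @ yc)
    gmean = g.mean(axis=0, dtype=np.float64)
    gy = (g.astype(np.float32).T @ yc.astype(np.float32)).astype(np.float64)
    gsq = np.einsum(
        "ij,ij->j", g.astype(np.float32), g.astype(np.float32), dtype=np.float64
    )
    sxx = gsq - n * gmean * gmean
    zero_var = sxx <= 0
    if np.any(zero_var):
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance genotype columns get z = 0",
            stacklevel=2,
        )
    sxx_safe = np.where(zero_var, 1.0, sxx)
    bhat = gy / sxx_safe
    rss = np.maximum(syy - bhat * gy, 0.0)
    se2 = rss / (n - 2) / sxx_safe
    with np.errstate(divide="ignore", invalid="ignore"):
        z = bhat / np.sqrt(se2)
    z[zero_var] = 0.0
    z[~np.isfinite(z)] = 0.0
    return z


def genotype_streams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    """Independent genotype and phenotype generators derived from one seed.

    Splitting the streams means the genotype matrix (and its sample LD,
    which depends only on n, m, the LD model and the seed) can be shared
    across scenarios that vary only k, h2 or the effect mode, without
    changing any result.
    """
    s_geno, s_pheno = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(s_geno), np.random.default_rng(s_pheno)


def simulate_locus(
    cfg: SimConfig,
    keep_genotypes: bool = True,
    genotypes: tuple[np.ndarray, "LDMatrix", np.ndarray] | None = None,
) -> SimResult:
    """Full pipeline: genotypes -> phenotype -> z-scores -> sample LD inputs.

    ``genotypes`` may supply a precomputed (g, ld, het) triple for this
    cfg's (n, m, LD model, seed) — the result is identical to computing it
    here because the genotype and phenotype random streams are independent.
    """
    rng_g, rng_p = genotype_streams(cfg.seed)
    if genotypes is None:
        g = simulate_genotypes(cfg, rng_g)
        ld, het, n = a_from_genotypes(g)
    else:
        g, ld, het = genotypes
        n = g.shape[0]
    y, beta, causal_idx, c1, c2 = simulate_phenotype(g, cfg, rng_p)
    z = gwas_zscores(g, y)
    return SimResult(
        g=g if keep_genotypes else None,
        beta=beta,
        causal_idx=causal_idx,
        y=y,
        z=z,
        ld=ld,
        het=het,
        n=n,
        c1=c1,
        c2=c2,
    )
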