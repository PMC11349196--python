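"""Readers and writers for on-disk locus artifacts.

Summary statistics are delimited text with a header; LD matrices are square
whitespace-delimited text (the PLINK ``--r square`` dialect, optionally
gzipped).  Posterior and credible-set reports are TSV.  Internally all
indexing is 0-based; reports carry 1-based ranks keyed by SNP id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """A file did not parse or validate; the message names the offender."""


DEFAULT_COLUMNS = {"snp": "SNP", "z": "Z", "maf": "MAF", "het": "HET", "n": "N"}


@dataclass
class SummaryStats:
    """Per-SNP GWAS z-scores with heterozygosities and sample size.

    Attributes
    ----------
    snp_ids : list of str
        Unique SNP identifiers.
    z : ndarray, shape (M,)
        GWAS z-scores.
    het : ndarray, shape (M,)
        Heterozygosity H_i = 2 f_i (1 - f_i) with f_i the minor allele
        frequency; each value lies in [0, 0.5].
    n : int
        GWAS sample size.
    """

    snp_ids: list[str]
    z: np.ndarray
    het: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.het = np.asarray(self.het, dtype=float)
        m = len(self.snp_ids)
        if m < 1:
            raise ParseError("summary statistics are empty")
        if self.z.shape != (m,) or self.het.shape != (m,):
            raise ParseError(
                f"length mismatch: {m} ids, {self.z.shape[0]} z, {self.het.shape[0]} het"
            )
        if len(set(self.snp_ids)) != m:
            seen: set[str] = set()
            dup = next(s for s in self.snp_ids if s in seen or seen.add(s))
            raise ParseError(f"duplicate SNP id {dup!r}")
        if not np.all(np.isfinite(self.z)):
            bad = int(np.flatnonzero(~np.isfinite(self.z))[0])
            raise ParseError(f"non-finite z-score for SNP {self.snp_ids[bad]!r}")
        if np.any(self.het < 0) or np.any(self.het > 0.5 + 1e-12):
            bad = int(np.flatnonzero((self.het < 0) | (self.het > 0.5 + 1e-12))[0])
            raise ParseError(
                f"heterozygosity {self.het[bad]} outside [0, 0.5] for SNP {self.snp_ids[bad]!r}"
            )
        if int(self.n) < 1:
            raise ParseError(f"sample size N={self.n} must be a positive integer")
        self.n = int(self.n)

    @property
    def m(self) -> int:
        return len(self.snp_ids)


@dataclass
class LDMatrix:
    """SNP-SNP Pearson correlation matrix; symmetric with unit diagonal."""

    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise ParseError(f"LD matrix must be square, got shape {self.r.shape}")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ParseError("LD matrix is not symmetric within 1e-8")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ParseError("LD matrix diagonal must be 1")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            i, j = np.unravel_index(int(np.argmax(np.abs(self.r))), self.r.shape)
            raise ParseError(f"|r[{i},{j}]| = {abs(self.r[i, j]):.6g} exceeds 1")

    @property
    def m(self) -> int:
        return self.r.shape[0]


def _maf_to_het(maf: np.ndarray, ids: list[str]) -> np.ndarray:
    maf = np.asarray(maf, dtype=float)
    if np.any(maf < 0) or np.any(maf > 1):
        bad = int(np.flatnonzero((maf < 0) | (maf > 1))[0])
        raise ParseError(f"MAF {maf[bad]} outside [0, 1] for SNP {ids[bad]!r}")
    folded = maf > 0.5
    if np.any(folded):
        warnings.warn(
            f"{int(folded.sum())} allele frequencies > 0.5 folded to the minor allele",
            stacklevel=2,
        )
        maf = np.where(folded, 1.0 - maf, maf)
    return 2.0 * maf * (1.0 - maf)


def read_sumstats(
    path,
    columns: dict[str, str] | None = None,
    n: int | None = None,
    sep: str | None = None,
) -> SummaryStats:
    """Read summary statistics from delimited text with a header.

    Parameters
    ----------
    path : str or Path
        File with columns for SNP id, z-score, and MAF or heterozygosity.
    columns : dict, optional
        Overrides for column names; keys among
        ``{"snp", "z", "maf", "het", "n"}``.
    n : int, optional
        GWAS sample size; required when no N column is present.
    sep : str, optional
        Field separator (default: any whitespace).
    """
    cols = dict(DEFAULT_COLUMNS)
    cols.update(columns or {})
    try:
        df = pd.read_csv(path, sep=sep or r"\s+", engine="python")
    except (OSError, pd.errors.ParserError) as exc:
        raise ParseError(f"cannot read summary statistics from {path}: {exc}") from exc
    for key in ("snp", "z"):
        if cols[key] not in df.columns:
            raise ParseError(f"missing required column {cols[key]!r} in {path}")
    ids = [str(s) for s in df[cols["snp"]]]
    z = pd.to_numeric(df[cols["z"]], errors="coerce").to_numpy()
    if np.any(~np.isfinite(z)):
        line = int(np.flatnonzero(~np.isfinite(z))[0])
        raise ParseError(f"non-numeric z at line {line + 2} (SNP {ids[line]!r}) in {path}")
    if cols["het"] in df.columns:
        het = pd.to_numeric(df[cols["het"]], errors="coerce").to_numpy()
    elif cols["maf"] in df.columns:
        het = _maf_to_het(pd.to_numeric(df[cols["maf"]], errors="coerce").to_numpy(), ids)
    else:
        raise ParseError(f"need a {cols['maf']!r} or {cols['het']!r} column in {path}")
    if cols["n"] in df.columns:
        n_file = df[cols["n"]].to_numpy()
        n = int(round(float(np.median(n_file))))
    elif n is None:
        raise ParseError(f"sample size N not in {path} and not supplied")
    try:
        return SummaryStats(snp_ids=ids, z=z, het=het, n=int(n))
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_sumstats(stats: SummaryStats, path) -> None:
    """Write summary statistics as TSV (SNP, Z, HET, N); round-trips exactly
    to the printed precision (17 significant digits)."""
    df = pd.DataFrame(
        {"SNP": stats.snp_ids, "Z": stats.z, "HET": stats.het, "N": stats.n}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_ld(path) -> LDMatrix:
    """Read a square whitespace-delimited LD matrix.

    The stored matrix is symmetrized as (R + R^T)/2 with the diagonal forced
    to 1, so the result always satisfies the LDMatrix invariants when the
    input asymmetry is within parsing tolerance.
    """
    try:
        raw = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError as exc:
        raise ParseError(f"ragged or non-numeric LD matrix in {path}: {exc}") from exc
    except OSError as exc:
        raise ParseError(f"cannot read LD matrix from {path}: {exc}") from exc
    if raw.shape[0] != raw.shape[1]:
        raise ParseError(f"LD matrix in {path} is {raw.shape[0]}x{raw.shape[1]}, not square")
    if np.any(np.abs(raw) > 1 + 1e-6):
        i, j = np.unravel_index(int(np.argmax(np.abs(raw))), raw.shape)
        raise ParseError(f"|r[{i},{j}]| = {abs(raw[i, j]):.6g} exceeds 1 in {path}")
    r = 0.5 * (raw + raw.T)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return LDMatrix(r=r)


def check_paired(stats: SummaryStats, ld: LDMatrix) -> None:
    """Raise if a summary-statistics/LD pair disagrees in dimension."""
    if stats.m != ld.m:
        raise ParseError(
            f"dimension mismatch: {stats.m} SNPs in summary statistics, "
            f"{ld.m} in LD matrix"
        )


def posterior_ranks(q: np.ndarray) -> np.ndarray:
    """1-based ranks by descending q; ties keep input order."""
    order = np.argsort(-np.asarray(q, dtype=float), kind="stable")
    ranks = np.empty(len(order), dtype=int)
    ranks[order] = np.arange(1, len(order) + 1)
    return ranks


def write_posteriors(snp_ids: list[str], state, path) -> None:
    """Write the fitted variational posterior as TSV.

    Columns: snp_id, q (posterior causal probability), mu (posterior effect
    mean), sigma2 (posterior effect variance), rank (1-based by descending q).
    """
    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "q": state.q,
            "mu": state.mu,
            "sigma2": state.sigma2,
            "rank": posterior_ranks(state.q),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_posteriors(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("snp_id", "q", "mu", "sigma2", "rank"):
        if col not in df.columns:
            raise ParseError(f"missing column {col!r} in posterior table {path}")
    return df


def write_credible_sets(sets, snp_ids: list[str], path) -> None:
    """Write credible sets as TSV, one row per set in index order.

    Columns: set (1-based index), n_snps, snp_ids (comma-joined), pk
    (cumulative posterior probability), purity (min pairwise absolute LD).
    """
    rows = [
        {
            "set": k + 1,
            "n_snps": len(cs.members),
            "snp_ids": ",".join(snp_ids[i] for i in cs.members),
            "pk": cs.pk,
            "purity": cs.purity,
        }
        for k, cs in enumerate(sets)
    ]
    df = pd.DataFrame(rows, columns=["set", "n_snps", "snp_ids", "pk", "purity"])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
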