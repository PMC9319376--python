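"""Instrument selection and strength diagnostics.

Candidate instruments are SNPs passing a p-value threshold (genome-wide
5e-8 for the metabolic traits; the relaxed 1e-5 for metabolites, whose GWAS
is far smaller).  Candidates are pruned by greedy LD clumping (r² < 0.001
within a 10,000 kb window by default), filtered for directionality with the
Steiger test, and summarized by the variance explained

    R² ≈ Σ_i β_i² / (β_i² + N·se(β_i)²)

and the instrument-strength F-statistic F = (N−K−1)·R² / (K·(1−R²)),
compared with the empirical threshold of 10.
"""

from __future__ import annotations

import abc
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .gwas_io import HarmonizedSet, SummaryStats

log = logging.getLogger(__name__)

F_WEAK_THRESHOLD = 10.0
ABERRANT_R2 = 0.9  # aggregate R² at/above this flags an implausible fit


# ---------------------------------------------------------------------------
# LD providers
# ---------------------------------------------------------------------------

class LDProvider(abc.ABC):
    """Pairwise LD (r²) lookup.  Returns a value in [0, 1] or None when the
    pair is not covered.  Must be symmetric with r²(a, a) = 1."""

    @abc.abstractmethod
    def r2(self, a: str, b: str) -> float | None:
        ...


class MatrixLDProvider(LDProvider):
    """Dense pairwise r² from an explicit table (TSV: id_a, id_b, r2)."""

    def __init__(self, pairs: pd.DataFrame | dict):
        if isinstance(pairs, dict):
            self._r2 = dict(pairs)
        else:
            self._r2 = {
                (str(r.id_a), str(r.id_b)): float(r.r2)
                for r in pairs.itertuples()
            }

    @classmethod
    def from_tsv(cls, path) -> "MatrixLDProvider":
        return cls(pd.read_csv(path, sep="\t"))

    def r2(self, a: str, b: str) -> float | None:
        if a == b:
            return 1.0
        v = self._r2.get((a, b))
        if v is None:
            v = self._r2.get((b, a))
        return v

    def to_tsv(self, path) -> None:
        rows = [{"id_a": a, "id_b": b, "r2": v} for (a, b), v in self._r2.items()]
        pd.DataFrame(rows, columns=["id_a", "id_b", "r2"]).to_csv(
            path, sep="\t", index=False
        )


class BlockLDProvider(LDProvider):
    """Block-diagonal LD: a fixed r² inside each block, 0 across blocks."""

    def __init__(self, block_of: dict[str, int], within_r2: float):
        self.block_of = dict(block_of)
        self.within_r2 = float(within_r2)

    def r2(self, a: str, b: str) -> float | None:
        if a == b:
            return 1.0
        ba, bb = self.block_of.get(a), self.block_of.get(b)
        if ba is None or bb is None:
            return None
        return self.within_r2 if ba == bb else 0.0

    def to_frame(self) -> pd.DataFrame:
        snps = sorted(self.block_of)
        rows = []
        for i, a in enumerate(snps):
            for b in snps[i + 1:]:
                if self.block_of[a] == self.block_of[b]:
                    rows.append({"id_a": a, "id_b": b, "r2": self.within_r2})
        return pd.DataFrame(rows, columns=["id_a", "id_b", "r2"])


# ---------------------------------------------------------------------------
# Selection and clumping
# ---------------------------------------------------------------------------

def select_candidates(ss: SummaryStats, p_threshold: float) -> pd.DataFrame:
    """Records with p < ``p_threshold``, sorted ascending by p-value."""
    df = ss.records
    out = df[df["pval"] < p_threshold].sort_values(
        ["pval", "chrom", "pos", "snp"], kind="mergesort"
    )
    return out.reset_index(drop=True)


def clump(
    candidates: pd.DataFrame,
    ld: LDProvider,
    r2_max: float = 0.001,
    window_kb: float = 10_000.0,
    unknown_policy: str = "independent",
) -> pd.DataFrame:
    """Greedy LD clumping.

    Repeatedly takes the lowest-p remaining SNP as the index variant and
    removes remaining SNPs on the same chromosome within ``window_kb`` of it
    with r² >= ``r2_max``.  Ties on p are broken by (chrom, pos, variant id)
    so the output does not depend on input order.  A pair with unknown LD is
    treated per ``unknown_policy``: ``independent`` (default, warn) keeps
    the SNP, ``dependent`` removes it.
    """
    if unknown_policy not in ("independent", "dependent"):
        raise ValidationError(f"unknown_policy {unknown_policy!r}")
    df = candidates.sort_values(
        ["pval", "chrom", "pos", "snp"], kind="mergesort"
    ).reset_index(drop=True)
    window = window_kb * 1000.0
    alive = np.ones(len(df), dtype=bool)
    kept_rows = []
    warned = False
    snp = df["snp"].to_numpy()
    chrom = df["chrom"].astype(str).to_numpy()
    pos = pd.to_numeric(df["pos"], errors="coerce").to_numpy(float)
    for i in range(len(df)):
        if not alive[i]:
            continue
        kept_rows.append(i)
        alive[i] = False
        for j in np.flatnonzero(alive):
            if chrom[j] != chrom[i]:
                continue
            if np.isfinite(pos[i]) and np.isfinite(pos[j]) and abs(pos[j] - pos[i]) > window:
                continue
            r2 = ld.r2(str(snp[i]), str(snp[j]))
            if r2 is None:
                if not warned:
                    log.warning(
                        "LD unknown for pair (%s, %s); treating as %s",
                        snp[i], snp[j], unknown_policy,
                    )
                    warned = True
                if unknown_policy == "dependent":
                    alive[j] = False
                continue
            if r2 >= r2_max:
                alive[j] = False
    return df.iloc[kept_rows].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Variance explained / F
# ---------------------------------------------------------------------------

def snp_r2(beta, se, n):
    """Per-SNP variance in the trait explained by the variant:
    β² / (β² + N·se²).  Vectorized over array inputs."""
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    n = np.asarray(n, float)
    if np.any(n <= 1):
        raise ValidationError("sample size must exceed 1 for snp_r2")
    if np.any(se <= 0):
        raise ValidationError("standard errors must be positive")
    b2 = beta ** 2
    return b2 / (b2 + n * se ** 2)


def f_statistic(r2_total: float, n: float, k: int) -> float:
    """Instrument-strength F = (N−K−1)·R² / (K·(1−R²))."""
    if not (0.0 <= r2_total < 1.0):
        raise ValidationError(
            f"aberrant R² = {r2_total:.4g}: must lie in [0, 1)"
        )
    if k < 1:
        raise ValidationError("k must be >= 1")
    if n <= k + 1:
        raise ValidationError(f"n={n} too small for k={k} instruments")
    return (n - k - 1) * r2_total / (k * (1.0 - r2_total))


def is_weak(f: float, threshold: float = F_WEAK_THRESHOLD) -> bool:
    return f <= threshold


@dataclass
class InstrumentSet:
    """Final instruments for one trait with strength diagnostics."""

    trait_id: str
    snps: pd.DataFrame  # snp, beta, se, pval (exposure scale)
    r2_total: float
    f_statistic: float

    @property
    def k(self) -> int:
        return len(self.snps)

    @property
    def weak(self) -> bool:
        return is_weak(self.f_statistic)

    @property
    def aberrant(self) -> bool:
        return self.r2_total >= ABERRANT_R2


def instrument_strength(
    trait_id: str, clumped: pd.DataFrame, n: float | None = None
) -> InstrumentSet:
    """Aggregate R² (sum of per-SNP contributions) and F over a clumped set."""
    if len(clumped) == 0:
        raise ValidationError(f"{trait_id}: no instruments")
    ns = clumped["n"].to_numpy(float) if n is None else np.full(len(clumped), n)
    r2 = float(np.sum(snp_r2(clumped["beta"], clumped["se"], ns)))
    k = len(clumped)
    n_eff = float(np.nanmean(ns))
    if r2 >= 1.0:
        raise ValidationError(
            f"{trait_id}: aberrant aggregate R² = {r2:.3g} (>= 1)"
        )
    return InstrumentSet(
        trait_id=trait_id,
        snps=clumped[["snp", "beta", "se", "pval"]].copy(),
        r2_total=r2,
        f_statistic=f_statistic(r2, n_eff, k),
    )


# ---------------------------------------------------------------------------
# Steiger directionality filter
# ---------------------------------------------------------------------------

def steiger_filter(
    h: HarmonizedSet, alpha: float = 0.05
) -> HarmonizedSet:
    """Drop instruments whose outcome association is significantly stronger
    than their exposure association (reverse-causation guard).

    Per SNP the variance explained in exposure and outcome is converted to a
    correlation magnitude r = √r² and compared with a two-sample Fisher-z
    test, SE = √(1/(N_exp−3) + 1/(N_out−3)).  A SNP is removed when
    r²_out > r²_exp and the one-sided p < ``alpha``; drops are recorded with
    reason ``steiger``.  Binary outcomes use the effective sample size.

    Multi-exposure sets use each SNP's strongest exposure association.
    """
    if np.any(~np.isfinite(h.nx)):
        raise ValidationError("per-exposure sample sizes required for Steiger")
    if not np.isfinite(h.n_outcome):
        raise ValidationError("outcome sample size required for Steiger")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign 0/0 at beta == 0
        r2x_all = np.column_stack([
            snp_r2(h.bx[:, l], h.sex[:, l], h.nx[:, l])
            for l in range(h.n_exposures)
        ])
    best = np.argmax(r2x_all, axis=1)
    rows = np.arange(h.n_snps)
    r2x = r2x_all[rows, best]
    nx = h.nx[rows, best]
    r2y = snp_r2(h.by, h.sey, np.full(h.n_snps, h.n_outcome))
    rx = np.sqrt(np.clip(r2x, 0.0, 1.0 - 1e-12))
    ry = np.sqrt(np.clip(r2y, 0.0, 1.0 - 1e-12))
    se_z = np.sqrt(1.0 / (nx - 3.0) + 1.0 / (h.n_outcome - 3.0))
    z = (np.arctanh(ry) - np.arctanh(rx)) / se_z
    p_one = stats.norm.sf(z)  # small when outcome association dominates
    drop = (r2y > r2x) & (p_one < alpha)
    return h.subset(~drop, "steiger")
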