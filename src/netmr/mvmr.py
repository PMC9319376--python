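"""Multivariable MR: direct effects of several exposures on one outcome.

The multivariable IVW extension regresses outcome effects on the matrix of
exposure effects (no intercept) with weights 1/sey², giving each exposure's
effect conditional on the others.  Instrument strength for exposure j given
the rest is summarized by a conditional F-statistic: the weighted residual
sum of squares after regressing exposure j's SNP effects on the other
exposures', divided by (k − L + 1).

Cross-trait sampling covariance between exposure estimates is taken as zero
(the intended use is exposures estimated in distinct cohorts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearityError, InsufficientInstrumentsError
from .gwas_io import HarmonizedSet, SummaryStats, harmonize
from .instruments import LDProvider, clump, select_candidates, steiger_filter
from .uvmr import Z95

_RCOND = 1e-10


@dataclass
class MVMRResult:
    exposures: list[str]
    betas: np.ndarray
    ses: np.ndarray
    pvals: np.ndarray
    conditional_f: np.ndarray
    n_snps: int
    cochran_q: float
    q_df: int
    q_p: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "exposure": self.exposures,
            "beta": self.betas,
            "se": self.ses,
            "ci_low": self.betas - Z95 * self.ses,
            "ci_high": self.betas + Z95 * self.ses,
            "pval": self.pvals,
            "conditional_f": self.conditional_f,
            "n_snps": self.n_snps,
        })

    def effect(self, exposure: str) -> dict:
        i = self.exposures.index(exposure)
        return {
            "beta": float(self.betas[i]), "se": float(self.ses[i]),
            "pval": float(self.pvals[i]),
            "conditional_f": float(self.conditional_f[i]),
        }


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(x, tol=_RCOND * np.abs(x).max()) < x.shape[1]:
        # name the culprits: column pairs with |correlation| ~ 1
        offenders = []
        with np.errstate(invalid="ignore"):
            c = np.corrcoef(x, rowvar=False)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if not np.isfinite(c[i, j]) or abs(c[i, j]) > 1 - 1e-8:
                    offenders.append((names[i], names[j]))
        raise CollinearityError(
            f"exposure effect matrix is rank deficient; "
            f"collinear exposures: {offenders or names}"
        )


def mvmr_ivw(h: HarmonizedSet) -> MVMRResult:
    """Multivariable IVW: WLS of by on the bx matrix through the origin,
    weights 1/sey², multiplicative random-effects SEs (σ̂² = Q/(k−L), no
    floor), per-exposure p from the normal distribution."""
    x = h.bx
    y = h.by
    k, L = x.shape
    if k <= L:
        raise InsufficientInstrumentsError(
            f"MVMR needs more SNPs than exposures (k={k}, L={L})"
        )
    _check_rank(x, h.exposure_ids)
    w = 1.0 / h.sey ** 2
    xtw = x.T * w
    xtwx = xtw @ x
    beta = np.linalg.solve(xtwx, xtw @ y)
    resid = y - x @ beta
    q = float(np.sum(w * resid ** 2))
    df = k - L
    sigma2 = q / df
    cov = sigma2 * np.linalg.inv(xtwx)
    ses = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(ses > 0, np.abs(beta) / ses, np.inf)
    pvals = 2.0 * stats.norm.sf(z)
    cf = np.array([conditional_f(h, j) for j in range(L)])
    return MVMRResult(
        exposures=list(h.exposure_ids),
        betas=beta, ses=ses, pvals=pvals, conditional_f=cf,
        n_snps=k, cochran_q=q, q_df=df,
        q_p=float(stats.chi2.sf(q, df)),
    )


def conditional_f(h: HarmonizedSet, j: int) -> float:
    """Conditional instrument strength of exposure j given the others.

    Regress exposure j's SNP effects on the remaining exposures' effects
    with weights 1/sex_j²; the conditional F is the weighted residual sum
    of squares divided by (k − L + 1).  It collapses to 0 when exposure j's
    effects are an exact linear combination of the others'.
    """
    x = h.bx
    k, L = x.shape
    if L < 2:
        raise InsufficientInstrumentsError("conditional F needs >= 2 exposures")
    xj = x[:, j]
    xo = np.delete(x, j, axis=1)
    w = 1.0 / h.sex[:, j] ** 2
    xtw = xo.T * w
    g, *_ = np.linalg.lstsq(xtw @ xo, xtw @ xj, rcond=None)
    resid = xj - xo @ g
    q_xj = float(np.sum(w * resid ** 2))
    return q_xj / (k - L + 1)


def mvmr_instruments(
    exposures: Mapping[str, SummaryStats],
    outcome: SummaryStats,
    ld: LDProvider,
    p_thresholds: Mapping[str, float] | float = 5e-8,
    clump_r2: float = 0.001,
    clump_kb: float = 10_000.0,
    steiger_alpha: float = 0.05,
) -> HarmonizedSet:
    """Joint instrument set for several exposures.

    Per-exposure candidates are pooled (a shared SNP keeps its smallest
    p-value), jointly clumped with the usual parameters, restricted to SNPs
    with effect estimates available in every exposure and the outcome, and
    Steiger-filtered against the outcome using each SNP's strongest exposure
    association.  Requires at least L+2 surviving SNPs.
    """
    exposures = dict(exposures)
    if len(exposures) < 2:
        raise InsufficientInstrumentsError("MVMR needs >= 2 exposures")
    union: dict[str, pd.Series] = {}
    for tid, ss in exposures.items():
        thr = (p_thresholds if isinstance(p_thresholds, float)
               else p_thresholds[tid])
        for _, rec in select_candidates(ss, thr).iterrows():
            cur = union.get(rec["snp"])
            if cur is None or rec["pval"] < cur["pval"]:
                union[rec["snp"]] = rec
    pooled = pd.DataFrame(list(union.values()))
    if pooled.empty:
        raise InsufficientInstrumentsError("no candidate instruments")
    clumped = clump(pooled, ld, r2_max=clump_r2, window_kb=clump_kb)
    h = harmonize(list(exposures.values()), outcome, snps=clumped["snp"])
    h.exposure_ids = list(exposures)  # caller's labels are canonical
    h = steiger_filter(h, alpha=steiger_alpha)
    L = len(exposures)
    if h.n_snps < L + 2:
        raise InsufficientInstrumentsError(
            f"under-identified: {h.n_snps} SNPs for {L} exposures "
            f"(need >= {L + 2})"
        )
    return h
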