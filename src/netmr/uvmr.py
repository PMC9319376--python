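"""Univariable two-sample MR estimators and pleiotropy diagnostics.

Given harmonized per-SNP effects (bx, sex) on an exposure and (by, sey) on
an outcome, the estimators here are:

* Wald ratio          by/bx (single SNP)
* IVW                 weighted regression through the origin, weights
                      1/sey²; multiplicative random effects scale the SE by
                      the residual overdispersion σ̂² = Q/(J−1)
* MR-Egger            weighted regression with a free intercept; a nonzero
                      intercept indicates directional horizontal pleiotropy
                      and the slope is a pleiotropy-adjusted estimate
* weighted median     consistent when instruments carrying ≥50% of the
                      weight are valid; SE by parametric bootstrap
* MR-PRESSO           simulation-based global heterogeneity test with a
                      per-SNP outlier test and outlier-corrected IVW

Heterogeneity is summarized by Cochran's Q with J−1 degrees of freedom.
All estimates are invariant to flipping the sign of (bx, by) jointly for
any SNP, and scale as 1/c when the exposure is rescaled by c.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InsufficientInstrumentsError, ValidationError
from .gwas_io import HarmonizedSet

Z95 = stats.norm.ppf(0.975)


@dataclass
class MREstimate:
    """A causal-effect estimate (log-OR per unit exposure when the outcome
    is binary)."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    @property
    def significant(self) -> bool:
        return self.pval < 0.05


@dataclass
class EggerIntercept:
    estimate: float
    se: float
    pval: float

    @property
    def directional_pleiotropy(self) -> bool:
        return self.pval < 0.05


@dataclass
class PressoResult:
    rss_observed: float
    global_p: float
    n_sim: int
    outlier_pvals: np.ndarray  # Bonferroni-adjusted, per SNP
    outliers: list[str]
    corrected: MREstimate | None


@dataclass
class PleiotropyReport:
    """Diagnostics accompanying a primary IVW estimate."""

    cochran_q: float = np.nan
    q_df: int = 0
    q_p: float = np.nan
    egger_intercept: float = np.nan
    egger_intercept_se: float = np.nan
    egger_intercept_p: float = np.nan
    presso_global_p: float = np.nan
    presso_outliers: list[str] = field(default_factory=list)
    presso_corrected: MREstimate | None = None


def _arrays(h) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(h, HarmonizedSet):
        return h.single()
    bx, sex, by, sey = (np.asarray(a, float) for a in h)
    return bx, sex, by, sey


def _estimate(method, beta, se, n_snps, df=None) -> MREstimate:
    if se > 0:
        if df is None:
            p = 2.0 * stats.norm.sf(abs(beta) / se)
            q = Z95
        else:
            p = 2.0 * stats.t.sf(abs(beta) / se, df)
            q = stats.t.ppf(0.975, df)
        lo, hi = beta - q * se, beta + q * se
    else:  # degenerate exact fit: the point is the whole interval
        p, lo, hi = (0.0 if beta != 0 else 1.0), beta, beta
    return MREstimate(method, float(beta), float(se), float(lo), float(hi),
                      float(p), int(n_snps))


# ---------------------------------------------------------------------------

def wald_ratio(bx: float, by: float, sex: float, sey: float,
               snp: str = "") -> MREstimate:
    """Single-SNP causal estimate by/bx with first-order SE sey/|bx|."""
    if bx == 0:
        raise ValidationError(f"zero exposure effect for SNP {snp or '?'}")
    beta = by / bx
    se = sey / abs(bx)
    return _estimate("wald", beta, se, 1)


def cochran_q(bx, by, sey, theta) -> tuple[float, int, float]:
    """Weighted heterogeneity statistic around a causal estimate theta."""
    w = 1.0 / np.asarray(sey, float) ** 2
    q = float(np.sum(w * (np.asarray(by) - theta * np.asarray(bx)) ** 2))
    df = len(w) - 1
    p = float(stats.chi2.sf(q, df)) if df > 0 else np.nan
    return q, df, p


def ivw(h, floor_variance: bool = False) -> tuple[MREstimate, PleiotropyReport]:
    """IVW with multiplicative random effects.

    Point estimate θ̂ = Σw·bx·by / Σw·bx² with w = 1/sey².  The SE is
    √(σ̂²/Σw·bx²) with σ̂² = Q/(J−1): no floor at 1 by default (pure
    multiplicative model); ``floor_variance=True`` applies the common
    max(σ̂², 1) variant for cross-checks against fixed-effect-floored
    implementations.  A single SNP degrades to the Wald ratio.
    """
    bx, sex, by, sey = _arrays(h)
    j = len(bx)
    if j == 0:
        raise InsufficientInstrumentsError("IVW needs at least one SNP")
    if j == 1:
        est = wald_ratio(bx[0], by[0], sex[0], sey[0])
        return est, PleiotropyReport(cochran_q=0.0, q_df=0, q_p=np.nan)
    w = 1.0 / sey ** 2
    denom = float(np.sum(w * bx ** 2))
    if denom == 0:
        raise ValidationError("all exposure effects are zero (singular design)")
    theta = float(np.sum(w * bx * by)) / denom
    q, df, q_p = cochran_q(bx, by, sey, theta)
    sigma2 = q / df
    if floor_variance:
        sigma2 = max(sigma2, 1.0)
    se = float(np.sqrt(sigma2 / denom))
    est = _estimate("ivw_mre", theta, se, j)
    return est, PleiotropyReport(cochran_q=q, q_df=df, q_p=q_p)


def egger(h) -> tuple[MREstimate, EggerIntercept]:
    """MR-Egger regression by = α + θ·bx, weights 1/sey².

    SNPs are first oriented so every bx ≥ 0 (both signs flipped where
    bx < 0).  The intercept α estimates the average directional pleiotropic
    effect; its p-value comes from a t distribution with J−2 df.  The slope
    is returned as the pleiotropy-corrected causal estimate.
    """
    bx, sex, by, sey = _arrays(h)
    j = len(bx)
    if j < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 SNPs, got {j}")
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip
    w = 1.0 / sey ** 2
    x = np.column_stack([np.ones(j), bx])
    xtw = x.T * w
    xtwx = xtw @ x
    coef = np.linalg.solve(xtwx, xtw @ by)
    resid = by - x @ coef
    rss = float(np.sum(w * resid ** 2))
    df = j - 2
    sigma2 = rss / df
    cov = sigma2 * np.linalg.inv(xtwx)
    ses = np.sqrt(np.diag(cov))
    slope = _estimate("egger_slope", coef[1], ses[1], j, df=df)
    p_int = 2.0 * stats.t.sf(abs(coef[0]) / ses[0], df) if ses[0] > 0 else (
        0.0 if coef[0] != 0 else 1.0
    )
    return slope, EggerIntercept(float(coef[0]), float(ses[0]), float(p_int))


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, cum, v))


def weighted_median(h, n_boot: int = 1000, seed: int | None = None) -> MREstimate:
    """Weighted median of per-SNP Wald ratios.

    Ratios θ_j = by/bx carry weights 1/se(θ_j)² with the first-order ratio
    SE sey/|bx|.  The estimate linearly interpolates the cumulative
    standardized weights to 0.5.  The SE is a parametric bootstrap: resample
    bx* ~ N(bx, sex), by* ~ N(by, sey), recompute, and take the SD across
    ``n_boot`` draws.  A seed is required for reproducibility.
    """
    bx, sex, by, sey = _arrays(h)
    j = len(bx)
    if j < 3:
        raise InsufficientInstrumentsError(
            f"weighted median needs >= 3 SNPs, got {j}"
        )
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    if seed is None:
        raise ValidationError("weighted_median requires an explicit seed")
    if np.any(bx == 0):
        raise ValidationError("zero exposure effect encountered in ratios")
    ratios = by / bx
    w = (bx / sey) ** 2  # 1/se(ratio)^2
    point = _weighted_median(ratios, w)
    rng = np.random.default_rng(seed)
    bx_s = rng.normal(bx, sex, size=(n_boot, j))
    by_s = rng.normal(by, sey, size=(n_boot, j))
    bx_s = np.where(bx_s == 0, np.finfo(float).tiny, bx_s)
    ratios_s = by_s / bx_s
    w_s = (bx_s / sey) ** 2
    boots = np.array([
        _weighted_median(ratios_s[i], w_s[i]) for i in range(n_boot)
    ])
    se = float(np.std(boots, ddof=1))
    return _estimate("weighted_median", point, se, j)


def _loo_ivw(bx, by, w):
    """Leave-one-out IVW estimates, vectorized over the last axis."""
    s_num = np.sum(w * bx * by, axis=-1, keepdims=True)
    s_den = np.sum(w * bx ** 2, axis=-1, keepdims=True)
    return (s_num - w * bx * by) / (s_den - w * bx ** 2)


def mr_presso(h, n_sim: int = 1000, seed: int | None = None,
              outlier_alpha: float = 0.05) -> PressoResult:
    """MR-PRESSO global heterogeneity and outlier tests.

    The observed statistic is RSS = Σ_j w_j (by_j − θ̂₍₋ⱼ₎·bx_j)² with
    θ̂₍₋ⱼ₎ the leave-one-out IVW estimate and w_j = 1/sey_j².  Its null
    distribution is built by parametric simulation (bx* ~ N(bx, sex),
    by*_j ~ N(θ̂₍₋ⱼ₎·bx_j, sey_j)); the global p is the fraction of
    simulated RSS at or above the observed value, floored at 1/(n_sim+1).
    Per-SNP outlier p-values compare each SNP's simulated weighted squared
    residuals with its observed one and are Bonferroni-adjusted by J;
    adjusted p < ``outlier_alpha`` flags the SNP and IVW is recomputed
    without the flagged SNPs as the corrected estimate.  (The distortion
    test of the original procedure is not part of this implementation.)
    """
    bx, sex, by, sey = _arrays(h)
    j = len(bx)
    if j < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO needs >= 4 SNPs, got {j}")
    if n_sim < 1000:
        raise ValidationError("n_sim must be >= 1000")
    if seed is None:
        raise ValidationError("mr_presso requires an explicit seed")
    snps = h.snps if isinstance(h, HarmonizedSet) else [str(i) for i in range(j)]
    w = 1.0 / sey ** 2
    theta_loo = np.asarray(_loo_ivw(bx, by, w)).reshape(j)
    obs_resid = w * (by - theta_loo * bx) ** 2
    rss_obs = float(np.sum(obs_resid))

    rng = np.random.default_rng(seed)
    bx_s = rng.normal(bx, sex, size=(n_sim, j))
    by_s = rng.normal(theta_loo * bx, sey, size=(n_sim, j))
    theta_loo_s = _loo_ivw(bx_s, by_s, w)
    resid_s = w * (by_s - theta_loo_s * bx_s) ** 2
    rss_s = np.sum(resid_s, axis=1)

    floor = 1.0 / (n_sim + 1.0)
    global_p = max(float(np.mean(rss_s >= rss_obs)), floor)
    outlier_p = np.maximum(np.mean(resid_s >= obs_resid, axis=0), floor)
    adj_p = np.minimum(outlier_p * j, 1.0)
    is_out = adj_p < outlier_alpha
    outliers = [s for s, o in zip(snps, is_out) if o]

    corrected = None
    if outliers and (j - len(outliers)) >= 2:
        keep = ~is_out
        corrected, _ = ivw((bx[keep], sex[keep], by[keep], sey[keep]))
        corrected.method = "ivw_presso_corrected"
    return PressoResult(rss_obs, global_p, n_sim, adj_p, outliers, corrected)


def full_uvmr(h, seed: int, n_boot: int = 1000, n_sim: int = 1000,
              floor_variance: bool = False) -> tuple[dict, PleiotropyReport]:
    """Run every applicable estimator on one harmonized pair.

    Returns ({method: MREstimate}, PleiotropyReport).  Methods whose
    instrument requirements are not met are silently omitted from the dict;
    the report collects Cochran's Q, the Egger intercept triple and the
    MR-PRESSO results where available.
    """
    est, report = ivw(h)
    out = {"ivw": est}
    bx, *_ = _arrays(h)
    j = len(bx)
    if j >= 3:
        slope, intercept = egger(h)
        out["egger"] = slope
        report.egger_intercept = intercept.estimate
        report.egger_intercept_se = intercept.se
        report.egger_intercept_p = intercept.pval
        out["weighted_median"] = weighted_median(h, n_boot=n_boot, seed=seed)
    if j >= 4:
        presso = mr_presso(h, n_sim=n_sim, seed=seed + 1)
        report.presso_global_p = presso.global_p
        report.presso_outliers = presso.outliers
        report.presso_corrected = presso.corrected
        if presso.corrected is not None:
            out["presso_corrected"] = presso.corrected
    return out, report
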