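"""Three-step network MR orchestration.

Step 1 estimates the total effect of each metabolic exposure (e.g. T2D,
BMI) on each outcome.  Step 2 screens every metabolite against every
outcome: nominal IVW significance, removal of associations with a
significant MR-Egger intercept (directional pleiotropy), MR-PRESSO outlier
correction when the global test fires, then a Bonferroni screen (0.05
divided by the number of metabolites with valid instruments) combined with
weighted-median robustness for "credible" status — nominal survivors remain
"suggestive".  Step 3 tests each exposure against the step-2 survivor
metabolites.  Metabolites causal in both steps 2 and 3 enter mediation:
product-of-coefficients indirect effect, proportion of the step-1 total
effect mediated, an MVMR model adjusting the metabolite for the exposure,
and an evidence tier.  Suggestive metabolites feed pathway enrichment and,
when a serum-correlation table is supplied, pairwise MVMR against their
|r| > 0.2 partners.

Every stochastic routine (weighted-median bootstrap, MR-PRESSO) is driven
by seeds derived deterministically from the run seed and the trait-pair
labels, so a re-run with the same config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import PathwayTable, hypergeom_enrich
from .errors import ConfigError, NetmrError
from .gwas_io import SummaryStats, TraitMeta, harmonize, read_summary_stats
from .instruments import (ABERRANT_R2, LDProvider, MatrixLDProvider, clump,
                          instrument_strength, is_weak, select_candidates,
                          steiger_filter)
from .mediation import (MediationResult, classify_mediator, indirect_effect,
                        proportion_mediated)
from .mvmr import mvmr_instruments, mvmr_ivw
from .uvmr import full_uvmr


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m."""
    if m < 1:
        raise ConfigError("family size must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ConfigError("alpha must lie in (0,1)")
    return alpha / m


def _derive_seed(base: int, *names: str) -> int:
    h = zlib.crc32("|".join(names).encode())
    return int((base * 1_000_003 + h) % (2 ** 31))


@dataclass
class NetworkConfig:
    """Thresholds, seeds and method settings for one pipeline run."""

    gw_sig: float = 5e-8            # exposure instrument threshold
    metabolite_sig: float = 1e-5    # relaxed metabolite threshold
    clump_r2: float = 0.001
    clump_kb: float = 10_000.0
    steiger_alpha: float = 0.05
    nominal_alpha: float = 0.05
    bonferroni_family_size: int | None = None  # default: metabolites with IVs
    aberrant_r2: float = ABERRANT_R2
    correlation_cutoff: float = 0.2
    n_boot: int = 1000
    n_sim: int = 5000
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("gw_sig", "metabolite_sig", "clump_r2", "steiger_alpha",
                     "nominal_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name}={v} must lie in (0,1)")
        if self.seed is None:
            raise ConfigError("a seed is mandatory (stochastic methods enabled)")


@dataclass
class NetworkData:
    """In-memory inputs for one run."""

    exposures: Mapping[str, SummaryStats]
    metabolites: Mapping[str, SummaryStats]
    outcomes: Mapping[str, SummaryStats]
    ld: LDProvider
    pathways: PathwayTable | None = None
    correlations: pd.DataFrame | None = None  # metabolite_a, metabolite_b, r


@dataclass
class NetworkReport:
    step1: pd.DataFrame
    step2: pd.DataFrame
    step3: pd.DataFrame
    mediation: pd.DataFrame
    mvmr_adjusted: pd.DataFrame
    mvmr_correlated: pd.DataFrame
    enrichment: pd.DataFrame
    manifest: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frames = {
            "step1.tsv": self.step1,
            "step2_screen.tsv": self.step2,
            "step3.tsv": self.step3,
            "mediation.tsv": self.mediation,
            "mvmr_adjusted.tsv": self.mvmr_adjusted,
            "mvmr_correlated.tsv": self.mvmr_correlated,
            "enrichment.tsv": self.enrichment,
        }
        for name, df in frames.items():
            df.to_csv(out / name, sep="\t", index=False, float_format="%.10g")
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=1))


# ---------------------------------------------------------------------------
# Single-pair MR fit
# ---------------------------------------------------------------------------

_FIT_COLUMNS = [
    "exposure", "outcome", "status", "k_snps", "r2_total", "f_stat",
    "beta", "se", "ci_low", "ci_high", "pval", "odds_ratio", "method",
    "ivw_beta", "ivw_se", "ivw_pval", "cochran_q", "q_df", "q_p",
    "egger_beta", "egger_intercept", "egger_intercept_p",
    "wm_beta", "wm_pval", "presso_global_p", "presso_outliers",
]


def _fit_pair(exposure: SummaryStats, outcome: SummaryStats, p_threshold: float,
              data: NetworkData, cfg: NetworkConfig, seed: int) -> dict:
    """Full univariable MR of one exposure on one outcome with diagnostics.

    Returns a flat row dict.  ``status`` != "ok" marks an excluded pair
    (no/weak instruments, aberrant R²) with every estimate NaN.
    """
    row = {
        "exposure": exposure.trait_id, "outcome": outcome.trait_id,
        "status": "ok", "k_snps": 0, "r2_total": np.nan, "f_stat": np.nan,
        "beta": np.nan, "se": np.nan, "ci_low": np.nan, "ci_high": np.nan,
        "pval": np.nan, "odds_ratio": np.nan, "method": "",
        "ivw_beta": np.nan, "ivw_se": np.nan, "ivw_pval": np.nan,
        "cochran_q": np.nan, "q_df": 0, "q_p": np.nan,
        "egger_beta": np.nan, "egger_intercept": np.nan,
        "egger_intercept_p": np.nan,
        "wm_beta": np.nan, "wm_pval": np.nan,
        "presso_global_p": np.nan, "presso_outliers": "",
    }
    cand = select_candidates(exposure, p_threshold)
    if cand.empty:
        row["status"] = "no_instruments"
        return row
    clumped = clump(cand, data.ld, r2_max=cfg.clump_r2, window_kb=cfg.clump_kb)
    try:
        h = harmonize(exposure, outcome, snps=clumped["snp"])
    except NetmrError as exc:
        row["status"] = f"harmonization_failed: {exc}"
        return row
    h = steiger_filter(h, alpha=cfg.steiger_alpha)
    if h.n_snps == 0:
        row["status"] = "no_instruments_post_filter"
        return row
    kept = clumped[clumped["snp"].isin(h.snps)]
    try:
        strength = instrument_strength(exposure.trait_id, kept)
    except NetmrError as exc:
        row["status"] = f"aberrant_r2: {exc}"
        return row
    row["k_snps"] = strength.k
    row["r2_total"] = strength.r2_total
    row["f_stat"] = strength.f_statistic
    if strength.r2_total >= cfg.aberrant_r2:
        row["status"] = "aberrant_r2"
        return row
    if is_weak(strength.f_statistic):
        row["status"] = "weak_instruments"
        return row

    ests, rep = full_uvmr(h, seed=seed, n_boot=cfg.n_boot, n_sim=cfg.n_sim)
    ivw_est = ests["ivw"]
    row.update(ivw_beta=ivw_est.beta, ivw_se=ivw_est.se, ivw_pval=ivw_est.pval,
               cochran_q=rep.cochran_q, q_df=rep.q_df, q_p=rep.q_p,
               egger_intercept=rep.egger_intercept,
               egger_intercept_p=rep.egger_intercept_p,
               presso_global_p=rep.presso_global_p,
               presso_outliers=";".join(rep.presso_outliers))
    if "egger" in ests:
        row["egger_beta"] = ests["egger"].beta
    if "weighted_median" in ests:
        row["wm_beta"] = ests["weighted_median"].beta
        row["wm_pval"] = ests["weighted_median"].pval
    # the effective estimate: outlier-corrected IVW when the global test fired
    eff = ivw_est
    if (np.isfinite(rep.presso_global_p) and rep.presso_global_p < 0.05
            and rep.presso_corrected is not None):
        eff = rep.presso_corrected
    row.update(beta=eff.beta, se=eff.se, ci_low=eff.ci_low, ci_high=eff.ci_high,
               pval=eff.pval, odds_ratio=eff.odds_ratio, method=eff.method)
    return row


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------

def run_network(data: NetworkData, config: NetworkConfig) -> NetworkReport:
    cfg = config
    seed = int(cfg.seed)
    skipped: dict[str, str] = {}

    # ---- step 1: total effects exposure -> outcome -----------------------
    step1_rows = []
    for eid, ess in data.exposures.items():
        for oid, oss in data.outcomes.items():
            row = _fit_pair(ess, oss, cfg.gw_sig, data, cfg,
                            _derive_seed(seed, "step1", eid, oid))
            row["exposure"], row["outcome"] = eid, oid  # mapping keys rule
            step1_rows.append(row)
            if row["status"] != "ok":
                skipped[f"step1:{eid}->{oid}"] = row["status"]
    step1 = pd.DataFrame(step1_rows, columns=_FIT_COLUMNS)

    # ---- step 2: metabolite -> outcome screen ----------------------------
    step2_rows = []
    valid_metabolites: set[str] = set()
    for mid, mss in data.metabolites.items():
        for oid, oss in data.outcomes.items():
            row = _fit_pair(mss, oss, cfg.metabolite_sig, data, cfg,
                            _derive_seed(seed, "step2", mid, oid))
            row["exposure"], row["outcome"] = mid, oid
            step2_rows.append(row)
            if row["status"] == "ok":
                valid_metabolites.add(mid)
            else:
                skipped[f"step2:{mid}->{oid}"] = row["status"]
    family = cfg.bonferroni_family_size or max(len(valid_metabolites), 1)
    bonf = bonferroni_threshold(cfg.nominal_alpha, family)
    for row in step2_rows:
        ok = row["status"] == "ok"
        nominal = ok and row["pval"] < cfg.nominal_alpha
        pleio = (ok and np.isfinite(row["egger_intercept_p"])
                 and row["egger_intercept_p"] < 0.05)
        row["egger_excluded"] = bool(pleio)
        row["suggestive"] = bool(nominal and not pleio)
        row["credible"] = bool(
            row["suggestive"] and row["pval"] < bonf
            and np.isfinite(row["wm_pval"]) and row["wm_pval"] < 0.05
        )
    step2 = pd.DataFrame(
        step2_rows,
        columns=_FIT_COLUMNS + ["egger_excluded", "suggestive", "credible"],
    )
    survivors = [
        (r["exposure"], r["outcome"]) for r in step2_rows if r["suggestive"]
    ]
    survivor_mets = sorted({m for m, _ in survivors})

    # ---- step 3: exposure -> metabolite ---------------------------------
    step3_rows = []
    step3_ix: dict[tuple[str, str], dict] = {}
    for eid, ess in data.exposures.items():
        for mid in survivor_mets:
            row = _fit_pair(ess, data.metabolites[mid], cfg.gw_sig, data, cfg,
                            _derive_seed(seed, "step3", eid, mid))
            row["exposure"], row["outcome"] = eid, mid
            step3_rows.append(row)
            step3_ix[(eid, mid)] = row
            if row["status"] != "ok":
                skipped[f"step3:{eid}->{mid}"] = row["status"]
    step3 = pd.DataFrame(step3_rows, columns=_FIT_COLUMNS)

    step1_ix = {(r["exposure"], r["outcome"]): r for r in step1_rows}
    step2_ix = {(r["exposure"], r["outcome"]): r for r in step2_rows}

    # ---- mediation + exposure-adjusted MVMR ------------------------------
    med_rows = []
    mvmr_rows = []
    for eid, ess in data.exposures.items():
        for mid, oid in survivors:
            s3 = step3_ix.get((eid, mid))
            if s3 is None or s3["status"] != "ok" or not (
                s3["pval"] < cfg.nominal_alpha
            ):
                continue
            s2 = step2_ix[(mid, oid)]
            s1 = step1_ix.get((eid, oid))
            ind = indirect_effect(s3["beta"], s3["se"], s2["beta"], s2["se"])
            total_beta = s1["beta"] if s1 and s1["status"] == "ok" else np.nan
            total_se = s1["se"] if s1 and s1["status"] == "ok" else np.nan
            prop = None
            if np.isfinite(total_beta) and total_beta != 0:
                prop = proportion_mediated(ind, total_beta, total_se)
            # MVMR: metabolite adjusted for the exposure
            mvmr_sig = False
            mvmr_status = "ok"
            try:
                hm = mvmr_instruments(
                    {mid: data.metabolites[mid], eid: ess},
                    data.outcomes[oid], data.ld,
                    p_thresholds={mid: cfg.metabolite_sig, eid: cfg.gw_sig},
                    clump_r2=cfg.clump_r2, clump_kb=cfg.clump_kb,
                    steiger_alpha=cfg.steiger_alpha,
                )
                mv = mvmr_ivw(hm)
                eff = mv.effect(mid)
                mvmr_sig = eff["pval"] < cfg.nominal_alpha
                mvmr_rows.append({
                    "metabolite": mid, "adjusted_for": eid, "outcome": oid,
                    **{f"metabolite_{k}": v for k, v in eff.items()},
                    **{f"covariable_{k}": v for k, v in mv.effect(eid).items()},
                    "n_snps": mv.n_snps, "status": "ok",
                })
            except NetmrError as exc:
                mvmr_status = str(exc)
                skipped[f"mvmr:{mid}+{eid}->{oid}"] = mvmr_status
                mvmr_rows.append({
                    "metabolite": mid, "adjusted_for": eid, "outcome": oid,
                    "status": mvmr_status,
                })
            positive = bool(
                ind.significant and np.isfinite(total_beta)
                and np.sign(ind.beta) == np.sign(total_beta)
            )
            tier = classify_mediator(mvmr_sig, positive)
            med_rows.append({
                "mediator": mid,
                "category": (data.pathways.category_of(mid)
                             if data.pathways else ""),
                "exposure": eid, "outcome": oid,
                "beta_xm": s3["beta"], "se_xm": s3["se"],
                "or_my": float(np.exp(s2["beta"])), "beta_my": s2["beta"],
                "or_xy": (float(np.exp(total_beta))
                          if np.isfinite(total_beta) else np.nan),
                "beta_indirect": ind.beta, "indirect_se": ind.se,
                "indirect_ci_low": ind.ci_low, "indirect_ci_high": ind.ci_high,
                "indirect_significant": ind.significant,
                "proportion_pct": prop.percent if prop else np.nan,
                "proportion_ci_low": prop.ci_low if prop else np.nan,
                "proportion_ci_high": prop.ci_high if prop else np.nan,
                "mvmr_significant": mvmr_sig, "mvmr_status": mvmr_status,
                "tier": tier,
            })
    mediation = pd.DataFrame(med_rows, columns=[
        "mediator", "category", "exposure", "outcome", "beta_xm", "se_xm",
        "or_my", "beta_my", "or_xy", "beta_indirect", "indirect_se",
        "indirect_ci_low", "indirect_ci_high", "indirect_significant",
        "proportion_pct", "proportion_ci_low", "proportion_ci_high",
        "mvmr_significant", "mvmr_status", "tier",
    ])
    mvmr_adjusted = pd.DataFrame(mvmr_rows)

    # ---- MVMR for correlated metabolite pairs ----------------------------
    corr_rows = []
    if data.correlations is not None and len(data.correlations):
        cdf = data.correlations
        for mid, oid in survivors:
            partners = set(
                cdf.loc[(cdf["metabolite_a"] == mid)
                        & (cdf["r"].abs() > cfg.correlation_cutoff),
                        "metabolite_b"]
            ) | set(
                cdf.loc[(cdf["metabolite_b"] == mid)
                        & (cdf["r"].abs() > cfg.correlation_cutoff),
                        "metabolite_a"]
            )
            for partner in sorted(partners & set(data.metabolites)):
                try:
                    hm = mvmr_instruments(
                        {mid: data.metabolites[mid],
                         partner: data.metabolites[partner]},
                        data.outcomes[oid], data.ld,
                        p_thresholds=cfg.metabolite_sig,
                        clump_r2=cfg.clump_r2, clump_kb=cfg.clump_kb,
                        steiger_alpha=cfg.steiger_alpha,
                    )
                    mv = mvmr_ivw(hm)
                    eff = mv.effect(mid)
                    corr_rows.append({
                        "metabolite": mid, "partner": partner, "outcome": oid,
                        **{f"metabolite_{k}": v for k, v in eff.items()},
                        "n_snps": mv.n_snps, "status": "ok",
                    })
                except NetmrError as exc:
                    skipped[f"mvmr_pair:{mid}+{partner}->{oid}"] = str(exc)
                    corr_rows.append({
                        "metabolite": mid, "partner": partner, "outcome": oid,
                        "status": str(exc),
                    })
    mvmr_correlated = pd.DataFrame(corr_rows)

    # ---- enrichment ------------------------------------------------------
    enr_frames = []
    if data.pathways is not None:
        for oid in data.outcomes:
            sel = sorted({m for m, o in survivors if o == oid}
                         & data.pathways.background)
            if sel:
                e = hypergeom_enrich(sel, data.pathways)
                e.insert(0, "outcome", oid)
                enr_frames.append(e)
    enrichment = (pd.concat(enr_frames, ignore_index=True) if enr_frames
                  else pd.DataFrame(columns=["outcome", "pathway", "k", "K",
                                             "n", "N", "p_hyper",
                                             "significant"]))

    manifest = {
        "package": "netmr",
        "version": __version__,
        "seed": seed,
        "config": dataclasses.asdict(cfg),
        "bonferroni_family_size": family,
        "bonferroni_threshold": bonf,
        "n_metabolites_with_instruments": len(valid_metabolites),
        "skipped": skipped,
        "assumptions": [
            "Steiger alpha and binary-trait effective-N convention "
            "(4/(1/ncase+1/nctrl)) are package defaults",
            "cross-trait sampling covariance assumed zero (distinct cohorts)",
            "conditional F computed with independent-samples weighting",
        ],
    }
    return NetworkReport(step1, step2, step3, mediation, mvmr_adjusted,
                         mvmr_correlated, enrichment, manifest)


# ---------------------------------------------------------------------------
# Config-file plumbing
# ---------------------------------------------------------------------------

def _load_trait(entry: dict, base: Path, tid: str) -> SummaryStats:
    meta = TraitMeta(
        trait_id=tid,
        trait_type=entry.get("trait_type", "continuous"),
        n=entry.get("n"),
        n_case=entry.get("n_case"),
        n_control=entry.get("n_control"),
    )
    return read_summary_stats(base / entry["path"], meta,
                              column_map=entry.get("column_map"))


def load_run(config_path) -> tuple[NetworkData, NetworkConfig]:
    """Build (NetworkData, NetworkConfig) from a YAML run config.

    Relative paths resolve against the config file's directory.
    """
    cfg_path = Path(config_path)
    raw = yaml.safe_load(cfg_path.read_text())
    base = cfg_path.parent
    try:
        exposures = {t: _load_trait(e, base, t)
                     for t, e in raw["exposures"].items()}
        metabolites = {t: _load_trait(e, base, t)
                       for t, e in raw["metabolites"].items()}
        outcomes = {t: _load_trait(e, base, t)
                    for t, e in raw["outcomes"].items()}
        ld = MatrixLDProvider.from_tsv(base / raw["ld"])
    except KeyError as exc:
        raise ConfigError(f"config missing section {exc}") from exc
    pathways = (PathwayTable.from_tsv(base / raw["pathways"])
                if raw.get("pathways") else None)
    correlations = (pd.read_csv(base / raw["correlations"], sep="\t")
                    if raw.get("correlations") else None)
    cfg = NetworkConfig(seed=raw.get("seed"), **(raw.get("thresholds") or {}))
    data = NetworkData(exposures, metabolites, outcomes, ld, pathways,
                       correlations)
    return data, cfg
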