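r"""Synthetic two-sample GWAS summary statistics under a known causal diagram.

The generator emulates the structure of a network-MR study without any
individual-level data: per-SNP association estimates are drawn directly at
the summary level for three non-overlapping cohorts — a binary exposure
(T2D-like, log-OR scale), one or two continuous mediator metabolites
(log10-unit scale, modest sample size as in metabolomic GWAS), and a binary
outcome (log-OR scale, case/control counts as in a host-genetics
meta-analysis).

Causal diagram (all coefficients known and retained in the truth object):

    SNP --γ--> exposure --θ_XM--> mediator --θ_MY--> outcome
                   \________________θ_direct_____________/

so the true per-SNP outcome effect is γ·(θ_direct + θ_XM·θ_MY) plus the
mediator-instrument path δ·θ_MY, plus any planted pleiotropy α.  Estimates
are sampled β̂ ~ N(true, se) with se = 1/sqrt(2·N·f·(1−f)) from allele
frequencies f ~ U(0.05, 0.5) (effective N for binary traits).  Planted
anomalies — directional pleiotropy, heterogeneous outliers, reverse-causal
SNPs (effects only in the outcome layer), palindromic alleles, block LD —
exercise every diagnostic in the pipeline and are identifiable by id.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .gwas_io import SummaryStats, TraitMeta, write_summary_stats
from .instruments import BlockLDProvider

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
_PALINDROMIC_PAIRS = [("A", "T"), ("C", "G")]


@dataclass
class SimulationParams:
    """Generating conditions for one synthetic system.

    Defaults mirror a desk-scale version of a metabolite mediation study:
    100 strong exposure instruments (per-SNP log-OR drawn from
    ±U(0.06, 0.12), typical of lead variants for a common binary trait,
    jointly explaining ~30% of the latent liability so the aggregate R²
    stays physical), 30 mediator-specific instruments (±U(0.02, 0.05)
    log10 units against a metabolite SD of 0.15 log10 units, sized so they
    clear the relaxed 1e-5 metabolite threshold at N=7824), a mediator
    cohort of 7,824 (the scale of published metabolomic GWAS), and large
    case/control cohorts for the binary exposure and outcome.
    """

    # genome layout
    n_exposure_snps: int = 100
    n_mediator_snps: int = 30
    n_null_snps: int = 0
    n_outlier_snps: int = 0
    n_reverse_snps: int = 0
    block_size: int = 1
    within_block_r2: float = 0.0
    snp_spacing_kb: float = 500.0
    palindromic_fraction: float = 0.0
    # causal coefficients
    theta_xm: float = 0.05
    theta_my: float = 0.5
    theta_direct: float = 0.02
    # planted anomalies
    pleiotropy_mean: float = 0.0   # directional α added to exposure SNPs
    pleiotropy_sd: float = 0.0     # balanced pleiotropy
    outlier_offset_se: float = 10.0
    reverse_effect: float = 0.1
    # effect-size draws
    gamma_range: tuple[float, float] = (0.06, 0.12)
    delta_range: tuple[float, float] = (0.02, 0.05)
    mediator_sd: float = 0.15  # phenotypic SD of log10 metabolite level
    # cohorts (non-overlapping samples per trait)
    exposure_n_case: int = 80_000
    exposure_n_control: int = 120_000
    mediator_n: int = 7_824
    outcome_n_case: int = 50_000
    outcome_n_control: int = 1_500_000
    # mediators
    n_mediators: int = 1
    mediator_overlap: float = 0.0  # fraction of δ SNPs shared by mediator 2

    def __post_init__(self) -> None:
        if self.block_size < 1:
            raise ConfigError("block_size must be >= 1")
        if self.n_mediators not in (1, 2):
            raise ConfigError("n_mediators must be 1 or 2")
        if self.n_outlier_snps > self.n_exposure_snps:
            raise ConfigError("more outliers than exposure SNPs")
        if not 0.0 <= self.mediator_overlap <= 1.0:
            raise ConfigError("mediator_overlap must be in [0,1]")


@dataclass
class SimulationTruth:
    """Everything the generator knew, for recovery tests."""

    seed: int
    params: SimulationParams
    snps: list[str]
    gamma: np.ndarray          # SNP -> exposure effects
    delta: np.ndarray          # SNP -> mediator direct effects (k x M)
    alpha: np.ndarray          # pleiotropic SNP -> outcome effects
    theta_xm: float
    theta_my: float
    theta_direct: float
    outlier_snps: list[str]
    reverse_snps: list[str]
    palindromic_snps: list[str]
    block_of: dict[str, int]
    mediator_correlation: float | None = None

    @property
    def theta_total(self) -> float:
        return self.theta_direct + self.theta_xm * self.theta_my

    @property
    def indirect(self) -> float:
        return self.theta_xm * self.theta_my

    def to_json(self, path) -> None:
        d = {
            "seed": self.seed,
            "params": dataclasses.asdict(self.params),
            "snps": self.snps,
            "gamma": self.gamma.tolist(),
            "delta": self.delta.tolist(),
            "alpha": self.alpha.tolist(),
            "theta_xm": self.theta_xm,
            "theta_my": self.theta_my,
            "theta_direct": self.theta_direct,
            "theta_total": self.theta_total,
            "outlier_snps": self.outlier_snps,
            "reverse_snps": self.reverse_snps,
            "palindromic_snps": self.palindromic_snps,
            "block_of": self.block_of,
            "mediator_correlation": self.mediator_correlation,
        }
        Path(path).write_text(json.dumps(d, indent=1))


@dataclass
class SimulatedSystem:
    exposure: SummaryStats
    mediators: list[SummaryStats]
    outcome: SummaryStats
    ld: BlockLDProvider
    truth: SimulationTruth

    @property
    def mediator(self) -> SummaryStats:
        return self.mediators[0]


def _se(n_eff: float, f: np.ndarray, trait_sd: float = 1.0) -> np.ndarray:
    return trait_sd / np.sqrt(2.0 * n_eff * f * (1.0 - f))


def _pval(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats
    z = np.abs(beta) / se
    p = 2.0 * stats.norm.sf(z)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def simulate_system(params: SimulationParams | None = None,
                    seed: int = 0) -> SimulatedSystem:
    """Draw one complete two-sample system; fully reproducible from ``seed``."""
    p = params or SimulationParams()
    rng = np.random.default_rng(seed)

    m_per_med = p.n_mediator_snps
    k = (p.n_exposure_snps + m_per_med * p.n_mediators
         + p.n_null_snps + p.n_reverse_snps)
    snps = [f"rs{i + 1}" for i in range(k)]

    # genome layout: blocks tile consecutive SNPs; chromosomes cycle 1..22
    block_of = {s: i // p.block_size for i, s in enumerate(snps)}
    n_blocks = max(block_of.values()) + 1
    chrom = np.array([(block_of[s] % 22) + 1 for s in snps])
    pos = np.empty(k, dtype=int)
    for b in range(n_blocks):
        idx = [i for i, s in enumerate(snps) if block_of[s] == b]
        base = (b // 22 + 1) * 20_000_000  # far apart: clump window safe
        for off, i in enumerate(idx):
            pos[i] = base + int(off * p.snp_spacing_kb * 1000)

    eaf = rng.uniform(0.05, 0.5, size=k)
    n_pal = int(round(p.palindromic_fraction * k))
    pal_idx = rng.choice(k, size=n_pal, replace=False) if n_pal else np.array([], int)
    ea = np.empty(k, dtype=object)
    oa = np.empty(k, dtype=object)
    for i in range(k):
        if i in set(pal_idx.tolist()):
            ea[i], oa[i] = _PALINDROMIC_PAIRS[rng.integers(2)]
        else:
            ea[i], oa[i] = _ALLELE_PAIRS[rng.integers(len(_ALLELE_PAIRS))]

    # ---- true effects ----------------------------------------------------
    gamma = np.zeros(k)
    exp_idx = np.arange(p.n_exposure_snps)
    lo, hi = p.gamma_range
    gamma[exp_idx] = rng.uniform(lo, hi, p.n_exposure_snps) * rng.choice(
        [-1.0, 1.0], p.n_exposure_snps
    )
    # within a block, non-lead SNPs tag the lead signal at √r² attenuation
    if p.block_size > 1:
        for b in range(n_blocks):
            idx = [i for i, s in enumerate(snps) if block_of[s] == b]
            for i in idx[1:]:
                gamma[i] = np.sqrt(p.within_block_r2) * gamma[idx[0]]

    delta = np.zeros((k, p.n_mediators))
    lo_d, hi_d = p.delta_range
    start = p.n_exposure_snps
    med1 = np.arange(start, start + m_per_med)
    delta[med1, 0] = rng.uniform(lo_d, hi_d, m_per_med) * rng.choice(
        [-1.0, 1.0], m_per_med
    )
    med_corr = None
    if p.n_mediators == 2:
        med2 = np.arange(start + m_per_med, start + 2 * m_per_med)
        delta[med2, 1] = rng.uniform(lo_d, hi_d, m_per_med) * rng.choice(
            [-1.0, 1.0], m_per_med
        )
        n_shared = int(round(p.mediator_overlap * m_per_med))
        if n_shared:
            shared = med1[:n_shared]
            delta[shared, 1] = delta[shared, 0]
            # implied genetic correlation, equal per-mediator heritability
            num = float(np.sum(delta[:, 0] * delta[:, 1]))
            den = float(np.sqrt(np.sum(delta[:, 0] ** 2)
                                * np.sum(delta[:, 1] ** 2)))
            med_corr = num / den if den else 0.0

    # pleiotropy and planted outliers live on exposure SNPs
    alpha = np.zeros(k)
    if p.pleiotropy_mean or p.pleiotropy_sd:
        alpha[exp_idx] = rng.normal(p.pleiotropy_mean, p.pleiotropy_sd,
                                    p.n_exposure_snps)
    out_idx = (rng.choice(exp_idx, size=p.n_outlier_snps, replace=False)
               if p.n_outlier_snps else np.array([], int))
    rev_start = k - p.n_reverse_snps
    rev_idx = np.arange(rev_start, k) if p.n_reverse_snps else np.array([], int)

    exp_meta = TraitMeta("exposure", "binary", n_case=p.exposure_n_case,
                         n_control=p.exposure_n_control)
    out_meta = TraitMeta("outcome", "binary", n_case=p.outcome_n_case,
                         n_control=p.outcome_n_control)
    se_x = _se(exp_meta.effective_n, eaf)
    se_m = _se(p.mediator_n, eaf, p.mediator_sd)
    se_y = _se(out_meta.effective_n, eaf)
    if p.n_outlier_snps:
        alpha[out_idx] += p.outlier_offset_se * se_y[out_idx]

    true_x = gamma.copy()
    true_m = gamma[:, None] * p.theta_xm + delta  # k x M
    true_y = (gamma * (p.theta_direct + p.theta_xm * p.theta_my)
              + delta.sum(axis=1) * p.theta_my + alpha)
    if p.n_reverse_snps:
        true_y[rev_idx] += p.reverse_effect * rng.choice(
            [-1.0, 1.0], p.n_reverse_snps
        )

    def _draw(true, se, meta) -> SummaryStats:
        beta = rng.normal(true, se)
        df = pd.DataFrame({
            "snp": snps, "chrom": chrom, "pos": pos, "ea": ea, "oa": oa,
            "eaf": eaf, "beta": beta, "se": se, "pval": _pval(beta, se),
            "n": float(meta.effective_n),
        })
        return SummaryStats(meta, df)

    exposure = _draw(true_x, se_x, exp_meta)
    mediators = [
        _draw(true_m[:, m],
              se_m,
              TraitMeta(f"metabolite_{m + 1}", "continuous", n=p.mediator_n))
        for m in range(p.n_mediators)
    ]
    outcome = _draw(true_y, se_y, out_meta)

    truth = SimulationTruth(
        seed=seed, params=p, snps=snps, gamma=gamma, delta=delta, alpha=alpha,
        theta_xm=p.theta_xm, theta_my=p.theta_my, theta_direct=p.theta_direct,
        outlier_snps=[snps[i] for i in out_idx],
        reverse_snps=[snps[i] for i in rev_idx],
        palindromic_snps=[snps[i] for i in pal_idx],
        block_of=block_of,
        mediator_correlation=med_corr,
    )
    ld = BlockLDProvider(block_of, p.within_block_r2)
    return SimulatedSystem(exposure, mediators, outcome, ld, truth)


# ---------------------------------------------------------------------------
# Named scenarios and fixture emission
# ---------------------------------------------------------------------------

SCENARIOS: dict[str, SimulationParams] = {
    "null": SimulationParams(theta_xm=0.0, theta_my=0.0, theta_direct=0.0),
    "valid_mediation": SimulationParams(),
    "directional_pleiotropy": SimulationParams(pleiotropy_mean=0.05),
    "outliers": SimulationParams(n_exposure_snps=20, n_outlier_snps=1),
    "reverse_causation": SimulationParams(n_reverse_snps=5),
    "weak_instruments": SimulationParams(gamma_range=(0.01, 0.02),
                                         exposure_n_case=2_000,
                                         exposure_n_control=3_000),
    "correlated_mediators": SimulationParams(n_mediators=2,
                                             mediator_overlap=0.6),
}


def write_fixture_suite(out_dir, scenario_name: str, seed: int = 0) -> dict:
    """Write summary-stat TSVs, LD table, pathway annotation, truth JSON and
    a ready-to-run pipeline config for one named scenario.

    Returns a dict of the paths written.
    """
    if scenario_name not in SCENARIOS:
        raise ConfigError(
            f"unknown scenario {scenario_name!r}; valid scenarios: "
            f"{sorted(SCENARIOS)}"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sys = simulate_system(SCENARIOS[scenario_name], seed=seed)
    p = sys.truth.params

    paths = {"exposure": out / "exposure.tsv", "outcome": out / "outcome.tsv"}
    write_summary_stats(sys.exposure, paths["exposure"])
    write_summary_stats(sys.outcome, paths["outcome"])
    med_entries = {}
    for m, ss in enumerate(sys.mediators):
        pth = out / f"{ss.trait_id}.tsv"
        write_summary_stats(ss, pth)
        paths[ss.trait_id] = pth
        med_entries[ss.trait_id] = {
            "path": pth.name, "trait_type": "continuous", "n": p.mediator_n,
        }
    paths["ld"] = out / "ld.tsv"
    sys.ld.to_frame().to_csv(paths["ld"], sep="\t", index=False)

    # minimal annotation: each mediator in its own pathway, plus background
    rows = []
    for ss in sys.mediators:
        rows.append({"metabolite_id": ss.trait_id,
                     "pathway": "glutamate metabolism",
                     "category": "Amino acid"})
    rows.append({"metabolite_id": "background_metabolite",
                 "pathway": "lysolipid", "category": "Lipid"})
    paths["pathways"] = out / "pathways.tsv"
    pd.DataFrame(rows).to_csv(paths["pathways"], sep="\t", index=False)

    if len(sys.mediators) == 2 and sys.truth.mediator_correlation is not None:
        paths["correlations"] = out / "correlations.tsv"
        pd.DataFrame([{
            "metabolite_a": sys.mediators[0].trait_id,
            "metabolite_b": sys.mediators[1].trait_id,
            "r": sys.truth.mediator_correlation,
        }]).to_csv(paths["correlations"], sep="\t", index=False)

    paths["truth"] = out / "truth.json"
    sys.truth.to_json(paths["truth"])

    config = {
        "seed": seed,
        "exposures": {
            "exposure": {"path": "exposure.tsv", "trait_type": "binary",
                         "n_case": p.exposure_n_case,
                         "n_control": p.exposure_n_control},
        },
        "metabolites": med_entries,
        "outcomes": {
            "outcome": {"path": "outcome.tsv", "trait_type": "binary",
                        "n_case": p.outcome_n_case,
                        "n_control": p.outcome_n_control},
        },
        "ld": "ld.tsv",
        "pathways": "pathways.tsv",
        "thresholds": {},
    }
    if "correlations" in paths:
        config["correlations"] = "correlations.tsv"
    paths["config"] = out / "config.yaml"
    paths["config"].write_text(yaml.safe_dump(config, sort_keys=False))
    return {k: str(v) for k, v in paths.items()}
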