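"""Reading, validating, writing, and harmonizing GWAS summary statistics.

Summary statistics for one trait are held in a :class:`SummaryStats`: trait
metadata plus a validated :class:`pandas.DataFrame` with canonical columns
``snp, chrom, pos, ea, oa, eaf, beta, se, pval, n``.  Effects for binary
traits are on the natural-log odds scale.

Harmonization aligns one or more exposure datasets and an outcome dataset to
shared effect alleles over a common SNP list, producing a
:class:`HarmonizedSet` — the in-memory contract consumed by every estimator
in the package.  Palindromic variants (A/T, C/G) are dropped unconditionally
because the strand cannot be resolved from alleles alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, HarmonizationError, ValidationError

VALID_BASES = frozenset("ACGT")

#: Default header dialect for tab-separated summary statistics.  Sources use
#: wildly different headers; a column map translates any of them onto this.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "SNP": "snp",
    "CHR": "chrom",
    "POS": "pos",
    "EA": "ea",
    "OA": "oa",
    "EAF": "eaf",
    "BETA": "beta",
    "SE": "se",
    "P": "pval",
    "N": "n",
}

MANDATORY = ("snp", "ea", "oa", "beta", "se", "pval")
OPTIONAL = ("chrom", "pos", "eaf", "n")


@dataclass(frozen=True)
class TraitMeta:
    """Metadata for one GWAS trait.

    ``n`` is the (global) sample size used when the file carries no per-SNP
    N column.  For binary traits, case/control counts drive the effective
    sample size 4/(1/n_case + 1/n_control), the standard convention for
    log-OR summary statistics.
    """

    trait_id: str
    trait_type: str = "continuous"  # or "binary"
    n: float | None = None
    n_case: int | None = None
    n_control: int | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValidationError(
                f"trait_type must be continuous|binary, got {self.trait_type!r}"
            )
        if self.trait_type == "binary" and (
            self.n_case is None or self.n_control is None
        ):
            if self.n is None:
                raise ValidationError(
                    f"binary trait {self.trait_id!r} needs n_case/n_control (or n)"
                )

    @property
    def effective_n(self) -> float | None:
        if self.trait_type == "binary" and self.n_case and self.n_control:
            return 4.0 / (1.0 / self.n_case + 1.0 / self.n_control)
        return self.n


class SummaryStats:
    """Validated per-SNP association records for a single trait."""

    def __init__(self, meta: TraitMeta, records: pd.DataFrame):
        self.meta = meta
        df = records.copy()
        missing = [c for c in MANDATORY if c not in df.columns]
        if missing:
            raise FormatError(
                f"{meta.trait_id}: missing mandatory column(s) {missing}"
            )
        for c in OPTIONAL:
            if c not in df.columns:
                df[c] = np.nan
        df = df[[*MANDATORY[:1], "chrom", "pos", *MANDATORY[1:3], "eaf",
                 *MANDATORY[3:], "n"]]
        # chromosome labels are nominal (1..22, X, MT): normalize to str
        df["chrom"] = df["chrom"].map(
            lambda c: str(c) if pd.notna(c) else c
        ).astype(object)
        self._validate(df)
        if df["n"].isna().all() and meta.effective_n is not None:
            df["n"] = float(meta.effective_n)
            self.n_imputed = True  # global-N fallback; flagged, not fatal
        else:
            self.n_imputed = False
            if df["n"].isna().any() and meta.effective_n is not None:
                df.loc[df["n"].isna(), "n"] = float(meta.effective_n)
        self.records = df.reset_index(drop=True)

    def _validate(self, df: pd.DataFrame) -> None:
        tid = self.meta.trait_id
        problems: list[str] = []
        if df["snp"].duplicated().any():
            dups = df.loc[df["snp"].duplicated(), "snp"].tolist()[:5]
            problems.append(f"duplicate variant IDs: {dups}")
        se = pd.to_numeric(df["se"], errors="coerce")
        bad_se = df.index[~(se > 0)].tolist()
        for i in bad_se:
            problems.append(
                f"row {i}: non-positive or missing se for variant {df.at[i, 'snp']!r}"
            )
        p = pd.to_numeric(df["pval"], errors="coerce")
        bad_p = df.index[~((p > 0) & (p <= 1))].tolist()
        for i in bad_p:
            problems.append(f"row {i}: p-value outside (0,1] for {df.at[i, 'snp']!r}")
        for col in ("ea", "oa"):
            bad = df.index[~df[col].astype(str).isin(VALID_BASES)].tolist()
            for i in bad:
                problems.append(
                    f"row {i}: invalid {col} base {df.at[i, col]!r} "
                    f"for {df.at[i, 'snp']!r}"
                )
        same = df.index[df["ea"] == df["oa"]].tolist()
        for i in same:
            problems.append(f"row {i}: effect allele equals other allele")
        eaf = pd.to_numeric(df["eaf"], errors="coerce")
        bad_f = df.index[(~eaf.isna()) & ~((eaf >= 0) & (eaf <= 1))].tolist()
        for i in bad_f:
            problems.append(f"row {i}: eaf outside [0,1]")
        if df["pos"].notna().any():
            pos = pd.to_numeric(df["pos"], errors="coerce")
            bad_pos = df.index[df["pos"].notna() & ~(pos >= 1)].tolist()
            for i in bad_pos:
                problems.append(f"row {i}: position < 1")
        if problems:
            raise ValidationError(f"{tid}: " + "; ".join(problems))

    # -- convenience ------------------------------------------------------
    @property
    def trait_id(self) -> str:
        return self.meta.trait_id

    @property
    def effective_n(self) -> float | None:
        return self.meta.effective_n

    def __len__(self) -> int:
        return len(self.records)

    def indexed(self) -> pd.DataFrame:
        return self.records.set_index("snp", drop=False)


def read_summary_stats(
    path,
    trait_meta: TraitMeta,
    column_map: Mapping[str, str] | None = None,
) -> SummaryStats:
    """Read a tab-delimited summary-statistics file.

    ``column_map`` maps file headers onto the canonical names; by default the
    :data:`DEFAULT_COLUMNS` dialect is assumed.  Gzip compression is handled
    transparently by pandas.
    """
    cmap = dict(DEFAULT_COLUMNS if column_map is None else column_map)
    df = pd.read_csv(path, sep="\t", dtype={"snp": str})
    present = {src: dst for src, dst in cmap.items() if src in df.columns}
    df = df.rename(columns=present)
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s) {missing}; "
            f"file has {list(df.columns)}"
        )
    return SummaryStats(trait_meta, df)


def write_summary_stats(ss: SummaryStats, path) -> None:
    """Write in the canonical tab-separated dialect (round-trips with
    :func:`read_summary_stats`)."""
    out = ss.records.rename(columns={v: k for k, v in DEFAULT_COLUMNS.items()})
    out.to_csv(path, sep="\t", index=False)


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    for a in (effect_allele, other_allele):
        if a not in VALID_BASES:
            raise ValidationError(f"invalid base {a!r}")
    pair = {effect_allele, other_allele}
    return pair == {"A", "T"} or pair == {"C", "G"}


@dataclass
class HarmonizedSet:
    """Exposure(s) and outcome effects aligned to shared effect alleles.

    ``bx``/``sex`` are (k SNPs x L exposures); ``by``/``sey`` length-k
    vectors.  ``nx`` carries per-SNP exposure sample sizes (k x L) and
    ``n_outcome`` the outcome's effective sample size.  ``dropped`` maps each
    discarded variant to the single reason it was discarded.
    """

    exposure_ids: list[str]
    outcome_id: str
    snps: list[str]
    ea: list[str]
    oa: list[str]
    bx: np.ndarray
    sex: np.ndarray
    by: np.ndarray
    sey: np.ndarray
    nx: np.ndarray
    n_outcome: float
    chrom: list = field(default_factory=list)
    pos: list = field(default_factory=list)
    dropped: dict[str, str] = field(default_factory=dict)
    flipped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bx = np.atleast_2d(np.asarray(self.bx, float))
        self.sex = np.atleast_2d(np.asarray(self.sex, float))
        if self.bx.shape[0] == 1 and len(self.snps) != 1:
            self.bx = self.bx.T
            self.sex = self.sex.T
        self.by = np.asarray(self.by, float)
        self.sey = np.asarray(self.sey, float)
        self.nx = np.atleast_2d(np.asarray(self.nx, float))
        if self.nx.shape[0] == 1 and len(self.snps) != 1:
            self.nx = self.nx.T
        k = len(self.snps)
        if not (self.bx.shape[0] == self.sex.shape[0] == len(self.by)
                == len(self.sey) == k):
            raise ValidationError("harmonized arrays have inconsistent row counts")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_exposures(self) -> int:
        return self.bx.shape[1]

    def single(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(bx, sex, by, sey) for a single-exposure set."""
        if self.n_exposures != 1:
            raise ValidationError(
                f"expected a single exposure, set has {self.n_exposures}"
            )
        return self.bx[:, 0], self.sex[:, 0], self.by, self.sey

    def subset(self, keep: np.ndarray, reason: str) -> "HarmonizedSet":
        """New set retaining ``keep`` (boolean mask); removed variants are
        recorded under ``reason``."""
        keep = np.asarray(keep, bool)
        dropped = dict(self.dropped)
        for s, k in zip(self.snps, keep):
            if not k:
                dropped[s] = reason
        idx = np.flatnonzero(keep)
        return HarmonizedSet(
            exposure_ids=list(self.exposure_ids),
            outcome_id=self.outcome_id,
            snps=[self.snps[i] for i in idx],
            ea=[self.ea[i] for i in idx],
            oa=[self.oa[i] for i in idx],
            bx=self.bx[idx],
            sex=self.sex[idx],
            by=self.by[idx],
            sey=self.sey[idx],
            nx=self.nx[idx],
            n_outcome=self.n_outcome,
            chrom=[self.chrom[i] for i in idx] if self.chrom else [],
            pos=[self.pos[i] for i in idx] if self.pos else [],
            dropped=dropped,
            flipped=list(self.flipped),
        )

    def report(self) -> pd.DataFrame:
        """Harmonization report: variant, action {kept, flipped, dropped},
        reason."""
        rows = []
        flipped = set(self.flipped)
        for s in self.snps:
            rows.append(
                {"variant": s,
                 "action": "flipped" if s in flipped else "kept",
                 "reason": ""}
            )
        for s, why in self.dropped.items():
            rows.append({"variant": s, "action": "dropped", "reason": why})
        return pd.DataFrame(rows, columns=["variant", "action", "reason"])


def harmonize(
    exposures: SummaryStats | Sequence[SummaryStats],
    outcome: SummaryStats,
    snps: Iterable[str] | None = None,
) -> HarmonizedSet:
    """Align exposure and outcome effects to shared effect alleles.

    ``snps`` is the candidate instrument list (typically post-clumping);
    by default the first exposure's full SNP list is used.  Per candidate:

    * absent from any dataset                -> dropped, reason ``missing``
    * palindromic in the reference exposure  -> dropped, ``palindromic``
    * alleles swapped in another dataset     -> that beta sign flipped, eaf
      complemented, variant recorded in ``flipped``
    * alleles matching neither orientation   -> dropped, ``allele_mismatch``
    """
    if isinstance(exposures, SummaryStats):
        exposures = [exposures]
    exposures = list(exposures)
    if not exposures:
        raise ValidationError("at least one exposure required")
    idx_exp = [e.indexed() for e in exposures]
    idx_out = outcome.indexed()
    candidates = list(snps) if snps is not None else list(idx_exp[0].index)

    dropped: dict[str, str] = {}
    flipped: list[str] = []
    kept, ea_l, oa_l, chrom_l, pos_l = [], [], [], [], []
    bx_rows, sex_rows, nx_rows, by_l, sey_l = [], [], [], [], []

    def _n_for(ss: SummaryStats, rec) -> float:
        n = rec["n"]
        if pd.notna(n):
            return float(n)
        en = ss.effective_n
        return float(en) if en is not None else np.nan

    for snp in candidates:
        if any(snp not in ix.index for ix in idx_exp) or snp not in idx_out.index:
            dropped[snp] = "missing"
            continue
        ref = idx_exp[0].loc[snp]
        ref_ea, ref_oa = str(ref["ea"]), str(ref["oa"])
        if is_palindromic(ref_ea, ref_oa):
            dropped[snp] = "palindromic"
            continue
        betas, ses, ns = [float(ref["beta"])], [float(ref["se"])], [
            _n_for(exposures[0], ref)
        ]
        ok = True
        was_flipped = False
        others = [(e, ix.loc[snp]) for e, ix in zip(exposures[1:], idx_exp[1:])]
        others.append((outcome, idx_out.loc[snp]))
        for ss, rec in others:
            a, o = str(rec["ea"]), str(rec["oa"])
            if (a, o) == (ref_ea, ref_oa):
                b = float(rec["beta"])
            elif (a, o) == (ref_oa, ref_ea):
                b = -float(rec["beta"])
                was_flipped = True
            else:
                dropped[snp] = "allele_mismatch"
                ok = False
                break
            if ss is outcome:
                by_l.append(b)
                sey_l.append(float(rec["se"]))
            else:
                betas.append(b)
                ses.append(float(rec["se"]))
                ns.append(_n_for(ss, rec))
        if not ok:
            continue
        kept.append(snp)
        ea_l.append(ref_ea)
        oa_l.append(ref_oa)
        chrom_l.append(ref["chrom"])
        pos_l.append(ref["pos"])
        bx_rows.append(betas)
        sex_rows.append(ses)
        nx_rows.append(ns)
        if was_flipped:
            flipped.append(snp)

    if not kept:
        raise HarmonizationError(
            f"no usable instruments shared by {[e.trait_id for e in exposures]} "
            f"and {outcome.trait_id} ({len(dropped)} candidates dropped)"
        )
    n_out = outcome.effective_n
    if n_out is None:
        n_out = float(np.nanmean(idx_out.loc[kept, "n"]))
    return HarmonizedSet(
        exposure_ids=[e.trait_id for e in exposures],
        outcome_id=outcome.trait_id,
        snps=kept,
        ea=ea_l,
        oa=oa_l,
        bx=np.array(bx_rows, float),
        sex=np.array(sex_rows, float),
        by=np.array(by_l, float),
        sey=np.array(sey_l, float),
        nx=np.array(nx_rows, float),
        n_outcome=float(n_out),
        chrom=chrom_l,
        pos=pos_l,
        dropped=dropped,
        flipped=flipped,
    )
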