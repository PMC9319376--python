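"""Hypergeometric pathway over-representation for prioritized metabolites.

Given a pathway annotation of the full metabolite background (one row per
metabolite-pathway membership) and a selected subset, each pathway with K
background members and k selected members out of n selected and N background
metabolites gets the upper-tail probability P(X >= k) under
Hypergeometric(N, K, n).  The observed count is included in the tail (the
standard over-representation convention) and no multiple-testing correction
is applied across pathways.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from scipy import stats

from .errors import ValidationError


class PathwayTable:
    """Metabolite -> pathway (and broad category) annotation."""

    COLUMNS = ("metabolite_id", "pathway", "category")

    def __init__(self, rows: pd.DataFrame):
        missing = [c for c in self.COLUMNS[:2] if c not in rows.columns]
        if missing:
            raise ValidationError(f"annotation table missing columns {missing}")
        df = rows.copy()
        if "category" not in df.columns:
            df["category"] = ""
        self.rows = df[list(self.COLUMNS)].drop_duplicates().reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path) -> "PathwayTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    @property
    def background(self) -> set[str]:
        return set(self.rows["metabolite_id"])

    @property
    def background_size(self) -> int:
        return self.rows["metabolite_id"].nunique()

    def category_of(self, metabolite_id: str) -> str:
        hit = self.rows.loc[self.rows["metabolite_id"] == metabolite_id, "category"]
        return str(hit.iloc[0]) if len(hit) else ""


def hypergeom_enrich(selected: Iterable[str], table: PathwayTable,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Per-pathway over-representation test of ``selected`` against the full
    annotated background.  Returns a frame (pathway, k, K, n, N, p_hyper,
    significant) sorted by p-value."""
    selected = set(selected)
    background = table.background
    stray = selected - background
    if stray:
        raise ValidationError(
            f"selected metabolites absent from background: {sorted(stray)}"
        )
    n_total = table.background_size
    n_sel = len(selected)
    rows = []
    for pathway, members in table.rows.groupby("pathway")["metabolite_id"]:
        mem = set(members)
        big_k = len(mem)
        k = len(mem & selected)
        p = float(stats.hypergeom.sf(k - 1, n_total, big_k, n_sel))
        rows.append({
            "pathway": pathway, "k": k, "K": big_k, "n": n_sel, "N": n_total,
            "p_hyper": p, "significant": p < alpha,
        })
    out = pd.DataFrame(
        rows, columns=["pathway", "k", "K", "n", "N", "p_hyper", "significant"]
    )
    return out.sort_values(["p_hyper", "pathway"], kind="mergesort").reset_index(
        drop=True
    )
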