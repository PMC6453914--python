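"""Cross-group consolidation, Venn partitions, and category-count statistics.

A gene classified in all four analysis groups (MC, FC, MR, FR) may or may
not receive the same inheritance mode in each. Consolidation records full
four-way consistency and applies a majority rule: a gene showing the same
mode in two or more groups is considered to show that mode in the tissue;
a 2-2 tie between two modes is ambiguous. Category counts are compared
with rank tests at the granularity the group tables provide (four group
observations per tissue per category).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .classify import UNCLASSIFIED

GROUP_ORDER = ("MC", "FC", "MR", "FR")


class SummaryError(ValueError):
    pass


def consolidate(calls: pd.DataFrame, groups: Sequence[str] = GROUP_ORDER) -> tuple[pd.DataFrame, dict]:
    """Per-gene cross-group mode agreement and majority-rule assignment.

    ``calls`` holds one row per (gene, group) with a ``mode`` column;
    duplicate (gene, group) pairs are an error. All-zero
    (``unclassified_zero``) calls count as absent. ``assigned_mode`` is the
    mode present in >= 2 groups, ``ambiguous`` on a 2-2 tie, else ``none``.

    Returns the per-gene table plus summary counts: genes consistent in
    all four groups (by mode) and genes assigned by the >=2-group rule.
    """
    if calls.duplicated(subset=["gene_id", "group"]).any():
        dup = calls[calls.duplicated(subset=["gene_id", "group"], keep=False)]
        raise SummaryError(
            f"duplicate (gene, group) calls, e.g. {dup.iloc[0]['gene_id']}/{dup.iloc[0]['group']}"
        )
    wide = (
        calls.pivot(index="gene_id", columns="group", values="mode")
        .reindex(columns=list(groups))
    )
    wide = wide.mask(wide == UNCLASSIFIED)

    records = []
    for gene_id, row in wide.iterrows():
        present = row.dropna()
        vc = present.value_counts()
        consistent = len(present) == len(groups) and len(vc) == 1
        if not vc.empty and vc.iloc[0] >= 2:
            top = vc[vc == vc.iloc[0]]
            assigned = top.index[0] if len(top) == 1 else "ambiguous"
        else:
            assigned = "none"
        rec = {"gene_id": gene_id}
        rec.update({g: row[g] for g in groups})
        rec["consistent_all_four"] = bool(consistent)
        rec["assigned_mode"] = assigned
        records.append(rec)
    table = pd.DataFrame(records).set_index("gene_id")

    consistent_tbl = table[table["consistent_all_four"]]
    summary = {
        "n_genes": int(len(table)),
        "n_consistent_all_four": int(len(consistent_tbl)),
        "consistent_by_mode": consistent_tbl["assigned_mode"].value_counts().to_dict(),
        "assigned_by_mode": table.loc[
            ~table["assigned_mode"].isin(["ambiguous", "none"]), "assigned_mode"
        ].value_counts().to_dict(),
        "n_ambiguous": int((table["assigned_mode"] == "ambiguous").sum()),
    }
    return table, summary


def venn_partition(gene_sets: Mapping[str, set]) -> dict[str, int]:
    """Exclusive region counts of the Venn partition of up to four sets.

    Returns every region (one per non-empty subset of set names, keyed by
    ``"&"``-joined names in input order) with the count of elements
    belonging to exactly those sets. Region counts sum to the union size.
    """
    names = list(gene_sets)
    region_counts: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(gene_sets[n] for n in combo)) if combo else set()
            outside = set.union(set(), *(gene_sets[n] for n in names if n not in combo))
            region_counts["&".join(combo)] = len(inside - outside)
    return region_counts


def test_category_counts(count_tables: Mapping[str, pd.DataFrame]) -> dict:
    """Rank tests on per-group category counts across and within tissues.

    ``count_tables`` maps tissue -> groups x modes count table (as produced
    by :func:`hybmode.classify.classify_all`). Computes a Kruskal-Wallis
    test across tissues on the per-group mis-expressed counts
    (over- + under-dominant; one observation per group), and within each
    tissue a two-sided Mann-Whitney U comparing Cor-dominant vs WL-dominant
    per-group counts. Exact p-values are used at these sample sizes when
    there are no ties.
    """
    if len(count_tables) < 2:
        raise SummaryError("need counts for at least two tissues")
    mis_by_tissue = {}
    for tissue, tbl in count_tables.items():
        for col in ("over_dominant", "under_dominant", "cor_dominant", "wl_dominant"):
            if col not in tbl.columns:
                raise SummaryError(f"count table for {tissue} lacks column {col!r}")
        mis = tbl["over_dominant"] + tbl["under_dominant"]
        if len(mis) < 2:
            raise SummaryError(f"tissue {tissue} has fewer than 2 group observations")
        mis_by_tissue[tissue] = mis.to_numpy()
    kw_stat, kw_p = stats.kruskal(*mis_by_tissue.values())

    dominant = {}
    for tissue, tbl in count_tables.items():
        u, p = stats.mannwhitneyu(
            tbl["cor_dominant"].to_numpy(),
            tbl["wl_dominant"].to_numpy(),
            alternative="two-sided",
            method="auto",
        )
        dominant[tissue] = {"U": float(u), "p_value": float(p)}
    return {
        "misexpressed_kruskal": {"H": float(kw_stat), "p_value": float(kw_p)},
        "dominant_direction_mannwhitney": dominant,
    }


@dataclass(frozen=True)
class DivergenceSummary:
    """Differential-expression summary fractions for one tissue.

    Percentages follow the reporting convention: two decimals for each
    direction, one decimal for the combined divergent fraction.
    """

    tissue: str
    n_detected: int
    n_up: int
    n_down: int
    frac_up: float
    frac_down: float
    frac_total_divergent: float


def summarize_divergence(tissue: str, n_detected: int, n_up: int, n_down: int) -> DivergenceSummary:
    """Up-/down-regulated gene fractions among detected genes."""
    if min(n_detected, n_up, n_down) < 0:
        raise SummaryError("counts must be non-negative")
    if n_up + n_down > n_detected:
        raise SummaryError(
            f"up ({n_up}) + down ({n_down}) exceeds detected ({n_detected}) in {tissue}"
        )
    if n_detected == 0:
        raise SummaryError("no detected genes")
    return DivergenceSummary(
        tissue=tissue,
        n_detected=n_detected,
        n_up=n_up,
        n_down=n_down,
        frac_up=round(100.0 * n_up / n_detected, 2),
        frac_down=round(100.0 * n_down / n_detected, 2),
        frac_total_divergent=round(100.0 * (n_up + n_down) / n_detected, 1),
    )
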