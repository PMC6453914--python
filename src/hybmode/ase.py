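"""Allele-specific expression analysis of dominant genes.

For genes called dominant, the hybrid's two alleles can be counted
separately via breed-diagnostic SNPs. Comparing the Cor/WL allele ratio in
hybrids with the Cor/WL expression ratio of the pure-bred parents
distinguishes cis-driven dominance (allelic imbalance mirrors the parental
ratio) from trans-driven dominance (both alleles expressed alike despite
diverged parents). The analysis splits dominant genes by parental
direction (Cor > WL vs Cor < WL) so opposite-signed ratios cannot cancel,
then fits ordinary least squares of log2 WL-side expression on log2
Cor-side expression in two strata — pure-bred parents and hybrid alleles —
and tests the Pearson correlation of the two log-ratios.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DOMINANT_MODES = ("cor_dominant", "wl_dominant")


class AseError(ValueError):
    pass


@dataclass(frozen=True)
class RegressionFit:
    """One OLS fit of log2(WL) on log2(Cor) plus Pearson statistics."""

    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int
    subset: str  # "Cor>WL" | "Cor<WL"
    stratum: str  # "parents" | "hybrid_alleles"

    def __post_init__(self) -> None:
        if self.n < 3:
            raise AseError(f"regression needs >= 3 genes, got {self.n}")
        if not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise AseError(f"invalid Pearson r {self.pearson_r}")


def scale_factors(
    unit_totals: Mapping[str, float], reference_depth: float | None = None
) -> dict[str, float]:
    """Total-count scale factor per hybrid unit.

    Rescales each unit's counts to a common reference depth (default: the
    mean of the supplied unit totals) so a fixed read cutoff means the
    same coverage in every library.
    """
    totals = dict(unit_totals)
    if any(t <= 0 for t in totals.values()):
        raise AseError("unit totals must be positive")
    if reference_depth is None:
        reference_depth = float(np.mean(list(totals.values())))
    return {u: reference_depth / t for u, t in totals.items()}


def filter_ase(
    ase: pd.DataFrame,
    min_normalized_reads: float = 10.0,
    unit_totals: Mapping[str, float] | None = None,
    *,
    scaling: str = "depth",
) -> pd.DataFrame:
    """Drop genes whose normalized allele-assignable total is below cutoff.

    ``ase`` is tidy (gene_id, unit, cor_count, wl_count, n_snps). With the
    default ``scaling="depth"`` each unit's totals are rescaled to the mean
    unit depth (total-count scaling) before applying the cutoff, so 10
    normalized reads is a depth-equalized coverage floor.
    ``scaling="percent"`` instead scales to percent of the unit's mapped
    reads, matching the percent normalization used for full expression
    profiles. ``unit_totals`` supplies each unit's total mapped reads;
    by default the summed allele counts per unit are used.
    """
    if ase.empty:
        return ase.copy()
    total = ase["cor_count"] + ase["wl_count"]
    if unit_totals is None:
        unit_totals = total.groupby(ase["unit"]).sum().to_dict()
    if scaling == "depth":
        factors = scale_factors(unit_totals)
        norm = total * ase["unit"].map(factors)
    elif scaling == "percent":
        norm = 100.0 * total / ase["unit"].map(dict(unit_totals))
    else:
        raise AseError(f"unknown scaling {scaling!r}")
    kept = ase.loc[norm >= min_normalized_reads].copy()
    logger.info(
        "ASE coverage filter: kept %d / %d gene-unit records", len(kept), len(ase)
    )
    return kept


def split_by_parental_direction(
    dominant_calls: pd.DataFrame,
) -> tuple[set, set]:
    """Partition dominant genes by the sign of Cor - WL parental expression.

    Input rows must all be dominant calls (either direction). Genes with
    exactly equal parental values carry no direction and are excluded with
    a warning.
    """
    bad = set(dominant_calls["mode"]) - set(DOMINANT_MODES)
    if bad:
        raise AseError(f"non-dominant modes in input: {sorted(bad)}")
    diff = dominant_calls["p_cor"] - dominant_calls["p_wl"]
    cor_gt = set(dominant_calls.loc[diff > 0, "gene_id"])
    cor_lt = set(dominant_calls.loc[diff < 0, "gene_id"])
    n_tied = int((diff == 0).sum())
    if n_tied:
        logger.warning("%d dominant gene(s) with p_cor == p_wl excluded from direction split", n_tied)
    return cor_gt, cor_lt


def _ols_log2(x: np.ndarray, y: np.ndarray, subset: str, stratum: str) -> RegressionFit:
    res = stats.linregress(np.log2(x), np.log2(y))
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=len(x),
        subset=subset,
        stratum=stratum,
    )


def ase_regression(
    parent_profile: pd.DataFrame,
    ase: pd.DataFrame,
    subset: Iterable,
    *,
    cor_unit: str = "Cor_M",
    wl_unit: str = "WL_M",
    subset_label: str = "Cor>WL",
) -> dict:
    """Parent-stratum and allele-stratum log-log fits plus a ratio correlation.

    Parameters
    ----------
    parent_profile
        Percent-expression frame containing ``cor_unit`` and ``wl_unit``
        columns (one sex's parental units).
    ase
        Allele counts for one hybrid unit (tidy frame; one row per gene).
    subset
        Gene ids to analyse (e.g. one direction of the dominant split).

    Returns a dict with two :class:`RegressionFit` entries (``parents``,
    ``hybrid_alleles``), the Pearson correlation between
    log2(parental Cor/WL) and log2(allelic Cor/WL) with its p-value, the
    number of genes used and the number dropped for zeros.

    Genes with a zero on any required side are excluded from the log-scale
    fits (no pseudocounts); fewer than 3 usable genes is an error.
    """
    subset = set(subset)
    ase_g = ase.drop_duplicates("gene_id").set_index("gene_id")
    genes = [g for g in parent_profile.index if g in subset and g in ase_g.index]
    if not genes:
        raise AseError("no genes shared between subset, profile and ASE table")
    pc = parent_profile.loc[genes, cor_unit].to_numpy(dtype=float)
    pw = parent_profile.loc[genes, wl_unit].to_numpy(dtype=float)
    ac = ase_g.loc[genes, "cor_count"].to_numpy(dtype=float)
    aw = ase_g.loc[genes, "wl_count"].to_numpy(dtype=float)
    usable = (pc > 0) & (pw > 0) & (ac > 0) & (aw > 0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("dropped %d gene(s) with zero values from log-scale fits", n_dropped)
    pc, pw, ac, aw = pc[usable], pw[usable], ac[usable], aw[usable]
    if len(pc) < 3:
        raise AseError(f"only {len(pc)} usable genes (need >= 3)")

    parents = _ols_log2(pc, pw, subset_label, "parents")
    alleles = _ols_log2(ac, aw, subset_label, "hybrid_alleles")
    with warnings.catch_warnings():
        # a perfectly trans regime yields a constant allele log-ratio; the
        # nan result is mapped to r=0 below, so the warning is expected
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        warnings.simplefilter("ignore", stats.NearConstantInputWarning)
        r, p = stats.pearsonr(np.log2(pc / pw), np.log2(ac / aw))
    # a constant log-ratio vector (e.g. a perfectly trans regime where every
    # allele ratio is exactly 1) has no defined correlation
    if math.isnan(r):
        r, p = 0.0, 1.0
    return {
        "parents": parents,
        "hybrid_alleles": alleles,
        "ratio_pearson_r": float(r),
        "ratio_pearson_p": float(p),
        "n": int(len(pc)),
        "n_dropped_zero": n_dropped,
        "subset": subset_label,
    }


def fits_to_json(result: dict) -> dict:
    """JSON-serialisable view of an :func:`ase_regression` result."""
    out = dict(result)
    for key in ("parents", "hybrid_alleles"):
        out[key] = asdict(out[key])
    return out
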