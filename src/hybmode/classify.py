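"""Six-way inheritance-mode classification under the 1.25-fold rule.

A hybrid expression value is *similar* to a parental value when their
symmetric ratio max/min falls below 1.25 (strictly; the boundary counts as
dissimilar). The hybrid's relation to its two parents then determines the
mode: similar to both -> conserved; similar to exactly one -> Cor- or
WL-dominant; similar to neither and strictly between -> additive; above
both -> over-dominant; below both -> under-dominant. The symmetric linear
ratio is equivalent to a |log fold| >= log(1.25) cut on log-transformed
percentages and sidesteps log-of-zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

CLASS_MODES = (
    "conserved",
    "additive",
    "cor_dominant",
    "wl_dominant",
    "over_dominant",
    "under_dominant",
)
UNCLASSIFIED = "unclassified_zero"
DEFAULT_THRESHOLD = 1.25


@dataclass(frozen=True)
class GroupDesign:
    """One analysis group: a parent pair and one hybrid unit of one sex.

    The four canonical groups pair the sex-matched pure-bred units with
    each reciprocal hybrid: MC/FC use CL (Cor male x WL female), MR/FR use
    LC (WL male x Cor female).
    """

    name: str
    cor_unit: str
    wl_unit: str
    hybrid_unit: str
    sex: str

    @property
    def units(self) -> tuple[str, str, str]:
        return (self.cor_unit, self.wl_unit, self.hybrid_unit)


DEFAULT_DESIGNS = (
    GroupDesign("MC", "Cor_M", "WL_M", "CL_M", "M"),
    GroupDesign("FC", "Cor_F", "WL_F", "CL_F", "F"),
    GroupDesign("MR", "Cor_M", "WL_M", "LC_M", "M"),
    GroupDesign("FR", "Cor_F", "WL_F", "LC_F", "F"),
)


def fold_ratio(a: float, b: float) -> float:
    """Symmetric fold ratio max(a,b)/min(a,b) of two non-negative values.

    Two zeros are maximally similar (ratio 1); a single zero is maximally
    dissimilar (+inf).
    """
    if a < 0 or b < 0:
        raise ValueError(f"expression values must be non-negative, got ({a}, {b})")
    if a == 0.0 and b == 0.0:
        return 1.0
    if a == 0.0 or b == 0.0:
        return math.inf
    return a / b if a >= b else b / a


def classify_gene(
    p_cor: float,
    p_wl: float,
    h: float,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    boundary_similar: bool = False,
) -> str:
    """Assign one inheritance mode from (Cor parent, WL parent, hybrid).

    ``boundary_similar`` controls whether a ratio exactly at the threshold
    counts as similar (default: dissimilar, i.e. similarity is strict
    ``ratio < threshold``).
    """
    if threshold <= 1.0:
        raise ValueError(f"threshold must exceed 1, got {threshold}")
    if p_cor < 0 or p_wl < 0 or h < 0:
        raise ValueError("expression values must be non-negative")
    if p_cor == 0.0 and p_wl == 0.0 and h == 0.0:
        return UNCLASSIFIED

    def similar(x: float, y: float) -> bool:
        r = fold_ratio(x, y)
        return r <= threshold if boundary_similar else r < threshold

    sim_cor = similar(h, p_cor)
    sim_wl = similar(h, p_wl)
    if sim_cor and sim_wl:
        return "conserved"
    if sim_cor:
        return "cor_dominant"
    if sim_wl:
        return "wl_dominant"
    lo, hi = min(p_cor, p_wl), max(p_cor, p_wl)
    if lo < h < hi:
        return "additive"
    if h > hi:
        return "over_dominant"
    return "under_dominant"


def classify_all(
    profile: pd.DataFrame,
    designs: tuple[GroupDesign, ...] = DEFAULT_DESIGNS,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    boundary_similar: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every gene in every analysis group.

    Parameters
    ----------
    profile
        Percent-expression frame (genes x breed-sex units) from
        :func:`hybmode.preprocess.make_profile`.
    designs
        Groups to classify; each must reference existing profile columns.

    Returns
    -------
    calls, counts
        ``calls``: one row per (gene, group) with the mode, the three
        percent values and both hybrid-parent fold ratios. ``counts``:
        groups x modes table of classifiable genes; all-zero
        (``unclassified_zero``) calls are excluded from the counts, so a
        group's row sums to its number of classifiable genes.
    """
    for d in designs:
        missing = [u for u in d.units if u not in profile.columns]
        if missing:
            raise KeyError(f"profile lacks unit column(s) {missing} needed by group {d.name}")
    rows = []
    for d in designs:
        pc = profile[d.cor_unit].to_numpy()
        pw = profile[d.wl_unit].to_numpy()
        ph = profile[d.hybrid_unit].to_numpy()
        for gid, c, w, h in zip(profile.index, pc, pw, ph):
            mode = classify_gene(c, w, h, threshold, boundary_similar=boundary_similar)
            rows.append(
                {
                    "gene_id": gid,
                    "group": d.name,
                    "mode": mode,
                    "p_cor": c,
                    "p_wl": w,
                    "h": h,
                    "fold_h_cor": fold_ratio(h, c),
                    "fold_h_wl": fold_ratio(h, w),
                }
            )
    calls = pd.DataFrame(rows)
    classifiable = calls[calls["mode"] != UNCLASSIFIED]
    counts = (
        classifiable.pivot_table(index="group", columns="mode", values="gene_id", aggfunc="count")
        .reindex(index=[d.name for d in designs], columns=list(CLASS_MODES))
        .fillna(0)
        .astype(int)
    )
    counts.columns.name = "mode"
    return calls, counts
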