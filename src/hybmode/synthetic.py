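"""Synthetic data with known ground truth for the hybrid-expression pipeline.

Emulates a reciprocal-cross RNA-seq design between two chicken breeds,
Cornish (Cor, a broiler) and White Leghorn (WL, a layer): pure-bred
offspring groups CC (Cor x Cor) and CW (WL x WL), and reciprocal F1
hybrids CL (Cor male x WL female) and LC (WL male x Cor female), each with
three replicates per sex. Counts are negative-binomial around per-gene
expected abundances constructed so that each gene realises a known
inheritance mode (conserved / additive / Cor-dominant / WL-dominant /
over-dominant / under-dominant) with a configurable safety margin from the
1.25-fold decision boundary. Hybrid allele-specific counts are binomial
splits of informative reads driven by a per-gene cis-ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import CountMatrix

MODES = (
    "conserved",
    "additive",
    "cor_dominant",
    "wl_dominant",
    "over_dominant",
    "under_dominant",
)

CROSSES = ("CC", "CW", "CL", "LC")
SEXES = ("M", "F")

#: default mixture, loosely shaped like the brain classification results
DEFAULT_MODE_PROPORTIONS = {
    "conserved": 0.55,
    "additive": 0.05,
    "cor_dominant": 0.14,
    "wl_dominant": 0.10,
    "over_dominant": 0.08,
    "under_dominant": 0.08,
}


class SimConfigError(ValueError):
    """Raised for an invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic reciprocal-cross experiment.

    Attributes
    ----------
    n_genes
        Number of simulated genes.
    mode_proportions
        Mixture over the six inheritance modes; must sum to 1.
    n_replicates
        Biological replicates per (cross, sex) group; the emulated design
        uses 3.
    mean_log2_expression, sd_log2_expression
        Log-normal parameters of per-gene baseline abundance (arbitrary
        relative units; only ratios matter after total-count scaling).
    parental_log2_divergence
        Typical log2 Cor/WL effect size for dominant genes; the bulk of
        parental divergence stays below 2-fold, as observed between these
        breeds.
    nb_dispersion
        Negative-binomial size parameter shared across genes
        (variance = m + m^2/size); large values approach Poisson.
    library_size
        Expected total reads per sample.
    frac_z_linked
        Fraction of genes placed on the Z chromosome.
    frac_all_zero
        Fraction of genes that are silent in every sample.
    cis_fraction
        Fraction of dominant genes whose hybrid allelic ratio mirrors the
        parental ratio (cis-driven); the rest are trans-like with equal
        allelic expression.
    snps_per_gene
        Poisson mean of informative (breed-diagnostic) SNPs per gene;
        genes drawing 0 produce no allele-specific counts.
    ase_capture
        Fraction of a gene's hybrid reads that overlap an informative SNP
        and are therefore allele-assignable.
    conserved_margin
        Conserved genes keep all pairwise expected ratios at or below this
        (default 1.1, safely inside the 1.25 threshold).
    nonconserved_margin
        Non-similar hybrid-parent contrasts are at least this fold
        (default 1.5, safely outside 1.25).
    tissue
        Tissue label stamped on every sample.
    seed
        Master seed; all stage generators derive from it.
    """

    n_genes: int = 15000
    mode_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MODE_PROPORTIONS)
    )
    n_replicates: int = 3
    mean_log2_expression: float = 8.0
    sd_log2_expression: float = 1.5
    parental_log2_divergence: float = 0.8
    nb_dispersion: float = 100.0
    library_size: int = 5_000_000
    frac_z_linked: float = 0.04
    frac_all_zero: float = 0.02
    cis_fraction: float = 0.5
    snps_per_gene: float = 2.5
    ase_capture: float = 0.25
    conserved_margin: float = 1.1
    nonconserved_margin: float = 1.5
    tissue: str = "brain"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_replicates <= 0 or self.library_size <= 0:
            raise SimConfigError("n_genes, n_replicates and library_size must be positive")
        unknown = set(self.mode_proportions) - set(MODES)
        if unknown:
            raise SimConfigError(f"unknown modes in mode_proportions: {sorted(unknown)}")
        props = [self.mode_proportions.get(m, 0.0) for m in MODES]
        if any(p < 0 for p in props):
            raise SimConfigError("mode_proportions must be non-negative")
        if abs(sum(props) - 1.0) > 1e-9:
            raise SimConfigError(f"mode_proportions must sum to 1, got {sum(props)}")
        for name in ("sd_log2_expression", "parental_log2_divergence", "nb_dispersion"):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be strictly positive")
        for name in ("frac_z_linked", "frac_all_zero", "cis_fraction", "ase_capture"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1]")
        if self.snps_per_gene < 0:
            raise SimConfigError("snps_per_gene must be non-negative")
        if not 1.0 <= self.conserved_margin < 1.25:
            raise SimConfigError("conserved_margin must lie in [1, 1.25)")
        if self.nonconserved_margin <= 1.25:
            raise SimConfigError("nonconserved_margin must exceed 1.25")

    def rng(self, stage: int) -> np.random.Generator:
        """Deterministic generator for a pipeline stage (0=truth, 1=counts, 2=ase...)."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stage,))
        )


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated gene.

    ``mu_*`` are expected relative abundances (pre library scaling);
    ``cis_ratio`` is the expected Cor-allele / WL-allele ratio in hybrids.
    """

    gene_id: str
    true_mode: str  # one of MODES or "all_zero"
    mu_cor: float
    mu_wl: float
    mu_hybrid: float
    cis_ratio: float
    chromosome_class: str  # "autosome" | "Z"
    n_snps: int


def _sym_jitter(rng: np.random.Generator, max_ratio: float, size: int) -> np.ndarray:
    """Multiplicative jitter with any pairwise ratio of two draws <= max_ratio."""
    half = math.sqrt(max_ratio)
    return np.exp(rng.uniform(-math.log(half), math.log(half), size=size))


def simulate_truth(config: SimConfig) -> list[SimTruth]:
    """Draw per-gene ground truth: mode, expected abundances, cis-ratio.

    Expected abundances respect the mode definitions with a safety margin:
    non-similar hybrid-parent contrasts are at least ``nonconserved_margin``
    fold, similar contrasts at most ``conserved_margin`` fold. For additive
    genes the hybrid sits at the arithmetic mid-parent, which forces a
    parental divergence of at least ``2*m - 1`` and ``m/(2-m)`` fold for a
    margin ``m``.
    """
    rng = config.rng(0)
    n = config.n_genes
    m = config.nonconserved_margin
    cm = config.conserved_margin

    base = np.exp2(rng.normal(config.mean_log2_expression, config.sd_log2_expression, n))
    modes = rng.choice(MODES, size=n, p=[config.mode_proportions.get(k, 0.0) for k in MODES])
    n_zero = int(round(config.frac_all_zero * n))
    zero_idx = set(rng.choice(n, size=n_zero, replace=False).tolist())
    is_z = rng.random(n) < config.frac_z_linked
    n_snps = rng.poisson(config.snps_per_gene, size=n)
    width = max(1, int(math.log10(max(n, 1))) + 1)

    # margin windows for dissimilar contrasts; ~1.05 head-room above the margin
    lo_fold = math.log2(1.05 * m)
    hi_fold = config.parental_log2_divergence + 0.5
    hi_fold = max(hi_fold, lo_fold + 0.1)
    # additive genes need wider parent-parent spread for mid-parent margins
    add_lo = math.log2(1.05 * max(2 * m - 1, m / (2 - m)))
    add_hi = add_lo + 1.0

    out: list[SimTruth] = []
    for i in range(n):
        gid = f"g{i + 1:0{width}d}"
        chrom_class = "Z" if is_z[i] else "autosome"
        if i in zero_idx:
            out.append(SimTruth(gid, "all_zero", 0.0, 0.0, 0.0, 1.0, chrom_class, int(n_snps[i])))
            continue
        mode = str(modes[i])
        mu = float(base[i])
        sign = 1.0 if rng.random() < 0.5 else -1.0
        if mode == "conserved":
            j = _sym_jitter(rng, cm, 2)
            cor, wl, hyb = mu, mu * float(j[0]), mu * float(j[1])
        elif mode == "additive":
            d = 2.0 ** (sign * rng.uniform(add_lo, add_hi))
            cor, wl = mu, mu * d
            hyb = 0.5 * (cor + wl)
        elif mode in ("cor_dominant", "wl_dominant"):
            d = 2.0 ** (sign * rng.uniform(lo_fold, hi_fold))
            cor, wl = mu, mu * d
            near = cor if mode == "cor_dominant" else wl
            hyb = near * float(_sym_jitter(rng, cm, 1)[0])
        elif mode == "over_dominant":
            d = 2.0 ** (sign * rng.uniform(0.0, config.parental_log2_divergence))
            cor, wl = mu, mu * d
            hyb = max(cor, wl) * 2.0 ** rng.uniform(lo_fold, lo_fold + 0.6)
        else:  # under_dominant
            d = 2.0 ** (sign * rng.uniform(0.0, config.parental_log2_divergence))
            cor, wl = mu, mu * d
            hyb = min(cor, wl) / 2.0 ** rng.uniform(lo_fold, lo_fold + 0.6)
        cis = 1.0
        if mode in ("cor_dominant", "wl_dominant") and rng.random() < config.cis_fraction:
            cis = cor / wl
        out.append(SimTruth(gid, mode, cor, wl, hyb, cis, chrom_class, int(n_snps[i])))
    return out


def _expected_means(truth: list[SimTruth], cross: str, library_size: int) -> np.ndarray:
    mu_key = {"CC": "mu_cor", "CW": "mu_wl", "CL": "mu_hybrid", "LC": "mu_hybrid"}[cross]
    mus = np.array([getattr(t, mu_key) for t in truth], dtype=float)
    total = mus.sum()
    if total == 0:
        raise SimConfigError("all simulated genes are silent; cannot scale to library size")
    return mus / total * library_size


def simulate_counts(truth: list[SimTruth], config: SimConfig) -> CountMatrix:
    """Negative-binomial read counts for every (cross, sex, replicate) sample.

    Expected counts are each gene's abundance for that cross, rescaled so
    the sample's expected total equals ``library_size``. The same seed
    always yields the identical matrix.
    """
    if not truth:
        raise SimConfigError("truth must be non-empty")
    rng = config.rng(1)
    gene_ids = [t.gene_id for t in truth]
    k = config.nb_dispersion

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for cross in CROSSES:
        means = _expected_means(truth, cross, config.library_size)
        for sex in SEXES:
            for rep in range(1, config.n_replicates + 1):
                name = f"{cross}_{sex}_{rep}"
                p = k / (k + np.where(means > 0, means, 1.0))
                draw = rng.negative_binomial(k, p)
                draw[means == 0] = 0
                cols[name] = draw
                meta_rows.append(
                    {"sample": name, "cross": cross, "sex": sex,
                     "tissue": config.tissue, "replicate": rep}
                )
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    samples = pd.DataFrame(meta_rows).set_index("sample")
    gene_chrom = pd.Series(
        ["Z" if t.chromosome_class == "Z" else "1" for t in truth],
        index=counts.index, name="chrom",
    )
    return CountMatrix(counts=counts, samples=samples, gene_chrom=gene_chrom)


def simulate_ase(
    truth: list[SimTruth], hybrid_counts: CountMatrix, config: SimConfig
) -> pd.DataFrame:
    """Allele-specific counts for hybrid genes covered by informative SNPs.

    For each hybrid unit (cross x sex), a gene's allele-assignable total is
    a binomial ``ase_capture`` thinning of its summed replicate counts; the
    Cor-allele count is then binomial with success probability
    ``cis_ratio / (1 + cis_ratio)``. Genes whose SNP draw is 0 are absent.

    Returns a tidy frame with columns
    ``gene_id, unit, cor_count, wl_count, n_snps``.
    """
    rng = config.rng(2)
    hyb_samples = hybrid_counts.samples[hybrid_counts.samples["cross"].isin(["CL", "LC"])]
    if hyb_samples.empty:
        raise SimConfigError("no hybrid (CL/LC) samples in count matrix")
    by_gene = {t.gene_id: t for t in truth}
    rows = []
    for (cross, sex), grp in hyb_samples.groupby(["cross", "sex"], sort=True):
        unit = f"{cross}_{sex}"
        totals = hybrid_counts.counts[grp.index.tolist()].sum(axis=1)
        for gid, total in totals.items():
            t = by_gene[gid]
            if t.n_snps == 0:
                continue
            informative = int(rng.binomial(int(total), config.ase_capture))
            p_cor = t.cis_ratio / (1.0 + t.cis_ratio)
            cor = int(rng.binomial(informative, p_cor))
            rows.append(
                {"gene_id": gid, "unit": unit, "cor_count": cor,
                 "wl_count": informative - cor, "n_snps": t.n_snps}
            )
    return pd.DataFrame(rows, columns=["gene_id", "unit", "cor_count", "wl_count", "n_snps"])


def truth_frame(truth: list[SimTruth]) -> pd.DataFrame:
    """Tabular view of the ground truth, indexed by gene."""
    return pd.DataFrame([t.__dict__ for t in truth]).set_index("gene_id")


def low_noise_config(n_genes: int = 10000, seed: int = 0, **overrides) -> SimConfig:
    """A tight-noise configuration used for mode-recovery checks.

    Deep libraries and near-Poisson dispersion keep the coefficient of
    variation of group means well under 5%, so expected abundances built
    with the default margins sit several standard errors from the
    1.25-fold boundary.
    """
    cfg = SimConfig(
        n_genes=n_genes,
        library_size=20_000_000,
        nb_dispersion=10_000.0,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# toy variant / reference generation for the pseudo-genome stage


def simulate_variants(
    seed: int = 0,
    chrom_lengths: dict[str, int] | None = None,
    n_snps: int = 50,
    mean_depth: float = 20.0,
):
    """Toy reference sequences plus breed-diagnostic SNPs with read depths.

    Returns ``(reference, snps)`` where ``reference`` maps chromosome name
    to sequence and ``snps`` is a list of
    :class:`hybmode.pseudogenome.SnpRecord`. Depths are Poisson around
    ``mean_depth`` so a realistic fraction falls below the >10-read filter.
    Chromosome "Z" exercises the relaxed Z-linked depth threshold.
    """
    from .pseudogenome import SnpRecord

    if chrom_lengths is None:
        chrom_lengths = {"1": 1000, "2": 800, "Z": 600}
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(3,)))
    bases = np.array(list("ACGT"))
    reference = {
        chrom: "".join(rng.choice(bases, size=length))
        for chrom, length in chrom_lengths.items()
    }
    total_len = sum(chrom_lengths.values())
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float) / total_len
    positions: set[tuple[str, int]] = set()
    snps = []
    while len(snps) < n_snps:
        chrom = str(rng.choice(chroms, p=weights))
        pos = int(rng.integers(1, chrom_lengths[chrom] + 1))
        if (chrom, pos) in positions:
            continue
        positions.add((chrom, pos))
        ref = reference[chrom][pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        snps.append(
            SnpRecord(
                chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
                depth_cor=int(rng.poisson(mean_depth)),
                depth_wl=int(rng.poisson(mean_depth)),
                chromosome_class="Z" if chrom == "Z" else "autosome",
            )
        )
    snps.sort(key=lambda s: (s.chrom, s.pos))
    return reference, snps
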