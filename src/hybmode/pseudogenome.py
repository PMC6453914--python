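"""Breed pseudo-genome construction: depth-filter SNPs, substitute into a reference.

Breed-diagnostic SNPs reduce mapping bias when hybrid reads are aligned:
substituting each breed's alleles into the reference yields parental
pseudo-genomes. SNPs are retained only when supported by more than 10
reads in each parental breed; on the Z chromosome, where effective depth
is lower (females carry a single Z), the cutoff relaxes to more than 4
reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")


class ReferenceMismatchError(ValueError):
    """Reference base at a SNP position does not match the record's ref allele."""


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNV with per-breed supporting read depth.

    ``pos`` is 1-based (VCF convention); ``chromosome_class`` marks
    Z-linked sites that use the relaxed depth threshold. ``gt_cor`` /
    ``gt_wl`` optionally carry the breed genotypes (``ref``/``alt``/``het``)
    when parsed from a VCF with genotype columns.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    depth_cor: int
    depth_wl: int
    chromosome_class: str = "autosome"
    gt_cor: str | None = None
    gt_wl: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_allele not in _VALID_BASES or self.alt_allele not in _VALID_BASES:
            raise ValueError(
                f"alleles must be single bases in ACGT, got "
                f"{self.ref_allele!r}/{self.alt_allele!r} at {self.chrom}:{self.pos}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles are identical at {self.chrom}:{self.pos}")
        if self.depth_cor < 0 or self.depth_wl < 0:
            raise ValueError("read depths must be non-negative")


@dataclass(frozen=True)
class DepthThresholds:
    """Exclusive minimum read depth per breed, by chromosome class."""

    autosome_min_exclusive: int = 10
    z_min_exclusive: int = 4

    def __post_init__(self) -> None:
        if self.autosome_min_exclusive < 0 or self.z_min_exclusive < 0:
            raise ValueError("depth thresholds must be non-negative")

    def for_class(self, chromosome_class: str) -> int:
        return self.z_min_exclusive if chromosome_class == "Z" else self.autosome_min_exclusive


def filter_snps(
    snps: list[SnpRecord], thresholds: DepthThresholds = DepthThresholds()
) -> list[SnpRecord]:
    """Keep SNPs strictly exceeding the depth threshold in *both* breeds.

    The comparison is strictly greater-than: an autosomal site at depth 10
    is rejected. Input order is preserved.
    """
    return [
        s
        for s in snps
        if s.depth_cor > thresholds.for_class(s.chromosome_class)
        and s.depth_wl > thresholds.for_class(s.chromosome_class)
    ]


def substitute_variants(
    reference: dict[str, str],
    snps: list[SnpRecord],
    *,
    check_ref: bool = True,
) -> dict[str, str]:
    """Substitute alternate alleles into reference sequences.

    Sequences differ from the input exactly at the SNP positions and keep
    their lengths. With ``check_ref`` (default), a mismatch between the
    reference base and a record's ref allele raises
    :class:`ReferenceMismatchError` naming the site, which also makes
    accidental double-substitution loud.
    """
    editable = {chrom: bytearray(seq, "ascii") for chrom, seq in reference.items()}
    for s in snps:
        if s.chrom not in editable:
            raise KeyError(f"SNP chromosome {s.chrom!r} absent from reference")
        seq = editable[s.chrom]
        if s.pos > len(seq):
            raise IndexError(
                f"SNP position {s.chrom}:{s.pos} beyond sequence length {len(seq)}"
            )
        current = chr(seq[s.pos - 1]).upper()
        if check_ref and current != s.ref_allele:
            raise ReferenceMismatchError(
                f"reference has {current!r} at {s.chrom}:{s.pos}, "
                f"expected {s.ref_allele!r}"
            )
        seq[s.pos - 1] = ord(s.alt_allele)
    return {chrom: seq.decode("ascii") for chrom, seq in editable.items()}


def select_breed_snps(snps: list[SnpRecord], breed: str) -> list[SnpRecord]:
    """SNPs to substitute for one breed's pseudo-genome.

    Keeps sites where the breed is homozygous for the alternate allele.
    Heterozygous sites are skipped (a single sequence cannot carry both
    alleles) with a logged count. Records without genotype information are
    kept as-is: a genotype-less table is assumed already breed-specific.
    """
    if breed not in ("cor", "wl"):
        raise ValueError(f"breed must be 'cor' or 'wl', got {breed!r}")
    attr = "gt_cor" if breed == "cor" else "gt_wl"
    kept, n_het = [], 0
    for s in snps:
        gt = getattr(s, attr)
        if gt is None or gt == "alt":
            kept.append(s)
        elif gt == "het":
            n_het += 1
    if n_het:
        logger.warning("skipped %d heterozygous %s sites during substitution", n_het, breed)
    return kept
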