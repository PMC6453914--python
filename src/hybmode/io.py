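"""Plain-text I/O: TSV count matrices and profiles, FASTA, VCF SNP tables."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .preprocess import CountMatrix, PreprocessError
from .pseudogenome import SnpRecord

logger = logging.getLogger(__name__)


# --- count matrices ---------------------------------------------------------

def write_counts_tsv(matrix: CountMatrix, counts_path, annotation_path=None) -> None:
    """Write counts as TSV (gene_id + one column per sample) and, optionally,
    a two-column gene annotation TSV (gene_id, chrom)."""
    matrix.counts.to_csv(counts_path, sep="\t")
    if annotation_path is not None:
        matrix.gene_chrom.rename("chrom").to_csv(annotation_path, sep="\t")


def parse_sample_name(name: str) -> dict:
    """Parse a `CROSS_SEX_REP` column name, e.g. ``CC_M_1``."""
    parts = name.split("_")
    if len(parts) != 3 or parts[0] not in {"CC", "CW", "CL", "LC"} or parts[1] not in {"M", "F"}:
        raise PreprocessError(
            f"sample column {name!r} is not of the form CROSS_SEX_REP (e.g. CC_M_1)"
        )
    return {"cross": parts[0], "sex": parts[1], "replicate": int(parts[2])}


def read_counts_tsv(counts_path, annotation_path, tissue: str = "unknown") -> CountMatrix:
    """Read a counts TSV plus gene annotation TSV into a :class:`CountMatrix`.

    Sample metadata is recovered from the column naming convention
    ``CROSS_SEX_REP``.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index.name = "gene_id"
    ann = pd.read_csv(annotation_path, sep="\t", index_col=0)
    if "chrom" not in ann.columns:
        raise PreprocessError("annotation TSV must have columns gene_id, chrom")
    meta = pd.DataFrame(
        [dict(sample=c, tissue=tissue, **parse_sample_name(c)) for c in counts.columns]
    ).set_index("sample")
    gene_chrom = ann["chrom"].reindex(counts.index)
    return CountMatrix(counts=counts, samples=meta, gene_chrom=gene_chrom)


# --- FASTA ------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# --- VCF SNP tables ---------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DPC,Number=1,Type=Integer,Description="Supporting read depth in Cornish">
##INFO=<ID=DPW,Number=1,Type=Integer,Description="Supporting read depth in White Leghorn">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_snps_vcf(snps: list[SnpRecord], path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write breed-diagnostic SNPs as an uncompressed VCF 4.2 table.

    Per-breed supporting depths travel in the INFO fields ``DPC``/``DPW``.
    """
    lines = ["##fileformat=VCFv4.2"]
    if contig_lengths:
        lines += [f"##contig=<ID={c},length={n}>" for c, n in contig_lengths.items()]
    lines += _VCF_HEADER.splitlines()[1:]
    for s in snps:
        lines.append(
            f"{s.chrom}\t{s.pos}\t.\t{s.ref_allele}\t{s.alt_allele}\t.\tPASS\t"
            f"DPC={s.depth_cor};DPW={s.depth_wl}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _classify_gt(gt_type: int) -> str | None:
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    return {0: "ref", 1: "het", 3: "alt"}.get(gt_type)


def read_snps_vcf(
    path,
    z_chroms: frozenset[str] = frozenset({"Z", "chrZ", "z"}),
    cor_sample: str = "COR",
    wl_sample: str = "WL",
) -> list[SnpRecord]:
    """Read biallelic SNVs from a VCF into :class:`SnpRecord` objects.

    Per-breed depths come from INFO ``DPC``/``DPW`` when present, otherwise
    from per-sample FORMAT ``DP`` of the named breed samples. Indels and
    multi-allelic records are skipped with a logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_idx = {name: i for i, name in enumerate(vcf.samples)}
    snps: list[SnpRecord] = []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        if v.REF not in "ACGT" or v.ALT[0] not in "ACGT":
            n_skipped += 1
            continue
        dpc, dpw = v.INFO.get("DPC"), v.INFO.get("DPW")
        gt_cor = gt_wl = None
        if dpc is None or dpw is None:
            if cor_sample not in sample_idx or wl_sample not in sample_idx:
                raise ValueError(
                    "VCF lacks DPC/DPW INFO fields and breed samples "
                    f"{cor_sample!r}/{wl_sample!r}"
                )
            depths = v.format("DP")
            if depths is None:
                raise ValueError(f"no DP FORMAT field at {v.CHROM}:{v.POS}")
            dpc = int(depths[sample_idx[cor_sample]][0])
            dpw = int(depths[sample_idx[wl_sample]][0])
            gt_cor = _classify_gt(int(v.gt_types[sample_idx[cor_sample]]))
            gt_wl = _classify_gt(int(v.gt_types[sample_idx[wl_sample]]))
        snps.append(
            SnpRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref_allele=v.REF,
                alt_allele=v.ALT[0],
                depth_cor=int(dpc),
                depth_wl=int(dpw),
                chromosome_class="Z" if v.CHROM in z_chroms else "autosome",
                gt_cor=gt_cor,
                gt_wl=gt_wl,
            )
        )
    if n_skipped:
        logger.warning("skipped %d non-biallelic-SNV record(s) while reading VCF", n_skipped)
    return snps
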