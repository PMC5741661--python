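"""File I/O for standard formats and the variant-level genotype filters.

Readers convert VCF/GFF3 1-based coordinates into the internal 0-based
half-open convention at the boundary. The site and per-genotype filters
implement the QC rules used for RNA-seq-derived SNP calls: site mapping
quality, depth and quality all >= 30, biallelic, > 3 bp from any indel;
homozygous calls need > 3 supporting reads and SNP quality > 20,
heterozygous calls need >= 2 reads per allele and genotype quality > 20.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    ExpressionTable,
    GeneAnnotation,
    GenotypeTable,
    RawVariantCall,
    Region,
)


class VcfParseError(ValueError):
    pass


def read_vcf(path, region_filter: Optional[Region] = None, strict: bool = True) -> GenotypeTable:
    """Read a VCF 4.x into a :class:`GenotypeTable`.

    GT codes map 0/0 -> 0, 0/1 -> 1, 1/1 -> 2, ./. -> MISSING. Fully phased
    files (``|`` separators) populate the haplotype tensor. Multiallelic
    records raise under ``strict``; otherwise they are skipped.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    chroms, pos, vids, rows, hap_rows = [], [], [], [], []
    all_phased = True
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            if strict:
                raise VcfParseError(
                    f"non-biallelic record at line {i + 1} ({var.CHROM}:{var.POS})"
                )
            continue
        if region_filter is not None:
            p0 = var.POS - 1
            if (
                var.CHROM != region_filter.chrom
                or p0 < region_filter.start
                or p0 >= region_filter.end
            ):
                continue
        gt = np.asarray(var.gt_types, dtype=np.int8)  # 0,1,2 hom/het/alt; 3 unknown
        gt[gt == 3] = MISSING
        chroms.append(var.CHROM)
        pos.append(var.POS)
        vids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        rows.append(gt)
        geno = np.asarray(var.genotypes, dtype=object)
        phased = all(bool(g[-1]) for g in var.genotypes)
        all_phased = all_phased and phased
        hap = np.full((len(samples), 2), MISSING, dtype=np.int8)
        for s, g in enumerate(var.genotypes):
            a, b = g[0], g[1]
            hap[s] = (a if a >= 0 else MISSING, b if b >= 0 else MISSING)
        hap_rows.append(hap)
    vcf.close()
    if not rows:
        return GenotypeTable(samples, [], np.array([], dtype=object),
                             np.array([], dtype=np.int64),
                             np.zeros((len(samples), 0), dtype=np.int8))
    genotypes = np.stack(rows, axis=1)
    haplotypes = None
    if all_phased:
        haplotypes = np.stack(hap_rows, axis=1)
        # missing haplotype alleles only at missing genotypes; clamp for invariant
        haplotypes[genotypes == MISSING] = 0
        haplotypes = np.where(haplotypes == MISSING, 0, haplotypes).astype(np.int8)
        hap_ok = haplotypes.sum(axis=2) == np.where(genotypes == MISSING, 0, genotypes)
        if not hap_ok.all():
            haplotypes = None
    try:
        return GenotypeTable(samples, vids, np.asarray(chroms, dtype=object),
                             np.asarray(pos), genotypes, haplotypes=haplotypes)
    except ValueError as exc:
        raise VcfParseError(str(exc)) from exc


def write_vcf(gt: GenotypeTable, path) -> None:
    """Write a GenotypeTable as a minimal VCF 4.2 (phased if haplotypes exist)."""
    sep = "|" if gt.haplotypes is not None else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(gt.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gt.sample_ids) + "\n")
        for j in range(gt.n_variants):
            calls = []
            for i in range(gt.n_samples):
                g = gt.genotypes[i, j]
                if g == MISSING:
                    calls.append(f".{sep}.")
                elif gt.haplotypes is not None:
                    a, b = gt.haplotypes[i, j]
                    calls.append(f"{a}{sep}{b}")
                else:
                    calls.append({0: f"0{sep}0", 1: f"0{sep}1", 2: f"1{sep}1"}[int(g)])
            fh.write(f"{gt.chrom[j]}\t{gt.pos[j]}\t{gt.variant_ids[j]}\tA\tG\t.\tPASS\t.\tGT\t"
                     + "\t".join(calls) + "\n")


def filter_variants(
    calls: Iterable[RawVariantCall],
    min_mq: float = 30,
    min_depth: float = 30,
    min_qual: float = 30,
    indel_dist: int = 3,
    hom_min_support: int = 4,
    hom_min_qual: float = 20,
    het_min_support: int = 2,
    het_min_gq: float = 20,
) -> GenotypeTable:
    """Apply the site- and genotype-level SNP filters to raw calls.

    Sites pass only with MQ, depth and quality all >= 30, biallelic, and more
    than ``indel_dist`` bp away from any indel record. Homozygous genotypes
    are kept only with supporting reads > 3 (i.e. >= 4) and site quality
    > 20; heterozygous genotypes only with >= 2 reads for each allele and
    genotype quality > 20; failing genotypes become MISSING.
    """
    calls = list(calls)
    keys = [(c.chrom, c.pos) for c in calls]
    if keys != sorted(keys):
        raise ValueError("raw calls must be sorted by chrom, pos")
    indel_pos: dict = {}
    for c in calls:
        if c.is_indel:
            indel_pos.setdefault(c.chrom, []).append(c.pos)

    sample_n = max((len(c.sample_calls) for c in calls), default=0)
    chroms, pos, vids, rows = [], [], [], []
    for c in calls:
        if c.is_indel:
            continue
        if c.mq < min_mq or c.depth < min_depth or c.qual < min_qual:
            continue
        if len(c.alt) != 1:
            continue
        near = indel_pos.get(c.chrom, [])
        if any(abs(c.pos - ip) <= indel_dist for ip in near):
            continue
        row = np.full(sample_n, MISSING, dtype=np.int8)
        for s, (g, ref_sup, alt_sup, gq) in enumerate(c.sample_calls):
            if g == MISSING:
                continue
            if g in (0, 2):
                support = ref_sup if g == 0 else alt_sup
                if support >= hom_min_support and c.qual > hom_min_qual:
                    row[s] = g
            elif g == 1:
                if ref_sup >= het_min_support and alt_sup >= het_min_support and gq > het_min_gq:
                    row[s] = 1
        chroms.append(c.chrom)
        pos.append(c.pos)
        vids.append(f"{c.chrom}_{c.pos}")
        rows.append(row)
    sample_ids = [f"S{i}" for i in range(sample_n)]
    if not rows:
        return GenotypeTable(sample_ids, [], np.array([], dtype=object),
                             np.array([], dtype=np.int64),
                             np.zeros((sample_n, 0), dtype=np.int8))
    return GenotypeTable(sample_ids, vids, np.asarray(chroms, dtype=object),
                         np.asarray(pos), np.stack(rows, axis=1))


def read_expression(path) -> ExpressionTable:
    """Read a gene x sample TSV of nonnegative abundances."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.isnull().any() or any(str(c).startswith("Unnamed") for c in df.columns):
        raise ValueError("expression TSV has a missing header cell")
    if df.index.duplicated().any():
        raise ValueError("duplicate gene_id in expression TSV")
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("negative expression value")
    return ExpressionTable(list(df.index.astype(str)), list(df.columns.astype(str)), values)


def write_expression(expr: ExpressionTable, path) -> None:
    pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids).to_csv(
        path, sep="\t", index_label="gene_id"
    )


def read_gene_annotation(path) -> list:
    """Read gene intervals from GFF3 (``gene`` features) or BED4+.

    GFF3 1-based inclusive coordinates become 0-based half-open; BED passes
    through unchanged.
    """
    path = str(path)
    genes = []
    with open(path) as fh:
        first_data = None
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            first_data = line
            break
    is_gff = path.endswith((".gff", ".gff3")) or (
        first_data is not None and len(first_data.split("\t")) >= 8
        and first_data.split("\t")[3].isdigit() and first_data.split("\t")[6] in "+-."
    )
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if is_gff:
                if f[2].lower() != "gene":
                    continue
                start, end = int(f[3]) - 1, int(f[4])
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                gid = attrs.get("ID", attrs.get("gene_id", f"{f[0]}:{f[3]}"))
                genes.append(GeneAnnotation(gid, f[0], start, end, f[6]))
            else:
                gid = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}"
                strand = f[5] if len(f) > 5 else "+"
                genes.append(GeneAnnotation(gid, f[0], int(f[1]), int(f[2]), strand))
    return genes


def write_regions(regions: Iterable[Region], path) -> None:
    """Write regions as BED (chrom, start, end, name, score), sorted."""
    regions = sorted(regions, key=lambda r: (str(r.chrom), r.start, r.end))
    with open(path, "w") as fh:
        for r in regions:
            name = r.stat_name or "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{r.stat_value}\n")
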