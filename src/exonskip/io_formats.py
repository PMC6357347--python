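"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions are fixed here and nowhere else: GTF and VCF are
1-based at the file boundary, BED is 0-based half-open, and everything
internal is 0-based half-open (see :mod:`exonskip.intervals`).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import pandas as pd
import pysam

from .intervals import GeneModel, GenomicInterval, Variant, flatten_exons
from .sre import MotifSet, SRESite

logger = logging.getLogger(__name__)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class ParseError(ValueError):
    """A malformed record in an input file."""


def _parse_gtf_attrs(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read exon (and optional CDS) features from a GTF file into gene models.

    GTF's 1-based inclusive coordinates are converted to 0-based half-open.
    Overlapping exon records within a gene are flattened into disjoint
    counting bins by breakpoint union; bin identifiers are assigned
    ``<gene_id>:E001`` … in genomic order. CDS features, when present,
    set per-bin coding lengths and phases.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}  # gene -> (chrom, strand)
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates")
            if end_i < start_i:
                raise ParseError(f"{path}:{lineno}: end < start")
            attr = _parse_gtf_attrs(attrs)
            gene_id = attr.get("gene_id")
            if not gene_id:
                raise ParseError(f"{path}:{lineno}: {feature} feature without gene_id")
            if gene_id not in meta:
                meta[gene_id] = (chrom, strand)
                order.append(gene_id)
            elif meta[gene_id] != (chrom, strand):
                raise ParseError(
                    f"{path}:{lineno}: gene {gene_id} spans chromosomes/strands"
                )
            iv = (start_i - 1, end_i)  # to 0-based half-open
            (exons if feature == "exon" else cds).setdefault(gene_id, []).append(iv)

    models = []
    for gene_id in order:
        recs = exons.get(gene_id)
        if not recs:
            continue  # CDS without exon records
        chrom, strand = meta[gene_id]
        bins = flatten_exons(recs)
        intervals = [GenomicInterval(chrom, s, e, strand) for s, e in bins]
        exon_ids = [f"{gene_id}:E{i + 1:03d}" for i in range(len(bins))]
        cds_lengths = [
            sum(max(0, min(e, ce) - max(s, cs)) for cs, ce in cds.get(gene_id, []))
            for s, e in bins
        ]
        cds_flags = [c > 0 for c in cds_lengths]
        models.append(
            GeneModel(
                gene_id=gene_id,
                intervals=intervals,
                exon_ids=exon_ids,
                cds_flags=cds_flags,
                cds_lengths=cds_lengths,
            )
        )
    return models


def write_gtf(models: list[GeneModel], path: str | Path, source: str = "exonskip") -> None:
    """Write gene models as GTF exon (and CDS) features, 1-based inclusive."""
    with open(path, "w") as fh:
        for m in models:
            for iv, exon_id, cds_len, phase in zip(
                m.intervals, m.exon_ids, m.cds_lengths, m.phase
            ):
                attrs = f'gene_id "{m.gene_id}"; exon_id "{exon_id}";'
                fh.write(
                    f"{iv.chrom}\t{source}\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{iv.strand}\t.\t{attrs}\n"
                )
                if cds_len > 0:
                    # coding bins in these models are fully coding
                    fh.write(
                        f"{iv.chrom}\t{source}\tCDS\t{iv.start + 1}\t{iv.end}\t.\t"
                        f"{iv.strand}\t{phase if phase is not None else 0}\t{attrs}\n"
                    )


def read_vcf(path: str | Path) -> tuple[list[Variant], pd.DataFrame]:
    """Read biallelic SNVs and genotype dosages from a VCF.

    Dosages count alt alleles (0/1/2), with missing genotypes as NaN.
    Multi-allelic records and indels are skipped with a logged warning.
    The minor-allele frequency of each variant is computed from the
    non-missing genotypes.
    """
    vf = pysam.VariantFile(str(path))
    if "GT" not in vf.header.formats:
        raise ParseError(f"{path}: VCF has no GT format field")
    samples = list(vf.header.samples)
    variants: list[Variant] = []
    rows = []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            logger.warning("skipping multi-allelic record at %s:%d", rec.chrom, rec.pos)
            continue
        ref, alt = rec.ref, rec.alts[0]
        if len(ref) != 1 or len(alt) != 1 or {ref, alt} - set("ACGT"):
            logger.warning("skipping non-SNV record at %s:%d", rec.chrom, rec.pos)
            continue
        dos = []
        for s in samples:
            gt = rec.samples[s]["GT"]
            if gt is None or any(a is None for a in gt):
                dos.append(float("nan"))
            else:
                dos.append(float(sum(gt)))
        ser = pd.Series(dos, index=samples)
        af = ser.mean() / 2.0 if ser.notna().any() else float("nan")
        maf = min(af, 1 - af) if af == af else None
        if maf is not None and maf <= 0:
            maf = None  # monomorphic
        vid = rec.id or f"{rec.chrom}:{rec.pos}:{ref}:{alt}"
        variants.append(Variant(vid, rec.chrom, rec.pos, ref, alt, maf))
        rows.append(ser.rename(vid))
    dosages = pd.DataFrame(rows) if rows else pd.DataFrame(columns=samples)
    return variants, dosages


def write_vcf(
    variants: list[Variant], dosages: pd.DataFrame, path: str | Path
) -> None:
    """Write biallelic SNVs with GT fields from a dosage table (0/1/2/NaN)."""
    samples = list(dosages.columns)
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    chroms = sorted({v.chrom for v in variants})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for v in sorted(variants, key=lambda x: (x.chrom, x.pos)):
            row = dosages.loc[v.id]
            gts = "\t".join(gt_code.get(row[s], "./.") for s in samples)
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_motifs(path: str | Path, sre_class: str) -> MotifSet:
    """Read a hexamer motif list, one 6-mer per line; duplicates are dropped."""
    hexamers = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            motif = line.strip().upper()
            if not motif:
                continue
            if len(motif) != 6 or set(motif) - set("ACGT"):
                raise ParseError(
                    f"{path}:{lineno}: not an ACGT hexamer: {motif!r}"
                )
            hexamers.add(motif)
    return MotifSet(sre_class=sre_class, hexamers=frozenset(hexamers))


def write_motifs(motifs: MotifSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in sorted(motifs.hexamers):
            fh.write(h + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a name → sequence mapping."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif name is not None:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed_sites(sites: list[SRESite], path: str | Path) -> None:
    """Write SRE sites as BED6 (0-based half-open), name = class:hexamer."""
    with open(path, "w") as fh:
        for s in sites:
            iv = s.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.sre_class}:{s.hexamer}\t0\t"
                f"{iv.strand}\n"
            )


def read_counts_tsv(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Read an exon × sample count table.

    The TSV must have columns ``exon_id``, ``gene_id`` and one integer
    column per sample. Returns (counts indexed by exon_id, exon → gene map).
    """
    df = pd.read_csv(path, sep="\t", dtype={"exon_id": str, "gene_id": str})
    for col in ("exon_id", "gene_id"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    df = df.set_index("exon_id")
    gene_of = df.pop("gene_id")
    counts = df.astype(int)
    if (counts.values < 0).any():
        raise ParseError(f"{path}: negative counts")
    return counts, gene_of


def write_counts_tsv(
    counts: pd.DataFrame, gene_of: pd.Series, path: str | Path
) -> None:
    out = counts.copy()
    out.insert(0, "gene_id", gene_of)
    out.to_csv(path, sep="\t", index_label="exon_id")


def read_table_tsv(path: str | Path, index_col: str = "sample_id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if index_col not in df.columns:
        raise ParseError(f"{path}: missing required column {index_col!r}")
    return df.set_index(index_col)
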