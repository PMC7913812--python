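"""Readers and writers for the standard formats the pipeline touches.

Genotype matrices travel as minimal VCF (one sample column per line, GT plus
per-site depth) or as wide TSV; segments as BED (0-based half-open);
annotations as a GFF3 subset (gene/mRNA/exon/CDS); parental variants as
minimal VCF with an INFO tag carrying the planted effect class; everything
else as TSV.  Internal coordinates are 1-based inclusive — only BED output
converts (start - 1).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import DONOR, HET, MISSING, RECURRENT, GenotypeMatrix, Segment
from .genes import GeneModel, Variant

log = logging.getLogger(__name__)

_GT_CODE = {(0, 0): RECURRENT, (0, 1): HET, (1, 0): HET, (1, 1): DONOR}


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunables with their documented defaults."""

    min_qual: float = 30.0
    max_missing: float = 0.2
    min_mean_dp: float = 1.5
    window: int = 15
    min_sites: int = 5
    lod_threshold: float = 2.5
    p_in: float = 0.05
    p_out: float = 0.10
    promoter_len: int = 2000
    min_fpkm: float = 2.0
    fold: float = 2.0
    min_tissues: int = 1
    seed: int = 0

    def manifest(self, **extra) -> dict:
        out = {"config": dataclasses.asdict(self)}
        out.update(extra)
        return out

    def write_manifest(self, path: str | Path, **extra) -> None:
        Path(path).write_text(json.dumps(self.manifest(**extra), indent=2) + "\n")


# ---------------------------------------------------------------------------
# VCF: genotype matrix
# ---------------------------------------------------------------------------

def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF 4.2: GT per line-sample, QUAL, INFO DP (summed depth)."""
    path = Path(path)
    n = matrix.n_lines
    gt_str = {RECURRENT: "0/0", HET: "0/1", DONOR: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        lengths = matrix.chrom_lengths or {}
        for chrom in matrix.chromosomes:
            if chrom in lengths:
                fh.write(f"##contig=<ID={chrom},length={lengths[chrom]}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.lines) + "\n")
        ref = matrix.sites.get("ref", pd.Series(["A"] * matrix.n_sites))
        alt = matrix.sites.get("alt", pd.Series(["T"] * matrix.n_sites))
        for j in range(matrix.n_sites):
            row = matrix.sites.iloc[j]
            dp = int(round(float(row["mean_dp"]) * n))
            cells = "\t".join(gt_str[int(c)] for c in matrix.calls[:, j])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t.\t{ref.iloc[j]}\t{alt.iloc[j]}"
                f"\t{float(row['qual']):g}\tPASS\tDP={dp}\tGT\t{cells}\n"
            )


def read_vcf_min(path: str | Path) -> GenotypeMatrix:
    """Read a minimal VCF into a genotype matrix.

    GT 0/0, 0/1, 1/1 and ./. become codes 0, 1, 2 and missing; multiallelic
    and indel records are skipped (count logged).  QUAL and INFO DP (mean
    depth = DP / n_samples) populate the QC metadata.
    """
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    if not samples:
        raise ValueError("VCF has no sample columns")
    chroms, poss, quals, dps, rows = [], [], [], [], []
    skipped = 0
    lengths = {c: vcf.header.contigs[c].length for c in vcf.header.contigs
               if vcf.header.contigs[c].length}
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1 or len(rec.ref) != 1 or len(rec.alts[0]) != 1:
            skipped += 1
            continue
        codes = np.empty(len(samples), dtype=np.int8)
        for i, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                codes[i] = MISSING
            else:
                codes[i] = _GT_CODE.get(tuple(gt), MISSING)
        chroms.append(rec.chrom)
        poss.append(rec.pos)
        quals.append(rec.qual if rec.qual is not None else 0.0)
        dp = rec.info.get("DP")
        dps.append(dp / len(samples) if dp is not None else np.nan)
        rows.append(codes)
    if skipped:
        log.info("skipped %d multiallelic/indel records", skipped)
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "qual": quals,
                          "mean_dp": dps})
    calls = np.vstack(rows).T if rows else np.empty((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(sites=sites, lines=samples, calls=calls,
                          chrom_lengths=lengths or None)


# ---------------------------------------------------------------------------
# VCF: parental variant table
# ---------------------------------------------------------------------------

def write_variants_vcf(variants: pd.DataFrame, path: str | Path) -> None:
    """Parental difference SNPs; INFO carries GENE and the planted class."""
    with open(Path(path), "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">\n')
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="Planted effect class">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, r in variants.iterrows():
            info = []
            if "gene" in r and pd.notna(r["gene"]):
                info.append(f"GENE={r['gene']}")
            if "planted_class" in r and pd.notna(r["planted_class"]):
                info.append(f"CLASS={r['planted_class']}")
            fh.write(f"{r['chrom']}\t{int(r['pos'])}\t.\t{r['ref']}\t{r['alt']}"
                     f"\t.\tPASS\t{';'.join(info) or '.'}\n")


def read_variants_vcf(path: str | Path) -> pd.DataFrame:
    vcf = pysam.VariantFile(str(path))
    rows = []
    skipped = 0
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1 or len(rec.ref) != 1 or len(rec.alts[0]) != 1:
            skipped += 1
            continue
        rows.append((rec.chrom, rec.pos, rec.ref, rec.alts[0],
                     rec.info.get("GENE"), rec.info.get("CLASS")))
    if skipped:
        log.info("skipped %d multiallelic/indel records", skipped)
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gene",
                                       "planted_class"])


def variants_from_frame(df: pd.DataFrame) -> list[Variant]:
    return [Variant(chrom=r["chrom"], pos=int(r["pos"]), ref=r["ref"], alt=r["alt"])
            for _, r in df.iterrows()]


# ---------------------------------------------------------------------------
# GFF3 + FASTA
# ---------------------------------------------------------------------------

def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """gene/mRNA/exon/CDS rows, one single-transcript model per gene."""
    with open(Path(path), "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            fh.write(f"{g.chrom}\t.\tgene\t{s}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            fh.write(f"{g.chrom}\t.\tmRNA\t{s}\t{e}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}.1;Parent={g.gene_id}\n")
            for (xs, xe) in g.exons:
                fh.write(f"{g.chrom}\t.\texon\t{xs}\t{xe}\t.\t{g.strand}\t.\t"
                         f"Parent={g.gene_id}.1\n")
            for (cs, ce) in g.cds:
                fh.write(f"{g.chrom}\t.\tCDS\t{cs}\t{ce}\t.\t{g.strand}\t0\t"
                         f"Parent={g.gene_id}.1\n")


def read_gff3_min(
    gff_path: str | Path,
    fasta_path: str | Path | None = None,
    promoter_len: int = 2000,
) -> list[GeneModel]:
    """Parse a gene/mRNA/exon/CDS GFF3 subset into gene models.

    Only the first mRNA of each gene is used (single-transcript models).
    When ``fasta_path`` is given, each model carries its chromosome sequence
    so variants can be classified against it.
    """
    import gffutils

    seqs: dict[str, str] = {}
    if fasta_path is not None:
        seqs = {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(str(gff_path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    out = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        parent = mrnas[0] if mrnas else gene
        exons = [(f.start, f.end) for f in db.children(parent, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(parent, featuretype="CDS")]
        if not exons:
            continue
        out.append(GeneModel(
            gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
            exons=sorted(exons), cds=sorted(cds) or sorted(exons),
            promoter_len=promoter_len, seq=seqs.get(gene.seqid, ""), seq_start=1,
        ))
    return out


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED / TSV
# ---------------------------------------------------------------------------

def write_bed(segments: list[Segment], path: str | Path) -> None:
    """Segments as BED: 0-based half-open, columns chrom/start/end/line/origin."""
    with open(Path(path), "w") as fh:
        for s in segments:
            if s.start < 1:
                raise ValueError(f"coordinate underflow in segment {s}")
            fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.line}\t{s.origin}\n")


def read_bed_segments(path: str | Path) -> list[Segment]:
    segs = []
    with open(path) as fh:
        for raw in fh:
            if not raw.strip():
                continue
            chrom, start, end, line, origin = raw.rstrip("\n").split("\t")[:5]
            segs.append(Segment(line=line, chrom=chrom, start=int(start) + 1,
                                end=int(end), origin=origin))
    return segs


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(Path(path), sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")


def write_matrix_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Wide TSV: chrom, pos, qual, mean_dp, then one genotype column per line."""
    write_tsv(matrix.to_frame(), path)


def read_matrix_tsv(path: str | Path,
                    chrom_lengths: dict[str, int] | None = None) -> GenotypeMatrix:
    df = read_tsv(path)
    meta = ["chrom", "pos", "qual", "mean_dp"]
    lines = [c for c in df.columns if c not in meta]
    calls = df[lines].to_numpy().T.astype(np.int8)
    return GenotypeMatrix(sites=df[meta], lines=lines, calls=calls,
                          chrom_lengths=chrom_lengths)


def write_chrom_lengths(lengths: dict[str, int], path: str | Path) -> None:
    write_tsv(pd.DataFrame(list(lengths.items()), columns=["chrom", "length"]), path)


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    df = read_tsv(path)
    return dict(zip(df["chrom"], df["length"].astype(int)))
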