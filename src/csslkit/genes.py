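"""Candidate-gene triage inside mapped intervals.

Given a gene annotation, a parental expression table (FPKM over eight
tissues) and the parental sequence variants, this module (1) lists the genes
overlapping a mapped interval, (2) removes genes with negligible expression
and counts tissues with a two-fold parental expression difference, (3)
classifies each variant's functional effect on the gene model by codon
translation, and (4) ranks the surviving genes by variant impact, then
differential-expression breadth, then expression level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

log = logging.getLogger(__name__)

IMPACT_CLASSES = {"stop_gain", "stop_loss", "missense", "splice_acceptor",
                  "splice_donor"}
EFFECT_CLASSES = IMPACT_CLASSES | {"synonymous", "intron", "promoter", "UTR",
                                   "intergenic"}

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class GeneModel:
    """Single-transcript gene model with its local reference sequence.

    ``exons`` and ``cds`` are 1-based inclusive plus-strand intervals sorted
    by start; ``seq`` is the plus-strand reference covering at least the gene
    span plus the promoter window, beginning at coordinate ``seq_start``.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    promoter_len: int = 2000
    seq: str = ""
    seq_start: int = 1

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        total = sum(e - s + 1 for s, e in self.cds)
        self.frame_ok = total % 3 == 0
        if not self.frame_ok:
            log.warning("%s: CDS length %d not divisible by 3", self.gene_id, total)

    # -- coordinates ------------------------------------------------------
    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def tss(self) -> int:
        """Transcription start site (strand-aware)."""
        return self.span[0] if self.strand == "+" else self.span[1]

    def introns(self) -> list[tuple[int, int]]:
        return [(e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    def promoter_interval(self) -> tuple[int, int]:
        if self.strand == "+":
            return self.tss() - self.promoter_len, self.tss() - 1
        return self.tss() + 1, self.tss() + self.promoter_len

    # -- sequence ---------------------------------------------------------
    def base_at(self, pos: int) -> str:
        i = pos - self.seq_start
        if not 0 <= i < len(self.seq):
            raise IndexError(f"{self.gene_id}: position {pos} outside local sequence")
        return self.seq[i].upper()

    def cds_plus_positions(self) -> list[int]:
        """Plus-strand coordinates of CDS bases in transcription order."""
        pos = [p for s, e in self.cds for p in range(s, e + 1)]
        return pos if self.strand == "+" else pos[::-1]

    def cds_sequence(self, override: dict[int, str] | None = None) -> str:
        """Coding-strand CDS sequence, optionally with substituted bases
        (``override`` maps plus-strand position -> plus-strand base)."""
        override = override or {}
        chars = []
        for s, e in self.cds:
            for p in range(s, e + 1):
                chars.append(override.get(p, self.base_at(p)))
        plus = "".join(chars)
        return plus if self.strand == "+" else _revcomp(plus)

    def cds_codon(self, index: int) -> str:
        cds = self.cds_sequence()
        return cds[3 * index:3 * index + 3]


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP: plus-strand ref (recurrent) and alt (donor) bases."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class EffectAnnotation:
    variant: Variant
    gene_id: str
    effect: str


# ---------------------------------------------------------------------------
# interval membership
# ---------------------------------------------------------------------------

def genes_in_interval(
    annotation: list[GeneModel], chrom: str, start: int, end: int
) -> list[GeneModel]:
    """Genes whose span overlaps [start, end] on ``chrom`` (any overlap,
    1-based inclusive; touching at an edge counts)."""
    if not any(g.chrom == chrom for g in annotation):
        raise ValueError(f"no annotated genes on chromosome {chrom!r}")
    out = []
    for g in annotation:
        if g.chrom != chrom:
            continue
        gs, ge = g.span
        if gs <= end and start <= ge:
            out.append(g)
    return out


# ---------------------------------------------------------------------------
# expression filter
# ---------------------------------------------------------------------------

def expression_filter(
    expr: pd.DataFrame,
    min_fpkm: float = 2.0,
    fold: float = 2.0,
    min_tissues: int = 1,
    epsilon: float = 0.01,
) -> pd.DataFrame:
    """Per-gene low-expression removal flag and differential-tissue count.

    A gene is removed iff FPKM < ``min_fpkm`` in every tissue for both
    parents.  A tissue is differential when the parental fold ratio
    ``max(p1,p2) / max(min(p1,p2), epsilon)`` exceeds ``fold`` (the epsilon
    floor handles zero FPKM).  Retained genes additionally need a
    differential count >= ``min_tissues``.  Missing tissues are skipped with
    a log message.  Returns columns gene / max_fpkm / de_tissues / removed /
    retained.
    """
    rows = []
    for gene, sub in expr.groupby("gene", sort=True):
        wide = sub.pivot_table(index="tissue", columns="parent", values="fpkm")
        if not {"donor", "recurrent"} <= set(wide.columns):
            raise ValueError(f"{gene}: both parents required in expression table")
        missing = wide.index[wide.isna().any(axis=1)]
        for t in missing:
            log.info("%s: tissue %s incomplete; skipped", gene, t)
        wide = wide.dropna()
        d = wide["donor"].to_numpy()
        r = wide["recurrent"].to_numpy()
        hi = np.maximum(d, r)
        lo = np.maximum(np.minimum(d, r), epsilon)
        de = int(((hi / lo) > fold).sum())
        low_everywhere = bool((hi < min_fpkm).all())
        max_fpkm = float(hi.max()) if len(hi) else 0.0
        removed = low_everywhere
        retained = (not removed) and de >= min_tissues
        rows.append((gene, max_fpkm, de, removed, retained))
    return pd.DataFrame(rows, columns=["gene", "max_fpkm", "de_tissues",
                                       "removed", "retained"])


# ---------------------------------------------------------------------------
# variant-effect classification
# ---------------------------------------------------------------------------

def classify_variant_effect(gene: GeneModel, variant: Variant) -> EffectAnnotation:
    """Primary functional class of a SNP on one gene model.

    Precedence: splice (2 bp at each intron end) > CDS codon change
    (stop_gain / stop_loss / missense / synonymous) > UTR > intron >
    promoter (within the upstream window) > intergenic.  Translation is
    performed on the coding strand with strand-aware complementation.  A ref
    allele mismatching the local reference sequence is a hard error.
    """
    pos, ref, alt = variant.pos, variant.ref.upper(), variant.alt.upper()
    if variant.chrom != gene.chrom:
        return EffectAnnotation(variant, gene.gene_id, "intergenic")
    span = gene.span
    pstart, pend = gene.promoter_interval()
    in_reach = (span[0] <= pos <= span[1]) or (pstart <= pos <= pend)
    if not in_reach:
        return EffectAnnotation(variant, gene.gene_id, "intergenic")
    if gene.base_at(pos) != ref:
        raise ValueError(
            f"{gene.gene_id}: ref allele {ref} does not match reference "
            f"{gene.base_at(pos)} at {gene.chrom}:{pos}"
        )

    # splice: first/last two intron bases; donor side faces the upstream exon
    for (is_, ie) in gene.introns():
        if pos in (is_, is_ + 1, ie - 1, ie):
            if gene.strand == "+":
                side = "splice_donor" if pos <= is_ + 1 else "splice_acceptor"
            else:
                side = "splice_acceptor" if pos <= is_ + 1 else "splice_donor"
            return EffectAnnotation(variant, gene.gene_id, side)

    in_cds = any(s <= pos <= e for s, e in gene.cds)
    if in_cds and gene.frame_ok:
        ref_cds = gene.cds_sequence()
        alt_cds = gene.cds_sequence(override={pos: alt})
        ref_aa = str(Seq(ref_cds).translate())
        alt_aa = str(Seq(alt_cds).translate())
        effect = _compare_proteins(ref_aa, alt_aa)
        return EffectAnnotation(variant, gene.gene_id, effect)

    in_exon = any(s <= pos <= e for s, e in gene.exons)
    if in_exon:
        return EffectAnnotation(variant, gene.gene_id, "UTR")
    if any(s <= pos <= e for s, e in gene.introns()):
        return EffectAnnotation(variant, gene.gene_id, "intron")
    if pstart <= pos <= pend:
        return EffectAnnotation(variant, gene.gene_id, "promoter")
    return EffectAnnotation(variant, gene.gene_id, "intergenic")


def _compare_proteins(ref_aa: str, alt_aa: str) -> str:
    """Classify a single-codon difference between two translations."""
    ref_stop = ref_aa.find("*")
    alt_stop = alt_aa.find("*")
    ref_stop = len(ref_aa) if ref_stop == -1 else ref_stop
    alt_stop = len(alt_aa) if alt_stop == -1 else alt_stop
    if alt_stop < ref_stop:
        return "stop_gain"
    if alt_stop > ref_stop:
        return "stop_loss"
    if ref_aa[:ref_stop] != alt_aa[:alt_stop]:
        return "missense"
    return "synonymous"


def classify_variants(
    genes: list[GeneModel], variants: list[Variant]
) -> list[EffectAnnotation]:
    """Classify each variant against every gene whose reach contains it."""
    out = []
    for v in variants:
        for g in genes:
            if g.chrom != v.chrom:
                continue
            ann = classify_variant_effect(g, v)
            if ann.effect != "intergenic":
                out.append(ann)
    return out


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

@dataclass
class CandidateReport:
    """Ranked candidate genes for one mapped interval."""

    interval: tuple[str, int, int]
    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def rank_candidates(
    interval_genes: list[GeneModel],
    expr_flags: pd.DataFrame,
    effects: list[EffectAnnotation],
    interval: tuple[str, int, int],
    promoter_min_snps: int = 5,
) -> CandidateReport:
    """Rank genes by (impactful variant, DE tissue count, max FPKM), descending.

    Impactful means a protein-changing or splice variant, or at least
    ``promoter_min_snps`` promoter SNPs (a promoter haplotype can drive
    expression change without touching the CDS).  Genes removed by the
    expression filter are listed but ranked last.  Ties break by gene id.
    """
    flags = expr_flags.set_index("gene")
    by_gene: dict[str, list[str]] = {}
    for ann in effects:
        by_gene.setdefault(ann.gene_id, []).append(ann.effect)
    rows = []
    for g in interval_genes:
        classes = by_gene.get(g.gene_id, [])
        n_promoter = sum(1 for c in classes if c == "promoter")
        impactful = bool(IMPACT_CLASSES & set(classes)) or n_promoter >= promoter_min_snps
        if g.gene_id in flags.index:
            de = int(flags.loc[g.gene_id, "de_tissues"])
            max_fpkm = float(flags.loc[g.gene_id, "max_fpkm"])
            removed = bool(flags.loc[g.gene_id, "removed"])
        else:
            de, max_fpkm, removed = 0, 0.0, True
        rows.append((g.gene_id, not removed, impactful, de, max_fpkm,
                     ";".join(sorted(set(classes))), n_promoter))
    df = pd.DataFrame(rows, columns=["gene", "expressed", "impactful",
                                     "de_tissues", "max_fpkm", "classes",
                                     "n_promoter_snps"])
    df = df.sort_values(
        by=["expressed", "impactful", "de_tissues", "max_fpkm", "gene"],
        ascending=[False, False, False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return CandidateReport(interval=interval, table=df)
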