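"""Haplotype assignment at candidate genes and background-matched contrasts.

Each line (or germplasm accession) is labelled at every candidate gene as
wild-type (all diagnostic SNPs match the donor parent), cultivated-type (all
match the recurrent parent), ``other`` (matches neither parent) or
``missing``.  The effect of one gene's wild haplotype is then demonstrated
by contrasting lines wild at that gene but cultivated at every other trait
locus against lines cultivated throughout — so the two groups differ only at
the focal gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DONOR, MISSING, RECURRENT
from .bsa import cpg

WILD, CULTIVATED, OTHER, NOCALL = "wild", "cultivated", "other", "missing"


def assign_haplotypes(
    calls: pd.DataFrame,
    diagnostic_snps: dict[str, list[str]],
) -> pd.DataFrame:
    """Label every unit at every candidate gene from its diagnostic SNPs.

    ``calls``: units x SNP-id genotype codes (0 recurrent-hom, 1 het,
    2 donor-hom, -1 missing).  ``diagnostic_snps``: gene -> SNP-id list.
    A unit is wild iff all diagnostic SNPs are donor-homozygous, cultivated
    iff all are recurrent-homozygous, missing if any call is absent, and
    other otherwise (heterozygous or mixed — excluded downstream).
    """
    out = {}
    for gene, snps in diagnostic_snps.items():
        if not snps:
            raise ValueError(f"no diagnostic SNPs for gene {gene}")
        sub = calls[snps].to_numpy()
        labels = np.full(len(calls), OTHER, dtype=object)
        labels[(sub == DONOR).all(axis=1)] = WILD
        labels[(sub == RECURRENT).all(axis=1)] = CULTIVATED
        labels[(sub == MISSING).any(axis=1)] = NOCALL
        out[gene] = labels
    return pd.DataFrame(out, index=calls.index)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class ContrastResult:
    """One focal-gene haplotype contrast against the all-cultivated background."""

    focal_gene: str
    n_wild: int
    n_background: int
    wild_range: tuple[float, float]
    background_range: tuple[float, float]
    wild_mean: float
    background_mean: float
    difference: float
    t: float | None
    p: float | None
    stars: str

    def to_row(self) -> dict:
        return {
            "gene": self.focal_gene,
            "n_wild": self.n_wild,
            "n_background": self.n_background,
            "wild_mean": self.wild_mean,
            "background_mean": self.background_mean,
            "difference": self.difference,
            "t": self.t,
            "p": self.p,
            "stars": self.stars,
        }


def background_matched_contrast(
    haplos: pd.DataFrame,
    pheno: pd.Series,
    focal_gene: str,
    background_genes: list[str],
    welch: bool = False,
) -> ContrastResult:
    """Wild-vs-cultivated contrast at one gene on a fixed cultivated background.

    Group A: wild at ``focal_gene`` and cultivated at every background gene.
    Group B: cultivated at the focal gene and every background gene.  Units
    labelled other/missing at any involved gene belong to neither group.
    Difference is mean(A) - mean(B), tested by two-sided Student's t (pooled
    variance); with fewer than two units in a group the means are still
    reported but no p-value.
    """
    if focal_gene in background_genes:
        raise ValueError("focal gene cannot be part of its own background")
    genes = [focal_gene] + list(background_genes)
    units = [u for u in haplos.index if u in pheno.index]
    lab = haplos.loc[units, genes]
    back_ok = (lab[background_genes] == CULTIVATED).all(axis=1)
    a_units = lab.index[(lab[focal_gene] == WILD) & back_ok]
    b_units = lab.index[(lab[focal_gene] == CULTIVATED) & back_ok]
    a = pheno.loc[a_units].to_numpy(dtype=float)
    b = pheno.loc[b_units].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"{focal_gene}: empty contrast group "
                         f"(wild n={len(a)}, background n={len(b)})")
    diff = float(a.mean() - b.mean())
    if len(a) >= 2 and len(b) >= 2 and (np.ptp(a) > 0 or np.ptp(b) > 0):
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        t, p = float(t), float(p)
    elif np.ptp(np.concatenate([a, b])) == 0:
        t, p = 0.0, 1.0  # identical observations
    else:
        t, p = None, None  # size-1 group: report means without a test
    return ContrastResult(
        focal_gene=focal_gene,
        n_wild=len(a),
        n_background=len(b),
        wild_range=(float(a.min()), float(a.max())),
        background_range=(float(b.min()), float(b.max())),
        wild_mean=float(a.mean()),
        background_mean=float(b.mean()),
        difference=diff,
        t=t,
        p=p,
        stars=_stars(p) if p is not None else "",
    )


def contrast_table(
    haplos: pd.DataFrame,
    pheno: pd.Series,
    genes: list[str],
) -> pd.DataFrame:
    """All single-gene contrasts for one trait; the all-cultivated background
    group is shared across focal genes.  A gene with no unit carrying its wild
    haplotype on the clean background is skipped (its allele pair cannot be
    demonstrated in this material)."""
    rows = []
    for g in genes:
        background = [x for x in genes if x != g]
        try:
            res = background_matched_contrast(haplos, pheno, g, background)
        except ValueError:
            continue
        rows.append(res.to_row())
    return pd.DataFrame(rows)


def scc_coincidence(
    haplos: pd.DataFrame,
    scc: pd.Series,
    gene: str,
    wild_category: str,
    cultivated_category: str = "yellow",
) -> float:
    """Consistency % between a colour gene's haplotype and the observed colour.

    Units labelled other/missing at the gene are excluded; the remaining
    units' predicted category (wild -> ``wild_category``, cultivated ->
    ``cultivated_category``) is compared with the phenotype using the C_P&G
    formula.
    """
    units = [u for u in haplos.index if u in scc.index]
    lab = haplos.loc[units, gene]
    keep = lab.isin([WILD, CULTIVATED])
    lab = lab[keep]
    obs = scc.loc[lab.index]
    predicted = lab.map({WILD: wild_category, CULTIVATED: cultivated_category})
    n_g = len(lab)
    n_pg = int((predicted == obs).sum())
    return cpg(n_pg, n_g)
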