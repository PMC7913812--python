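"""Candidate-gene triage: interval lookup, expression filter, effect classifier."""

import numpy as np
import pandas as pd
import pytest

from csslkit import (
    GeneModel,
    Variant,
    classify_variant_effect,
    expression_filter,
    genes_in_interval,
    rank_candidates,
)
from csslkit.genes import EffectAnnotation
from csslkit.simulate import TISSUES, random_gene_model, plant_variant


def _gene(gene_id="g1", chrom="c1", start=3001, strand="+",
          exon_lens=(30, 30), intron_len=100, promoter_len=2000, seq=None):
    exons = []
    p = start
    for i, el in enumerate(exon_lens):
        exons.append((p, p + el - 1))
        p += el + (intron_len if i < len(exon_lens) - 1 else 0)
    span = (exons[0][0], exons[-1][1])
    seq_start = span[0] - promoter_len - 10
    if seq is None:
        rng = np.random.default_rng(1)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, span[1] + 20 - seq_start + 1)])
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, exons=exons,
                     cds=exons, promoter_len=promoter_len, seq=seq,
                     seq_start=seq_start)


class TestGenesInInterval:
    def _annotation(self):
        return [_gene(f"g{i}", start=3001 + i * 1000, exon_lens=(60,))
                for i in range(7)]

    def test_edge_touching_counts(self):
        ann = self._annotation()
        g0 = ann[0]
        hit = genes_in_interval(ann, "c1", g0.span[1], g0.span[1] + 10)
        assert g0 in hit

    def test_disjoint_excluded(self):
        ann = self._annotation()
        assert genes_in_interval(ann, "c1", 1, 1000) == []

    def test_matches_brute_force_overlap(self):
        ann = self._annotation()
        start, end = 4500, 6200
        got = {g.gene_id for g in genes_in_interval(ann, "c1", start, end)}
        want = {g.gene_id for g in ann
                if not (g.span[1] < start or g.span[0] > end)}
        assert got == want

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError):
            genes_in_interval(self._annotation(), "c9", 1, 10)


class TestExpressionFilter:
    def _expr(self, donor, recurrent, gene="g1"):
        rows = []
        for t, d, r in zip(TISSUES, donor, recurrent):
            rows.append((gene, t, "donor", d))
            rows.append((gene, t, "recurrent", r))
        return pd.DataFrame(rows, columns=["gene", "tissue", "parent", "fpkm"])

    def test_fold_pattern_counted(self):
        # >2-fold in 7 of 8 tissues
        donor = [113.96, 8.69, 14.96, 8.76, 7.05, 2.57, 16.18, 11.98]
        recur = [109.98, 20.01, 3.55, 9.02, 4.25, 9.49, 24.26, 32.42]
        out = expression_filter(self._expr(donor, recur)).iloc[0]
        assert out["de_tissues"] == 4  # flower, 14seed, 35seed, 21pod
        assert not out["removed"]

    def test_low_everywhere_removed(self):
        out = expression_filter(self._expr([1.9] * 8, [1.9] * 8)).iloc[0]
        assert out["removed"] and not out["retained"]

    def test_zero_fpkm_uses_epsilon_floor(self):
        donor = [0.0] + [5.0] * 7
        recur = [5.0] + [5.0] * 7
        out = expression_filter(self._expr(donor, recur)).iloc[0]
        assert out["de_tissues"] == 1

    def test_monotone_in_fold_and_floor(self):
        rng = np.random.default_rng(3)
        rows = []
        for g in range(12):
            donor = rng.uniform(0, 30, 8)
            recur = rng.uniform(0, 30, 8)
            rows.append(self._expr(donor, recur, gene=f"g{g}"))
        expr = pd.concat(rows, ignore_index=True)
        loose = expression_filter(expr, min_fpkm=1.0, fold=1.5)
        tight = expression_filter(expr, min_fpkm=4.0, fold=3.0)
        keep_loose = set(loose[loose["retained"]]["gene"])
        keep_tight = set(tight[tight["retained"]]["gene"])
        assert keep_tight <= keep_loose


CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def oracle_classify(gene: GeneModel, variant: Variant) -> str:
    """Translate-both-alleles oracle, built per base with an explicit codon
    table — independent of the production classifier's machinery."""
    pos, alt = variant.pos, variant.alt
    introns = []
    ex = sorted(gene.exons)
    for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
        introns.append((e1 + 1, s2 - 1))
    for (s, e) in introns:
        if pos in (s, s + 1, e - 1, e):
            two_low = pos in (s, s + 1)
            if gene.strand == "+":
                return "splice_donor" if two_low else "splice_acceptor"
            return "splice_acceptor" if two_low else "splice_donor"
    cds_positions = [p for s, e in sorted(gene.cds) for p in range(s, e + 1)]
    if pos in cds_positions:
        def translate(base_override):
            bases = []
            for p in cds_positions:
                b = base_override if p == pos else gene.base_at(p)
                bases.append(b)
            if gene.strand == "-":
                bases = [_COMP[b] for b in reversed(bases)]
            aas = []
            for i in range(0, len(bases) - 2, 3):
                aas.append(CODON_TABLE["".join(bases[i:i + 3])])
            return aas
        ref_aa = translate(gene.base_at(pos))
        alt_aa = translate(alt)
        ref_stop = ref_aa.index("*") if "*" in ref_aa else len(ref_aa)
        alt_stop = alt_aa.index("*") if "*" in alt_aa else len(alt_aa)
        if alt_stop < ref_stop:
            return "stop_gain"
        if alt_stop > ref_stop:
            return "stop_loss"
        return "missense" if ref_aa[:ref_stop] != alt_aa[:alt_stop] else "synonymous"
    if any(s <= pos <= e for s, e in gene.exons):
        return "UTR"
    if any(s <= pos <= e for s, e in introns):
        return "intron"
    ps, pe = gene.promoter_interval()
    if ps <= pos <= pe:
        return "promoter"
    return "intergenic"


class TestClassifier:
    def test_stop_gain_plus_strand_codon_start(self):
        # CDS = ATG CGA ...: C->T at codon 2 start makes TGA
        seq_start = 1
        cds = "ATGCGAGGCTAA"
        seq = "A" * 99 + cds + "A" * 20
        gene = GeneModel("g", "c1", "+", exons=[(100, 111)], cds=[(100, 111)],
                         promoter_len=50, seq=seq, seq_start=seq_start)
        eff = classify_variant_effect(gene, Variant("c1", 103, "C", "T"))
        assert eff.effect == "stop_gain"

    def test_splice_acceptor_last_intron_base(self):
        gene = _gene(exon_lens=(30, 30), intron_len=100)
        intron_end = gene.exons[1][0] - 1
        ref = gene.base_at(intron_end)
        alt = "A" if ref != "A" else "C"
        eff = classify_variant_effect(gene, Variant("c1", intron_end, ref, alt))
        assert eff.effect == "splice_acceptor"

    def test_promoter_window(self):
        gene = _gene(promoter_len=2000)
        pos = gene.span[0] - 500
        ref = gene.base_at(pos)
        alt = "A" if ref != "A" else "C"
        eff = classify_variant_effect(gene, Variant("c1", pos, ref, alt))
        assert eff.effect == "promoter"

    def test_ref_mismatch_is_hard_error(self):
        gene = _gene()
        pos = gene.span[0]
        wrong = "A" if gene.base_at(pos) != "A" else "C"
        with pytest.raises(ValueError):
            classify_variant_effect(gene, Variant("c1", pos, wrong, "G"))

    def test_matches_translation_oracle_on_random_genes(self):
        """Both strands, random positions: classifier equals the independent
        per-base translation oracle."""
        rng = np.random.default_rng(77)
        checked = 0
        for i in range(150):
            gene = random_gene_model(rng, f"g{i}", "c1", 50_000 + i * 30_000)
            lo = gene.promoter_interval()[0] if gene.strand == "+" else gene.span[0]
            hi = gene.span[1] if gene.strand == "+" else gene.promoter_interval()[1]
            for _ in range(6):
                pos = int(rng.integers(lo, hi + 1))
                ref = gene.base_at(pos)
                alt = rng.choice([b for b in "ACGT" if b != ref])
                got = classify_variant_effect(gene, Variant("c1", pos, ref, alt))
                assert got.effect == oracle_classify(gene, Variant("c1", pos, ref, alt))
                checked += 1
        assert checked == 900

    def test_strand_symmetry_under_reverse_complement(self):
        """Mirroring the locus (reverse-complementing coordinates, sequence and
        alleles) leaves every variant's class unchanged."""
        rng = np.random.default_rng(99)
        comp = _COMP
        for i in range(30):
            gene = random_gene_model(rng, f"g{i}", "c1", 60_000 + i * 30_000)
            L = gene.seq_start + len(gene.seq) + 1_000  # mirror axis
            mirror = GeneModel(
                gene_id=gene.gene_id, chrom=gene.chrom,
                strand="-" if gene.strand == "+" else "+",
                exons=[(L - e, L - s) for s, e in gene.exons],
                cds=[(L - e, L - s) for s, e in gene.cds],
                promoter_len=gene.promoter_len,
                seq="".join(comp[b] for b in reversed(gene.seq)),
                seq_start=L - (gene.seq_start + len(gene.seq) - 1),
            )
            for cls in ("missense", "stop_gain", "synonymous"):
                try:
                    pos, ref, alt = plant_variant(gene, cls, rng)
                except ValueError:
                    continue  # gene lacks a plantable codon for this class
                direct = classify_variant_effect(gene, Variant("c1", pos, ref, alt))
                mirrored = classify_variant_effect(
                    mirror, Variant("c1", L - pos, comp[ref], comp[alt]))
                assert direct.effect == mirrored.effect == cls


class TestRanking:
    def _flags(self, rows):
        return pd.DataFrame(rows, columns=["gene", "max_fpkm", "de_tissues",
                                           "removed", "retained"])

    def test_planted_causal_ranks_first(self):
        rng = np.random.default_rng(8)
        causal = random_gene_model(rng, "causal", "c1", 100_000, n_exons=3)
        decoys = [random_gene_model(rng, f"d{i}", "c1", 200_000 + i * 30_000)
                  for i in range(5)]
        genes = [causal] + decoys
        flags = self._flags(
            [("causal", 30.0, 5, False, True)]
            + [(d.gene_id, 10.0, 0, False, False) for d in decoys])
        pos, ref, alt = plant_variant(causal, "stop_gain", rng)
        effects = [EffectAnnotation(Variant("c1", pos, ref, alt), "causal",
                                    "stop_gain")]
        report = rank_candidates(genes, flags, effects, ("c1", 1, 500_000))
        assert report.table.iloc[0]["gene"] == "causal"

    def test_same_impact_tier_decided_by_de_then_fpkm(self):
        g1 = _gene("a"); g2 = _gene("b", start=20_000)
        flags = self._flags([("a", 10.0, 4, False, True),
                             ("b", 50.0, 4, False, True)])
        effects = [
            EffectAnnotation(Variant("c1", 1, "A", "T"), "a", "stop_gain"),
            EffectAnnotation(Variant("c1", 2, "A", "T"), "b", "missense"),
        ]
        report = rank_candidates([g1, g2], flags, effects, ("c1", 1, 50_000))
        # stop_gain does not outrank missense: same tier -> FPKM decides
        assert report.table.iloc[0]["gene"] == "b"

    def test_promoter_set_counts_as_impactful(self):
        g = _gene("p")
        flags = self._flags([("p", 20.0, 3, False, True)])
        effects = [EffectAnnotation(Variant("c1", i, "A", "T"), "p", "promoter")
                   for i in range(11)]
        report = rank_candidates([g], flags, effects, ("c1", 1, 50_000),
                                 promoter_min_snps=5)
        assert bool(report.table.iloc[0]["impactful"])
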