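# csslkit

Analysis toolkit for **chromosome segment substitution line (CSSL)
populations** — panels of near-isogenic lines in which each line carries one
or a few donor-genome segments (e.g. from a wild relative) in a recurrent,
cultivated-parent background.  Such panels let a breeder or geneticist map a
trait to a single introgressed segment and then to a candidate gene, because
the genetic background noise has been bred away.

The package covers the full chain from genotypes to demonstrated gene-alleles:

1. **Segment maps** — QC-filter low-coverage SNP calls, infer each line's
   donor/recurrent segments and recombination breakpoints, and bin SNPs into
   co-segregating block markers (SNPLDBs) that tile the genome.
2. **Qualitative mapping** — bulk-segregant style co-segregation of a
   categorical trait (here, seed-coat colour) with the consistency statistic
   C<sub>P&G</sub> = n<sub>pg</sub>/n<sub>g</sub> × 100%.
3. **Quantitative mapping** — broad-sense heritability from multi-environment
   ANOVA, and a stepwise-cofactor likelihood-ratio additive QTL scan on line
   means: LOD = n·ln(RSS₀/RSS₁)/(2 ln 10), additive effect (ADD) under ±1
   genotype coding, PVE per marker.
4. **Candidate genes** — triage of genes inside a mapped block by parental
   expression (FPKM floor, two-fold differential tissues) and variant-effect
   classification (missense / stop gain / stop loss / splice / promoter) via
   codon translation on the coding strand.
5. **Haplotype demonstration** — wild/cultivated haplotype labels at candidate
   genes and background-matched group contrasts (Student's *t*) that isolate
   one gene's allele effect on an otherwise identical genetic background.
6. **Synthetic data** — a first-class simulator of the whole study design
   (backcross + selfing breeding scheme with marker-assisted gamete selection,
   Poisson-depth genotype observation, epistatic colour loci, multi-QTL
   flowering trait with target heritability, planted causal variants) with
   truth records for parameter-recovery testing.

## Worked example

Simulate a study-emulating panel (177 lines, 20 chromosomes, two epistatic
seed-coat-colour loci, six flowering-time QTL at heritability 0.956) and run
the pipeline on the truth genotypes:

```python
from csslkit import heritability, find_cosegregating_markers, group_lines
from csslkit.qtl import env_means, marker_design, rstep_cofactors, lrt_scan
from csslkit.segmap import build_snpldb_map, compute_map_stats
from csslkit.simulate import simulate_paper_study

matrix, truth, arch, scc, dtf = simulate_paper_study(seed=1)

by_line = {}
for s in truth.segments:
    by_line.setdefault(s.line, []).append(s)
pmap = build_snpldb_map(by_line, truth.genome.chrom_lengths)
stats = compute_map_stats(pmap)
print(f"{len(pmap.markers)} SNPLDB markers; "
      f"mean recovery {stats.mean_recovery:.2f}%; "
      f"{stats.mean_segments_per_line:.1f} donor segments/line")

print(f"broad-sense heritability: {heritability(dtf, 'dtf').h2:.3f}")

hits = find_cosegregating_markers(pmap, group_lines(scc), "yellow")
print(hits[hits.cosegregating][["marker", "contrast", "n_pg", "n_g", "cpg"]]
      .to_string(index=False))

means = env_means(dtf, "dtf")
lines = [l for l in pmap.lines if l in means.index]
y = means.loc[lines].to_numpy()
X, _ = marker_design(pmap, lines)
res = lrt_scan(y, X, rstep_cofactors(y, X), pmap=pmap)
top = res[res.declared].nlargest(6, "lod")
print(top[["marker", "chrom", "lod", "add", "pve"]].round(2).to_string(index=False))
```

prints

```
1351 SNPLDB markers; mean recovery 96.56%; 5.4 donor segments/line
broad-sense heritability: 0.955
     marker        contrast  n_pg  n_g  cpg
Gm01_LDB_66 green_vs_yellow    11   11  100
Gm08_LDB_13 black_vs_yellow     4    4  100
     marker chrom   lod   add   pve
 Gm12_LDB_8  Gm12 87.58  2.60 26.29
Gm17_LDB_67  Gm17 87.22  1.99 26.01
Gm17_LDB_66  Gm17 81.73  2.01 25.55
Gm10_LDB_48  Gm10 78.68  3.63 20.24
Gm15_LDB_46  Gm15 54.34 -1.17  9.34
Gm17_LDB_64  Gm17 54.04  2.00 21.90
```

Reading the output: the breakpoint-union map bins ~3,000 SNPs into 1,351
block markers; both colour loci co-segregate perfectly with their phenotype
class (C<sub>P&G</sub> = 100%); the ANOVA heritability estimate recovers the
simulated target; and the scan's declared peaks sit in the blocks carrying
the planted QTL, with fitted additive effects (e.g. +3.63 d on Gm10, −1.17 d
on Gm15) close to the planted values (+3.68, −1.00).  Adjacent declared
markers on one chromosome (Gm17) are linked blocks supporting the same QTL.

The same steps are available as a command-line pipeline:

```bash
csslkit simulate --preset paper --seed 1 --out run/
csslkit qc       --vcf run/genotypes.vcf --out run/qc.vcf
csslkit segments --vcf run/qc.vcf --chrom-lengths run/chrom_lengths.tsv --out run/segs.bed
csslkit map      --segments run/segs.bed --chrom-lengths run/chrom_lengths.tsv \
                 --out-markers run/markers.tsv --out-codes run/codes.tsv
csslkit bsa      --markers run/markers.tsv --codes run/codes.tsv \
                 --chrom-lengths run/chrom_lengths.tsv --phenotypes run/scc.tsv \
                 --out run/bsa.tsv
csslkit qtl      --markers run/markers.tsv --codes run/codes.tsv \
                 --chrom-lengths run/chrom_lengths.tsv --phenotypes run/phenotypes.tsv \
                 --out run/qtl.tsv
```

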