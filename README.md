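# hapmet

Haplotype-resolved CpG methylation analysis for nanopore long reads.

Nanopore sequencing reads native DNA, so a single read carries both the
SNPs that identify its parental haplotype and the signal-level evidence of
5-methylcytosine at its CpG sites. In an F1 hybrid this makes it possible
to reconstruct both parental methylomes at modest (~10x) coverage —
something short-read bisulfite approaches struggle with because they need
a SNP inside every short fragment. `hapmet` implements the full analysis
chain for this design:

1. **Per-read haplotyping** from two evidence streams. Each basecalled
   base over a known strain SNP with quality *q* receives a score

       S(q) = 1 − exp(−0.6927 − 0.1203·q),

   contributing *S* if it matches the reference allele and 1 − *S* if it
   matches the alternate; the read's aggregate haplotype value is
   h = (1/n) Σᵢ {Sᵢ or 1 − Sᵢ}. Signal-space genotype calls (an HMM
   re-alignment of the raw current, nanopolish `phase-reads` dialect) are
   scored the same way after a −35 quality offset. The two calls
   H = sgn(h − ½) are combined by an ordered rule table requiring at
   least five informative SNPs and resolving disagreements by count
   (3× rule) and then by confidence (3× rule on |h − ½|).
2. **Maternal recombination resolution**: three-way haplotyping
   (reference / second maternal strain / paternal strain), 100-kb window
   proportions, and a CART-style recursive partition (minsplit = 5,
   cp = 0.1) that segments each chromosome; segments with > 50% FVB-like
   reads have their maternal SNP alleles swapped.
3. **Probabilistic methylation calling**: per read and per CpG *call
   group* (runs of CpGs < 11 bp apart share one call), the methylated /
   unmethylated log-likelihood pair (nanopolish `call-methylation`
   dialect) is converted by Bayes' rule with prior p₀ = 0.5 into
   β = 1 / (1 + ((1 − p₀)/p₀)·L_C/L_M), then averaged over reads per
   haplotype.
4. **Differential methylation**: per call group, methylated/total counts
   per haplotype-sample enter a beta-binomial Wald test with the arcsine
   link Y = arcsin(2(X + ½)/(N + 1) − 1), dispersion shrinkage, the
   1e-5 site threshold, and region aggregation ranked by the area
   statistic — parent-of-origin and strain contrasts from the reciprocal
   crosses.
5. **Concordance and context**: per-site comparison against bisulfite
   calls (thresholds 0.36 nanopore / 0.5 bisulfite), gene-to-DMR
   distances, and length-adaptive loess smoothing
   (α = 0.1 + 8·10⁻¹¹·max(10⁵ − L, 0)²) for per-read visualization
   tracks.

A synthetic-data generator (`hapmet.simulate`) produces every input the
pipeline consumes — SAM alignments, VCF SNP tables, methylation and
signal-score TSVs, bisulfite calls, gene BED — with known truth, so the
whole chain is testable without any sequencing data.

## Worked example

Simulate a reciprocal-cross dataset, haplotype the reads, call
methylation per haplotype and detect DMRs:

```sh
hapmet simulate --seed 11 --out sim --coverage 30
hapmet haplotype --sam sim/cross1.sam --vcf sim/cast.vcf \
    --signal-tsv sim/cross1.signal.tsv --out hap1.tsv
hapmet haplotype --sam sim/cross2.sam --vcf sim/cast.vcf \
    --signal-tsv sim/cross2.signal.tsv --out hap2.tsv
hapmet call-methylation --methylation-tsv sim/cross1.methylation.tsv \
    --haplotype-tsv hap1.tsv --maternal-allele ref --out sum1.tsv
hapmet call-methylation --methylation-tsv sim/cross2.methylation.tsv \
    --haplotype-tsv hap2.tsv --maternal-allele alt --out sum2.tsv
hapmet detect-dmr --summary-tsv sum1.tsv --summary-tsv sum2.tsv \
    --out-prefix dmr
```

`dmr.parent_of_origin.bed` then holds the ranked parent-of-origin DMRs
(BED6+: name = rank, score = area statistic, then contrast, site count
and mean methylation difference). On the seed above the top entries are

```
chr1  300772  301187  1  73.9806  .  parent_of_origin  12  0.802778
chr1  900473  900928  2  67.7336  .  parent_of_origin  11  0.794328
```

— both inside the two maternally methylated regions the simulation
planted at chr1:300000–302000 and chr1:900000–902000, with the
strain-contrast list (`dmr.strain.bed`) picking up only the planted
strain-specific region near chr1:1500000. A maternal FVB block can be
planted with `hapmet simulate --fvb-segment chr1:400000-700000` and
recovered with `hapmet resolve-recombination`; `hapmet compare-rrbs`,
`hapmet distance` and `hapmet smooth` cover bisulfite concordance,
gene-to-DMR distances and per-read loess tracks.

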