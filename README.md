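# ibdcoef

Rank-invariant estimation of individual inbreeding and kinship coefficients
from biallelic SNP genotypes, with the supporting machinery needed to
validate such estimators end to end: pedigree coancestry algebra, a
gene-dropping simulator that tracks identity by descent (ibd) exactly, and
a runs-of-homozygosity caller.

## The problem

The inbreeding coefficient *F*<sub>j</sub> is the probability that the two
alleles individual *j* carries at a locus are identical by descent relative
to some reference population. *F* itself is not estimable from genotypes
alone — ibd is always relative to a reference that the data do not
identify. What is estimable is the **within-population** inbreeding
coefficient

  *f*<sub>j</sub> = (*F*<sub>j</sub> − θ<sub>S</sub>) / (1 − θ<sub>S</sub>),

the inbreeding of *j* measured against the average coancestry θ<sub>S</sub>
of a reference set of individuals chosen by the investigator.

Most popular estimators (PLINK `--het`, GCTA `--ibc`, VanRaden GRM
diagonals) plug sample allele frequencies into moment formulas. Their
large-sample expectations are confounded by each individual's average
kinship ψ<sub>j</sub> with the rest of the sample:

| estimator | large-sample expectation |
|---|---|
| f̂<sub>HOM</sub> = 1 − Σ<sub>l</sub>H̃<sub>jl</sub> / Σ<sub>l</sub>2p̃<sub>l</sub>(1−p̃<sub>l</sub>) | *f*<sub>j</sub> |
| f̂<sub>UNI</sub><sup>w</sup> = Σ<sub>l</sub>[X²−(1+2p̃)X+2p̃²] / Σ<sub>l</sub>2p̃(1−p̃) | *f*<sub>j</sub> − 2ψ<sub>j</sub> |
| f̂<sub>STD</sub><sup>w</sup> = Σ<sub>l</sub>(X−2p̃)² / Σ<sub>l</sub>2p̃(1−p̃) − 1 | *f*<sub>j</sub> − 4ψ<sub>j</sub> |
| f̂<sub>AS</sub> = Σ<sub>l</sub>(Ã<sub>jl</sub>−Ã<sub>Sl</sub>) / Σ<sub>l</sub>(1−Ã<sub>Sl</sub>) | *f*<sub>j</sub> (all *n*) |

Because ψ<sub>j</sub> changes with the sample, the *ranking* of
f̂<sub>UNI</sub>/f̂<sub>STD</sub> estimates changes when the reference
sample changes — the same genotype can look most or least inbred depending
on which other individuals are analysed alongside it.

The **allele-sharing estimator** f̂<sub>AS</sub> avoids allele frequencies
entirely. It compares an individual's homozygosity
Ã<sub>jl</sub> = (X<sub>jl</sub>−1)² to the mean sharing
Ã<sub>Sl</sub> between pairs of reference individuals. For fixed genotypes
it is a strictly increasing linear function of total homozygosity, so its
ranking over any set of individuals is *invariant* to the choice of
reference set, it is unbiased for *f*<sub>j</sub> at every sample size, and
it needs no minor-allele-frequency filtering.

## Worked example

Simulate a five-generation random-mating pedigree from 50 founders, drop
founder-labelled gametes over a 20-chromosome map (2,000 markers), paint
founder SNP haplotypes onto the labels, and estimate:

```python
import numpy as np, ibdcoef as ib

ped  = ib.simulate_random_mating_pedigree(50, 5, mean_offspring=2.0, seed=11)
gmap = ib.GeneticMap.uniform(n_chrom=20, length_cm=100.0, spacing_cm=1.0)
res  = ib.drop_gametes(ped, gmap, seed=12)
hap  = ib.generate_founder_haplotypes(50, gmap.n_markers, seed=13)
G    = ib.paint_genotypes(res, hap)

nf    = np.flatnonzero(~ped.is_founder)
gold  = ib.gold_coefficients(res, nf)          # realized ibd, exact
table = ib.estimate_table(G.subset_samples(nf),
                          estimators=["f_AS", "psi_AS", "f_HOM",
                                      "f_UNI_w", "f_STD_w"])
print(table.head(5).round(4))
```

```
             f_AS  psi_AS   f_HOM  f_UNI_w  f_STD_w
sample_id
G1-9      -0.0373  0.0057 -0.0407  -0.0521  -0.0635
G1-10      0.0101  0.0040  0.0069  -0.0012  -0.0092
G1-1      -0.0373 -0.0576 -0.0407   0.0746   0.1898
G1-34     -0.0011  0.0175 -0.0043  -0.0394  -0.0744
G1-35      0.0185  0.0163  0.0153  -0.0173  -0.0499

non-founders: 152   markers: 2000
gold theta_S = 0.0325   gold F_W = 0.0122   gold f_W = -0.0211
mean f_AS    = -0.0180   corr(f_AS, gold f) = 0.651
```

Reading the output: `f_AS` and `f_HOM` agree closely (they share a target),
while `f_UNI_w` and `f_STD_w` differ from them by exactly 2ψ̂ and 4ψ̂ —
individual `G1-1` has a strongly negative average kinship (ψ̂ = −0.058), so
the frequency-based estimators inflate its apparent inbreeding (0.07, 0.19)
relative to its allele-sharing value (−0.04). Negative estimates are
meaningful: they flag individuals less inbred than the sample is related on
average. The mean f̂<sub>AS</sub> matches the gold within-population mean
(−0.018 vs −0.021); at this marker density individual estimates carry
sampling noise (correlation 0.65 with realized *f*; it reaches 0.90 at the
full 20,000-marker density, matching the run in `tests/test_acceptance.py`).

The same workflow is available from the shell:

```sh
ibdcoef simulate --founders 50 --generations 5 --loci 2000 --seed 11 --out-prefix sim
ibdcoef estimate --vcf sim.vcf --out est
ibdcoef roh --vcf sim.vcf --min-snps 100 --min-kb 100 --out roh
ibdcoef rank --estimates est.estimates.tsv --out ranks.tsv
```

## Layout

- `ibdcoef.genotypes` — dosage matrices, allele-sharing statistics
- `ibdcoef.estimators` — all SNP-by-SNP estimators, expectations, ranks
- `ibdcoef.pedigree` — coancestry recursion, path-counting oracle, Table-style parameter transforms
- `ibdcoef.genedrop` — pedigree simulation, recombination, gold ibd, genotype painting
- `ibdcoef.roh` — consecutive-run ROH caller and F_ROH
- `ibdcoef.io` / `ibdcoef.cli` — VCF/TSV readers and writers, subcommands
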