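# Methods

## Model

All estimators address allelic dependence at biallelic SNPs. Writing
`X[j,l]` for the dosage of a counted allele, the within-individual sharing
indicator is `A[j,l] = (X[j,l]-1)^2` (1 for homozygotes, 0 for
heterozygotes) and the between-individual sharing for a pair is
`A[j,j',l] = (1 + (X[j,l]-1)(X[j',l]-1))/2`. Under an ibd model in which
the probability of a heterozygote is `2*pi*(1-pi)*(1-F_j)` for an unknown
ancestral frequency `pi`, the expectations of `1 - A[j,l]` and
`1 - A_S[l]` (the pair average over a reference set) share the nuisance
factor `2*pi*(1-pi)`, which cancels in the ratio

    f_AS_j = sum_l (A[j,l] - A_S[l]) / sum_l (1 - A_S[l]).

This is the package's central estimator. Its key structural property needs
no asymptotics: for fixed genotypes it is `a_S + b_S * (total homozygosity
of j)` with `b_S > 0` common to all individuals, so enlarging or shrinking
the reference set rescales the estimates linearly and never reorders them.
The frequency-based estimators (`f_HOM`, `f_UNI`, `f_STD`, the grid-search
MLE) are implemented alongside for comparison; their large-sample targets
are `f_j`, `f_j - 2*psi_j` and `f_j - 4*psi_j` respectively, where `psi_j`
is the individual's average within-population kinship with the rest of the
sample. All multi-locus combinations are ratios of averages (numerators
and denominators summed over loci before dividing); the unweighted UNI/STD
variants average per-locus ratios and exist because they are in wide use,
not because they are recommended — their per-locus denominators
`2*p*(1-p)` up-weight rare alleles and destabilize the estimates.

Estimates are reported relative to a *reference set*: the individuals whose
pair-average sharing (or allele frequency) anchors zero. Every estimator
accepts a reference subset while reporting estimates for all individuals,
which is how population/continent/world comparisons are produced.

## Finite-sample expectations

`expected_value()` evaluates closed-form finite-`n` expectations for the
weighted estimators in terms of the parametric `f_j`, `f_W`, `psi_j` of
the reference sample. The allele-sharing rows are exact at every `n`; the
`f_HOM` rows carry the classic `-(1+f_W)/(2n)` small-sample depression,
which the replicated simulation study in the test suite confirms at
`n = 20`. The UNI/STD finite-`n` rows are evaluated as conventionally
printed, but direct Monte Carlo under Hardy–Weinberg sampling (and exact
algebra for the independent case, where the per-locus UNI numerator has
expectation `-p(1-p)/n`) supports a `-1/(2n-1)` correction rather than the
printed `-3/(2n-1)`; the simulation-based tests therefore validate UNI/STD
against their large-sample targets `f - 2 psi` and `f - 4 psi` with an
explicit order-`1/n` bias allowance, and no test asserts the UNI/STD
finite-`n` rows against simulation.

## Pedigree algebra

Coancestry is computed by the tabular recursion (`theta(j,k)` = mean of
parental coancestries with `k`; self-coancestry `(1 + theta(p1,p2))/2`),
with founders unrelated and non-inbred unless a founder kinship matrix is
supplied. An independent path-counting evaluation of
`F_j = sum over paths (1/2)^n (1 + F_A)` is kept in the package as the
cross-check oracle; it is exponential in pedigree depth and intended for
validation, not production. Within-population parameters apply
`f = (F - theta_S)/(1 - theta_S)` to a chosen subset; the `psi_j` average
to zero over the subset by construction. One-known-parent records are
rejected by default (an explicit option promotes the missing parent to a
new founder) and matrices are dense — pedigrees here are desk-scale.

## Gene dropping

The simulator reproduces a validation design in which truth is observed
rather than inferred:

- **Pedigree**: hermaphroditic monogamous random mating. Each generation
  is shuffled into pairs without replacement (an odd individual is left
  unpaired), each pair produces Poisson(`mean_offspring`) children, and
  selfing is impossible by construction. Defaults — 50 founders, 5
  generations, mean two offspring — give a closed population of a few
  hundred with average coancestry of a few percent. Mate pairing schemes
  differ among forward simulators; with per-offspring random parent draws
  instead of monogamous broods, drift (and hence coancestry) would be
  somewhat faster for the same census size.
- **Meiosis**: Haldane model. Per chromosome, a random start haplotype and
  a Poisson(`length in Morgans`) number of crossovers placed uniformly on
  the cM scale; no interference, no mutation. The default map is 20
  chromosomes of 1 Morgan with a marker every 0.1 cM (20,000 markers);
  the bundled scaled-down map uses 1 cM spacing (2,000 markers).
- **Gold standard**: each founder carries two globally unique allele
  labels, so realized inbreeding is the fraction of markers at which an
  individual's two labels match, and realized coancestry is the match
  fraction over the four cross-haplotype comparisons. These are exact
  realized ibd proportions, not estimates. Per-individual average kinship
  is computed in O(nL) from per-marker label counts; the full pairwise
  matrix is O(n^2 L) and computed on demand.
- **Painting**: founder label `k` is replaced by row `k` of a founder
  haplotype matrix, so ibd implies identity in state at every marker. The
  default founder model draws per-locus frequencies from a `1/x` density
  truncated to `[1/(4 n_f), 1 - 1/(4 n_f)]` — a neutral-spectrum-like
  choice that yields many rare variants and keeps loci off fixation — with
  haplotype alleles i.i.d. Bernoulli given the frequency. Coalescent
  output (e.g. msprime) can be supplied as a ready-made haplotype matrix
  instead.

What the generator does *not* emulate: linkage disequilibrium among
founder haplotypes under the default frequency-spectrum model (sites are
independent given frequencies; use supplied coalescent haplotypes for
realistic LD), mutation during dropping, selection, migration, overlapping
generations, and genotyping error. Passing tests therefore demonstrate
correctness of the estimators under the ibd model and the stated meiosis
model, not robustness to genotyping artefacts.

## Runs of homozygosity

`detect_roh` is a deterministic consecutive-run scan, not a sliding-window
vote: per individual and chromosome it reports maximal non-overlapping
runs containing at most `max_het` heterozygous and `max_missing` missing
calls, trimmed to homozygous endpoints, subject to `min_snps` (default
100) and `min_kb` (default 100). Candidate windows start only on
homozygous calls so that a leading heterozygote cannot silently consume
the het budget of a longer run; the scan is verified against exhaustive
enumeration. `F_ROH` divides summed segment lengths by the genome length
(sum of per-chromosome spans unless overridden). F_ROH targets absolute
`F` rather than within-population `f`, but its value is conditional on the
calling parameters and has no closed-form expectation.

## Numerical choices

- Missing genotypes: per-locus pairwise deletion everywhere; frequencies,
  sharing averages and denominators use only individuals genotyped at the
  locus. Loci with fewer than two genotyped reference individuals error by
  default (`on_unusable_locus="drop"` skips them).
- Monomorphic loci: kept for allele-sharing and weighted frequency-based
  estimators (their numerator and denominator contributions vanish
  together); dropped automatically for the unweighted variants whose
  per-locus ratio is undefined.
- The pairwise allele-sharing kinship matrix has two modes: `exact`
  (denominator `sum(1 - A_S)`; off-diagonal mean exactly zero when the
  reference is the whole sample) and `large_sample` (denominator
  `sum 2p(1-p)`; satisfies `psi_AS_jj' = psi_STD_jj' + psi_AS_j +
  psi_AS_j'` identically). The two differ at order `1/n`; individual
  `psi_AS` defaults to the closed large-sample form, which sums to zero
  exactly.
- MLE grid: `[-1, 1]` in steps of 0.001, per-point validity checks on
  every log argument, ties broken toward the smaller `f`.
- Ranks: average ranks for ties. Identity tests use 1e-10 tolerances
  (pure rational arithmetic in floating point); rank comparisons round to
  1e-9 first because exact ties can differ by one ulp across summation
  orders.
- Reproducibility: all simulation entry points take integer seeds (or
  Generators); the CLI derives per-stage child seeds from one master seed
  and records them in a run-metadata JSON.

## Problem sizes in the test suite

The replicated bias study runs 200 gene drops of a 50-founder,
5-generation pedigree at 2,000 markers — chosen so that Monte-Carlo
standard errors resolve the `O(1/n)` biases under study while the suite
stays fast; single-shot correlation checks between estimates and realized
ibd run once at the full 20,000-marker density, where estimation noise no
longer masks the inbreeding spread of a random pedigree realization.

## Known limitations

- Estimator variances are not reported; only point estimates.
- No LD pruning or MAF filtering options: the allele-sharing estimator
  needs neither, and the frequency-based estimators are provided for
  comparison rather than production use.
- The ROH caller does not classify segments by length (recent vs ancient
  ibd) and is not a hidden-Markov model.
- Pedigree coancestry is dense `O(n^2)` memory; not intended for
  livestock-scale pedigrees.
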