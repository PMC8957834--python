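# corepanel

Select a small "core" panel of SNPs whose joint genotypes uniquely identify
every sample in a genotyped population, and emit per-sample DNA fingerprint
codes.

Breeding programmes and germplasm banks need to tell hundreds of closely
related varieties apart cheaply. Whole-genome SNP matrices (millions of loci)
can do this trivially but are far too large to assay routinely; the practical
question is combinatorial: find ~100 loci out of M candidates such that no two
samples share a genotype profile. `corepanel` solves this feature-compression
problem with a genetic algorithm (GA) and validates the resulting panel with
the population-genetic statistics used for fingerprint panels (PIC, pairwise
genotype-mismatch distances, panel-vs-full distance correlation).

## Method

Given an N-samples x M-loci diploid biallelic genotype matrix S (states 0/0,
0/1, 1/1, ./.), candidate loci are first filtered:

1. drop loci with missing-call fraction > 1% (strict);
2. drop loci with fewer than 2 samples of either homozygote class;
3. thin adjacent loci on the same chromosome with genotype-dosage r² > 0.95
   (standard cascade pruning by default; a `literal_retain` mode keeps exactly
   the members of high-r² adjacent pairs instead).

A GA individual is a panel g = (l₁, …, l_C) of C distinct locus indices. Its
raw fitness is

    F = U / N,

where U is the number of samples whose profile — the ordered tuple of
genotype codes at the panel's loci — occurs exactly once among the N samples.
The population of P panels evolves by fitness-proportional roulette selection
(optionally through linear rank fitness FitnV(pos) = 2 − sp + 2(sp−1)(pos−1)/(Nind−1)
or its nonlinear analogue), single-point tail-swap crossover with duplicate
repair, mutation of round(0.3·C) positions, and an elitist merge of parents
and offspring truncated back to P, for X generations. Ties among equally fit
final panels go to the panel spread most evenly across chromosomes.

Fingerprints code each panel genotype as 0/0 → `1`, 1/1 → `2`, 0/1 → `0`,
missing → `-`, giving one length-C string per sample.

A synthetic-population module (Balding–Nichols subgroup model with
configurable missingness and duplicated adjacent loci) makes the whole
pipeline testable without any external dataset.

## Worked example

```sh
corepanel pipeline --samples 50 --loci 300 --panel-size 12 \
    --pop-size 30 --iters 100 --seed 42 --out demo
```

logs (abridged):

```
pipeline: simulated 50 x 300
pipeline[filter:missing]: 300 -> 178
pipeline[filter:homozygote]: 178 -> 131
pipeline[filter:ld]: 131 -> 121
select: best fitness 1.0000 after 50 generations; panel of 12 loci
pipeline: 50/50 distinct fingerprint codes, mean PIC 0.3375
```

The simulator drew 50 samples over 300 loci; the three filters kept 121
candidate loci; the GA found a 12-SNP panel with fitness 1.0, i.e. all 50
samples are uniquely identified, and every fingerprint code in
`demo/fingerprints.tsv` is distinct:

```
sample  code
S0001   002022220221
S0002   201020202020
S0003   200000200022
```

`demo/report.json` holds the validation statistics, e.g. discrimination
fraction 1.0, mean panel PIC 0.337 (the biallelic ceiling is 0.375), and the
closest pair of samples differing at 1 of the 12 panel loci. The library API
mirrors the CLI: `simulate_population`, `apply_filters`, `run_ga`,
`binary_fingerprint`, `evaluate_panel`.

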