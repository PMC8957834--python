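# Methods

## Problem and model

Given N diploid samples genotyped at M biallelic SNPs, a *core panel* is a
set of C loci whose joint genotypes distinguish every sample. Finding the
smallest or best such subset is a combinatorial feature-selection problem
(subset search over C(M, C) panels), attacked here with a genetic algorithm
over panels. The deliverable per sample is a fingerprint string over
`{0, 1, 2, -}` (0/1 → `0`, 0/0 → `1`, 1/1 → `2`, missing → `-`).

Genotypes are stored as a samples x loci `int8` matrix over
{REF_HOM = 0, HET = 1, ALT_HOM = 2, MISSING = −1}; the observed states double
as ALT dosage. Inside the GA the matrix is mapped to the integer codes
45 (missing), 97 (0/0), 98 (1/1), 104 (0/1) — the ASCII codes of `-`, `a`,
`b`, `h`, mirroring the A/B/h/- text encoding used in the TSV interchange
format. The two encodings are bijective with the call states; round-trips are
exact.

## Filtering

Three stages, fixed order, each idempotent and reported per locus:

| stage | rule (locus survives iff) | default |
|---|---|---|
| missing | missing fraction ≤ `max_missing_fraction` (strictly greater removed) | 0.01 |
| homozygote | ≥ `min_homozygote_count` samples of *each* homozygote class | 2 |
| LD | see below | r² > 0.95 |

Adjacent-pair r² is the squared Pearson correlation of ALT dosages over
samples called at both loci, computed only for neighbouring loci on the same
chromosome. Pairs with < 2 complete observations or zero variance at either
locus get r² = 0 by convention. The default LD mode is a standard
left-to-right cascade prune: a running survivor is kept and the next locus is
dropped whenever its r² with the survivor exceeds the threshold, so a run of
duplicated loci keeps exactly one representative. A `literal_retain` mode
instead keeps exactly the loci participating in at least one high-r² adjacent
pair; this inverts pruning and empties a matrix with no LD, but is provided
because the rule is sometimes stated that way. Only adjacent pairs are
tested — with position-sorted reduced-representation data this is where
redundant markers sit, and it keeps the stage O(M).

## Genetic algorithm

* **Individual**: an ordered array of C distinct locus indices.
* **Fitness** F = U/N: the fraction of samples whose profile — the *ordered
  tuple* of panel genotype codes — is unique in the population. A sum of
  codes would collapse distinct profiles (e.g. 97+104 = 98+103-type
  collisions) and is deliberately not used. With `missing_wildcard` enabled,
  a missing call matches any genotype, and a sample counts as identified
  only when no other sample is compatible with it — a conservative mode for
  data with substantial missingness (O(N²C) instead of O(NC), off by
  default).
* **Selection**: probabilities Oᵢ = Fᵢ/ΣF (uniform when ΣF = 0), sampled by
  cumulative-interval roulette. Optional rank transforms replace raw fitness
  first: linear FitnV(pos) = 2 − sp + 2(sp−1)(pos−1)/(Nind−1) with selection
  pressure sp ∈ [1, 2], or nonlinear Nind·X^(pos−1)/Σ X^(i−1) with free base
  X > 0. Members are ranked ascending so pos = Nind is the best; both
  transforms sum to Nind. Default is `none` (raw fitness): the transforms are
  exposed but not wired in implicitly, since nothing forces a particular
  pairing of ranking and roulette.
* **Crossover** (probability 0.8): single point B1 uniform on [1, C−1], tails
  swapped; a locus duplicated within a child is replaced by the smallest
  locus absent from that child, in ascending order, making repair
  deterministic given the crossover point. C = 1 panels pass through
  unchanged.
* **Mutation** (probability 0.1): round(0.3·C) distinct positions
  (half-away-from-zero rounding; the fraction is configurable) are emptied
  and refilled by draws without replacement from the ascending list of loci
  absent from the remainder of the panel, so an emptied locus may re-enter.
* **Merge**: parents and offspring are concatenated, panels with identical
  locus *sets* are deduplicated, and the top P by fitness survive (stable
  sort, parents first on ties). If deduplication leaves fewer than P, fresh
  random panels refill the population; on tiny universes that exhaust all
  distinct C-subsets, duplicates are admitted after a bounded number of
  draws. Elitism makes the best-fitness trace non-decreasing.
* **Termination**: X generations (default 500), or early once the best
  fitness has been 1.0 for 50 consecutive generations — at 1.0 further
  search cannot improve the objective, and the patience window lets the rest
  of the population consolidate alternative optimal panels for the
  tie-break.
* **Tie-break**: among final panels sharing the maximal fitness, the one
  minimising the maximum per-chromosome locus count (most even genomic
  spread) wins; remaining ties go to the lexicographically smallest sorted
  index tuple.

Defaults: C = 100, P = 100, X = 500, crossover 0.8, mutation 0.1, fraction
0.3. All randomness flows from one `numpy` Generator seeded by `rng_seed`;
runs are bit-identical under a fixed seed. An exhaustive
`brute_force_best_panel` (guarded at 10⁶ combinations) serves as an
independent optimality oracle in the tests.

## Panel validation

* **Discrimination fraction**: F of the chosen panel with missing-as-symbol
  semantics; fingerprint codes are pairwise distinct iff this is 1.0.
* **Pairwise differing loci**: counts of panel loci where both samples are
  called and differ (symmetric, zero diagonal, ≤ C).
* **Mismatch distance**: differing / shared non-missing loci; pairs sharing
  no called locus get distance 1 with a warning. This simple
  genotype-mismatch proportion is used because the panel-vs-full comparison
  only needs a monotone pairwise dissimilarity.
* **Panel fit**: Pearson correlation of the strict upper triangles of the
  panel and full-matrix distance matrices (a Mantel-style statistic;
  "correlation between two genotype matrices" of different widths is
  otherwise undefined). Equal matrices give exactly 1; the mean correlation
  grows with panel size on simulated data.
* **Allele frequency and PIC**: p = (2·ref_hom + het)/(2·called);
  PIC = 1 − (p² + q²) − 2p²q², the standard biallelic form, with ceiling
  0.375 at p = 0.5 and symmetry in p ↔ q.

## Synthetic populations

The simulator emulates a structured diversity panel, not a genealogy: per
locus an ancestral REF frequency is uniform on [0.05, 0.95]; each of K
subgroups perturbs it with a Balding–Nichols Beta draw at divergence F
(default 0.15, a moderate differentiation typical of crop and livestock
panels); genotypes are Binomial(2, q) dosages; samples are assigned to
subgroups round-robin. A fraction of loci (default 10%) are exact copies of
their left neighbour, giving known perfect-LD adjacent pairs for the LD
filter; targets are isolated so each contributes exactly one such pair.
Missingness is injected independently per call (default 1%). Loci are split
evenly over `n_chromosomes` with positions 1000, 2000, … per chromosome.
Defaults (200 samples x 1000 loci, 5 subgroups) describe a mid-sized
diversity panel and are the conditions the end-to-end checks run under.

What the simulator does *not* model: recombination-driven LD decay,
haplotype genealogies, genotyping error biased by depth, polyploid dosage
ambiguity. Passing tests therefore demonstrate the correctness and
convergence of the algorithmics under realistic marginal allele-frequency
and structure conditions, not calibration against any real organism's LD
landscape.

## Numerical and design notes

* Missing calls are ordinary profile symbols by default, so two samples
  differing only in missingness count as distinguished; `missing_wildcard`
  gives the conservative alternative.
* Dosage r² (not haplotype r²) is used for LD: genotype data here are
  unphased.
* VCF reading keeps only biallelic SNP records (multi-allelic, indel and
  symbolic records are skipped with a logged count); phase separators are
  ignored; half-calls are missing. Positions stay 1-based throughout.
* Degenerate inputs: empty panels give empty fingerprints; a constant
  distance triangle makes the panel-fit correlation an error rather than a
  NaN; all-missing loci give NaN allele frequency with a warning.
* Problem sizes in the test suite (8 x 15 exhaustive oracle with C = 3;
  200 x 1000 end-to-end with C = 100; 20-replicate property checks at
  40–100 samples) were chosen so each check exercises the intended regime
  while the whole suite stays interactive.

## Limitations

* Fitness counts exact profile uniqueness only; it does not optimise the
  margin (minimum pairwise differing loci), which matters for assay error
  tolerance. The pairwise-differing report exposes the margin post hoc.
* The GA is single-population and single-objective by design; no
  multi-objective spread/fitness trade-off.
* `literal_retain` LD mode can remove all loci when no adjacent pair is in
  LD; it is provided for fidelity to the alternative rule statement, not as
  a recommended default.
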