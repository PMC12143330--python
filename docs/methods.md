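# Methods

`hapase` implements allele-specific expression (ASE) inference for phased,
multi-tissue bulk RNA-seq cohorts. This note records the statistical model,
the defaults and why they are set where they are, what the synthetic-data
generator does and does not emulate, and the numerical choices a maintainer
would want to know about.

## The beta-binomial model of allelic counts

At a heterozygous SNV covered by `n` reads, the number of reads supporting
one allele is modeled as beta-binomial with mean allelic ratio `α ∈ (0,1)`
and overdispersion `ρ ∈ [0,1)` under the intraclass-correlation (ICC)
parameterization

    a = α(1−ρ)/ρ,   b = (1−α)(1−ρ)/ρ,

so that the correlation between any two reads at the locus equals `ρ`
exactly and `ρ → 0` recovers the binomial (`ρ = 0` is treated as an exact
binomial). Overdispersion absorbs the extra-binomial variance of allelic
fractions (sampling of transcriptional bursts, library amplification) that
makes a plain binomial test anticonservative.

**Two-tailed p-value.** The default (`inclusive`) tail definition is
`p = min(1, 2·min(P(X ≤ x), P(X ≥ x)))`. The alternative `literal`
mode, `p = min(1, 2·min(CDF(x), 1−CDF(x)))`, is retained because it is the
textbook "twice the CDF or its complement" rule; it returns exactly 0 at
`x = n` (and is asymmetric, because its lower tail includes the observation
while its upper tail excludes it). A p-value of 0 at monoallelic sites
breaks rank-based FDR, which is why `inclusive` — strictly positive
everywhere and symmetric under the balanced null — is the default. The
inclusive test is conservative: its exact type-I error at nominal 0.05,
computed by enumerating the rejection region, is ≤ 0.05 at every depth the
test suite checks.

**Testing.** Each sample (animal × tissue) is an independent testing family:
all of a sample's informative SNVs are tested against the balanced null
(`α₀ = 0.5`, constant `ρ = 0.001`) and Benjamini-Hochberg corrected
together; gene-level tests form a second, separate family per sample. The
tested count is the reference count (haplotype-1 count at gene level); the
null is symmetric so the choice is immaterial, and a test asserts this.

**Gene-level ASE** is the same beta-binomial test applied to phased
haplotype-aggregated counts: per sample and gene, `x` sums the reads on
haplotype 1 across the gene's phased SNVs and `y` sums all reads. This keeps
one self-consistent likelihood from SNV level through the mixture model —
it is the same aggregation the tissue-switching model consumes — rather than
introducing a second, meta-analytic gene statistic. Aggregating reads across
SNVs double-counts fragments that span two SNVs; at typical SNV spacing this
is rare, and it biases toward conservatism in no particular allelic
direction.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `min_reads` | 10 | reads | below ~10 reads the two-tailed test cannot reach p < 0.05 even for monoallelic counts; shallower sites are uninformative |
| `rho` | 0.001 | ICC | the cohort-wide constant; the empirical per-SNV MLE median on dispersion-calibration data sits near this value (the generator's truth, recovered within a factor of ~1.5 by the test suite) |
| `null_alpha` | 0.5 | ratio | balanced expression; reference bias measured separately is ~0.5, so no null shift is warranted |
| `fdr_q` | 0.05 | — | conventional BH threshold, strict inequality `q < 0.05` |
| `k_max` | 3 | components | tissues per animal ≤ 11; more than 3 allelic regimes per gene is not identifiable at that N |
| `min_ase_snvs` | 4 | SNVs | eligibility for the mixture and imprinting screens: enough independent phased sites to trust the haplotype signal |
| `min_ase_tissues` | 6 | tissues | a switching call needs a majority of tissues showing ASE to compare regimes |
| `delta` | 0.1 | ratio | side band around 0.5 for switching: a component must sit clearly on one side (α < 0.4 or α > 0.6) |
| min component weight | 1/(2N) | — | lets a single flipped tissue out of N ≥ 6 still form a detectable component |
| `min_animals_per_side` | 2 | animals | cross-animal switching requires at least two animals favoring each canonical haplotype |
| mixture starts | 10 random + deterministic (standalone); 4/3 random in the cohort scan | — | see "Numerical choices" |

## Dispersion estimation

Per SNV, `(α, ρ)` are estimated jointly by maximizing the beta-binomial
likelihood across that SNV's samples on the `(logit α, log ρ)` scale with
`ρ` bounded to `[1e−8, 0.5]`, from two deterministic starts. Estimating `α`
jointly (rather than fixing `α = 0.5`) avoids inflating `ρ̂` at genuinely
imbalanced SNVs, at the cost of absorbing some dispersion into `α̂` for
SNVs observed in few samples. Only SNVs with ≥ `min_reads` reads per
retained observation and both alleles seen in at least one sample enter the
estimate; the median of the per-SNV MLEs is reported, and the constant used
downstream defaults to 0.001 (settable to the estimated median).

## Power analysis

Power is computed two ways, which must agree: Monte Carlo (10,000 simulated
datasets per effect × depth cell, the procedure a simulation study would
run) and exact enumeration (`power = Σ pmf_alt(x)` over the rejection region
`{x : p(x) < 0.05}`), which is the deterministic oracle. Alternative draws
use the same `ρ` as the null. The default grid spans allelic ratios
0.01–0.99 (step 0.07) × depths {200, 100, 75, 50, 25, 10}.

## The tissue-switching mixture model

Within an animal, a gene's per-tissue haplotype-1 counts `x_i` of `y_i`
follow

    L(x, y | π, α, ϕ) = Π_i Σ_k π_k · BB(x_i; y_i, α_k, ϕ),

with `Σπ_k = 1`, `π_k > 0`, `0 < α_k < 1`, and one shared overdispersion
`ϕ`. K is chosen by forward likelihood-ratio testing: starting at K = 1,
K+1 is accepted while `2Δℓ` exceeds the χ² critical value with **2 degrees
of freedom per added component** (one ratio, one weight) at p < 0.05.
Mixture-order LRTs are non-regular (the true null distribution at the
boundary is a mixture of χ²s, making df = 2 conservative); the calibration
test confirms empirically that a second component is accepted in well under
10% of single-regime replicates. Reported components are sorted by `α`;
the log-likelihood is invariant to permutation.

A fitted pair is **consistent** when K = 1 or all components sit on one
side of 0.5, and **switching** when components with weight ≥ 1/(2N) sit on
both sides of the `±delta` band. Pairs with components inside the band on
one side only are neither (reported as such).

## Canonical haplotype labels and cross-animal comparison

Within-animal haplotype labels are arbitrary, so cross-animal statements
need an anchor. Per gene, the anchor SNV is the lowest-position site
heterozygous in the most animals; canonical haplotype 1 carries the
*reference* allele at the anchor. Animals not heterozygous at the anchor
are oriented transitively: oriented animals vote on which allele each
remaining site carries on canonical haplotype 1, and unoriented animals are
matched through the best-ranked shared site. The procedure is deterministic
given the input; genes with no shared heterozygous site are flagged
non-comparable and excluded from cross-animal calls. Labels are comparable
across animals within a gene, never between genes.

A gene × tissue shows **cross-animal switching** when ≥ 2 ASE animals favor
canonical haplotype 1 and ≥ 2 favor haplotype 2.

## Imprinting screen

Candidates must have ≥ 4 distinct ASE SNVs phased into a single haplotype
block, and be *completely* monoallelic (zero reads from one haplotype) in
every sample where the gene is ASE, with one expressed haplotype per animal
(tier "within-animal-consistent"). Genes whose expressed haplotype is also
the same canonical haplotype in every animal are tier
"all-sample-consistent" — the imprinting-like signature; per-animal splits
suggest cis-regulatory haplotype effects instead. A supplied list of known
imprinted genes only populates a flag column; it never affects candidacy.

## The synthetic-data generator

The generator emulates the cohort shape the pipeline targets: 12 animals ×
11 tissues, ~1,000 genes, SNVs per gene `1 + NB(r=4, p=0.25)` (median 12),
per-SNV-sample depth `NB(r=10, p=1/6)` (median 48, floor 0 so the ≥ 10-read
filter is exercised naturally), heterozygosity probability 0.6 per
animal-SNV, counts beta-binomial with `ρ = 0.001`, and planted gene classes
(70% balanced, 20% biallelic ASE with ratios drawn U(0.7, 0.9), 5%
monoallelic/imprinted, 3% tissue-switching, 2% cross-animal-switching).
Which founder haplotype a gene over-expresses is a coin flip per gene, so
reference and alternate alleles are favored equally often cohort-wide and
the measured reference bias is ~0.5. Reference bias is a logit shift of the
mean reference fraction, off by default (`ref_bias = 0.5`). Half of the
imprinted genes express one founder in every animal (tier-2-like); the
other half pick the expressed founder per animal (tier-1-only-like).

Each gene has exactly **two founder haplotypes** — one carrying the
alternate allele at every SNV of the gene, one the reference — and every
heterozygous animal carries both, with local haplotype-1/2 labels (and
phase blocks, when `phase_block_split_prob > 0`) randomized. This makes
cross-animal canonicalization exactly recoverable, which is what the
pipeline tests need. It is a deliberate simplification: real genes segregate
many founder haplotypes with partial allele sharing, recombination breaks
founder identity along the gene, alignment bias is allele-specific rather
than a global shift, and counts at nearby SNVs are correlated through shared
fragments. Passing tests on synthetic cohorts therefore demonstrate the
statistical machinery (calibration, recovery, bookkeeping), not robustness
to those real-data artifacts.

The committed worked fixture is a hand-constructed 2-animal × 3-tissue ×
5-gene dataset covering every branch (balanced, strong ASE, monoallelic,
one flipped tissue, an unphased SNV, and four sub-threshold rows); golden
result tables pin the full pipeline byte-for-byte.

## Numerical choices

* **PMF/CDF** are evaluated from a log-space table over the full support
  built from cumulative sums of `log(a+j)`/`log(b+j)` (log rising
  factorials). This stays accurate for the enormous shape parameters tiny
  `ρ` produces, where `betaln`-difference forms lose ~1e−6 in the log; the
  binomial limit then holds to 1e−6 at `ρ = 1e−9`. Tail p-values accumulate
  each tail from its own end of the support, so extreme p-values (down to
  ~1e−300) keep full relative accuracy, and `P(X ≥ 0)` is exactly 1.
* **Vectorized testing** groups records by depth and reuses one table per
  unique `n` — cohort-scale SNV testing is a table lookup.
* **Likelihood terms inside optimizers** use the `gammaln` form (valid for
  the optimizer range `ρ ≥ 1e−8`) with analytic gradients via `digamma`;
  because `ϕ` is shared, `a_k + b_k` is component-independent, which both
  simplifies the gradient and removes one special-function call.
* **Mixture optimization** works on unconstrained transforms (`logit α`,
  softmax weight logits, scaled-logit `ϕ` in `[1e−8, 0.5]`), box-bounded to
  ±14 so boundary-monoallelic series register as converged instead of
  drifting along flat directions. Multi-start policy: deterministic starts
  at per-tissue ratio quantiles (two `ϕ` scales), a warm start that splits
  the widest component of the (K−1)-fit (which also guarantees the nested
  log-likelihood ordering), plus random restarts (10 standalone; 3 in the
  cohort scan, where the warm and quantile starts carry most of the
  weight — a documented speed/robustness trade-off).
* **Cohort-scale fitting** stacks series in blocks of 64 into one
  block-diagonal optimization (the likelihood separates, so the joint
  optimum is the per-series optima): each start gets a short exploratory
  run, then the per-series best is polished to convergence. A test verifies
  the batched fitter reproduces the per-series fitter (same K, same `α̂`,
  |Δℓ| < 1e−3) on heterogeneous inputs.
* **Ties and degenerate inputs:** `P(X ≥ 0) = 1` exactly; both-zero allele
  counts give undefined (NaN) fold change and are excluded; genes observed
  in one tissue are skipped by the mixture; empty testing families are
  skipped with a log message; identical counts across tissues give
  Kruskal-Wallis H = 0, p = 1 without calling into the rank machinery.
* **Determinism:** every stochastic routine takes an explicit seed; the
  cohort scan derives per-block seeds from the pipeline seed via
  `SeedSequence`. Same seed, same platform → byte-identical outputs.

## Scale of the shipped checks

The test suite and the acceptance script size their simulations to run on a
single CPU in minutes while keeping the statistical conditions stated above:
mixture recovery uses 200 replicates at 11 tissues × depth 200; dispersion
recovery uses 1,000 SNVs × 125 samples; the end-to-end check runs the full
1,000-gene default cohort twice (once for recall, once for determinism);
the acceptance script's cohort uses 500 genes. These sizes are the package's
own choices and are stated here so they can be scaled up deliberately.

## Known limitations

* Gene-level aggregation assumes correct phasing; a phase switch inside a
  gene flips counts between haplotypes mid-gene. Multi-block genes are
  flagged (`single_block`) and excluded from the imprinting screen but not
  from gene-level testing.
* The constant-dispersion assumption ignores gene- or tissue-specific
  overdispersion; the mixture model's shared `ϕ` makes the same trade.
* The LRT df = 2 convention is conservative rather than exact at the
  mixture boundary.
* Parent-of-origin assignment is out of reach without pedigree or
  parental genotypes; the imprinting screen reports consistency patterns
  only.
* Overlapping genes duplicate their shared SNVs into each gene (flagged
  ambiguous), which double-uses those reads in gene-level families.
* Read-level artifacts (mapping bias, duplicates, WASP-style filtering)
  are assumed handled upstream of the allele-count tables.
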