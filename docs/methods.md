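# Methods

This note documents the models, conventions and numerical choices behind
`abcoal`, in the spirit of a simulator/inference package's model
documentation: what is computed, under which assumptions, and what the
validation does and does not establish.

## Data model and site masking

The atomic unit is one locus's haplotype alignment with species labels.
Alignments are assumed pre-aligned, intron-free and non-recombining; within
each locus a single site mask is applied: any column containing `N` or `-`
in *any* sequence is excluded from *all* site-based statistics (complete
deletion). One consistent mask keeps S, π, Φ<sub>ST</sub> and the
shared/fixed classification comparable within a locus; haplotype grouping
uses the retained sites only. Site indices are 0-based internally and
1-based in reports. The species order recorded in a dataset is fixed and
determines the (1,2), (1,3), (2,3) pair ordering of every pairwise output.

## Summary statistics

Per species and locus (n sequences, L retained sites):
S; η = Σ(alleles−1) per site; h and H_d = n/(n−1)(1−Σp²);
k = mean pairwise differences; π = k/L; θ_W = S/a_{n−1},
a_m = Σ_{i≤m} 1/i.

**Tajima's D** uses the standard variance normalisation
D = (k − S/a₁)/√(e₁S + e₂S(S−1)). The variance coefficients vanish
identically for n ≤ 3, so D is reported as undefined there (NaN), as for
S = 0 — undefined is never silently 0.

**Fu & Li's D/F**: the starred (within-sample singleton) variant is the
default, since an outgroup is dataset-dependent; its variance coefficients
also vanish for n ≤ 3. The outgroup variant polarises external-branch
mutations by parsimony (derived singletons relative to an aligned outgroup
sequence); outgroup-ambiguous sites join the mask. Multi-allelic sites cap
the singleton count at η per site.

**Fu's F_S**: S′ = P(K ≥ h_obs | θ = k) from the Ewens sampling formula,
P(K = j) ∝ |s(n, j)| θ^j / θ^{(n)}, with unsigned Stirling numbers built by
exact integer recurrence and evaluated in log space. S′ is clipped to
[1e−12, 1−1e−12] before the logit (clipped values are flagged), so a sample
whose haplotype count is certain (h = 1) yields a large finite value rather
than ±∞.

**Φ_ST** is the distance-based AMOVA fixation index on pairwise
difference counts: σ²_a/(σ²_a+σ²_w) from the usual SSD decomposition. It
can be legitimately negative (for identical groups of size n it equals
−1/(n−1) exactly); values are not clipped. The permutation p-value counts
label permutations with Φ ≥ observed, including the observed arrangement in
numerator and denominator; the default is 10,000 permutations (999 in the
test suite for speed). With very small groups the permutation distribution
is coarse and p is conservative.

**Ka/Ks** follows Nei–Gojobori (equal pathway weighting, Jukes–Cantor
correction), pooled over all between-species sequence pairs. Changes to stop
codons are excluded from synonymous-site counting; mutational pathways
passing through stops are discarded unless every pathway is blocked; codons
with masked sites are skipped. The ratio is undefined when Ks = 0.

**Shared/fixed polymorphism**: each retained site is classified exactly once
as private to one species (s₁/s₂), shared polymorphic (Sp), a fixed
difference (Fp), or monomorphic-identical. The parallel-mutation expectation
E[Sp] = s₁s₂/L uses the retained (post-masking) length.

### The ABC statistic vector

A dataset is reduced to an ordered vector of across-locus means: per species
{S, h, k, D, F_S} (15 entries for three species); per pair the absolute
deviations of those means (15), mean Φ_ST (3) and mean between-species
pairwise differences, counted per locus (3) — 36 entries. Undefined
per-locus values are imputed to 0 (the neutral-expectation centre) before
averaging, with the imputation count recorded; this is the only place
undefined values are replaced. A correlation-pruned layout is available
(iteratively dropping the statistic with the largest maximum absolute
correlation in a reference table, e.g. down to 31 entries) and any explicit
subset can be configured; the default keeps all 36.

## The demographic model space

Three species (a, b, c) with current diploid sizes N_a, N_b, N_c. A recent
split at t0 joins the topology's sister pair into an ancestor of size
N_A(pair); an older split at t1 joins everything into the root of size N_A.
Topologies: top1 = ((a,b),c), top2 = ((a,c),b), top3 = ((b,c),a). Gene flow:
SI (all rates zero) or IM with six directed rates. Temporal variants cross
continuous/recent migration with continuous/recent expansion around
changepoints t_mig = t_exp = 3,000 generations (the horizon of intensified
agriculture in the emulated system): recent migration acts only more
recently than t_mig; recent expansion multiplies the three species sizes by
`pre_exp_ratio` < 1 more anciently than t_exp (ancestral sizes are separate
parameters and unaffected).

Conventions, chosen once and used everywhere:

* **Diploid time scale**: pairwise coalescence rate 1/(2N) per generation,
  θ = 4Nμ, so migration reports as 2Nm of the recipient population.
* **Migration**: the forward rate m[i→j] is the fraction of the *recipient*
  population j replaced by migrants from i per generation. Backward in
  time, a lineage currently in j therefore moves to i at exactly m[i→j] —
  no population-size ratio enters under this recipient-fraction definition
  (a ratio N_j/N_i would be the conversion for source-side emigration
  fractions, a different parameterisation).
* **Ancestral gene flow**: the model carries rates only among the three
  sampled species, so migration ceases at t0 (and at t_mig under recent
  migration). Gene flow between the post-t0 ancestor and the remaining
  species is outside the model space.
* **Mutation**: Poisson on branches; default finite-sites Jukes–Cantor
  (parallel and back mutation possible, as the shared-polymorphism analysis
  presumes), with an infinite-sites mode for speed and analytic tests that
  errors informatively when mutations exceed sites. Per-locus relative
  rates are drawn once per dataset from Gamma(shape 2) normalised to mean 1.
* **Reproducibility**: per-locus (tree, mutation) seeds are derived by a
  counter-based scheme from the master seed, so parallel and serial
  execution, and the fused statistics path and the sequence-materialising
  path, produce identical results.

The event-driven kernel (compiled with numba) draws exponential waiting
times from the total coalescence + migration rate within piecewise-constant
epochs, applying population merges and size/rate changes at epoch
boundaries. Validation: closed-form panmictic expectations
(E[T₂] = 2N, E[TMRCA] = 4N(1−1/n), E[S] = θa_{n−1}, E[k] = θ); distributional
agreement with a discrete-generation forward Wright–Fisher oracle (explicit
multinomial parent tables; deliberately refused above N = 500) including a
two-deme migration case; and distributional agreement of per-locus
statistics with msprime configured to the same IM model.

**Calibration**: absolute units use a 36-MY outgroup clade split and a
0.11-yr generation time; per-locus μ can be calibrated as
JC(divergence)/(2·36 MY)·0.11.

## ABC

**Priors** (documented defaults; the study's own were not recoverable):
N_a, N_b, N_c log-uniform [10⁶, 2×10⁸]; ancestral sizes as log-uniform
factors [1/30, 1/2] of the mean of their daughter sizes (which keeps them
ordered plausibly without hard constraints); t1 uniform [9.1×10⁶, 3.6×10⁷]
generations (≈1–4 MY); t0 = U(0.2, 0.9)·t1, guaranteeing t0 < t1 by
construction; directed 2Nm log-uniform [0.1, 3] under IM; expansion ratio
log-uniform [1/30, 1/3]; μ fixed (10⁻⁹ by default, or calibrated).

**Rejection** is Euclidean on statistics standardized by the reference
table's mean/SD (zero-variance columns dropped and logged); ties break by
stable row index. The retained count defaults to 500 of 10,000 rows per
model at desk scale (the full-scale settings — ≥10⁶ simulations, 5,000
retained, 2,000 pseudo-datasets — are configuration, not code).

**Regression adjustment** is a local-linear (GLM) fit of each free
parameter on the retained statistics with Epanechnikov weights in distance,
shifted to the observed point. Parameters are adjusted on an unbounded
scale — logit of the bound-scaled value, on the log scale for log-uniform
priors — and back-mapped, so adjusted draws always respect the prior
support and derived quantities (t0 from its fraction) keep their
constraints. A singular or non-finite fit falls back to the unadjusted
sample with a warning. Optional PLS projection (NIPALS, via scikit-learn;
cross-checked against an independent implementation in the tests) can
reduce the statistic space before distance and regression for estimation;
model choice always uses the raw standardized statistics.

**Model choice**: tables are pooled under a common standardization; each
model's posterior probability is its share of the jointly retained nearest
rows (equal model priors; zero-retained models get the floor 1/(R+1) with a
warning), Bayes factors are probability ratios, and a multinomial-logistic
estimator is available as a diagnostic only. **Robustness** simulates
pseudo-observed datasets from each side's prior, classifies them against
fresh reference tables, and reports the correctly-assigned fraction per
direction plus the mean (ties count 0.5). When a comparison side contains
several models (the topology comparison), the side's score is the mean of
its members' probabilities, renormalised across sides. An ABC-MCMC sampler
(uniform proposals on the transformed scale, acceptance threshold at the
δ = 0.1 distance quantile of a pilot table) is provided for parameter
estimation only.

**Posterior summaries**: mode from a Gaussian KDE (Silverman bandwidth) on
the log scale for scale parameters, searched within the HPD interval; HPD
as the shortest contiguous interval containing ⌈mass·n⌉ sorted draws
(requiring ≥100 draws); and a prior-likeness flag per parameter — a
two-sample KS statistic against the prior marginal below 0.1 marks
parameters the data barely update (typically direction-resolved migration),
so weak identifiability is reported instead of hidden.

## The synthetic study generator

`generate_study_like` emulates the target study design: 20 loci × 384
sites, samples 20/18/17, generating model top2-IM with continuous migration
and recent expansion, parameter point at the inferred history (t0 = 1.3 MY,
t1 = 2.6 MY; sizes 65.5/114.0/31.9 million; ancestral 11.6 and 4.0 million;
directed 2Nm from 0 to 1.04). Two values that history leaves open are fixed
here with the following rationale:

* **μ = 1.5×10⁻¹⁰ per site per generation** — the calibration recipe above
  applied to a typical ~10% nuclear-gene divergence at the 36-MY split.
  This reproduces the observed diversity scale (π ≈ 0.01) at the stated
  population sizes.
* **pre_exp_ratio = 0.3** — inside the [1/30, 1/3] prior and matching the
  ~3–6× contrast between recent and first-ancestor sizes, which is what
  makes the genealogies star-like (long external branches truncated by the
  ancestral size drop) and Fu's F_S predominantly negative, as in the
  emulated data.

The generator reports realized Hd, π and Φ_ST ranges against the emulated
envelopes (Hd ≈ 0.86–0.92, π ≈ 0.01, Φ_ST 0–0.86). What it does *not*
emulate: sequencing/PCR error, pooling artefacts, intra-locus
recombination, selection, and locus-specific intron structure — passing
tests show the inference machinery is self-consistent under the model
family, not that real data satisfy the model.

## Scales, runtime and limitations

Desk scale (the default everywhere: 10,000-row tables, 500 retained, 200
pseudo-datasets per side, 25 recovery replicates) keeps every benchmark in
minutes on one CPU; the full-scale settings are available by configuration.
Under these conditions the topology and recent-expansion robustness
benchmarks meet the emulated reference values, while SI-vs-IM robustness
measures ≈0.90: with the documented priors, strict-isolation draws near the
low-divergence corner (t1 ≈ 9×10⁶ generations with N near the 2×10⁸ upper
bound, t1/2N < 0.05) are statistically indistinguishable from
weak-migration IM, an identifiability limit of the prior space rather than
of the estimator. Other known limitations: no within-locus recombination
or gene conversion; one changepoint per epoch; migration only among sampled
species; the model-choice estimator is a retained-share approximation whose
probabilities are Monte-Carlo noisy at the floor.
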