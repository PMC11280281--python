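# Methods

## The model family

For a trait recorded once per animal, three nested linear mixed models
partition phenotypic variance:

* **M1** `y = Xb + Zu + e` — direct additive effects only,
  `var(u) = A σ²_a`, `var(e) = I σ²_e`.
* **M2** `y = Xb + Zu + Wd + e` — adds a maternal genetic effect `d`
  attached to each record's dam, with
  `var([u; d]) = G0 ⊗ A`, `G0 = [[σ²_a, σ_am], [σ_am, σ²_m]]`.
  The direct–maternal covariance σ_am is always sampled, never pinned at 0.
* **M3** adds a maternal permanent environmental effect per dam,
  `var(pe) = I σ²_pe`.

`X` carries an intercept plus reference-coded generation and hatch dummies
(first level dropped; any full-rank coding gives the same variance
components). No generation×hatch interaction is fitted. `W` columns index
pedigree animals because dams are animals; `Mpe` columns index only dams
with progeny records, and a dam needs no record of her own to receive a
`pe` effect. Records whose dam is unknown have no defined maternal link:
they are kept under M1 but excluded (and counted) under M2/M3. When several
models are compared on one trait the CLI drops unknown-dam records for all
of them first, because DICs computed on different data are not comparable.

## Pedigree and relationship matrix

Pedigrees are renumbered topologically (parents before offspring; animals
appearing only as parents become founders; cycles and self-parenting are
errors). Unknown parents are treated as unrelated, non-inbred base animals;
no phantom-parent grouping. Inbreeding is computed by the Meuwissen–Luo
recursion, dense `A` by the tabular method (guarded by a configurable cap,
default 5,000 animals), and sparse `A⁻¹` directly by Henderson's rules with
inbreeding-corrected Mendelian-sampling variances. Because the original
analysis tool-chain does not document whether its A⁻¹ used inbreeding, both
modes are provided (`use_inbreeding` flag); the inbreeding-aware mode is
the default since full-sib-design lines accumulate inbreeding quickly.

## Gibbs sampler

One iteration performs, in a fixed order (a single seeded generator per
chain, so runs are bitwise reproducible):

1. one scalar-Gibbs sweep over all location effects. The coefficient
   matrix `C = T'T + σ²_e Σ*` (with `T = [X Z W Mpe]` and `Σ*` the
   `G0⁻¹ ⊗ A⁻¹` / `I/σ²_pe` contributions) lives on a fixed sparsity
   pattern; only its values are refreshed each round, and the sweep kernel
   is jit-compiled when numba is present (a pure-python reference kernel is
   the fallback).
2. the genetic (co)variance: under M1 a scaled-inverse-χ² draw from
   `u'A⁻¹u`; under M2/M3 an inverse-Wishart draw (Bartlett construction)
   with scale `[[u'A⁻¹u, u'A⁻¹d], [·, d'A⁻¹d]]` plus prior scale and
   `q + prior df` degrees of freedom. A non-positive-definite draw (only
   possible numerically) is retried up to 10 times, then the chain aborts
   with the offending scale matrix.
3. σ²_pe from `pe'pe` with the number of dams as data df, and σ²_e from
   `e'e` with `n` df. Divergence (non-finite or absurdly large σ²_e)
   aborts with the recent draws attached.

The conditional deviance `−2 log N(y | Tθ, Iσ²_e)` is recorded at every
retained draw. Default protocol: 200,000 iterations, 2,000 burn-in, thin
50; retained draws = ⌊(iters − burn)/thin⌋.

**Starting values**: the sample phenotypic variance split evenly over the
fitted components, σ_am = 0, locations 0.

**Priors**: nothing is known about the original priors, so the default is
weakly informative and user-replaceable: scaled-inverse-χ² with 2 df for
scalar variances, inverse-Wishart with 3 df for `G0`, each with prior scale
equal to half the sample phenotypic variance divided by the number of
fitted components (off-diagonal prior scale 0). A `flat` mode sets all
prior df and scales to zero. At study scale (≈1,400 records) the data term
(`q ≈ 1,800` or `n` df) dominates either choice.

## Bivariate chains

Genetic and environmental correlations between two traits use a
direct-additive model per trait with a shared pedigree: per-draw 2×2
genetic (`G0`) and residual (`R0`) covariance matrices from inverse-Wishart
full conditionals, correlations computed per draw as
`r = cov/√(var·var)`. Animals recorded for only one trait are handled by
data augmentation: the missing trait's residual is imputed from its
conditional normal given the observed trait's residual, which leaves the
observed-data posterior intact. A fixed-effect level never observed for a
trait folds into that trait's reference level (this affects only the
imputation mean). Because a single-site sweep is order-dependent, the two
traits are canonically ordered by name inside the sampler and the output
transposed back; exchanging the inputs therefore yields exactly transposed
draws for the same seed.

## Posterior summaries and diagnostics

* **Derived ratios** are computed per draw: `σ²_p` is the sum of all
  fitted components **including σ_am** (back-calculation against published
  tables of this model family reproduces their printed heritabilities only
  under this convention; the exclusive convention is behind a flag), then
  `h²_add = σ²_a/σ²_p` etc. Draws with non-positive `σ²_p` are excluded
  from ratio summaries and counted. The ratio of posterior means is also
  reported as a cross-check; the two agree to about two decimals in
  practice.
* **HPDI**: shortest contiguous interval over the sorted draws containing
  `⌈level·N⌉` of them; ties break toward the lower start. It is never wider
  than the equal-tailed interval.
* **ESS** from the integrated autocorrelation time with Geyer's
  initial-monotone truncation of paired autocorrelations.
* **Geweke z** compares the first 10% against the last 50% of the chain,
  with segment variances estimated by Bartlett-windowed spectral densities
  at frequency zero (window ≈ √n).

## Model choice

Conditional DIC: `D̄` is the mean recorded deviance; the plug-in
`D(θ̄)` evaluates the deviance at the posterior means of the location fit
and of σ²_e (means, not medians); `pD = D̄ − D(θ̄)` and
`DIC = D̄ + pD`. Negative `pD` is flagged but not fatal. The lowest DIC is
selected; differences below 0.5 are reported as ties with the simpler
model preferred. The marginal-deviance DIC variant is out of scope, so
absolute DIC values are comparable only within a fitting run, and only the
ranking is validated.

## Synthetic populations

The generator reproduces the statistical structure the models assume — it
is the package's substitute for confidential flock data. Defaults mirror
the target study design: 50 sires × 250 dams (1:5), 3 discrete
generations, 5 hatches, 2 recorded female progeny per dam (≈1,500 records,
q ≈ 1,800 with base parents — the order of the real flock's 1,434 birds).
Matings are full-sib-design (each dam to one sire); next-generation
parents are drawn **at random** from the previous generation — the real
line's index selection is deliberately not emulated because selection
would bias the variance-recovery checks and no index weights are
available. Founder `(u, d)` pairs come from `N(0, G0)`; offspring get the
parental mean plus a Mendelian sampling term with covariance
`½(1 − (F_s + F_d)/2)·G0`; dams with progeny records get
`pe ~ N(0, σ²_pe)`; records add `e ~ N(0, σ²_e)` and fixed effects.
Fixed-effect levels default to steps of 0.5 phenotypic SD so that a model
ignoring them is detectably wrong. Hatches are assigned per dam-litter,
uniformly within generation. A missingness operator thins records per
trait and can blank whole generations (some late traits exist for two
generations only in the target design). The truth manifest stores every
sampled effect.

What the generator does **not** emulate: selection (hence no Bulmer
effect), overlapping generations, sex-limited recording asymmetries,
non-normal residuals, heterogeneous variances across generations, and
genotype×environment structure beyond additive generation/hatch shifts.
Passing recovery tests therefore demonstrates correctness of the machinery
under the models' own assumptions, not robustness to their violation on
real flocks.

## Validation protocol and problem sizes

The test suite validates, among others: exact reproduction of published
heritability arithmetic from posterior-mean components; `A⁻¹·A = I` within
1e-8 on 50 random pedigrees (q ≤ 200); bitwise chain reproducibility;
conjugate closed-form checks of the variance full conditionals
(Kolmogorov–Smirnov against the matching inverse-gamma); HPDI coverage of
generating components at the study-scale design with reduced chains
(40,000/2,000/20; 5 replicates per model, pooled coverage ≥ 85%); DIC
ranking of a maternal model above M1 on maternal data (5 study-scale
replicates); bivariate recovery of `r_g = 0.8`, `r_e = 0.3` within ±0.1 at
~1,100 records per trait, and `r_g > 0.99` for a duplicated trait; ESS/
Geweke calibration on i.i.d. and AR(1) chains; and the ±3 SD screen
removing 0.27% ± 0.05% of a large Gaussian sample. Replicate counts and
chain lengths are the package's validation protocol choices; the library
defaults remain the full 200,000-iteration protocol.

## Known limitations

* Single-site location updates mix more slowly than blocked samplers on
  strongly confounded effects (e.g. σ_am with few dams); the long default
  chain compensates at study scale.
* The dense `A` path is for inspection and small pedigrees; all fitting
  uses sparse `A⁻¹`.
* DIC is reported in its conditional form only; model probabilities,
  Bayes factors and WAIC are out of scope.
* The maternal models require known dams; heavy unknown-dam data shrinks
  the comparable record set.
* `h²` ratios are summarized from per-draw ratios; with very small
  phenotypic variances the flagged-draw count should be checked.
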