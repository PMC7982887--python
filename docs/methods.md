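# Methods

## Model

The unit of analysis is a genus-level lineage on one archipelago. Two
responses are modeled jointly as a piecewise structural-equation model
(SEM): the number of distinct ploidy levels the lineage carries on the
archipelago, and the natural log of its endemic species count. The causal
diagram has four exogenous drivers — stem age, a binary ploidy-change-at-
colonization indicator, source-pool size (congeneric species outside the
archipelago), and repeat colonization (coded as island monophyly, 1 =
single colonization) — and the two endogenous responses, connected by
seven directed paths P1–P7 (see the package docstring of
`ploidypath.path_sem`). Archipelago membership is deliberately *not* a
node of the diagram: it enters every regression as fixed intercept
heterogeneity, plus a by-archipelago slope for ploidy levels in the
diversity equation and for stem age in the ploidy equation. The reported
"single" coefficient of a varying slope is the reference-archipelago
slope; deviations are reported separately as island effects in both the
deviation-contrast and cell-means parameterizations, since either may be
wanted when comparing archipelagos.

Each submodel is a weighted phylogenetic generalized least squares (PGLS)
regression. Under Brownian trait evolution, the covariance of two tips is
proportional to the branch length they share from the root, giving the
correlation matrix R of the dated tree (standardized per-tip, so
non-ultrametric inputs are handled). Observation weights are treated as
known: the error covariance is σ²·V with V = D^{1/2} R D^{1/2} and
D_ii = (1/w_i)^k. The default variance power is k = 1 (variance inversely
proportional to the weight, the standard known-weights convention); k = 2
(variance ∝ 1/w²) is available behind `variance_power`. Weights are
w = 1/√(stem-age SD) for the species-count model and w = proportion of
endemic species with chromosome counts for the ploidy model.

Estimation is exact GLS through a Cholesky factorization of V — V is
never inverted explicitly. REML is the default reporting method; ML is
used for all directed-separation fits so that p-values of added terms are
comparable across nested models. One deliberate convention: standard
errors and t statistics always use the residual-variance estimate with
n − p in the denominator, under ML as well as REML. This is the unbiased
scale under which the t statistics are exactly t-distributed with n − p
degrees of freedom when the model is correct; the two methods differ only
in the log-likelihood and the σ² they quote.

## Directed separation

The basis set contains one independence claim per non-adjacent node pair,
excluding exogenous–exogenous pairs (whose association is left free), with
conditioning set equal to the union of both members' parents — validated
in the test suite against a brute-force path-blocking d-separation oracle
on random DAGs rather than assumed. Each claim is tested by regressing the
endogenous member on its conditioning set plus the "missing" predictor.
When the response has a submodel, the claim reuses that submodel's full
design (archipelago intercepts and by-archipelago slopes included): the
conditioning nodes are then exactly the submodel's predictors, and the
test inherits the island structure of the model it audits. Omitting the
island slope terms here would make the claim regression misspecified
relative to the fitted SEM and measurably inflates the type-I error of the
global test. Claim p-values combine into Fisher's C = −2 Σ ln p, compared
to χ² with 2k df; an empty basis set yields C = 0, df = 0, p = 1, and a
claim with p = 0 is clamped to the machine minimum with a warning.

Significance is reported at 0.05, two-sided, with no multiple-testing
correction across paths. R² defaults to the squared Pearson correlation
between fitted and observed response; a likelihood-ratio pseudo-R²
against the correlation- and weight-matched intercept-only model is
available behind `r2_flavor="pseudo"`.

## Data rules

- Divergence-time SDs absent from the table are derived from 95%
  HPD/CI bounds by the longer-tail normality rule,
  max(upper − mean, mean − lower)/1.96.
- Inclusion requires at least two native species, a dated phylogeny, and
  at least one chromosome count; Galápagos records never survive these
  criteria in practice.
- A zero or missing stem-age SD is floored at the smallest positive SD in
  the dataset (avoids an infinite weight while preserving the certainty
  ordering). Chromosome-count completeness is floored at 1/n_endemic —
  but only for integer species counts, where "at least one counted
  specimen" is meaningful; continuous model-scale counts (from the
  latent-response generator mode, below) carry no such floor.
- Unknown monophyly or ploidy-change indicators in retained records
  default to false with a logged warning; the binary predictors admit no
  missing level.
- Canonical record order is archipelago (NZ, CI, HI, JF) then lineage_id;
  every design matrix and covariance matrix inherits it.
- Lineages map to one designated representative tip each; when two
  lineages share a source tip (same genus on two archipelagos), the tip is
  split into a cherry with 1e−8 Myr arms, preserving positive
  semidefiniteness while encoding near-identical history.
- Natural log throughout. Ploidy levels and source-pool size enter
  untransformed by default; `log_ploidy` and `log_pool` flags implement
  the alternatives, since either reading is defensible for skewed
  predictors.

## Synthetic data

The generator draws whole studies with the structure the estimator
assumes. A pure-birth (Yule) tree supplies the phylogeny; pendant branch
lengths play the role of stem ages (self-consistent with "stem age"
semantics on a pruned tree), rescaled so the mean stem age is 13.16 Myr.
Default conditions mirror the compiled four-archipelago dataset: 150
lineages with archipelago probabilities 98/23/23/6 ÷ 150; ploidy-change
probability 18/150; monophyly probability 67/150; completeness
Beta(0.94, 0.26) truncated to [0.3, 1] (mean ≈ 0.78); stem-age SDs
about 20% of the age with log-normal scatter. The source pool is
log-normal with median 51, capped at 2000. The observed pool quartiles
(5–275) would imply a log-sd near 3; combined with a linear raw-pool
effect, that tail would generate absurd ploidy counts, so the generator
narrows the spread (log-sd 1.5) as a package convention — the published
quartiles and a globally linear pool effect are not jointly satisfiable.

Responses follow their linear predictors plus Brownian noise standardized
to unit tip variance and scaled per lineage by 1/√w — exactly the
heteroscedastic, phylogenetically correlated error the estimator assumes.
Default true coefficients (see `DEFAULT_ENDEMIC_COEFS` /
`DEFAULT_PLOIDY_COEFS`) are a package convention chosen once to give
Table-2-like marginal ranges (mean ploidy ≈ 1.6–2, log-scale endemic
mean ≈ 2, R² ≈ 0.3–0.4); the coefficient of the absent
PloidyChange → EndemicDiversity edge is 0, making the generator
diagram-consistent. A `monophyletic` entry may be added to the ploidy
equation's truth to create the RepeatColonization → PloidyLevels path the
diagram omits, for misspecification and power studies.

Two response modes:

- `round_counts=True` (default): ploidy levels are rounded and floored at
  1; endemic counts are exp-transformed, rounded, floored at 1. This is
  the realistic mode — integer counts, validated records.
- `round_counts=False` (latent): responses stay continuous, under which
  the fitted model is *exactly* correctly specified. Calibration and
  coverage studies use this mode, so they test the estimator rather than
  the rounding discretization. In the rounded mode, a short fixed-point
  loop keeps the stored completeness consistent with the 1/n_endemic
  floor that the pipeline would apply.

The discretization is not innocuous: flooring ploidy levels at 1 censors
a substantial share of lineages (realistically — most island lineages
carry a single ploidy level), and at n = 150 the global Fisher's C test
detects the resulting departure from the Gaussian working model in
roughly half of rounded-mode replicates. Single-seed Fisher's C values on
rounded data therefore vary widely; calibration claims about the test
itself are made in the latent mode, where rejection sits at the nominal
5%.

What the generator does **not** emulate: taxonomic error, non-Brownian
trait evolution (no Pagel's λ or OU), dysploidy or any mechanistic
chromosome-number model, sampling covariance between stem age and its SD,
or correlation among exogenous drivers. Passing calibration here shows
the machinery is correct under its own assumptions, not that real island
data satisfy them.

## Numerical choices

- Cholesky of V with a 1e−10 diagonal jitter fallback; approximate
  condition number above 1e10 logs a warning.
- R is declared non-PSD below eigenvalue −1e−8; in [−1e−8, 0) a 1e−8
  diagonal jitter is applied and logged.
- Rank deficiency is detected by matrix rank and reported with the
  offending columns via pivoted QR (e.g. an archipelago with one lineage
  and a varying slope).
- Claims and edges are emitted in fixed topological order; all simulation
  randomness flows from one seeded generator per run, with the seed
  recorded in every output.

## Problem sizes

The test suite runs the closed-form GLS oracle on instances up to n = 12,
the covariance oracle on 100 trees up to 20 tips, the d-separation oracle
on 100 random 6-node DAGs, Fisher's C calibration on 1,000 replicates at
n = 150, CI coverage on 500 replicates at n = 150, and bias shrinkage on
200 replicates each at n ∈ {50, 150, 400}. The acceptance script uses 500
calibration and 200 recovery replicates. At n = 50 the smallest
archipelago often has fewer than two lineages; such replicates are
rank-deficient by construction, logged, and excluded from recovery
summaries.

## Known limitations

- The supplementary lineage table of the motivating study is not
  redistributable here, so the pipeline's agreement with its published
  coefficients can only be checked by users who supply that table plus a
  pruned megatree; all shipped validation is simulation-based.
- Brownian correlation is fixed, not estimated; count likelihoods
  (Poisson/negative-binomial) are out of scope by design — responses are
  modeled on the log-normal scale.
- The d-separation layer reports a claim's p-value from an ML refit of
  the response's submodel; a flagged "missing path" can still have a
  non-significant coefficient when added to the final model, and the
  package reports both without reconciling them.
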