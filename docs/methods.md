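# Methods

This note documents the statistical model, the numerical choices, and the
limits of what the test suite demonstrates.

## Effect-size meta-analysis

Per study, expression change is Hedges' g: the condition-minus-control
mean difference divided by the pooled standard deviation, multiplied by
the small-sample correction J = 1 − 3/(4·df − 1) with df = n1 + n2 − 2.
Its within-study sampling variance uses the conventional large-sample
form v = (n1+n2)/(n1·n2) + g²/(2·df). A gene with fewer than two samples
in a group or zero pooled variance yields a missing estimate, never an
infinite one; missing genes are carried through (and annotated), not
dropped.

Pooling uses the random-effects model y_j = μ + τ_j + ε_j. τ² is
initialised at the DerSimonian–Laird moment estimate (clamped at zero)
and iterated with the standard REML estimating equation

    τ² ← Σ w²[(y − μ)² − v] / Σ w² + 1/Σ w,   w = 1/(v + τ²),

clamping at zero each step, with tolerance 1e−8 on max(|Δμ|, |Δτ²|) and
at most 100 iterations; non-convergence is recorded in a flag and the
last iterate returned. Agreement with an independent Fisher-scoring REML
implementation is ~1e−6 on a fixed six-study input (frozen in the test
suite). With a single contributing study τ² is unidentifiable: the
implementation returns μ = y, σ = √v, τ² = 0, converged. A `tau2_fixed`
argument exists solely for limit checks (τ² = 0 gives the inverse-variance
fixed-effects mean); it is not part of the pipeline, since fixed-effects
pooling cannot absorb between-study heterogeneity.

Direction convention, fixed package-wide: condition minus control,
positive = up-regulated, right tail small for up-regulation. This is what
makes the later per-tail maxP fusion meaningful.

## Moderated testing

The per-study test is an ordinary two-group OLS fit (β = case mean −
control mean, pooled residual variance s², df = n1 + n2 − 2) followed by
empirical-Bayes shrinkage: a scaled inverse-χ²(d0, s0²) prior is fitted
to the observed s² by moment matching on log s² — the excess variance of
log s² over trigamma(df/2) is inverted through the trigamma function
(Newton iteration) to give d0, and the prior scale follows from the mean.
Under-dispersion takes the d0 = ∞ branch (all posterior variances equal
s0²; Student tails at df + d0 are evaluated at a capped df of 1e7, which
is normal to ~1e−7). The posterior variance (d0·s0² + df·s²)/(d0 + df)
replaces s² in the t-statistic. On a fixed heterogeneous-variance
fixture this reproduces the reference empirical-Bayes implementation's
d0, s0², posterior variances and p-values to 1e−8 (values frozen in the
suite). Only the two-group design is supported — the pipeline needs
exactly one contrast, and any other per-study test producing one-tailed
p-values could be substituted.

## p-value combination and gene selection

The cross-study combiner uses the average of the m one-tailed p-values as
its statistic. Its exact null CDF (mean of m iid uniforms) is evaluated
on the sum scale by the Irwin–Hall alternating sum. Numerically the
alternating sum in double precision is fine below ~20 terms (worst-case
absolute error ~1e−8 at m = 19) but is catastrophically cancelled well
before m = 50 (terms reach ~1e19 while the sum is O(1)); the
implementation therefore evaluates m ≥ 20 in exact rational arithmetic,
and the *pipeline* switches to the N(1/2, 1/(12m)) approximation at
M_SWITCH = 20, where the sup-norm gap to the exact CDF is below 0.01
(asserted by test). Upstream p-values of exactly 0 or 1 are nudged to
1e−300 / 1 − 1e−16 before averaging to guard the CDF endpoints.

Averaging is intentionally robust: one p-value of 1e−300 among ten nulls
moves the statistic by at most 0.1 and leaves the combined p
non-significant, where Fisher's product collapses below 1e−50. The flip
side is lower sensitivity to a single strong study — by design, since the
goal is consistency across studies.

Fusion is per-tail maxP, p_l = max(ep_l, bp_l) and p_r = max(ep_r, bp_r):
a gene must be significant from both the testing and the effect-size
perspective. The two tails are folded into one ranked list as
2·min(p_l, p_r) capped at 1, followed by a single BH pass and a 1% FDR
cutoff (doubling the minimum tail preserves validity; adjusting tails
separately would yield two incommensurable lists). At the 1% level the
effect-size component alone forces |μ/σ| ≥ Φ⁻¹(0.995) > 2, so every
selected gene's pooled effect exceeds twice its standard error — asserted
empirically on every simulated run.

## Pathway impact

Pathways are signed directed graphs; duplicate (u, g) edges collapse by
summing their signs (curated edge lists contain duplicates, and the
propagation formula admits any real weight). The perturbation-factor
recursion PF = ΔE + B·PF, B[g,u] = β_ug/N_ds(u), is solved directly as
(I − B)PF = ΔE — exact for DAGs (equals topological-order forward
propagation) and the principled fixed point for cycles. A condition
number above 1e12 marks the pathway untestable; it is excluded with a
warning rather than scored from a meaningless solve. ΔE is the pooled μ
for signature genes and 0 otherwise, so perturbation is propagated only
for the prioritised genes.

The pathway total ΣPF(g) is linear in ΔE, so it equals w·ΔE with
w = (I − B)⁻ᵀ1 computed once per pathway; the permutation null (the
on-pathway signature μ multiset reassigned to uniform random measurable
nodes, same count) then costs one dot product per permutation. This is
algebraically identical to re-solving per permutation and is verified
against `compute_pf` in the tests. The null is centered at its median and
the two-sided tail uses the add-one rule, so p_pert ≥ 1/(n_perm + 1);
n_perm defaults to 2000. Each pathway draws its permutation stream from a
seed derived from (run seed, pathway id), so results are independent of
collection order. A pathway carrying no signature gene gets p_pert = 1 by
convention. Permutation is over gene labels only: at the meta-analysis
stage the per-study samples have already been absorbed into the pooled
statistics, so a sample-level permutation is not reconstructable from the
pipeline's inputs.

Over-representation (`p_de`) is the hypergeometric upper tail of the
signature count on the pathway. The default universe is genes measured in
at least one study *and* annotated to at least one pathway — the measured
transcriptome differs across platforms, and restricting to annotated
genes keeps `p_de` comparable across pathway collections;
`universe_mode="measured"` exposes the alternative. `p_de` and `p_pert`
are combined by Fisher's method (χ² with 4 df), BH-adjusted across
testable pathways, and called significant at FDR ≤ 5%.

## Synthetic data

The generator mirrors the pooling model: each DE gene's study-level true
effect is drawn N(μ*, τ²*) and expressed as a case-mean shift in
noise-SD units; DE signs alternate so both tails are exercised. Every
study receives an additive batch shift (SD 0.5 by default) applied to all
genes and both groups — it moves the expression scale between studies
without changing any true SMD, which is exactly why standardized
differences are pooled instead of raw ones. An optional group-confounded
mode adds the shift to cases only, reproducing the failure mode that
inflates naive analyses. Defaults: 2,000 genes, 5 studies, 20 vs 20
samples, 5% DE at μ* = 1.0, τ²* = 0.05, unit noise — a moderate
multi-cohort design under which the pipeline's operating characteristics
are measured (sensitivity ~0.9 at gene FDR 1%, planted pathway ranked
1st).

Pathways: 50 random signed graphs (sizes 15–40, edge density 0.08, 30%
repression) over random gene subsets, plus one planted pathway whose core
(15 nodes by default) is drawn from the up-regulated DE genes and wired
as an activation chain; core nodes keep the chain as their only
out-edges, so the coherent signal accumulates downstream instead of being
divided across random targets. The planted pathway's background edges are
resampled if they happen to close a singular feedback loop — the ground
truth must be testable; decoys may remain singular, exercising the
exclusion path.

What the generator does **not** emulate: platform-specific probe
artifacts, RNA-seq count distributions (inputs are assumed gene-level,
log-scale), correlated noise between genes, or realistic scale-free
pathway topologies. Passing tests therefore demonstrate the statistical
machinery — estimation, calibration, propagation, ranking — under the
stated generative model, not performance on any particular real cohort.

## Problem sizes and determinism

The test suite and the acceptance script use one full-size replicate
(2,000 genes, 5 studies, 50 pathways, n_perm = 2000) plus replicated runs
at n_perm = 500 for recovery/specificity rates, and smaller fixtures for
unit-level checks; these sizes give stable Monte-Carlo estimates while
keeping a complete run in tens of seconds. All randomness flows from
explicit seeds (the CLI requires one); reruns with identical inputs and
seed produce byte-identical output tables, which the suite asserts at the
file level (TSV readers use round-trip float parsing, so checkpointing
through text files is lossless).

## Known limitations

- Gene matching is exact-string; no identifier mapping is shipped.
- Interaction weights are ±1; no curated strength tables.
- The moderated test supports only the two-group design (no covariates,
  no expression-level variance trend, no robust prior fitting).
- Cyclic pathways whose propagation system is near-singular are excluded
  rather than regularised.
- With a single study the between-study variance is reported as 0 and the
  pooled standard error understates full uncertainty; results then reduce
  to a single-study analysis and are annotated as such (`n_studies = 1`).
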