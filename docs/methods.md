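# Methods

`gdmnma` implements a comparative-efficacy workflow for hypoglycemic agents
in gestational diabetes mellitus (GDM): arm-level data pooling, frequentist
random-effects pairwise meta-analysis, Bayesian random-effects network
meta-analysis (NMA) over the metformin / insulin / glyburide network, a
heterogeneity-triggered leave-one-out sensitivity procedure, subgroup
analysis by GDM diagnostic criteria, treatment ranking, and funnel-plot
coordinates.  This note records the models, the defaults and why they were
chosen, the numerical decisions, and what the synthetic-data experiments do
and do not demonstrate.

## Data model

The unit of input is the **study arm**: `(study_id, treatment, size)` plus
either an event count (dichotomous outcomes, analysed as odds ratios) or a
mean and SD (continuous outcomes, analysed as mean differences).  Arms
sharing a `study_id` form one randomized trial; each study optionally
carries a diagnostic-criteria label (`IADPSG` / `non-IADPSG` / `unknown`)
used by the subgroup analysis.  Treatments are open-ended strings; the
packaged registry `metformin, insulin, glyburide` fixes the canonical node
order (reference first).  Multi-arm trials are accepted by the model;
`OutcomeDataset.filter_arms` is the explicit extraction step for trials
whose extra arms (diet, acarbose, ...) fall outside the analysed network —
we prefer an explicit filter over silently dropping arms at read time.

## Summary-statistic conversion and pooling

Trials reporting skewed outcomes as median with range and/or IQR are
converted to mean/SD before analysis:

* **hozo**: mean (a + 2m + b)/4; SD range/4 for 15 < n ≤ 70, range/6 for
  n > 70, and the exact small-sample expression for n ≤ 15.
* **wan** (default, the more recent calibration): the same mean estimators,
  with SD denominators `2·Φ⁻¹((n − 0.375)/(n + 0.25))` (range) and
  `2·Φ⁻¹((0.75n − 0.125)/(n + 0.25))` (IQR); when both summaries are present
  the two SD estimators are averaged and the combined mean estimator
  (a + 2q1 + 2m + 2q3 + b)/8 is used.

Both conversions agree exactly on zero-spread input.  Arms on the same
treatment are pooled with the n-weighted mean.  Two pooled-SD conventions
are offered because the workflow's source combination rule, taken literally,
reduces algebraically to the **n-weighted mean of arm SDs** (its
(SD_j + x̄_j) terms cancel the weighted mean exactly): that literal rule is
the default (`sd_method="printed"`), and the conventional variance-preserving
pooled SD — which additionally counts between-arm mean dispersion and is
never smaller — is available as `sd_method="variance"`.  Neither is guessed
to be "intended"; both are implemented and the choice is recorded in output.

## Pairwise meta-analysis

Per-study effects are the 2×2-table log odds ratio
(`v = 1/a + 1/b + 1/c + 1/d`, Haldane 0.5 added to all four cells of a study
containing any zero cell — the RevMan convention) or the mean difference
(`v = sd₁²/n₁ + sd₂²/n₂`).  Studies with zero events (or zero non-events) in
*both* arms are non-informative for the OR: they are excluded from the
pairwise contrast, reported as such, and retained in the Bayesian arm-based
likelihood, which handles them naturally.

Pooling is DerSimonian–Laird: fixed-effect weights `w = 1/v` give Cochran's
`Q`; `τ² = max(0, (Q − df)/(Σw − Σw²/Σw))`; random-effects weights
`w* = 1/(v + τ²)` give the pooled effect with a normal-quantile 95% CI
(1.96, matching standard pairwise tools; no t correction).  The
heterogeneity index is `H = max(1, √(Q/max(1, df)))`, floored at 1 as in the
conventional definition; H > 3 is the trigger for the sensitivity procedure.
Funnel coordinates are comparison-adjusted: per-study effect minus the
comparison's pooled estimate, against the standard error.

## Bayesian network meta-analysis

Arm-based likelihood with study baselines and exchangeable trial effects:

* dichotomous: `r_ik ~ Binomial(n_ik, p_ik)`, `logit(p_ik) = μ_i + δ_ik`
* continuous: `x̄_ik ~ Normal(μ_i + δ_ik, sd_ik²/n_ik)` (arm-level input, so
  multi-arm continuous trials stay coherent)

with `δ = 0` for each study's baseline arm (its first treatment in registry
order; the model's contrasts are invariant to this choice) and

* consistency model: `δ_ik ~ N(d[t_ik] − d[t_base], τ²)`
* UME (unrelated mean effects): `δ_ik ~ N(d_edge, τ²)`, one unconstrained
  mean per directly observed comparison — the inconsistency check.

Multi-arm trials use the standard ½ between-arm correlation, implemented by
sequential conditional sampling (j-th non-baseline arm: conditional mean
`md_j + (1/j)Σ_{l<j}(δ_l − md_l)`, variance `τ²(j+1)/(2j)`).

**Priors.**  `d, μ ~ N(0, effect_prior_sd²)` and `τ ~ Uniform(0, tau_upper)`.
Defaults are resolved from the outcome scale: 15 × a scale constant of 2
log-odds units (so SD 30) and `tau_upper = 5` for log ORs; 15 × the largest
observed arm SD and `tau_upper` = that SD for mean differences.  These are
the vague-prior conventions of standard NMA tooling, wide relative to any
plausible effect on each scale; sensitivity to them is negligible whenever
the data carry information (the calibration experiment below checks this
empirically).

**Sampler.**  Single-site random-walk Metropolis within a fixed Gibbs scan
(baselines, trial effects, basic parameters, τ), with per-parameter proposal
scales adapted toward 44% acceptance in batches of 50 iterations **during
burn-in only**, so the retained chain is time-homogeneous and satisfies
detailed balance.  Two-arm studies (the entire default network) are updated
as vectorized blocks.  Defaults: 4 chains, 20,000 burn-in, 50,000 retained
draws, thin 1; identical seeds give bit-identical draws (chain seeds are
spawned from one `SeedSequence`).  Convergence is monitored with the classic
Gelman–Rubin PSRF per basic parameter and τ; any value above 1.1 attaches an
explicit warning to the result rather than failing or staying silent.

**Summaries.**  Every pairwise contrast is formed per draw from basic
parameters (`d_AB = d_A − d_B`), so the consistency identity
`d_AC = d_AB + d_BC` holds exactly by construction.  Point estimate is the
posterior median — deliberately robust for the heavily skewed ORs that
sparse-event outcomes produce — with an equal-tailed 95% credible interval.
OR summaries are computed as percentiles on the log scale and exponentiated;
equal-tailed percentiles commute with monotone transforms, and this
convention makes pair reversal an exact OR inversion.  Rank probabilities
come from per-draw sorting of the basic parameters (a `direction` flag says
whether lower is clinically better), with SUCRA as a scalar convenience.

## Per-outcome procedures

`run_outcome` produces the full bundle: DL pairwise result per direct
comparison, the **network H** (unweighted mean of per-edge H, with
single-study edges contributing H = 1, and `NaN` when no edge is estimable),
the consistency fit, a league table in the reporting order
Met vs Ins / Met vs Gly / Ins vs Gly, and rank probabilities.

`sensitivity_leave_one_out` triggers when network H exceeds 3 (strictly).
The omission rule is **greedy iterated single omission**: repeatedly remove
the one study whose omission minimizes the recomputed network H, requiring
every direct comparison to retain at least two studies and H to strictly
decrease, until H ≤ 3 or no admissible removal helps (then the report is
flagged `exhausted` with the best-achieved H).  A single fixed omission
cannot reproduce the observed behavior of this procedure in practice, where
sensitivity rows drop one or several studies; greedy H-minimization is the
simplest rule consistent with both, and is documented here as this package's
operationalization rather than a claim about any particular historical
analysis.  The reduced dataset is refit (pairwise + NMA).

`subgroup_by_criteria` splits on the IADPSG flag, refits each labeled
subgroup independently, excludes unknown-label studies with a logged
warning, and reports a disconnected subgroup pairwise-only with an explicit
flag.

## Synthetic data

The generator emulates the structure of the GDM evidence base — it makes no
attempt to reproduce any particular trial's values.  Defaults: a connected
3-treatment network with direct edges metformin–insulin (15 trials),
glyburide–insulin (10), metformin–glyburide (4); per-arm sizes uniform on
50–150 (≈5,800 participants across the 29 two-arm trials); true log ORs
(−0.431, 0, +0.462) for (metformin, insulin, glyburide), the
neonatal-hypoglycemia-like ordering with Met-vs-Ins OR 0.65 and Ins-vs-Gly
OR 0.63; between-study SD τ = 0.15; baseline log-odds N(−1.1, 0.5²)
(common-event archetype, ~25% control risk).  A `rare` archetype
(N(−4.6, 0.5²), ~1%) exercises zero cells naturally.  Continuous outcomes
use outcome-typical arm SDs (3 kg for gestational weight gain, ~450 g for
birth weight) with log-normal between-arm spread, and an optional fraction
of studies is emitted through median/range/IQR summaries — computed at the
expected normal order-statistic positions — and round-tripped through the
quantile conversion, exercising that code path in the pipeline.

Per trial on edge (A, B): `μ_i ~ N(baseline)`,
`δ_i ~ N(d_B − d_A, τ²)`, and arm outcomes from the exact likelihood the
analysis assumes.  What passing tests on these data show is therefore
**internal correctness and calibration under the assumed model** — correct
likelihood, priors that do not distort well-informed posteriors, correct
interval construction.  What they do not show: robustness to real-data
violations such as non-exchangeable heterogeneity, outcome-dependent
reporting, arm-size imbalance correlated with effects, or misclassified
diagnostic criteria.

## Verification experiments

(all runnable via `tests/` and `scripts/acceptance.py`; problem sizes were
chosen as the smallest that make each check statistically sharp)

* **Closed-form oracle**: DL pooling is compared with an independent
  step-by-step evaluation of the moment equations on 1,000 random 2–10-study
  instances, agreeing to 1e-10; statsmodels' DL implementation provides a
  second, library cross-check on the non-truncated instances.
* **Numerical-integration oracle**: on a two-treatment, three-study network
  the exact posterior of d is computed by dense quadrature over
  (μ_i, δ_i, d, τ); the MCMC posterior mean and median agree to < 0.02.
* **Calibration**: 100 replications of the default 29-trial design
  (reduced sampler settings: 2 chains, 1,500 burn-in, 4,000 draws) give 95%
  CrI coverage of each basic contrast within the binomial band [0.88, 0.99]
  and posterior-median bias below 0.05.
* **Structural identities**: consistency additivity per draw; exact OR
  inversion under pair reversal; rank rows/columns summing to one.
* **Sensitivity procedure**: a study placed 5 marginal SDs
  (√(v + τ²)) from the true contrast — on the common-events side, so its
  inverse-variance weight stays typical — is the first omission in ≥ 99 of
  100 seeded replicates; omission traces are strictly decreasing in H by
  construction of the greedy rule (asserted, not assumed).
* **Exchangeability**: with all true effects equal on a symmetric (8/8/8)
  network, rank probabilities averaged over 60 replicates are within 3 MC
  standard errors of 1/3.  (On the asymmetric 15/10/4 geometry this uniform
  limit does *not* hold — treatments with less direct evidence get wider
  posteriors and hence more extreme ranks — which is why the symmetric
  geometry is used for this check.)

## Numerical choices and degenerate inputs

* Haldane correction 0.5 applied to all four cells, only for studies
  containing a zero cell; double-zero (or double-all-event) studies raise a
  typed error for the pairwise path.
* τ² truncated at 0 (the usual DL convention); `H` floored at 1.
* MCMC initial values are data-driven (empirical logits/means) with small
  per-chain jitter, and the τ start is drawn from (0.1, 0.4) × `tau_upper`,
  giving modestly overdispersed starts so the PSRF diagnostic is meaningful.
* Empty datasets yield empty, trivially connected geometry; a zero-trial
  generator design yields a valid empty dataset; disconnected networks are
  refused by the consistency model with the components named.
* CSV round trips are exact: floats written with `%.17g` and parsed with
  pandas' `round_trip` converter.

## Known limitations

* The sampler is single-site Metropolis: adequate for these network sizes
  (tens of studies, 3 treatments), but τ mixes slowly on very sparse
  networks; the PSRF warning is the guardrail.  No node-splitting
  inconsistency assessment (the UME model plus the H statistic is the
  inconsistency surface); no meta-regression; no informative priors.
* No imputation of missing SDs from p-values or CIs; quantile summaries are
  the only supported indirect report.
* Funnel output is coordinates only (visual assessment); no Egger/Begg
  regression tests.
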