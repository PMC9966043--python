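# Methods

This note documents the models implemented in `ocutrial`, the defaults
and why they were chosen, what the synthetic-trial generator does and does
not emulate, and the numerical choices that matter for reproducing
results.

## 1. Derived biometry

All axial segments are millimetres except central corneal thickness (CCT)
and choroidal thickness (ChT), which are carried in micrometres as
clinical reports print them; the µm→mm conversion happens at the single
point of use inside each formula, never on the stored columns.

- **Spherical equivalent.** SE = sphere + cylinder/2 (D). Readings are
  normalized to the minus-cylinder convention on construction, because SE
  is invariant to sphero-cylindric transposition only if one convention is
  applied consistently. Autorefractor readings with quality score < 7 are
  discarded; the remaining readings are averaged component-wise. No
  qualifying reading yields a missing value, not an exception.
- **Vitreous chamber depth.** VCD = AL − CCT/1000 − ACD − LT, where ACD is
  the endothelium-to-lens distance as biometers report it. A non-positive
  VCD is physically impossible and raises. The reconstruction identity
  VCD + CCT/1000 + ACD + LT = AL holds exactly for every processed record.
- **Bennett lens power.** The crystalline lens is replaced by a thin lens
  between two principal planes placed c₁·LT behind the anterior lens
  surface and c₂·LT in front of the posterior surface. The ACD entering
  the formula is re-referenced to the corneal epithelium (ACD_epi =
  CCT/1000 + ACD). Defaults c₁ = 0.596, c₂ = 0.358 are Bennett's original
  schematic-eye constants; studies that customize these constants to their
  population can supply them through `BennettConstants`, which also
  exposes the refractive index (default 4/3) and an optional
  spectacle-to-cornea vertex distance (default 0 mm: handheld
  autorefraction is treated as corneal-plane refraction). Because the
  constants are population-tunable, published mean lens powers are
  reproduced to a band (±0.7 D) rather than a point.
- **Eye averaging.** Parameters are averaged over the two eyes for all
  analyses. Derived quantities are computed per eye and then averaged;
  for the linear ones (SE, VCD, Km) the order provably does not matter,
  and for the nonlinear lens power the per-eye route matches how the
  quantity is defined. If one eye is missing, the other is used alone
  rather than dropping the participant.

## 2. Synthetic trial generator

The generator states a world resembling a three-arm, three-site,
placebo-controlled trial in 97 myopic children (32/32/33 per arm) with
visits at months 0/3/6 and two eyes per child.

- Baseline means and SDs per outcome come from the emulated cohort's
  baseline table (e.g. AL 24.48 ± 0.84 mm, SE −3.02 ± 1.27 D).
- Arm-by-visit mean changes come from the emulated change-from-baseline
  table: the placebo trajectory plus, for the active arms, the reported
  differences from placebo (e.g. loading-dose AL −0.08 mm at month 3,
  −0.13 mm at month 6).
- Within-participant visit covariance defaults to the baseline variance
  with lag-0.8 correlation between adjacent visits (AR-structure). The
  true visit covariance of such cohorts is unreported; 0.8 is chosen high
  because biometrics track strongly within a child, and it is a config
  knob (`visit_rho`, or a full `visit_cov` override per outcome).
- The two eyes are drawn around the participant's latent trajectory with
  marginal inter-eye correlation 0.98 (biometrics of fellow eyes are
  near-duplicates); site effects are additive constants drawn once per
  simulation with SD 0.1 baseline-SD; dropout is whole-visit, monotone
  and MCAR with per-visit probability 1/97, matching a single withdrawal.
- Refraction is emitted as five quality-scored readings whose
  quality-filtered mean reproduces the latent SE exactly (per-reading
  noise is centred over the qualifying subset), so the generator's SE
  truth survives the averaging pipeline bit-exactly.

The generator simulates the *measured* quantities (AL, CCT, ACD, LT, ChT,
Km split into K1/K2, latent SE); VCD, LP and Km are derived downstream,
so their treatment effects are implied rather than dialled — e.g. the
implied VCD effect equals the AL − ACD − LT effects, consistent with the
emulated tables to printed rounding.

What it does **not** emulate: device-specific noise spectra, segmentation
error in choroidal maps, accommodation dynamics, informative dropout, and
any genuine coupling between SE changes and structural changes (the
outcomes are drawn independently given arm and visit). A green
longitudinal-model test therefore establishes correct estimation of the
stated mean/covariance structure, not biological realism; mediation
recovery is tested against a separate generator
(`simulate_mediation_system`) with explicit β/γ truth.

## 3. Constrained linear mixed model

Participant i with arm g(i), site s(i) and observed visit subset obs(i)
contributes a multivariate-normal sub-vector with

    E[y_it] = μ₀ + site_{s(i)} + δ[g(i), t],  δ[·, baseline] ≡ 0,
    Cov[y_i] = Σ[obs(i), obs(i)].

- **Baseline constraint.** μ₀ is shared across arms (the design
  randomizes, so arms are exchangeable at baseline); switching the
  constraint off replaces μ₀ by per-arm baseline means. The constraint
  pools baseline information across arms, so even baseline-only
  participants inform the treatment contrasts.
- **Covariance.** Σ is unstructured and shared across arms (a per-arm Σ
  is deliberately not the default: the emulated analyses describe a
  single residual covariance); a compound-symmetry option exists. Σ is
  parametrized by its log-Cholesky factor, making the REML optimization
  unconstrained and every iterate positive definite.
- **Estimation.** Fixed effects are profiled out by GLS at each candidate
  Σ; the profiled REML criterion is maximized by L-BFGS-B (ftol 1e−12,
  gtol 1e−7, max 500 iterations, up to 3 jittered restarts). Line-search
  breakdown at a numerically flat gradient (max |∇| < 1e−4) is treated as
  convergence; otherwise a Nelder–Mead polish from the stalled point
  finishes the maximization before a restart is attempted.
  Initialization: OLS means and the complete-case sample
  covariance of OLS residuals (diagonal fallback, small ridge).
  Participants are grouped by missingness pattern so each REML evaluation
  is a handful of vectorized solves.
- **Inference.** A contrast c′b has variance c′(Σᵢ Xᵢ′Vᵢ⁻¹Xᵢ)⁻¹c.
  Satterthwaite df = 2V²/(g′Wg), with g the central-finite-difference
  gradient (relative step 1e−4) of the contrast variance in the
  covariance parameters and W the inverse observed information (numerical
  Hessian of the negative REML criterion, cached across contrasts). This
  reproduces the one-sample df = n−1 exactly and the balanced two-sample
  df ≈ 2n−2; with singular information the df falls back to ∞ (normal
  approximation) with a warning.

Degenerate inputs: fewer participants than fixed-effect parameters raises
a rank error; a single visit is allowed only without the baseline
constraint (it reduces to one- or two-sample normal models, which the
test suite uses as closed-form oracles).

## 4. Mediation decomposition

Change scores (visit minus baseline, after eye averaging) are analysed on
participants complete for the dependent change and all mediator changes
at that visit — the complete-case set is visit-specific. ChT enters the
mediation in mm (its coefficient is then per-mm, commensurate with AL)
while I/O stays in µm; the conversion is logged by the pipeline.

Four least-squares fits on the same rows: ΔSE ~ arm + ΔAL + ΔLP + ΔChT
(giving γ per mediator and the direct effects δ_D), and Δm ~ arm per
mediator (giving β). Mediator models contain arm only — no site or
baseline covariates — mirroring how the intermediate-outcome models are
specified in this literature; a site-adjusted variant can be composed by
pre-residualizing if needed. Then δ_m = β·γ, δ_I = Σδ_m, δ_T = δ_D + δ_I,
which equals the ΔSE ~ arm coefficient *exactly* by nested-OLS algebra;
the implementation computes both and the tests assert agreement to 1e−10.
Percentages are 100·δ_component/δ_T; they can exceed 100 or be negative,
and direct + mediated percentages sum to 100 exactly.

The joint covariance of all coefficients is the sandwich of the stacked
estimating equations of the four fits. This retains the β–γ covariances
across models (treating the fits as independent would mis-state the
uncertainty of β·γ) and is heteroskedasticity-robust as a side effect.
Products and sums use the delta method — se²(β·γ) = β²var(γ) + γ²var(β) +
2βγ·cov(β,γ), collapsing to the Sobel formula when the covariance is
zero — with normal-approximation p-values and CIs; between-arm contrasts
of any component use the same machinery and are antisymmetric under arm
swap. Mediators whose design matrix has condition number > 1e10 raise a
collinearity error naming the worst pair (this is why ACD and VCD, which
are arithmetically entangled with AL, are not offered as mediators).

## 5. Multiplicity, sample size, pipeline

- **FDR.** Benjamini–Hochberg step-up within two explicit families,
  adjusted separately: (i) all pairwise-vs-placebo change contrasts
  across the nine outcomes and two follow-up visits (36 p-values);
  (ii) the mediation effect-size-difference p-values for the direct and
  per-mediator components across visits (8 p-values) — sums (indirect,
  total) are excluded since they aggregate adjusted components. Every
  adjusted p-value's family is recorded in the output tables.
- **Sample size.** n per group = ceil(2(z₁₋α/₂ + z_power)²·sd²/Δ²), the
  two-sided normal approximation (α = 0.05, power 0.8, sd 0.69 D,
  Δ = 0.6 D gives 21). An iterated t-quantile variant is available behind
  a flag and is never smaller.
- **Pipeline.** Raw (or simulated) CSV → derivation → eye averaging →
  per-outcome cLMM (AL, CCT, ACD, LT, VCD, ChT, SE, Km, LP) → mediation
  at months 3 and 6 → FDR → CSV tables + JSON summary + timestamped log
  (seed, config hash, library versions). Outputs are a pure function of
  (input, config, seed); model failures for one outcome are logged and do
  not abort the bundle.

## 6. Known limitations

- Bennett constants default to the schematic-eye values; analyses of real
  cohorts should customize c₁/c₂ and will shift mean LP by a few tenths
  of a diopter.
- The Satterthwaite route (finite differences of the contrast variance)
  is one of several in circulation; closed-form cases are reproduced
  exactly, but third-party mixed-model software may differ in the third
  decimal of the df on unbalanced data.
- The mediation estimand is the linear product-of-coefficients
  decomposition; it is not a counterfactual natural-effects analysis and
  assumes no exposure–mediator interaction.
- The generator's independence of outcomes given arm means cross-outcome
  mediation structure in full-trial simulations is null by construction;
  parameter-recovery tests for the mediation stage therefore use the
  dedicated linear-system generator.
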