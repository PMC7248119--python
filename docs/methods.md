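# Model and methods

## The system

`quorumevo` simulates the evolution of quorum-sensing (QS) control of a
cooperative trait in group-structured populations of digital bacteria.
Each individual carries up to three heritable traits:

- **p** — basal signal production rate (uM/s per unit cell density),
- **S_Th** — signal response threshold (uM): the individual expresses its
  cooperative phenotype only where the local equilibrium signal exceeds
  S_Th (strict inequality; ties stay OFF),
- **r** — auto-regulation ratio (dimensionless): positive feedback that
  raises production up to a factor (1 + r) at signal saturation.

The ecological challenge is density sensing: cooperation only pays in
environments whose cell density N exceeds a critical threshold N_Th, and
individuals must infer "N > N_Th" from the signal their group accumulates.

## Signal dynamics

Extracellular signal S in a group at stationary density N follows

    dS/dt = sum_g p_g (1 + r_g S/(K + S)) N_g  -  (u + m) S,

where the sum runs over the group's founder genotypes, each allocated an
equal density share N_g = N/G; u is the environmental decay rate, m an
optional mass-transfer (diffusion/advection) loss, and K the feedback's
half-saturation concentration. Signal is assumed to equilibrate fast
relative to the ecological timescale, so the simulator uses the
closed-form equilibrium: with basal load A = Σ p_g N_g and feedback load
B = Σ p_g r_g N_g, S* is the unique non-negative root of

    (u + m) S² + ((u + m)K − A − B) S − A K = 0,

which reduces to S* = A/(u + m) without feedback, and to the familiar
S* = pN/u for a clone in a closed environment. A = 0 returns S* = 0: the
feedback loop is never primed without basal production. An explicit ODE
integrator (`integrate_signal_ode`, LSODA at rtol 1e-12 with horizon
doubling until the endpoint is stationary) exists purely as a test oracle;
near-critical feedback (B close to (u+m)K) relaxes much more slowly than
1/(u+m), which is why the oracle extends its own horizon.

### The half-saturation constant K

Default K = 10 uM. The evolved working range of S* is a few uM; placing K
above that range keeps the feedback term responsive (quasi-linear) where
decisions happen. If K sits far below the working range the Michaelis
term saturates and r degenerates into a constant multiplier on p — a
phenotype indistinguishable from raising basal production, which removes
the group-conditional character that makes auto-regulation a distinct
trait. K is a configuration value and all equilibria accept any K > 0.

## Payoff

Each generation every group is evaluated across a panel of testing
densities (default: 100 densities evenly spaced on the linear scale from
10^1.5 to 1e5 cells/uL; the panel median, 5.0016e4 cells/uL, doubles as
the default N_Th). At each density, with f = (ON members)/G the
cooperating fraction under equal density shares:

    payoff = baseline + [N > N_Th] · B_coop · f − [ON] · C_coop − C_sig · p_eff

- the public-good benefit is linear in f, shared by every member
  (including OFF free-riders) and gated by a hard density step;
- the cooperation cost C_coop is paid only when expressing;
- the signalling cost is proportional to realised per-capita production
  p_eff = p(1 + r S*/(K + S*)) (auto mode) or p, so induced signalling is
  itself costly.

Fitness is the arithmetic mean payoff over the density panel. Defaults:
baseline 1000, B_coop 300, C_coop 100, C_sig 1e9. The signalling-cost
default is calibrated so that the clonal evolved optimum sits at
p ≈ 4–6e-9 uM/s with S_Th ≈ 2–3 uM — a well-tuned density sensor interior
to the trait box.

This linear benefit form has a hard structural consequence: a lone
cooperator in a group of G nets B_coop/G − C_coop per supra-threshold
density, so individually profitable cooperation requires G < B_coop/C_coop.
The default ratio of 3 places the collapse of cooperation at mean founder
numbers around 3–4, which is where the mixing experiments probe it. The
fixed-G = 5 assortment experiment instead uses B_coop = 600 (ratio 6 > G):
with the default ratio, five-founder groups lie entirely outside the
cooperative window and the experiment's premise — evolved cooperation at
G = 5 — cannot exist. Note also that the ON/OFF crossing density shifts
with cheat load identically with and without feedback (at the crossing
S = S_Th fixes the induction factor), so auto-regulation cannot move this
window edge; its effects operate through establishment dynamics, response
synchrony and cost conditionality.

## The generational loop

Wright–Fisher-like, non-overlapping generations at fixed pool size:

1. **Group founding.** The propagule pool is randomly permuted and cut
   into groups. Founder counts per group are either fixed (G) or drawn as
   max(Poisson(λ_G), 1) — mean λ_G + e^(−λ_G), i.e. 2.135 at λ_G = 2 — with
   a zero-truncated Poisson (mean λ_G/(1 − e^(−λ_G)), 4.073 at λ_G = 4)
   selectable; the last group absorbs any remainder, so individuals are
   conserved exactly.
2. **Evaluation** across the density panel as above.
3. **Selection.** Offspring are drawn multinomially with weights
   payoff − min(payoff) + ε (ε = 1e-9 of the payoff span). The shift keeps
   weights valid on any payoff scale while preserving order; a fully tied
   generation falls back to uniform drift.
4. **Mutation.** Each unfrozen trait mutates independently with
   probability 0.1 per reproduction, adding Gaussian noise with SD 2 % of
   the trait's bound range, reflected into [0, bound]. Bounds default to
   p ≤ 1e-7 uM/s, S_Th ≤ 50 uM, r ≤ 10. Freeze flags implement the
   genetic-constraint regimes (signal-evolving / response-evolving); r is
   frozen except in auto-regulation runs. Lineage ids are inherited and
   refreshed on mutation, giving a cheap diversity readout.
5. **Cheat injection** (optional): a fixed fraction of offspring is
   replaced by immutable constitutive cheats (p = 0, S_Th at its bound,
   never mutating).

Runs are bit-reproducible given (config, seed); replicate seeds derive
deterministically from a master seed and stay below 2^31.

## Analyses

- **ON-fraction curves**: each individual evaluated solo across the panel.
- **Coordination-line regression**: OLS of evolved mean S_Th on evolved
  mean p across conditions, against the parameter-free prediction
  S_Th = p N_Th/u (slope N_Th/u = 5.0016e8 at the defaults).
- **Cooperative investment**: the fraction of panel densities at which an
  individual is ON within its group's signal context — a [0, 1] quantity
  comparable across regulatory architectures (1 for constitutive
  cooperators, 0 for cheats).
- **Assortment**: OLS of group-mean investment on individual investment;
  slopes compared across architectures by the standard ANCOVA
  interaction F-test on the pooled regression. "Tighter" assortment is
  read from slope (closer to 1) and R²; raw residual variance is not
  comparable across arms because stronger group differentiation inflates
  it even as the relationship tightens.
- **Two-level Price partition**: with group mean fitness W_g, group mean
  trait z̄_g, and fitness-weighted within-group offspring means, the
  between-group term Cov(W_g, z̄_g)/W̄ and within-group term
  E[W_g Δz̄_g]/W̄ (group-size-weighted) sum to the realised change in the
  population mean trait exactly; the identity is enforced to 1e-10 in
  tests on fuzzed populations. Transmission bias from mutation lives in
  the within term and has zero expectation under the unbiased mutation
  kernel.
- **Spandrel assay**: for a fixed strain at fixed density, S*(m) =
  pN/(u + m) (feedback form if r > 0) against its threshold yields the
  critical loss rate m* = pN/S_Th − u (root-finding for r > 0) below
  which it cooperates — diffusion sensing as a byproduct of
  density-sensing adaptation.

## Study conditions and problem sizes

Full-scale conditions (pool 5,000, 5,000 generations, 30 replicates,
last-50-generation summaries) are the configuration defaults. All
experiments bundled in `experiments.py` and the presets run at desk
scale: pool 500, 500 generations, 100-density panel, 2–25 replicates per
condition, summaries over the last 50 generations. At this scale:

- The clonal cost sweep (8 signalling costs spanning 5e8–1e10, 3
  replicates each) reproduces the coordination line with R² ≈ 0.9996–0.9998
  and slope within ~7 % of N_Th/u. Rarely (~1–2 % of replicates) a run
  fails to establish cooperation within the horizon; per-cost averages
  therefore cover replicates whose final ON-fraction reaches 0.2 (about
  half the panel is supra-threshold for a converged sensor, so 0.2
  separates evolved from unevolved cleanly), falling back to all
  replicates if none establish.
- The mixing sweep (clonal, λ_G = 2, λ_G = 4; 5 replicates) shows the
  coercive escalation of p and S_Th at λ_G = 2 and payoff collapse toward
  baseline at λ_G = 4.
- The auto-regulation contrast at λ_G = 4 uses 25 replicates per arm
  because the feedback's desk-scale contribution is to the probability
  that cooperation establishes at all (its maintenance advantage needs
  evolved r well above what 500 generations produce); the ordering of arm
  means is genuinely stochastic at this scale.
- The G = 5 assortment experiment pools last-generation investments of 3
  replicates per arm (~1,500 points each).

## Numerical choices

- Closed-form equilibria throughout the hot path; the B = 0 branch
  returns A/(u+m) directly so the feedback-free reduction is bit-exact.
- The quadratic discriminant b² + 4(u+m)AK is computed in that form
  (always positive for A > 0; root product −AK/(u+m) < 0 guarantees a
  unique non-negative root).
- Reflection at trait bounds uses modular folding, exact for any step
  size.
- OLS and the ANCOVA F-test go through statsmodels; the ODE oracle
  through scipy's LSODA.
- Degenerate inputs raise: zero-variance predictors, zero mean fitness in
  the Price partition, invalid configs (unknown keys rejected).

## What the generator emulates — and does not

The synthetic environment captures patchy density variation (the panel),
genetic mixing at group founding, and signal-mediated social feedback. It
does not model growth dynamics (densities are exogenous carrying
capacities), spatial structure within groups, signal diffusion gradients,
receptor kinetics, multi-signal architectures, or recombination.
Passing desk-scale tests therefore demonstrates the evolutionary logic of
signal/response coordination, coercion, auto-regulation and spandrels in
this idealised setting — not quantitative predictions for any real
bacterial system, and not the full-scale (5,000 × 5,000 × 30) behaviour,
which is out of desk reach. Known limitations: the auto-regulation
maintenance advantage reported at full scale is not separable from noise
at desk scale (only its establishment advantage is); evolved r at desk
scale reaches ~1–3 rather than its full-scale plateau; and the linear
benefit form ties the cooperation window rigidly to B_coop/C_coop, which
is why per-experiment benefit values are documented above.
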