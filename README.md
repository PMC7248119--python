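# quorumevo

Agent-based *in silico* evolution of quorum-sensing (QS) controlled
cooperation. Populations of digital bacteria carry heritable signalling
traits — basal signal production rate `p`, response threshold `S_Th` and,
optionally, an auto-regulation ratio `r` — and evolve under patchy
density variation and controlled genetic mixing. The package is for
researchers in microbial social evolution who want a small, fast,
fully reproducible sandbox for questions like: when does signal/response
coordination evolve, when do coercive or cheating strategies take over,
what does positive feedback buy, and which capabilities are adaptations
versus spandrels?

## The model in brief

Signal in a group at density `N` follows

    dS/dt = Σ_g p_g (1 + r_g · S/(K+S)) · N_g − (u + m) S,

summed over founder genotypes with equal density shares `N_g = N/G`, and
equilibrates to the non-negative root of a quadratic — `S* = pN/u` for a
clone in a closed environment. An individual cooperates where `S* > S_Th`.
Cooperation pays only above a critical density `N_Th`: with cooperating
fraction `f`,

    payoff = baseline + [N > N_Th]·B_coop·f − [ON]·C_coop − C_sig·p_eff.

Each generation the propagule pool is scattered into groups (founder
counts `max(Poisson(λ_G), 1)`, or fixed `G`), evaluated across 100
testing densities from 10^1.5 to 1e5 cells/uL, selected in proportion to
payoff, and mutated. Because the optimal threshold satisfies
`S_Th = p·N_Th/u`, signal and response co-evolve along a coordination
line; costlier signalling drives "whispering" (low `p`, low `S_Th`),
while genetic mixing favours coercive (high `p`, high `S_Th`) strategies.

Full model details, parameter tables and the desk-scale study conditions
are in [`docs/methods.md`](docs/methods.md).

## A worked example

`examples/02_coordination_game.py` evolves small clonal populations at
three signalling costs and fits the coordination line:

```text
C_sig        evolved p     evolved S_Th   predicted S_Th = p*N_Th/u
5.0e+08   1.293e-08      6.098          6.469
2.0e+09   2.520e-09      1.055          1.260
8.0e+09   7.034e-10      0.283          0.352

OLS of S_Th on p: slope 4.785e+08 (predicted N_Th/u = 5.002e+08), R^2 = 0.9998
```

Each row is one evolved population (pool 500, 500 generations, averages
over the last 50): as signalling gets more expensive the evolved
production rate drops and the response threshold falls in proportion, so
every population still flips ON at the same critical density
(5.0016e4 cells/uL) — the regression of threshold on production across
costs is essentially perfect and its slope matches the predicted
constraint `N_Th/u`.

The other scripts in `examples/` each demonstrate one capability:
signal equilibria and the ODE cross-check, coercion under genetic mixing,
auto-regulation and individual–group assortment, the two-level Price
partition of selection, and the diffusion-sensing spandrel assay.

## Command line

A thin CLI wraps the library for batch runs:

```bash
quorumevo run --preset clonal-cost-sweep --seed 1 --out runs/sweep --scale 0.5
quorumevo analyze --run-dir runs/sweep
quorumevo spandrel --p 4.37e-9 --sth 2.15 --n 8.5e4
```

`run` writes per-generation records (CSV), replicate summaries (JSON) and
a TOML config echo that reproduces the run exactly; `analyze`
post-processes a run directory; `spandrel` needs no evolution — it maps a
strain's cooperation region across mass-transfer rates directly.

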