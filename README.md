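# cromics

Spatio-temporal, individual-based simulation of microbial communities
in which **macromolecular crowding** shapes what every cell sees.
Cells and secreted extracellular polymeric substances (EPS) are hard
spheres on a lattice; scaled particle theory (SPT) converts their local
size distribution into an activity coefficient γ per box and
metabolite,

    ln γ = −ln(1−S3) + [6S2/(1−S3)]R + [12S1/(1−S3) + 18S2²/(1−S3)²]R²
         + [8S0/(1−S3) + 24S1·S2/(1−S3)² + 24S2³/(1−S3)³]R³,

where S0..S3 are the crowder size moments (S3 = occupied volume
fraction) and R the metabolite radius.  γ raises the effective
concentration a cell senses, C_eff = ρ·γ·10⁶/V_box, and slows
diffusion, D_eff = D0/γ.  Metabolite fields obey
∂ρ/∂t = ∇·(D_eff ∇ρ) (Crank–Nicolson or lattice-Boltzmann solver);
each agent is a *metabacterium* (a fixed bundle of identical cells)
whose uptake is bounded by Michaelis–Menten kinetics on C_eff,
v_U = V_M·C_eff/(K_M+C_eff), and whose growth and exchange fluxes come
from a small stoichiometric model solved as a linear program.  Growth,
division with shoving, starvation shrinkage/death and random-walk
motility close the loop.  Fitness over a run is
F = ln(ρ_T/ρ_0)/t_sim, with relative fitness w = F₁/F₂.

Intended users: computational microbiologists studying how physical
crowding couples to cross-feeding, competition and biofilm structure.

## Worked example

Two *E. coli* biofilm variants compete on glucose and O₂ supplied from
the top of a 3D column: a wild type and a mutant that secretes
0.43 g EPS per g_DW of growth (costing it 30% of its growth rate, but
making its side of the biofilm less dense):

```python
from cromics import build_eps_scenario, run, fitness, relative_fitness

cfg, state = build_eps_scenario(nx_ibm=8, nz_ibm=16, f_eps=0.43,
                                t_sim=8.0, seed=0)
rho0 = {sp: state.total_biomass(sp) for sp in ("wt", "eps")}
traj = run(state, cfg.params, stop_on_full=True)
for sp in ("wt", "eps"):
    f = fitness(rho0[sp], traj.biomass[sp][-1], traj.times[-1])
    print(f"{sp}: {rho0[sp]:.3e} -> {traj.biomass[sp][-1]:.3e} g_DW, "
          f"fitness {f:.3f} /h")
w = relative_fitness(
    fitness(rho0["eps"], traj.biomass["eps"][-1], traj.times[-1]),
    fitness(rho0["wt"], traj.biomass["wt"][-1], traj.times[-1]))
print(f"relative fitness w_eps = {w:.3f}")
```

prints

```
wt: 7.310e-10 -> 2.229e-09 g_DW, fitness 0.139 /h
eps: 3.117e-10 -> 1.241e-09 g_DW, fitness 0.173 /h
relative fitness w_eps = 1.240
```

The mutant pays 30% at the flux level yet wins (w > 1) because its
less dense structure lets nutrients penetrate deeper and its front
reaches the supply face sooner — the spatial payoff of EPS secretion.

A command-line entry point wraps the same machinery:

```bash
cromics run crossfeed --seed 1 --out out/ --crowding on
cromics validate --tier worked
cromics analyze out/ --metric abundance
```

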