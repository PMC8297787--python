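# Methods

## Model overview

`cromics` simulates a microbial community on a regular lattice with two
coupled resolutions: metabolite fields live on a coarse lattice (the
"CN lattice", after the Crank–Nicolson solver that advances them) and
individual agents occupy a finer "IbM lattice" whose boxes each hold at
most one agent.  Every CN box owns `coarse_factor**dims` IbM boxes; 2D
systems are a monolayer of rectangular prisms with an explicit height
`dz`, so no mathematics is special-cased on dimensionality.

An agent is a *metabacterium*: a fixed count `metaB` of identical cells
treated as one super-individual.  Each macro step of length `dt` (h):

1. **Crowding.**  Cells and attached EPS are hard spheres.  Per CN box,
   scaled particle theory (SPT) turns the size moments S0..S3 of the
   local crowder population into an activity coefficient per metabolite,

   ln γ = −ln(1−S3) + [6S2/(1−S3)]R + [12S1/(1−S3) + 18S2²/(1−S3)²]R²
        + [8S0/(1−S3) + 24S1S2/(1−S3)² + 24S2³/(1−S3)³]R³,

   with S_x = π/(6V_box) [Σ_l ρ_l N_A/10³ (2R_l)^x + Σ_cells (2R_c)^x].
   γ is the ratio of box volume to the volume available to a metabolite
   of radius R; it raises the effective concentration a cell senses,
   C_eff = ρ γ 10⁶ / V_box (mM), and lowers diffusion, D_eff = D0/γ.
   Solutes below 400 Da are volumeless (R = 0), for which γ reduces
   exactly to 1/(1−S3).  S3 ≥ 1 (overfilled box) is a hard error.

2. **Metabolism** (each of the `dt/dt_cn` substeps).  Active uptake is
   bounded by Michaelis–Menten kinetics on C_eff, v_U = V_M C/(K_M+C);
   passive uptake by min(V_M, pool/(M dt)).  Agents sharing a CN box
   receive pool shares proportional to V_M·M_cell, so results are
   independent of agent iteration order, and every non-clamped uptake
   is additionally capped by its share so pools can never go negative.
   A small stoichiometric model per species is solved as an LP
   (scipy/HiGHS): maximize the biomass flux v_bio subject to internal
   mass balance, an ATP maintenance lower bound, proportional couplings
   (methionine or EPS secretion = ratio × v_bio), and the uptake
   bounds; a secondary LP minimizes the L1 norm of exchange fluxes at
   the optimum so degenerate secretion profiles are reproducible.  If
   even maintenance is infeasible the cell shrinks at
   v_shrinkage = 1.6×10⁻² h⁻¹ with zero exchange.  Masses and box
   amounts then update linearly: M ← M(1 + v_bio dt),
   ρ ← ρ + v_ex M dt, and growing EPS secretors accumulate attached
   EPS at f_EPS g per g_DW of new biomass.

3. **Diffusion** (same substeps).  ∂ρ/∂t = ∇·(D_eff ∇ρ) with per-box
   D_eff, via either a finite-volume θ-scheme (θ = 1/2 Crank–Nicolson
   by default) with harmonic-mean interface diffusivities and one
   sparse LU factorization per crowding state, or a BGK
   lattice-Boltzmann scheme (D2Q5/D3Q7, per-box relaxation time
   τ = 1/2 + D_eff dt/(c_s² Δx²)).  Boundary dialects per face:
   zero-flux, periodic, absorbing (C = 0 outside), fixed concentration
   (face layer reset to its target effective concentration after every
   step), plus field-wide clamps that hold a metabolite at a target
   C_eff in every box.
4. **Cell rules** (once per macro step): death below the minimal mass,
   division when M ≥ metaB·M_max,sp (mother keeps her box, the daughter
   takes a random free neighbor or shoves a breadth-first chain of
   neighbors toward the nearest free box), and diffusive random walks
   with hop probability 2·dims·D_sp·dt/Δx².

A per-step ledger itemizes, for every metabolite, cellular exchange,
boundary loss and clamp injection, and asserts that they explain the
total change to 1×10⁻⁸ relative.  All randomness flows from one master
seed through named substreams (placement, division, walk, sampling), so
identical configs and seeds give identical trajectories, and
checkpoints capture RNG state for bitwise-identical continuation.

## Numerical choices

* θ = 1/2 is second-order but non-monotone when D dt/Δx² is large; the
  shipped scenario configs use θ = 1 (backward Euler), which is an
  M-matrix scheme and cannot produce negative amounts at the coarse
  substeps production runs use.  Unit tests exercise θ = 1/2 within its
  monotone range.
* One sparse factorized solve is used in any dimension (desk-scale
  lattices are at most a few thousand boxes); this is exactly
  conservative and avoids operator-splitting error.
* The LBM lattices use standard rest weights (w0 = 1/3 in 2D, 1/4 in
  3D); τ ≤ 1/2 raises a stability error, and accuracy degrades for
  τ ≫ 2, so the scheme suits fine time steps.  It is validated against
  the CN solver (≤1% relative L2 on smooth heterogeneous fields) and
  against the analytic Gaussian variance.
* LP responses are cached per (species, uptake-bound vector) with
  bounds rounded *down* to `quantize_digits` (default 2) significant
  figures, so a cached solution can never overdraw the pool its bound
  came from.  This collapses the per-agent LP count by one to two
  orders of magnitude at a ≤1% systematic underestimate of uptake.
* Field-wide clamped metabolites are treated as an externally
  maintained bath: their uptake bound is the Michaelis–Menten cap alone
  and the clamp restores the target after every substep.  Stepping the
  diffusion solver on a clamped field and then resetting it is
  equivalent to resetting, so the solve is skipped.
* Division splits mass (and attached EPS) 1:1 by default, with an
  optional uniform asymmetry; shoving picks uniformly among equidistant
  free boxes under the seeded stream.

## Shipped scenarios and the scale-reduction rule

Two communities are shipped, with every *per-box* quantity — box
edges, concentrations, kinetic constants, cell masses and specific
volumes, EPS parameters — at its published study value:

* **2D cross-feeding pair** (`build_crossfeed_scenario`): a
  methionine-auxotroph lactose consumer (toy network: lactose → carbon
  + secreted galactose; fermentation → acetate + ATP; biomass needs
  carbon, ATP and methionine; maintenance 2 mmol ATP g_DW⁻¹ h⁻¹) and
  an acetate/galactose consumer whose mutant secretes methionine at
  r_meth = 0.5 mmol per g_DW of growth.  Lactose and O2 are clamped at
  2.92 / 0.21 mM effective concentration; exchanged metabolites start
  at zero.  The box height dz sets the initial crowding (2%, 20%, 40%)
  via dz = M υ_sp/(V_occ Δx²).  One metabacterium represents
  round(7.5×10⁻¹⁰/4.89×10⁻¹³) ≈ 1534 cells (the spot-mass bookkeeping:
  3×10⁻⁷ g_DW per 400-metabacterium spot); initial masses are
  normal(4.89×10⁻¹³, 1.32×10⁻¹³) g_DW per cell × metaB, truncated at
  0.1× the mean.
* **3D EPS biofilm** (`build_eps_scenario`): a glucose/O2 consumer
  (respiration, acetate-overflow fermentation, optional acetate
  respiration) whose mutant secretes EPS at f_EPS ∈ {0.11, 0.43} g per
  g_DW with *the same precursor cost per gram as biomass*, so the LP
  growth optimum under fixed supply is exactly the wild-type optimum
  divided by (1 + f_EPS).  Cells per metabacterium follow
  metaB = round(0.52·Δx³/(M_max υ_sp + f_EPS M_max υ_EPS)) — 27 (WT),
  20 (f = 0.11), 12 (f = 0.43) at Δx = 5.7×10⁻³ mm — and the division
  threshold is metaB·M_max,sp, so a full box holds the same cell+EPS
  volume for every variant.  Glucose (5 mM) and O2 (0.21 mM) are fixed
  at the top face; x and y are periodic; cells are non-motile.

**Scale reduction.**  The published geometries (400×400 and 22×22×68
IbM boxes) are too large for routine runs; the builders accept reduced
box counts.  Shrinking the domain at fixed diffusivity would change the
*regime*: the full 10 mm system has a domain-crossing diffusion time of
hours — comparable to the growth time scale — whereas a 0.6 mm domain
would be effectively well mixed and both the crowding effect on
metabolite redistribution and the depth structure of the biofilm would
vanish.  The builders therefore rescale all diffusivities (and the
agent motility) by the squared length ratio — (nx_ibm/400)² for the 2D
community, (nz_ibm/68)² for the biofilm — which leaves the
domain-crossing time, the exchange-versus-leakage partition and the
nutrient penetration depth (in box units) invariant.  At full scale the
factor is 1 and the published diffusivities are used unchanged.

Two desk-scale deviations from the published setups are deliberate and
exposed as parameters: the partner species' non-growth maintenance is 0
(at reduced carbon fluxes a maintenance lower bound becomes an
all-or-nothing infeasibility cliff that prevents the community from
bootstrapping; the lactose consumer keeps maintenance 2, which drives
the overflow secretion that seeds the mutualism), and the qualitative
validation fixtures choose the metabolite boundary (absorbing, as
published, for the leakage-sensitive crowding experiment with
segregated colonies; sealed/zero-flux to emulate the interior of a
large system for the inoculum-convergence experiment).

## What the synthetic scenarios do and do not show

The toy stoichiometric networks reproduce the *exchange topology* and
the coupling structure of the published communities (obligate
methionine/carbon exchange; growth-proportional secretion with an
exact 1/(1+f) growth cost), not genome-scale flux values.  Directional
community-level findings — crowding lowering total biomass, crowding
and initial frequency raising the secreting mutant's fitness, EPS
secretion paying off spatially — replicate as seed-averaged signs on
reduced grids; the published magnitudes (e.g. the 76.3%/23.7% ratio
convergence or the 7% methionine-secretion penalty) are properties of
the genome-scale models and are only reachable through the opt-in SBML
backend with user-supplied model files.  Real communities additionally
feature non-spherical cells, electrostatics, attachment mechanics,
product inhibition (acetate toxicity is deliberately excluded) and
regulatory adaptation, none of which are modeled.

## Known limitations

* The per-box BGK relaxation handles smoothly varying D_eff well but is
  not a bit-match to any particular crowding-LBM derivation; treat the
  CN solver as the reference.
* Shoving moves a single breadth-first chain of agents one box each;
  mechanical relaxation of whole colonies is not modeled.
* Membrane-penetrating metabolites simply omit the cell term from
  their crowding moments; this is an approximation isolated behind the
  `penetrates_membrane` flag (off for all shipped metabolites).
* Metabolism and diffusion are operator-split at `dt_cn`; uptake within
  a substep can consume at most the standing box pool, so very coarse
  substeps underestimate flux-limited uptake (first-order convergence,
  checked by a halving test).  The shipped configs keep
  v_bio·dt_cn ≲ 0.05.
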