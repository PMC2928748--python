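# Methods

`metevo` simulates the adaptive evolution of small metabolic networks in
which promiscuous group-transfer enzymes specialize under a
specificity–activity trade-off, and asks how the selective environment —
one stable medium versus fluctuation over several — shapes the knockout
robustness and flux structure of the evolved networks.

## The model

**Metabolites.** A metabolite is a combination of `n_groups` abstract
biochemical groups (default 5), each present or absent, giving
`2**n_groups = 32` species identified with the integer value of their
bit pattern. Every species carries a free energy drawn once per world
from U(0, 1) (dimensionless; thermal energy is scaled to 1).

**Enzymes.** Enzyme *i* transfers one specific group by a ping-pong
mechanism: a donor passes the group to the enzyme (which enters its
bound state E1) and later the enzyme passes it to an acceptor. Each
half-reaction *j* follows the linear law

    v = k_ij (E0 X_d − E1 X_a / q_ij),

with `q_ij = exp(G_d − G_a − ΔG_E)` the equilibrium constant assembled
from the metabolite free energies and the enzyme's bound-state free
energy difference ΔG_E ~ U(0, 1). All 16 metabolites containing the
group are potential donors; their group-stripped partners are the
acceptors. A net transfer couples two half-reactions, so a functional
enzyme needs at least two active rate constants; an enzyme with **more
than two** is *multifunctional*.

**Transporters** are passive: `v = T t_j (X_j − X_ext_j)` (positive =
efflux). The environment is an infinite reservoir: nutrients sit at a
fixed external concentration (1.0 by default; the single concentration
scale can be absorbed into the rate constants) and all other external
concentrations are 0, i.e. excreted waste never accumulates outside.

**Trade-off.** Each gene's rate constants satisfy
`Σ_j k_ij^(1/α) = 1` with α = 2: specializing on fewer reactions buys
over-proportionally higher rate constants (a transporter dedicated to
one metabolite gets 4× the rate constant of one split over two).

**Growth and fitness.** Biomass condenses four world-specific
metabolites at rate `v_BM = k_BM Π X_b` (k_BM = 1), consuming one unit
of each; growth dilutes every metabolite at
`W = v_BM / (C0 + C_E E + C_T T)` with costs C0 = 10, C_E = C_T = 1 per
unit dosage. Fitness on one medium is the steady-state growth rate; in
the fluctuating environment it is the geometric mean of the growth
rates over the media M1, M2 and R — fluctuation is implemented as
simultaneous selection, not literal temporal switching.

**Media.** A minimal medium is a complementary metabolite pair
{m, complement(m)} — exactly one donor and one acceptor of every group,
the cheapest medium that can support biomass formation. A world draws
two distinct pairs (M1, M2); the rich medium R is their union.

**Evolution.** The walk is deterministic strong-selection/weak-mutation
hill climbing: every candidate mutation of the current network is
evaluated and the best one is fixed if it improves fitness by more than
`delta_fit = 1e-9` (relative). Kinetic mutations move one reaction's
root-scale value `k^(1/α)` by ±m (m = 0.05, clipped to [0, 1]) and
rescale the gene's other roots proportionally so the budget stays
exhausted; a fully specialized gene stepping down spreads the freed
budget uniformly. Gene duplications append an independently mutable
copy at dosage 1; deletions remove one gene. Copy-number mutations are
considered only when no kinetic mutation is beneficial (they compete in
one pool under the `dupfreq` variant). Ties go to the first candidate
in the deterministic enumeration order, and identical gene copies are
evaluated once — the first copy wins any tie, so the result equals the
full sweep. A run ends at a local optimum (no beneficial candidate; the
final network is re-audited by an exhaustive sweep) or at
`max_generations = 2000`, in which case it is flagged and excluded from
ensemble aggregates.

The unspecific ancestor has one enzyme per group with all 16 rate
constants equal (k = 1/256) and a single transporter carrying all 32
metabolites (t = 1/1024), all dosages 1.

**Background-activity variant.** `variant: background` adds a rate
floor `k_bg = 1e-4 · (1/16)²` to every enzyme half-reaction on top of
the constrained rates, so any network retains a residual capability for
every reaction and evolution can start from arbitrary networks.

## Steady states

At a fixed point the bound-enzyme states have the exact closed form
`E1_i = E_i S_d / (S_d + S_a)` with `S_d = Σ k_ij X_d`,
`S_a = Σ (k_ij/q_ij) X_a`, so the solver eliminates them and finds the
root of the reduced 32-metabolite system with a damped Newton iteration
(analytic Jacobian, non-negativity projection, backtracking line
search); the growth rate enters the dilution term as an algebraic
function of the state, so W is self-consistent by construction.
Metabolites that cannot be reached from the medium through active
reactions are pinned to exactly zero. A pseudo-transient continuation
(adaptive implicit Euler) rescues cold starts and the rare stall, and
along an evolutionary walk every candidate is warm-started from the
parent's steady state. Newton polishes to the numerical floor
(residual ≲ 1e-14), well below the `delta_fit` decision threshold; a
solve that cannot reach a residual of `ss_tol = 1e-9` is reported
non-converged and the caller treats that fitness as 0 (so lethal or
runaway mutants are comparable, not exceptional). An independent route
— stiff integration of the full (X, E1) ODE with a Newton polish — is
kept as `steady_state(..., method="integrate")` and the test suite
checks the two routes agree to 1e-6.

Identical gene copies (the model's dosage mechanism) are aggregated
into one kinetic row with summed dosage before solving; this is exact
because fluxes are linear in dosage at fixed concentrations.

## Analyses

**Types and knockouts.** Genes with the same group and the same active
support (reactions with k above `eps_active = 1e-6`) form one *type*;
single-copy knockouts of duplicated genes are trivially buffered, so
robustness distributions remove whole types and report
`W_knockout / W_wildtype` (the biomass-rate ratio is emitted
alongside). Stable-evolved networks are measured on their own medium;
V-evolved networks on each single medium (Rob-V-M1/M2/R) and over all
media (Rob-V-V, geometric mean); aggregate-table robustness for V
networks is the rich-medium measurement. Trajectory-level robustness
(the per-generation mean knockout fitness) instead uses single-gene
knockouts, which is what makes the transient buffering by a fresh
duplicate visible.

**Independent fluxes.** The stoichiometric matrix has one column per
coupled net transfer (each unordered pair of active slots of an enzyme
type), one exchange column per active transport slot of each
transporter type, and one biomass column; columns are per *type*, so
dosage copies do not inflate the count. The independent-flux count is
the null-space dimension (columns − rank, singular values below
1e-8 · max counting as zero). A network with no active reactions has an
empty matrix and zero fluxes.

**Role of multifunctional enzymes.** A multifunctional type is an
*isoenzyme* if another same-group type shares one of its active
reactions; otherwise it is a *nonessential extra* if some active
reaction carries zero steady-state flux or can be removed without
lowering the biomass rate; the residual label is *essential*.

## Problem sizes and defaults

All model constants default to the study conditions (α = 2, m = 0.05,
k_BM = 1, C0/C_E/C_T = 10/1/1, 5 groups, 4 biomass metabolites, 2
media in the fluctuating set plus their union). Greedy walks typically
terminate after 400–1100 fixed mutations. Ensemble analyses are run at
reduced replicate counts chosen as a compromise between statistical
power and single-CPU runtime: the bundled acceptance script uses 5
replicate worlds per scenario (~10–15 min) and the test suite uses 4;
the original contrasts were established on 100-replicate ensembles, so
scaled-down runs are expected to reproduce the orderings between
scenarios, not the printed magnitudes. The `batch`/`report` CLI runs
arbitrary replicate counts.

## What the generator does and does not emulate

Worlds are drawn exactly as the study conditions prescribe: free
energies i.i.d. U(0, 1), minimal media as random complementary pairs,
four random biomass metabolites, enzyme bound-state energies U(0, 1).
The model abstracts away real biochemistry: there is no chemistry
beyond 5-bit group composition, no enzyme saturation beyond the
ping-pong state pair, no stochastic kinetics, no population genetics
(the walk is a single deterministic lineage), and environmental
fluctuation acts through the geometric mean rather than explicit
switching dynamics. Passing tests therefore demonstrate properties of
this model class, not of any organism's metabolism.

## Numerical choices and limitations

- Rate-root feasibility uses a 1e-12 slack (a root below it counts as
  zero, above 1−1e-12 as fully specialized).
- The beneficial-mutation threshold (1e-9 relative) sits well above the
  solver's residual floor but below typical mutation effects; walks can
  therefore fix long tails of micro-improvements, which is the main
  runtime cost on rugged worlds.
- Proportional rescaling never drives a rate root to exactly zero (only
  the ±m clip does), so evolved genes can retain small side activities
  above `eps_active`; the active-support threshold, not exact zeroness,
  defines function. Multifunctionality counts are sensitive to this
  threshold.
- Knockout mutants that fail to converge even after pseudo-transient
  rescue are scored as fitness 0; this is conservative for mutants
  whose true steady state is marginal.
- M1- and R-evolved networks in the same world can converge to the same
  local optimum when the R walk ends up importing only one nutrient
  pair; this is a genuine property of greedy walks here, not an error.
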