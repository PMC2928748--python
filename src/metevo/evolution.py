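"""Greedy adaptive walks: mutation enumeration, fixation, and trajectories.

Evolution follows the strong-selection weak-mutation regime as a
deterministic hill climb: every possible mutation of the current network
is evaluated, the best one is fixed if it improves fitness by more than
`delta_fit` (relative), and the walk ends at a local optimum where no
kinetic mutation, duplication, or deletion is beneficial.

Kinetic mutations move one reaction's root-scale rate k**(1/alpha) by
+-m (clipped to [0, 1]) and rescale the gene's other roots by a common
factor so the trade-off budget stays exactly exhausted.  Duplications
append an independently mutable copy of a gene at dosage 1; deletions
remove a gene.  In the main model copy-number mutations are only
considered when no kinetic mutation is beneficial; with
``params.dup_frequent`` all candidates compete in one pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .kinetics import Pack, reachable_metabolites, solve_steady_X
from .model_core import (
    ModelParams,
    Network,
    Scenario,
    active_support,
    as_scenario,
)

__all__ = [
    "Mutation",
    "GenerationRecord",
    "Trajectory",
    "apply_kinetic_mutation",
    "mutated_roots",
    "enumerate_mutations",
    "greedy_step",
    "evolve",
    "continue_evolution",
    "is_local_optimum",
    "mean_single_knockout_fitness",
]


@dataclass(frozen=True)
class Mutation:
    """One heritable change: kind in {kinetic_up, kinetic_down, duplication,
    deletion}; gene_type in {enzyme, transporter}; reaction_index is set for
    kinetic mutations only."""

    kind: str
    gene_type: str
    gene_index: int
    reaction_index: int | None = None

    def __str__(self) -> str:
        s = f"{self.kind} {self.gene_type}[{self.gene_index}]"
        if self.reaction_index is not None:
            s += f" slot {self.reaction_index}"
        return s


@dataclass
class GenerationRecord:
    generation: int
    mutation: Mutation
    fitness: float
    n_enzymes: int
    n_transporters: int
    n_unique_enzymes: int
    n_unique_transporters: int
    mean_knockout_fitness: float | None = None


@dataclass
class Trajectory:
    """Per-generation log of a greedy walk."""

    start_fitness: float
    records: list[GenerationRecord] = field(default_factory=list)
    terminated: bool = False
    start_mean_knockout_fitness: float | None = None

    @property
    def fitnesses(self) -> list[float]:
        return [r.fitness for r in self.records]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "generation": r.generation,
                "mutation": str(r.mutation),
                "kind": r.mutation.kind,
                "fitness": r.fitness,
                "n_enzymes": r.n_enzymes,
                "n_transporters": r.n_transporters,
                "n_unique_enzymes": r.n_unique_enzymes,
                "n_unique_transporters": r.n_unique_transporters,
                "mean_knockout_fitness": r.mean_knockout_fitness,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)


def mutated_roots(roots: np.ndarray, slot: int, direction: int,
                  m: float) -> np.ndarray | None:
    """Root vector after a +-m kinetic step on `slot`, or None if infeasible.

    The other roots are rescaled proportionally to keep sum(roots) == 1; if
    the gene was fully specialized (all budget on `slot`) a downward step
    spreads the freed budget uniformly over the other slots.
    """
    r0 = float(roots[slot])
    if direction > 0:
        if r0 >= 1.0 - 1e-12:
            return None
        r1 = min(r0 + m, 1.0)
    else:
        if r0 <= 1e-12:
            return None
        r1 = max(r0 - m, 0.0)
    out = roots.copy()
    rest = 1.0 - r0
    if rest > 1e-12:
        out *= (1.0 - r1) / rest
    else:
        out[:] = (1.0 - r1) / (roots.size - 1)
    out[slot] = r1
    return out


def apply_kinetic_mutation(gene, reaction_index: int, direction: int,
                           params: ModelParams):
    """Return a copy of the gene with the kinetic mutation applied.

    Raises ValueError for infeasible moves (decreasing a zero rate or
    increasing a fully specialized one).
    """
    new = mutated_roots(gene.roots, reaction_index, direction, params.m)
    if new is None:
        raise ValueError("infeasible kinetic mutation")
    g = gene.copy()
    g.roots = new
    return g


def enumerate_mutations(network: Network, params: ModelParams) -> list[Mutation]:
    """All candidate mutations in deterministic order.

    Kinetic moves first (enzymes by index, then transporters; slots
    ascending; up before down; infeasible moves omitted), then one
    duplication and one deletion candidate per gene.
    """
    out: list[Mutation] = []
    genes = [("enzyme", i, g) for i, g in enumerate(network.enzymes)]
    genes += [("transporter", i, g) for i, g in enumerate(network.transporters)]
    for gtype, gi, gene in genes:
        for slot in range(gene.roots.size):
            r = float(gene.roots[slot])
            if r < 1.0 - 1e-12:
                out.append(Mutation("kinetic_up", gtype, gi, slot))
            if r > 1e-12:
                out.append(Mutation("kinetic_down", gtype, gi, slot))
    for gtype, gi, gene in genes:
        out.append(Mutation("duplication", gtype, gi))
        out.append(Mutation("deletion", gtype, gi))
    return out


def _apply_mutation(network: Network, mut: Mutation, params: ModelParams) -> Network:
    net = network.copy()
    pool = net.enzymes if mut.gene_type == "enzyme" else net.transporters
    if mut.kind in ("kinetic_up", "kinetic_down"):
        direction = 1 if mut.kind == "kinetic_up" else -1
        pool[mut.gene_index] = apply_kinetic_mutation(
            pool[mut.gene_index], mut.reaction_index, direction, params)
    elif mut.kind == "duplication":
        pool.append(pool[mut.gene_index].copy())
    elif mut.kind == "deletion":
        del pool[mut.gene_index]
    else:
        raise ValueError(f"unknown mutation kind {mut.kind}")
    return net


def _beneficial(f_new: float, f_old: float, delta: float) -> bool:
    if f_old <= 0.0:
        return f_new > 0.0
    return f_new > f_old * (1.0 + delta)


class _Evaluator:
    """Evaluates candidate fitness fast by patching a packed parent network
    in place and warm-starting the steady-state solver from the parent's
    per-medium states."""

    def __init__(self, network: Network, scenario: Scenario, params: ModelParams,
                 warm: dict[str, np.ndarray] | None = None):
        self.network = network
        self.params = params
        self.scenario = scenario
        self.world = network.world
        self.media = [(lbl, network.world.media[lbl].external) for lbl in scenario.media]
        self.pack = Pack(network, params)
        self.warm = dict(warm) if warm else {}
        self.free = {lbl: reachable_metabolites(self.pack, ext)
                     for lbl, ext in self.media}
        self.parent_fitness, self.parent_states = self._fitness_packed(
            self.pack, self.free, self.warm)

    def _solve_W(self, pack: Pack, ext, free, x0) -> tuple[float, np.ndarray, bool]:
        if not free[pack.bm].all():
            return 0.0, np.zeros(pack.n_met), True  # biomass unreachable: dead
        if x0 is not None:
            x0 = np.where(free, np.maximum(x0, 1e-8), 0.0)
        X, ok, _res = solve_steady_X(pack, ext, free, x0, self.params.ss_tol)
        if not ok:
            return 0.0, X, False
        _F, W, _v = _kernels.rhs(X, *pack.kernel_args(ext, free))
        return float(W), X, True

    def _fitness_packed(self, pack: Pack, free: dict, warm: dict
                        ) -> tuple[float, dict[str, np.ndarray]]:
        logs = 0.0
        states: dict[str, np.ndarray] = {}
        for lbl, ext in self.media:
            W, X, _ok = self._solve_W(pack, ext, free[lbl], warm.get(lbl))
            states[lbl] = X
            if W <= 0.0:
                return 0.0, states
            logs += np.log(W)
        return float(np.exp(logs / len(self.media))), states

    # -- candidate evaluation -------------------------------------------------

    def eval_kinetic(self, mut: Mutation, new_roots: np.ndarray) -> float:
        p = self.params
        pack = self.pack
        if mut.gene_type == "enzyme":
            gene = self.network.enzymes[mut.gene_index]
            cls = int(pack.enz_class_of[mut.gene_index])
            old_row = pack.K[cls]
            new_row = new_roots**p.alpha + p.k_bg
            if pack.Edos[cls] == gene.dosage:
                pattern_changed = bool(np.any((old_row > 0) != (new_row > 0)))
            else:  # remaining copies keep the old pattern alive
                pattern_changed = bool(np.any((new_row > 0) & ~(old_row > 0)))
            view = pack.with_enzyme_mutation(mut.gene_index, gene.dosage, new_row)
        else:
            gene = self.network.transporters[mut.gene_index]
            new_ttot = pack.ttot - gene.dosage * gene.rates \
                + gene.dosage * new_roots**p.alpha
            np.maximum(new_ttot, 0.0, out=new_ttot)
            pattern_changed = bool(np.any((pack.ttot > 0) != (new_ttot > 0)))
            view = pack.with_ttot(new_ttot)
        if pattern_changed:
            free = {lbl: reachable_metabolites(view, ext)
                    for lbl, ext in self.media}
        else:
            free = self.free
        f, _states = self._fitness_packed(view, free, self.parent_states)
        return f

    def eval_network(self, net: Network) -> float:
        pack = Pack(net, self.params)
        free = {lbl: reachable_metabolites(pack, ext) for lbl, ext in self.media}
        f, _states = self._fitness_packed(pack, free, self.parent_states)
        return f


def _gene_signature(gene_type: str, gene) -> tuple:
    if gene_type == "enzyme":
        return ("e", gene.group, gene.state_dG, gene.dosage, gene.roots.tobytes())
    return ("t", gene.dosage, gene.roots.tobytes())


def _representative_genes(network: Network) -> tuple[set[tuple[str, int]], dict]:
    """First gene index of every identical-gene class, with multiplicities.

    Identical gene copies (the model's dosage mechanism) yield identical
    candidate fitnesses, so evaluating one representative per class gives the
    same greedy choice as the full sweep under the first-wins tie-break.
    """
    reps: set[tuple[str, int]] = set()
    mult: dict[tuple[str, int], int] = {}
    for gtype, pool in (("enzyme", network.enzymes),
                        ("transporter", network.transporters)):
        seen: dict[tuple, tuple[str, int]] = {}
        for i, g in enumerate(pool):
            sig = _gene_signature(gtype, g)
            if sig not in seen:
                seen[sig] = (gtype, i)
                reps.add((gtype, i))
                mult[(gtype, i)] = 1
            else:
                mult[seen[sig]] += 1
    return reps, mult


def greedy_step(network: Network, scenario: "Scenario | str", params: ModelParams,
                *, _evaluator: _Evaluator | None = None
                ) -> tuple[Network, Mutation | None]:
    """One generation: fix the best beneficial mutation, or return the
    unchanged network and None at a local optimum.

    Kinetic candidates are tried first; duplications/deletions only when no
    kinetic candidate is beneficial (unless ``params.dup_frequent``).  Ties
    go to the earliest candidate in enumeration order (for identical gene
    copies only the first is evaluated; later copies can never win a strict
    tie-break).
    """
    sc = as_scenario(scenario)
    ev = _evaluator or _Evaluator(network, sc, params)
    f0 = ev.parent_fitness
    reps, _mult = _representative_genes(network)
    candidates = [m for m in enumerate_mutations(network, params)
                  if (m.gene_type, m.gene_index) in reps]
    kinetic = [m for m in candidates if m.kind.startswith("kinetic")]
    structural = [m for m in candidates if not m.kind.startswith("kinetic")]

    def best_of(muts: list[Mutation]) -> tuple[float, Mutation | None]:
        bf, bm_ = -np.inf, None
        for mut in muts:
            if mut.kind.startswith("kinetic"):
                gene = (network.enzymes[mut.gene_index]
                        if mut.gene_type == "enzyme"
                        else network.transporters[mut.gene_index])
                direction = 1 if mut.kind == "kinetic_up" else -1
                roots = mutated_roots(gene.roots, mut.reaction_index, direction,
                                      params.m)
                if roots is None:
                    continue
                f = ev.eval_kinetic(mut, roots)
            else:
                f = ev.eval_network(_apply_mutation(network, mut, params))
            if f > bf:
                bf, bm_ = f, mut
        return bf, bm_

    if params.dup_frequent:
        pools = [kinetic + structural]
    else:
        pools = [kinetic, structural]

    for pool in pools:
        bf, mut = best_of(pool)
        if mut is not None and _beneficial(bf, f0, params.delta_fit):
            return _apply_mutation(network, mut, params), mut
    return network, None


def is_local_optimum(network: Network, scenario: "Scenario | str",
                     params: ModelParams) -> bool:
    """Exhaustive audit: no single mutation is beneficial."""
    _net, mut = greedy_step(network, scenario, params)
    return mut is None


def mean_single_knockout_fitness(network: Network, scenario: "Scenario | str",
                                 params: ModelParams,
                                 warm: dict[str, np.ndarray] | None = None) -> float:
    """Mean relative fitness over single-gene knockouts (one gene removed at
    a time), the robustness measure tracked along trajectories."""
    sc = as_scenario(scenario)
    ev = _Evaluator(network, sc, params, warm=warm)
    f0 = ev.parent_fitness
    if f0 <= 0.0:
        raise ValueError("wild type has zero fitness; knockout ratio undefined")
    reps, mult = _representative_genes(network)
    num = 0.0
    den = 0
    for gtype, gi in sorted(reps, key=lambda k: (k[0], k[1])):
        ko = _apply_mutation(network, Mutation("deletion", gtype, gi), params)
        r = ev.eval_network(ko) / f0
        num += r * mult[(gtype, gi)]
        den += mult[(gtype, gi)]
    return num / den if den else float("nan")


def evolve(start: Network, scenario: "Scenario | str", params: ModelParams,
           max_generations: int = 2000, *, track_robustness: bool = False,
           log=None) -> tuple[Network, Trajectory]:
    """Run the greedy walk to a local optimum (or `max_generations`).

    Returns the final network and the trajectory.  ``trajectory.terminated``
    is False when the generation cap was hit; such runs are excluded from
    ensemble aggregates by the batch runner.
    """
    sc = as_scenario(scenario)
    network = start.copy()
    ev = _Evaluator(network, sc, params)
    traj = Trajectory(start_fitness=ev.parent_fitness)
    if track_robustness:
        traj.start_mean_knockout_fitness = mean_single_knockout_fitness(
            network, sc, params, warm=ev.parent_states)

    for gen in range(1, max_generations + 1):
        new_net, mut = greedy_step(network, sc, params, _evaluator=ev)
        if mut is None:
            traj.terminated = True
            break
        network = new_net
        ev = _Evaluator(network, sc, params, warm=ev.parent_states)
        rec = GenerationRecord(
            generation=gen,
            mutation=mut,
            fitness=ev.parent_fitness,
            n_enzymes=len(network.enzymes),
            n_transporters=len(network.transporters),
            n_unique_enzymes=len({(e.group, active_support(e, params))
                                  for e in network.enzymes}),
            n_unique_transporters=len({active_support(t, params)
                                       for t in network.transporters}),
        )
        if track_robustness:
            rec.mean_knockout_fitness = mean_single_knockout_fitness(
                network, sc, params, warm=ev.parent_states)
        traj.records.append(rec)
        if log is not None:
            log(f"gen={gen} {mut} fitness={rec.fitness:.6e} "
                f"nE={rec.n_enzymes} nT={rec.n_transporters}")
    return network, traj


def continue_evolution(v_network: Network, stable_scenario: "Scenario | str",
                       params: ModelParams, max_generations: int = 2000,
                       **kwargs) -> tuple[Network, Trajectory]:
    """Evolve a fluctuating-environment product further under a stable medium
    (the V -> VM1/VM2/VR arm of the study design)."""
    return evolve(v_network, stable_scenario, params, max_generations, **kwargs)
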