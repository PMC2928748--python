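"""Knockout robustness, enzyme classification, independent fluxes, ensembles.

Evolved networks hold dosage as identical gene copies, so the unit of
analysis is the gene *type*: all genes with the same group and the same
active-reaction support.  Robustness is measured by removing a whole
type at once (single-copy knockouts of an isoenzyme pair are trivially
buffered) and reporting the mutant/wild-type ratio of the steady-state
growth rate (the biomass-rate ratio is reported alongside).

The independent-flux count of a network is the dimension of the null
space of its stoichiometric matrix, whose columns are the coupled net
group transfers of each enzyme type, the exchange reactions of each
transporter type, and the biomass reaction.

`batch_run` drives the whole study design over an ensemble of seeds:
evolution under the stable media M1/M2/R and the fluctuating scenario V,
continued evolution of the V products under each stable medium, and the
ten knockout-fitness distributions (Rob-M1 ... Rob-RfromV).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evolution import Trajectory, continue_evolution, evolve
from .kinetics import steady_state
from .model_core import (
    Medium,
    ModelParams,
    Network,
    acceptors_of_group,
    active_support,
    as_scenario,
    donors_of_group,
    equilibrium_constants,
    initial_network,
    sample_world,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EnzymeType",
    "enzyme_types",
    "knockout_network",
    "knockout_fitness",
    "knockout_profile",
    "is_multifunctional",
    "classify_multifunctional_role",
    "half_reaction_fluxes",
    "stoichiometric_matrix",
    "independent_flux_count",
    "nullity",
    "BatchResult",
    "batch_run",
    "RUN_LABELS",
    "ROBUSTNESS_LABELS",
]

RUN_LABELS = ("M1", "M2", "R", "V", "M1fromV", "M2fromV", "RfromV")
ROBUSTNESS_LABELS = (
    "Rob-M1", "Rob-M2", "Rob-R",
    "Rob-V-M1", "Rob-V-M2", "Rob-V-R", "Rob-V-V",
    "Rob-M1fromV", "Rob-M2fromV", "Rob-RfromV",
)


@dataclass(frozen=True)
class EnzymeType:
    """All genes sharing one catalytic function (identical active support)."""

    members: tuple[int, ...]
    support: frozenset[int]
    is_transporter: bool
    group: int | None = None

    @property
    def n_members(self) -> int:
        return len(self.members)


def enzyme_types(network: Network, params: ModelParams) -> list[EnzymeType]:
    """Partition genes into types by identical active-reaction support.

    Enzymes and transporters are partitioned separately; enzyme types are
    additionally keyed by their transferred group.  Ordering is deterministic
    (first member index, enzymes before transporters).
    """
    out: list[EnzymeType] = []
    groups: dict[tuple, list[int]] = {}
    for i, e in enumerate(network.enzymes):
        key = (e.group, active_support(e, params))
        groups.setdefault(key, []).append(i)
    for (g, supp), members in sorted(groups.items(), key=lambda kv: kv[1][0]):
        out.append(EnzymeType(tuple(members), supp, False, g))
    tgroups: dict[frozenset, list[int]] = {}
    for i, t in enumerate(network.transporters):
        tgroups.setdefault(active_support(t, params), []).append(i)
    for supp, members in sorted(tgroups.items(), key=lambda kv: kv[1][0]):
        out.append(EnzymeType(tuple(members), supp, True))
    return out


def is_multifunctional(etype: EnzymeType, params: ModelParams) -> bool:
    """An enzyme is multifunctional when it maintains more than two active
    half-reactions, i.e. more than one coupled group transfer."""
    if etype.is_transporter:
        raise ValueError("multifunctionality is defined for enzymes only")
    return len(etype.support) > 2


def knockout_network(network: Network, etype: EnzymeType) -> Network:
    """Network with every member gene of the type removed."""
    net = network.copy()
    drop = set(etype.members)
    if etype.is_transporter:
        net.transporters = [t for i, t in enumerate(net.transporters) if i not in drop]
    else:
        net.enzymes = [e for i, e in enumerate(net.enzymes) if i not in drop]
    return net


def _fitness_and_vbm(network: Network, media: list[Medium],
                     params: ModelParams,
                     warm: dict[str, np.ndarray] | None = None,
                     collect: dict[str, np.ndarray] | None = None
                     ) -> tuple[float, float]:
    """(geometric-mean growth rate, geometric-mean biomass rate) over media;
    zeros propagate, non-convergence counts as zero.  `warm` provides
    per-medium starting states (e.g. the wild type's, when scoring a
    knockout); `collect` receives the solved states."""
    lw = lv = 0.0
    for med in media:
        x0 = warm.get(med.label) if warm else None
        r = steady_state(network, med, params, x0=x0)
        if collect is not None and r.converged:
            collect[med.label] = r.state.X
        w = r.W if r.converged else 0.0
        v = r.v_BM if r.converged else 0.0
        if w <= 0.0 or v <= 0.0:
            return 0.0, 0.0
        lw += np.log(w)
        lv += np.log(v)
    n = len(media)
    return float(np.exp(lw / n)), float(np.exp(lv / n))


def _media_of(network: Network, measure) -> list[Medium]:
    if isinstance(measure, Medium):
        return [measure]
    if isinstance(measure, str) and measure in network.world.media:
        return [network.world.media[measure]]
    sc = as_scenario(measure)
    return [network.world.media[lbl] for lbl in sc.media]


def knockout_fitness(network: Network, etype: EnzymeType, measure,
                     params: ModelParams) -> float:
    """Relative fitness w_ko / w_wt of deleting a whole gene type.

    `measure` is a medium label, a Medium, or a scenario (geometric mean over
    its media).  Raises if the wild type is dead on the reference measure.
    """
    media = _media_of(network, measure)
    wt_states: dict[str, np.ndarray] = {}
    w_wt, _ = _fitness_and_vbm(network, media, params, collect=wt_states)
    if w_wt <= 0.0:
        raise ValueError("wild-type fitness is zero on the reference medium")
    w_ko, _ = _fitness_and_vbm(knockout_network(network, etype), media, params,
                               warm=wt_states)
    return w_ko / w_wt


def knockout_profile(network: Network, measure, params: ModelParams) -> pd.DataFrame:
    """Per-type knockout table: relative growth rate and biomass rate."""
    media = _media_of(network, measure)
    wt_states: dict[str, np.ndarray] = {}
    w_wt, v_wt = _fitness_and_vbm(network, media, params, collect=wt_states)
    if w_wt <= 0.0:
        raise ValueError("wild-type fitness is zero on the reference medium")
    rows = []
    for etype in enzyme_types(network, params):
        w_ko, v_ko = _fitness_and_vbm(knockout_network(network, etype), media,
                                      params, warm=wt_states)
        rows.append({
            "kind": "transporter" if etype.is_transporter else "enzyme",
            "group": etype.group,
            "support": ",".join(str(s) for s in sorted(etype.support)),
            "support_size": len(etype.support),
            "n_members": etype.n_members,
            "multifunctional": (not etype.is_transporter
                                and is_multifunctional(etype, params)),
            "rel_W": w_ko / w_wt,
            "rel_vBM": v_ko / v_wt if v_wt > 0 else np.nan,
        })
    return pd.DataFrame(rows)


def half_reaction_fluxes(network: Network, medium, params: ModelParams
                         ) -> np.ndarray:
    """Steady-state net flux of every half-reaction, per gene (nE x slots);
    positive = group flows from the donor onto the enzyme."""
    if isinstance(medium, str):
        medium = network.world.media[medium]
    res = steady_state(network, medium, params)
    X, E1 = res.state.X, res.state.E1
    world = network.world
    out = np.zeros((len(network.enzymes), params.n_enzyme_slots))
    for i, enz in enumerate(network.enzymes):
        k = enz.rates + params.k_bg
        d = donors_of_group(enz.group, world.n_groups)
        a = acceptors_of_group(enz.group, world.n_groups)
        q = equilibrium_constants(world, enz)
        e0 = enz.dosage - E1[i]
        out[i] = k * (e0 * X[d] - E1[i] * X[a] / q)
    return out


def classify_multifunctional_role(network: Network, etype: EnzymeType,
                                  params: ModelParams, medium: str = "R"
                                  ) -> str:
    """Why is a multifunctional enzyme dispensable?

    "isoenzyme": some of its active reactions are also covered by another
    type of the same group.  Otherwise "nonessential_extra" if it maintains
    an active reaction that is not directly involved in biomass production
    (zero steady-state flux, or removing the reaction does not reduce the
    biomass rate).  "essential" if neither applies.
    """
    if etype.is_transporter or not is_multifunctional(etype, params):
        raise ValueError("role classification applies to multifunctional enzymes")
    for other in enzyme_types(network, params):
        if other.is_transporter or other.members == etype.members:
            continue
        if other.group == etype.group and other.support & etype.support:
            return "isoenzyme"
    med = network.world.media[medium] if isinstance(medium, str) else medium
    flux = half_reaction_fluxes(network, med, params)
    type_flux = flux[list(etype.members)].sum(axis=0)
    scale = np.max(np.abs(type_flux)) if type_flux.size else 0.0
    base = steady_state(network, med, params)
    for slot in sorted(etype.support):
        if abs(type_flux[slot]) <= 1e-9 * max(scale, 1e-30):
            return "nonessential_extra"
        pruned = network.copy()
        for gi in etype.members:
            pruned.enzymes[gi].roots[slot] = 0.0
        r = steady_state(pruned, med, params)
        v = r.v_BM if r.converged else 0.0
        if v >= base.v_BM * (1.0 - 1e-6):
            return "nonessential_extra"
    return "essential"


def stoichiometric_matrix(network: Network, params: ModelParams,
                          return_labels: bool = False):
    """Stoichiometric matrix over the internal metabolites.

    One column per coupled net transfer (each unordered pair of active slots
    of an enzyme type: donor1 + acceptor2 -> acceptor1 + donor2), one exchange
    column per active slot of each transporter type (+ efflux convention,
    a single -1 entry), and one biomass column (-1 per biomass metabolite).
    Identical gene copies share their type's columns, so dosage does not
    inflate the flux count.
    """
    world = network.world
    M = world.n_metabolites
    cols: list[np.ndarray] = []
    labels: list[str] = []
    for etype in enzyme_types(network, params):
        if etype.is_transporter:
            for j in sorted(etype.support):
                c = np.zeros(M)
                c[j] = -1.0
                cols.append(c)
                labels.append(f"T{etype.members[0]}:exch:{j}")
            continue
        d = donors_of_group(etype.group, world.n_groups)
        a = acceptors_of_group(etype.group, world.n_groups)
        for j1, j2 in itertools.combinations(sorted(etype.support), 2):
            c = np.zeros(M)
            c[d[j1]] -= 1.0
            c[a[j1]] += 1.0
            c[a[j2]] -= 1.0
            c[d[j2]] += 1.0
            cols.append(c)
            labels.append(f"E{etype.members[0]}:g{etype.group}:{j1}-{j2}")
    if cols:  # a network with no active reactions has no flux system at all
        c = np.zeros(M)
        for b in world.biomass_set:
            c[b] -= 1.0
        cols.append(c)
        labels.append("biomass")
    S = np.column_stack(cols) if cols else np.zeros((M, 0))
    return (S, labels) if return_labels else S


def nullity(matrix: np.ndarray, rtol: float = 1e-8) -> int:
    """Null-space dimension by rank-nullity; singular values below
    rtol * max(sv) count as zero."""
    if matrix.size == 0:
        return matrix.shape[1] if matrix.ndim == 2 else 0
    sv = np.linalg.svd(matrix, compute_uv=False)
    rank = int(np.sum(sv > rtol * sv[0])) if sv.size and sv[0] > 0 else 0
    return matrix.shape[1] - rank


def independent_flux_count(network: Network, params: ModelParams) -> int:
    """Number of independent steady-state fluxes: dim ker of the
    stoichiometric matrix."""
    return nullity(stoichiometric_matrix(network, params))


# ---------------------------------------------------------------------------
# ensemble runner

@dataclass
class BatchResult:
    """Tables and evolved networks from an ensemble of simulations."""

    networks: pd.DataFrame
    robustness: pd.DataFrame
    evolved: dict[tuple[str, int], Network] = field(default_factory=dict)
    trajectories: dict[tuple[str, int], Trajectory] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Ensemble aggregates per evolutionary scenario, one column per run
        label (the layout of a properties-and-robustness overview table).

        Fluctuating-environment (V) robustness entries are those measured in
        the rich medium; stable-evolved networks are measured where they
        evolved.
        """
        rows = {}
        net = self.networks[self.networks["terminated"]]
        rob = self.robustness
        for lbl in RUN_LABELS:
            sub = net[net["run_label"] == lbl]
            if sub.empty:
                continue
            dist = "Rob-V-R" if lbl == "V" else f"Rob-{lbl}"
            rsub = rob[(rob["dist_label"] == dist) & (rob["kind"] == "enzyme")]
            multi = rsub[rsub["multifunctional"]]
            mono = rsub[~rsub["multifunctional"]]
            pernet = rsub.groupby("seed").agg(
                mean_rob=("rel_W", "mean"),
                has_multi=("multifunctional", "any"))
            col = {
                "n_networks": len(sub),
                "independent_fluxes_mean": sub["independent_fluxes"].mean(),
                "enzymes_per_network": sub["n_enzyme_types"].mean(),
                "multifunctional_per_network": sub["n_multifunctional"].mean(),
                "pct_networks_with_multifunctional":
                    100.0 * (sub["n_multifunctional"] > 0).mean(),
                "pct_enzymes_multifunctional":
                    100.0 * sub["n_multifunctional"].sum()
                    / max(sub["n_enzyme_types"].sum(), 1),
                "robustness_multifunctional_mean":
                    multi["rel_W"].mean() if len(multi) else np.nan,
                "robustness_monofunctional_mean":
                    mono["rel_W"].mean() if len(mono) else np.nan,
                "robustness_networks_with_multifunctional":
                    pernet[pernet["has_multi"]]["mean_rob"].mean()
                    if pernet["has_multi"].any() else np.nan,
                "robustness_networks_without_multifunctional":
                    pernet[~pernet["has_multi"]]["mean_rob"].mean()
                    if (~pernet["has_multi"]).any() else np.nan,
            }
            rows[lbl] = col
        return pd.DataFrame(rows)

    def ks_matrix(self, value: str = "rel_W") -> tuple[pd.DataFrame, pd.DataFrame]:
        """Pairwise two-sample KS tests between the knockout-fitness
        distributions; returns (statistics, p-values) as symmetric frames."""
        from scipy.stats import ks_2samp

        labels = [l for l in ROBUSTNESS_LABELS
                  if (self.robustness["dist_label"] == l).any()]
        D = pd.DataFrame(0.0, index=labels, columns=labels)
        P = pd.DataFrame(1.0, index=labels, columns=labels)
        samples = {l: self.robustness.loc[self.robustness["dist_label"] == l,
                                          value].to_numpy()
                   for l in labels}
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                r = ks_2samp(samples[a], samples[b])
                D.loc[a, b] = D.loc[b, a] = r.statistic
                P.loc[a, b] = P.loc[b, a] = r.pvalue
        return D, P


def _network_row(network: Network, params: ModelParams, run_label: str,
                 seed: int, fit: float, terminated: bool) -> dict:
    types = enzyme_types(network, params)
    etypes = [t for t in types if not t.is_transporter]
    n_multi = sum(is_multifunctional(t, params) for t in etypes)
    S = stoichiometric_matrix(network, params)
    return {
        "run_label": run_label,
        "seed": seed,
        "terminated": terminated,
        "fitness": fit,
        "n_enzyme_genes": len(network.enzymes),
        "n_transporter_genes": len(network.transporters),
        "n_enzyme_types": len(etypes),
        "n_transporter_types": len(types) - len(etypes),
        "n_multifunctional": n_multi,
        "active_reactions": S.shape[1],
        "independent_fluxes": nullity(S),
    }


def _robustness_rows(network: Network, measure, dist_label: str, run_label: str,
                     seed: int, params: ModelParams) -> list[dict]:
    prof = knockout_profile(network, measure, params)
    prof.insert(0, "dist_label", dist_label)
    prof.insert(1, "run_label", run_label)
    prof.insert(2, "seed", seed)
    return prof.to_dict("records")


def batch_run(scenarios=("M1", "M2", "R", "V"), n_replicates: int = 20,
              seed0: int = 0, params: ModelParams | None = None, *,
              include_continued: bool = True, max_generations: int = 2000,
              progress: bool = False) -> BatchResult:
    """Run the full study design over seeds seed0 .. seed0+n_replicates-1.

    Per seed: sample a world, evolve the unspecific ancestor under each
    requested scenario, continue the V product under each stable medium
    (when V is included), and measure type-level knockout robustness for
    every distribution label.  Runs that hit the generation cap are logged
    and excluded from aggregate tables.
    """
    params = params or ModelParams()
    net_rows: list[dict] = []
    rob_rows: list[dict] = []
    result = BatchResult(pd.DataFrame(), pd.DataFrame())
    stable = [s for s in scenarios if s in ("M1", "M2", "R")]

    for i in range(n_replicates):
        seed = seed0 + i
        world = sample_world(seed, params)
        start = initial_network(world, params)
        if progress:
            print(f"[batch] seed {seed}")

        def _record(net, traj, run_label, measures):
            fit = traj.fitnesses[-1] if traj.records else traj.start_fitness
            net_rows.append(_network_row(net, params, run_label, seed, fit,
                                         traj.terminated))
            result.evolved[(run_label, seed)] = net
            result.trajectories[(run_label, seed)] = traj
            if not traj.terminated:
                logger.warning("run %s seed %d hit the generation cap; "
                               "excluded from aggregates", run_label, seed)
                return
            for dist_label, measure in measures:
                rob_rows.extend(_robustness_rows(net, measure, dist_label,
                                                 run_label, seed, params))

        for sc in stable:
            net, traj = evolve(start, sc, params, max_generations)
            _record(net, traj, sc, [(f"Rob-{sc}", sc)])

        if "V" in scenarios:
            netV, trajV = evolve(start, "V", params, max_generations)
            _record(netV, trajV, "V",
                    [("Rob-V-M1", "M1"), ("Rob-V-M2", "M2"),
                     ("Rob-V-R", "R"), ("Rob-V-V", "V")])
            if include_continued and trajV.terminated:
                for sc in ("M1", "M2", "R"):
                    netC, trajC = continue_evolution(netV, sc, params,
                                                     max_generations)
                    _record(netC, trajC, f"{sc}fromV",
                            [(f"Rob-{sc}fromV", sc)])

    result.networks = pd.DataFrame(net_rows)
    result.robustness = pd.DataFrame(rob_rows)
    return result
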