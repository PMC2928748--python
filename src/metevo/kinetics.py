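"""Rate laws, the cell ODE, steady states, growth rate, and fitness.

The intracellular state is the vector of metabolite concentrations X
(one per species) plus the concentration of the group-bound form E1 of
every enzyme gene.  Enzymes obey ping-pong half-reaction kinetics
``v = k_ij (E0 X_d - E1 X_a / q_ij)``; transporters are passive,
``v = T t_ij (X_j - X_ext_j)`` (positive = efflux); biomass forms at
``v_BM = k_BM * prod(X_b)`` over the biomass metabolites, consuming one
unit of each, and every metabolite is diluted at the growth rate
``W = v_BM / (C0 + C_E E + C_T T)``.

Fitness on one medium is the steady-state growth rate; in a fluctuating
environment it is the geometric mean of the growth rates over the media.

Two routes to the steady state are provided: the fast default
(Newton on the reduced metabolite system, bound-enzyme states eliminated
by their steady-state closed form; pseudo-transient fallback) and an
independent full-ODE integration route (``method="integrate"``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .model_core import (
    Medium,
    ModelParams,
    Network,
    Scenario,
    acceptors_of_group,
    as_scenario,
    donors_of_group,
    equilibrium_constants,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CellState",
    "SteadyStateResult",
    "half_reaction_rate",
    "transport_rate",
    "biomass_rate",
    "growth_rate",
    "ode_rhs",
    "steady_state",
    "fitness",
]


@dataclass
class CellState:
    """Intracellular concentrations: metabolites X and bound enzyme states E1."""

    X: np.ndarray
    E1: np.ndarray

    def copy(self) -> "CellState":
        return CellState(self.X.copy(), self.E1.copy())


@dataclass
class SteadyStateResult:
    state: CellState
    v_BM: float
    W: float
    converged: bool
    residual_norm: float


# ---------------------------------------------------------------------------
# reference rate laws (plain numpy; these are the readable single-reaction
# forms and the integrands of the independent full-ODE route)

def half_reaction_rate(network: Network, enzyme_index: int, reaction_index: int,
                       state: CellState, params: ModelParams) -> float:
    """Signed rate of one half-reaction; positive = group flows onto the enzyme."""
    enz = network.enzymes[enzyme_index]
    k = enz.rates[reaction_index] + params.k_bg
    if k == 0.0:
        return 0.0
    d = int(donors_of_group(enz.group, network.world.n_groups)[reaction_index])
    a = int(acceptors_of_group(enz.group, network.world.n_groups)[reaction_index])
    q = float(equilibrium_constants(network.world, enz)[reaction_index])
    e1 = float(state.E1[enzyme_index])
    e0 = enz.dosage - e1
    return float(k * (e0 * state.X[d] - e1 * state.X[a] / q))


def transport_rate(network: Network, transporter_index: int, metabolite_id: int,
                   state: CellState, medium: Medium) -> float:
    """Signed transport rate; positive = efflux out of the cell."""
    tr = network.transporters[transporter_index]
    t = tr.rates[metabolite_id]
    return float(tr.dosage * t * (state.X[metabolite_id] - medium.external[metabolite_id]))


def biomass_rate(state: CellState, world, params: ModelParams) -> float:
    """v_BM = k_BM * product of the biomass metabolite concentrations."""
    return float(params.k_BM * np.prod(state.X[list(world.biomass_set)]))


def growth_rate(v_BM: float, network: Network, params: ModelParams) -> float:
    """W = v_BM / (C0 + C_E * total enzyme dose + C_T * total transporter dose)."""
    denom = (params.C0
             + params.C_E * network.total_enzyme_dosage
             + params.C_T * network.total_transporter_dosage)
    return float(v_BM / denom)


def ode_rhs(network: Network, medium: Medium, state: CellState,
            params: ModelParams) -> CellState:
    """Time derivatives of the full cell state (metabolites and bound enzymes).

    The enzymatic terms conserve each biochemical group across metabolites
    plus bound enzyme states; biomass drain, transport, and growth dilution
    exchange material with the outside.
    """
    X = np.asarray(state.X, dtype=np.float64)
    E1 = np.asarray(state.E1, dtype=np.float64)
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(E1)):
        raise ValueError("non-finite cell state")
    if np.any(X < 0):
        raise ValueError("negative metabolite concentration")

    world = network.world
    dX = np.zeros_like(X)
    dE1 = np.zeros_like(E1)

    vbm = biomass_rate(state, world, params)
    W = growth_rate(vbm, network, params)

    for i, enz in enumerate(network.enzymes):
        k = enz.rates + params.k_bg
        act = k > 0
        if not np.any(act):
            continue
        d = donors_of_group(enz.group, world.n_groups)
        a = acceptors_of_group(enz.group, world.n_groups)
        q = equilibrium_constants(world, enz)
        e0 = enz.dosage - E1[i]
        v = k * (e0 * X[d] - E1[i] * X[a] / q)
        dX[d] -= v
        dX[a] += v
        dE1[i] = v.sum()

    for tr in network.transporters:
        dX -= tr.dosage * tr.rates * (X - medium.external)

    dX[list(world.biomass_set)] -= vbm
    dX -= W * X
    return CellState(dX, dE1)


# ---------------------------------------------------------------------------
# packed representation for the compiled kernels

class Pack:
    """Flat array view of a (network, params) pair for the compiled kernels.

    Identical enzyme genes (same group, state free energy, and rate vector)
    are aggregated into one kinetic row with their dosages summed -- exact,
    because the fluxes of identical genes are linear in dosage at fixed
    concentrations.  `enz_class_of[i]` maps gene i to its row.
    """

    __slots__ = ("enz_d", "enz_a", "K", "Q", "Edos", "ttot", "bm", "kBM",
                 "denom", "n_met", "enz_class_of")

    def __init__(self, network: Network, params: ModelParams):
        world = network.world
        M = world.n_metabolites
        S = params.n_enzyme_slots
        self.n_met = M
        sigs: dict[tuple, int] = {}
        reps: list[int] = []
        dose: list[float] = []
        self.enz_class_of = np.zeros(len(network.enzymes), dtype=np.int64)
        for i, enz in enumerate(network.enzymes):
            sig = (enz.group, enz.state_dG, enz.roots.tobytes())
            cls = sigs.get(sig)
            if cls is None:
                cls = sigs[sig] = len(reps)
                reps.append(i)
                dose.append(enz.dosage)
            else:
                dose[cls] += enz.dosage
            self.enz_class_of[i] = cls
        nC = len(reps)
        self.enz_d = np.zeros((nC, S), dtype=np.int64)
        self.enz_a = np.zeros((nC, S), dtype=np.int64)
        self.K = np.zeros((nC, S))
        self.Q = np.ones((nC, S))
        self.Edos = np.asarray(dose)
        for cls, i in enumerate(reps):
            enz = network.enzymes[i]
            self.enz_d[cls] = donors_of_group(enz.group, world.n_groups)
            self.enz_a[cls] = acceptors_of_group(enz.group, world.n_groups)
            self.K[cls] = enz.rates + params.k_bg
            self.Q[cls] = equilibrium_constants(world, enz)
        self.ttot = np.zeros(M)
        for tr in network.transporters:
            self.ttot += tr.dosage * tr.rates
        self.bm = np.asarray(world.biomass_set, dtype=np.int64)
        self.kBM = params.k_BM
        self.denom = (params.C0
                      + params.C_E * network.total_enzyme_dosage
                      + params.C_T * network.total_transporter_dosage)

    def kernel_args(self, ext: np.ndarray, free: np.ndarray) -> tuple:
        return (self.enz_d, self.enz_a, self.K, self.Q, self.Edos, self.ttot,
                ext, self.bm, self.kBM, self.denom, free)

    def with_enzyme_mutation(self, gene_index: int, gene_dosage: float,
                             new_row: np.ndarray) -> "Pack":
        """Shallow clone whose kinetics reflect one gene's rate row replaced.

        If the gene shares its class with other copies, the class keeps the
        remaining dosage and the mutant becomes a new row of its own.
        """
        cls = int(self.enz_class_of[gene_index])
        view = object.__new__(Pack)
        for slot in Pack.__slots__:
            setattr(view, slot, getattr(self, slot))
        if self.Edos[cls] == gene_dosage:  # singleton class: swap the row
            K = self.K.copy()
            K[cls] = new_row
            view.K = K
            return view
        view.enz_d = np.vstack([self.enz_d, self.enz_d[cls:cls + 1]])
        view.enz_a = np.vstack([self.enz_a, self.enz_a[cls:cls + 1]])
        view.Q = np.vstack([self.Q, self.Q[cls:cls + 1]])
        view.K = np.vstack([self.K, new_row[None, :]])
        Edos = np.append(self.Edos, gene_dosage)
        Edos[cls] -= gene_dosage
        view.Edos = Edos
        return view

    def with_ttot(self, ttot: np.ndarray) -> "Pack":
        view = object.__new__(Pack)
        for slot in Pack.__slots__:
            setattr(view, slot, getattr(self, slot))
        view.ttot = ttot
        return view


def reachable_metabolites(pack: Pack, ext: np.ndarray) -> np.ndarray:
    """Boolean mask of metabolites that can hold nonzero concentration.

    Sources are importable nutrients.  A donor->acceptor edge needs only an
    active rate constant; the reverse edge additionally needs the enzyme to
    be loadable, i.e. some active slot with a reachable donor.
    """
    return _kernels.reachable(pack.enz_d, pack.enz_a, pack.K, pack.ttot, ext)


def _bound_states(network: Network, params: ModelParams, X: np.ndarray) -> np.ndarray:
    """Closed-form steady-state bound-enzyme concentrations given X."""
    world = network.world
    E1 = np.empty(len(network.enzymes))
    for i, enz in enumerate(network.enzymes):
        k = enz.rates + params.k_bg
        d = donors_of_group(enz.group, world.n_groups)
        a = acceptors_of_group(enz.group, world.n_groups)
        q = equilibrium_constants(world, enz)
        sd = float(np.sum(k * X[d]))
        sa = float(np.sum(k / q * X[a]))
        E1[i] = enz.dosage * sd / (sd + sa) if sd + sa > 0 else enz.dosage / 2.0
    return E1


def solve_steady_X(pack: Pack, ext: np.ndarray, free: np.ndarray,
                   x0: np.ndarray | None, tol: float) -> tuple[np.ndarray, bool, float]:
    """Fast path to the steady metabolite vector.

    With a warm start (x0 from a nearby solved network) Newton runs first and
    a pseudo-transient march rescues the rare stall.  Cold starts instead run
    the pseudo-transient march from the standard near-empty cell (X = 1e-3)
    before polishing with Newton: the march follows the ODE flow, which keeps
    multi-stable systems on the fixed point the cell would actually reach,
    where raw Newton could jump basins.
    """
    M = pack.n_met
    args = pack.kernel_args(ext, free)
    cold = x0 is None
    if cold:
        x0 = np.full(M, 1e-3)

    def _newton(xs):
        try:
            return _kernels.newton(xs, *args, tol, 80)
        except Exception:  # singular Jacobian
            return xs, False, np.inf

    def _march(xs, steps):
        try:
            return _kernels.ptc(xs, *args, tol, 1.0, steps)
        except Exception:
            return xs, False, np.inf

    if cold:
        Xp, okp, resp = _march(x0, 1500)
        X, ok, res = _newton(Xp)
        if not ok and (okp or resp < res):
            X, ok, res = Xp, okp, resp
    else:
        X, ok, res = _newton(x0)
    rounds = 0
    while not ok and rounds < 3:
        rounds += 1
        Xp, okp, resp = _march(X if np.all(np.isfinite(X)) else x0, 1500)
        X2, ok2, res2 = _newton(Xp)
        if ok2 or res2 < res:
            X, ok, res = X2, ok2, res2
        elif okp or resp < res:
            X, ok, res = Xp, okp, resp
        else:
            break
    return X, bool(ok), float(res)


def steady_state(network: Network, medium: "Medium | str", params: ModelParams,
                 *, x0: np.ndarray | None = None, method: str = "auto",
                 t_max: float = 1e6) -> SteadyStateResult:
    """Compute the steady state of a network on a medium.

    method "auto"/"newton": reduced-system Newton, with a pseudo-transient
    rescue march for cold or difficult starts; method "integrate": stiff
    integration of the full ODE (scipy BDF) with a Newton polish, kept as an
    independent route.  Non-convergence is reported honestly; callers treat
    the fitness of such networks as zero.
    """
    if isinstance(medium, str):
        medium = network.world.media[medium]
    pack = Pack(network, params)
    ext = medium.external
    free = reachable_metabolites(pack, ext)
    tol = params.ss_tol

    if method in ("auto", "newton"):
        X, ok, res = solve_steady_X(pack, ext, free, x0, tol)
    elif method == "integrate":
        X, ok, res = _integrate_to_steady(network, medium, params, pack, free, t_max,
                                          x0=x0)
    else:
        raise ValueError(f"unknown method {method!r}")

    E1 = _bound_states(network, params, X)
    state = CellState(X, E1)
    vbm = biomass_rate(state, network.world, params)
    W = growth_rate(vbm, network, params) if ok else 0.0
    if not ok:
        logger.warning("steady state did not converge (residual %.3g); fitness "
                       "treated as 0", res)
    return SteadyStateResult(state, vbm, W, bool(ok), float(res))


def _integrate_to_steady(network: Network, medium: Medium, params: ModelParams,
                         pack: Pack, free: np.ndarray, t_max: float,
                         x0: np.ndarray | None = None) -> tuple[np.ndarray, bool, float]:
    """Independent route: integrate the full (X, E1) ODE until quiescent, then
    polish with Newton on the reduced system."""
    from scipy.integrate import solve_ivp

    world = network.world
    M = world.n_metabolites
    nE = len(network.enzymes)
    X0 = np.full(M, 1e-3) if x0 is None else np.asarray(x0, dtype=float).copy()
    X0[~free] = 0.0
    E10 = np.array([e.dosage / 2.0 for e in network.enzymes])
    y = np.concatenate([X0, E10])

    def f(_t, yv):
        st = CellState(np.maximum(yv[:M], 0.0), yv[M:])
        d = ode_rhs(network, medium, st, params)
        return np.concatenate([d.X, d.E1])

    t0 = 0.0
    span = 10.0
    tol = params.ss_tol
    ok = False
    res = np.inf
    while t0 < t_max:
        sol = solve_ivp(f, (t0, t0 + span), y, method="BDF",
                        rtol=1e-9, atol=1e-12)
        if not sol.success:
            break
        y = sol.y[:, -1]
        y[:M] = np.maximum(y[:M], 0.0)
        y[:M][~free] = 0.0
        Fv, _w, _v = _kernels.rhs(np.ascontiguousarray(y[:M]),
                                  *pack.kernel_args(medium.external, free))
        res = float(np.max(np.abs(Fv[free]))) if free.any() else 0.0
        if res < max(tol, 1e-11):
            ok = True
            break
        t0 += span
        span *= 4.0
    X = np.ascontiguousarray(y[:M])
    try:
        Xn, okn, resn = _kernels.newton(X, *pack.kernel_args(medium.external, free),
                                        tol, 80)
        if okn or resn < res:
            X, ok, res = Xn, bool(okn) or ok, resn
    except Exception:
        pass
    return X, ok, float(res)


def fitness(network: Network, scenario: "Scenario | str | Medium",
            params: ModelParams) -> float:
    """Fitness of a network in a selective environment.

    One medium: the steady-state growth rate W.  Fluctuating: the geometric
    mean of W over the scenario's media (zero on any medium means zero
    overall).  Non-converged steady states contribute zero.
    """
    if isinstance(scenario, Medium):
        media = [scenario]
    else:
        sc = as_scenario(scenario)
        media = [network.world.media[lbl] for lbl in sc.media]
    ws = []
    for med in media:
        r = steady_state(network, med, params)
        w = r.W if r.converged else 0.0
        if w <= 0.0:
            return 0.0
        ws.append(w)
    return float(np.exp(np.mean(np.log(ws))))
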