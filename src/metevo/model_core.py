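"""Core objects of the group-transfer metabolic model.

Metabolites are built from a small set of abstract biochemical groups
(5 by default).  Each group is present or absent, so a metabolite is a
bit pattern and the universe holds ``2**n_groups`` species (32 by
default).  Enzymes transfer one specific group between metabolites via a
ping-pong mechanism; transporters passively exchange metabolites with
the environment.  Each enzyme or transporter distributes a fixed
catalytic budget over its possible reactions: the roots ``k_ij**(1/alpha)``
sum to one, so specializing on few reactions buys disproportionately
higher rate constants (a specificity-activity trade-off).

A :class:`World` collects the random draws that define one evolutionary
universe: metabolite free energies, the two complementary nutrient pairs
that form the minimal media M1 and M2 (the rich medium R is their
union), and the four biomass metabolites.  A :class:`Network` is the
evolving individual: a list of enzyme genes and transporter genes over a
shared world.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "Metabolite",
    "Medium",
    "World",
    "Enzyme",
    "Transporter",
    "Network",
    "ModelParams",
    "Scenario",
    "SCENARIOS",
    "as_scenario",
    "complement",
    "group_bits",
    "donors_of_group",
    "acceptors_of_group",
    "sample_world",
    "initial_network",
    "tradeoff_residual",
    "equilibrium_constant",
    "equilibrium_constants",
    "active_support",
]


def complement(metabolite_id: int, n_groups: int = 5) -> int:
    """Return the metabolite with every group bit flipped.

    The pair ``{id, complement(id)}`` contains a donor and an acceptor of
    every group, which is exactly what a minimal medium must provide.
    """
    mask = (1 << n_groups) - 1
    if not 0 <= metabolite_id <= mask:
        raise ValueError(f"metabolite id {metabolite_id} outside 0..{mask}")
    return metabolite_id ^ mask


def group_bits(metabolite_id: int, n_groups: int = 5) -> tuple[int, ...]:
    """Presence (1) or absence (0) of each group, lowest group first."""
    return tuple((metabolite_id >> g) & 1 for g in range(n_groups))


@functools.lru_cache(maxsize=None)
def _donor_acceptor_idx(n_groups: int, group: int) -> tuple[np.ndarray, np.ndarray]:
    n_met = 1 << n_groups
    donors = np.array([m for m in range(n_met) if (m >> group) & 1], dtype=np.int64)
    acceptors = donors ^ (1 << group)
    donors.setflags(write=False)
    acceptors.setflags(write=False)
    return donors, acceptors


def donors_of_group(group: int, n_groups: int = 5) -> np.ndarray:
    """Ids of all metabolites that carry `group` (possible donors), ascending."""
    return _donor_acceptor_idx(n_groups, group)[0]


def acceptors_of_group(group: int, n_groups: int = 5) -> np.ndarray:
    """Acceptor ids aligned slot-by-slot with :func:`donors_of_group`."""
    return _donor_acceptor_idx(n_groups, group)[1]


@dataclass(frozen=True)
class Metabolite:
    """One species of the universe; `id` equals the value of its bit pattern."""

    id: int
    groups: tuple[int, ...]
    free_energy: float

    def __post_init__(self) -> None:
        if self.id != sum(b << g for g, b in enumerate(self.groups)):
            raise ValueError("metabolite id inconsistent with group bits")
        if not 0.0 <= self.free_energy <= 1.0:
            raise ValueError("free energy outside [0, 1]")


@dataclass
class Medium:
    """External metabolite concentrations; nonzero only for nutrients."""

    label: str
    external: np.ndarray

    @property
    def nutrients(self) -> tuple[int, ...]:
        return tuple(int(i) for i in np.nonzero(self.external > 0)[0])

    @property
    def external_conc(self) -> dict[int, float]:
        return {j: float(c) for j, c in enumerate(self.external) if c > 0}


@dataclass
class World:
    """All per-simulation random choices: energies, media, biomass targets."""

    seed: int
    n_groups: int
    free_energies: np.ndarray
    biomass_set: tuple[int, ...]
    media: dict[str, Medium]

    def __post_init__(self) -> None:
        n_met = 1 << self.n_groups
        if self.free_energies.shape != (n_met,):
            raise ValueError("free energy vector has wrong length")
        if len(set(self.biomass_set)) != len(self.biomass_set):
            raise ValueError("biomass metabolites must be distinct")

    @property
    def n_metabolites(self) -> int:
        return 1 << self.n_groups

    @property
    def metabolites(self) -> list[Metabolite]:
        return [
            Metabolite(m, group_bits(m, self.n_groups), float(self.free_energies[m]))
            for m in range(self.n_metabolites)
        ]


@dataclass(frozen=True)
class ModelParams:
    """Model constants.

    alpha         trade-off exponent; the roots k**(1/alpha) of each gene sum to 1
    m             mutation step applied on the root scale
    k_BM          biomass condensation rate constant
    C0, C_E, C_T  biomass cost of structure, per enzyme dose, per transporter dose
    nutrient_conc external concentration assigned to each nutrient
    eps_active    rate constants above this count as an active reaction
    delta_fit     minimal relative fitness gain that counts as beneficial
    k_bg          background rate floor added to every enzyme reaction
                  (0 in the main model)
    dup_frequent  if True, duplications/deletions compete with kinetic
                  mutations in a single candidate pool
    """

    alpha: float = 2.0
    m: float = 0.05
    k_BM: float = 1.0
    C0: float = 10.0
    C_E: float = 1.0
    C_T: float = 1.0
    nutrient_conc: float = 1.0
    eps_active: float = 1e-6
    delta_fit: float = 1e-9
    k_bg: float = 0.0
    dup_frequent: bool = False
    n_groups: int = 5
    n_biomass: int = 4
    ss_tol: float = 1e-9

    def __post_init__(self) -> None:
        if not self.alpha > 1:
            raise ValueError("alpha must be > 1")
        if not self.m > 0:
            raise ValueError("mutation step m must be > 0")
        if min(self.C0, self.C_E, self.C_T) <= 0:
            raise ValueError("biomass costs must be > 0")
        if self.n_groups < 2:
            raise ValueError("need at least 2 groups")
        if self.n_biomass < 1 or self.n_biomass > (1 << self.n_groups):
            raise ValueError("invalid biomass set size")

    @property
    def n_metabolites(self) -> int:
        return 1 << self.n_groups

    @property
    def n_enzyme_slots(self) -> int:
        return 1 << (self.n_groups - 1)


@dataclass
class Enzyme:
    """A group-transfer enzyme gene.

    `roots` holds k_ij**(1/alpha) for the 2**(n_groups-1) possible donors of
    the enzyme's group; the trade-off constraint is sum(roots) == 1.
    `state_dG` is the free-energy difference between the group-bound and
    unbound enzyme states.
    """

    group: int
    state_dG: float
    roots: np.ndarray
    alpha: float
    dosage: float = 1.0

    def __post_init__(self) -> None:
        self.roots = np.asarray(self.roots, dtype=np.float64)
        if np.any(self.roots < 0):
            raise ValueError("rate roots must be nonnegative")

    @property
    def rates(self) -> np.ndarray:
        """Rate constants k_ij = roots**alpha."""
        return self.roots**self.alpha

    def copy(self) -> "Enzyme":
        return Enzyme(self.group, self.state_dG, self.roots.copy(), self.alpha, self.dosage)


@dataclass
class Transporter:
    """A passive transporter gene; one rate-constant slot per metabolite."""

    roots: np.ndarray
    alpha: float
    dosage: float = 1.0

    def __post_init__(self) -> None:
        self.roots = np.asarray(self.roots, dtype=np.float64)
        if np.any(self.roots < 0):
            raise ValueError("rate roots must be nonnegative")

    @property
    def rates(self) -> np.ndarray:
        return self.roots**self.alpha

    def copy(self) -> "Transporter":
        return Transporter(self.roots.copy(), self.alpha, self.dosage)


@dataclass
class Network:
    """The evolving individual: enzyme and transporter genes over a world."""

    enzymes: list[Enzyme]
    transporters: list[Transporter]
    world: World

    def copy(self) -> "Network":
        return Network(
            [e.copy() for e in self.enzymes],
            [t.copy() for t in self.transporters],
            self.world,
        )

    @property
    def n_genes(self) -> int:
        return len(self.enzymes) + len(self.transporters)

    @property
    def total_enzyme_dosage(self) -> float:
        return float(sum(e.dosage for e in self.enzymes))

    @property
    def total_transporter_dosage(self) -> float:
        return float(sum(t.dosage for t in self.transporters))


@dataclass(frozen=True)
class Scenario:
    """A selective environment: one medium, or several with geometric-mean fitness."""

    label: str
    media: tuple[str, ...]

    @property
    def fluctuating(self) -> bool:
        return len(self.media) > 1


SCENARIOS: dict[str, Scenario] = {
    "M1": Scenario("M1", ("M1",)),
    "M2": Scenario("M2", ("M2",)),
    "R": Scenario("R", ("R",)),
    "V": Scenario("V", ("M1", "M2", "R")),
}


def as_scenario(scenario: "Scenario | str") -> Scenario:
    if isinstance(scenario, Scenario):
        return scenario
    try:
        return SCENARIOS[scenario]
    except KeyError:
        raise ValueError(
            f"unknown scenario {scenario!r}; expected one of {sorted(SCENARIOS)}"
        ) from None


def tradeoff_residual(rates: np.ndarray, alpha: float) -> float:
    """sum_j rates_j**(1/alpha) - 1; zero when the trade-off budget is exhausted."""
    rates = np.asarray(rates, dtype=np.float64)
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    return float(np.sum(rates ** (1.0 / alpha)) - 1.0)


def sample_world(seed: int, params: ModelParams | None = None) -> World:
    """Draw a world: free energies ~ U(0,1), two complementary nutrient pairs,
    a rich medium as their union, and `n_biomass` distinct biomass metabolites.

    A pure function of (seed, params): repeated calls are bitwise identical.
    """
    params = params or ModelParams()
    n_met = params.n_metabolites
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    energies = rng.uniform(0.0, 1.0, size=n_met)

    d1 = int(rng.integers(n_met))
    pair1 = frozenset((d1, complement(d1, params.n_groups)))
    while True:
        d2 = int(rng.integers(n_met))
        pair2 = frozenset((d2, complement(d2, params.n_groups)))
        if pair2 != pair1:
            break
    biomass = tuple(sorted(int(x) for x in rng.choice(n_met, size=params.n_biomass, replace=False)))

    def _medium(label: str, nutrients: Iterable[int]) -> Medium:
        ext = np.zeros(n_met)
        for j in nutrients:
            ext[j] = params.nutrient_conc
        return Medium(label, ext)

    media = {
        "M1": _medium("M1", pair1),
        "M2": _medium("M2", pair2),
        "R": _medium("R", pair1 | pair2),
    }
    return World(seed, params.n_groups, energies, biomass, media)


def initial_network(world: World, params: ModelParams | None = None) -> Network:
    """The unspecific ancestor: one enzyme per group with equal rate constants
    on every donor, and a single transporter carrying every metabolite, all at
    dosage one.  Enzyme state free-energy differences are drawn U(0,1),
    reproducibly from the world seed.
    """
    params = params or ModelParams()
    if params.n_groups != world.n_groups:
        raise ValueError("params.n_groups does not match world")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=world.seed, spawn_key=(1,)))
    dgs = rng.uniform(0.0, 1.0, size=world.n_groups)
    n_slots = params.n_enzyme_slots
    enzymes = [
        Enzyme(g, float(dgs[g]), np.full(n_slots, 1.0 / n_slots), params.alpha)
        for g in range(world.n_groups)
    ]
    transporters = [
        Transporter(np.full(world.n_metabolites, 1.0 / world.n_metabolites), params.alpha)
    ]
    return Network(enzymes, transporters, world)


def equilibrium_constant(donor: Metabolite, acceptor: Metabolite, enzyme: Enzyme) -> float:
    """Equilibrium constant of the half-reaction donor + E(0) <-> acceptor + E(1).

    q = exp(G_donor - G_acceptor - state_dG) with thermal energy scaled to 1;
    the bound enzyme state carries the extra free energy `state_dG`.
    """
    bit = 1 << enzyme.group
    if not donor.id & bit:
        raise ValueError("donor does not carry the enzyme's group")
    if acceptor.id != donor.id ^ bit:
        raise ValueError("acceptor is not the donor stripped of the enzyme's group")
    return float(np.exp(donor.free_energy - acceptor.free_energy - enzyme.state_dG))


def equilibrium_constants(world: World, enzyme: Enzyme) -> np.ndarray:
    """Vector of q_ij over the enzyme's donor slots (aligned with its roots)."""
    donors = donors_of_group(enzyme.group, world.n_groups)
    acceptors = acceptors_of_group(enzyme.group, world.n_groups)
    g = world.free_energies
    return np.exp(g[donors] - g[acceptors] - enzyme.state_dG)


def active_support(gene: "Enzyme | Transporter", params: ModelParams) -> frozenset[int]:
    """Reaction slots whose rate constant exceeds the activity threshold.

    The support is judged on the gene's own (trade-off constrained) rates;
    the background floor `k_bg` of the variant model does not count.
    """
    return frozenset(int(j) for j in np.nonzero(gene.rates > params.eps_active)[0])
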