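"""Deep-lake food-web topology fixtures and stochastic scenario generators.

The fixture ships the 24-guild pelagic food-web topology (names, size classes
as log2 body mass in pgC, diets, group/compartment memberships) and the
8-group link structure (25 trophic links including the cannibalistic
carnivorous-crustacean self-loop, plus 7 detrital release links into the PDOM
pool).

The generators emit mass-balanced carbon and phosphorus flow networks for the
7 seasonal phases and guild-level biomass trajectories with controllable
evenness, emulating the canonical seasonal succession of a temperate
deep-lake plankton community: a spring bloom with few strong basal flows,
a clear-water phase dominated by a keystone herbivorous crustacean, and an
even, interconnected late-succession flow pattern. Every generated network
closes each node's budget explicitly, so mass-balance residuals are at
machine precision, and all randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np

from .core import (
    PDOM,
    PHASES,
    BiomassSeries,
    FlowNetwork,
    FlowNetworkError,
    Guild,
    GuildTable,
)
from .diversity import DEFAULT_BETA_BY_GROUP, ExergyWeights
from .trophic import DEFAULT_PPMR_WEIGHTS

__all__ = [
    "LakeTopology",
    "ScenarioConfig",
    "Scenario",
    "lake_topology_fixture",
    "generate_balanced_network",
    "derive_p_network",
    "generate_seasonal_scenario",
    "generate_biomass_series",
]

GROUPS = ("Phy", "Bac", "HNF", "Cil", "Rot", "HerbCru", "CarnCru", "Fish")

GROUP_TO_COMPARTMENT = {
    "Phy": "Auto", "Bac": "Bac", "HNF": "Bactv", "Cil": "Herb", "Rot": "Herb",
    "HerbCru": "Herb", "CarnCru": "Carn", "Fish": "Carn", PDOM: PDOM,
}

# (id, name, group, compartment, dietary_group, size_class, diet, edibility, feeding_type)
# Size class is log2(average body mass in pgC). Diets list resource guild ids.
_GUILD_ROWS = (
    (1, "Alg1", "Phy", "Auto", "Auto", 6, (), "well-edible", "producer"),
    (2, "Alg2", "Phy", "Auto", "Auto", 8, (), "less-edible", "producer"),
    (3, "Alg3", "Phy", "Auto", "Auto", 5, (), "specialist-only", "producer"),
    (4, "Alg4", "Phy", "Auto", "Auto", 7, (), "less-edible", "producer"),
    (5, "Alg5", "Phy", "Auto", "Auto", 3, (), "well-edible", "producer"),
    (6, "APP", "Phy", "Auto", "Auto", -2, (), "less-edible", "producer"),
    (7, "Bac", "Bac", "Bac", "Auto", -6, (PDOM,), "n/a", "osmotroph"),
    (8, "HNF", "HNF", "Bactv", "Herb", 3, (6, 7), "n/a", "B"),
    (9, "Cil1", "Cil", "Bactv", "Herb", 8, (6, 7), "n/a", "B"),
    (10, "Cil2", "Cil", "Herb", "Herb", 11, (1, 5, 6, 7, 8), "n/a", "B/H"),
    (11, "Cil3", "Cil", "Herb", "Herb", 12, (1, 2, 5, 8), "n/a", "H"),
    (12, "Cil4", "Cil", "Herb", "Herb", 13, (1, 5, 8), "n/a", "H"),
    (13, "Cil5", "Cil", "Herb", "Herb", 16, (1, 2, 4, 5, 8, 9, 10, 11), "n/a", "O"),
    (14, "Rot1", "Rot", "Herb", "Herb", 14, (1, 5, 6, 7, 8), "n/a", "B/H"),
    (15, "Rot2", "Rot", "Herb", "Herb", 15, (1, 2, 3, 4, 5, 8, 9), "n/a", "H/O"),
    (16, "Rot3", "Rot", "Herb", "Herb", 16, (1, 2, 3, 4, 5, 8, 9), "n/a", "O"),
    (17, "Asp", "Rot", "Carn", "Carn", 16,
     (2, 3, 4, 8, 9, 10, 11, 12, 13, 14, 15, 16), "n/a", "C"),
    (18, "Dap", "HerbCru", "Herb", "Herb", 23, tuple(range(1, 17)), "n/a", "H/O"),
    (19, "Cyc", "CarnCru", "Carn", "Omni", 20,
     (1, 2, 3, 4, 5) + tuple(range(8, 20)), "n/a", "C/O"),
    (20, "Lep", "CarnCru", "Carn", "Carn", 26, (17, 18), "n/a", "C"),
    (21, "Fish1", "Fish", "Carn", "Carn", 40, (14, 15, 16, 17, 18, 19), "n/a", "C"),
    (22, "Fish2", "Fish", "Carn", "Carn", 42, (18, 19, 20), "n/a", "C"),
    (23, "Fish3", "Fish", "Carn", "Carn", 45, (18, 19, 20), "n/a", "C"),
    (24, "Fish4", "Fish", "Carn", "Carn", 46, (18, 19, 20, 21, 22), "n/a", "C"),
)

# 8-group diets (resource group -> consumer group), the basis of the
# mass-balanced flow networks. Self-loops at Cil, Rot and CarnCru arise from
# intraguild predation and cannibalism at the guild level.
_GROUP_DIETS = {
    "Bac": (PDOM,),
    "HNF": ("Phy", "Bac"),
    "Cil": ("Phy", "Bac", "HNF", "Cil"),
    "Rot": ("Phy", "Bac", "HNF", "Cil", "Rot"),
    "HerbCru": ("Phy", "Bac", "HNF", "Cil", "Rot"),
    "CarnCru": ("Phy", "Cil", "Rot", "HerbCru", "CarnCru"),
    "Fish": ("Rot", "HerbCru", "CarnCru"),
}


@dataclass(frozen=True)
class LakeTopology:
    """The fixed food-web topology at its three biotic aggregation levels."""

    guilds: GuildTable
    groups: tuple
    trophic_links: tuple        # (resource group, consumer group), 25 links
    detrital_links: tuple       # (group, PDOM), 7 links
    group_of_node: dict         # guild-id-string / PDOM -> group label
    compartment_of_group: dict  # 8 groups + PDOM -> 5 compartments + PDOM
    exergy_weights: ExergyWeights
    ppmr_weights: tuple

    @property
    def nodes8(self) -> tuple:
        return self.groups + (PDOM,)

    def guild_feeding_link_count(self) -> int:
        """Number of guild-level feeding links implied by the diets
        (including the PDOM uptake link of the bacteria)."""
        return len(self.guilds.feeding_links(include_pdom=True))


@lru_cache(maxsize=1)
def lake_topology_fixture() -> LakeTopology:
    """The shipped 24-guild / 8-group / 5-compartment topology fixture."""
    guilds = GuildTable([Guild(*row) for row in _GUILD_ROWS])
    trophic = tuple(
        (r, c) for c, diet in _GROUP_DIETS.items() for r in diet
    )
    detrital = tuple((g, PDOM) for g in GROUPS if g != "Bac")
    group_of_node = {str(g.id): g.group for g in guilds}
    group_of_node[PDOM] = PDOM
    return LakeTopology(
        guilds=guilds,
        groups=GROUPS,
        trophic_links=trophic,
        detrital_links=detrital,
        group_of_node=group_of_node,
        compartment_of_group=dict(GROUP_TO_COMPARTMENT),
        exergy_weights=ExergyWeights(dict(DEFAULT_BETA_BY_GROUP)),
        ppmr_weights=DEFAULT_PPMR_WEIGHTS,
    )


# ---------------------------------------------------------------------------
# Scenario configuration
# ---------------------------------------------------------------------------

def _per_phase(values) -> dict:
    return dict(zip(PHASES, values))


@dataclass
class ScenarioConfig:
    """Parameters of the synthetic seasonal scenario.

    Phase-keyed dials encode the seasonal narrative: total-system-throughput
    multipliers peak in spring, the Dirichlet flow-evenness concentration α
    rises from few-strong-links spring values towards even late-succession
    flows, and the keystone factor concentrates clear-water-phase ingestion
    through the herbivorous crustaceans. All fractions are per unit ingestion.
    """

    seed: int = 0

    # --- flow networks ---
    base_tst: float = 1.2e6                     # µgC m⁻² d⁻¹ scale of spring GPP
    tst_multiplier: dict = field(default_factory=lambda: _per_phase(
        (0.15, 1.0, 1.4, 0.9, 0.8, 0.55, 0.2)))
    alpha: dict = field(default_factory=lambda: _per_phase(
        (1.2, 0.5, 1.0, 2.0, 4.0, 8.0, 2.5)))
    keystone_factor: float = 0.8                # CWP HerbCru grazing boost (0 = off)
    bacterial_share: float = 1.0 / 9.0          # bacterial production : GPP
    phy_resp_frac: float = 0.25
    phy_exud_frac: float = 0.15
    resp_frac: dict = field(default_factory=lambda: {
        "Bac": 0.45, "HNF": 0.40, "Cil": 0.40, "Rot": 0.40,
        "HerbCru": 0.35, "CarnCru": 0.35, "Fish": 0.30})
    egestion_frac: dict = field(default_factory=lambda: {
        "Bac": 0.0, "HNF": 0.20, "Cil": 0.20, "Rot": 0.25,
        "HerbCru": 0.30, "CarnCru": 0.25, "Fish": 0.25})
    grazing: dict = field(default_factory=lambda: {
        "HNF": 0.50, "Cil": 0.50, "Rot": 0.35,
        "HerbCru": 0.60, "CarnCru": 0.55, "Fish": 0.45})
    self_loop_frac: float = 0.04
    storage_frac: float = 0.25                  # share of leftover production stored

    # --- stoichiometry (µgC / µgP) ---
    cp_by_group: dict = field(default_factory=lambda: {
        "Bac": 50.0, "HNF": 100.0, "Cil": 110.0, "Rot": 120.0,
        "HerbCru": 90.0, "CarnCru": 85.0, "Fish": 80.0, PDOM: 180.0})
    cp_phy_by_phase: dict = field(default_factory=lambda: _per_phase(
        (110.0, 90.0, 130.0, 160.0, 280.0, 240.0, 150.0)))

    # --- biomass series ---
    n_snapshots: int = 4                        # snapshots per phase
    base_biomass_total: float = 5.0e6           # µgC m⁻² at amplitude 1
    biomass_amplitude: dict = field(default_factory=lambda: _per_phase(
        (0.5, 1.2, 2.0, 1.5, 2.5, 2.2, 0.8)))
    dominance: dict = field(default_factory=lambda: _per_phase(
        (0.30, 0.35, 0.15, 0.65, 0.10, 0.10, 0.35)))
    dominant_guild: dict = field(default_factory=lambda: _per_phase(
        (18, 1, 1, 18, 2, 2, 18)))
    biomass_concentration: float = 150.0        # Dirichlet precision within phase
    fish_fraction: dict = field(default_factory=lambda: _per_phase(
        (0.10, 0.05, 0.04, 0.05, 0.05, 0.06, 0.12)))

    def validate(self) -> None:
        for g in GROUPS[1:]:
            e = self.egestion_frac[g] if g in self.egestion_frac else 0.0
            r = self.resp_frac[g]
            if not 0 < r < 1 or not 0 <= e < 1 or e + r + self.self_loop_frac >= 1:
                raise FlowNetworkError(f"infeasible budget fractions for {g!r}")
        for ph in PHASES:
            if self.alpha[ph] <= 0:
                raise FlowNetworkError("alpha must be positive")
            if self.tst_multiplier[ph] <= 0:
                raise FlowNetworkError("TST multiplier must be positive")


@dataclass
class Scenario:
    """One realization of the synthetic seasonal study."""

    config: ScenarioConfig
    topology: LakeTopology
    phases: tuple
    networks: dict          # phase -> {"C": FlowNetwork, "P": FlowNetwork}
    production: dict        # phase -> {node: net production, µgC m⁻² d⁻¹}
    biomass: BiomassSeries  # 20 plankton guilds
    fish_biomass: dict      # phase -> adult fish biomass, µgC m⁻²
    cp: dict                # phase -> {node: C:P of that node's biomass}


# ---------------------------------------------------------------------------
# Network generation
# ---------------------------------------------------------------------------

# Consumers in a feeding (trophic) processing order; every resource of a
# consumer except itself appears earlier in the order.
_CONSUMER_ORDER = ("HNF", "Cil", "Rot", "HerbCru", "CarnCru", "Fish")

_SELF_LOOP_GROUPS = frozenset(
    c for c, diet in _GROUP_DIETS.items() if c in diet
)


def _draw_diet_uniforms(rng: np.random.Generator) -> dict:
    """One uniform vector per consumer: the scenario's latent diet preferences."""
    return {
        c: rng.uniform(size=len([r for r in _GROUP_DIETS[c] if r != c]))
        for c in _CONSUMER_ORDER
    }


def _dirichlet_from_uniforms(u: np.ndarray, alpha: float) -> np.ndarray:
    """Dirichlet(α,...,α) weights via inverse-CDF-transformed gammas.

    For fixed uniforms the weights vary smoothly and near-monotonically in α
    (common-random-number coupling across phases); marginally each draw is an
    exact symmetric Dirichlet(α).
    """
    from scipy.stats import gamma as _gamma

    g = _gamma.ppf(u, a=alpha)
    g = np.clip(g, 1e-300, None)
    return g / g.sum()


def generate_balanced_network(topology: LakeTopology, cfg: ScenarioConfig,
                              phase: str, rng: np.random.Generator | None = None,
                              diet_uniforms: Mapping[str, np.ndarray] | None = None) -> FlowNetwork:
    """One mass-balanced 8-group + PDOM carbon network for one phase.

    Diet fractions are Dirichlet(α)-distributed over each consumer's
    resources; gross primary production enters as the import of the
    phytoplankton; each consumer harvests a bounded share of the remaining
    production of its resources; budgets close via respiration and egestion
    fractions of ingestion, with leftovers split between export and biomass
    storage. Node residuals are zero to machine precision.

    ``diet_uniforms`` (one uniform vector per consumer) carries the latent
    diet preferences of a whole scenario, so that phases differ by their
    evenness α while a consumer's preference ranking persists across the
    year; omitted, fresh preferences are drawn from ``rng``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if diet_uniforms is None:
        diet_uniforms = _draw_diet_uniforms(rng)
    cfg.validate()
    if phase not in PHASES:
        raise FlowNetworkError(f"unknown phase {phase!r}")

    nodes = topology.nodes8
    net = FlowNetwork.empty("C", phase, nodes)
    net.units = "ugC m-2 d-1"
    ix = {n: i for i, n in enumerate(nodes)}
    alpha = cfg.alpha[phase]

    gpp = cfg.base_tst * cfg.tst_multiplier[phase]
    net.imports[ix["Phy"]] = gpp
    net.respiration[ix["Phy"]] = cfg.phy_resp_frac * gpp
    net.T[ix["Phy"], ix[PDOM]] += cfg.phy_exud_frac * gpp
    supply = {n: 0.0 for n in nodes}
    supply["Phy"] = gpp * (1.0 - cfg.phy_resp_frac - cfg.phy_exud_frac)

    # bacterial loop: uptake from PDOM fixed by the production share
    g_bac = cfg.bacterial_share * gpp
    net.T[ix[PDOM], ix["Bac"]] = g_bac
    net.respiration[ix["Bac"]] = cfg.resp_frac["Bac"] * g_bac
    supply["Bac"] = g_bac * (1.0 - cfg.resp_frac["Bac"])
    ingestion = {"Bac": g_bac}

    for c in _CONSUMER_ORDER:
        resources = [r for r in _GROUP_DIETS[c] if r != c]
        w = _dirichlet_from_uniforms(np.asarray(diet_uniforms[c]), alpha)
        u = w / w.max()                       # proportional harvest caps, max 1
        g = cfg.grazing[c]
        if c == "HerbCru" and phase == "CWP":
            g = min(g * (1.0 + cfg.keystone_factor), 0.95)
        g0 = 0.0
        for r, frac in zip(resources, u):
            take = g * frac * supply[r]
            if take > 0:
                net.T[ix[r], ix[c]] += take
                supply[r] -= take
                g0 += take
        self_loop = cfg.self_loop_frac * g0 if c in _SELF_LOOP_GROUPS else 0.0
        if self_loop > 0:
            net.T[ix[c], ix[c]] += self_loop
        intake = g0 + self_loop
        ingestion[c] = intake
        egest = cfg.egestion_frac[c] * intake
        if egest > 0:
            net.T[ix[c], ix[PDOM]] += egest
        resp = cfg.resp_frac[c] * intake
        net.respiration[ix[c]] += resp
        supply[c] = intake - egest - resp - self_loop
        if supply[c] < 0:
            raise FlowNetworkError(f"infeasible budget at {c!r}")

    # close leftovers: export + storage
    for n in GROUPS:
        left = supply[n]
        if left < -1e-9 * gpp:
            raise FlowNetworkError(f"negative leftover at {n!r}")
        left = max(left, 0.0)
        net.storage_out[ix[n]] += cfg.storage_frac * left
        net.exports[ix[n]] += (1.0 - cfg.storage_frac) * left

    pdom_in = net.T[:, ix[PDOM]].sum()
    pdom_left = pdom_in - g_bac
    if pdom_left < 0:
        raise FlowNetworkError(
            "infeasible budget: bacterial uptake exceeds detrital supply"
        )
    net.storage_out[ix[PDOM]] += cfg.storage_frac * pdom_left
    net.exports[ix[PDOM]] += (1.0 - cfg.storage_frac) * pdom_left

    # exact closure: absorb float rounding into the larger boundary side
    _snap_balance(net)
    return net


def _snap_balance(net: FlowNetwork) -> None:
    """Absorb float rounding so every node balances to ~1e-15 relative."""
    inputs = net.T.sum(axis=0) + net.imports + net.storage_in
    outputs = net.T.sum(axis=1) + net.exports + net.storage_out + net.respiration
    resid = inputs - outputs
    for i in range(len(net.nodes)):
        r = resid[i]
        if r > 0:
            net.exports[i] += r
        elif r < 0:
            take = min(net.exports[i], -r)
            net.exports[i] -= take
            net.storage_in[i] += (-r) - take


def _cp_of_node(cfg: ScenarioConfig, phase: str) -> dict:
    cp = dict(cfg.cp_by_group)
    cp["Phy"] = cfg.cp_phy_by_phase[phase]
    return cp


def derive_p_network(net_c: FlowNetwork, cp: Mapping[str, float]) -> FlowNetwork:
    """Phosphorus companion of a carbon network.

    Each internal P-flow is the C-flow divided by the C:P ratio of its
    resource node; phosphorus carries no respiratory loss. Node budgets are
    re-closed through exports and the two storage terms (a node whose P
    outputs exceed its P inputs draws the difference from stored biomass).
    """
    nodes = net_c.nodes
    net = FlowNetwork.empty("P", net_c.phase, nodes)
    net.units = "ugP m-2 d-1"
    for i, a in enumerate(nodes):
        ratio = float(cp[a])
        if ratio <= 0:
            raise FlowNetworkError(f"C:P for {a!r} must be positive")
        net.T[i, :] = net_c.T[i, :] / ratio
        net.imports[i] = net_c.imports[i] / ratio
    inputs = net.T.sum(axis=0) + net.imports
    outputs = net.T.sum(axis=1)
    resid = inputs - outputs
    storage_frac = 0.5
    for i in range(len(nodes)):
        r = resid[i]
        if r >= 0:
            net.storage_out[i] = storage_frac * r
            net.exports[i] = (1.0 - storage_frac) * r
        else:
            net.storage_in[i] = -r
    _snap_balance(net)
    return net


def _production_from_network(net: FlowNetwork, cfg: ScenarioConfig) -> dict:
    """Net production per biotic node implied by the budget fractions."""
    ix = {n: i for i, n in enumerate(net.nodes)}
    prod = {}
    gpp = net.imports[ix["Phy"]]
    prod["Phy"] = gpp * (1.0 - cfg.phy_resp_frac - cfg.phy_exud_frac)
    for c in GROUPS[1:]:
        intake = net.T[:, ix[c]].sum()
        egest = cfg.egestion_frac.get(c, 0.0) * intake
        resp = cfg.resp_frac[c] * intake
        prod[c] = max(intake - egest - resp, 0.0)
    return prod


def generate_seasonal_scenario(cfg: ScenarioConfig | None = None,
                               topology: LakeTopology | None = None) -> Scenario:
    """All seven phases of one synthetic year: matched C/P networks,
    production, guild biomass trajectories and fish biomass."""
    if cfg is None:
        cfg = ScenarioConfig()
    if topology is None:
        topology = lake_topology_fixture()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    networks = {}
    production = {}
    cp_all = {}
    diet_uniforms = _draw_diet_uniforms(rng)
    for phase in PHASES:
        net_c = generate_balanced_network(topology, cfg, phase, rng,
                                          diet_uniforms=diet_uniforms)
        cp = _cp_of_node(cfg, phase)
        networks[phase] = {"C": net_c, "P": derive_p_network(net_c, cp)}
        production[phase] = _production_from_network(net_c, cfg)
        cp_all[phase] = cp

    biomass = generate_biomass_series(topology.guilds, cfg, rng)
    fish = {
        ph: cfg.fish_fraction[ph] * cfg.biomass_amplitude[ph] * cfg.base_biomass_total
        for ph in PHASES
    }
    return Scenario(cfg, topology, PHASES, networks, production, biomass, fish, cp_all)


# ---------------------------------------------------------------------------
# Biomass generation
# ---------------------------------------------------------------------------

# day-of-year midranges per phase for placing snapshots
_PHASE_DOY_RANGE = {
    "Late Winter": (20, 55), "Early Spring": (65, 100), "Late Spring": (110, 138),
    "CWP": (143, 163), "Summer": (170, 240), "Autumn": (250, 300),
    "Early Winter": (310, 355),
}

N_PLANKTON_GUILDS = 20


def generate_biomass_series(guilds: GuildTable, cfg: ScenarioConfig | None = None,
                            rng: np.random.Generator | None = None) -> BiomassSeries:
    """Biomass snapshots of the 20 plankton guilds on the 7-phase axis.

    Per phase, relative biomasses are Dirichlet draws around a mixture of a
    uniform profile and a phase-specific dominant guild (the clear-water
    phase puts its dominance weight on the keystone herbivorous crustacean,
    producing the bimodal evenness profile with the phase-4 diversity
    minimum); absolute totals follow a phase amplitude.
    """
    if cfg is None:
        cfg = ScenarioConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ids = [g.id for g in guilds if g.id <= N_PLANKTON_GUILDS]
    if len(ids) != N_PLANKTON_GUILDS:
        raise FlowNetworkError("guild table lacks the 20 plankton guilds")
    times = []
    rows = []
    for ph in PHASES:
        d = cfg.dominance[ph]
        dom = cfg.dominant_guild[ph]
        m = np.full(N_PLANKTON_GUILDS, (1.0 - d) / N_PLANKTON_GUILDS)
        m[ids.index(dom)] += d
        total = cfg.biomass_amplitude[ph] * cfg.base_biomass_total
        lo, hi = _PHASE_DOY_RANGE[ph]
        days = np.linspace(lo, hi, cfg.n_snapshots)
        for day in days:
            rel = rng.dirichlet(cfg.biomass_concentration * m)
            times.append(float(day))
            rows.append(rel * total)
    return BiomassSeries(
        times=tuple(times),
        guild_ids=tuple(ids),
        B=np.array(rows),
        units="ugC m-2",
    )
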