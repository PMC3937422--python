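"""Domain types and plumbing for mass-balanced food-web flow networks.

A flow network holds the internal trophic/detrital flows between functional
compartments of a pelagic food web for one element (carbon or phosphorus) in
one seasonal phase, together with the boundary flows (imports, exports,
respiration and biomass-storage terms) that close every compartment's budget.
Flows are in µg element m⁻² d⁻¹ unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PDOM",
    "PHASES",
    "FlowNetworkError",
    "Guild",
    "GuildTable",
    "FlowNetwork",
    "FlowSelection",
    "BiomassSeries",
    "BalanceReport",
    "phase_of_day",
    "selected_flows",
    "read_flow_network",
    "write_flow_network",
    "validate_mass_balance",
    "total_system_throughput",
    "aggregate_network",
    "disaggregate_flows",
]

#: Label of the dead particulate and dissolved organic matter pool.
PDOM = "PDOM"

#: The standardized seasonal phase axis (1-based order is meaningful).
PHASES = (
    "Late Winter",
    "Early Spring",
    "Late Spring",
    "CWP",
    "Summer",
    "Autumn",
    "Early Winter",
)

# Day-of-year boundaries used to map continuous time points onto the 7 phases.
# Upper bound (inclusive) per phase, in order of PHASES.
_PHASE_UPPER_DOY = (60, 105, 140, 165, 245, 305, 366)

# Virtual node labels for boundary flows when a selection includes them.
IMPORT_NODE = "<import>"
EXPORT_NODE = "<export>"
RESPIRATION_NODE = "<respiration>"
STORAGE_NODE = "<storage>"


class FlowNetworkError(ValueError):
    """Raised for malformed, inconsistent or infeasible flow-network input."""


def phase_of_day(day: float) -> str:
    """Map a day-of-year (1..366) to its seasonal phase label."""
    d = float(day)
    if not 1 <= d <= 366:
        raise FlowNetworkError(f"day-of-year {day!r} outside 1..366")
    for label, upper in zip(PHASES, _PHASE_UPPER_DOY):
        if d <= upper:
            return label
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Guilds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Guild:
    """One functional guild of the 24-guild pelagic food web.

    ``size_class`` is log2 of the average individual body mass in pgC.
    ``diet`` lists resource guild ids (integers) and/or the :data:`PDOM` label.
    """

    id: int
    name: str
    group: str           # one of the 8 major functional groups
    compartment: str     # one of the 5 trophic compartments
    dietary_group: str   # Auto / Herb / Omni / Carn
    size_class: int
    diet: tuple = ()
    edibility: str = "n/a"
    feeding_type: str = "n/a"


class GuildTable:
    """Ordered collection of guilds with id lookup and invariant checks."""

    def __init__(self, guilds: Sequence[Guild]):
        self.guilds = tuple(guilds)
        self._by_id = {g.id: g for g in self.guilds}
        if len(self._by_id) != len(self.guilds):
            raise FlowNetworkError("duplicate guild ids")
        for g in self.guilds:
            for r in g.diet:
                if r != PDOM and r not in self._by_id:
                    raise FlowNetworkError(
                        f"guild {g.id} diet references unknown resource {r!r}"
                    )

    def __iter__(self):
        return iter(self.guilds)

    def __len__(self):
        return len(self.guilds)

    def __getitem__(self, guild_id: int) -> Guild:
        return self._by_id[guild_id]

    @property
    def ids(self) -> tuple:
        return tuple(g.id for g in self.guilds)

    def members(self, group: str) -> tuple:
        """Ids of the guilds belonging to a major functional group."""
        return tuple(g.id for g in self.guilds if g.group == group)

    def feeding_links(self, include_pdom: bool = True) -> list:
        """All (resource, consumer) guild-level feeding links from the diets."""
        links = []
        for g in self.guilds:
            for r in g.diet:
                if r == PDOM and not include_pdom:
                    continue
                links.append((r, g.id))
        return links

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": g.id,
                "name": g.name,
                "group": g.group,
                "compartment": g.compartment,
                "dietary_group": g.dietary_group,
                "size_class": g.size_class,
                "diet": ";".join(str(r) for r in g.diet),
                "edibility": g.edibility,
                "feeding_type": g.feeding_type,
            }
            for g in self.guilds
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Biomass series
# ---------------------------------------------------------------------------

@dataclass
class BiomassSeries:
    """Time × guild biomass matrix on the standardized seasonal axis.

    ``times`` are day-of-year values (or phase labels); ``B[t, g]`` is the
    biomass of guild ``guild_ids[g]`` at ``times[t]`` in ``units``.
    """

    times: tuple
    guild_ids: tuple
    B: np.ndarray
    units: str = "ugC m-2"

    def __post_init__(self):
        self.times = tuple(self.times)
        self.guild_ids = tuple(self.guild_ids)
        self.B = np.asarray(self.B, dtype=float)
        if self.B.shape != (len(self.times), len(self.guild_ids)):
            raise FlowNetworkError(
                f"B has shape {self.B.shape}, expected "
                f"({len(self.times)}, {len(self.guild_ids)})"
            )
        if (self.B < 0).any():
            raise FlowNetworkError("negative biomass")

    def relative(self) -> np.ndarray:
        """Row-normalized relative biomasses (each snapshot sums to 1)."""
        tot = self.B.sum(axis=1, keepdims=True)
        if (tot <= 0).any():
            raise FlowNetworkError("snapshot with zero total biomass")
        return self.B / tot

    def phase_labels(self) -> tuple:
        """Phase label of every time point (times must be day-of-year)."""
        return tuple(phase_of_day(t) for t in self.times)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.B, columns=[str(g) for g in self.guild_ids])
        df.insert(0, "time", self.times)
        return df


# ---------------------------------------------------------------------------
# Flow networks
# ---------------------------------------------------------------------------

class FlowSelection(Enum):
    """Which flow multiset an index is computed on.

    ``TROPHIC_DETRITAL``: internal flows only (feeding + detrital links).
    ``FULL_THROUGHPUT``: internal flows plus imports, exports, respiration and
    both biomass-storage terms.
    """

    TROPHIC_DETRITAL = "trophic_detrital"
    FULL_THROUGHPUT = "full_throughput"


@dataclass
class FlowNetwork:
    """One phase's mass-balanced flow network for one element (C or P)."""

    element: str
    phase: str
    nodes: tuple
    T: np.ndarray                      # internal flows, T[i, j] = i -> j
    imports: np.ndarray
    exports: np.ndarray
    respiration: np.ndarray
    storage_in: np.ndarray
    storage_out: np.ndarray
    units: str = "ugX m-2 d-1"

    def __post_init__(self):
        self.nodes = tuple(self.nodes)
        s = len(self.nodes)
        self.T = np.asarray(self.T, dtype=float)
        if self.T.shape != (s, s):
            raise FlowNetworkError(f"T has shape {self.T.shape}, expected ({s},{s})")
        for name in ("imports", "exports", "respiration", "storage_in", "storage_out"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (s,):
                raise FlowNetworkError(f"{name} has shape {v.shape}, expected ({s},)")
            setattr(self, name, v)
        if (self.T < 0).any():
            raise FlowNetworkError("negative flow in T")
        for name in ("imports", "exports", "respiration", "storage_in", "storage_out"):
            if (getattr(self, name) < 0).any():
                raise FlowNetworkError(f"negative flow in {name}")

    # -- convenience -------------------------------------------------------

    @classmethod
    def empty(cls, element: str, phase: str, nodes: Sequence[str]) -> "FlowNetwork":
        s = len(nodes)
        z = np.zeros(s)
        return cls(element, phase, tuple(nodes), np.zeros((s, s)),
                   z.copy(), z.copy(), z.copy(), z.copy(), z.copy())

    def index(self, node: str) -> int:
        try:
            return self.nodes.index(node)
        except ValueError:
            raise FlowNetworkError(f"unknown node {node!r}") from None

    def flow(self, source: str, target: str) -> float:
        return float(self.T[self.index(source), self.index(target)])

    def copy(self) -> "FlowNetwork":
        return replace(
            self,
            T=self.T.copy(),
            imports=self.imports.copy(),
            exports=self.exports.copy(),
            respiration=self.respiration.copy(),
            storage_in=self.storage_in.copy(),
            storage_out=self.storage_out.copy(),
        )

    def internal_links(self, tol: float = 0.0) -> list:
        """(source, target) pairs carrying internal flow above ``tol``."""
        out = []
        for i, a in enumerate(self.nodes):
            for j, b in enumerate(self.nodes):
                if self.T[i, j] > tol:
                    out.append((a, b))
        return out

    def scaled(self, factor: float) -> "FlowNetwork":
        """All flows multiplied by a positive constant (for invariance tests)."""
        if factor <= 0:
            raise FlowNetworkError("scale factor must be positive")
        net = self.copy()
        net.T *= factor
        net.imports *= factor
        net.exports *= factor
        net.respiration *= factor
        net.storage_in *= factor
        net.storage_out *= factor
        return net


def selected_flows(net: FlowNetwork, sel: FlowSelection) -> list:
    """The flow multiset of a selection, as (source, target, value) triples.

    Boundary flows appear with virtual endpoint labels so that entropy-type
    indices have a well-defined joint distribution over flow endpoints.
    Zero flows are omitted.
    """
    flows = []
    for i, a in enumerate(net.nodes):
        for j, b in enumerate(net.nodes):
            v = net.T[i, j]
            if v > 0:
                flows.append((a, b, float(v)))
    if sel is FlowSelection.FULL_THROUGHPUT:
        for i, a in enumerate(net.nodes):
            if net.imports[i] > 0:
                flows.append((IMPORT_NODE, a, float(net.imports[i])))
            if net.storage_in[i] > 0:
                flows.append((STORAGE_NODE, a, float(net.storage_in[i])))
            if net.exports[i] > 0:
                flows.append((a, EXPORT_NODE, float(net.exports[i])))
            if net.respiration[i] > 0:
                flows.append((a, RESPIRATION_NODE, float(net.respiration[i])))
            if net.storage_out[i] > 0:
                flows.append((a, STORAGE_NODE, float(net.storage_out[i])))
    elif sel is not FlowSelection.TROPHIC_DETRITAL:
        raise FlowNetworkError(f"unknown flow selection {sel!r}")
    return flows


def total_system_throughput(net: FlowNetwork, sel: FlowSelection = FlowSelection.FULL_THROUGHPUT) -> float:
    """Total system throughput: the sum of the selected flow multiset.

    With ``FULL_THROUGHPUT`` this counts every internal flow plus each
    boundary flow once (the "sum of all compartmental flows" convention).
    """
    flows = selected_flows(net, sel)
    if not flows:
        raise FlowNetworkError("empty selection: network carries no flow")
    return float(sum(v for _, _, v in flows))


# ---------------------------------------------------------------------------
# Mass balance
# ---------------------------------------------------------------------------

@dataclass
class BalanceReport:
    """Per-node residuals of the steady-state budget and a pass/fail verdict."""

    residuals: dict
    relative: dict
    rtol: float
    passed: bool
    worst_node: str

    def __bool__(self) -> bool:
        return self.passed


def validate_mass_balance(net: FlowNetwork, rtol: float = 1e-6) -> BalanceReport:
    """Check input = output for every node within a relative tolerance.

    residual_i = (Σ_j T_ji + I_i + TI_i) − (Σ_k T_ik + E_i + TE_i + R_i);
    a node passes iff |residual_i| ≤ rtol · max(inputs_i, outputs_i).
    """
    inputs = net.T.sum(axis=0) + net.imports + net.storage_in
    outputs = net.T.sum(axis=1) + net.exports + net.storage_out + net.respiration
    resid = inputs - outputs
    scale = np.maximum(np.maximum(inputs, outputs), 1e-300)
    rel = np.abs(resid) / scale
    ok = np.abs(resid) <= rtol * np.maximum(inputs, outputs)
    worst = net.nodes[int(np.argmax(rel))]
    return BalanceReport(
        residuals={n: float(r) for n, r in zip(net.nodes, resid)},
        relative={n: float(r) for n, r in zip(net.nodes, rel)},
        rtol=rtol,
        passed=bool(ok.all()),
        worst_node=worst,
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_NODE_COLS = ("import", "export", "respiration", "storage_in", "storage_out")


def write_flow_network(net: FlowNetwork, edge_file, node_file, meta_file=None) -> None:
    """Write a network as two CSVs (edges, nodes) plus an optional YAML header."""
    edges = pd.DataFrame(
        [(a, b, v) for a, b, v in selected_flows(net, FlowSelection.TROPHIC_DETRITAL)],
        columns=["source", "target", "flow"],
    )
    edges.to_csv(edge_file, index=False)
    nodes = pd.DataFrame({
        "node": net.nodes,
        "import": net.imports,
        "export": net.exports,
        "respiration": net.respiration,
        "storage_in": net.storage_in,
        "storage_out": net.storage_out,
    })
    nodes.to_csv(node_file, index=False)
    if meta_file is not None:
        with open(meta_file, "w") as fh:
            yaml.safe_dump(
                {"element": net.element, "phase": net.phase, "units": net.units}, fh
            )


def read_flow_network(edge_file, node_file, meta_file=None,
                      element: str = "C", phase: str = "") -> FlowNetwork:
    """Read a network from the two-CSV layout written by :func:`write_flow_network`.

    Unknown nodes in the edge list are an error; missing boundary columns
    default to zero; negative or duplicated flows are rejected.
    """
    try:
        edges = pd.read_csv(edge_file, float_precision="round_trip")
        nodes = pd.read_csv(node_file, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FlowNetworkError(f"malformed CSV: {exc}") from exc
    for col in ("source", "target", "flow"):
        if col not in edges.columns:
            raise FlowNetworkError(f"edge file missing column {col!r}")
    if "node" not in nodes.columns:
        raise FlowNetworkError("node file missing column 'node'")
    if meta_file is not None:
        with open(meta_file) as fh:
            meta = yaml.safe_load(fh) or {}
        element = meta.get("element", element)
        phase = meta.get("phase", phase)

    node_labels = tuple(str(n) for n in nodes["node"])
    net = FlowNetwork.empty(element, phase, node_labels)
    attr_of_col = {"import": "imports", "export": "exports",
                   "respiration": "respiration",
                   "storage_in": "storage_in", "storage_out": "storage_out"}
    for col in _NODE_COLS:
        if col in nodes.columns:
            vals = nodes[col].fillna(0.0).to_numpy(dtype=float)
        else:
            vals = np.zeros(len(node_labels))
        if (vals < 0).any():
            raise FlowNetworkError(f"negative flow in node column {col!r}")
        setattr(net, attr_of_col[col], vals)

    seen = set()
    for row in edges.itertuples(index=False):
        a, b, v = str(row.source), str(row.target), float(row.flow)
        if v < 0:
            raise FlowNetworkError(f"negative flow on edge {a}->{b}")
        if (a, b) in seen:
            raise FlowNetworkError(f"duplicate edge {a}->{b}")
        seen.add((a, b))
        net.T[net.index(a), net.index(b)] = v
    return net


# ---------------------------------------------------------------------------
# Resolution changes
# ---------------------------------------------------------------------------

def aggregate_network(net: FlowNetwork, mapping: Mapping[str, str]) -> FlowNetwork:
    """Merge nodes into supernodes, summing internal and boundary flows.

    Intra-supernode flows are retained as self-loops; balance and every
    boundary total are conserved exactly.
    """
    for n in net.nodes:
        if n not in mapping:
            raise FlowNetworkError(f"aggregation mapping missing node {n!r}")
    supernodes = []
    for n in net.nodes:  # preserve first-appearance order
        s = mapping[n]
        if s not in supernodes:
            supernodes.append(s)
    out = FlowNetwork.empty(net.element, net.phase, supernodes)
    out.units = net.units
    pos = {s: k for k, s in enumerate(supernodes)}
    for i, a in enumerate(net.nodes):
        ia = pos[mapping[a]]
        out.imports[ia] += net.imports[i]
        out.exports[ia] += net.exports[i]
        out.respiration[ia] += net.respiration[i]
        out.storage_in[ia] += net.storage_in[i]
        out.storage_out[ia] += net.storage_out[i]
        for j, b in enumerate(net.nodes):
            out.T[ia, pos[mapping[b]]] += net.T[i, j]
    return out


def disaggregate_flows(net8: FlowNetwork, guilds: GuildTable,
                       group_of_node: Mapping[str, str] | None = None) -> FlowNetwork:
    """Spread group-level flows uniformly over compatible guild-level links.

    Each group-to-group flow is divided equally among the guild-level feeding
    links it covers (resource guild in the resource group and listed in the
    consumer guild's diet). Flows into/out of :data:`PDOM` are split uniformly
    over the member guilds of the group side. Boundary flows are split
    uniformly over member guilds so that re-aggregation reproduces ``net8``
    exactly. Total flow is conserved per group pair.
    """
    if group_of_node is None:
        group_of_node = {n: n for n in net8.nodes}
    guild_nodes = [str(g.id) for g in guilds]
    nodes = tuple(guild_nodes) + ((PDOM,) if PDOM in net8.nodes else ())
    out = FlowNetwork.empty(net8.element, net8.phase, nodes)
    out.units = net8.units

    members = {}
    for n in net8.nodes:
        grp = group_of_node[n]
        if n == PDOM:
            members[n] = [PDOM]
        else:
            ids = [str(i) for i in guilds.ids if guilds[i].group == grp]
            if not ids:
                raise FlowNetworkError(f"no guilds mapped to group {n!r}")
            members[n] = ids

    diet_sets = {g.id: set(g.diet) for g in guilds}

    for i, a in enumerate(net8.nodes):
        for j, b in enumerate(net8.nodes):
            v = net8.T[i, j]
            if v == 0:
                continue
            if b == PDOM:
                # detrital release: each member guild contributes equally
                links = [(m, PDOM) for m in members[a]]
            elif a == PDOM:
                links = [(PDOM, m) for m in members[b]
                         if PDOM in diet_sets[int(m)]]
            else:
                links = [
                    (r, c)
                    for c in members[b]
                    for r in members[a]
                    if int(r) in diet_sets[int(c)]
                ]
            if not links:
                raise FlowNetworkError(
                    f"group flow {a}->{b} has no compatible guild-level link"
                )
            share = v / len(links)
            for r, c in links:
                out.T[out.index(r), out.index(c)] += share

    for i, a in enumerate(net8.nodes):
        ms = members[a]
        for attr in ("imports", "exports", "respiration", "storage_in", "storage_out"):
            v = getattr(net8, attr)[i]
            if v == 0:
                continue
            share = v / len(ms)
            vec = getattr(out, attr)
            for m in ms:
                vec[out.index(m)] += share
    return out
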