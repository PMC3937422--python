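"""Information-theoretic and weighted small-world indices on flow networks.

The ascendency family treats the flow multiset as a joint distribution over
(source, sink) endpoints: flow diversity H_flow is its Shannon entropy,
average mutual information AMI the association between sources and sinks, and
the conditional entropy Φ = H_flow − AMI the residual uncertainty (relative
overhead). Ascendency Asc = TST·AMI, development capacity K_dev = TST·H_flow,
relative ascendency Asc_rel = AMI/H_flow. The weighted link density
Conn_w = base^(Φ/2) ("effective number of connections per node") and the
weighted connectance C_w = Conn_w/S extend binary connectance to quantified
webs: with perfectly even flows on a k-regular web, Conn_w equals the binary
link density L/S exactly.

Entropies are in bits by default and the link-density exponent uses the same
base as the entropies so the two stay mutually consistent; both are
configurable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core import (
    FlowNetwork,
    FlowNetworkError,
    FlowSelection,
    selected_flows,
    total_system_throughput,
)

__all__ = [
    "InfoSummary",
    "SmallWorldSummary",
    "flow_information",
    "weighted_connectance",
    "ascendency_suite",
    "fitness",
    "weighted_path_length",
    "weighted_clustering",
    "small_world_summary",
    "strongest_shortest_path",
    "binary_link_stats",
]


@dataclass
class InfoSummary:
    """Throughput, entropy and ascendency indices of one flow network."""

    tst: float
    h_flow: float            # bits
    ami: float               # bits
    phi: float               # conditional entropy H_flow - AMI, bits
    conn_w: float            # effective links per node
    c_w: float               # weighted connectance
    asc: float               # ascendency TST * AMI
    k_dev: float             # development capacity TST * H_flow
    overhead: float          # K_dev - Asc
    asc_rel: float           # AMI / H_flow
    fitness: float           # -Asc_rel * ln(Asc_rel), k = 1


@dataclass
class SmallWorldSummary:
    """Weighted small-world characteristics of one flow network."""

    d: float                 # weighted characteristic path length
    d_norm: float
    q: float                 # weighted average clustering coefficient
    q_norm: float
    conn_bin: float          # L / S
    c_bin: float             # L / S^2
    n_unreachable_pairs: int


def flow_information(net: FlowNetwork, sel: FlowSelection = FlowSelection.FULL_THROUGHPUT,
                     base: float = 2.0) -> tuple:
    """(TST, H_flow, AMI, Φ) of the selected flow multiset.

    H_flow = −Σ (T_ij/TST)·log(T_ij/TST) measures flow evenness relative to
    TST; AMI = Σ (T_ij/TST)·log(T_ij·TST / (T_i· · T_·j)) the coupling between
    flow sources and sinks. Zero flows are skipped.
    """
    flows = selected_flows(net, sel)
    if not flows:
        raise FlowNetworkError("empty flow set")
    tst = sum(v for _, _, v in flows)
    out_sum: dict = {}
    in_sum: dict = {}
    for a, b, v in flows:
        out_sum[a] = out_sum.get(a, 0.0) + v
        in_sum[b] = in_sum.get(b, 0.0) + v
    log = math.log
    h = 0.0
    ami = 0.0
    for a, b, v in flows:
        p = v / tst
        h -= p * log(p)
        ami += p * log(v * tst / (out_sum[a] * in_sum[b]))
    h /= log(base)
    ami /= log(base)
    # clip the tiny negative rounding noise on exact-independence webs
    ami = max(ami, 0.0)
    return float(tst), float(h), float(ami), float(h - ami)


def weighted_connectance(net: FlowNetwork, sel: FlowSelection = FlowSelection.TROPHIC_DETRITAL,
                         base: float = 2.0) -> tuple:
    """(Conn_w, C_w): effective link density and weighted connectance.

    Conn_w = base^(Φ/2) with Φ from the same flow set and log base; C_w
    divides by the number S of network nodes touched by the selected flows
    (virtual boundary endpoints do not count).
    """
    _, _, _, phi = flow_information(net, sel, base=base)
    touched = set()
    for a, b, _ in selected_flows(net, sel):
        if a in net.nodes:
            touched.add(a)
        if b in net.nodes:
            touched.add(b)
    s = len(touched)
    conn_w = float(base ** (phi / 2.0))
    return conn_w, conn_w / s


def fitness(asc_rel: float) -> float:
    """System fitness F = −Asc_rel·ln(Asc_rel), with F(0) = F(1) = 0.

    F is maximized at Asc_rel = 1/e ≈ 0.36, the predicted attractor of
    sustainable flow organization.
    """
    if not 0.0 <= asc_rel <= 1.0:
        raise ValueError("Asc_rel must lie in [0, 1]")
    if asc_rel in (0.0, 1.0):
        return 0.0
    return float(-asc_rel * math.log(asc_rel))


def ascendency_suite(net: FlowNetwork, sel: FlowSelection = FlowSelection.FULL_THROUGHPUT,
                     cw_sel: FlowSelection = FlowSelection.TROPHIC_DETRITAL,
                     base: float = 2.0) -> InfoSummary:
    """All ascendency-family indices of one network.

    The entropy/ascendency indices default to the full throughput flow set
    (boundary flows included); the connectance pair defaults to internal
    trophic + detrital flows only, since connectance counts feeding links.
    """
    tst, h, ami, phi = flow_information(net, sel, base=base)
    if h == 0.0:
        raise FlowNetworkError("H_flow = 0: relative ascendency undefined")
    conn_w, c_w = weighted_connectance(net, cw_sel, base=base)
    asc = tst * ami
    k_dev = tst * h
    asc_rel = ami / h
    return InfoSummary(
        tst=tst, h_flow=h, ami=ami, phi=phi,
        conn_w=conn_w, c_w=c_w,
        asc=asc, k_dev=k_dev, overhead=k_dev - asc,
        asc_rel=asc_rel, fitness=fitness(min(max(asc_rel, 0.0), 1.0)),
    )


# ---------------------------------------------------------------------------
# Weighted small-world metrics (symmetrized web)
# ---------------------------------------------------------------------------

def _symmetric_weights(net: FlowNetwork) -> tuple:
    """Symmetrized edge weights w[i][j] = T_ij + T_ji (self-loops dropped)."""
    W = net.T + net.T.T
    np.fill_diagonal(W, 0.0)
    return net.nodes, W


def binary_link_stats(net: FlowNetwork, include_self_loops: bool = False) -> tuple:
    """(S, L, Conn_bin, C_bin) of the realized directed binary web.

    S counts nodes touched by at least one internal flow; L counts directed
    internal links with positive flow (self-loops excluded by default, as
    they enter neither paths nor triangles).
    """
    links = [(a, b) for a, b in net.internal_links()
             if include_self_loops or a != b]
    touched = {n for ab in links for n in ab}
    s = len(touched)
    l = len(links)
    if s == 0:
        raise FlowNetworkError("empty graph")
    return s, l, l / s, l / s ** 2


def _relative_strengths(nodes, W) -> np.ndarray:
    """f_ij = w_ij / max(s_i, s_j) with s = total symmetrized node strength."""
    s = W.sum(axis=1)
    F = np.zeros_like(W)
    nz = W > 0
    for i, j in zip(*np.nonzero(nz)):
        F[i, j] = W[i, j] / max(s[i], s[j])
    return F


def strongest_shortest_path(net: FlowNetwork, source: str, target: str) -> list:
    """The minimal-hop path carrying the largest summed relative flow strength.

    Candidate paths are the shortest (fewest-link) paths of the symmetrized
    web; among them the one maximizing Σ f over its edges is selected, with
    lexicographic order as the final tie-break. Flow strengths therefore pick
    WHICH shortest route couples two guilds; the distance itself is the hop
    count.
    """
    nodes, W = _symmetric_weights(net)
    F = _relative_strengths(nodes, W)
    G = nx.Graph()
    G.add_nodes_from(nodes)
    for i, j in zip(*np.nonzero(W)):
        if i < j:
            G.add_edge(nodes[i], nodes[j])
    try:
        paths = list(nx.all_shortest_paths(G, source, target))
    except nx.NetworkXNoPath:
        raise FlowNetworkError(f"no path between {source!r} and {target!r}") from None
    idx = {n: i for i, n in enumerate(nodes)}

    def score(path):
        return sum(F[idx[a], idx[b]] for a, b in zip(path[:-1], path[1:]))

    return max(paths, key=lambda p: (score(p), [-idx[n] for n in p]))


def weighted_path_length(net: FlowNetwork, directed: bool = False,
                         normalized: bool = True) -> tuple:
    """(D, D_norm, n_unreachable): characteristic path length and normalization.

    D is the mean hop distance over reachable pairs of distinct nodes of the
    realized web (symmetrized by default; unordered pairs). Unreachable pairs
    are excluded and counted. D_norm = D / (ln S / ln Conn_bin), the expected
    path length of a uniform random graph with the same link density;
    normalization requires Conn_bin > 1 (an error unless ``normalized=False``,
    which reports D_norm as NaN).
    """
    nodes, W = _symmetric_weights(net)
    s_bin, l_bin, conn_bin, _ = binary_link_stats(net)
    touched = [n for i, n in enumerate(nodes)
               if W[i].sum() > 0 or net.T[i, i] > 0]
    if directed:
        G = nx.DiGraph()
        G.add_nodes_from(touched)
        for i, j in zip(*np.nonzero(net.T)):
            if i != j:
                G.add_edge(nodes[i], nodes[j])
        pairs = [(a, b) for a in touched for b in touched if a != b]
    else:
        G = nx.Graph()
        G.add_nodes_from(touched)
        for i, j in zip(*np.nonzero(W)):
            if i < j:
                G.add_edge(nodes[i], nodes[j])
        pairs = list(itertools.combinations(touched, 2))
    lengths = dict(nx.all_pairs_shortest_path_length(G))
    dists = []
    unreachable = 0
    for a, b in pairs:
        d = lengths.get(a, {}).get(b)
        if d is None:
            unreachable += 1
        else:
            dists.append(d)
    if not dists:
        raise FlowNetworkError("no reachable node pairs")
    d_mean = float(np.mean(dists))
    if conn_bin <= 1:
        if normalized:
            raise FlowNetworkError(
                "Conn_bin <= 1: random-graph normalization undefined")
        return d_mean, float("nan"), unreachable
    d_norm = d_mean / (math.log(s_bin) / math.log(conn_bin))
    return d_mean, d_norm, unreachable


def weighted_clustering(net: FlowNetwork) -> tuple:
    """(Q, Q_norm): weighted average clustering and its connectance normalization.

    Per node i, q_i = [Σ over ordered neighbor pairs (j,k) with the j–k edge
    present of (w_ij + w_ik)/2] / (s_i·(K_i − 1)), on the symmetrized web with
    s_i the node strength and K_i the degree (the flow-weighted triplet
    formula; nodes of degree < 2 contribute 0, self-loops never close
    triangles). Q_norm = Q / C_bin with C_bin = L/S² of the directed binary
    web.
    """
    nodes, W = _symmetric_weights(net)
    A = (W > 0).astype(float)
    touched = [i for i in range(len(nodes))
               if A[i].sum() > 0 or net.T[i, i] > 0]
    if not touched:
        raise FlowNetworkError("empty graph")
    strength = W.sum(axis=1)
    degree = A.sum(axis=1)
    qs = []
    for i in touched:
        k = degree[i]
        if k < 2:
            qs.append(0.0)
            continue
        nbrs = np.nonzero(A[i])[0]
        num = 0.0
        for j in nbrs:
            for l in nbrs:
                if j != l and A[j, l] > 0:
                    num += (W[i, j] + W[i, l]) / 2.0
        qs.append(num / (strength[i] * (k - 1)))
    q = float(np.mean(qs))
    _, _, _, c_bin = binary_link_stats(net)
    return q, q / c_bin


def small_world_summary(net: FlowNetwork) -> SmallWorldSummary:
    d, d_norm, unreachable = weighted_path_length(net)
    q, q_norm = weighted_clustering(net)
    s, l, conn_bin, c_bin = binary_link_stats(net)
    return SmallWorldSummary(d=d, d_norm=d_norm, q=q, q_norm=q_norm,
                             conn_bin=conn_bin, c_bin=c_bin,
                             n_unreachable_pairs=unreachable)
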