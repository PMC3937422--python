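"""Trophic-structure metrics on flow networks and size-structured biomass.

Trophic positions are flow-weighted: a consumer's position is one plus the
ingestion-weighted mean position of its resources, with producers at 1 and the
detritus pool at 0. The same decomposition distributes biomass or production
over integer trophic levels (pyramids), from which the trophic transfer
efficiency follows as the production ratio between adjacent levels. Transfer
efficiency can alternatively be estimated from the normalized biomass size
spectrum and the predator-prey body mass ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import PDOM, FlowNetwork, FlowNetworkError

__all__ = [
    "TrophicDecomposition",
    "trophic_positions",
    "mean_trophic_position",
    "trophic_pyramid",
    "transfer_efficiency_production",
    "transfer_efficiency_from_spectrum",
    "weighted_ppmr",
    "DEFAULT_PPMR_WEIGHTS",
    "size_spectrum_slope",
    "metabolic_activity",
    "fit_allometric_exponent",
    "system_residence_time",
    "diet_composition",
    "diet_stoichiometry",
    "restrict_chain",
]

#: Ingestion-share weights of the four grazing-chain PPMRs
#: (carnivore:herbivore, carnivore:omnivore, herbivore:well-edible autotroph,
#: herbivore:less-edible autotroph).
DEFAULT_PPMR_WEIGHTS = (0.1, 0.1, 0.4, 0.4)


@dataclass
class TrophicDecomposition:
    """Trophic position and fractional integer-level weights per node."""

    nodes: tuple
    tp: dict                 # node -> trophic position (float)
    levels: dict             # node -> {integer level k: weight p_i(k)}

    def level_matrix(self, max_level: int | None = None) -> tuple:
        ks = sorted({k for w in self.levels.values() for k in w})
        if max_level is not None:
            ks = [k for k in ks if k <= max_level]
        M = np.array([[self.levels[n].get(k, 0.0) for k in ks] for n in self.nodes])
        return ks, M


def _ingestion_fractions(net: FlowNetwork):
    """Row-stochastic diet-fraction matrix f[i, j] = share of i's ingestion from j."""
    intake = net.T.sum(axis=0)
    S = len(net.nodes)
    F = np.zeros((S, S))
    for i in range(S):
        if intake[i] > 0:
            F[i, :] = net.T[:, i] / intake[i]
    return F, intake


def trophic_positions(net: FlowNetwork, consumers: Sequence[str] | None = None,
                      tol: float = 1e-12, max_level: int = 500) -> TrophicDecomposition:
    """Flow-weighted trophic positions and fractional level weights.

    Basal assignment: the detritus pool (:data:`PDOM`) sits at position 0;
    nodes without any ingestion links are producers at position 1. Every
    other node solves TP_i = 1 + Σ_j f_ij TP_j with f_ij the fraction of i's
    ingestion taken from j; cycles (including cannibalistic self-loops) are
    handled by the linear solve. Level weights follow the recursion
    p_i(k) = Σ_j f_ij p_j(k−1), truncated once the unassigned mass is < tol.

    Passing ``consumers`` declares nodes that must have positive ingestion;
    a declared consumer without ingestion is an error.
    """
    F, intake = _ingestion_fractions(net)
    S = len(net.nodes)
    idx = {n: i for i, n in enumerate(net.nodes)}
    if consumers is not None:
        for c in consumers:
            if intake[idx[c]] <= 0:
                raise FlowNetworkError(f"consumer {c!r} has zero total ingestion")

    basal = np.zeros(S, dtype=bool)
    pdom = np.zeros(S, dtype=bool)
    for i, n in enumerate(net.nodes):
        if n == PDOM:
            pdom[i] = True
        elif intake[i] <= 0:
            basal[i] = True

    # TP: (I - F) tp = b, with b = 1 for everything except PDOM (whose row of
    # F is zero and whose b is 0). Producers have zero F rows, so tp = 1.
    A = np.eye(S) - F
    b = np.where(pdom, 0.0, 1.0)
    A[pdom, :] = 0.0
    A[pdom, pdom] = 1.0
    A[basal, :] = 0.0
    A[basal, basal] = 1.0
    try:
        tp = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        raise FlowNetworkError(
            "singular trophic system: closed consumer loop with no basal path"
        ) from None

    # Level weights by dynamic programming over k.
    levels: dict = {n: {} for n in net.nodes}
    prev = np.where(pdom, 1.0, 0.0)          # p(0)
    for i in np.nonzero(pdom)[0]:
        levels[net.nodes[i]][0] = 1.0
    assigned = prev.copy()
    k = 0
    while k < max_level:
        k += 1
        cur = F @ prev
        cur[basal] = 1.0 if k == 1 else 0.0
        cur[pdom] = 0.0
        for i in range(S):
            if cur[i] > 0:
                levels[net.nodes[i]][k] = levels[net.nodes[i]].get(k, 0.0) + float(cur[i])
        assigned += cur
        prev = cur
        if np.all(1.0 - assigned <= tol):
            break
    if np.any(1.0 - assigned > 1e-6):
        bad = net.nodes[int(np.argmin(assigned))]
        raise FlowNetworkError(
            f"trophic level weights for {bad!r} do not converge "
            "(closed consumer loop with no basal path?)"
        )
    # Distribute any tiny truncation remainder onto the last reached level so
    # that Σ_k p_i(k) = 1 holds to machine precision.
    for i, n in enumerate(net.nodes):
        rem = 1.0 - sum(levels[n].values())
        if levels[n] and abs(rem) > 0:
            kmax = max(levels[n])
            levels[n][kmax] += rem
    return TrophicDecomposition(net.nodes, {n: float(t) for n, t in zip(net.nodes, tp)}, levels)


def mean_trophic_position(dec: TrophicDecomposition, consumers: Sequence[str],
                          weights: Mapping[str, float] | None = None) -> float:
    """Average trophic position of a consumer set.

    ``weights`` are typically consumer biomasses; omit them for an unweighted
    mean. The default consumer set in the seasonal analysis is the grazing
    chain (HNF, Cil, Rot, HerbCru, CarnCru, Fish).
    """
    if not consumers:
        raise FlowNetworkError("empty consumer set")
    tps = np.array([dec.tp[c] for c in consumers])
    if weights is None:
        return float(tps.mean())
    w = np.array([float(weights[c]) for c in consumers])
    if w.sum() <= 0:
        raise FlowNetworkError("consumer weights sum to zero")
    return float((tps * w).sum() / w.sum())


def trophic_pyramid(dec: TrophicDecomposition, quantity: Mapping[str, float]) -> dict:
    """Distribute a per-node quantity (biomass or production) over integer levels.

    level_k = Σ_i quantity_i · p_i(k); the pyramid total equals the input
    total exactly.
    """
    pyramid: dict = {}
    for n in dec.nodes:
        q = float(quantity.get(n, 0.0))
        if q == 0.0:
            continue
        for k, w in dec.levels[n].items():
            pyramid[k] = pyramid.get(k, 0.0) + q * w
    return dict(sorted(pyramid.items()))


def transfer_efficiency_production(pyramid: Mapping[int, float],
                                   levels: Sequence[int] = (1, 2, 3),
                                   mean: str = "geometric") -> float:
    """Trophic transfer efficiency from a production pyramid.

    TE averages the production ratios P_{k+1}/P_k across the given levels;
    efficiencies compose multiplicatively, hence the geometric mean default
    (``mean="arithmetic"`` is available).
    """
    ratios = []
    for lo, hi in zip(levels[:-1], levels[1:]):
        p_lo = pyramid.get(lo, 0.0)
        p_hi = pyramid.get(hi, 0.0)
        if p_lo <= 0 or p_hi <= 0:
            raise FlowNetworkError(f"zero production at level {lo if p_lo <= 0 else hi}")
        ratios.append(p_hi / p_lo)
    r = np.asarray(ratios)
    if mean == "geometric":
        return float(np.exp(np.log(r).mean()))
    if mean == "arithmetic":
        return float(r.mean())
    raise ValueError(f"unknown mean type {mean!r}")


def transfer_efficiency_from_spectrum(sss: float, ppmr: float, a: float = 0.25) -> float:
    """Transfer efficiency from the size-spectrum slope and the PPMR.

    From B_{k+1}/B_k = TE·PPMR^a and the normalized-spectrum convention,
    TE = PPMR^(SSS + 1 − a), with ``a`` the magnitude of the allometric
    production exponent (default 0.25).
    """
    if ppmr <= 1:
        raise FlowNetworkError("PPMR must exceed 1")
    return float(ppmr ** (sss + 1.0 - a))


def weighted_ppmr(ppmrs: Sequence[float], weights: Sequence[float] = DEFAULT_PPMR_WEIGHTS) -> float:
    """Weighted geometric mean PPMR = Π ppmr_i^{w_i} with Σw_i = 1."""
    p = np.asarray(ppmrs, dtype=float)
    w = np.asarray(weights, dtype=float)
    if p.shape != w.shape:
        raise ValueError("ppmrs and weights differ in length")
    if (p <= 0).any():
        raise ValueError("PPMRs must be positive")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")
    return float(np.exp((w * np.log(p)).sum()))


def size_spectrum_slope(size_classes: Sequence[int], biomass: Sequence[float]) -> float:
    """Slope of the normalized biomass size spectrum.

    Size class m spans [2^m, 2^(m+1)) pgC (linear width 2^m); the biomass per
    class is normalized by that width and the slope is the OLS fit of
    log2(normalized biomass) against the class index m. Empty classes are
    dropped; a spectrum of equal biomass per class has slope −1 (Sheldon
    spectrum).
    """
    m = np.asarray(size_classes, dtype=float)
    b = np.asarray(biomass, dtype=float)
    if m.shape != b.shape:
        raise ValueError("size_classes and biomass differ in length")
    if len(set(m.tolist())) != m.size:
        raise ValueError("size classes must be distinct")
    if (b < 0).any():
        raise ValueError("biomass must be nonnegative")
    keep = b > 0
    if keep.sum() < 2:
        raise FlowNetworkError("need at least 2 non-empty size classes")
    y = np.log2(b[keep]) - m[keep]       # log2(B_m / 2^m)
    slope = np.polyfit(m[keep], y, 1)[0]
    return float(slope)


def metabolic_activity(production, biomass) -> tuple:
    """System and per-group mass-specific metabolic activity.

    Returns (P_tot/B_tot, per-group P_i/B_i vector) in d⁻¹; groups with zero
    biomass get NaN in the per-group vector.
    """
    p = np.asarray(production, dtype=float)
    b = np.asarray(biomass, dtype=float)
    if p.shape != b.shape:
        raise ValueError("production and biomass differ in length")
    if b.sum() <= 0:
        raise FlowNetworkError("total biomass must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        per_group = np.where(b > 0, p / b, np.nan)
    return float(p.sum() / b.sum()), per_group


def fit_allometric_exponent(pb_ratios, body_mass) -> float:
    """OLS exponent A of P/B ∝ M^A from per-group P/B ratios and body masses."""
    pb = np.asarray(pb_ratios, dtype=float)
    m = np.asarray(body_mass, dtype=float)
    keep = np.isfinite(pb) & (pb > 0) & (m > 0)
    if keep.sum() < 2:
        raise ValueError("need at least 2 groups with positive P/B and mass")
    return float(np.polyfit(np.log(m[keep]), np.log(pb[keep]), 1)[0])


def system_residence_time(net: FlowNetwork, biomass: Mapping[str, float]) -> float:
    """Mean residence time of the element in the system, in days.

    Operational stock-over-outflow definition: SRT = Σ_i B_i / Σ_i (E_i + R_i).
    Phosphorus networks carry no respiratory loss, so SRT_P reduces to
    stock/export.
    """
    stock = sum(float(biomass.get(n, 0.0)) for n in net.nodes)
    outflow = float(net.exports.sum() + net.respiration.sum())
    if outflow <= 0:
        raise FlowNetworkError("zero system outflow")
    return stock / outflow


def diet_composition(net: FlowNetwork, resource_classes: Mapping[str, str],
                     consumers: Sequence[str] | None = None) -> dict:
    """Per-consumer and pooled ingestion fractions by resource class.

    ``resource_classes`` maps resource nodes to a class label (e.g. autotroph,
    bacterial, animal); flows from unmapped resources (e.g. detritus) are
    ignored. Returns ``{"per_consumer": {consumer: {class: frac}},
    "pooled": {class: frac}}``; fractions sum to 1 per consumer.
    """
    if consumers is None:
        intake = net.T.sum(axis=0)
        consumers = [n for i, n in enumerate(net.nodes) if intake[i] > 0]
    per: dict = {}
    pooled: dict = {}
    for c in consumers:
        j = net.index(c)
        totals: dict = {}
        for i, r in enumerate(net.nodes):
            v = net.T[i, j]
            if v <= 0 or r not in resource_classes:
                continue
            cls = resource_classes[r]
            totals[cls] = totals.get(cls, 0.0) + v
        tot = sum(totals.values())
        if tot <= 0:
            raise FlowNetworkError(f"consumer {c!r} has zero classified ingestion")
        per[c] = {cls: v / tot for cls, v in totals.items()}
        for cls, v in totals.items():
            pooled[cls] = pooled.get(cls, 0.0) + v
    ptot = sum(pooled.values())
    return {"per_consumer": per,
            "pooled": {cls: v / ptot for cls, v in pooled.items()}}


def diet_stoichiometry(net_c: FlowNetwork, net_p: FlowNetwork,
                       consumers: Sequence[str] | None = None) -> dict:
    """Flow-weighted C:P ratio of each consumer's ingested diet (µgC/µgP)."""
    if net_c.nodes != net_p.nodes:
        raise FlowNetworkError("C and P networks have different node sets")
    if (net_c.T > 0).astype(int).tolist() != (net_p.T > 0).astype(int).tolist():
        raise FlowNetworkError("C and P networks have different link sets")
    intake_c = net_c.T.sum(axis=0)
    intake_p = net_p.T.sum(axis=0)
    if consumers is None:
        consumers = [n for i, n in enumerate(net_c.nodes) if intake_c[i] > 0]
    out = {}
    for c in consumers:
        j = net_c.index(c)
        if intake_p[j] <= 0:
            raise FlowNetworkError(f"consumer {c!r} has zero P ingestion")
        out[c] = float(intake_c[j] / intake_p[j])
    return out


def restrict_chain(net: FlowNetwork, drop: Sequence[str]) -> FlowNetwork:
    """Sub-network with the given nodes (and their flows) removed.

    Used to restrict pyramids and transfer efficiency to the grazing chain
    (dropping PDOM and bacteria) or to the detritus chain. The result is not
    mass-balanced; it only supplies ingestion fractions for the decomposition.
    """
    keep = [n for n in net.nodes if n not in set(drop)]
    idx = [net.index(n) for n in keep]
    sub = FlowNetwork.empty(net.element, net.phase, keep)
    sub.T = net.T[np.ix_(idx, idx)].copy()
    sub.imports = net.imports[idx].copy()
    sub.exports = net.exports[idx].copy()
    sub.respiration = net.respiration[idx].copy()
    sub.storage_in = net.storage_in[idx].copy()
    sub.storage_out = net.storage_out[idx].copy()
    return sub
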