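"""Per-phase orchestration: index series, phase statistics, composite index.

Runs every system-level succession index over a seasonal scenario (seven
phases of matched C/P flow networks plus guild biomass trajectories),
averages within phases, classifies each index's seasonal trend, normalizes
the four key indices (transfer efficiency, mass-specific metabolic activity,
functional diversity, weighted connectance) to [0, 1] and combines them into
the composite succession index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import PDOM, PHASES, FlowNetworkError, disaggregate_flows
from .diversity import eco_exergy, shannon_diversity, succession_rate
from .flowinfo import ascendency_suite, small_world_summary
from .synth import GROUPS, Scenario
from .trophic import (
    mean_trophic_position,
    restrict_chain,
    size_spectrum_slope,
    system_residence_time,
    transfer_efficiency_production,
    trophic_positions,
    trophic_pyramid,
    weighted_ppmr,
)

__all__ = [
    "IndexSeries",
    "PhaseStats",
    "phase_statistics",
    "minmax_normalize",
    "composite_index",
    "spearman_correlation",
    "classify_trend",
    "run_full_analysis",
    "GRAZING_CONSUMERS",
]

#: Consumer groups of the grazing chain used for the average trophic position.
GRAZING_CONSUMERS = ("HNF", "Cil", "Rot", "HerbCru", "CarnCru", "Fish")


@dataclass
class IndexSeries:
    """One named index with per-phase (or per-time) values and metadata."""

    name: str
    values: dict
    units: str = ""
    metadata: dict = field(default_factory=dict)

    def vector(self, keys: Sequence = PHASES) -> np.ndarray:
        return np.array([self.values[k] for k in keys], dtype=float)


@dataclass
class PhaseStats:
    phase_means: dict
    annual_mean: float
    annual_sd: float
    missing: tuple


def phase_statistics(phase_labels: Sequence[str], values: Sequence[float]) -> PhaseStats:
    """Within-phase arithmetic means and the annual mean ± sd across phases.

    The annual statistics are taken over the (up to 7) phase means, not over
    raw observations; empty phases are reported and excluded with a warning.
    """
    if len(phase_labels) != len(values):
        raise ValueError("labels and values differ in length")
    by_phase: dict = {ph: [] for ph in PHASES}
    for ph, v in zip(phase_labels, values):
        if ph not in by_phase:
            raise ValueError(f"unknown phase {ph!r}")
        by_phase[ph].append(float(v))
    means = {ph: float(np.mean(vs)) for ph, vs in by_phase.items() if vs}
    missing = tuple(ph for ph in PHASES if ph not in means)
    if missing:
        warnings.warn(f"phases without observations: {missing}", stacklevel=2)
    if not means:
        raise ValueError("no observations in any phase")
    arr = np.array([means[ph] for ph in PHASES if ph in means])
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return PhaseStats(means, float(arr.mean()), sd, missing)


def minmax_normalize(values) -> np.ndarray:
    """Rescale to [0, 1] via (V − min V) / (max V − min V)."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("degenerate range: max equals min")
    return (v - lo) / (hi - lo)


def composite_index(te, pb, hbio, cw=None, include_cw: bool = True) -> np.ndarray:
    """Composite succession index per phase.

    The arithmetic mean of the min-max-normalized transfer efficiency,
    functional diversity, weighted connectance and the *inverted* normalized
    metabolic activity (1 − P_tot/B_tot after normalization), so that every
    component increases with successional progress. ``include_cw=False``
    drops the connectance term (for the flow-data-free variant).
    """
    parts = [minmax_normalize(te), 1.0 - minmax_normalize(pb), minmax_normalize(hbio)]
    if include_cw:
        if cw is None:
            raise ValueError("include_cw=True requires the C_w vector")
        parts.append(minmax_normalize(cw))
    return np.mean(np.stack(parts), axis=0)


def spearman_correlation(x, y) -> tuple:
    """Spearman rank correlation (r_S, two-sided p) between two index series."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise ValueError("series differ in length")
    if xv.size < 4:
        raise ValueError("need at least 4 paired points")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("constant series have undefined rank correlation")
    r, p = stats.spearmanr(xv, yv)
    return float(r), float(p)


def classify_trend(values, phases: Sequence[int] = (2, 3, 4, 5, 6),
                   rel_threshold: float = 0.05) -> str:
    """Classify the growing-season trend of a 7-phase index series.

    Operates on the biotically driven phases (2–6 by default). Classes:
    ``const`` (relative range below threshold), ``up``/``down`` (monotone),
    ``uni`` (one sign change of the phase-to-phase differences),
    ``bi`` (two or more).
    """
    v = np.asarray(values, dtype=float)
    if v.size != len(PHASES):
        raise ValueError("expected one value per phase")
    sel = v[[p - 1 for p in phases]]
    rng = sel.max() - sel.min()
    scale = np.max(np.abs(sel))
    if scale == 0 or rng <= rel_threshold * scale:
        return "const"
    diffs = np.diff(sel)
    signs = [np.sign(d) for d in diffs if abs(d) > rel_threshold * rng]
    if not signs:
        return "const"
    changes = sum(1 for a, b in zip(signs[:-1], signs[1:]) if a != b)
    if changes == 0:
        return "up" if signs[0] > 0 else "down"
    if changes == 1:
        return "uni"
    return "bi"


# ---------------------------------------------------------------------------
# Full analysis over a scenario
# ---------------------------------------------------------------------------

def _group_biomass(scn: Scenario, phase: str) -> dict:
    """Phase-mean biomass pooled by functional group (plankton + fish)."""
    labels = scn.biomass.phase_labels()
    rows = [i for i, ph in enumerate(labels) if ph == phase]
    if not rows:
        raise FlowNetworkError(f"no biomass snapshots in phase {phase!r}")
    mean_b = scn.biomass.B[rows].mean(axis=0)
    out = {g: 0.0 for g in GROUPS}
    for gid, b in zip(scn.biomass.guild_ids, mean_b):
        out[scn.topology.guilds[gid].group] += float(b)
    out["Fish"] += scn.fish_biomass[phase]
    return out


def _phase_mean_guild_biomass(scn: Scenario, phase: str) -> np.ndarray:
    labels = scn.biomass.phase_labels()
    rows = [i for i, ph in enumerate(labels) if ph == phase]
    return scn.biomass.B[rows].mean(axis=0)


def _ppmr_components(scn: Scenario, phase: str) -> list:
    """The four grazing-chain PPMRs from biomass-weighted mean body masses.

    Dietary groups: carnivores vs herbivores, carnivores vs omnivores,
    herbivores vs well-edible autotrophs, herbivores vs less-edible
    autotrophs. Body mass per guild is 2^size_class pgC.
    """
    guilds = scn.topology.guilds
    b = _phase_mean_guild_biomass(scn, phase)
    mass = {g.id: 2.0 ** g.size_class for g in guilds}

    def mean_mass(ids):
        ids = [i for i in ids if i in scn.biomass.guild_ids]
        w = np.array([b[scn.biomass.guild_ids.index(i)] for i in ids])
        m = np.array([mass[i] for i in ids])
        if w.sum() <= 0:
            return float(m.mean())
        return float((w * m).sum() / w.sum())

    herb = [g.id for g in guilds if g.dietary_group == "Herb"]
    omni = [g.id for g in guilds if g.dietary_group == "Omni"]
    carn = [g.id for g in guilds if g.dietary_group == "Carn" and g.id <= 20]
    auto_well = [g.id for g in guilds
                 if g.dietary_group == "Auto" and g.edibility == "well-edible"]
    auto_less = [g.id for g in guilds
                 if g.dietary_group == "Auto" and g.edibility == "less-edible"]
    m_herb = mean_mass(herb)
    m_carn = mean_mass(carn)
    return [
        m_carn / m_herb,
        m_carn / mean_mass(omni),
        m_herb / mean_mass(auto_well),
        m_herb / mean_mass(auto_less),
    ]


_REPORT_ROWS = (
    ("H_bio", "Functional diversity", "bits"),
    ("sigma", "Succession rate", "d-1"),
    ("C:P", "Food quality (phytoplankton C:P)", "ugC/ugP"),
    ("SRT_C", "System residence time C", "d"),
    ("SRT_P", "System residence time P", "d"),
    ("TP", "Avg. trophic position", "-"),
    ("P/B", "Mass-specific metabolic activity", "d-1"),
    ("PPMR", "Predator-prey body mass ratio", "-"),
    ("TE", "Trophic transfer efficiency", "-"),
    ("C_w", "Weighted connectance", "-"),
    ("H_flow", "Shannon flow diversity", "bits"),
    ("D_norm", "Weighted char. path length", "-"),
    ("Q_norm", "Weighted cluster coefficient", "-"),
    ("Asc_rel", "Relative ascendency", "-"),
    ("Ex_sp", "Specific eco-exergy", "Ex/gC"),
)


def compute_index_series(scn: Scenario) -> dict:
    """Every system-level index, per phase, as :class:`IndexSeries` objects."""
    missing = [f for f in ("networks", "production", "biomass", "fish_biomass")
               if getattr(scn, f, None) is None]
    if missing:
        raise FlowNetworkError(f"scenario missing inputs: {missing}")

    series: dict = {key: {} for key, _, _ in _REPORT_ROWS}
    guilds = scn.topology.guilds
    labels = scn.biomass.phase_labels()
    rel = scn.biomass.relative()

    # snapshot-level indices -> phase means
    hbio_labels, hbio_vals = [], []
    sss_labels, sss_vals = [], []
    sig_labels, sig_vals = [], []
    size_class = {g.id: g.size_class for g in guilds}
    for t in range(len(scn.biomass.times)):
        hbio_labels.append(labels[t])
        hbio_vals.append(shannon_diversity(scn.biomass.B[t]))
        classes: dict = {}
        for gid, b in zip(scn.biomass.guild_ids, scn.biomass.B[t]):
            classes[size_class[gid]] = classes.get(size_class[gid], 0.0) + b
        sss_labels.append(labels[t])
        sss_vals.append(size_spectrum_slope(list(classes), list(classes.values())))
        if t > 0:
            dt = scn.biomass.times[t] - scn.biomass.times[t - 1]
            if dt > 0:
                sig_labels.append(labels[t])
                sig_vals.append(succession_rate(rel[t - 1], rel[t], dt))
    hbio_stats = phase_statistics(hbio_labels, hbio_vals)
    sss_stats = phase_statistics(sss_labels, sss_vals)
    sig_stats = phase_statistics(sig_labels, sig_vals)

    sss_series = {}
    for phase in PHASES:
        series["H_bio"][phase] = hbio_stats.phase_means[phase]
        series["sigma"][phase] = sig_stats.phase_means[phase]
        sss_series[phase] = sss_stats.phase_means[phase]

        net_c = scn.networks[phase]["C"]
        net_p = scn.networks[phase]["P"]
        prod = scn.production[phase]
        gb = _group_biomass(scn, phase)

        # phytoplankton C:P from the matched internal flows out of Phy
        i_phy = net_c.index("Phy")
        c_out = net_c.T[i_phy].sum()
        p_out = net_p.T[i_phy].sum()
        series["C:P"][phase] = c_out / p_out

        series["SRT_C"][phase] = system_residence_time(net_c, gb)
        stock_p = {g: gb[g] / scn.cp[phase][g] for g in GROUPS}
        series["SRT_P"][phase] = system_residence_time(net_p, stock_p)

        dec = trophic_positions(net_c)
        series["TP"][phase] = mean_trophic_position(dec, GRAZING_CONSUMERS, gb)

        plankton = [g for g in GROUPS if g != "Fish"]
        p_tot = sum(prod[g] for g in plankton)
        b_tot = sum(gb[g] for g in plankton)
        series["P/B"][phase] = p_tot / b_tot

        series["PPMR"][phase] = weighted_ppmr(
            _ppmr_components(scn, phase), scn.topology.ppmr_weights
        )

        grazing = restrict_chain(net_c, (PDOM, "Bac"))
        gdec = trophic_positions(grazing)
        pyramid = trophic_pyramid(gdec, {g: prod[g] for g in GROUPS if g != "Bac"})
        series["TE"][phase] = transfer_efficiency_production(pyramid)

        info = ascendency_suite(net_c)
        series["C_w"][phase] = info.c_w
        series["H_flow"][phase] = info.h_flow
        series["Asc_rel"][phase] = info.asc_rel

        net24 = disaggregate_flows(net_c, guilds)
        sw = small_world_summary(net24)
        series["D_norm"][phase] = sw.d_norm
        series["Q_norm"][phase] = sw.q_norm

        groups20 = [guilds[gid].group for gid in scn.biomass.guild_ids]
        bio = list(_phase_mean_guild_biomass(scn, phase)) + [scn.fish_biomass[phase]]
        _, ex_sp = eco_exergy(bio, groups20 + ["Fish"], scn.topology.exergy_weights)
        series["Ex_sp"][phase] = ex_sp

    units = {key: u for key, _, u in _REPORT_ROWS}
    names = {key: n for key, n, _ in _REPORT_ROWS}
    out = {
        key: IndexSeries(names[key], vals, units[key],
                         metadata={"key": key, "winter_phases_flagged": True})
        for key, vals in series.items()
    }
    out["SSS"] = IndexSeries("Size spectrum slope", sss_series, "-",
                             metadata={"key": "SSS"})
    return out


def run_full_analysis(scn: Scenario) -> pd.DataFrame:
    """The seasonal succession report: one row per system-level index.

    Columns: the per-phase means, the trend class over phases 2–6, the
    early (phases 2/3), intermediate (phase 4) and late (phases 5/6) values,
    and the annual mean ± sd across the 7 phase means. Winter phases
    (1 and 7) are included but reflect abiotic forcing rather than biotic
    succession.
    """
    series = compute_index_series(scn)
    rows = []
    for key, name, unit in _REPORT_ROWS:
        s = series[key]
        v = s.vector(PHASES)
        rows.append({
            "index": name,
            "abbr": key,
            "trend": classify_trend(v),
            "early": f"{v[1]:.3g}/{v[2]:.3g}",
            "intermediate": float(v[3]),
            "late": f"{v[4]:.3g}/{v[5]:.3g}",
            "annual_mean": float(v.mean()),
            "annual_sd": float(v.std(ddof=1)),
            "units": unit,
            **{f"phase_{i + 1}": float(x) for i, x in enumerate(v)},
        })
    return pd.DataFrame(rows)
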