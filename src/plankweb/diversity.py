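"""Biomass-based indices: functional diversity, succession rate, eco-exergy.

Functional diversity H_bio is the Shannon entropy (bits by default) of the
relative biomass distribution across plankton guilds. The succession rate σ
is the per-day summed absolute change of that distribution between two
snapshots. Eco-exergy weights each group's biomass with a proteome-information
equivalence factor β; the specific eco-exergy is eco-exergy per unit biomass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ExergyWeights",
    "DEFAULT_BETA_BY_GROUP",
    "shannon_diversity",
    "succession_rate",
    "eco_exergy",
]

#: Eco-exergy equivalence factors β per major functional group. Unicellular
#: zooplankton (HNF, ciliates) share one factor; crustaceans share one.
DEFAULT_BETA_BY_GROUP: dict = {
    "Phy": 20.0,
    "Bac": 8.5,
    "HNF": 39.0,
    "Cil": 39.0,
    "Rot": 163.0,
    "HerbCru": 232.0,
    "CarnCru": 232.0,
    "Fish": 499.0,
}

#: Reference energy content of detritus (metadata; Ex is reported in
#: g detritus equivalents per area).
DETRITUS_REFERENCE_KJ_PER_G = 18.7


@dataclass(frozen=True)
class ExergyWeights:
    """β equivalence factor per group plus the detritus reference energy."""

    beta_by_group: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BETA_BY_GROUP)
    )
    detritus_kj_per_g: float = DETRITUS_REFERENCE_KJ_PER_G

    def __post_init__(self):
        for g, b in self.beta_by_group.items():
            if b < 1:
                raise ValueError(f"beta for {g!r} must be >= 1, got {b}")

    def beta_for(self, groups: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.beta_by_group[g] for g in groups], dtype=float)
        except KeyError as exc:
            raise ValueError(f"no beta factor for group {exc.args[0]!r}") from None


def shannon_diversity(biomass, base: float = 2.0) -> float:
    """Shannon diversity H of a nonnegative biomass vector, in log-``base`` units.

    H = −Σ b_i log(b_i) over relative biomasses b_i = B_i / B_tot, with the
    usual convention 0·log 0 = 0. Invariant to rescaling total biomass.
    """
    b = np.asarray(biomass, dtype=float)
    if (b < 0).any():
        raise ValueError("biomass must be nonnegative")
    tot = b.sum()
    if tot <= 0:
        raise ValueError("total biomass must be positive")
    p = b[b > 0] / tot
    p = p[p > 0]  # guard underflow of extreme biomass ratios
    return float(-(p * np.log(p)).sum() / np.log(base))


def succession_rate(b1, b2, dt: float = 1.0) -> float:
    """Succession rate σ = Σ_i |b2_i − b1_i| / dt (d⁻¹).

    ``b1`` and ``b2`` are relative-biomass vectors over the same guild set
    (each summing to 1); ``dt`` is the time step in days. σ ranges from 0
    (no compositional change) to 2/dt (complete guild replacement).
    """
    v1 = np.asarray(b1, dtype=float)
    v2 = np.asarray(b2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("mismatched guild sets")
    if dt <= 0:
        raise ValueError("dt must be positive")
    for name, v in (("b1", v1), ("b2", v2)):
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} must sum to 1 (got {v.sum()!r})")
    return float(np.abs(v2 - v1).sum() / dt)


def eco_exergy(biomass, groups: Sequence[str],
               weights: ExergyWeights | None = None) -> tuple:
    """Eco-exergy Ex = Σ β_i B_i and specific eco-exergy Ex_sp = Ex / B_tot.

    ``biomass`` is per guild (or pooled group); ``groups`` gives each entry's
    functional group so the matching β applies. With B in gC m⁻², Ex is in
    g detritus equivalents m⁻². For an all-zero community Ex = 0 and Ex_sp is
    returned as NaN (undefined).
    """
    if weights is None:
        weights = ExergyWeights()
    b = np.asarray(biomass, dtype=float)
    if (b < 0).any():
        raise ValueError("biomass must be nonnegative")
    if len(groups) != b.size:
        raise ValueError("biomass and groups differ in length")
    beta = weights.beta_for(groups)
    ex = float((beta * b).sum())
    tot = b.sum()
    ex_sp = float(ex / tot) if tot > 0 else float("nan")
    return ex, ex_sp
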