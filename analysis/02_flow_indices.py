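#!/usr/bin/env python
"""Information-theoretic and small-world indices of every phase network.

Recomputes the scenario of 01_generate_scenario.py (same seed) and tabulates,
per phase: TST, flow diversity, AMI, ascendency family, weighted link density
and connectance on the 8-group web, and the weighted small-world metrics on
the uniformly disaggregated 24-guild web. Writes results/flow_indices.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from plankweb import (
    PHASES,
    ScenarioConfig,
    ascendency_suite,
    disaggregate_flows,
    generate_seasonal_scenario,
    small_world_summary,
)

SEED = 42
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> int:
    scn = generate_seasonal_scenario(ScenarioConfig(seed=SEED))
    rows = []
    for ph in PHASES:
        net = scn.networks[ph]["C"]
        info = ascendency_suite(net)
        net24 = disaggregate_flows(net, scn.topology.guilds)
        sw = small_world_summary(net24)
        rows.append({
            "phase": ph, "TST": info.tst, "H_flow": info.h_flow,
            "AMI": info.ami, "Phi": info.phi, "Asc": info.asc,
            "K_dev": info.k_dev, "Asc_rel": info.asc_rel,
            "fitness": info.fitness, "Conn_w": info.conn_w, "C_w": info.c_w,
            "D": sw.d, "D_norm": sw.d_norm, "Q": sw.q, "Q_norm": sw.q_norm,
        })
    df = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "flow_indices.csv", index=False)
    with pd.option_context("display.width", 200, "display.float_format",
                           lambda v: f"{v:.4g}"):
        print(df.to_string(index=False))
    print("\nGrowing-season pattern: C_w rises "
          f"({df.C_w.iloc[1]:.3f} -> {df.C_w.iloc[5]:.3f}) while Asc_rel falls "
          f"({df.Asc_rel.iloc[1]:.3f} -> {df.Asc_rel.iloc[5]:.3f}); "
          f"D_norm is nearly constant (sd {df.D_norm.std():.2g}).")
    return 0


if __name__ == "__main__":
    sys.exit(main())
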