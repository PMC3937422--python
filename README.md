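# plankweb

System-level indices of seasonal plankton succession on quantified food webs.

Seasonal plankton succession in temperate lakes is a natural model of
secondary succession: in a few months the pelagic community passes from a
spring bloom of small, fast-growing algae, through a clear-water phase
dominated by a keystone herbivorous crustacean, to a diverse late-summer and
autumn community. Whether that progression is *quantifiable at the system
level* — and which indices capture it — is a question that cuts across
ecosystem theory, metabolic theory, food-web theory, information theory and
thermodynamics. `plankweb` implements the full set of candidate indices as a
tested pipeline over mass-balanced carbon/phosphorus flow networks, for
ecologists who want to benchmark successional progress in their own flow
data or probe the behaviour of these indices on controlled synthetic webs.

## The indices

Biomass-based — functional diversity `H_bio = −Σ b_i log₂ b_i` over relative
guild biomasses; succession rate `σ = Σ|Δb_i|/Δt`; eco-exergy
`Ex = Σ β_i B_i` with proteome-information equivalence factors β (bacteria
8.5 … fish 499) and specific eco-exergy `Ex_sp = Ex/B_tot`.

Size- and flow-based trophic structure — flow-weighted trophic positions
`TP_i = 1 + Σ_j f_ij TP_j` (producers at 1, detritus at 0) with fractional
level weights, biomass/production pyramids, trophic transfer efficiency `TE`
as the geometric-mean production ratio across levels 1–3 of the grazing
chain or via `TE = PPMR^(SSS+1−A)` from the normalized biomass size-spectrum
slope `SSS` and the weighted predator–prey body-mass ratio `PPMR`;
mass-specific metabolic activity `P_tot/B_tot`; system residence times
`SRT = stock/outflow`; diet composition and diet C:P.

Information-theoretic — on the flow multiset `T_ij` with total throughput
`TST`: flow diversity `H_flow`, average mutual information `AMI`, ascendency
`Asc = TST·AMI`, development capacity `K_dev = TST·H_flow`, relative
ascendency `Asc_rel = AMI/H_flow`, fitness `F = −Asc_rel ln Asc_rel`
(maximal at 1/e), and the weighted connectance
`C_w = 2^(Φ/2)/S` with `Φ = H_flow − AMI` — the "effective links per node"
normalized by web size, which reduces exactly to binary link density for
perfectly even flows.

Weighted small-world metrics — characteristic path length `D` (normalized by
the random-graph expectation `ln S / ln Conn_bin`) and the flow-weighted
clustering coefficient `Q` (normalized by binary connectance `C_bin = L/S²`).

The pipeline averages every index per seasonal phase (7-phase standardized
axis), classifies trends, and combines the four key indices (`TE`,
`P_tot/B_tot` inverted, `H_bio`, `C_w`) into a min-max-normalized composite
succession index.

Because field-measured, phase-wise flow matrices are not distributable with
the package, a first-class synthetic generator (`plankweb.synth`) produces
mass-balanced C/P networks on the shipped 24-guild / 8-group lake topology
and guild biomass trajectories with controllable evenness, reproducing the
seasonal structure the indices are meant to detect (see `docs/methods.md`).

## Worked example

```python
from plankweb import (FlowNetwork, ascendency_suite, eco_exergy,
                      shannon_diversity, validate_mass_balance)

net = FlowNetwork.empty("C", "Summer", ("Phy", "Herb", "Carn", "PDOM"))
for (a, b), v in {("Phy", "Herb"): 60.0, ("Herb", "Carn"): 15.0,
                  ("Phy", "PDOM"): 15.0, ("Herb", "PDOM"): 15.0,
                  ("Carn", "PDOM"): 5.0}.items():
    net.T[net.index(a), net.index(b)] = v
net.imports[net.index("Phy")] = 100.0       # primary production
net.respiration[:] = [25.0, 30.0, 10.0, 0.0]
net.exports[net.index("PDOM")] = 35.0       # sedimentation

print(validate_mass_balance(net, 1e-9).passed)
info = ascendency_suite(net)
print(f"TST={info.tst:.1f}  H_flow={info.h_flow:.3f} bits  "
      f"AMI={info.ami:.3f} bits  Asc_rel={info.asc_rel:.3f}  C_w={info.c_w:.3f}")
print(f"H_bio={shannon_diversity([50.0, 30.0, 20.0]):.3f} bits")
print(eco_exergy([50.0, 30.0, 20.0], ["Phy", "HerbCru", "Fish"]))
```

prints

```
True
TST=310.0  H_flow=2.849 bits  AMI=1.609 bits  Asc_rel=0.565  C_w=0.382
H_bio=1.485 bits
(17940.0, 179.4)
```

The toy web is perfectly balanced; of its 2.85 bits of flow-pattern
uncertainty, 1.61 bits are resolved by knowing each flow's source
(`Asc_rel = 0.565`: a strongly channelled, early-succession-like web);
`C_w = 0.382` says the flows behave like ~1.5 effective feeding links per
node on this 4-node web. The three-pool community holds 17 940 g detritus
equivalents of eco-exergy, 179.4 per unit biomass — between the crustacean
(232) and phytoplankton (20) equivalence factors, pulled up by the fish pool.

## The analysis

Numbered drivers under `analysis/` run the full study on a synthetic year
(seed 42) and write their tables under `results/`:

1. `01_generate_scenario.py` — generate and write the per-phase C/P networks
   (machine-precision mass balance) and the biomass series.
2. `02_flow_indices.py` — TST, `H_flow`, `AMI`, ascendency family, `C_w`,
   and the small-world metrics per phase: the weighted connectance rises
   across the growing season while relative ascendency falls, and `D_norm`
   stays constant.
3. `03_succession_report.py` — the 15-row seasonal report with trend
   classes, the composite succession index (which rises monotonically from
   early spring to autumn), and Spearman correlations among the key indices.

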