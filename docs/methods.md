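# Methods

`plankweb` computes system-level indices of seasonal plankton succession on
mass-balanced food-web flow networks, and generates synthetic seasonal
scenarios so the whole pipeline is exercisable without field data. This note
documents the model conventions, the parameters that matter, what the
generator does and does not emulate, and the numerical choices made where the
definitions in the literature are ambiguous.

## Flow networks and mass balance

A `FlowNetwork` holds, for one element (C or P) and one seasonal phase, the
matrix of internal flows `T[i, j]` (µg element m⁻² d⁻¹ from node *i* to node
*j*, feeding and detrital links alike), plus per-node boundary flows:
imports `I`, exports `E`, respiration `R`, and two nonnegative biomass-storage
terms `TI` (flow drawn from declining stock) and `TE` (flow into accumulating
stock). Storage is never a signed quantity. The steady-state budget per node
is

    Σ_j T_ji + I_i + TI_i  =  Σ_k T_ik + E_i + TE_i + R_i

`validate_mass_balance` reports the residual of this identity per node and
passes a node iff `|residual| ≤ rtol · max(inputs, outputs)`. The default
tolerance is 1e-6; synthetic networks close their budgets explicitly and pass
at 1e-9 (residuals are at float rounding, ~1e-16 relative). Imported
empirical networks typically balance only approximately; a looser rtol
(≈0.05) is then appropriate and should be stated with the results.
Phosphorus networks carry `R = 0`: there is no respiratory phosphorus loss.

**Total system throughput.** `TST` is the sum of the selected flow multiset.
Two selections are used throughout: `trophic_detrital` (internal flows only)
and `full_throughput` (internal flows plus each boundary flow counted once).
Some authors instead define TST as the sum of node throughputs; with balanced
networks the two differ only in how boundary flows are attributed, and the
flow-multiset convention is used here because it extends unambiguously to
both flow selections.

**Resolution changes.** Aggregation sums flows within supernode pairs
(intra-group flows become self-loops, which are legal — cannibalistic
self-loops exist in the topology) and conserves TST and every boundary total
exactly. Disaggregation spreads each group-level flow uniformly over the
guild-level feeding links it covers; re-aggregating reproduces the group
network exactly, but the disaggregated network is not claimed to balance per
guild — it supplies ingestion weights for guild-resolution network metrics
only. Uniform splitting is the maximum-entropy choice when guild-level flow
magnitudes are unmeasured; its known cost is that keystone-driven flow
concentration *within* a group is invisible at guild resolution (see
Limitations).

## Biomass-based indices

* **Functional diversity** `H_bio = −Σ b_i log2 b_i` over relative guild
  biomasses, in bits (base configurable). Range `[0, log2 S]`, invariant to
  total-biomass rescaling.
* **Succession rate** `σ = Σ_i |b_i(t2) − b_i(t1)| / Δt` (d⁻¹): the summed
  absolute change of the relative-biomass composition per day. The exact
  historical variant of this rate statistic differs between authors
  (absolute-sum vs root-sum-square); the absolute-sum form is used because
  its units and range (0 to 2/Δt, the latter at complete community
  replacement) match the reported seasonal magnitudes, and the variant name
  is recorded in output metadata so an alternative can be added without
  breaking the interface.
* **Eco-exergy** `Ex = Σ β_i B_i` (g detritus equivalents per area, with B in
  gC; reference energy 18.7 kJ/g detritus), `Ex_sp = Ex / B_tot`. The β
  equivalence factors express proteome information content per unit biomass:
  bacteria 8.5, phytoplankton 20, unicellular zooplankton (HNF, ciliates) 39,
  rotifers 163, crustaceans 232, fish 499. Adult fish enter as one pooled
  biomass with β = 499, giving S = 21 pools (20 plankton guilds + fish).
  `Ex_sp` is bounded by the extreme β values; for zero total biomass `Ex = 0`
  and `Ex_sp` is NaN.

## Trophic structure

Trophic positions are flow-weighted: PDOM (the dead-organic-matter pool) sits
at position 0, nodes without ingestion links (producers) at 1, and every
consumer solves `TP_i = 1 + Σ_j f_ij TP_j` with `f_ij` the fraction of *i*'s
ingestion taken from resource *j*. Bacteria, feeding purely on PDOM, come out
at position 1 without special-casing. Cycles (omnivory loops, cannibalistic
self-loops) are handled by the linear solve; a closed consumer loop with no
basal path is singular and raises. Fractional level weights follow
`p_i(k) = Σ_j f_ij p_j(k−1)`, truncated once the unassigned probability mass
falls below 1e-12 (cycle contributions shrink geometrically); the tiny
truncation remainder is folded into the last reached level so `Σ_k p_i(k) = 1`
holds exactly, and `Σ_k k·p_i(k) = TP_i` to 1e-9 (tested against an explicit
all-paths expansion oracle on small webs).

* **Pyramids**: `level_k = Σ_i quantity_i · p_i(k)` distributes biomass or
  production over integer levels; totals are conserved exactly. Grazing-chain
  pyramids are computed on the sub-network with PDOM and bacteria removed
  (detritus chain: the complementary restriction), so that level 1 of the
  grazing chain is primary production.
* **Transfer efficiency** from production: the geometric mean of
  `P_2/P_1` and `P_3/P_2` (efficiencies compose multiplicatively; an
  arithmetic-mean flag exists). From the size spectrum:
  `TE = PPMR^(SSS + 1 − A)`, derived from `B_{k+1}/B_k = TE · PPMR^A` under
  the normalized-spectrum convention, with `A = 0.25` the magnitude of the
  allometric production exponent (configurable). The two routes agree exactly
  on communities constructed to satisfy the generating law (tested).
* **PPMR**: weighted geometric mean of the four grazing-chain ratios
  (carnivore:herbivore, carnivore:omnivore, herbivore:well-edible autotroph,
  herbivore:less-edible autotroph) with ingestion-share weights
  (0.1, 0.1, 0.4, 0.4).
* **Size spectrum**: class *m* spans `[2^m, 2^{m+1})` pgC; class biomass is
  normalized by the linear width `2^m` and the slope (SSS) is the OLS fit of
  `log2(B_m / 2^m)` on *m*. Empty classes are dropped, not imputed. Equal
  biomass per logarithmic class (Sheldon spectrum) gives SSS = −1 exactly.
* **Residence times**: the operational stock-over-outflow definition
  `SRT = Σ B_i / Σ (E_i + R_i)` in days; for P networks this reduces to
  stock/export. Field studies often adopt SRT values from independent tracer
  work; outputs here are labelled as the stock/outflow estimate.
* **Diet composition and quality**: per-consumer ingestion fractions by
  resource class (herbivory/bacterivory/carnivory), computed separately per
  element; diet C:P as the flow-weighted ratio of C to P ingestion.

## Flow-information indices

All entropy-type indices treat the selected flow multiset as a joint
distribution over (source, sink) endpoints; boundary flows enter with virtual
endpoint labels when the full-throughput selection is active.

* `H_flow = −Σ (T_ij/TST) log2 (T_ij/TST)` — flow diversity (evenness).
* `AMI = Σ (T_ij/TST) log2 (T_ij·TST / (T_i· T_·j))` — source–sink coupling.
* `Φ = H_flow − AMI` — conditional entropy / relative overhead.
* `Asc = TST·AMI`, `K_dev = TST·H_flow`, overhead `L_over = K_dev − Asc`,
  `Asc_rel = AMI/H_flow`, fitness `F = −Asc_rel·ln Asc_rel` (k = 1; F is 0 at
  both boundaries by continuity and maximal at `Asc_rel = 1/e ≈ 0.36`).
* `Conn_w = base^(Φ/2)` — effective links per node — and `C_w = Conn_w / S`
  with S the number of nodes touched by the selected flows.

Flow-set defaults: the ascendency family uses `full_throughput`; the
connectance pair uses `trophic_detrital`, since connectance by definition
counts feeding links only. Both are selectable.

**Base consistency.** Entropies are in bits, and the link-density exponent
uses the same base (`Conn_w = 2^(Φ/2)`). Published formulations sometimes mix
`e^(0.5Φ)` with bit-valued entropies; keeping one base throughout is what
makes the identity `Conn_w = L/S` exact for perfectly even flows on k-regular
webs (tested), and the base is a single configurable parameter.

## Weighted small-world metrics

Computed on the symmetrized web (`w_ij = T_ij + T_ji`, self-loops dropped):
two guilds are neighbours if either feeds on the other, the reading under
which intraguild predation creates triangles.

* **Characteristic path length** `D`: mean hop distance over reachable
  unordered pairs; `D_norm = D / (ln S / ln Conn_bin)` with
  `Conn_bin = L/S` of the realized directed binary web (normalization
  requires `Conn_bin > 1`). The published definition selects, per pair, the
  path maximizing the summed relative flow strength
  `f_ij = w_ij / max(s_i, s_j)`; taken globally that rule is degenerate
  (longer paths accumulate more strength, contradicting the D = 1 value of a
  complete uniform web), so flow strengths select *which* minimal-hop path
  couples a pair — exposed as `strongest_shortest_path` — while the distance
  is the hop count. A consequence worth stating: on a fixed topology `D` is
  the binary path length, which is exactly why this index barely moves
  seasonally while the flow-weighted clustering does.
* **Clustering** `q_i = [Σ over ordered neighbour pairs (j,k), j–k edge
  present, of (w_ij + w_ik)/2] / (s_i (K_i − 1))` — the flow-weighted triplet
  formula (node strength `s_i`, degree `K_i`; degree-<2 nodes contribute 0;
  self-loops never close triangles). `Q` is the node mean, `Q_norm = Q/C_bin`
  with `C_bin = L/S²`. `Q ∈ [0, 1]`; both metrics are checked against
  exhaustive triple/path enumeration on all small webs.
* A `directed=True` flag provides directed path lengths; clustering is
  defined on the symmetrized web only.

## Pipeline conventions

Phase means are arithmetic means of within-phase observations; annual
statistics are mean ± sd (ddof = 1) across the seven phase means. Min-max
normalization maps each index's phase vector onto [0, 1]; the composite
succession index is the arithmetic mean of normalized TE, `1 −` normalized
`P_tot/B_tot`, normalized `H_bio` and (optionally) normalized `C_w`, making
it invariant to affine rescaling of any input. Trend classes over phases 2–6
(the biotically driven growing season): relative range < 5 % → `const`;
otherwise sign changes of consecutive phase differences (differences below
5 % of the range are ignored): 0 → `up`/`down`, 1 → `uni`, ≥ 2 → `bi`. These
thresholds are declared, tunable conventions — descriptive labels, not
claims about any particular historical labelling rule. Winter phases are
reported but flagged as abiotically forced. Spearman correlations use
mid-ranks and the two-sided t approximation (scipy).

## Topology fixture

The shipped 24-guild table (six phytoplankton guilds, bacteria, HNF, five
ciliate guilds, four rotifer guilds, herbivorous crustaceans, two carnivorous
crustacean guilds, four fish guilds) carries size classes (log2 body mass in
pgC, from −6 for bacteria to 46 for piscivorous fish), diets, edibility tags
and the group/compartment/dietary-group memberships. Its diets enumerate 107
guild–guild feeding links plus the PDOM uptake of the bacteria (108 links
total; published counts for this web differ by one, reflecting revisions
between source datasets). The 8-group web has 25 trophic links — including
the cannibalistic CarnCru self-loop — and 7 detrital links (every group
except bacteria releases to PDOM). The guild table and the group link list
come from different measurement campaigns and are not perfectly nested (the
group web omits an HNF→CarnCru and a Fish→Fish link that the guild diets
imply); the group web is authoritative for flow generation, and
disaggregation uses only guild links compatible with it, which makes
`aggregate(disaggregate(net8)) = net8` exact.

## The synthetic seasonal generator

The generator defines the study conditions; it emulates the canonical
seasonal succession of a temperate, deep, meso-/eutrophic lake:

1. **Diet fractions** of each consumer over its group-level resources are
   symmetric Dirichlet(α) draws. α is the single flow-evenness knob: spring
   phases get low α (few strong links), late phases high α (even flows).
   Default schedule over phases 1–7: (1.2, 0.5, 1.0, 2.0, 4.0, 8.0, 2.5).
   Within one scenario the underlying uniforms are drawn once per consumer
   and pushed through the Gamma inverse CDF per phase (common-random-number
   coupling): marginally each phase is an exact Dirichlet(α), while a
   consumer's preference *ranking* persists across the year — a realistic
   trait persistence that also makes the seasonal evenness gradient express
   itself near-deterministically per seed.
2. **Gross primary production** enters as the phytoplankton import,
   `base_tst` (1.2·10⁶ µgC m⁻² d⁻¹) times a phase multiplier peaking in late
   spring (0.15, 1.0, 1.4, 0.9, 0.8, 0.55, 0.2) — a >10-fold winter-to-bloom
   contrast. Bacterial uptake from PDOM is fixed at 1/9 of GPP (the observed
   primary:bacterial production ratio).
3. **Budget closure**, processed in trophic order: respiration and egestion
   are fixed fractions of ingestion per group (respiration 0.30–0.45,
   egestion 0.20–0.30; phytoplankton respires 0.25 and exudes 0.15 of GPP);
   each consumer harvests at most its grazing intensity (0.35–0.6) of the
   remaining production of each resource, scaled by its Dirichlet
   preferences; groups with topological self-loops cannibalize 4 % of their
   ingestion; leftovers split 75/25 between export and biomass storage;
   PDOM's surplus after bacterial uptake exports as sedimentation. This
   closure order lets small-web expected flows be computed by hand, and
   guarantees nonnegative flows and machine-precision balance — an
   infeasible fraction set raises rather than silently rebalancing.
4. **Clear-water phase**: the keystone factor (default 0.8) multiplies the
   herbivorous crustaceans' grazing intensity in phase 4 (capped at 0.95),
   concentrating ingestion through the keystone consumer; 0 disables the
   mechanism entirely.
5. **Phosphorus**: `T^P_ij = T^C_ij / (C:P of resource i)`, with group C:P
   profiles of 50 (bacteria) to 180 (detritus) µgC/µgP and a phytoplankton
   C:P rising from 90 in early spring to 280 in summer (nutrient depletion).
   P budgets re-close through exports and storage — a node whose P outputs
   exceed inputs draws on stored biomass — and carry zero respiration.
6. **Biomass**: per phase, 4 snapshots of 20-guild relative compositions are
   Dirichlet draws (precision 150) around a mixture of a uniform profile and
   a phase-specific dominant guild; the CWP puts dominance 0.65 on the
   keystone herbivorous crustacean (the functional-diversity minimum), early
   phases moderate dominance on bloom algae, summer/autumn near-uniform
   profiles (the late-succession diversity plateau). Totals scale a base of
   5·10⁶ µgC m⁻² by phase amplitudes (0.5–2.5); adult fish biomass is a
   phase-dependent 4–12 % on top.

These defaults were fixed once from the seasonal narrative and the
construction requirements (the evenness gradient must actually express
itself in the connectance, and the CWP dominance in the diversity minimum);
the Monte-Carlo recovery rates of the constructed trends (weighted
connectance non-decreasing and relative ascendency decreasing over phases
2–6 in ≥ 90 % of seeds, CWP diversity minimum in ≥ 95 %) are asserted in the
acceptance suite. Seven phases × two elements per scenario and 100-seed
Monte-Carlo batches keep the full suite under a minute on one CPU.

**What the generator does not emulate.** No population dynamics (phases are
independent draws, not an ODE trajectory); no interannual variability; no
taxonomic resolution below functional guilds; uniform disaggregation cannot
create guild-level flow concentration, so the keystone peak of the weighted
clustering coefficient seen in field data at guild resolution does not
reproduce (our `Q_norm` is nearly constant — a documented consequence, not a
bug); absolute index magnitudes (e.g. `C_w` ≈ 0.3 rather than ≈ 0.2) are not
calibrated to any particular lake. Passing tests therefore demonstrate the
correctness and the qualitative seasonal behaviour of the index machinery,
not quantitative agreement with any specific field dataset.

## Known limitations

* Field flow matrices balance only approximately; the strict default rtol
  must be relaxed for imported data.
* The path-length index ignores flow magnitudes by construction (see above);
  use `strongest_shortest_path` when the identity of the coupling route
  matters.
* `trophic_positions` requires every consumer to reach a basal node; isolated
  consumer loops raise rather than being assigned arbitrary positions.
* The trend classifier is a convention; near-threshold seasonal patterns can
  legitimately flip between `const` and a directional class under small
  parameter changes.
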