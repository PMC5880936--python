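# Methods

## The problem

In anaerobic (flooded) soil, microbial respiration funnels electrons from a
limited donor pool to competing terminal electron acceptors (TEAs):
Fe(III), sulfate, CO2 (methanogenesis) and — in pentachlorophenol (PCP)
polluted soil — the chlorinated aromatic itself, which is respired by
reductive dechlorination.  `soilredox` converts end-of-incubation
measurements of these processes into a common currency, micromoles of
electron equivalents (eeq) per bottle, so treatment effects (a sorbent and
electron-shuttling amendment such as biochar or AQDS, or a
sulfate-reduction inhibitor such as molybdate) can be compared as shifts
of a single electron budget.  A companion set of community statistics
analyses the paired 16S amplicon data.

## Electron accounting

Each process is described by a balanced half reaction with a fixed eeq per
mole of compound turned over:

| process | couple | eeq/mol |
|---|---|---|
| Fe(III) reduction | Fe3+ + e- = Fe2+ | 1 |
| sulfate reduction | SO4^2- + 9H+ + 8e- = HS- + 4H2O | 8 |
| methanogenesis | CH3COOH = CH4 + CO2 / CO2 + 8H+ + 8e- = CH4 + 2H2O | 8 |
| dechlorination | 2 e- per Cl removed (PCP -> TeCP -> TCP -> DCP) | 2 per step |

The registry is machine-checked for charge balance (oxidised-side charge +
protons − electrons = reduced-side charge, byproduct ions included).
Acetoclastic methanogenesis is a disproportionation with no free
electrons; its eeq value of 8 per mol CH4 is the bookkeeping convention
for the electrons embodied in the acetate consumed.

Per-bottle electrons are computed from endpoint concentration changes
against a **sterile abiotic baseline**:

* `e_Fe = Δ[Fe(II)] (mg/g) × soil_mass / M_Fe × 1` — Fe(II) *rises* over
  the baseline;
* `e_SO4 = −Δ[SO4] × soil_mass / M_SO4 × 8` — sulfate *drops* below the
  baseline;
* `e_CH4 = CH4(permil)/1000 × gas_basis × 8` — sterile soil releases no
  methane, so no baseline term;
* `e_dechlor = Σ_products n_product × 2 ΔCl` — computed from accumulated
  TeCP/TCP/DCP, **not** from PCP disappearance, so abiotic sorption losses
  (which dominate sterile bottles) cannot inflate the ledger.

Negative baseline-corrected deltas are clipped to zero with a logged
warning rather than raised: at 3 replicates and ~5% measurement noise,
small negatives are routine and an error would make real tables unusable.

### Parameters and defaults

* **Bottle geometry**: 15 g air-dry soil, 30 mL water, 150 mL serum
  bottle, 25 °C.  Only the soil mass enters the concentration-to-moles
  conversions.
* **Headspace gas basis** (default 1000 µmol per bottle): CH4 is measured
  as permil of headspace gas, and the permil→moles conversion needs a
  total-gas amount.  The default is a *calibration* constant that makes
  1 permil ↔ 1 µmol CH4; it reproduces the per-bottle methane electron
  values this workflow targets to within 0.5%, whereas a physical 1-atm
  25 °C headspace of ~114 mL would hold ~4.7 mmol of gas.  The two
  endpoint/electron pairs used for the calibration imply bases of 999.3
  and 995.4 µmol — mutually inconsistent at the 0.4% level — so the round
  1000 µmol is adopted and exposed as `BottleGeometry.headspace_gas_basis`.
* **Baseline strategy** (default `matched`): the sterile mean of the same
  amendment; `pooled` (all sterile bottles) is the fallback and an option.
  Amendment-matched is the default because sorbing amendments (biochar)
  shift the sterile endpoint themselves.
* **Molar masses**: IUPAC values; Fe 55.845, SO4 96.06, CH4 16.04,
  PCP 266.34, TeCP 231.89, TCP 197.45, DCP 163.00 g/mol.
* **DCP** is carried in the ladder (6 eeq from PCP) although it typically
  contributes zero: it is a measured analyte and the ladder should not
  silently drop it.

### Group statistics

Within each treatment group, amendments are compared by one-way ANOVA
with Tukey-HSD post-hoc pairs at the 5% level, displayed as compact
letters (levels sharing a letter are not significantly different).  The
letters are the maximal cliques of the non-significance graph, ordered by
descending mean; with the handful of levels in a treatment table, clique
enumeration is exact.  Cells with fewer than 2 replicates, or all-equal
data, suppress statistics (NA) and share a single letter.  Tukey HSD is
one defensible choice for the post-hoc; the workflow this mirrors states
only a one-way ANOVA at 5%.

## Community statistics

All five analyses are first-principles implementations; established
packages are used only as containers (`skbio.DistanceMatrix`,
`skbio.TreeNode`), for primitive steps (isotonic regression inside NMDS),
and as independent cross-checks in the tests.

* **Alpha diversity**: Shannon (−Σ p ln p, natural log), Simpson
  (1 − Σ p²), classic Chao1 (S_obs + F1²/2F2, the F2=0 correction
  F1(F1−1)/(2(F2+1))), and ACE with the conventional rare-abundance
  cutoff of 10 (falling back to Chao1 when every rare taxon is a
  singleton, where the ACE coverage estimate is undefined).
* **Generalized UniFrac** with moderation parameter α (default 0.5):
  `d(A,B) = Σ_b b(p_A+p_B)^α |p_A−p_B|/(p_A+p_B) / Σ_b b(p_A+p_B)^α` over
  branches with p_A+p_B>0, where p are branch-subtended relative
  abundances after total-count normalisation (no rarefaction).  α=1
  recovers weighted normalized UniFrac (verified against scikit-bio to
  machine precision); the root branch is excluded as it carries no
  signal.
* **NMDS**: non-metric SMACOF minimising Kruskal stress-1
  (√(Σ(d−d̂)²/Σd²)).  Initialisation is classical (Torgerson) metric
  scaling; 19 additional restarts jitter that solution with Gaussian
  noise of 0.3× the configuration SD.  Each iteration fits disparities by
  isotonic regression of configuration distances on dissimilarity order
  (rescaled to preserve Σd²) and applies a Guttman transform; iteration
  stops when the best stress has not improved by 1e-6 over 10
  iterations.  The best-so-far stress trace is non-increasing by
  construction; the reported stress always matches the returned
  coordinates.  k up to n−1 axes is allowed (an n-point simplex embeds
  exactly in n−1 dimensions).
* **PERMANOVA**: Anderson's pseudo-F from the Gower-centred partition of
  squared distances, `p = (1 + #{F_perm ≥ F_obs}) / (1 + permutations)`
  under label permutation (seeded).  The pseudo-F agrees with scikit-bio
  to 1e-10; type-I error is confirmed nominal by simulation.
* **Taxa aggregation**: counts summed per lineage at a rank
  (domain…genus); missing rank labels become `unclassified_<parent>`;
  lineages under the dominance threshold pool into `other`; per-sample
  relative abundances sum to 1.  Default thresholds: 2% for family-level
  panels, 1% for genus-level/dominant-OTU panels.
* **Associations**: Spearman ρ with average ranks for ties.  p-values are
  exact (full permutation distribution of Σd²) for tie-free samples with
  n ≤ 9 and otherwise use the t-approximation with n−2 df; tied data fall
  back to the t-approximation at any n because the tabulated exact
  distribution assumes distinct ranks.  Benjamini–Hochberg step-up is
  applied across the full taxa×variable matrix by default (per-variable
  scope is an option), and significance is judged on adjusted p < 0.05
  (raw-p filtering is an option).

## The synthetic-data generator

`simulate_incubation` emulates the 27-bottle endpoint experiment.  Per
biotic bottle it draws electron allocations around per-cell means,
inverts the stoichiometry into observable concentrations (adding the
sterile baseline for Fe(II), subtracting the drop for sulfate, converting
to permil for CH4) and emits the drawn allocations as a hidden
ground-truth ledger in a sidecar table; sterile bottles get baseline
chemistry, sorption-only PCP losses and zero methane.  Noise is
multiplicative lognormal (mean 1, CV 5% by default) on every
concentration-like quantity — concentrations are positive and
right-skewed — and additive Gaussian on Eh (σ=10 mV) and pH (σ=0.1),
scaled with the CV so `noise_cv=0` is exactly deterministic.  The
replicate-level dispersions of the real experiment are unpublished; the
5% CV is an assumption chosen to be of the order of routine wet-chemistry
precision.

The preset allocations encode the study conditions: biotic cells at
(Fe, SO4, CH4) = (1217, 165, 1600), (2096, 125, 1600) and
(1800, 501, 1600) µmol e− for control/AQDS/biochar, molybdate cells at
(1234, 62.5, {34.7, 0, 1352.8}), TeCP accumulation of 10/4.5/10 µg/g
(5/1.2/5 under molybdate) with 0.5 µg/g TCP throughout, sterile Fe(II)
baselines of 4.4/5.0/6.8 mg/g and sulfate baselines of 0.74/0.77/0.74
mg/g.  These means reproduce the endpoint contrasts and the electron
ledger this pipeline targets — group totals of ≈3570 (biotic) and ≈1760
(molybdate) µmol e−, a 0.493 ratio — and are fixed; they are conditions,
not tuning knobs.  The generator is parametrised by this explicit
per-cell allocation table rather than a pool-times-weights factorisation:
the table is what the endpoint contrasts pin down, and a weights encoding
would be an equivalent reparameterisation.

`simulate_community` draws Dirichlet-multinomial counts (default depth
20 000, precision θ=200) around a base composition holding the named
responder families (SB-1, Desulforudaceae, the Desulfobulbaceae /
Desulfobacteraceae sulfate reducers, Dehalobacteriaceae, …) plus
lognormally-distributed filler OTUs, applies treatment fold-changes
(e.g. SB-1 ×5.9 under biochar, Desulforudaceae ×2.2 under AQDS,
sulfate reducers ×0.1 under molybdate) before renormalisation, and pairs
the table with a random bifurcating tree with exponential branch lengths
(mean 0.1).  Optional covariate links multiply a taxon's proportion by
`exp(β·z)` of a per-sample covariate, inducing taxon–environment
correlations for the association analysis.

**What the simulator does not emulate:** temporal dynamics (endpoints
only), read-level sequencing error and chimeras, compositional coupling
between the chemistry and the community beyond the explicit covariate
links, spatial soil heterogeneity, and any real phylogenetic signal in
the tree (topology is random).  Passing tests therefore demonstrate that
the *pipeline* is correct and well-calibrated under its stated
assumptions, not that the biological conclusions transfer to arbitrary
real soils.

## Numerical choices and degenerate inputs

* Ledger components are clipped at zero (never negative); `e_total` is
  the exact component sum.
* UniFrac pairs with no shared or unshared mass (both samples empty on
  every branch) return distance 0; unmatched OTU/leaf names raise with
  the offending ids listed.
* NMDS rejects asymmetric inputs and k ≥ n; stress below 1e-12 stops
  iteration early.
* PERMANOVA warns on singleton groups (the permutation distribution is
  restricted) and refuses single-group designs.
* Spearman on a constant vector returns NaN (undefined), which BH passes
  through without affecting the other tests.
* Determinism: every stochastic routine takes a seed; equal configs give
  byte-identical outputs.

## Problem sizes

The test-suite and acceptance computations use the experiment's native
sizes (27 bottles, 18 community samples, 120 OTUs) and simulation scales
chosen for precise calibration checks at interactive runtimes: 100
random ≤6-leaf trees for the UniFrac oracle, 1000 null datasets
(99 permutations each) for PERMANOVA type-I error, 500 null 20×8
matrices for the BH calibration, and 20–30 independent experiments for
recovery-bias estimates.

## Known limitations

* The permil→moles gas basis is calibrated, not physical; absolute
  methane electron values inherit its ~0.5% ambiguity.
* The exact sterile Fe(II) baseline used in the original analysis is not
  recoverable from published values; the amendment-matched default
  (≈5.0 mg/g for AQDS) reproduces the published Fe electron numbers but
  other choices within the published sterile range (4.4–6.8 mg/g) shift
  `e_Fe` by up to ±25%.
* Dechlorination electrons from product accumulation and from PCP
  disappearance disagree in general (sorption); this package reports the
  product-based value only.
* PERMANOVA supports one factor; no nested or interaction designs.
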