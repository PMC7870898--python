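# autocatnet

Computational analysis of autocatalytic RNA reaction networks: how the
topology of a catalytic network controls what it produces, how fast it grows,
and how strongly its composition shifts when a new catalytic species appears.

The system modeled is a set of self-assembling ribozymes derived from a group
I intron. Each species is identified by two nucleotides — the variable
position M of its internal guide sequence (IGS, `gMg`) and the variable
position N of its tag (`cNu`) — giving 16 species. A species whose IGS
base-pairs with another species' tag catalyzes that species' covalent
ligation, so any species set plus a rate table induces a directed reaction
network. The package is aimed at researchers in systems chemistry and origin
of life studies who want to simulate, process and analyze such network
landscapes.

## The models at the core

**Kinetics.** Covalent catalyst concentrations follow the parameter-free
linear model

```
ẋ_i = Σ_j α_ij x_j + β_ij ,   x(0) = 0
```

where α_ij (min⁻¹) is catalysis of species *i*'s formation by covalent
catalysts of species *j* and β_ij (µM·min⁻¹) the constant contribution of
noncovalent fragment complexes. The solution is computed exactly through the
exponential of the augmented matrix `[[A, b], [0, 0]]`. Species fractions are
x_i(t)/Σx_j(t) at the 60-min incubation; yield is Σx_i(t) in µM.

**Perturbation.** For networks G and G′ = G ∪ {a}, with V their common
species set and fractions renormalized within V,

```
p_{G→G′} = Σ_{v∈V} |y′_v − y_v| ∈ [0, 2].
```

Under the in-degree approximation of compositions this has a closed-form
prediction from four topology parameters — breadth *n* (species of G targeted
by *a*), novelty *m* (species of G sharing *a*'s IGS), background strength
σ_G (sum of catalytic rates inside G) and *a*'s rate *e*:

```
p̂ = 2n (1 − n·m/s) / (s + n),   s = σ_G / e.
```

**Trajectories.** Networks grown by random single-species accretion
accumulate perturbation; inflexions of the cumulative series (classified by
the absolute discrete third derivative, "strong" = top quartile) mark sudden
compositional shifts and coincide with catalytic innovations (first
appearance of a strong IGS/tag interaction type).

**Droplet pipeline.** Barcoded-sequencing UMI records are deduplicated,
read-filtered, decoded (hairpin reporters with ≥ 7.5 % of hairpin UMIs define
the droplet's fragment content), thresholded (≥ 10 hairpin and ≥ 20 ribozyme
UMIs) and converted to species fractions and a yield in µM via the reporters
of known concentration.

## Worked example

```python
from autocatnet import (SpeciesId, build_network, default_rate_table,
                        predict_fractions, perturbation, perturbation_params,
                        predict_perturbation)

table = default_rate_table()          # placeholder rates; load measured ones via RateTable.from_csv
G  = build_network([SpeciesId("A","U"), SpeciesId("U","A"), SpeciesId("U","C")], table)
Gp = build_network([*G.species, SpeciesId("G","C")], table)

before, after = predict_fractions(G, 60), predict_fractions(Gp, 60)
p = perturbation(before, after, set(G.species))
p_hat, valid = predict_perturbation(perturbation_params(G, SpeciesId("G","C"), table))
print(f"measured p = {p:.3f}, predicted p_hat = {p_hat:.3f} (valid={valid}), yield {after.yield_uM:.3f} uM")
```

prints

```
measured p = 1.119, predicted p_hat = 1.053 (valid=True), yield 0.147 uM
```

Adding the GC catalyst is a catalytic innovation (no prior catalyst shares
its IGS, m = 0) hitting a weakly connected network (σ_G/e = 0.9), so more
than half of the composition mass of the common species redistributes. The
topology-based prediction, built on the in-degree approximation of the full
kinetics, anticipates the measured perturbation closely; the 4-species
network's 60-min yield is 0.15 µM.

## The analysis

Numbered drivers under `analysis/` reproduce the full chain on synthetic
data; each prints what it found and writes tables under `results/`:

1. `01_design_combinations.py` — entropy-maximizing design of the 24
   fragment-mixture combinations (50 slots).
2. `02_simulate_experiment.py` — droplet fusion, incubation kinetics and
   barcoded-sequencing simulation (UMI records + ground truth).
3. `03_process_droplets.py` — the UMI pipeline; reports fraction/yield
   recovery against ground truth.
4. `04_landscape_analysis.py` — ranking conservation, yield ranking,
   model-vs-measurement correlation, σ_G–yield correlation, growth–variation
   trade-off (run again after 05 for the trade-off test).
5. `05_perturbation_analysis.py` — all single-addition (G, G′) pairs, measured
   vs predicted perturbation.
6. `06_trajectory_study.py` — growth-trajectory ensembles across catalytic
   densities (sparse: few strong variations; dense: many weak ones).

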