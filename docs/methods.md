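# Methods

## The chemistry and its parameterization

A catalytic species is a (IGS letter M, tag letter N) pair over the RNA
alphabet {A, C, G, U}; the concrete chemistry has 16 species. Species *j*
catalyzes formation of species *i* when its IGS base-pairs the tag of *i*;
rates are looked up in a table over (IGS letter, tag letter) pairs, with two
components per pair matching the titration model `v0 = αx + β`: α (min⁻¹)
for covalent catalysts, β (µM·min⁻¹) for noncovalent fragment complexes.
Time is fixed to minutes and concentration to µM throughout.

The shipped default table is a clearly-labeled placeholder, not a set of
measured constants. It encodes the measured *ordering* — G:C = C:G maximal,
A:U = U:A weaker, wobble (G:U, U:G) and mismatches zero — with magnitudes
α(G,C) = 0.012 min⁻¹, α(A,U) = 0.0036 min⁻¹ and β = 0.05·α.
These were chosen once so that 60-min incubations of the networks produced by
simulated 1–5-droplet fusions span roughly 0.05–1 µM in total yield, i.e. an
order-of-magnitude spread with typical values a few tenths of a µM, which is
the regime where the 0.08-µM yield threshold of the trade-off analysis is
meaningful. All quantitative entry points accept a user-supplied table
(`RateTable.from_csv`, columns `igs,tag,alpha,beta`; missing rows read as 0).
Graph edges are α-pairs at or above `edge_threshold` (default 10⁻⁶ min⁻¹),
which draws only Watson–Crick interactions under the default table.

## Kinetics

The linear model `ẋ = A x + b`, x(0) = 0, with `A[i,j] = α(igs_j, tag_i)`
and `b[i] = Σ_j β(igs_j, tag_i)` over the species present, neglects
substrate depletion and treats noncovalent complex formation as fast
(characteristic time 1/(0.65 µM⁻¹min⁻¹ · 1.6 µM) ≈ 1 min versus the 60-min
incubation). It is therefore an early-reaction-time model; the default
evaluation time is the experimental 60 min and is configurable. The solution
is the top-right block of `expm(t·[[A, b],[0, 0]])`, which is exact, handles
singular A (rows of species receiving no catalysis), and is cross-checked in
the tests against an adaptive step-controlled integrator at 10⁻⁸ relative
tolerance on random networks.

Two centrality approximations bracket the full model: weighted in-degree
(exact in the noncovalent-only regime, where x = b·t at all times) and the
leading eigenvector of A (the Perron direction that x(t) approaches in the
covalent-only regime at long times, when the dominant eigenvalue is simple).
Eigenvector centrality is computed by power iteration from the uniform
vector at 10⁻¹² convergence tolerance with an iteration cap; pure-rotation
degeneracies (complex dominant eigenvalues) are flagged as non-converged
rather than raised. In-degree weights default to α; β-weights select the
noncovalent regime.

## Perturbation statistic and its analytical prediction

The perturbation between nested networks G and G′ = G ∪ {a} is the L1
distance between their compositions renormalized on the common set
V = species(G); it lies in [0, 2] with 2 a complete compositional switch.
The analytical prediction `p̂ = 2n(1 − n·m/s)/(s + n)`, s = σ_G/e, uses:

- n — number of species of G targeted by a (a's possible self-target is
  excluded: the statistic lives on V);
- m — number of species of G sharing a's IGS (m = 0 is a catalytic
  innovation);
- σ_G — sum of α rates over all directed interactions present in G,
  self-loops included, each ordered pair counted once, only edges at or
  above the edge threshold (σ_G sums α only; β contributions are a
  different unit and belong to the noncovalent regime);
- e — the α rate of a's strong pair, determined by a's IGS.

Outside its validity region (any target's renormalized fraction would
decrease, equivalently p̂ < 0 in the worst case) the raw value is reported
with `valid = False` rather than clamped, so downstream statistics can
filter. The derivation's assumptions were reconstructed from the formula
itself and verified constructively: on networks where every target's prior
in-degree comes only from the m same-IGS catalysts at rate e, the direct
in-degree perturbation equals p̂ to 10⁻¹⁰; on arbitrary networks it equals
the generalized form `2en(σ_G − D_T)/(σ_G(σ_G + ne))` with D_T the targets'
total prior in-degree, which reduces to p̂ at D_T = n·m·e. No discrepancy
was found.

## Landscape statistics

Droplet compositions are grouped by exact species set; means, standard
deviations and SEMs are replicate statistics. Ranking conservation uses
strict inequality of mean fractions (exact ties count as conserved — ties
are measure-zero on real data but the convention must be fixed for synthetic
input); for each unordered species pair the minority orientation's share of
co-occurrences is compared to the 10 % threshold, and pairs co-occurring in
fewer than two networks are excluded from the denominator. The
growth–variation trade-off is a one-sided Fisher exact test (alternative:
fewer strongly-perturbable and high-yield networks than independence) with
the conditional-MLE odds ratio and exact 95 % CI. Binned summaries
(model-vs-measurement, σ_G-vs-yield) discard bins with fewer than 10 points.

## Growth trajectories and inflexion analysis

Trajectories draw a uniform random start set and addition order without
replacement; per-step perturbations use in-degree compositions by default
(fast, and the regime in which the analytical theory is exact), with
kinetic-model compositions behind a flag. Steps with zero composition mass
contribute p = 0 with a logged warning instead of aborting the trajectory.

Inflexions of the cumulative series P use the discrete second difference
d2[k] = P[k+1] − 2P[k] + P[k−1]; a sign change (zeros between opposite signs
are crossed) marks an inflexion at the last index of the old sign, with
sharpness |P[k+2] − 3P[k+1] + 3P[k] − P[k−1]| = |d2[k+1] − d2[k]|. Curvature
below 10⁻¹² of the series scale counts as flat, so numerically linear series
report no inflexions. "Strong" means sharpness at or above the 75th
percentile (linear interpolation), pooled over the ensemble by default
(per-trajectory by flag — the two conventions coexist in the source
figures' legends; pooled is the better-determined statistic at desk scale).
Waiting times are defined between consecutive strong inflexions, i.e. from
rank 2 on, since rank 1 has no predecessor.

A catalytic innovation at step k is the creation of at least one edge whose
(IGS, tag) letter pair is a designated strong pair absent from all edges
before the step — {G·C, C·G} in the concrete chemistry, every specific pair
in abstract chemistries.

The abstract chemistry for the density study is an L×L species grid
(default L = 24) with a pool of at most 24 specific interaction types, one
per letter (a generalized complementarity: letter i's IGS pairs letter i's
tag), all at uniform rate e. Catalytic density — the probability that one
random species catalyzes another — is |interactions|/L²; it is varied by
random removal from the pool. The scaled study defaults (200 trajectories,
2 → 50–60 species) reproduce the directional results of the full-scale
configuration (1000 trajectories, 2 → 100) in seconds; the full scale
remains available through the same function.

## Synthetic data generator

The generator emulates the structure of the droplet experiment: 24
fragment-mixture combinations distributing 50 fragment slots, selected among
random candidates by maximizing the summed histogram entropies (20
fixed-width bins over the observed range) of the leading eigenvalue λ₁ and
the gap λ₁ − λ₂ of the rate matrix across simulated random fusions (the
experimental campaign screened 100,000 candidates over 10,000 fusions; the
scaled defaults are 1,000/1,000). Each simulated droplet fuses k ~ uniform
{1..5} mixtures (the empirical fusion distribution was video-derived and is
not printed; uniform is the configurable default), computes the union
network's true composition and yield through the same kinetics code path the
analysis uses, and emits:

- hairpin UMIs per encoded reporter, Poisson with mean `umis_per_uM` ×
  effective reporter concentration (0.03 µM × 0.1 dilution of a small
  droplet into the fused volume);
- ribozyme UMIs, Poisson(`umis_per_uM` × yield) — or a fixed depth for
  sampling studies — multinomially distributed over the true fractions and
  capped at `max_ribozyme_umis` (finite per-droplet sequencing depth);
- per-UMI read counts 1 + Poisson(mean − 1), plus Poisson-many spurious
  single-read UMIs per droplet for the read filter to remove.

Because UMI capture is proportional to concentration with a single
efficiency for both molecule classes, the pipeline's reporter-based
UMI-to-µM conversion is consistent by construction and yield recovery is
unbiased up to Poisson noise and the depth cap. What the generator does
*not* emulate: barcode collisions and PCR cross-over between droplets,
sequencing-error structure within reads, reporter-specific capture biases,
and any nonlinearity of the true kinetics — so passing recovery tests
demonstrate correctness of the processing logic under the stated sampling
model, not robustness to those real-data artifacts.

Unions with no catalytic interaction produce nothing; the generator emits
such droplets with reporters only (NaN ground-truth fractions, zero yield),
and the pipeline rejects them at the ribozyme-UMI threshold, as in the real
protocol.

## Pipeline conventions

Droplet thresholds are implemented non-strictly (≥ 10 hairpin, ≥ 20 ribozyme
UMIs) and configurably; the source text mixes "more than 10 … and 20" with
"the threshold of 20". Read-per-UMI minimums default to 2 for both classes
(the distribution that fixed them experimentally is not available) and are
configurable. The per-reporter effective concentration is the nominal
0.03 µM scaled by a configurable dilution factor (default 0.1,
a small droplet fused into ~10× its volume), since the conversion constant
is not stated explicitly.

## Problem sizes

Default desk-scale sizes — 1,500 simulated droplets, 200-trajectory
ensembles growing to 50–60 species, 1,000-candidate design screens — were
chosen so the whole analysis chain and test suite run in minutes on one CPU
while preserving every directional result; all are parameters, and the
full-scale configurations are reachable through the same entry points.

## Known limitations

- The measured α/β values live in supplementary material that is not
  bundled; all quantitative results shown here use the placeholder table and
  are therefore structural/qualitative, not numerical reproductions.
- Multistability of preformed networks (history-dependent compositions) is
  outside the linear model and not simulated.
- Multi-species additions, species removal and compartment selection cycles
  are out of scope.
- The closed-form perturbation prediction assumes all of an added catalyst's
  target edges share one rate e; mixed-rate targets are handled by the
  measured statistic but not by the closed form.
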