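# Methods

## Model family

All variants describe `m` competing microbial species in a well-mixed,
continuously diluted habitat. Abundances `s_i` are dimensionless (scaled by
the carrying capacity `Nm`), so a monoculture at equilibrium sits at
`1 - D/mu`. The classic Lotka–Volterra (LV) backbone is

    ds_i/dt = mu_i s_i (1 - s_i - sum_{j!=i} gamma_ji s_j) - D s_i,

where `gamma_ji >= 0` is the competitive effect of species *j* on species
*i* and `D` (hr⁻¹) a uniform dilution/death rate. Horizontal gene transfer
(HGT) adds, for every ordered species pair, a carrier subpopulation
`p_ij <= s_i`: cells of species *i* that have acquired the mobile genetic
element (MGE) native to species *j*. Carriers obey

    dp_ij/dt = g_ij p_ij (1 - s_i - sum gamma_ji s_j)
               + (s_i - p_ij) sum_k eta_jki p_kj - (D + kappa_ij) p_ij,

with mass-action conjugation at rate `eta` (donor pool `p_kj`, including
the element's native species `p_jj = s_j`), segregation loss `kappa`, and a
carrier growth rate `g_ij = mu_i (1+lam_ij) prod_{k!=i,j}(1+lam_ik p_ik/s_i)`.
Carriage multiplies the host's growth rate by `1 + lam_ij`, giving the
effective rate

    mu_i^e = mu_i prod_{j!=i} (1 + lam_ij p_ij / s_i),
    mu_i   = mu0_i (1 + lam_ii),

so species partially exchange their growth benefits or burdens. With
`eta = 0` and no initial carriers the system is exactly classic LV.

Assumptions baked into the family: species never lose their own native
element entirely; intra- and inter-species transfer occur at the same rate
unless a full `eta[j,k,i]` tensor is supplied; self-inhibition is
unaffected by acquired MGEs; no demographic noise, plasmid copy-number or
incompatibility mechanics, and no within-species genotype structure beyond
carrier/non-carrier.

Variants:

- **interaction_mod** — acquired elements also change niche overlap: the
  effective competition of species *j* on *i* is
  `gamma_ji + delta_j * p_ji / s_j`. Only the two-species form of this
  coupling is fully pinned down by the printed analyses; the multispecies
  generalization used here (carriage of *i*-native elements by *j*
  increases *j*'s overlap with *i*) reduces exactly to that two-species
  form.
- **epistasis** — the growth effect of an element depends on its host:
  `lam_ij = xi_j * lam_jj`. Ratios `xi > 0` are magnitude epistasis,
  `xi < 0` sign epistasis (the element flips from burden to benefit or
  vice versa between hosts).
- **selection** — strong environmental selection (e.g. antibiotics): only
  carriers of a single resistance element grow, non-carriers decay at `D`.
  One donor species starts with the element (`p` is a vector here).
- **niche** — species interact only within shared niches, each niche with
  its own carrying capacity in (0, 1]; cross-niche pairs do not compete.
- **metacommunity** — a u×v grid of patches sharing one parameterization,
  coupled by passive nearest-neighbor dispersal at rate `omega` for both
  species and carriers, with no-flux boundaries.

## Parameters, units, defaults

| parameter | meaning | default | unit |
|---|---|---|---|
| `mu0` | basal (chromosomal) growth rate | 0.5 | hr⁻¹ |
| `lam` | MGE growth effect (> −1) | derived from `mu/mu0 − 1` | — |
| `gamma` | competition strength | 1.05–1.5 by analysis | — |
| `eta` | transfer rate | 0–0.4 scanned | hr⁻¹ |
| `kappa` | segregation loss | 0.005 | hr⁻¹ |
| `D` | dilution/death | 0.2 | hr⁻¹ |
| `omega` | patch dispersal | 0.001 | hr⁻¹ |

`eta` is the *population-scale* rate: an empirically measured per-cell
conjugation efficiency `eta_c` (cells⁻¹·mL·hr⁻¹) corresponds to
`eta = Nm * eta_c`, so 1e-2 hr⁻¹ means 1e-11 at `Nm = 1e9` cells/mL and
1e-14 at 1e12 cells/mL (`eta_from_empirical` / `eta_to_empirical`).

The dispersal default needs justification since no standard value exists:
dispersal must be slow relative to growth (~0.5 hr⁻¹) for patch-level
multistability to survive coupling. Scanning `omega` over 1e-4–5e-3 on
5×5 grids of 10-species patches shows the qualitative regional-diversity
pattern is stable up to ~1e-3 but collapses to spatial homogeneity by
5e-3; the default 1e-3 hr⁻¹ sits at the upper edge of the robust regime
(roughly: one migrant per thousand cells per hour).

## Stability-landscape protocol

1. **Initial conditions.** `s_i ~ U(0,1)` iid; carriers start native-only
   (`p_ii = s_i`, `p_ij = 0`), optionally `p_ij ~ U(0, s_i)`; for the
   selection variant the donor alone carries the element. One master seed
   spawns one RNG substream per initialization, so draw *k* depends only on
   (seed, *k*) and enlarging the ensemble never reshuffles earlier draws.
2. **Relaxation.** Each initialization is integrated to equilibrium
   (default horizon 2000 hr, extended in 500-hr chunks to at most
   10,000 hr) and flagged converged when the residual `max |dy/dt|` falls
   below 1e-6 hr⁻¹. The residual check guards against mistaking slow
   transients for equilibria, which a fixed horizon alone would do.
3. **Clustering.** Converged steady states (species vectors only, with
   abundances below 1e-6 floored to zero so near-extinct tails do not
   split clusters) are grouped by single-linkage at a Euclidean threshold:
   0.01 for two-species analyses, 0.05 for m ≥ 3. Single linkage
   (connected components of the sub-threshold distance graph) is the
   unique partition consistent with the pairwise rule "closer than the
   threshold means same attractor". The all-extinct state counts as an
   attractor if reached.
4. **Summary.** Basin fractions are the Monte-Carlo estimator
   `x_i = (members of basin i)/(converged members)`;
   `chi = exp(-sum x_i log x_i)`.

Phase diagrams mark a (mu1, mu2) cell bistable when >1 attractor is found
(200 initializations, threshold 0.01). Bistability fractions sample
parameter sets (e.g. growth-rate pairs on U(0,1)) and report the fraction
with ≥2 attractors; all sweeps reuse common random numbers across the
compared transfer rates so eta differences are not confounded with
sampling noise.

## Numerical choices

- **Integrator.** Single trajectories: LSODA (adaptive, stiff-capable),
  rtol 1e-6, atol 1e-9; residuals at closed-form LV fixed points are below
  1e-12. Ensembles are stacked into one vectorized system (members remain
  decoupled; only adaptive step control is shared) and integrated with
  RK45 in 250-hr chunks, retiring members as they converge; if the stacked
  step collapses, the chunk falls back to per-member LSODA. Halving
  tolerances moves five-species steady states by < 1e-4.
- **Domain guards.** Negative abundances and carrier overshoots are
  clamped on solver *output* (chunk boundaries), never inside the RHS.
  Inside the RHS the carrier fraction `p_ij/s_i` is 0 for extinct species
  and clipped to [0, 1] — inactive on the physical domain `0 <= p <= s`,
  and a smooth extension over the small excursions an adaptive solver
  makes outside it (without the clip, unphysical `p > s` states can
  self-amplify and collapse the step size).
- **Limit cycles** are screened by a proxy: states a window apart that
  still differ by more than the clustering threshold while both residuals
  exceed tolerance. None arise in the model family's standard
  parameterizations; the proxy is exercised with a synthetic rotation
  field in the tests.
- **Degenerate inputs.** `gamma1*gamma2 = 1` removes the coexistence fixed
  point (reported as absent); non-viable species (`mu <= D`) make the
  closed-form bistability condition false by definition; all-zero
  compositions have undefined diversity and raise.

## Detection of the HGT-promotion threshold

Scanning transfer rates over decades (1e-7…1 hr⁻¹) on randomized 8-species
communities shows mean attractor counts that are nearly flat at small eta
and rise steeply above ~1e-2…1e-1. Two protocol details matter here.

First, the observation window is part of the measurement. Any positive
transfer rate eventually seeds carriers whose modes self-amplify whenever
`D*lam > kappa`; once every resident species carries every element, all
effective growth rates collapse onto the common value
`mu0 * prod_j (1+lam_j)` — transfer *neutralizes* growth differences, so
with `gamma > 1` every single-species state becomes a stable attractor at
the same height. New attractors therefore already exist at small eta, but
with minuscule basins (order 1% of composition space at eta ~ 1e-3),
growing with eta. Scans consequently use the fixed-window protocol
(`fixed_horizon=True`, exactly 2000 hr, all endpoints clustered): with the
adaptive extension protocol, relaxation continues until even the slowest
carriage transients resolve, and the measured landscape differs from the
eta = 0 landscape at every positive eta.

Second, the onset estimator. The zero-margin rule "first eta whose mean
count exceeds the eta = 0 mean" (reported as `onset_eta`) is noise-limited:
counts are small integers and the tiny new basins are sampled erratically,
so single ±1 replicate flips can trip the comparison anywhere on the
small-eta plateau. The package therefore also reports a
`promotion_threshold`: each eta's counts are compared with the eta = 0
counts of the same replicates (paired by common initializations and
growth-rate draws) with a one-sided paired t-test at the 1% level; the
threshold is the largest grid value below the smallest eta from which the
excess is significant at every larger eta. Because the underlying basin
growth is smooth in log-eta, the located decade carries an intrinsic
±1-decade resolution that no estimator at feasible ensemble sizes can
remove; both statistics are reported so users can see the raw profile.

## What the generators emulate — and what they do not

The samplers reproduce the randomization schemes of the standard analyses:
growth rates uniform on stated ranges (default U(0.3, 0.7) for
multispecies sweeps; U(0, 1) for two-species phase-diagram draws), MGE
effects `lam ~ U(-alpha, alpha)`, homogeneous or uniformly heterogeneous
competition matrices, random niche structures (2…m/2 niches, U(0,1]
capacities), and selection communities with a single donor. They emulate
idealized well-mixed communities with pairwise competitive interactions
only — no cross-feeding, no environmental fluctuations, no spatial
structure below the patch scale, no strain-level variation. Passing tests
therefore demonstrate the internal consistency and reproducibility of the
model's predictions, not their accuracy for any particular natural
microbiome.

## Problem sizes

Default analysis sizes are the standard protocol sizes (500
initializations for multispecies ensembles, 200 for two-species phase
diagrams; 10 replicates for eta scans). The test suite runs scaled-down
versions chosen as the smallest sizes at which each qualitative outcome is
stable across seeds: 8 replicates × 300 initializations for the
promotion-threshold scan, 40 parameter draws × 100 initializations for
direction-of-effect fractions, 5×5 grids of 10-species patches for
metacommunity diversity.

## Known limitations

- Attractor counts from finite ensembles are lower bounds; very small
  basins (< ~1/n_init) are sampled erratically. chi is the more stable
  summary and is reported alongside counts everywhere.
- Near basin boundaries trajectories can stall at saddle equilibria with
  residuals below tolerance; such members are counted where they stopped.
  This mirrors the fixed-horizon behavior of the standard protocol but
  inflates count variance slightly; it is the main reason the promotion
  threshold uses a significance test rather than a zero-margin comparison.
- The multispecies interaction-modification and epistasis forms are
  natural generalizations constrained only by their two-species special
  cases (see above); alternative generalizations are conceivable.
- Dispersal couples patches linearly; no long-range kernels, and no
  per-patch parameter heterogeneity.
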