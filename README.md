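# mgecomm

**Multistability of microbial communities undergoing horizontal gene transfer.**

Microbial communities in identical environments often rest in *alternative
stable states* — different species compositions that persist under the same
conditions, with regime shifts between them triggered by changes in initial
abundances. `mgecomm` simulates communities of competing microbes that
exchange mobile genetic elements (MGEs, e.g. conjugative plasmids) and
quantifies how the rate of horizontal gene transfer (HGT) reshapes their
stability landscape. It is aimed at microbial ecologists and modelers who
want to explore when gene flow creates, or destroys, alternative stable
states — locally and across metacommunities.

## The model

Species abundances `s_i` (scaled by carrying capacity) follow a
Lotka–Volterra competition model with dilution `D`; HGT adds carrier
subpopulations `p_ij` — cells of species *i* carrying the element native to
species *j*:

    ds_i/dt   = mu_i^e s_i (1 - s_i - sum_{j!=i} gamma_ji s_j) - D s_i
    dp_ij/dt  = mu_i (1+lam_ij) [prod_{k!=i,j} (1 + lam_ik p_ik/s_i)] p_ij (1 - s_i - sum gamma_ji s_j)
                + (s_i - p_ij) sum_k eta p_kj - (D + kappa) p_ij

with the effective growth rate `mu_i^e = mu_i prod_{j!=i} (1 + lam_ij p_ij/s_i)`
and `mu_i = mu0_i (1 + lam_ii)`. Transfer is mass-action at rate `eta`
(hr⁻¹), segregation loss at rate `kappa`. Model variants cover: classic LV
(no MGEs), two-species and m-species plasmid exchange, MGE-modified
competition (`gamma + delta p/s`), host-dependent growth effects (epistasis
ratios `xi`), strong environmental selection (only carriers grow), niche
structure, and grids of patches coupled by nearest-neighbor dispersal.

Multistability is measured by ensemble sampling: many uniform random initial
compositions are relaxed to equilibrium, steady states are clustered into
attractors (single-linkage at a Euclidean threshold), and the landscape is
summarized by the attractor count and the **multistability coefficient**

    chi = exp(-sum_i x_i log x_i),

the exponential Shannon entropy of the basin fractions `x_i` (chi = 1 when
monostable; chi = number of attractors when basins are equal).

## Worked example

A five-species community with growth rates 0.52/0.48/0.44/0.60/0.31 hr⁻¹,
uniform competition 1.05, plasmid loss 0.005 hr⁻¹ and dilution 0.2 hr⁻¹ is
monostable without HGT, but transfer at 0.4 hr⁻¹ creates four alternative
stable states, each dominated by a different species:

```python
import mgecomm as mg

model = mg.demo_five_species(eta=0.4)
aset = mg.count_stable_states(model, n_init=500, threshold=0.05, seed=1)
print(aset.n_attractors)                 # 4
print(aset.basin_counts)                 # [149  82 232  37]
print(round(aset.chi, 3))                # 3.341
print(aset.representatives.round(3))
# [[0.423 0.    0.    0.    0.   ]
#  [0.    0.421 0.    0.    0.   ]
#  [0.    0.    0.    0.424 0.   ]
#  [0.    0.    0.42  0.    0.   ]]
```

Without transfer the same community always converges to one state:

```python
aset0 = mg.count_stable_states(mg.demo_five_species(eta=0.0),
                               n_init=500, threshold=0.05, seed=1)
print(aset0.n_attractors, round(aset0.chi, 3))   # 1 1.0
```

The four basin counts (149/82/232/37 of 500 random initializations) say the
landscape is uneven: chi ≈ 3.3 rather than 4 because one basin captures
nearly half of the composition space.

The same analyses are scriptable from the shell:

```bash
mgecomm ensemble --fixture five_species --eta 0.4 --n-init 500 --seed 1 --out results/demo
mgecomm fixtures --list
```

Every run writes CSV results plus a JSON manifest (config, seeds, versions)
that replays to byte-identical outputs.

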