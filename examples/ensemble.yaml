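# Count the stable states of the packaged five-species community at a
# transfer rate of 0.4/hr:
#   mgecomm ensemble --config examples/ensemble.yaml
schema: mgecomm/experiment-v1
kind: ensemble
seed: 1
fixture: five_species
outdir: results/five_species_eta04
params:
  eta: 0.4
  n_init: 500
  threshold: 0.05
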