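# Demo: simulate a backcross segregating recessive insensitivity on chr2 at
# 55 cM, phenotype it from emergence days, and run the scan chain.
#   lunaqtl run --config examples/demo.yaml
out_dir: demo_out
seed: 1
regime: turbulence
day1: 1
bandwidth: 10
n_perm: 1000
cross_type: BC
simulate:
  n: 200
  cross_type: BC
stages: [phenotype, reduce, scan, cim, fit, empanel]
em_runs: 200
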