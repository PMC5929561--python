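# baseline CF-centre conduction experiment (desk scale)
tissue:
  nx: 10
  ny: 10
  nz: 100
  sigma: 3.0
  seed: 1
model:
  g_na: 0.6    # set to 0.0 to observe conduction failure
simulation:
  duration_ms: 600.0
  stagnation_ms: 100.0
output:
  dir: cf_center_out
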