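# smoke-test configuration: small lattice, completes in well under a minute
tissue:
  nx: 6
  ny: 6
  nz: 30
  sigma: 2.0
  seed: 5
model:
  g_na: 0.6
simulation:
  duration_ms: 80.0
  record_every_ms: 0.5
  stagnation_ms: 50.0
  equilibrate_ms: 60.0
output:
  dir: tiny_out
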