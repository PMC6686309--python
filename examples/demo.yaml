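# Demo configuration: simulate a five-taxon kelp-like plastome data set and
# run the full pipeline on it.  Runs in well under a minute.
#   plastcomp run --config examples/demo.yaml --out demo_out
reference: S_japonica
simulate:
  seed: 42
  genome_length: 40000
  n_cds: 40
  n_trna: 9
  ir_length: 2000
analysis:
  bootstrap_reps: 100
  seed: 42
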