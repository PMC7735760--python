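# End-to-end demo: a 2000-molecule mixture of one irregular and two
# regular oligonucleosome patterns, simulate -> call -> footprint ->
# cluster -> enrich.  Run:
#   samosa run --config examples/demo.yaml --out demo_run
simulate:
  seed: 11
  n_molecules: 2000
  patterns:
    - pattern_id: irs
      pattern_type: irregular
      weight: 0.3
      n_nucleosomes: 7
      flank5: 25
      flank3: 25
    - pattern_id: nrl172
      nrl: 172
      weight: 0.35
      n_nucleosomes: 7
      flank5: 25
      flank3: 25
    - pattern_id: nrl193
      nrl: 193
      weight: 0.35
      n_nucleosomes: 7
      flank5: 25
      flank3: 25
call:
  seed: 3
footprint:
  mode: invivo
cluster:
  seed: 5
  resolution: 0.3
enrich:
  fdr: 0.1
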