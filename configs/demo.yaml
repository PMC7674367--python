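# Demo run: one synthetic three-layer slide (molecular / Purkinje /
# granular) through detection and morphometry, plus a 3-population,
# 8-animals-per-population cell table with a 0.5-SD F-vs-M location shift
# through multi-aspect inference, ranking and the descriptive report.
#
# Usage:  cytomorph run --config configs/demo.yaml
# Any key omitted here keeps the library default; see
# cytomorph.pipeline.DEFAULT_CONFIG for the full schema.
seed: 42
out_dir: demo_out
stages: [simulate, detect, measure, test, rank, report]
table:
  animals_per_population: 8
  cells_per_animal: 150
  location_effects_sd: {M: -0.5, F: 0.5, FM: 0.0}
test:
  B: 999
rank:
  alpha: 0.05
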