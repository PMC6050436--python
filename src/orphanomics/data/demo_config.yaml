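# Demo pipeline configuration over the packaged fixtures: metabolite
# annotation, pathway-coverage integration, and the five-species Venn demo.
seed: 1
inputs:
  metabolites: fixture:table1_metabolites.tsv
  pathways: fixture:table2_pathways.tsv
  detected_ecs: fixture:demo_detected_ecs.tsv
  species_ecs: fixture:species_ecs_demo.tsv
params:
  required_present: null
  normalize: total
  impute: half_row_min
  evalue_max: 1.0e-10
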