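# Demo pipeline configuration: a reduced synthetic study (half-size toy
# genome, three groups of three samples) that runs end to end in well under
# a minute while exercising every stage.
seed: 7
out_dir: results/pipeline_demo
simulation:
  n_chroms: 2
  chrom_length: 500000
  pericentromere_halfwidth: 80000
  n_genes: 100
  n_transposons: 75
cv_repeats: 50
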