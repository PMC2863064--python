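# Full simulation-study grid: 3 disease models x 2 LD levels x 4 MAFs.
# Run:  dassomb evaluate examples/power_grid.yaml --out power.tsv --seed 1
n_datasets: 50
alpha: 0.05
bonferroni: false
max_cond_size: 3
cells:
  - {model_id: 1, marginal_effect: 0.3, ld_r2: 0.7, maf_disease: 0.05}
  - {model_id: 1, marginal_effect: 0.3, ld_r2: 0.7, maf_disease: 0.1}
  - {model_id: 1, marginal_effect: 0.3, ld_r2: 0.7, maf_disease: 0.2}
  - {model_id: 1, marginal_effect: 0.3, ld_r2: 0.7, maf_disease: 0.5}
  - {model_id: 1, marginal_effect: 0.3, ld_r2: 1.0, maf_disease: 0.05}
  - {model_id: 1, marginal_effect: 0.3, ld_r2: 1.0, maf_disease: 0.1}
  - {model_id: 1, marginal_effect: 0.3, ld_r2: 1.0, maf_disease: 0.2}
  - {model_id: 1, marginal_effect: 0.3, ld_r2: 1.0, maf_disease: 0.5}
  - {model_id: 2, marginal_effect: 0.3, ld_r2: 0.7, maf_disease: 0.05}
  - {model_id: 2, marginal_effect: 0.3, ld_r2: 0.7, maf_disease: 0.1}
  - {model_id: 2, marginal_effect: 0.3, ld_r2: 0.7, maf_disease: 0.2}
  - {model_id: 2, marginal_effect: 0.3, ld_r2: 0.7, maf_disease: 0.5}
  - {model_id: 2, marginal_effect: 0.3, ld_r2: 1.0, maf_disease: 0.05}
  - {model_id: 2, marginal_effect: 0.3, ld_r2: 1.0, maf_disease: 0.1}
  - {model_id: 2, marginal_effect: 0.3, ld_r2: 1.0, maf_disease: 0.2}
  - {model_id: 2, marginal_effect: 0.3, ld_r2: 1.0, maf_disease: 0.5}
  - {model_id: 3, marginal_effect: 0.6, ld_r2: 0.7, maf_disease: 0.05}
  - {model_id: 3, marginal_effect: 0.6, ld_r2: 0.7, maf_disease: 0.1}
  - {model_id: 3, marginal_effect: 0.6, ld_r2: 0.7, maf_disease: 0.2}
  - {model_id: 3, marginal_effect: 0.6, ld_r2: 0.7, maf_disease: 0.5}
  - {model_id: 3, marginal_effect: 0.6, ld_r2: 1.0, maf_disease: 0.05}
  - {model_id: 3, marginal_effect: 0.6, ld_r2: 1.0, maf_disease: 0.1}
  - {model_id: 3, marginal_effect: 0.6, ld_r2: 1.0, maf_disease: 0.2}
  - {model_id: 3, marginal_effect: 0.6, ld_r2: 1.0, maf_disease: 0.5}
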