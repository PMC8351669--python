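# Per-tissue constants used in the original GSE132040 study, for users
# reproducing that analysis with `agingnet run-all --config`.
min_library_size: 4000000
zk_threshold: 2
low_count: 10
min_age_months: 3
n_top_pca: 500
max_k: 8
slope_alpha: 0.1
pass_fraction: 0.01
min_module_size: 50
merge_height: 0.15
module_r_min: 0.5
module_fdr: 0.05
mmgs_min: 0.5
mmgs_alpha: 0.05
hub_gs: 0.2
hub_mm: 0.8
map_cutoff: 0.7
map_metric: overlap
map_inflation: 2.0
# per-tissue values (select with pipeline.study_defaults_for / --study-defaults):
#   min_per_segment: brain 3, heart 4, liver 3, muscle 2, pancreas 2
#   r2_cutoff:       brain 0.2, heart 0.2, liver 0.1, muscle 0.3, pancreas 0.3
#   soft_power:      brain 7, heart 7, liver 5, muscle 6, pancreas 7
#   deep_split:      2 everywhere except liver (4)
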