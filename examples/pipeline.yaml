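# Full pipeline run: DSLB quantification, GUV Poisson analysis,
# colocalization, and FRAP plateau comparison. All randomness derives
# from the single seed below.
seed: 1
out_dir: results/pipeline
stages: [dslb, guv, coloc, frap]
dslb:
  sim:
    n_singles: 600
    n_trimers: 120
    n_clusters: 48
  quant:
    threshold_molecules: 5.0
    cluster_min: 10.0
guv:
  sim:
    n_liposomes: 100
    lambda_clusters: 0.72
  analysis:
    cluster_threshold_factor: 2.0
coloc:
  sim:
    overlap_fraction: 0.31
frap:
  n_traces: 5
  sim_in:
    mobile_fraction: 0.74
    noise_sd: 0.03
  sim_out:
    mobile_fraction: 1.0
    noise_sd: 0.03
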