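# Bundled demo pipeline configuration: a desk-scale synthetic study that
# completes in well under a minute on one CPU. All thresholds are explicit.
seed: 7
sim:
  chrS_length: 8000000
  chrG_length: 8000000
  n_ctcf_loops: 80
  n_h3k27ac_interactions: 400
  n_genes: 600
  n_background_windows: 300
  n_weak_sites: 30
  n_nonlooping_h3k27ac: 100
qc:
  min_distance: 10000
  min_count: 4
  rule: max
classify:
  slack: 0
  span_mode: midpoint
diff:
  pre: untreated
  post: IAA
  alpha: 0.05
  min_lfc: 1.0
  pseudocount: 1.0
atac:
  alpha: 0.05
  min_lfc: 1.0
expression:
  alpha: 0.05
  min_lfc: 1.0
  rescue_tolerance: 0.5
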