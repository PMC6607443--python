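# Frozen configuration: combination weights from the LOO ROC grid
# search and thresholds calibrated on the LOO score cloud of the
# packaged training table.  Regenerate with scripts/freeze_config.py.
alpha: 1.0
log_base: 2
weight_grid:
  start: 0.0
  stop: 2.0
  step: 0.1
weights:
  identity_bg: 1.6
  identity_nb: 0.3
  volume_bg: 0.5
  volume_nb: 0.0
  polarity_nb: 0.4
thresholds:
  theta_aa: 14.488531188673488
  theta_vp: 2.992585805648128
  theta_hc: 3.814933377277156
thresholds_published:
  theta_aa: 12.9
  theta_vp: 0.1
  theta_hc: 2.7
loo_auc:
  s_aa: 0.987342
  s_vp: 0.941456
loo_confusion:
  tp: 59
  fp: 2
  tn: 30
  fn: 20
anchor_pattern: '[ST]Q[ST]'
anchor_pattern_extended: '[STIV][QM][STIV]'
disorder_threshold: 0.5
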