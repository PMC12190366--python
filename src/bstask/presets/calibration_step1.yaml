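# Unlimited-response-time calibration run: the full 121-trial BS sequence
# (one unscored lead-in + 30 scored trials per condition), no deadlines.
# Feed the logged RTs to `bstask calibrate` to derive available times.
protocol: hmw_blocks
block_count: 1
per_block_counts:
  1: 30
  2: 30
  3: 30
  4: 30
isi_feedback_ms: 500
practice_accuracy_gate: 0.90
available_times: null
max_run_length: 4
task_order: [bs]
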