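# Workload-comparison protocol: the BS task and the 2-back task, 8 blocks
# each with 8 scored trials (two per condition), 20 s rests, NASA-TLX after
# each task.
protocol: hmw_blocks
block_count: 8
per_block_counts:
  1: 2
  2: 2
  3: 2
  4: 2
rest_duration_ms: 20000
isi_feedback_ms: 500
practice_accuracy_gate: 0.90
available_times:
  1: 2300
  2: 3000
  3: 2600
  4: 2800
max_run_length: 4
task_order: [bs, 2back]
twoback_letter_ms: 500
twoback_blank_ms: 2000
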