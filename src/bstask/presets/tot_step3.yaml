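# 30-minute fatigue-induction protocol: 6 five-minute blocks of the BS task
# under calibrated time pressure, VAS after every block (plus baseline), and
# a 3-minute PVT before and after.
protocol: tot_induction
block_count: 6
block_duration_ms: 300000
isi_feedback_ms: 500
practice_accuracy_gate: 0.90
available_times:
  1: 2300
  2: 3000
  3: 2600
  4: 2800
vas_schedule:
  pre_first_block: true
  after_each_block: true
pvt_duration_ms: 180000
pvt_interval_bounds: [2000, 10000]
max_run_length: 4
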