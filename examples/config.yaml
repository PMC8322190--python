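# Decode a synthetic 60 s dichotic trial with the recurrent deep Q-agent.
seed: 0
out: results/demo
n_trials: 2
schedule: {segment_s: 30.0, total_s: 60.0, start_side: left}
generator:
  n_channels: 128
  fs: 128.0
  attended_gain: 1.0
  unattended_gain: 0.2
  noise_sd: 0.5
  seed: 0
state:
  window_s: 1.0
  hop_samples: 8
learner_kind: dql-rnn
learner:
  n_hidden: 16          # reduced from the reference width of 100 for speed
  n_hidden_layers: 1
  max_inner_iters: 25
  learning_rate: 0.1
eval_epsilon: 0.02
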