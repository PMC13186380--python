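# Desk-scale smoke configuration: 20 short episodes at 0.2 Hz input.
seed: 5
sim:
  n_episodes: 20
  duration_minutes_lognormal: [60.0, 0.2]
  max_duration_minutes: 90.0
  event_rates:
    respiratory: 1.0
    cardiovascular: 1.0
window:
  input_hz: 0.2
  no_context: false
train:
  arch: combined_transformer_vector_reduced
  task: respiratory
  hp:
    epochs: 1
    model_width: 32
    attention_heads: 2
    transformer_layers: 1
    hidden_dim: 16
evaluate:
  max_fpr: 0.20
  bootstrap_iterations: 200
explain:
  steps: 16
  n_windows: 3
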