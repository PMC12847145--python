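response_threshold: 0.55
settle_cycles: 50
max_cycles: 1000
integration_mode: net_input
layers:
  color_hidden:
    unit_labels:
    - red
    - green
    - neutral
    lateral_inhibition: -2.0
    unit_params:
    - gain: 1.0
      bias: 4.0
      integration_rate: 0.1
    - gain: 1.0
      bias: 4.0
      integration_rate: 0.1
    - gain: 1.0
      bias: 4.0
      integration_rate: 0.1
  word_hidden:
    unit_labels:
    - red
    - green
    - neutral
    lateral_inhibition: -2.0
    unit_params:
    - gain: 1.0
      bias: 4.0
      integration_rate: 0.1
    - gain: 1.0
      bias: 4.0
      integration_rate: 0.1
    - gain: 1.0
      bias: 4.0
      integration_rate: 0.1
  emotion_hidden:
    unit_labels:
    - negative
    - neutral
    - positive
    lateral_inhibition: -2.0
    unit_params:
    - gain: 1.0
      bias: 4.0
      integration_rate: 0.1
    - gain: 1.0
      bias: 4.0
      integration_rate: 0.1
    - gain: 1.0
      bias: 4.0
      integration_rate: 0.1
  task_control:
    unit_labels:
    - color_naming
    - word_reading
    - emotional_processing
    lateral_inhibition: -2.0
    unit_params:
    - gain: 1.0
      bias: 0.0
      integration_rate: 0.1
    - gain: 1.0
      bias: 0.0
      integration_rate: 0.1
    - gain: 1.0
      bias: 0.0
      integration_rate: 0.1
  response:
    unit_labels:
    - red
    - green
    lateral_inhibition: -1.0
    unit_params:
    - gain: 1.0
      bias: 1.4
      integration_rate: 0.1
    - gain: 1.0
      bias: 1.4
      integration_rate: 0.1
weights:
- source: color_hidden
  target: response
  matrix:
  - - 2.0
    - 0.0
  - - 0.0
    - 2.0
  - - 0.0
    - 0.0
- source: response
  target: color_hidden
  matrix:
  - - 2.0
    - 0.0
    - 0.0
  - - 0.0
    - 2.0
    - 0.0
- source: word_hidden
  target: response
  matrix:
  - - 2.6
    - 0.0
  - - 0.0
    - 2.6
  - - 0.0
    - 0.0
- source: response
  target: word_hidden
  matrix:
  - - 2.6
    - 0.0
    - 0.0
  - - 0.0
    - 2.6
    - 0.0
- source: emotion_hidden
  target: response
  matrix:
  - - 0.1
    - 0.1
  - - 0.1
    - 0.1
  - - 0.1
    - 0.1
- source: response
  target: emotion_hidden
  matrix:
  - - 0.1
    - 0.1
    - 0.1
  - - 0.1
    - 0.1
    - 0.1
- source: task_control
  target: color_hidden
  matrix:
  - - 4.0
    - 4.0
    - 4.0
  - - 0.0
    - 0.0
    - 0.0
  - - 0.0
    - 0.0
    - 0.0
- source: color_hidden
  target: task_control
  matrix:
  - - 4.0
    - 0.0
    - 0.0
  - - 4.0
    - 0.0
    - 0.0
  - - 4.0
    - 0.0
    - 0.0
- source: task_control
  target: word_hidden
  matrix:
  - - 0.0
    - 0.0
    - 0.0
  - - 4.0
    - 4.0
    - 4.0
  - - 0.0
    - 0.0
    - 0.0
- source: word_hidden
  target: task_control
  matrix:
  - - 0.0
    - 4.0
    - 0.0
  - - 0.0
    - 4.0
    - 0.0
  - - 0.0
    - 4.0
    - 0.0
- source: task_control
  target: emotion_hidden
  matrix:
  - - 0.0
    - 0.0
    - 0.0
  - - 0.0
    - 0.0
    - 0.0
  - - 2.0
    - 2.0
    - 2.0
- source: emotion_hidden
  target: task_control
  matrix:
  - - 0.0
    - 0.0
    - 2.0
  - - 0.0
    - 0.0
    - 2.0
  - - 0.0
    - 0.0
    - 2.0
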