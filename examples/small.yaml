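# Minute-scale demo configuration: two accelerometer-like channels,
# two gesture classes plus Null, a 4-map / 6-cell DeepConvLSTM and a
# 3-epoch training budget. See docs/methods.md for the defaults.
synthetic:
  channels_per_modality: [[acc, 2]]
  noise_sd: [[acc, 0.05]]
  template_amp: [[acc, 1.0]]
  n_classes: 3
  gestures_per_class: 8
training:
  max_epochs: 3
  patience: 5
  batch_size: 20
model:
  n_maps: 4
  n_hidden: 6
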