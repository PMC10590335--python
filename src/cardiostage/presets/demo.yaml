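# Tiny demonstration preset: 5 full-length (8-h) synthetic nights
# (a 4:1 train/validation split).
n_nights: 5
synthetic:
  duration_h: 8.0
training:
  batch_size: 2
  learning_rate: 1.0e-3
  max_epochs: 5
  patience: 5
finetune_nights: 2
finetune:
  batch_size: 2
  learning_rate: 1.0e-4
  max_epochs: 3
  patience: 3
  freeze_encoder: true
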