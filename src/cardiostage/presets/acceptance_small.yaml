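# Desk-scale experiment preset: 60 synthetic nights of 4 h.
# The generator keeps its physiological defaults (wake 70 BPM vs deep
# 56 BPM, a 14-BPM gap); nights are shortened to 4 h so a full
# train-and-evaluate cycle runs on one CPU in minutes.
n_nights: 60
synthetic:
  duration_h: 4.0
training:
  batch_size: 8
  learning_rate: 1.0e-3
  max_epochs: 50
  patience: 50
finetune_nights: 15
finetune:
  batch_size: 5
  learning_rate: 1.0e-4
  max_epochs: 30
  patience: 30
  freeze_encoder: true
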