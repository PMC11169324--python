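# Desk-scale study configuration: 130+130 phantom cases (100 train / 30 test
# per class), 48-px slices, 3x2 montages, tiny batch-normalized CNN, four
# simulated annotators with one systematic under-annotator (A1).
seed: 0

phantom:
  image_size: 48
  slices_per_case: 30
  noise_sd: 4.0

montage:
  count: 6
  interval: 5
  layout: [3, 2]
  orientation: vertical
  train_montages_per_case: 1
  test_montages_per_case: 5   # 30 positive test cases -> 150 annotated images

dataset:
  n_pos: 130
  n_neg: 130
  n_test: [30, 30]

model:
  backbone: tiny
  h1: 16
  h2: 8

train:
  learning_rate: 1.0e-2
  lr_decay: 1.0e-6
  patience: 10
  max_epochs: 20
  batch_size: 16

evaluate:
  n_boot: 2000
  ci_level: 0.95

annotators:
  - {annotator_id: A1, area_scale: 0.6, boundary_jitter_sd: 1.0, omission_prob: 0.05}
  - {annotator_id: A2, area_scale: 1.0, boundary_jitter_sd: 1.0, omission_prob: 0.05}
  - {annotator_id: A3, area_scale: 1.0, boundary_jitter_sd: 1.0, omission_prob: 0.05}
  - {annotator_id: A4, area_scale: 1.0, boundary_jitter_sd: 1.0, omission_prob: 0.05}

saliency:
  layer: ""            # empty -> last conv block (batch-normalized output)
  activation_floor: 0.0
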