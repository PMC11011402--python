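# Full-scale settings (GPU-class budgets; untested in CI).
seed: 0
n_classes: 1
scene:
  image_size: [640, 640]
augment:
  preset_size: 640
arch:
  width_base: 32
  depths: [1, 2, 3, 1]
hyp:
  batch_size: 16
  lr0: 0.01
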