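# Miniature CPU-scale run: 160 px inputs, narrow backbone.
seed: 0
n_classes: 1
scene:
  image_size: [160, 160]
  n_fruit: [1, 4]
  fruit_radius: [10, 28]
  n_leaf_occluders: [3, 8]
augment:
  preset_size: 160
arch:
  width_base: 8
  depths: [1, 1, 1, 1]
hyp:
  batch_size: 8
  lr0: 0.02
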