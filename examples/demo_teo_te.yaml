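# Four-cell demonstration study: TEO/TE x pre/post on synthetic data.
# TEO cells use the temporally flat (step) category profile; TE cells use
# the within-trial ramp; post-training cells get a contrast gain of 1.5.
# Scale is kept small so the full pipeline runs in well under a minute.
cells:
  - name: TEO_pre
    synthetic:
      n_neurons: 15
      images_per_category: 12
      trials_per_image: 5
      profile: step
      category_contrast: 2.0
      selective_fraction: 0.5
      latency_mean: 40.0
      latency_sd: 10.0
      training_gain: 1.0
      area: TEO
      session: pre
      seed: 101
  - name: TEO_post
    synthetic:
      n_neurons: 15
      images_per_category: 12
      trials_per_image: 5
      profile: step
      category_contrast: 2.0
      selective_fraction: 0.5
      latency_mean: 40.0
      latency_sd: 10.0
      training_gain: 1.5
      area: TEO
      session: post
      seed: 102
  - name: TE_pre
    synthetic:
      n_neurons: 15
      images_per_category: 12
      trials_per_image: 5
      profile: ramp
      ramp_end: 255.0
      category_contrast: 2.5
      selective_fraction: 0.5
      latency_mean: 40.0
      latency_sd: 10.0
      training_gain: 1.0
      area: TE
      session: pre
      seed: 103
  - name: TE_post
    synthetic:
      n_neurons: 15
      images_per_category: 12
      trials_per_image: 5
      profile: ramp
      ramp_end: 255.0
      category_contrast: 2.5
      selective_fraction: 0.5
      latency_mean: 40.0
      latency_sd: 10.0
      training_gain: 1.5
      area: TE
      session: post
      seed: 104
windows:
  start_min: -100.0
  start_max: 350.0
  width: 100.0
  step: 25.0
decoder:
  k: 5
  seed: 7
  reg: 1.0
inversion: ridge
responsiveness:
  baseline: [-200.0, 0.0]
  stimulus: [0.0, 350.0]
  alpha: 0.05
  family: per_neuron
contrasts:
  early: [0.0, 100.0]
  late: [250.0, 350.0]
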