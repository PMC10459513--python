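# Desk-scale synthetic experiment: 3 classes, 100 neurons, 300 presentations.
# Trains in about a minute on one CPU; expected test accuracy well above 90%
# with a handful of synaptic wiring events.
seed: 1
network:
  n_neurons: 100
dataset:
  kind: synthetic
  n_classes: 3
  n_train: 300
  n_test: 60
  noise_sd: 20.0
training:
  family: poisson
  repetitions: 10
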