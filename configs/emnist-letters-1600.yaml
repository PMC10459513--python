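# EMNIST lower-case letters a-j (10 classes), 1600 neurons.  EMNIST stores
# images transposed relative to MNIST, hence the orientation flag; the
# label filter keeps the by-class labels of lower-case a-j and remaps them
# to 0-9.  Documented protocol only — needs the EMNIST IDX files on disk
# and hours of simulation.
seed: 1
network:
  n_neurons: 1600
dataset:
  kind: idx
  transpose: true
  emnist_letters: true
  train_images: data/emnist-byclass-train-images-idx3-ubyte
  train_labels: data/emnist-byclass-train-labels-idx1-ubyte
  test_images: data/emnist-byclass-test-images-idx3-ubyte
  test_labels: data/emnist-byclass-test-labels-idx1-ubyte
training:
  family: poisson
  repetitions: 10
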