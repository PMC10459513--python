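# Full-size replication protocol: 1600 first/second-layer neurons trained on
# 75,000 MNIST presentations, tested on 10,000 held-out digits with the
# accuracy averaged over 10 repetitions.  Requires the MNIST IDX files on
# disk (never auto-downloaded) and several hours of single-core simulation;
# this configuration documents the protocol, it is not exercised by the test
# suite.
#
#   spikewire train --config configs/mnist-1600.yaml --out runs/mnist-1600
#   spikewire evaluate --checkpoint runs/mnist-1600/checkpoint.npz \
#       --config configs/mnist-1600.yaml --repetitions 10
seed: 1
network:
  n_neurons: 1600
dataset:
  kind: idx
  train_images: data/train-images-idx3-ubyte
  train_labels: data/train-labels-idx1-ubyte
  test_images: data/t10k-images-idx3-ubyte
  test_labels: data/t10k-labels-idx1-ubyte
training:
  family: poisson
  repetitions: 10
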