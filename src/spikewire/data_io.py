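"""Dataset handling: IDX (MNIST/EMNIST) files and synthetic image generation.

The IDX container is the big-endian binary format the MNIST and EMNIST
distributions use: magic bytes ``00 00 <type> <ndim>`` followed by ``ndim``
32-bit dimensions and the raw payload.  Only the unsigned-byte type (0x08)
is needed for images and labels.

The synthetic generator builds class-structured 28x28 images without any
download: each class has a fixed geometric prototype (bars, crosses, rings —
sparse bright strokes on a dark background, as in handwritten-digit data),
and instances are drawn with a small random translation plus additive
Gaussian pixel noise, clipped to [0, 255].
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .encoding import IMAGE_SHAPE, ImageSample

__all__ = [
    "Dataset",
    "IDXFormatError",
    "read_idx_array",
    "write_idx_array",
    "read_idx",
    "write_idx",
    "generate_synthetic_dataset",
    "EMNIST_LOWERCASE_AJ",
]

_IDX_UBYTE = 0x08

# EMNIST "byclass" labels of lower-case letters a-j, remapped to 0-9.
EMNIST_LOWERCASE_AJ = {36 + k: k for k in range(10)}


class IDXFormatError(ValueError):
    """Raised for malformed IDX files, with the failing byte offset."""


@dataclass
class Dataset:
    """An ordered collection of labeled 28x28 images."""

    images: np.ndarray  # (n, 28, 28) uint8
    labels: np.ndarray  # (n,) int
    n_classes: int
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 3 or self.images.shape[1:] != IMAGE_SHAPE:
            raise ValueError(f"images must be (n, 28, 28), got {self.images.shape}")
        if self.labels.shape != (self.images.shape[0],):
            raise ValueError("labels length does not match image count")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.n_classes):
            raise ValueError("labels must lie in [0, n_classes)")

    def __len__(self) -> int:
        return self.images.shape[0]

    def __getitem__(self, idx: int) -> ImageSample:
        return ImageSample(self.images[idx], int(self.labels[idx]))

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]


def read_idx_array(path) -> np.ndarray:
    """Read one IDX file into a numpy array (unsigned-byte payload)."""
    data = Path(path).read_bytes()
    if len(data) < 4:
        raise IDXFormatError(f"{path}: truncated header at offset 0")
    zero1, zero2, dtype, ndim = struct.unpack(">BBBB", data[:4])
    if zero1 != 0 or zero2 != 0:
        raise IDXFormatError(f"{path}: bad magic bytes at offset 0")
    if dtype != _IDX_UBYTE:
        raise IDXFormatError(f"{path}: unsupported type code 0x{dtype:02x} at offset 2")
    header_end = 4 + 4 * ndim
    if len(data) < header_end:
        raise IDXFormatError(f"{path}: truncated dimension list at offset 4")
    dims = struct.unpack(f">{ndim}I", data[4:header_end])
    expected = int(np.prod(dims)) if dims else 0
    payload = data[header_end:]
    if len(payload) != expected:
        raise IDXFormatError(
            f"{path}: payload of {len(payload)} bytes at offset {header_end}, "
            f"expected {expected}"
        )
    return np.frombuffer(payload, dtype=np.uint8).reshape(dims).copy()


def write_idx_array(path, array: np.ndarray) -> None:
    """Write a uint8 numpy array as an IDX file."""
    array = np.ascontiguousarray(array, dtype=np.uint8)
    with open(path, "wb") as fh:
        fh.write(struct.pack(">BBBB", 0, 0, _IDX_UBYTE, array.ndim))
        fh.write(struct.pack(f">{array.ndim}I", *array.shape))
        fh.write(array.tobytes())


def read_idx(
    image_path,
    label_path,
    transpose: bool = False,
    label_map: dict[int, int] | None = None,
    n_classes: int | None = None,
    name: str = "idx",
) -> Dataset:
    """Read an IDX image/label pair into a Dataset.

    Parameters
    ----------
    transpose : bool
        EMNIST stores images transposed relative to MNIST; set True to
        correct the orientation.
    label_map : dict, optional
        Keep only samples whose raw label is a key, remapping to the value
        (e.g. ``EMNIST_LOWERCASE_AJ`` selects lower-case a-j as classes
        0-9).
    """
    images = read_idx_array(image_path)
    labels = read_idx_array(label_path)
    if images.ndim != 3:
        raise IDXFormatError(f"{image_path}: expected 3-d image array, got {images.ndim}-d")
    if labels.ndim != 1:
        raise IDXFormatError(f"{label_path}: expected 1-d label array, got {labels.ndim}-d")
    if images.shape[0] != labels.shape[0]:
        raise IDXFormatError(
            f"image count {images.shape[0]} does not match label count {labels.shape[0]}"
        )
    if transpose:
        images = images.transpose(0, 2, 1)
    labels = labels.astype(np.int64)
    if label_map is not None:
        keep = np.isin(labels, list(label_map))
        images, labels = images[keep], labels[keep]
        labels = np.array([label_map[int(v)] for v in labels], dtype=np.int64)
    if n_classes is None:
        n_classes = int(labels.max()) + 1 if labels.size else 0
    return Dataset(images, labels, n_classes, name)


def write_idx(image_path, label_path, dataset: Dataset) -> None:
    """Write a Dataset as an IDX image/label file pair."""
    write_idx_array(image_path, dataset.images)
    write_idx_array(label_path, dataset.labels.astype(np.uint8))


# ---------------------------------------------------------------------------
# synthetic data

_FG = 230  # foreground stroke intensity


def _prototype(class_idx: int) -> np.ndarray:
    """Fixed geometric prototype for one class (bright strokes on black)."""
    img = np.zeros(IMAGE_SHAPE, dtype=float)
    y, x = np.mgrid[0:28, 0:28]
    c = 13.5
    if class_idx == 0:  # vertical bar
        img[4:24, 12:16] = _FG
    elif class_idx == 1:  # horizontal bar
        img[12:16, 4:24] = _FG
    elif class_idx == 2:  # main diagonal
        img[np.abs((y - 4) - (x - 4)) <= 1] = _FG
        img[:4] = img[24:] = 0
    elif class_idx == 3:  # anti-diagonal
        img[np.abs((y - 4) + (x - 23)) <= 1] = _FG
        img[:4] = img[24:] = 0
    elif class_idx == 4:  # plus
        img[5:23, 12:16] = _FG
        img[12:16, 5:23] = _FG
    elif class_idx == 5:  # X
        d1 = np.abs((y - 4) - (x - 4)) <= 1
        d2 = np.abs((y - 4) + (x - 23)) <= 1
        img[d1 | d2] = _FG
        img[:4] = img[24:] = 0
    elif class_idx == 6:  # square outline
        img[6:22, 6:22] = _FG
        img[9:19, 9:19] = 0
    elif class_idx == 7:  # filled disc
        img[(y - c) ** 2 + (x - c) ** 2 <= 5.5**2] = _FG
    elif class_idx == 8:  # ring
        r2 = (y - c) ** 2 + (x - c) ** 2
        img[(r2 <= 8.5**2) & (r2 >= 5.0**2)] = _FG
    elif class_idx == 9:  # T
        img[5:9, 5:23] = _FG
        img[9:23, 12:16] = _FG
    else:
        raise ValueError("at most 10 synthetic classes are defined")
    return img


def _translate(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    out = np.zeros_like(img)
    ys = slice(max(dy, 0), 28 + min(dy, 0))
    xs = slice(max(dx, 0), 28 + min(dx, 0))
    ys_src = slice(max(-dy, 0), 28 + min(-dy, 0))
    xs_src = slice(max(-dx, 0), 28 + min(-dx, 0))
    out[ys, xs] = img[ys_src, xs_src]
    return out


def generate_synthetic_dataset(
    n_classes: int,
    n_samples: int,
    noise_sd: float = 20.0,
    rng: np.random.Generator | int | None = None,
    max_shift: int = 2,
    name: str = "synthetic",
) -> Dataset:
    """Generate a balanced, seeded synthetic dataset of 28x28 images.

    Each sample is its class prototype shifted by a uniform integer offset
    in [-max_shift, max_shift] on both axes, plus additive Gaussian pixel
    noise of standard deviation ``noise_sd``, clipped to [0, 255].  Classes
    cycle so the set is balanced; identical seeds give identical datasets.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be at least 2")
    if n_classes > 10:
        raise ValueError("at most 10 synthetic classes are defined")
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(rng)
    protos = [_prototype(i) for i in range(n_classes)]

    images = np.empty((n_samples, *IMAGE_SHAPE), dtype=np.uint8)
    labels = np.empty(n_samples, dtype=np.int64)
    for i in range(n_samples):
        cls = i % n_classes
        dy, dx = rng.integers(-max_shift, max_shift + 1, size=2)
        img = _translate(protos[cls], int(dy), int(dx))
        img = img + rng.normal(0.0, noise_sd, size=IMAGE_SHAPE)
        images[i] = np.clip(img, 0, 255).round().astype(np.uint8)
        labels[i] = cls
    return Dataset(images, labels, n_classes, name)
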