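"""Poisson rate coding of grayscale images into spike trains.

Each of the 784 pixels of a 28x28 image maps onto one input-layer neuron.
Pixel intensity (0-255) is converted linearly to a firing rate between 0 and
127.5 Hz (intensity / 2), and each neuron emits an independent Poisson spike
train at that rate for the presentation duration (350 ms by default).  The
Poisson process is realized as a Bernoulli draw per timestep with success
probability rate*dt, which is the standard discrete-time approximation (at
dt = 1 ms the maximum probability is 0.1275).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ImageSample", "SpikeRecord", "pixel_to_rate", "poisson_encode"]

IMAGE_SHAPE = (28, 28)
N_INPUT = IMAGE_SHAPE[0] * IMAGE_SHAPE[1]


@dataclass
class ImageSample:
    """A 28x28 grayscale image with intensities in [0, 255] and optional label."""

    pixels: np.ndarray
    label: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != IMAGE_SHAPE:
            raise ValueError(f"expected {IMAGE_SHAPE} image, got {self.pixels.shape}")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("pixel intensities must lie in [0, 255]")


@dataclass
class SpikeRecord:
    """Binary spike raster over one presentation plus per-neuron totals.

    ``raster`` is (timesteps x neurons); ``counts`` holds the per-neuron
    spike totals S_n over the presentation window.
    """

    raster: np.ndarray
    counts: np.ndarray
    duration_ms: float = 350.0
    dt: float = 1.0

    @classmethod
    def from_raster(
        cls, raster: np.ndarray, duration_ms: float, dt: float
    ) -> "SpikeRecord":
        raster = np.asarray(raster, dtype=np.uint8)
        return cls(raster, raster.sum(axis=0).astype(np.int64), duration_ms, dt)

    def __post_init__(self) -> None:
        n_steps = int(round(self.duration_ms / self.dt))
        if self.raster.shape[0] != n_steps:
            raise ValueError(
                f"raster has {self.raster.shape[0]} rows, expected "
                f"duration_ms/dt = {n_steps}"
            )
        if not np.array_equal(self.raster.sum(axis=0), self.counts):
            raise ValueError("counts do not match raster column sums")


def pixel_to_rate(intensity):
    """Map pixel intensity 0-255 linearly onto a firing rate in Hz.

    255 maps to 127.5 Hz (intensity divided by two); accepts scalars or
    arrays.
    """
    arr = np.asarray(intensity, dtype=float)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("intensity out of range [0, 255]")
    rate = arr / 2.0
    return float(rate) if np.isscalar(intensity) else rate


def poisson_encode(
    image: ImageSample | np.ndarray,
    duration_ms: float = 350.0,
    dt: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> SpikeRecord:
    """Encode an image as independent per-pixel Poisson spike trains.

    Parameters
    ----------
    image : ImageSample or (28, 28) array
    duration_ms : float
        Presentation length; must be an integer multiple of ``dt``.
    dt : float
        Timestep in ms.
    rng : numpy Generator or seed
        Identical seeds produce bit-identical rasters.

    Returns
    -------
    SpikeRecord
        Raster of shape (duration_ms/dt, 784) in flattened row-major pixel
        order.
    """
    if isinstance(image, ImageSample):
        pixels = image.pixels
    else:
        pixels = ImageSample(np.asarray(image)).pixels

    n_steps_f = duration_ms / dt
    n_steps = int(round(n_steps_f))
    if abs(n_steps_f - n_steps) > 1e-9 or n_steps <= 0:
        raise ValueError("duration_ms must be a positive integer multiple of dt")

    rate_per_ms = pixel_to_rate(pixels).ravel() / 1000.0  # spikes per ms
    p = rate_per_ms * dt
    if np.any(p > 1.0):
        raise ValueError(
            f"rate*dt exceeds 1 (max {p.max():.3f}); decrease dt"
        )

    rng = np.random.default_rng(rng)
    raster = (rng.random((n_steps, p.size)) < p).astype(np.uint8)
    return SpikeRecord.from_raster(raster, duration_ms, dt)
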