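"""V1 front-end: a bank of zero-mean Gabor filters with on/off rectification.

Each input canvas is convolved at native resolution (reflect padding), the
responses are half-wave rectified into separate +/- polarity channels, and
then block-averaged down to a square retinal lattice whose side equals the
first-layer grid of the hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from skimage.measure import block_reduce


@dataclass(frozen=True)
class GaborBank:
    orientations: tuple          # degrees
    frequencies: tuple           # cycles/pixel
    sigma_per_cycle: float
    kernels: tuple               # kernels[i_orient][i_freq] -> 2-D array

    @property
    def n_channels(self) -> int:
        return len(self.orientations) * len(self.frequencies) * 2


def _gabor_kernel(theta_deg: float, freq: float, sigma: float) -> np.ndarray:
    half = int(np.ceil(3.0 * sigma))
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(np.float64)
    th = np.deg2rad(theta_deg)
    xr = x * np.cos(th) + y * np.sin(th)
    env = np.exp(-(x ** 2 + y ** 2) / (2.0 * sigma ** 2))  # isotropic envelope
    g = env * np.cos(2.0 * np.pi * freq * xr)
    g -= env * (g.sum() / env.sum())     # remove DC while keeping the envelope shape
    return g / np.linalg.norm(g)


def build_bank(orientations=(0.0, 45.0, 90.0, 135.0),
               frequencies=(0.0625, 0.125, 0.25),
               sigma_per_cycle: float = 0.4) -> GaborBank:
    """Build a unit-L2, DC-free Gabor bank.

    ``sigma_per_cycle`` sets the envelope width as a fraction of the carrier
    wavelength, so bandwidth is constant across frequency.
    """
    if len(orientations) < 1 or len(frequencies) < 1:
        raise ValueError("need at least one orientation and one frequency")
    for f in frequencies:
        if not 0.0 < f < 0.5:
            raise ValueError(f"frequency {f} outside (0, 0.5) cycles/pixel (Nyquist)")
    kernels = tuple(
        tuple(_gabor_kernel(th, f, sigma_per_cycle / f) for f in frequencies)
        for th in orientations
    )
    return GaborBank(tuple(orientations), tuple(frequencies),
                     sigma_per_cycle, kernels)


@dataclass
class V1Response:
    """Rectified firing rates on the retinal lattice.

    ``rates`` is indexed (lattice_row, lattice_col, orientation, frequency,
    polarity) with polarity 0 = on (positive lobe) and 1 = off.
    """

    rates: np.ndarray
    lattice_size: int

    @property
    def flat(self) -> np.ndarray:
        return self.rates.reshape(-1)


def _convolve_reflect(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    half = kernel.shape[0] // 2
    padded = np.pad(img, half, mode="reflect")
    return signal.fftconvolve(padded, kernel, mode="valid")


def filter_image(img: np.ndarray, bank: GaborBank, lattice_size: int) -> V1Response:
    """Convolve, rectify into on/off channels, subsample to the lattice."""
    img = np.asarray(img)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("image must be square and 2-D")
    side = img.shape[0]
    if lattice_size > side:
        raise ValueError("lattice_size exceeds image side")
    if side % lattice_size != 0:
        raise ValueError("image side must be a multiple of lattice_size")
    block = side // lattice_size
    x = img.astype(np.float64)
    if np.issubdtype(img.dtype, np.integer):
        x = x / 255.0

    n_or, n_fr = len(bank.orientations), len(bank.frequencies)
    rates = np.empty((lattice_size, lattice_size, n_or, n_fr, 2))
    for i in range(n_or):
        for j in range(n_fr):
            resp = _convolve_reflect(x, bank.kernels[i][j])
            on = np.clip(resp, 0.0, None)
            off = np.clip(-resp, 0.0, None)
            rates[:, :, i, j, 0] = block_reduce(on, (block, block), np.mean)
            rates[:, :, i, j, 1] = block_reduce(off, (block, block), np.mean)
    return V1Response(rates=rates, lattice_size=lattice_size)
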