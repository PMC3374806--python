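"""Feed-forward S1 -> C1 -> S2 -> C2 hierarchy.

The hierarchy alternates selectivity (S) and invariance (C) stages in the
style of the classical simple-to-complex cell cascade:

* **S1** — a bank of 64 Gabor filters (16 sizes from 7x7 to 37x37 in steps
  of two pixels, 4 orientations) applied by normalized cross-correlation.
* **C1** — local max pooling over position and over pairs of adjacent
  filter sizes ("scale bands"), yielding 8 bands x 4 orientations of
  complex-cell maps.
* **S2** — radial-basis ("bell-shaped") tuning of n x n x 4 windows of C1
  activity against stored prototype patches.
* **C2** — a global max of each prototype's S2 responses over all positions
  and all bands, producing a position- and scale-tolerant feature vector.

All responses are bounded in [0, 1]; C2 entries are strictly positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ORIENTATIONS",
    "GaborFilter",
    "GaborBank",
    "S1Maps",
    "C1Maps",
    "Prototype",
    "preprocess",
    "build_gabor_bank",
    "apply_s1",
    "pool_c1",
    "compute_c1",
    "extract_patch",
    "s2_responses",
    "compute_c2",
]

#: Filter orientations in degrees.
ORIENTATIONS: tuple[int, ...] = (0, 45, 90, 135)

#: Default receptive-field sizes (pixels, odd, 7..37 step 2).
DEFAULT_SIZES: tuple[int, ...] = tuple(range(7, 39, 2))

# Gabor envelope width sigma and carrier wavelength lambda per filter size,
# following the parameter table of the standard HMAX benchmark
# implementation; the aspect ratio gamma is 0.3 throughout.
DEFAULT_SIGMA: dict[int, float] = {
    7: 2.8, 9: 3.6, 11: 4.5, 13: 5.4, 15: 6.3, 17: 7.3, 19: 8.2, 21: 9.2,
    23: 10.2, 25: 11.3, 27: 12.3, 29: 13.4, 31: 14.6, 33: 15.8, 35: 17.0,
    37: 18.2,
}
DEFAULT_LAMBDA: dict[int, float] = {
    7: 3.5, 9: 4.6, 11: 5.6, 13: 6.8, 15: 7.9, 17: 9.1, 19: 10.3, 21: 11.5,
    23: 12.7, 25: 14.1, 27: 15.4, 29: 16.8, 31: 18.2, 33: 19.7, 35: 21.2,
    37: 22.8,
}
DEFAULT_GAMMA: float = 0.3

#: C1 spatial pooling grid size per band (overlap is half the grid).
DEFAULT_POOL_SIZES: tuple[int, ...] = (8, 10, 12, 14, 16, 18, 20, 22)

#: Legal prototype patch edge lengths (in C1 grid units).
PATCH_SIZES: tuple[int, ...] = (4, 8, 12, 16, 20, 24)

#: Default S2 sharpness: scales the tuning width sigma_n^2 = s * 4 n^2 so
#: that the median squared distance between unrelated C1 patches maps to a
#: response of about e^-1 rather than saturating near 1.
DEFAULT_SHARPNESS: float = 5e-4

_EPS = 1e-12


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaborFilter:
    """A single zero-mean, unit-norm Gabor filter."""

    size: int
    orientation: int
    wavelength: float
    sigma: float
    gamma: float
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.size % 2 == 0:
            raise ValueError(f"filter size must be odd, got {self.size}")


@dataclass(frozen=True)
class GaborBank:
    """The full S1 filter bank grouped into scale bands.

    ``bands[b]`` holds the two adjacent filter sizes pooled by C1 band
    ``b``; ``pool_sizes[b]`` / ``pool_strides[b]`` give the C1 spatial
    pooling grid for that band.
    """

    filters: tuple[GaborFilter, ...]
    bands: tuple[tuple[int, int], ...]
    pool_sizes: tuple[int, ...]
    pool_strides: tuple[int, ...]
    orientations: tuple[int, ...] = ORIENTATIONS

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(sorted({f.size for f in self.filters}))

    def filters_for(self, size: int) -> list[GaborFilter]:
        """Filters of one size, ordered by orientation."""
        by_theta = {f.orientation: f for f in self.filters if f.size == size}
        return [by_theta[t] for t in self.orientations]


class S1Maps(dict):
    """Simple-cell response maps keyed by ``(filter_size, orientation)``.

    Each value is a 2D array of responses in [0, 1]; maps for filters
    larger than the image are empty arrays.
    """


@dataclass
class C1Maps:
    """Complex-cell maps: one ``(H_b, W_b, 4)`` array per scale band."""

    bands: tuple[np.ndarray, ...]

    def __len__(self) -> int:
        return len(self.bands)

    def band(self, b: int) -> np.ndarray:
        return self.bands[b]


@dataclass(frozen=True)
class Prototype:
    """An intermediate-level feature: an n x n x 4 block of C1 activity."""

    id: int
    size: int
    values: np.ndarray  # (n, n, 4)
    provenance: tuple = ()  # (image_id, band, row, col)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.size, self.size, 4):
            raise ValueError(
                f"prototype values must be {(self.size, self.size, 4)}, "
                f"got {v.shape}"
            )
        object.__setattr__(self, "values", v)

    @property
    def is_low_energy(self) -> bool:
        """True when the patch carries (almost) no C1 activity."""
        return float(np.abs(self.values).sum()) < _EPS


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(raw_image: np.ndarray, target_height: int = 140) -> np.ndarray:
    """Convert a raster image to [0, 1] grayscale at a fixed height.

    Color images are collapsed with the Rec.601 luminance weights; integer
    images are scaled by their dtype range. The width is rescaled to
    preserve the aspect ratio (rounded to the nearest pixel). An image
    already at the target height passes through without resampling.
    """
    img = np.asarray(raw_image)
    if img.size == 0:
        raise ValueError("cannot preprocess a zero-area image")
    if img.ndim == 3:
        if img.shape[2] == 4:  # drop alpha
            img = img[..., :3]
        img = img @ np.array([0.299, 0.587, 0.114])
    elif img.ndim != 2:
        raise ValueError(f"expected a 2D or 3D raster, got ndim={img.ndim}")
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(float) / np.iinfo(img.dtype).max
    else:
        img = img.astype(float)
    h, w = img.shape
    if h != target_height:
        from skimage.transform import resize

        new_w = max(1, round(w * target_height / h))
        img = resize(img, (target_height, new_w), anti_aliasing=True,
                     mode="reflect")
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# S1: Gabor filter bank
# ---------------------------------------------------------------------------

def gabor_weights(size: int, orientation: float, wavelength: float,
                  sigma: float, gamma: float) -> np.ndarray:
    """Zero-mean, unit-L2-norm Gabor weights on a circular aperture."""
    if size % 2 == 0:
        raise ValueError(f"filter size must be odd, got {size}")
    half = size // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    # the orientation names the bar/edge direction the filter prefers
    # (0 deg = horizontal bar), so the carrier runs perpendicular to it
    theta = np.deg2rad(orientation + 90.0)
    xr = x * np.cos(theta) + y * np.sin(theta)
    yr = -x * np.sin(theta) + y * np.cos(theta)
    w = np.exp(-(xr ** 2 + (gamma * yr) ** 2) / (2.0 * sigma ** 2))
    w *= np.cos(2.0 * np.pi * xr / wavelength)
    w[x ** 2 + y ** 2 > half ** 2] = 0.0  # circular receptive field
    w -= w.mean()
    w /= np.linalg.norm(w)
    return w


def build_gabor_bank(
    sizes: Sequence[int] = DEFAULT_SIZES,
    orientations: Sequence[int] = ORIENTATIONS,
    sigma: dict[int, float] | None = None,
    wavelength: dict[int, float] | None = None,
    gamma: float = DEFAULT_GAMMA,
    pool_sizes: Sequence[int] = DEFAULT_POOL_SIZES,
) -> GaborBank:
    """Build the S1 bank: ``len(sizes) x len(orientations)`` filters in
    bands of two adjacent sizes each.

    The defaults give the canonical 64-filter bank (sizes 7..37 step 2,
    orientations 0/45/90/135) in 8 bands with pooling grids 8..22
    (overlap = half the grid).
    """
    sizes = tuple(sizes)
    if any(s % 2 == 0 for s in sizes):
        raise ValueError("all filter sizes must be odd")
    if len(sizes) % 2 != 0:
        raise ValueError("need an even number of sizes to pair into bands")
    sigma = dict(DEFAULT_SIGMA if sigma is None else sigma)
    wavelength = dict(DEFAULT_LAMBDA if wavelength is None else wavelength)
    filters = tuple(
        GaborFilter(
            size=s, orientation=t, wavelength=wavelength[s], sigma=sigma[s],
            gamma=gamma,
            weights=gabor_weights(s, t, wavelength[s], sigma[s], gamma),
        )
        for s in sizes
        for t in orientations
    )
    bands = tuple(
        (sizes[2 * b], sizes[2 * b + 1]) for b in range(len(sizes) // 2)
    )
    pool_sizes = tuple(pool_sizes)[: len(bands)]
    if len(pool_sizes) != len(bands):
        raise ValueError("one pooling grid size per band is required")
    strides = tuple(max(1, g // 2) for g in pool_sizes)  # overlap = g/2
    return GaborBank(filters=filters, bands=bands, pool_sizes=pool_sizes,
                     pool_strides=strides, orientations=tuple(orientations))


def _window_sq_norms(padded_cumsum_sq: np.ndarray, k: int) -> np.ndarray:
    """L2 norms of all valid k x k windows from a padded integral image."""
    sq = padded_cumsum_sq
    s = (sq[k:, k:] - sq[:-k, k:] - sq[k:, :-k] + sq[:-k, :-k])
    return np.sqrt(np.maximum(s, 0.0))


# Kernel spectra are reused across images of identical shape; keyed by the
# bank object identity so a rebuilt bank never serves stale spectra.
_KERNEL_FFT_CACHE: dict[tuple, tuple] = {}


def _kernel_ffts(bank: GaborBank, shape: tuple[int, int]):
    from scipy import fft as sp_fft

    key = (id(bank), shape)
    hit = _KERNEL_FFT_CACHE.get(key)
    if hit is not None:
        return hit
    sizes = [s for s in bank.sizes if s <= min(shape)]
    kmax = max(sizes)
    fshape = (sp_fft.next_fast_len(shape[0] + kmax - 1),
              sp_fft.next_fast_len(shape[1] + kmax - 1))
    kernels = np.stack([
        np.pad(f.weights[::-1, ::-1],
               ((0, fshape[0] - s), (0, fshape[1] - s)))
        for s in sizes for f in bank.filters_for(s)
    ])
    spectra = sp_fft.rfft2(kernels, axes=(1, 2))
    _KERNEL_FFT_CACHE.clear()  # keep at most one bank/shape combination
    _KERNEL_FFT_CACHE[key] = (sizes, fshape, spectra)
    return sizes, fshape, spectra


def apply_s1(image: np.ndarray, bank: GaborBank) -> S1Maps:
    """Convolve the image with every Gabor filter.

    The response at each position is the absolute normalized
    cross-correlation: the filter is zero-mean and unit-norm, and the
    image window is L2-normalized, so responses lie in [0, 1] and are
    contrast-polarity invariant. Only valid (fully overlapping) windows
    are computed, so maps shrink with filter size. Filters larger than
    the image yield empty maps and a warning.
    """
    from scipy import fft as sp_fft

    image = np.asarray(image, dtype=float)
    h, w = image.shape
    out = S1Maps()
    skipped = [s for s in bank.sizes if s > min(h, w)]
    if skipped:
        warnings.warn(
            f"image {image.shape} smaller than filter size(s) {skipped}; "
            "their maps are empty", stacklevel=2)
        for s in skipped:
            for theta in bank.orientations:
                out[(s, theta)] = np.empty((0, 0))
    if len(skipped) == len(bank.sizes):
        return out
    sizes, fshape, spectra = _kernel_ffts(bank, (h, w))
    img_fft = sp_fft.rfft2(image, fshape)
    # one inverse FFT batch gives the full linear correlation of the image
    # with every filter; the valid part for size k is the [k-1:h, k-1:w]
    # corner of its full-convolution plane
    conv = sp_fft.irfft2(img_fft[None] * spectra, fshape, axes=(1, 2))
    cs = np.pad(np.cumsum(np.cumsum(image ** 2, axis=0), axis=1),
                ((1, 0), (1, 0)))
    i = 0
    for k in sizes:
        norms = np.maximum(_window_sq_norms(cs, k), _EPS)
        for theta in bank.orientations:
            resp = np.abs(conv[i, k - 1:h, k - 1:w]) / norms
            np.clip(resp, 0.0, 1.0, out=resp)
            out[(k, theta)] = resp
            i += 1
    return out


# ---------------------------------------------------------------------------
# C1: local max pooling
# ---------------------------------------------------------------------------

def _pool_max(x: np.ndarray, g: int, stride: int) -> np.ndarray:
    """Max over g x g windows sampled every ``stride`` cells."""
    g = min(g, *x.shape)
    win = sliding_window_view(x, (g, g))[::stride, ::stride]
    return win.max(axis=(-2, -1))


def pool_c1(s1: S1Maps, bank: GaborBank) -> C1Maps:
    """Pool S1 maps into complex-cell bands.

    Each C1 cell takes the max of its spatial pooling window over both
    member filter sizes of its band, separately per orientation. The two
    scales' grids are cropped to their common extent before the
    cross-scale max.
    """
    bands = []
    for b, (s_a, s_b) in enumerate(bank.bands):
        g, stride = bank.pool_sizes[b], bank.pool_strides[b]
        per_theta = []
        for theta in bank.orientations:
            maps = [s1[(s_a, theta)], s1[(s_b, theta)]]
            pooled = [_pool_max(m, g, stride) for m in maps if m.size > 0]
            if not pooled:
                per_theta.append(np.empty((0, 0)))
                continue
            h = min(p.shape[0] for p in pooled)
            w = min(p.shape[1] for p in pooled)
            per_theta.append(
                np.max([p[:h, :w] for p in pooled], axis=0))
        h = min(p.shape[0] for p in per_theta)
        w = min(p.shape[1] for p in per_theta)
        bands.append(np.stack([p[:h, :w] for p in per_theta], axis=-1))
    return C1Maps(bands=tuple(bands))


def compute_c1(image: np.ndarray, bank: GaborBank) -> C1Maps:
    """Convenience: S1 then C1 in one call."""
    return pool_c1(apply_s1(image, bank), bank)


# ---------------------------------------------------------------------------
# S2 / C2: prototype tuning and global max
# ---------------------------------------------------------------------------

def extract_patch(c1: C1Maps, band: int, row: int, col: int, n: int,
                  image_id: int = -1, proto_id: int = -1) -> Prototype:
    """Copy an n x n x 4 window of C1 activity out as a prototype."""
    grid = c1.band(band)
    if row < 0 or col < 0 or row + n > grid.shape[0] or col + n > grid.shape[1]:
        raise IndexError(
            f"patch [{row}:{row + n}, {col}:{col + n}] out of bounds for "
            f"band {band} grid {grid.shape[:2]}")
    values = grid[row:row + n, col:col + n, :].copy()
    p = Prototype(id=proto_id, size=n, values=values,
                  provenance=(image_id, band, row, col))
    if p.is_low_energy:
        warnings.warn("extracted a low-energy (near-zero) patch",
                      stacklevel=2)
    return p


def s2_sigma_sq(n: int, sharpness: float = DEFAULT_SHARPNESS) -> float:
    """Tuning width sigma^2 for patch size n: proportional to the element
    count 4 n^2, keeping dynamic range comparable across patch sizes."""
    return sharpness * 4.0 * n * n


def s2_responses(c1: C1Maps, p: Prototype,
                 sharpness: float = DEFAULT_SHARPNESS) -> list[np.ndarray | None]:
    """Bell-shaped tuning of the prototype against every C1 window.

    At each valid position the response is
    ``exp(-||X - p||^2 / (2 sigma_n^2))`` with the patch-size-dependent
    width from :func:`s2_sigma_sq`; responses lie in (0, 1]. Returns one
    response grid per band (``None`` where the patch does not fit).
    """
    n = p.size
    two_sig = 2.0 * s2_sigma_sq(n, sharpness)
    flat = p.values.reshape(-1)
    out: list[np.ndarray | None] = []
    any_fit = False
    for grid in c1.bands:
        if grid.shape[0] < n or grid.shape[1] < n:
            out.append(None)
            continue
        any_fit = True
        win = sliding_window_view(grid, (n, n, 4)).reshape(
            grid.shape[0] - n + 1, grid.shape[1] - n + 1, -1)
        d2 = ((win - flat) ** 2).sum(axis=-1)
        out.append(np.exp(-d2 / two_sig))
    if not any_fit:
        raise ValueError(
            f"patch size {n} exceeds every C1 band grid")
    return out


def compute_c2(c1: C1Maps, prototypes: Iterable[Prototype],
               sharpness: float = DEFAULT_SHARPNESS) -> np.ndarray:
    """Global max of each prototype's S2 responses over positions and bands.

    Returns a vector with one strictly positive entry in (0, 1] per
    prototype; an empty prototype pool gives an empty vector (an
    untrained model).
    """
    protos = list(prototypes)
    if not protos:
        return np.empty(0)
    return np.array([
        max(float(r.max()) for r in s2_responses(c1, p, sharpness)
            if r is not None and r.size)
        for p in protos
    ])
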