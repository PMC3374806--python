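"""Seeded synthetic face / distractor image generator.

The generator is the packaged stand-in for a photographic face-vs-clutter
benchmark: schematic faces (a head oval, two eye blobs, a mouth bar) are
rendered over low-contrast cluttered backgrounds with seeded jitter in
position, scale and contrast. Distractors are block-scrambled versions of
faces: they contain the same local parts with identical first-order pixel
statistics (a scramble is a permutation), but the configural arrangement
of the parts — what the intermediate-level prototypes are supposed to
capture — is destroyed. Classification therefore cannot rely on mean
luminance or local edge statistics alone.

Salt-and-pepper corruption replaces an exact, seeded-random set of pixels
with black or white, so the nominal noise level is exact per image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "FaceParams",
    "DEFAULT_NOISE_LEVELS",
    "generate_face",
    "generate_distractor",
    "add_salt_pepper",
    "make_benchmark",
    "Benchmark",
]

DEFAULT_NOISE_LEVELS: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8)

#: Canvas edge length (pixels); images come out at the model's working height.
CANVAS: int = 140


@dataclass(frozen=True)
class FaceParams:
    """Jittered geometry of one schematic face on a CANVAS x CANVAS canvas.

    All parts are guaranteed inside the canvas; draw via
    :meth:`from_seed` for seeded jitter around the canonical layout.
    """

    center: tuple[float, float] = (70.0, 70.0)      # (row, col)
    head_axes: tuple[float, float] = (45.0, 34.0)   # (semi-minor=row, col)
    eye_offset: tuple[float, float] = (14.0, 15.0)  # rows above, cols aside
    eye_radius: float = 5.0
    mouth_drop: float = 20.0                        # rows below center
    mouth_halfwidth: float = 12.0
    mouth_halfheight: float = 2.0
    contrast: float = 0.8
    clutter: float = 0.08
    seed: int = 0

    @classmethod
    def from_seed(cls, seed: int) -> "FaceParams":
        rng = np.random.default_rng(seed)
        return cls(
            center=(70 + rng.uniform(-8, 8), 70 + rng.uniform(-8, 8)),
            head_axes=(45 * rng.uniform(0.85, 1.1),
                       34 * rng.uniform(0.85, 1.1)),
            eye_offset=(14 + rng.uniform(-2, 2), 15 + rng.uniform(-2.5, 2.5)),
            eye_radius=5 * rng.uniform(0.8, 1.2),
            mouth_drop=20 + rng.uniform(-3, 3),
            mouth_halfwidth=12 * rng.uniform(0.8, 1.2),
            mouth_halfheight=2 + rng.uniform(0, 1.5),
            contrast=0.8 * rng.uniform(0.8, 1.2),
            clutter=0.08 * rng.uniform(0.5, 1.5),
            seed=seed,
        )


def _background(rng: np.random.Generator, clutter: float) -> np.ndarray:
    """Low-pass filtered noise around mid-gray."""
    noise = gaussian_filter(rng.standard_normal((CANVAS, CANVAS)), sigma=6.0)
    noise /= max(noise.std(), 1e-9)
    return 0.5 + clutter * noise


def _soft_ellipse(shape: tuple[int, int], center, axes,
                  softness: float = 1.5) -> np.ndarray:
    """[0, 1] mask of an axis-aligned ellipse with soft edges."""
    rr, cc = np.mgrid[: shape[0], : shape[1]].astype(float)
    d = np.sqrt(((rr - center[0]) / axes[0]) ** 2
                + ((cc - center[1]) / axes[1]) ** 2)
    return np.clip((1.0 - d) * axes[0] / softness / 4.0 + 0.5, 0.0, 1.0)


def generate_face(params: FaceParams | int) -> np.ndarray:
    """Render one schematic face; deterministic per seed.

    An ``int`` argument is shorthand for ``FaceParams.from_seed(int)``.
    """
    if isinstance(params, (int, np.integer)):
        params = FaceParams.from_seed(int(params))
    rng = np.random.default_rng(params.seed)
    img = _background(rng, params.clutter)
    cr, cc = params.center
    k = params.contrast
    head = _soft_ellipse((CANVAS, CANVAS), (cr, cc), params.head_axes)
    img += 0.18 * k * head
    dr, dc = params.eye_offset
    for sign in (-1.0, 1.0):
        eye = _soft_ellipse((CANVAS, CANVAS), (cr - dr, cc + sign * dc),
                            (params.eye_radius, params.eye_radius))
        img -= 0.45 * k * eye
    mouth = _soft_ellipse((CANVAS, CANVAS), (cr + params.mouth_drop, cc),
                          (params.mouth_halfheight, params.mouth_halfwidth))
    img -= 0.35 * k * mouth
    return np.clip(img, 0.0, 1.0)


def generate_distractor(seed: int, block: int = 28) -> np.ndarray:
    """Block-scrambled face: matched parts and statistics, no face layout.

    The canvas is cut into ``block`` x ``block`` tiles which are randomly
    permuted and rotated in multiples of 90 degrees. A permutation leaves
    the pixel histogram (hence mean luminance) of the source face exactly
    unchanged while destroying the eyes/mouth configuration.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5C]))
    face = generate_face(int(rng.integers(2 ** 31)))
    g = CANVAS // block
    tiles = [face[i * block:(i + 1) * block, j * block:(j + 1) * block]
             for i in range(g) for j in range(g)]
    order = rng.permutation(len(tiles))
    rots = rng.integers(0, 4, size=len(tiles))
    out = face.copy()
    for k, (src, rot) in enumerate(zip(order, rots)):
        i, j = divmod(k, g)
        out[i * block:(i + 1) * block, j * block:(j + 1) * block] = (
            np.rot90(tiles[src], rot))
    return out


def add_salt_pepper(image: np.ndarray, level: float,
                    seed: int = 0) -> np.ndarray:
    """Replace exactly ``round(level * n_pixels)`` distinct pixels by 0 or 1.

    Salt and pepper are equally likely per corrupted pixel; all other
    pixels are untouched. ``level`` 0 is the identity; 1 blackens or
    whitens every pixel.
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"noise level must be in [0, 1], got {level}")
    out = np.asarray(image, dtype=float).copy()
    k = round(level * out.size)
    if k == 0:
        return out
    rng = np.random.default_rng(seed)
    idx = rng.choice(out.size, size=k, replace=False)
    out.ravel()[idx] = rng.integers(0, 2, size=k).astype(float)
    return out


@dataclass
class Benchmark:
    """A labelled synthetic face/distractor set.

    ``train_images`` are always noise-free; ``test_sets[level]`` holds a
    balanced (images, labels) pair at one salt-and-pepper level. Labels
    are +1 for faces, -1 for distractors.
    """

    train_images: list = field(default_factory=list)
    train_labels: np.ndarray = field(default_factory=lambda: np.empty(0))
    test_sets: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def noise_levels(self) -> tuple[float, ...]:
        return tuple(self.test_sets)


def make_benchmark(n_faces: int = 60, n_distractors: int = 60,
                   noise_levels: Sequence[float] = DEFAULT_NOISE_LEVELS,
                   seed: int = 0,
                   n_train_per_class: int = 60) -> Benchmark:
    """Generate the full benchmark: a noise-free training set plus one
    balanced test set of ``n_faces + n_distractors`` fresh images per
    noise level (5 levels x 120 images = 600 test stimuli at the
    defaults). Deterministic per seed.
    """
    if min(n_faces, n_distractors, n_train_per_class) < 1:
        raise ValueError("image counts must be >= 1")
    for lv in noise_levels:
        if not 0.0 <= lv <= 1.0:
            raise ValueError(f"noise level must be in [0, 1], got {lv}")
    root = np.random.SeedSequence(seed)
    ss_train, ss_test = root.spawn(2)

    def _seeds(ss, n):
        return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]

    ss_train_f, ss_train_d, ss_order = ss_train.spawn(3)
    train_images = (
        [generate_face(s) for s in _seeds(ss_train_f, n_train_per_class)]
        + [generate_distractor(s) for s in _seeds(ss_train_d,
                                                  n_train_per_class)])
    train_labels = np.array([1] * n_train_per_class
                            + [-1] * n_train_per_class)
    # present the two classes interleaved, not in blocks: the vigilance
    # stream is order-sensitive and a blocked order is unrealistic
    order = np.random.default_rng(ss_order).permutation(len(train_images))
    train_images = [train_images[i] for i in order]
    train_labels = train_labels[order]
    test_sets = {}
    for lv, ss_lv in zip(noise_levels, ss_test.spawn(len(noise_levels))):
        ss_f, ss_d, ss_n = ss_lv.spawn(3)
        clean = ([generate_face(s) for s in _seeds(ss_f, n_faces)]
                 + [generate_distractor(s) for s in _seeds(ss_d, n_distractors)])
        noise_seeds = _seeds(ss_n, len(clean))
        images = [add_salt_pepper(im, lv, s)
                  for im, s in zip(clean, noise_seeds)]
        labels = np.array([1] * n_faces + [-1] * n_distractors)
        test_sets[float(lv)] = (images, labels)
    return Benchmark(train_images=train_images, train_labels=train_labels,
                     test_sets=test_sets, seed=seed)
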