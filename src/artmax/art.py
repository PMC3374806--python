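"""Vigilance-gated, append-only prototype learning.

This module implements the adaptive-resonance-style match/mismatch loop
that replaces random patch sampling in the standard HMAX training stage.
Each training image is presented exactly once:

1. its C2 vector is computed against the current prototype pool;
2. the *P* most active C2 units are selected as the candidate
   representation of the image (top-down match);
3. every selected unit whose response falls below the vigilance
   threshold *rho* is a mismatch — the stored prototypes cannot account
   for that part of the image — and triggers extraction of fresh patches
   from the image's own C1 activity, which are appended to the pool.

The pool is strictly append-only: learning new images never modifies or
removes existing prototypes, which is the stability half of the
stability-plasticity dilemma; the vigilance test supplies the
plasticity half. Re-presenting a learned image adds nothing, because its
own patches match themselves with response 1.

A seeded random-patch sampler (:func:`random_patch_baseline`) reproduces
the indiscriminate patch selection of the standard HMAX training stage
and serves as the comparison baseline throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .hierarchy import (
    C1Maps,
    DEFAULT_SHARPNESS,
    GaborBank,
    PATCH_SIZES,
    Prototype,
    build_gabor_bank,
    compute_c1,
    compute_c2,
)

__all__ = [
    "VigilanceConfig",
    "PrototypePool",
    "PresentationRecord",
    "present_image",
    "train_stream",
    "random_patch_baseline",
]


@dataclass(frozen=True)
class VigilanceConfig:
    """Parameters of the vigilance learning loop.

    Parameters
    ----------
    rho:
        Vigilance threshold in [0, 1]. A selected C2 unit with response
        below ``rho`` is a mismatch. Low values give broad, frozen pools;
        values near 1 demand near-exact matches and grow many specific
        prototypes. There is no canonical value; 0.9 is a default that
        favours few but informative features.
    top_p:
        Number of most-active C2 units deemed sufficient to represent one
        image (*P*).
    patch_sizes:
        Patch edge lengths (C1 grid units) drawn from when a mismatch
        triggers extraction.
    new_per_mismatch:
        Patches appended per mismatching slot.
    seed:
        Seed for the patch-site sampler.
    max_prototypes:
        Optional hard cap on pool growth; ``None`` means unbounded. Used
        to train a model with a prescribed feature budget.
    site_policy:
        Where a mismatch-triggered patch is taken from.
        ``"random"`` (default) — uniform over valid (band, row, col)
        sites, the convention of the random-sampling training stage this
        model extends. ``"uncovered"`` — draw ``n_site_candidates``
        random sites within one random band and keep the one least
        explained by the current same-size prototypes (novelty-directed
        extraction). ``"energy"`` — the valid window with the highest
        summed C1 activity (deterministic).
    n_site_candidates:
        Candidate sites examined by the ``"uncovered"`` policy.
    sharpness:
        S2 tuning-width multiplier passed through to the hierarchy. The
        default maps the typical squared distance between unrelated C1
        patches to a response of about e^-1, so the match value actually
        resolves similar from dissimilar patches instead of saturating.
    """

    rho: float = 0.9
    top_p: int = 5
    patch_sizes: tuple[int, ...] = (4, 8, 12, 16)
    new_per_mismatch: int = 1
    seed: int = 0
    max_prototypes: int | None = None
    site_policy: str = "random"
    n_site_candidates: int = 8
    sharpness: float = DEFAULT_SHARPNESS

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"vigilance rho must be in [0, 1], got {self.rho}")
        if self.top_p < 1:
            raise ValueError("top_p must be a positive integer")
        if self.new_per_mismatch < 1:
            raise ValueError("new_per_mismatch must be a positive integer")
        bad = set(self.patch_sizes) - set(PATCH_SIZES)
        if not self.patch_sizes or bad:
            raise ValueError(
                f"patch_sizes must be a non-empty subset of {PATCH_SIZES}, "
                f"got {self.patch_sizes}")
        if self.site_policy not in ("uncovered", "random", "energy"):
            raise ValueError(f"unknown site_policy {self.site_policy!r}")
        if self.n_site_candidates < 1:
            raise ValueError("n_site_candidates must be >= 1")


class PrototypePool:
    """An append-only, ordered collection of prototypes.

    Elements are never modified or removed once added — this is the
    model's stability guarantee — and ids increase strictly with
    insertion order. ``created_at[i]`` records the index of the image
    whose presentation added prototype ``i`` (-1 when unknown).
    """

    def __init__(self) -> None:
        self._protos: list[Prototype] = []
        self._created_at: list[int] = []

    def __len__(self) -> int:
        return len(self._protos)

    def __iter__(self):
        return iter(self._protos)

    def __getitem__(self, i: int) -> Prototype:
        return self._protos[i]

    @property
    def prototypes(self) -> tuple[Prototype, ...]:
        return tuple(self._protos)

    @property
    def created_at(self) -> tuple[int, ...]:
        return tuple(self._created_at)

    def append(self, values: np.ndarray, size: int, provenance: tuple,
               image_index: int = -1) -> Prototype:
        """Append a new prototype; its id is the next free integer."""
        p = Prototype(id=len(self._protos), size=size, values=values,
                      provenance=provenance)
        self._protos.append(p)
        self._created_at.append(image_index)
        return p

    def append_prototype(self, p: Prototype, image_index: int = -1) -> Prototype:
        """Append an existing patch, re-identified for this pool."""
        return self.append(p.values, p.size, p.provenance, image_index)

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        """Serialize to JSON (header + per-prototype value payload).

        The round trip is bit-exact: floats are emitted with ``repr``
        (shortest round-trip) precision.
        """
        return json.dumps({
            "format": "artmax-pool",
            "version": 1,
            "prototypes": [
                {
                    "id": p.id,
                    "size": p.size,
                    "provenance": list(p.provenance),
                    "created_at": self._created_at[i],
                    "values": p.values.ravel().tolist(),
                }
                for i, p in enumerate(self._protos)
            ],
        })

    @classmethod
    def from_json(cls, text: str) -> "PrototypePool":
        doc = json.loads(text)
        if doc.get("format") != "artmax-pool":
            raise ValueError("not a prototype-pool document")
        pool = cls()
        for rec in doc["prototypes"]:
            n = rec["size"]
            values = np.array(rec["values"], dtype=float).reshape(n, n, 4)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pool.append(values, n, tuple(rec["provenance"]),
                            rec["created_at"])
        return pool

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "PrototypePool":
        with open(path) as fh:
            return cls.from_json(fh.read())


@dataclass(frozen=True)
class PresentationRecord:
    """Outcome of presenting one image to the learning loop."""

    image_id: int
    selected_values: tuple[float, ...]   # top-P C2 responses (empty pool: ())
    selected_ids: tuple[int, ...]        # prototype ids of the selected units
    matched: tuple[bool, ...]            # per selected slot: response >= rho
    n_unfilled: int                      # P minus available C2 units
    n_added: int                         # prototypes appended


def _valid_sites(c1: C1Maps, n: int) -> list[tuple[int, int, int]]:
    """All (band, max_row, max_col) bands admitting an n x n patch."""
    sites = []
    for b, grid in enumerate(c1.bands):
        if grid.shape[0] >= n and grid.shape[1] >= n:
            sites.append((b, grid.shape[0] - n + 1, grid.shape[1] - n + 1))
    return sites


def _sample_patch(c1: C1Maps, cfg: VigilanceConfig,
                  rng: np.random.Generator,
                  pool: "PrototypePool | None" = None,
                  ) -> tuple[int, int, int, int]:
    """Choose (band, row, col, n) for a new patch under the site policy."""
    fitting = [n for n in cfg.patch_sizes if _valid_sites(c1, n)]
    if not fitting:
        raise ValueError(
            f"no patch size in {cfg.patch_sizes} fits any C1 band")
    n = int(rng.choice(fitting))
    sites = _valid_sites(c1, n)

    def draw() -> tuple[int, int, int]:
        b, nrows, ncols = sites[int(rng.integers(len(sites)))]
        return b, int(rng.integers(nrows)), int(rng.integers(ncols))

    if cfg.site_policy == "random":
        return (*draw(), n)
    if cfg.site_policy == "uncovered":
        # keep the candidate window whose best match against the stored
        # same-size prototypes is worst: the least-explained content.
        # candidates come from a single uniformly drawn band so the
        # policy spreads within a scale without skewing the allocation
        # across scales (distance magnitudes differ between bands)
        same = ([p.values.reshape(-1) for p in pool if p.size == n]
                if pool is not None else [])
        band, nrows, ncols = sites[int(rng.integers(len(sites)))]
        cands = [(band, int(rng.integers(nrows)), int(rng.integers(ncols)))
                 for _ in range(cfg.n_site_candidates)]
        if not same:
            return (*cands[0], n)
        bank = np.stack(same)
        best_site, best_novelty = cands[0], -np.inf
        for b, r, c in cands:
            win = c1.band(b)[r:r + n, c:c + n, :].reshape(-1)
            novelty = float(((bank - win) ** 2).sum(axis=1).min())
            # larger distance to nearest stored patch == less covered
            if novelty > best_novelty:
                best_novelty, best_site = novelty, (b, r, c)
        return (*best_site, n)
    # "energy": deterministic, the window with the largest summed activity
    best, best_e = None, -1.0
    for b, nrows, ncols in sites:
        grid = c1.band(b).sum(axis=-1)
        cs = np.pad(np.cumsum(np.cumsum(grid, 0), 1), ((1, 0), (1, 0)))
        wins = cs[n:, n:] - cs[:-n, n:] - cs[n:, :-n] + cs[:-n, :-n]
        r, c = np.unravel_index(int(wins.argmax()), wins.shape)
        if wins[r, c] > best_e:
            best, best_e = (b, int(r), int(c), n), float(wins[r, c])
    return best


def _as_c1(image, bank: GaborBank) -> C1Maps:
    return image if isinstance(image, C1Maps) else compute_c1(image, bank)


def present_image(image, pool: PrototypePool, cfg: VigilanceConfig,
                  bank: GaborBank | None = None,
                  rng: np.random.Generator | None = None,
                  image_id: int = -1) -> PresentationRecord:
    """Present one image to the vigilance loop, growing ``pool`` in place.

    ``image`` may be a preprocessed grayscale array or a precomputed
    :class:`~artmax.hierarchy.C1Maps` (the latter avoids recomputing the
    filter cascade when images are revisited). Ties in the top-P
    selection break toward the lower (older) prototype id.

    Returns the :class:`PresentationRecord`; the updated pool is the one
    passed in (append-only mutation).
    """
    if bank is None:
        bank = _default_bank()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    c1 = _as_c1(image, bank)
    c2 = compute_c2(c1, pool, cfg.sharpness)
    k = min(cfg.top_p, len(c2))
    if k > 0:
        # sort by (-response, id): highest response first, older id on ties
        order = np.lexsort((np.arange(len(c2)), -c2))[:k]
        sel_vals = tuple(float(c2[i]) for i in order)
        sel_ids = tuple(int(i) for i in order)
        matched = tuple(v >= cfg.rho for v in sel_vals)
    else:
        sel_vals, sel_ids, matched = (), (), ()
    n_unfilled = cfg.top_p - k
    n_mismatch = sum(not m for m in matched) + n_unfilled
    n_added = 0
    for _ in range(n_mismatch * cfg.new_per_mismatch):
        if cfg.max_prototypes is not None and len(pool) >= cfg.max_prototypes:
            break
        b, r, c, n = _sample_patch(c1, cfg, rng, pool=pool)
        patch = c1.band(b)[r:r + n, c:c + n, :].copy()
        if np.abs(patch).sum() < 1e-12:
            warnings.warn("appending a low-energy (near-zero) patch",
                          stacklevel=2)
        pool.append(patch, n, (image_id, b, r, c), image_index=image_id)
        n_added += 1
    return PresentationRecord(
        image_id=image_id, selected_values=sel_vals, selected_ids=sel_ids,
        matched=matched, n_unfilled=n_unfilled, n_added=n_added)


_BANK_CACHE: list = []


def _default_bank() -> GaborBank:
    if not _BANK_CACHE:
        _BANK_CACHE.append(build_gabor_bank())
    return _BANK_CACHE[0]


def train_stream(images: Sequence, cfg: VigilanceConfig,
                 bank: GaborBank | None = None,
                 pool: PrototypePool | None = None,
                 ) -> tuple[PrototypePool, list[PresentationRecord]]:
    """Fold :func:`present_image` over an image stream, once per image.

    Learning is single-presentation: each image is seen exactly once, in
    order. The result is prefix-consistent — the pool after *k* images
    equals the pool trained on the length-*k* prefix alone.
    """
    if not len(images):
        raise ValueError("training stream must be non-empty")
    if bank is None:
        bank = _default_bank()
    if pool is None:
        pool = PrototypePool()
    rng = np.random.default_rng(cfg.seed)
    records = []
    for i, image in enumerate(images):
        records.append(
            present_image(image, pool, cfg, bank=bank, rng=rng, image_id=i))
    return pool, records


def random_patch_baseline(images: Sequence, n_patches: int,
                          patch_sizes: Sequence[int] = (4, 8, 12, 16),
                          seed: int = 0,
                          bank: GaborBank | None = None) -> PrototypePool:
    """Indiscriminate patch sampling — the standard HMAX training stage.

    Samples ``n_patches`` patches uniformly over (image, band, position)
    with sizes drawn uniformly from ``patch_sizes``, resampling when a
    size fits no band of the chosen image. Deterministic under ``seed``.
    """
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    if bank is None:
        bank = _default_bank()
    rng = np.random.default_rng(seed)
    c1s = [_as_c1(img, bank) for img in images]
    pool = PrototypePool()
    while len(pool) < n_patches:
        i = int(rng.integers(len(c1s)))
        n = int(rng.choice(list(patch_sizes)))
        sites = _valid_sites(c1s[i], n)
        if not sites:
            continue  # patch size fits no band of this image: resample
        b, nrows, ncols = sites[int(rng.integers(len(sites)))]
        r, c = int(rng.integers(nrows)), int(rng.integers(ncols))
        patch = c1s[i].band(b)[r:r + n, c:c + n, :].copy()
        pool.append(patch, n, (i, b, r, c), image_index=i)
    return pool
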