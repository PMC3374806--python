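"""Stability diagnostic: average minimum patch distance over learning.

The experiment measures whether newly learned prototypes crowd out old
knowledge. Images arrive in steps of *m* (default 2). After each step the
training pool has grown — by vigilance-gated extraction for the proposed
model, or by an equal count of random patches for the baseline — and we
measure how far each patch of a test bag is from its nearest training
patch (Euclidean distance on the flattened n x n x 4 values). The test
bag is either re-extracted each step from all previously seen images
except the current step's (the default, probing retention of the
model's own past) or a fixed held-out image set. A falling trace means
the pool increasingly covers the test material without forgetting: the
trend slope is the stability summary, more negative being more stable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .art import (
    PrototypePool,
    VigilanceConfig,
    present_image,
    random_patch_baseline,
)
from .evaluation import run_classification
from .hierarchy import C1Maps, GaborBank, Prototype

__all__ = [
    "StabilityTrace",
    "avg_min_distance",
    "extract_test_patches",
    "stability_run",
    "stability_compare",
    "trend_slope",
    "patch_size_sweep",
]


@dataclass
class StabilityTrace:
    """Per-step record of one stability run."""

    model: str                       # "proposed" | "baseline"
    patch_size: int
    steps: list                      # step index, from 1
    images_seen: list
    pool_sizes: list
    distances: list                  # average minimum distance per step

    def slope(self) -> float:
        return trend_slope(self.distances)


def avg_min_distance(test_patches: Sequence[Prototype],
                     train_patches: Sequence[Prototype]) -> float:
    """Mean over test patches of the distance to the closest train patch.

    Distances are Euclidean on the flattened n x n x 4 values and are
    only defined between patches of equal size; a test patch with no
    size-compatible training partner is an error.
    """
    if not len(test_patches) or not len(train_patches):
        raise ValueError("both patch sets must be non-empty")
    by_size: dict[int, np.ndarray] = {}
    for n in {p.size for p in train_patches}:
        by_size[n] = np.stack([p.values.ravel() for p in train_patches
                               if p.size == n])
    mins = []
    for p in test_patches:
        bank = by_size.get(p.size)
        if bank is None:
            raise ValueError(
                f"no training patch of size {p.size} to compare against")
        d = np.linalg.norm(bank - p.values.ravel(), axis=1)
        mins.append(float(d.min()))
    return float(np.mean(mins))


def extract_test_patches(c1_list: Sequence[C1Maps], per_image: int,
                         patch_sizes: Sequence[int],
                         seed: int = 0) -> list[Prototype]:
    """Random-site patches from the held-out bag (same policy as training)."""
    pool = random_patch_baseline(c1_list, per_image * len(c1_list),
                                 patch_sizes=patch_sizes, seed=seed)
    return list(pool)


def stability_run(stream_c1: Sequence[C1Maps],
                  test_patches,
                  cfg: VigilanceConfig,
                  m_per_step: int = 2,
                  bank: GaborBank | None = None,
                  model: str = "proposed",
                  matched_pool_sizes: Sequence[int] | None = None,
                  ) -> StabilityTrace:
    """Run one model over the stream and trace the distance per step.

    ``model="proposed"`` grows the pool by vigilance learning;
    ``model="baseline"`` appends random patches from the same step's
    images instead, up to the per-step pool sizes in
    ``matched_pool_sizes`` (required), so both traces compare
    equal-sized pools drawn from the same images at every step.

    ``test_patches`` is either one fixed patch list (a held-out bag,
    measured at every step) or a per-step sequence of patch lists
    (``None`` entries skip the measurement at that step, recorded as
    NaN) as produced for the growing seen-images protocol.
    """
    if model not in ("proposed", "baseline"):
        raise ValueError(f"unknown model tag {model!r}")
    if model == "baseline" and matched_pool_sizes is None:
        raise ValueError("baseline runs need matched_pool_sizes")
    n_steps = len(stream_c1) // m_per_step
    if n_steps < 1:
        raise ValueError("stream shorter than one step")
    per_step = (list(test_patches) if test_patches
                and isinstance(test_patches[0], (list, tuple, type(None)))
                else [list(test_patches)] * n_steps)
    trace = StabilityTrace(model=model, patch_size=min(cfg.patch_sizes),
                           steps=[], images_seen=[], pool_sizes=[],
                           distances=[])
    pool = PrototypePool()
    rng = np.random.default_rng(cfg.seed)
    for step in range(n_steps):
        batch = stream_c1[step * m_per_step:(step + 1) * m_per_step]
        if model == "proposed":
            for j, c1 in enumerate(batch):
                present_image(c1, pool, cfg, bank=bank, rng=rng,
                              image_id=step * m_per_step + j)
        else:
            need = matched_pool_sizes[step] - len(pool)
            if need > 0:
                extra = random_patch_baseline(
                    batch, need, patch_sizes=cfg.patch_sizes,
                    seed=int(rng.integers(2 ** 31)))
                for p in extra:
                    pool.append(p.values, p.size, p.provenance)
        bag = per_step[step]
        trace.steps.append(step + 1)
        trace.images_seen.append((step + 1) * m_per_step)
        trace.pool_sizes.append(len(pool))
        trace.distances.append(
            avg_min_distance(bag, list(pool)) if bag else float("nan"))
    return trace


def stability_compare(stream_c1: Sequence[C1Maps],
                      cfg: VigilanceConfig,
                      m_per_step: int = 2,
                      bank: GaborBank | None = None,
                      test_bag: str | Sequence[C1Maps] = "seen",
                      test_patches_per_image: int | None = None,
                      test_seed: int = 991,
                      ) -> tuple[StabilityTrace, StabilityTrace]:
    """Proposed-vs-baseline stability under the matched-count protocol.

    The baseline draws exactly as many random patches per step as
    vigilance learning added, from the same images, so pool sizes agree
    at every step. The test bag is either

    * ``"seen"`` (default) — at each step, fresh random-site patches are
      extracted from every image seen so far *except* the current step's
      m images; the bag grows with the stream, and the first step has no
      bag (NaN). This probes how well the pool keeps representing its
      own past.
    * an explicit list of held-out C1 maps — a fixed disjoint bag whose
      patches are extracted once.

    Test patches are plain C1 windows, so the same patch sets serve both
    models.
    """
    per_image = (cfg.top_p if test_patches_per_image is None
                 else test_patches_per_image)
    n_steps = len(stream_c1) // m_per_step
    if isinstance(test_bag, str):
        if test_bag != "seen":
            raise ValueError(f"unknown test bag mode {test_bag!r}")
        seed_seq = np.random.SeedSequence(test_seed).spawn(n_steps)
        test_patches = []
        for step, ss in enumerate(seed_seq):
            seen = stream_c1[: step * m_per_step]
            if not seen:
                test_patches.append(None)
                continue
            s = int(ss.generate_state(1)[0] % (2 ** 31))
            test_patches.append(extract_test_patches(
                seen, per_image, cfg.patch_sizes, seed=s))
    else:
        test_patches = extract_test_patches(
            list(test_bag), per_image, cfg.patch_sizes, seed=test_seed)
    proposed = stability_run(stream_c1, test_patches, cfg,
                             m_per_step=m_per_step, bank=bank,
                             model="proposed")
    baseline = stability_run(stream_c1, test_patches, cfg,
                             m_per_step=m_per_step, bank=bank,
                             model="baseline",
                             matched_pool_sizes=proposed.pool_sizes)
    return proposed, baseline


def trend_slope(distances: Sequence[float]) -> float:
    """Least-squares slope of the distance trace against the step index.

    NaN entries (steps without a test bag) are excluded; their step
    indices keep their position on the time axis.
    """
    d = np.asarray(distances, dtype=float)
    t = np.arange(d.size, dtype=float)
    keep = ~np.isnan(d)
    if keep.sum() < 2:
        raise ValueError("need at least two trace points")
    return float(np.polyfit(t[keep], d[keep], 1)[0])


def patch_size_sweep(train_c1, train_labels, test_c1, test_labels,
                     sizes: Sequence[int],
                     cfg: VigilanceConfig,
                     m_per_step: int = 2,
                     bank: GaborBank | None = None,
                     test_bag_c1: Sequence[C1Maps] | None = None):
    """Stability slope and classification accuracy per patch size.

    For each size the vigilance model is retrained with that single
    patch size; the stability trace runs over the training stream (held
    out bag: the test images unless a separate bag is given) and the
    classification protocol scores the test set. Returns a DataFrame
    with one row per size, supporting the stability-versus-performance
    comparison.
    """
    import pandas as pd

    from .art import train_stream

    bag = "seen" if test_bag_c1 is None else test_bag_c1
    rows = []
    for n in sizes:
        size_cfg = replace(cfg, patch_sizes=(int(n),))
        prop, base = stability_compare(train_c1, size_cfg,
                                       m_per_step=m_per_step, bank=bank,
                                       test_bag=bag)
        pool, _ = train_stream(train_c1, size_cfg, bank=bank)
        res = run_classification(train_c1, train_labels,
                                 test_c1, test_labels, pool,
                                 sharpness=size_cfg.sharpness)
        rows.append({
            "patch_size": int(n),
            "slope_proposed": prop.slope(),
            "slope_baseline": base.slope(),
            "pool_size": len(pool),
            "equilibrium_acc": res.equilibrium_acc,
        })
    return pd.DataFrame(rows)
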