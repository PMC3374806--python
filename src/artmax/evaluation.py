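"""Classification head and signal-detection evaluation.

C2 feature vectors are classified by a linear support-vector machine and
scored with signal-detection measures:

* **equilibrium accuracy** — accuracy at the decision threshold where the
  false-positive rate equals the miss rate;
* **d'** — ``z(hit rate) - z(false-alarm rate)`` with the standard
  1/(2N) correction for perfect rates;
* **ROC envelopes** — vertically averaged mean, min and max ROC curves
  over repeated runs;
* a repeated random-split protocol reporting mean +/- SD accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

from .art import PrototypePool, VigilanceConfig, train_stream
from .hierarchy import DEFAULT_SHARPNESS, GaborBank, compute_c2

__all__ = [
    "EvalResult",
    "fit_linear_classifier",
    "equilibrium_accuracy",
    "equilibrium_point",
    "d_prime",
    "roc_envelope",
    "RocEnvelope",
    "feature_matrix",
    "run_classification",
    "repeated_protocol",
    "sweep_vigilance",
]


@dataclass
class EvalResult:
    """Decision scores plus the derived signal-detection summary."""

    scores: np.ndarray
    labels: np.ndarray
    equilibrium_acc: float
    hit_rate: float
    false_alarm_rate: float
    dprime: float
    fpr: np.ndarray
    tpr: np.ndarray


def _check_two_class(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not (np.any(labels == 1) and np.any(labels == -1)):
        raise ValueError("both classes (+1 and -1) must be present")
    return labels


def fit_linear_classifier(features: np.ndarray, labels: np.ndarray,
                          C: float = 1.0) -> SVC:
    """Fit a maximum-margin linear SVM on raw C2 features.

    Features are used unstandardized — C2 entries already live in (0, 1]
    on a common scale. Deterministic given the data.
    """
    _check_two_class(labels)
    clf = SVC(kernel="linear", C=C)
    clf.fit(np.asarray(features, dtype=float), labels)
    return clf


def equilibrium_point(scores: Sequence[float],
                      labels: Sequence[int]) -> tuple[float, float]:
    """The threshold where false alarms balance misses, and its accuracy.

    Sweeps every achievable threshold (classify ``score >= t`` as
    positive, plus the all-negative cut) and picks the one minimizing
    ``|FPR - FNR|``; ties resolve to the lower threshold. Returns
    ``(threshold, accuracy)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_class(labels)
    pos, neg = labels == 1, labels == -1
    n_pos, n_neg = pos.sum(), neg.sum()
    cuts = np.concatenate([np.unique(scores), [np.inf]])
    best_t, best_acc, best_gap = cuts[0], 0.0, np.inf
    for t in cuts:  # ascending: first (lowest) threshold wins ties
        pred_pos = scores >= t
        fpr = (pred_pos & neg).sum() / n_neg
        fnr = (~pred_pos & pos).sum() / n_pos
        gap = abs(fpr - fnr)
        if gap < best_gap - 1e-12:
            best_gap = gap
            best_t = t
            best_acc = ((pred_pos & pos).sum()
                        + (~pred_pos & neg).sum()) / labels.size
    return float(best_t), float(best_acc)


def equilibrium_accuracy(scores: Sequence[float],
                         labels: Sequence[int]) -> float:
    """Accuracy at the equilibrium threshold (see
    :func:`equilibrium_point`)."""
    return equilibrium_point(scores, labels)[1]


def d_prime(hit_rate: float, false_alarm_rate: float,
            n_signal: int | None = None,
            n_noise: int | None = None) -> float:
    """Signal-detection sensitivity ``z(H) - z(F)``.

    Perfect rates are undefined under the normal quantile, so when trial
    counts are supplied, 0 is replaced by ``1/(2N)`` and 1 by
    ``1 - 1/(2N)`` (the standard log-linear correction); without counts,
    rates must already lie strictly inside (0, 1).
    """
    def clip(rate: float, n: int | None) -> float:
        if rate in (0.0, 1.0):
            if n is None:
                raise ValueError(
                    "rate of exactly 0 or 1 needs a trial count to clip")
            lo = 1.0 / (2 * n)
            return lo if rate == 0.0 else 1.0 - lo
        return rate

    h = clip(float(hit_rate), n_signal)
    f = clip(float(false_alarm_rate), n_noise)
    if not (0 < h < 1 and 0 < f < 1):
        raise ValueError("rates must be in (0, 1) after clipping")
    return float(norm.ppf(h) - norm.ppf(f))


@dataclass
class RocEnvelope:
    """Mean/min/max ROC curves on a common false-positive-rate grid."""

    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    min_tpr: np.ndarray
    max_tpr: np.ndarray


def roc_envelope(results: Sequence[EvalResult | tuple],
                 grid_points: int = 101) -> RocEnvelope:
    """Vertically average ROC curves across runs.

    Accepts :class:`EvalResult` objects or raw ``(fpr, tpr)`` pairs. Each
    curve is linearly interpolated onto a common FPR grid; the min/max
    envelopes bound every individual run pointwise.
    """
    if not len(results):
        raise ValueError("need at least one run")
    grid = np.linspace(0.0, 1.0, grid_points)
    curves = []
    for r in results:
        fpr, tpr = (r.fpr, r.tpr) if isinstance(r, EvalResult) else r
        curves.append(np.interp(grid, fpr, tpr))
    curves = np.vstack(curves)
    return RocEnvelope(fpr_grid=grid, mean_tpr=curves.mean(axis=0),
                       min_tpr=curves.min(axis=0), max_tpr=curves.max(axis=0))


# ---------------------------------------------------------------------------
# end-to-end protocol
# ---------------------------------------------------------------------------

def feature_matrix(c1_list: Sequence, pool: PrototypePool,
                   sharpness: float = DEFAULT_SHARPNESS) -> np.ndarray:
    """Stack C2 vectors of many images into an (images x pool) matrix."""
    return np.array([compute_c2(c1, pool, sharpness) for c1 in c1_list])


def run_classification(train_c1, train_labels, test_c1, test_labels,
                       pool: PrototypePool,
                       sharpness: float = DEFAULT_SHARPNESS,
                       C: float = 1.0) -> EvalResult:
    """Train the linear SVM on C2 features and score the test set.

    The hit and false-alarm rates (hence d') are taken at the
    equilibrium threshold, the same operating point the accuracy is
    reported at, so sensitivity is measured free of decision bias.
    """
    test_labels = _check_two_class(test_labels)
    clf = fit_linear_classifier(
        feature_matrix(train_c1, pool, sharpness), train_labels, C=C)
    scores = clf.decision_function(feature_matrix(test_c1, pool, sharpness))
    t_eq, acc = equilibrium_point(scores, test_labels)
    pred = scores >= t_eq
    pos, neg = test_labels == 1, test_labels == -1
    hit = (pred & pos).sum() / pos.sum()
    fa = (pred & neg).sum() / neg.sum()
    dp = d_prime(hit, fa, n_signal=int(pos.sum()), n_noise=int(neg.sum()))
    fpr, tpr, _ = roc_curve(test_labels, scores)
    return EvalResult(scores=scores, labels=test_labels,
                      equilibrium_acc=acc, hit_rate=float(hit),
                      false_alarm_rate=float(fa), dprime=dp,
                      fpr=fpr, tpr=tpr)


def repeated_protocol(c1_list: Sequence, labels: np.ndarray,
                      build_pool: Callable[[Sequence, np.ndarray, int],
                                           PrototypePool],
                      n_runs: int = 20, seed: int = 0,
                      n_train_per_class: int | None = None,
                      sharpness: float = DEFAULT_SHARPNESS,
                      C: float = 1.0,
                      ) -> tuple[float, float, list[EvalResult]]:
    """Repeated random-split evaluation; reports mean and SD accuracy.

    Each run draws a fresh seeded split (equal class counts; half of each
    class by default), calls ``build_pool(train_c1, train_labels,
    run_seed)`` to learn features on the training half only, and scores
    the held-out half at the equilibrium point.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    labels = _check_two_class(labels)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == -1)
    results = []
    root = np.random.SeedSequence(seed)
    for run_ss in root.spawn(n_runs):
        rng = np.random.default_rng(run_ss)
        run_seed = int(run_ss.generate_state(1)[0] % (2 ** 31))
        tr, te = [], []
        for idx in (pos_idx, neg_idx):
            k = (len(idx) // 2 if n_train_per_class is None
                 else n_train_per_class)
            perm = rng.permutation(idx)
            tr.extend(perm[:k])
            te.extend(perm[k:])
        tr, te = np.array(tr), np.array(te)
        pool = build_pool([c1_list[i] for i in tr], labels[tr], run_seed)
        results.append(run_classification(
            [c1_list[i] for i in tr], labels[tr],
            [c1_list[i] for i in te], labels[te],
            pool, sharpness=sharpness, C=C))
    accs = np.array([r.equilibrium_acc for r in results])
    return float(accs.mean()), float(accs.std()), results


def sweep_vigilance(train_c1, train_labels, held_out_c1, held_out_labels,
                    rhos: Sequence[float],
                    base_cfg: VigilanceConfig,
                    bank: GaborBank | None = None,
                    C: float = 1.0) -> list[dict]:
    """Evaluate candidate vigilance values on a held-out set.

    Returns one record per rho with the learned pool size and held-out
    equilibrium accuracy, supporting the convention of choosing the
    vigilance that attains the highest performance with the fewest
    prototypes.
    """
    from dataclasses import replace

    out = []
    for rho in rhos:
        cfg = replace(base_cfg, rho=float(rho))
        pool, _ = train_stream(train_c1, cfg, bank=bank)
        res = run_classification(train_c1, train_labels,
                                 held_out_c1, held_out_labels, pool,
                                 sharpness=cfg.sharpness, C=C)
        out.append({"rho": float(rho), "pool_size": len(pool),
                    "equilibrium_acc": res.equilibrium_acc})
    return out
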