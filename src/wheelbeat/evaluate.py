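"""Evaluation protocols and biometric metrics.

Two protocols mirror realistic enrolment regimes on the synthetic cohorts:

- ``70-30``: per subject, the chronologically first 70% of ensembles train
  and the last 30% test; with ``folds > 1`` the subject's sequence is
  instead partitioned into contiguous blocks and each block serves as the
  test set of one fold (so every ensemble is tested exactly once).
- ``30s``: only ensembles wholly inside the first 30 s of each subject's
  first recording train; everything else tests (scarce-enrolment regime).

Because 5 s frames advance by 1 s, chronologically adjacent frames share
4 s of signal; any test frame overlapping a training frame of the same
recording is excluded before scoring to avoid leakage.

Metrics: IDR (closed-set identification accuracy) and EER.  The EER is the
equal-error point of the ROC convex hull (the standard pool-adjacent-
violators construction used in speaker verification), which interpolates
between achievable operating points and is invariant under strictly
monotone score transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from wheelbeat.recognize import (
    DecisionState,
    score_matrix,
    train,
)

__all__ = [
    "ProtocolConfig",
    "FrameDataset",
    "MetricsReport",
    "split",
    "exclude_overlapping",
    "compute_idr",
    "compute_eer",
    "evaluate_protocol",
]

FRAME_S = 5.0


@dataclass(frozen=True)
class ProtocolConfig:
    """Evaluation protocol: split kind, folds, RNG seed."""

    kind: str = "70-30"            # "70-30" | "30s"
    folds: int = 1
    train_fraction: float = 0.7
    train_window_s: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("70-30", "30s"):
            raise ValueError("protocol kind must be '70-30' or '30s'")
        if self.folds < 1:
            raise ValueError("folds must be at least 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train fraction must lie in (0, 1)")


@dataclass
class FrameDataset:
    """Per-ensemble features with identity, time and recording bookkeeping.

    ``t`` is each frame's start time within its recording; ``group``
    identifies the recording (trip) so overlap exclusion never reaches
    across different recordings.
    """

    X: np.ndarray
    y: np.ndarray
    t: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y)
        self.t = np.asarray(self.t, dtype=float)
        self.group = np.asarray(self.group)
        n = self.X.shape[0]
        if not (self.y.size == self.t.size == self.group.size == n):
            raise ValueError("dataset arrays must align")

    def __len__(self) -> int:
        return self.X.shape[0]


def split(dataset: FrameDataset, cfg: ProtocolConfig, fold: int = 0
          ) -> tuple[np.ndarray, np.ndarray]:
    """Train/test indices, stratified per subject, chronologically contiguous.

    ``70-30`` with ``folds == 1``: first ``train_fraction`` of each
    subject's ensembles (in dataset order) train, the rest test.  With
    ``folds == k > 1``: block ``fold`` of k contiguous blocks tests, the
    others train.  ``30s``: ensembles of each subject's first recording
    whose frame lies wholly inside the first ``train_window_s`` seconds
    train; all other ensembles test.
    """
    if not 0 <= fold < cfg.folds:
        raise ValueError("fold out of range")
    train_idx: list[int] = []
    test_idx: list[int] = []
    for subject in np.unique(dataset.y):
        idx = np.flatnonzero(dataset.y == subject)
        n = idx.size
        if cfg.kind == "70-30":
            if cfg.folds == 1:
                cut = int(round(cfg.train_fraction * n))
                train_idx.extend(idx[:cut])
                test_idx.extend(idx[cut:])
            else:
                lo = int(round(fold * n / cfg.folds))
                hi = int(round((fold + 1) * n / cfg.folds))
                test_idx.extend(idx[lo:hi])
                train_idx.extend(idx[:lo])
                train_idx.extend(idx[hi:])
        else:  # 30s
            groups = dataset.group[idx]
            first = groups[0]
            in_first = groups == first
            fits = dataset.t[idx] + FRAME_S <= cfg.train_window_s
            is_train = in_first & fits
            train_idx.extend(idx[is_train])
            test_idx.extend(idx[~is_train])
    return np.asarray(sorted(train_idx), int), np.asarray(sorted(test_idx), int)


def exclude_overlapping(dataset: FrameDataset, train_idx: np.ndarray,
                        test_idx: np.ndarray, frame_s: float = FRAME_S
                        ) -> np.ndarray:
    """Drop test frames sharing signal with any training frame.

    Frames overlap when they come from the same recording and their start
    times differ by less than the frame length.
    """
    keep = []
    for i in test_idx:
        same = train_idx[dataset.group[train_idx] == dataset.group[i]]
        if same.size and np.any(np.abs(dataset.t[same] - dataset.t[i]) < frame_s):
            continue
        keep.append(i)
    return np.asarray(keep, int)


def compute_idr(predictions, truths) -> float:
    """Identification rate: fraction of test ensembles correctly identified."""
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.size != truths.size or predictions.size == 0:
        raise ValueError("predictions and truths must align and be non-empty")
    return float(np.mean(predictions == truths))


def _roc_points(genuine: np.ndarray, impostor: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC operating points (FPR, TPR, threshold) for accept iff score >= t."""
    thresholds = np.unique(np.concatenate([genuine, impostor]))[::-1]
    fpr = [0.0]
    tpr = [0.0]
    thr = [np.inf]
    for th in thresholds:
        fpr.append(float(np.mean(impostor >= th)))
        tpr.append(float(np.mean(genuine >= th)))
        thr.append(float(th))
    return np.asarray(fpr), np.asarray(tpr), np.asarray(thr)


def _upper_hull(fpr: np.ndarray, tpr: np.ndarray, thr: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper convex hull of the ROC points (monotone-chain)."""
    pts = sorted(zip(fpr, tpr, thr), key=lambda p: (p[0], p[1]))
    hull: list[tuple[float, float, float]] = []
    for p in pts:
        while len(hull) >= 2:
            (x1, y1, _), (x2, y2, _) = hull[-2], hull[-1]
            cross = (x2 - x1) * (p[1] - y1) - (y2 - y1) * (p[0] - x1)
            if cross >= 0:  # hull turns the wrong way; drop the middle point
                hull.pop()
            else:
                break
        hull.append(p)
    h = np.asarray(hull)
    return h[:, 0], h[:, 1], h[:, 2]


def compute_eer(genuine, impostor) -> tuple[float, float]:
    """Equal error rate and its threshold, from the ROC convex hull.

    Finds where the hull crosses the FAR = FRR (tpr = 1 - fpr) line,
    interpolating linearly along the crossing segment; the threshold is
    interpolated with the same weight between the segment's endpoint
    thresholds.  Returns ``(eer, threshold)`` with EER as a fraction.
    """
    genuine = np.asarray(genuine, dtype=float)
    impostor = np.asarray(impostor, dtype=float)
    if genuine.size == 0 or impostor.size == 0:
        raise ValueError("need both genuine and impostor scores")
    fpr, tpr, thr = _upper_hull(*_roc_points(genuine, impostor))
    # f = tpr + fpr - 1 rises from -1 at (0,0) to +1 at (1,1)
    f = tpr + fpr - 1.0
    k = int(np.searchsorted(f >= 0, True))
    if k == 0:
        return float(fpr[0]), float(thr[0])
    f0, f1 = f[k - 1], f[k]
    w = 0.0 if f1 == f0 else (0.0 - f0) / (f1 - f0)
    eer = float(fpr[k - 1] + w * (fpr[k] - fpr[k - 1]))
    t0 = thr[k - 1] if np.isfinite(thr[k - 1]) else thr[k]
    t1 = thr[k]
    threshold = float(t0 + w * (t1 - t0))
    return eer, threshold


@dataclass
class MetricsReport:
    """Identification/authentication metrics of one protocol run."""

    idr: float
    eer: float
    idr_weighted: float | None = None
    eer_user_mean: float | None = None
    per_identity: dict = field(default_factory=dict)
    n_train: int = 0
    n_test: int = 0
    folds: int = 1

    def to_dict(self) -> dict:
        return {
            "idr": self.idr,
            "eer": self.eer,
            "idr_weighted": self.idr_weighted,
            "eer_user_mean": self.eer_user_mean,
            "per_identity": self.per_identity,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "folds": self.folds,
        }


def _weighted_predictions(dataset: FrameDataset, test_idx: np.ndarray,
                          S: np.ndarray, classes: np.ndarray,
                          n_history: int = 4, sigma_s: float = 2.0
                          ) -> np.ndarray:
    """Chronological past-score smoothing within each recording."""
    from wheelbeat.recognize import weight_scores

    preds = np.empty(test_idx.size, dtype=object)
    order = np.lexsort((dataset.t[test_idx], dataset.group[test_idx].astype(str),
                        dataset.y[test_idx].astype(str)))
    states: dict = {}
    for pos in order:
        i = test_idx[pos]
        key = (str(dataset.y[i]), str(dataset.group[i]))
        state = states.setdefault(key, DecisionState(n_history=n_history,
                                                     sigma_s=sigma_s))
        t = float(dataset.t[i])
        sw = weight_scores(state, S[pos], t_now=t)
        state.push(t, S[pos])
        preds[pos] = str(classes[int(np.argmax(sw))])
    return preds.astype(str)


def evaluate_protocol(dataset: FrameDataset, cfg: ProtocolConfig,
                      kind: str = "svm", model_config: dict | None = None,
                      weighted: bool = False, user_tuned: bool = False,
                      seed: int = 0) -> MetricsReport:
    """Train, score and measure under one protocol.

    Returns IDR and pooled EER (full cross-claims: every test ensemble is
    claimed against every enrolled identity), averaged over folds.  With
    ``weighted`` the report also carries the IDR after past-score
    smoothing; with ``user_tuned`` the mean of per-identity EERs (the
    per-user-threshold analogue of the pooled EER).
    """
    idrs, eers, widrs, ueers = [], [], [], []
    per_identity: dict[str, list] = {}
    n_train_total = n_test_total = 0
    for fold in range(cfg.folds):
        train_idx, test_idx = split(dataset, cfg, fold)
        test_idx = exclude_overlapping(dataset, train_idx, test_idx)
        if train_idx.size == 0 or test_idx.size == 0:
            raise ValueError("protocol produced an empty train or test set")
        model = train(dataset.X[train_idx], dataset.y[train_idx], kind=kind,
                      config=model_config, seed=seed)
        S = score_matrix(model, dataset.X[test_idx])
        truths = dataset.y[test_idx].astype(str)
        preds = np.asarray([str(model.classes[i]) for i in np.argmax(S, axis=1)])
        idrs.append(compute_idr(preds, truths))
        if weighted:
            wpreds = _weighted_predictions(dataset, test_idx, S, model.classes)
            widrs.append(compute_idr(wpreds, truths))

        fold_eers = []
        for i, identity in enumerate(model.classes):
            genuine = S[truths == str(identity), i]
            impostor = S[truths != str(identity), i]
            if genuine.size == 0 or impostor.size == 0:
                continue
            eer_i, _ = compute_eer(genuine, impostor)
            fold_eers.append(eer_i)
            per_identity.setdefault(str(identity), []).append(eer_i)
        # pooled EER over all claims
        genuine_all = np.concatenate(
            [S[truths == str(c), i] for i, c in enumerate(model.classes)])
        impostor_all = np.concatenate(
            [S[truths != str(c), i] for i, c in enumerate(model.classes)])
        eer, _ = compute_eer(genuine_all, impostor_all)
        eers.append(eer)
        if user_tuned and fold_eers:
            ueers.append(float(np.mean(fold_eers)))
        n_train_total += train_idx.size
        n_test_total += test_idx.size

    return MetricsReport(
        idr=float(np.mean(idrs)),
        eer=float(np.mean(eers)),
        idr_weighted=float(np.mean(widrs)) if widrs else None,
        eer_user_mean=float(np.mean(ueers)) if ueers else None,
        per_identity={k: float(np.mean(v)) for k, v in per_identity.items()},
        n_train=n_train_total,
        n_test=n_test_total,
        folds=cfg.folds,
    )
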