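"""KNN classification of filtered spectral features and clip-level aggregation.

A window's preictal posterior is the class-1 share of exponential
distance weights over its K nearest training windows:

    Pr(G=1 | x) = sum_{y in K1} exp(-||y - x||^2 / 2)
                / sum_{y in K}  exp(-||y - x||^2 / 2)

with K the K-neighbour set and K1 its class-1 subset.  The n window
posteriors of a clip are aggregated into one preictal probability by
complementing the geometric mean of the complements:

    Pr(preictal | clip) = 1 - (prod_t (1 - p_t))^(1/n)

which for a 600 s clip under 60 s / 30 s windows runs over n = 19 windows.

Cross-validation is leave-one-seizure-out: each one-hour preictal sequence
is the validation unit of exactly one fold, with interictal sequences
distributed round-robin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .filters import FilterWeights, apply_filters
from .iodata import ClipManifest, IEEGClip
from .spectral import WindowSpec, clip_spectrum

DEFAULT_K = 40


@dataclass
class KNNModel:
    """Distance-weighted KNN over standardized feature rows.

    Features are standardized with the training mean/scale before any
    distance is computed (constant features get scale 1); the model itself
    is just the training matrix.
    """

    features: np.ndarray
    labels: np.ndarray
    k: int = DEFAULT_K
    standardize: bool = True
    mean_: np.ndarray = field(init=False, repr=False)
    scale_: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.labels = np.asarray(self.labels).astype(int)
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels disagree on sample count")
        if self.k < 1 or self.k > self.features.shape[0]:
            raise ValueError(
                f"K={self.k} outside [1, N={self.features.shape[0]}]"
            )
        present = set(np.unique(self.labels))
        if not present <= {0, 1}:
            raise ValueError(f"labels must be 0/1, got {sorted(present)}")
        if present != {0, 1}:
            raise ValueError("both classes must be present in the training set")
        if self.standardize:
            self.mean_ = self.features.mean(axis=0)
            scale = self.features.std(axis=0, ddof=0)
            scale[scale == 0] = 1.0
            self.scale_ = scale
        else:
            self.mean_ = np.zeros(self.features.shape[1])
            self.scale_ = np.ones(self.features.shape[1])
        self._std_features = (self.features - self.mean_) / self.scale_

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]


def knn_posterior(model: KNNModel, x: np.ndarray) -> float:
    """Preictal posterior for one feature vector (see module docstring).

    Neighbour ties at the K-th distance are broken by stable training-row
    order.  Weights are evaluated with a max-shift in log space so that the
    nearest neighbour always contributes weight 1; if every shifted weight
    still underflows the class-1 fraction among the K neighbours is
    returned.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    if x.shape[0] != model.features.shape[1]:
        raise ValueError(
            f"x has {x.shape[0]} features, model expects {model.features.shape[1]}"
        )
    xs = (x - model.mean_) / model.scale_
    d2 = np.einsum("ij,ij->i", model._std_features - xs, model._std_features - xs)
    order = np.argsort(d2, kind="stable")[: model.k]
    d2k = d2[order]
    w = np.exp(-(d2k - d2k.min()) / 2.0)
    total = w.sum()
    labels_k = model.labels[order]
    if total == 0 or not np.isfinite(total):  # pragma: no cover - max-shift prevents this
        return float(labels_k.mean())
    return float(w[labels_k == 1].sum() / total)


def knn_posteriors(model: KNNModel, xs: np.ndarray) -> np.ndarray:
    return np.array([knn_posterior(model, x) for x in np.atleast_2d(xs)])


def aggregate(window_posteriors: Sequence[float]) -> float:
    """Clip-level preictal probability: complement of the geometric mean of complements.

    Computed in log space; any window posterior of exactly 1 forces the
    aggregate to 1.
    """
    p = np.asarray(window_posteriors, dtype=float)
    if p.size == 0:
        raise ValueError("no window posteriors to aggregate")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("window posteriors must lie in [0, 1]")
    if np.any(p == 1.0):
        return 1.0
    with np.errstate(divide="ignore"):
        return float(1.0 - np.exp(np.mean(np.log1p(-p))))


@dataclass(frozen=True)
class ClipPrediction:
    clip_name: str
    window_posteriors: np.ndarray
    preictal_probability: float


@dataclass(frozen=True)
class Fold:
    validation_sequences: tuple[int, ...]
    training_sequences: tuple[int, ...]


@dataclass(frozen=True)
class FoldPlan:
    folds: tuple[Fold, ...]


def sequence_ids(manifest_rows: pd.DataFrame) -> pd.Series:
    """Assign a one-hour-sequence id to each clip row of one (subject, kind).

    Clips are scanned in ascending segment_index; a new sequence starts
    whenever sequence_index fails to increase (contest sequences run 1..6).
    """
    rows = manifest_rows.sort_values("segment_index")
    ids = np.empty(len(rows), dtype=int)
    seq, prev = 0, None
    for i, s in enumerate(rows["sequence_index"].to_numpy()):
        if prev is not None and s <= prev:
            seq += 1
        ids[i] = seq
        prev = s
    return pd.Series(ids, index=rows.index)


def loso_folds(manifest: ClipManifest, subject_id: str) -> FoldPlan:
    """Leave-one-seizure-out folds for one subject.

    Each preictal one-hour sequence (one seizure) is the validation unit of
    exactly one fold; interictal sequences join validation sets round-robin
    by ascending sequence id.  Sequence ids are globally numbered with
    preictal sequences first.
    """
    pre = manifest.select(subject_id, "preictal")
    inter = manifest.select(subject_id, "interictal")
    if pre.empty:
        raise ValueError(f"subject {subject_id} has no preictal sequences")
    pre_ids = sequence_ids(pre)
    n_pre = int(pre_ids.max()) + 1
    if n_pre < 2:
        raise ValueError(
            f"subject {subject_id} has {n_pre} preictal sequence(s); need >= 2 for LOSO"
        )
    inter_ids = sequence_ids(inter) + n_pre if not inter.empty else pd.Series(dtype=int)
    n_inter = (int(inter_ids.max()) + 1 - n_pre) if len(inter_ids) else 0
    all_ids = set(range(n_pre + n_inter))
    folds = []
    for v in range(n_pre):
        val = [v] + [n_pre + j for j in range(n_inter) if j % n_pre == v]
        train = sorted(all_ids - set(val))
        folds.append(Fold(tuple(val), tuple(train)))
    return FoldPlan(tuple(folds))


def fold_sequence_table(manifest: ClipManifest, subject_id: str) -> pd.DataFrame:
    """Per-clip table with the sequence id used by loso_folds."""
    parts = []
    pre = manifest.select(subject_id, "preictal")
    n_pre = 0
    if not pre.empty:
        ids = sequence_ids(pre)
        n_pre = int(ids.max()) + 1
        pre = pre.assign(sequence_id=ids)
        parts.append(pre)
    inter = manifest.select(subject_id, "interictal")
    if not inter.empty:
        parts.append(inter.assign(sequence_id=sequence_ids(inter) + n_pre))
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()


def predict_clips(
    weights: FilterWeights,
    model: KNNModel,
    clips: Sequence[IEEGClip],
    window_spec: WindowSpec = WindowSpec(),
    spectrum: str = "magnitude",
    log_order: str = "pre",
) -> list[ClipPrediction]:
    """Run the full pipeline on each clip: windows -> spectra -> filters -> KNN -> aggregate."""
    predictions = []
    for clip in clips:
        tensor = clip_spectrum(clip, window_spec, spectrum, log_order)
        feats = apply_filters(tensor, weights)
        posts = knn_posteriors(model, feats)
        predictions.append(
            ClipPrediction(
                clip_name=clip.name,
                window_posteriors=posts,
                preictal_probability=aggregate(posts),
            )
        )
    return predictions
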