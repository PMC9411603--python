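"""Training protocol and ensembling.

For every hyperparameter combination from the covering array, k-fold
cross-validation (record-level, stratified) trains k fold-models; the fold
with the lowest validation loss — averaged over its final epochs to damp
noise — becomes that combination's *single optimal model*. At inference a
record's slices are scored and their softmax vectors averaged; the ensemble
takes the plurality vote over the single optimal models' labels ("minority
obeys the majority"), breaking ties by the highest summed probability and
then by class order.
"""
from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .model import DseResNetClassifier, encode_aux
from .nn.layers import DTYPE
from .preprocess import EcgPreprocessor, TwoDimSlice
from .records import CLASSES, EcgRecord


@dataclass(frozen=True)
class TrainConfig:
    """One training run: covering-array hyperparameters plus protocol knobs.

    `model` carries `DseResNetClassifier` architecture overrides (reduced
    configurations for desk-scale runs); `val_window` is the number of final
    epochs whose validation losses are averaged for fold selection.
    """

    learning_rate: float = 0.1
    dropout: float = 0.5
    momentum: float = 0.9
    epochs: int = 50
    folds: int = 5
    batch_size: int = 32
    seed: int = 0
    val_window: int = 5
    model: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if self.epochs < 1:
            raise ValueError("need at least 1 epoch")


@dataclass
class FoldResult:
    fold_index: int
    train_loss_curve: list[float]
    val_loss_curve: list[float]
    val_acc_curve: list[float]
    final_val_loss: float
    model: DseResNetClassifier | None
    diverged: bool = False


@dataclass
class EnsemblePrediction:
    model_labels: list[str]
    model_probs: list[np.ndarray]
    tally: dict[str, int]
    final_label: str
    tie_broken: bool


# ---------------------------------------------------------------------------
# Fold splitting
# ---------------------------------------------------------------------------

def split_folds(
    records: list[EcgRecord], k: int = 5, seed: int = 0
) -> list[list[str]]:
    """Partition record ids into k disjoint, class-stratified folds.

    Splitting is by record, never by slice, so all slices of a record share
    a fold (no train/validation leakage). Classes with fewer than k records
    are assigned round-robin with a warning. Deterministic given `seed`.
    """
    if len(records) < k:
        raise ValueError(f"need at least {k} records for {k} folds")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {}
    for rec in records:
        by_class.setdefault(rec.label or "", []).append(rec.record_id)
    folds: list[list[str]] = [[] for _ in range(k)]
    ptr = 0
    for label in sorted(by_class, key=lambda c: CLASSES.index(c) if c in CLASSES else 99):
        ids = sorted(by_class[label])
        rng.shuffle(ids)
        if 0 < len(ids) < k:
            warnings.warn(
                f"class {label!r} has {len(ids)} records (< {k} folds); "
                "assigning round-robin", stacklevel=2,
            )
        for record_id in ids:
            folds[ptr % k].append(record_id)
            ptr += 1
    return folds


# ---------------------------------------------------------------------------
# Slice batching
# ---------------------------------------------------------------------------

def slices_to_arrays(
    slices: list[TwoDimSlice], age_mean: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Stack slices into (X, y, aux) network inputs.

    Slices inherit their record's label. Returns the age mean actually used
    for missing-age imputation so inference can reuse it.
    """
    X = np.stack([s.values for s in slices]).astype(DTYPE)
    y = np.array([s.label for s in slices])
    aux, age_mean = encode_aux(
        [s.age for s in slices], [s.sex for s in slices], age_mean
    )
    return X, y, aux, age_mean


def train_combination(
    slices: list[TwoDimSlice],
    records: list[EcgRecord],
    config: TrainConfig,
) -> tuple[FoldResult, list[FoldResult]]:
    """k-fold cross-validation of one hyperparameter combination.

    Returns the single optimal model's fold (lowest validation loss averaged
    over the final `val_window` epochs) plus all fold results. Folds whose
    training diverges are excluded from selection; if every fold diverges a
    RuntimeError is raised.
    """
    folds = split_folds(records, k=config.folds, seed=config.seed)
    results: list[FoldResult] = []
    for f, val_ids in enumerate(folds):
        val_set = set(val_ids)
        train_slices = [s for s in slices if s.record_id not in val_set]
        val_slices = [s for s in slices if s.record_id in val_set]
        Xt, yt, auxt, age_mean = slices_to_arrays(train_slices)
        Xv, yv, auxv, _ = slices_to_arrays(val_slices, age_mean)
        clf = DseResNetClassifier(
            learning_rate=config.learning_rate,
            dropout=config.dropout,
            momentum=config.momentum,
            epochs=config.epochs,
            batch_size=config.batch_size,
            random_state=config.seed + f,
            restore_best=True,
            **config.model,
        )
        try:
            clf.fit(Xt, yt, aux=auxt, validation_data=(Xv, yv, auxv),
                    classes=tuple(sorted(set(yt) | set(yv), key=CLASSES.index)))
        except FloatingPointError as exc:
            warnings.warn(f"fold {f} diverged: {exc}", stacklevel=2)
            results.append(FoldResult(f, [], [], [], np.inf, None, diverged=True))
            continue
        clf.age_mean_ = age_mean
        window = clf.val_loss_curve_[-config.val_window:]
        results.append(
            FoldResult(
                fold_index=f,
                train_loss_curve=clf.loss_curve_,
                val_loss_curve=clf.val_loss_curve_,
                val_acc_curve=clf.val_acc_curve_,
                final_val_loss=float(np.mean(window)),
                model=clf,
            )
        )
    valid = [r for r in results if not r.diverged]
    if not valid:
        raise RuntimeError("no valid fold: training diverged in every fold")
    best = min(valid, key=lambda r: (r.final_val_loss, r.fold_index))
    return best, results


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def _aligned_proba(model: DseResNetClassifier, proba_row: np.ndarray) -> np.ndarray:
    full = np.zeros(len(CLASSES))
    for j, cls in enumerate(model.classes_):
        full[CLASSES.index(cls)] = proba_row[j]
    return full


def predict_record(
    model: DseResNetClassifier,
    record: EcgRecord,
    preprocessor: EcgPreprocessor | None = None,
) -> tuple[str, np.ndarray]:
    """Record-level prediction: mean of per-slice softmax vectors, argmax.

    The returned probability vector is aligned to the full 9-class order.
    """
    preprocessor = preprocessor or EcgPreprocessor()
    slices = preprocessor.transform([record])
    X = np.stack([s.values for s in slices]).astype(DTYPE)
    aux, _ = encode_aux(
        [record.age] * len(slices), [record.sex] * len(slices),
        getattr(model, "age_mean_", None),
    )
    proba = model.predict_proba(X, aux=aux).mean(axis=0)
    full = _aligned_proba(model, proba)
    return str(CLASSES[int(full.argmax())]), full


def vote(
    labels: list[str],
    probs: list[np.ndarray] | None = None,
) -> EnsemblePrediction:
    """Plurality vote over per-model labels ("minority obeys the majority").

    Ties break by the highest summed probability among the tied labels, then
    by class order; `tie_broken` records whether the tie-break fired.
    """
    if not labels:
        raise ValueError("cannot vote over an empty prediction list")
    if probs is None:
        probs = [np.full(len(CLASSES), 1.0 / len(CLASSES)) for _ in labels]
    tally = Counter(labels)
    top = max(tally.values())
    tied = [lab for lab, n in tally.items() if n == top]
    if len(tied) == 1:
        final, tie_broken = tied[0], False
    else:
        summed = {
            lab: sum(p[CLASSES.index(lab)] for p in probs) for lab in tied
        }
        best = max(summed.values())
        final = min(
            (lab for lab, s in summed.items() if s == best),
            key=CLASSES.index,
        )
        tie_broken = True
    return EnsemblePrediction(
        model_labels=list(labels),
        model_probs=[np.asarray(p) for p in probs],
        tally={lab: int(n) for lab, n in tally.items()},
        final_label=final,
        tie_broken=tie_broken,
    )


def ensemble_predict(
    models: list[DseResNetClassifier],
    record: EcgRecord,
    preprocessor: EcgPreprocessor | None = None,
) -> EnsemblePrediction:
    """Vote of all single optimal models on one record."""
    labels, probs = [], []
    for model in models:
        lab, p = predict_record(model, record, preprocessor)
        labels.append(lab)
        probs.append(p)
    return vote(labels, probs)
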