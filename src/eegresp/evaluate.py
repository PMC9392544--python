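"""Cross-validated evaluation: fold planning, metrics, and the CV driver.

The protocol: segments are divided into ``n_folds`` stratified folds; in each
iteration one fold is the test partition and the remaining segments are split
7:2 into training and validation, giving a global 70/20/10 split. The
training partition alone is augmented. Metrics (sensitivity, specificity,
accuracy, precision, F-measure, Cohen's kappa, ROC-AUC) are computed per
fold and reported as mean +/- SD; confusion counts are summed across folds.

Two leakage policies exist. ``segment_level`` stratifies individual epochs —
statistically optimistic, since epochs of one subject then appear on both
sides of the split. ``subject_level`` keeps every subject's epochs in a
single fold and is the recommended protocol for generalisation claims.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .augment import AugmentConfig, augment_training_partition
from .nn import ArchitectureSpec, CNNLSTM, TrainConfig, default_architecture
from .recording import SegmentTensor

__all__ = [
    "FoldPlan", "make_fold_plan", "ConfusionMatrix", "MetricsReport",
    "confusion_from_predictions", "sensitivity_specificity_accuracy",
    "cohen_kappa", "roc_auc", "CrossValidation", "run_cross_validation",
    "METRIC_NAMES",
]

METRIC_NAMES = ("sensitivity", "specificity", "overall_accuracy", "precision",
                "recall", "f_measure", "cohen_kappa", "auc")


# ---------------------------------------------------------------------------
# Fold planning


@dataclass
class FoldPlan:
    """Assignment of segments to folds and, per fold, to train/val/test.

    ``assignments[i]`` is the fold whose TEST partition holds segment ``i``;
    ``partition[f]`` is an array of ``"train"``/``"validation"``/``"test"``
    strings, one per segment, for fold ``f``.
    """

    n_folds: int
    assignments: np.ndarray
    partition: dict[int, np.ndarray]
    leakage_policy: str
    seed: int

    def indices(self, fold: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        part = self.partition[fold]
        return (np.flatnonzero(part == "train"),
                np.flatnonzero(part == "validation"),
                np.flatnonzero(part == "test"))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"segment": np.arange(len(self.assignments)),
                           "fold": self.assignments})
        for f in range(self.n_folds):
            df[f"partition_fold{f}"] = self.partition[f]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def from_csv(path, leakage_policy: str = "unknown", seed: int = -1) -> "FoldPlan":
        df = pd.read_csv(path)
        folds = sorted(int(c.removeprefix("partition_fold"))
                       for c in df.columns if c.startswith("partition_fold"))
        return FoldPlan(
            n_folds=len(folds),
            assignments=df["fold"].to_numpy(),
            partition={f: df[f"partition_fold{f}"].to_numpy() for f in folds},
            leakage_policy=leakage_policy, seed=seed,
        )


def _stratified_split(idx: np.ndarray, labels: np.ndarray, frac: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Split ``idx`` into (1-frac, frac) parts preserving label proportions."""
    first, second = [], []
    for cls in np.unique(labels[idx]):
        pool = idx[labels[idx] == cls]
        pool = rng.permutation(pool)
        n_second = int(round(frac * len(pool)))
        second.append(pool[:n_second])
        first.append(pool[n_second:])
    return np.concatenate(first), np.concatenate(second)


def make_fold_plan(tensor: SegmentTensor, n_folds: int = 10,
                   policy: str = "segment_level", seed: int = 0,
                   validation_fraction: float = 2 / 9) -> FoldPlan:
    """Build a stratified cross-validation plan.

    Per fold, the non-test remainder is split into train and validation with
    ``validation_fraction`` (default 2/9, giving the global 70/20/10 split).
    Under ``subject_level`` every subject's segments share one fold and the
    train/validation split is also by subject.
    """
    if policy not in ("segment_level", "subject_level"):
        raise ValueError(f"unknown leakage policy {policy!r}")
    labels = tensor.labels
    n = tensor.n_segments
    rng = np.random.default_rng(seed)
    assignments = np.empty(n, dtype=np.int64)

    if policy == "segment_level":
        for cls, count in zip(*np.unique(labels, return_counts=True)):
            if count < n_folds:
                raise ValueError(
                    f"class {cls} has only {count} segments for {n_folds} folds")
            pool = rng.permutation(np.flatnonzero(labels == cls))
            assignments[pool] = np.arange(len(pool)) % n_folds
    else:
        subjects = tensor.subject_ids
        # a subject's stratum is its label set (handles pre/post designs where
        # one subject legitimately contributes both classes)
        subj_label: dict[str, tuple] = {}
        for s in np.unique(subjects):
            subj_label[s] = tuple(sorted(set(labels[subjects == s].tolist())))
        strata: dict[tuple, list[str]] = {}
        for s, lab in subj_label.items():
            strata.setdefault(lab, []).append(s)
        subj_fold: dict[str, int] = {}
        offset = 0
        for lab in sorted(strata):
            members = sorted(strata[lab])
            if len(members) < n_folds and len(strata) == len(members) == 1:
                raise ValueError("not enough subjects for the requested folds")
            perm = rng.permutation(len(members))
            for j, mi in enumerate(perm):
                subj_fold[members[mi]] = (j + offset) % n_folds
            offset += len(members)
        for i in range(n):
            assignments[i] = subj_fold[subjects[i]]

    partition: dict[int, np.ndarray] = {}
    for f in range(n_folds):
        part = np.empty(n, dtype=object)
        test_mask = assignments == f
        part[test_mask] = "test"
        rest = np.flatnonzero(~test_mask)
        frng = np.random.default_rng((seed, f))
        if policy == "segment_level":
            train_idx, val_idx = _stratified_split(rest, labels, validation_fraction, frng)
        else:
            # stratified by subject label-set so validation sees every class
            rest_subjects = np.unique(tensor.subject_ids[rest])
            by_stratum: dict[tuple, list[str]] = {}
            for s in rest_subjects:
                lab = tuple(sorted(set(labels[tensor.subject_ids == s].tolist())))
                by_stratum.setdefault(lab, []).append(s)
            val_subj: set[str] = set()
            for lab in sorted(by_stratum):
                members = sorted(by_stratum[lab])
                n_val = max(1, int(round(validation_fraction * len(members))))
                picked = frng.permutation(members)[:n_val]
                val_subj.update(picked.tolist())
            in_val = np.isin(tensor.subject_ids[rest], list(val_subj))
            val_idx, train_idx = rest[in_val], rest[~in_val]
        part[train_idx] = "train"
        part[val_idx] = "validation"
        partition[f] = part.astype(str)
    return FoldPlan(n_folds=n_folds, assignments=assignments,
                    partition=partition, leakage_policy=policy, seed=seed)


# ---------------------------------------------------------------------------
# Metrics


class UndefinedMetricError(ValueError):
    """A metric's denominator is zero for this confusion matrix."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts (positive class fixed by the model definition:
    responder, or post-rTMS, is the positive class)."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.tp, self.fn], [self.fp, self.tn]],
            index=["actual_pos", "actual_neg"],
            columns=["pred_pos", "pred_neg"],
        )


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def sensitivity_specificity_accuracy(cm: ConfusionMatrix) -> dict[str, float]:
    """Rate metrics from a confusion matrix.

    sensitivity (= recall) = tp/(tp+fn); specificity = tn/(tn+fp);
    accuracy = (tp+tn)/total; precision = tp/(tp+fp); F-measure = harmonic
    mean of precision and sensitivity. A zero denominator raises
    :class:`UndefinedMetricError` rather than silently returning 0.
    """
    if cm.total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    out: dict[str, float] = {}
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("no positive ground-truth cases: sensitivity undefined")
    out["sensitivity"] = cm.tp / (cm.tp + cm.fn)
    out["recall"] = out["sensitivity"]
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("no negative ground-truth cases: specificity undefined")
    out["specificity"] = cm.tn / (cm.tn + cm.fp)
    out["overall_accuracy"] = (cm.tp + cm.tn) / cm.total
    if cm.tp + cm.fp == 0:
        raise UndefinedMetricError("no positive predictions: precision undefined")
    out["precision"] = cm.tp / (cm.tp + cm.fp)
    denom = out["precision"] + out["sensitivity"]
    out["f_measure"] = (2 * out["precision"] * out["sensitivity"] / denom
                        if denom > 0 else 0.0)
    return out


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement: ``(p_o - p_e) / (1 - p_e)`` with
    ``p_e`` from the product of row and column marginals. Degenerate
    marginals (``p_e = 1``) return 0 with a warning."""
    n = cm.total
    if n == 0:
        raise UndefinedMetricError("empty confusion matrix")
    p_o = (cm.tp + cm.tn) / n
    p_pos_true = (cm.tp + cm.fn) / n
    p_pos_pred = (cm.tp + cm.fp) / n
    p_e = p_pos_true * p_pos_pred + (1 - p_pos_true) * (1 - p_pos_pred)
    if abs(1.0 - p_e) < 1e-15:
        warnings.warn("degenerate marginals: kappa defined as 0", RuntimeWarning,
                      stacklevel=2)
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formulation;
    ties contribute one half."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC-AUC needs both classes present")
    from scipy.stats import rankdata
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Cross-validation driver


@dataclass
class MetricsReport:
    """Per-fold metrics, their mean/SD, and the aggregated confusion matrix."""

    per_fold: pd.DataFrame
    confusion: ConfusionMatrix
    leakage_policy: str
    n_folds: int

    @property
    def mean(self) -> pd.Series:
        return self.per_fold[list(METRIC_NAMES)].mean()

    @property
    def std(self) -> pd.Series:
        return self.per_fold[list(METRIC_NAMES)].std(ddof=1)

    def summary(self) -> str:
        lines = [
            f"Cross-validated metrics ({self.n_folds} folds, "
            f"{self.leakage_policy} splitting)",
            f"  test epochs evaluated: {self.confusion.total}",
            "  aggregated confusion [tp fp / fn tn]: "
            f"[{self.confusion.tp} {self.confusion.fp} / "
            f"{self.confusion.fn} {self.confusion.tn}]",
        ]
        mean, std = self.mean, self.std
        for m in METRIC_NAMES:
            sd = std[m]
            sd_txt = f" (+/-{sd:.3f})" if np.isfinite(sd) else ""
            lines.append(f"  {m:<17s} {mean[m]:.3f}{sd_txt}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        df = self.per_fold.copy()
        mean_row = {"fold": "mean", **self.mean.to_dict()}
        std_row = {"fold": "sd", **self.std.to_dict()}
        return pd.concat([df, pd.DataFrame([mean_row, std_row])], ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        import json
        payload = {
            "n_folds": self.n_folds,
            "leakage_policy": self.leakage_policy,
            "confusion": {"tp": self.confusion.tp, "fp": self.confusion.fp,
                          "tn": self.confusion.tn, "fn": self.confusion.fn},
            "mean": {k: float(v) for k, v in self.mean.items()},
            "sd": {k: (float(v) if np.isfinite(v) else None)
                   for k, v in self.std.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


class CrossValidation:
    """Statmodels-style driver: configure once, :meth:`run` to get results.

    Per fold: augment ONLY the training partition, fit a fresh network, and
    evaluate on the untouched test partition. By default only real (not
    artificial) segments are ever evaluated; ``test_on_artificial=True``
    reproduces the strict sizing arithmetic where augmentation precedes
    partitioning.
    """

    def __init__(self, tensor: SegmentTensor,
                 arch: ArchitectureSpec | None = None,
                 train_cfg: TrainConfig | None = None,
                 augment_cfg: AugmentConfig | None = None,
                 plan: FoldPlan | None = None,
                 n_folds: int = 10, policy: str = "segment_level",
                 seed: int = 0) -> None:
        self.tensor = tensor
        self.arch = arch or default_architecture(
            (tensor.segment_len, tensor.n_channels))
        self.train_cfg = train_cfg or TrainConfig()
        self.augment_cfg = augment_cfg
        self.plan = plan or make_fold_plan(tensor, n_folds, policy, seed)
        self.seed = seed

    def run(self, folds: Iterable[int] | None = None) -> MetricsReport:
        plan = self.plan
        tensor = self.tensor
        fold_list = list(folds) if folds is not None else list(range(plan.n_folds))
        rows = []
        total_cm = ConfusionMatrix()
        for f in fold_list:
            train_idx, val_idx, test_idx = plan.indices(f)
            test_labels = tensor.labels[test_idx]
            if np.unique(test_labels).size < 2:
                raise ValueError(f"fold {f} has a single-class test partition")
            train_part = tensor.subset(train_idx)
            if self.augment_cfg is not None:
                from dataclasses import replace as _rep
                cfg = _rep(self.augment_cfg, seed=self.augment_cfg.seed + 1000 * f)
                train_part = augment_training_partition(train_part, cfg)
                # augmentation sanity: artificial parents must lie inside the
                # training partition (they index rows of train_part by build)
                art = train_part.meta["is_artificial"].to_numpy()
                assert not art[: len(train_idx)].any()
            from dataclasses import replace as _rep
            cfg_f = _rep(self.train_cfg, seed=self.train_cfg.seed + f)
            model = CNNLSTM(self.arch, cfg_f)
            model.fit(train_part, tensor.subset(val_idx) if len(val_idx) else None)
            proba = model.predict_proba(tensor.data[test_idx])
            pred = proba.argmax(axis=1)
            cm = confusion_from_predictions(test_labels, pred)
            total_cm = total_cm + cm
            try:
                rates = sensitivity_specificity_accuracy(cm)
            except UndefinedMetricError as exc:
                # e.g. a fold where the model predicts a single class: flag
                # the undefined rates as NaN instead of failing the whole CV
                warnings.warn(f"fold {f}: {exc}", RuntimeWarning, stacklevel=2)
                rates = {m: np.nan for m in
                         ("sensitivity", "recall", "specificity",
                          "overall_accuracy", "precision", "f_measure")}
                rates["overall_accuracy"] = (cm.tp + cm.tn) / cm.total
            row = {"fold": f, **rates,
                   "cohen_kappa": cohen_kappa(cm),
                   "auc": roc_auc(proba[:, 1], test_labels),
                   "n_test": len(test_idx)}
            rows.append(row)
        report = MetricsReport(per_fold=pd.DataFrame(rows), confusion=total_cm,
                               leakage_policy=plan.leakage_policy,
                               n_folds=len(fold_list))
        return report


def run_cross_validation(tensor: SegmentTensor, arch=None, train_cfg=None,
                         augment_cfg=None, plan=None, **kwargs) -> MetricsReport:
    """Functional wrapper around :class:`CrossValidation`."""
    cv = CrossValidation(tensor, arch=arch, train_cfg=train_cfg,
                         augment_cfg=augment_cfg, plan=plan, **kwargs)
    return cv.run()
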