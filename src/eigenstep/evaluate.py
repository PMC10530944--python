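"""Stratified k-fold evaluation and confusion-matrix reporting.

The cross-validation protocol refits every learned stage — eigenspace,
stepwise selection, classifier — on the training folds only, projects and
predicts the held-out fold, and accumulates one confusion matrix over all
folds.  Reports follow the row-normalized-percentage table layout common in
the medical image classification literature: rows are truth, columns are
prediction, each supported row sums to 100, and the headline "average" is
the unweighted (macro) mean of the diagonal recognition rates.  The
support-weighted average — algebraically the overall accuracy — is reported
alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .datatypes import LabeledImageSet, ValidationError
from .eigen import fit_eigenmodel, project
from .mlp import predict as mlp_predict
from .mlp import train as mlp_train
from .preprocess import SmoothingKernel, smooth_dataset
from .stepwise import LabelVector, partial_statistic, run_stepwise

logger = logging.getLogger(__name__)


@dataclass
class FoldPlan:
    """Per-sample fold assignment for stratified k-fold cross-validation."""

    k: int
    assignments: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=np.int64)

    def test_mask(self, fold: int) -> np.ndarray:
        return self.assignments == fold


def make_folds(
    labels: np.ndarray | LabelVector, k: int = 10, seed: int = 0
) -> FoldPlan:
    """Stratified fold assignment with seeded shuffling.

    Within each class the (shuffled) members are dealt round-robin over a
    (shuffled) fold order, so per-fold class counts deviate from perfect
    proportionality by at most one sample.  A class thinner than ``k`` may
    be absent from some *test* folds but lands in at most one fold per
    member, so every training fold retains it as long as the class has at
    least two members — thinner classes are rejected.
    """
    if isinstance(labels, LabelVector):
        labels = labels.y
    y = np.asarray(labels, dtype=np.int64)
    n = len(y)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > n:
        raise ValidationError(f"k={k} exceeds the number of samples ({n})")
    rng = np.random.default_rng(seed)
    assignments = np.full(n, -1, dtype=np.int64)
    for cls in np.unique(y):
        members = rng.permutation(np.flatnonzero(y == cls))
        if len(members) < 2:
            raise ValidationError(
                f"class {cls} has {len(members)} member(s); need at least 2"
            )
        fold_order = rng.permutation(k)
        for i, idx in enumerate(members):
            assignments[idx] = fold_order[i % k]
    counts = np.bincount(assignments, minlength=k)
    if (counts == 0).any():
        raise ValidationError(
            f"fold(s) {np.flatnonzero(counts == 0).tolist()} are empty; "
            "reduce k or add data"
        )
    return FoldPlan(k=k, assignments=assignments, seed=seed)


@dataclass
class ConfusionReport:
    """Confusion counts plus the derived percentage table and per-class metrics.

    ``row_percent[i, j]`` is the percentage of true-class-i samples
    predicted as class j (100 * count / row sum; zero-support rows are
    NaN).  ``macro_average`` is the unweighted mean of the diagonal over
    supported rows; ``weighted_average`` is the support-weighted mean,
    identical to overall accuracy in percent.  Raw doubles are retained;
    rounding (half-even, 2 decimals) happens only in the display helpers.
    """

    counts: np.ndarray
    row_percent: np.ndarray
    per_class: pd.DataFrame
    macro_average: float
    weighted_average: float
    class_names: list[str]

    def to_dict(self) -> dict:
        return {
            "class_names": self.class_names,
            "counts": self.counts.astype(int).tolist(),
            "row_percent": [
                [None if np.isnan(v) else round(float(v), 2) for v in row]
                for row in self.row_percent
            ],
            "per_class": self.per_class.to_dict(orient="index"),
            "macro_average": round(float(self.macro_average), 2),
            "weighted_average": round(float(self.weighted_average), 2),
        }

    def to_text(self) -> str:
        """Row-percentage table in the conventional published layout."""
        names = self.class_names
        width = max(len(n) for n in names) + 2
        lines = ["Recognition Rates (%)"]
        lines.append(" " * width + "".join(f"{n:>10}" for n in names))
        for i, name in enumerate(names):
            cells = "".join(
                f"{'--' if np.isnan(v) else format(round(float(v), 2), '.2f'):>10}"
                for v in self.row_percent[i]
            )
            lines.append(f"{name:<{width}}" + cells)
        lines.append(f"Average (macro)    {self.macro_average:.2f}")
        lines.append(f"Average (weighted) {self.weighted_average:.2f}")
        return "\n".join(lines)

    def per_class_csv(self) -> str:
        return self.per_class.to_csv()


def summarize(
    counts: np.ndarray, class_names: list[str] | None = None
) -> ConfusionReport:
    """Build the full report from a raw G x G confusion-count matrix."""
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValidationError(f"counts must be square, got shape {counts.shape}")
    if (counts < 0).any():
        raise ValidationError("counts must be non-negative")
    if counts.sum() == 0:
        raise ValidationError("confusion matrix is all zero")
    counts = counts.astype(np.int64)
    g = counts.shape[0]
    if class_names is None:
        class_names = [f"class_{i}" for i in range(g)]

    support = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        row_percent = 100.0 * counts / support[:, None]

    total = counts.sum()
    rows = {}
    for i, name in enumerate(class_names):
        tp = counts[i, i]
        fn = support[i] - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        rows[name] = {
            "TP": int(tp), "TN": int(tn), "FP": int(fp), "FN": int(fn),
            "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
            "specificity": tn / (tn + fp) if tn + fp else np.nan,
        }
    per_class = pd.DataFrame.from_dict(rows, orient="index")

    diag = np.diag(row_percent)
    supported = support > 0
    macro = float(np.mean(diag[supported]))
    weighted = float(100.0 * np.trace(counts) / total)
    return ConfusionReport(
        counts=counts,
        row_percent=row_percent,
        per_class=per_class,
        macro_average=macro,
        weighted_average=weighted,
        class_names=list(class_names),
    )


def report_from_rates(
    row_percent: np.ndarray,
    support: np.ndarray | None = None,
    class_names: list[str] | None = None,
) -> tuple[float, float | None]:
    """Macro (and, given supports, weighted) average of a published rate table.

    Takes a row-normalized percentage confusion matrix as printed in the
    literature and returns the unweighted mean of its diagonal, plus the
    support-weighted mean when per-class sample counts are supplied.
    Useful for re-deriving the headline "average" of a published table.
    """
    row_percent = np.asarray(row_percent, dtype=np.float64)
    if row_percent.ndim != 2 or row_percent.shape[0] != row_percent.shape[1]:
        raise ValidationError("row_percent must be a square matrix")
    diag = np.diag(row_percent)
    macro = float(np.mean(diag))
    weighted = None
    if support is not None:
        support = np.asarray(support, dtype=np.float64)
        weighted = float(np.sum(diag * support) / np.sum(support))
    return macro, weighted


def _select_features(train_scores, train_labels, n_classes, stepwise_config):
    """Stepwise selection with a smallest-p fallback when nothing clears entry."""
    lv = LabelVector(train_labels, n_classes)
    result = run_stepwise(train_scores, lv, stepwise_config)
    selected = result.selected
    if not selected:
        pvals = [
            partial_statistic(train_scores, [], j, lv, "enter")[1]
            for j in range(train_scores.shape[1])
        ]
        selected = [int(np.argmin(pvals))]
        logger.info("no feature cleared alpha_enter; falling back to feature %d",
                    selected[0])
    return selected, result


def _prepare(dataset: LabeledImageSet, config: PipelineConfig) -> LabeledImageSet:
    if config.preprocess.filter_size is not None:
        return smooth_dataset(dataset, SmoothingKernel(config.preprocess.filter_size))
    return dataset


def _fold_seed(base_seed: int, fold: int) -> int:
    return (base_seed * 1_000_003 + fold + 1) % (2**31 - 1)


def cross_validate(
    dataset: LabeledImageSet,
    config: PipelineConfig,
    plan: FoldPlan | None = None,
) -> ConfusionReport:
    """Evaluate the full pipeline with stratified k-fold cross-validation.

    For each fold the smoothing filter (stateless) is applied, then the
    eigenspace, the stepwise selection and the classifier are fitted on the
    training folds only; the held-out fold is projected and predicted, and
    counts accumulate into one confusion matrix.  With
    ``config.eval.global_fit`` the eigenspace and selection are instead
    fitted once on all data (a deliberately leakier protocol for
    comparison) and only the classifier is refitted per fold.
    """
    if plan is None:
        plan = make_folds(dataset.labels, config.eval.n_folds, config.eval.seed)
    if len(plan.assignments) != len(dataset):
        raise ValidationError(
            f"fold plan covers {len(plan.assignments)} samples, "
            f"dataset has {len(dataset)}"
        )
    smoothed = _prepare(dataset, config)
    flat = smoothed.flatten()
    g = dataset.n_classes
    counts = np.zeros((g, g), dtype=np.int64)

    global_model = global_selected = None
    if config.eval.global_fit:
        k_eff = min(config.pca_k, len(dataset) - 1, flat.shape[1])
        global_model = fit_eigenmodel(flat, k_eff)
        scores_all = project(global_model, flat)
        global_selected, _ = _select_features(
            scores_all.scores, dataset.labels, g, config.stepwise
        )

    for fold in range(plan.k):
        test_mask = plan.test_mask(fold)
        train_mask = ~test_mask
        x_tr, y_tr = flat[train_mask], dataset.labels[train_mask]
        x_te, y_te = flat[test_mask], dataset.labels[test_mask]
        try:
            if config.eval.global_fit:
                model, selected = global_model, global_selected
            else:
                k_eff = min(config.pca_k, len(x_tr) - 1, x_tr.shape[1])
                model = fit_eigenmodel(x_tr, k_eff)
                selected, _ = _select_features(
                    project(model, x_tr).scores, y_tr, g, config.stepwise
                )
            tr_scores = project(model, x_tr).scores[:, selected]
            te_scores = project(model, x_te).scores[:, selected]
            mlp_config = replace(
                config.mlp,
                input_dim=len(selected),
                output_dim=g,
                seed=_fold_seed(config.eval.seed, fold),
            )
            net, _ = mlp_train(tr_scores, y_tr, mlp_config)
            pred, _ = mlp_predict(net, te_scores)
        except Exception as exc:
            raise RuntimeError(f"fold {fold}: {exc}") from exc
        np.add.at(counts, (y_te, pred), 1)
        logger.info("fold %d: %d train / %d test, %d features selected",
                    fold, len(x_tr), len(x_te), len(selected))

    return summarize(counts, list(dataset.class_names))


def run_baseline(
    dataset: LabeledImageSet,
    adapter,
    config: PipelineConfig,
    plan: FoldPlan | None = None,
) -> ConfusionReport:
    """Identical CV protocol with ``adapter`` replacing the selection+MLP stage.

    ``adapter`` must implement ``fit(X, y)`` and ``predict(X) -> labels``;
    it receives the full eigenspace scores (no stepwise selection), which
    is how alternative classifiers are benchmarked against the hybrid
    pipeline.
    """
    if not (hasattr(adapter, "fit") and hasattr(adapter, "predict")):
        raise ValidationError(
            f"adapter {adapter!r} must implement fit(X, y) and predict(X)"
        )
    if plan is None:
        plan = make_folds(dataset.labels, config.eval.n_folds, config.eval.seed)
    smoothed = _prepare(dataset, config)
    flat = smoothed.flatten()
    g = dataset.n_classes
    counts = np.zeros((g, g), dtype=np.int64)
    for fold in range(plan.k):
        test_mask = plan.test_mask(fold)
        x_tr, y_tr = flat[~test_mask], dataset.labels[~test_mask]
        x_te, y_te = flat[test_mask], dataset.labels[test_mask]
        k_eff = min(config.pca_k, len(x_tr) - 1, x_tr.shape[1])
        model = fit_eigenmodel(x_tr, k_eff)
        tr_scores = project(model, x_tr).scores
        te_scores = project(model, x_te).scores
        try:
            adapter.fit(tr_scores, y_tr)
            pred = np.asarray(adapter.predict(te_scores))
        except Exception as exc:
            raise RuntimeError(
                f"baseline adapter {type(adapter).__name__} failed on fold "
                f"{fold}: {exc}"
            ) from exc
        np.add.at(counts, (y_te, pred), 1)
    return summarize(counts, list(dataset.class_names))
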