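"""Stepwise linear discriminant feature selection (SWLDA).

Predictors are admitted and removed one at a time by partial significance
tests rather than used wholesale.  The class labels are indicator-coded and
regressed on the selected predictor columns; the contribution of one
candidate conditional on the current set is measured by the Wilks'-lambda
ratio of residual-scatter determinants with and without that candidate,
converted to an exact partial F (for one added predictor the Rao transform
is exact).  With two classes the indicator response collapses to a single
column and the partial F reduces to the squared partial t of an ordinary
least-squares fit — the classical special case.

The forward pass admits the candidate with the smallest enter p-value when
it clears ``alpha_enter``; the backward pass then drops the selected
feature with the largest remove p-value while it exceeds ``alpha_remove``.
The loop stops when neither rule fires or the feature cap is reached.
Requiring ``alpha_enter <= alpha_remove`` prevents enter/remove cycling;
an iteration guard catches any residual oscillation and surfaces it as an
error rather than returning silently truncated output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datatypes import ValidationError
from .eigen import FeatureMatrix

logger = logging.getLogger(__name__)


class CollinearityError(ValueError):
    """The current model's residual scatter is numerically singular."""


class IterationGuardError(RuntimeError):
    """The stepwise loop exceeded its iteration budget without converging.

    Carries the partial :class:`SelectionResult` as ``result``.
    """

    def __init__(self, message: str, result: "SelectionResult"):
        super().__init__(message)
        self.result = result


@dataclass
class LabelVector:
    """Integer class labels plus their one-hot indicator coding."""

    y: np.ndarray
    n_classes: int

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)
        present = np.unique(self.y)
        if len(self.y) == 0:
            raise ValidationError("empty label vector")
        missing = set(range(self.n_classes)) - set(present.tolist())
        if missing or present.min() < 0 or present.max() >= self.n_classes:
            raise ValidationError(
                f"labels must cover every class in [0, {self.n_classes}); "
                f"missing {sorted(missing)}" if missing else
                f"labels out of range [0, {self.n_classes})"
            )

    @property
    def indicator(self) -> np.ndarray:
        """N x G one-hot matrix."""
        out = np.zeros((len(self.y), self.n_classes))
        out[np.arange(len(self.y)), self.y] = 1.0
        return out


@dataclass(frozen=True)
class StepwiseConfig:
    """Thresholds and caps for the forward/backward selection loop.

    The operating defaults are alpha_enter 0.35, alpha_remove 0.40 and a
    125-feature cap; :meth:`screening_preset` gives the stricter 0.15/0.20
    pair sometimes quoted for the initial screening run.
    """

    alpha_enter: float = 0.35
    alpha_remove: float = 0.40
    max_features: int = 125
    max_iterations: int = 1000
    backward: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha_enter <= self.alpha_remove < 1:
            raise ValidationError(
                "need 0 < alpha_enter <= alpha_remove < 1 to rule out "
                f"enter/remove cycling, got {self.alpha_enter}/{self.alpha_remove}"
            )
        if self.max_features < 0:
            raise ValidationError("max_features must be >= 0")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")

    @classmethod
    def screening_preset(cls, **overrides) -> "StepwiseConfig":
        defaults = dict(alpha_enter=0.15, alpha_remove=0.20)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class StepRecord:
    step_index: int
    action: str  # "enter" | "remove"
    feature_id: int
    statistic: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "step_index": self.step_index,
            "action": self.action,
            "feature_id": int(self.feature_id),
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
        }


@dataclass
class SelectionResult:
    selected: list[int]
    trace: list[StepRecord] = field(default_factory=list)
    terminated_reason: str = "no-candidate"

    def to_dict(self) -> dict:
        return {
            "selected": [int(f) for f in self.selected],
            "trace": [r.to_dict() for r in self.trace],
            "terminated_reason": self.terminated_reason,
        }


def _as_scores(features: FeatureMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(features, FeatureMatrix):
        return features.scores, features.feature_ids
    arr = np.asarray(features, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError(f"features must be 2-D, got shape {arr.shape}")
    return arr, np.arange(arr.shape[1])


def _as_labels(labels: LabelVector | np.ndarray, n_classes: int | None = None):
    if isinstance(labels, LabelVector):
        return labels
    y = np.asarray(labels, dtype=np.int64)
    if n_classes is None:
        n_classes = int(y.max()) + 1 if len(y) else 0
    return LabelVector(y, n_classes)


def fld_weights(
    features: FeatureMatrix | np.ndarray, labels: LabelVector | np.ndarray
) -> np.ndarray:
    """Least-squares discriminant weights of the indicator regression.

    Solves ``min ||M W - Y||`` for the p x G weight matrix, i.e. the
    normal-equations solution ``(M'M)^-1 M'Y`` computed through a stable
    factorization.  When ``M'M`` is singular the minimum-norm pseudoinverse
    solution is returned and a warning is logged.
    """
    scores, _ = _as_scores(features)
    if scores.shape[1] == 0:
        raise ValidationError("empty feature set")
    lv = _as_labels(labels)
    response = lv.indicator if lv.n_classes > 1 else lv.y.astype(float)[:, None]
    weights, _, rank, _ = np.linalg.lstsq(scores, response, rcond=None)
    if rank < scores.shape[1]:
        warnings.warn(
            f"feature matrix is rank deficient (rank {rank} < {scores.shape[1]}); "
            "returning the minimum-norm solution",
            stacklevel=2,
        )
        logger.warning("rank-deficient discriminant fit: rank %d < %d",
                       rank, scores.shape[1])
    return weights


def _residual_logdet(design: np.ndarray, response: np.ndarray) -> float:
    """log det of the residual cross-product matrix of response on design.

    The scatter is positive semidefinite by construction; an eigenvalue
    that is zero relative to the response's total sum of squares means the
    design fits that response direction exactly, reported as -inf.
    """
    coef, _, _, _ = np.linalg.lstsq(design, response, rcond=None)
    resid = response - design @ coef
    scatter = resid.T @ resid
    eigenvalues = np.linalg.eigvalsh(scatter)
    threshold = 1e-12 * float(np.sum(response * response))
    if np.any(eigenvalues <= threshold):
        return -np.inf
    return float(np.sum(np.log(eigenvalues)))


def _design(scores: np.ndarray, cols: list[int]) -> np.ndarray:
    n = scores.shape[0]
    return np.column_stack([np.ones(n), scores[:, cols]]) if cols else np.ones((n, 1))


def partial_statistic(
    features: FeatureMatrix | np.ndarray,
    selected: list[int],
    candidate: int,
    labels: LabelVector | np.ndarray,
    mode: str = "enter",
) -> tuple[float, float]:
    """Partial F and p-value for one candidate conditional on a selected set.

    ``selected`` and ``candidate`` index columns of ``features``.  In
    ``enter`` mode the candidate is tested for addition to ``selected``; in
    ``remove`` mode it must already belong to ``selected`` and is tested
    for deletion.  The statistic is the exact Rao F transform of the
    Wilks'-lambda determinant ratio with hypothesis dimension 1; its
    reference distribution is F(q, nu_E - q + 1) with q = G - 1 indicator
    responses and nu_E the full model's residual degrees of freedom.
    """
    scores, _ = _as_scores(features)
    lv = _as_labels(labels)
    if mode == "enter":
        if candidate in selected:
            raise ValidationError(f"candidate {candidate} already selected")
        reduced = list(selected)
        full = list(selected) + [candidate]
    elif mode == "remove":
        if candidate not in selected:
            raise ValidationError(f"candidate {candidate} not in selected set")
        full = list(selected)
        reduced = [f for f in selected if f != candidate]
    else:
        raise ValidationError(f"mode must be 'enter' or 'remove', got {mode!r}")

    n = scores.shape[0]
    g = lv.n_classes
    if g < 2:
        raise ValidationError("need at least two classes")
    q = g - 1  # one indicator column is redundant given the intercept
    response = lv.indicator[:, :q]

    nu_error = n - len(full) - 1
    df2 = nu_error - q + 1
    if df2 < 1:
        raise ValidationError(
            f"insufficient residual degrees of freedom (nu_E={nu_error}, q={q})"
        )

    logdet_reduced = _residual_logdet(_design(scores, reduced), response)
    if not np.isfinite(logdet_reduced):
        raise CollinearityError(
            f"reduced model (without feature {candidate}) has a singular "
            "residual scatter; selected features already fit the labels exactly"
        )
    logdet_full = _residual_logdet(_design(scores, full), response)

    wilks = float(np.exp(min(logdet_full - logdet_reduced, 0.0)))
    if wilks <= 0.0:
        return np.inf, 0.0
    f_stat = max((1.0 - wilks) / wilks * df2 / q, 0.0)
    p_value = float(stats.f.sf(f_stat, q, df2))
    return float(f_stat), p_value


def run_stepwise(
    features: FeatureMatrix | np.ndarray,
    labels: LabelVector | np.ndarray,
    config: StepwiseConfig = StepwiseConfig(),
) -> SelectionResult:
    """Forward/backward stepwise selection over feature columns.

    Each iteration first tries to admit the unselected feature with the
    smallest enter p-value (ties broken by lower feature id) when it is
    below ``alpha_enter`` and the cap leaves room, then repeatedly drops
    the selected feature with the largest remove p-value while it exceeds
    ``alpha_remove``.  The full enter/remove trace is recorded; the
    procedure is deterministic, so re-running it on identical inputs
    replays the identical trace.
    """
    scores, feature_ids = _as_scores(features)
    lv = _as_labels(labels)
    n, p = scores.shape
    if p < 1:
        raise ValidationError("at least one feature required")
    if n <= lv.n_classes:
        raise ValidationError(f"need more samples ({n}) than classes ({lv.n_classes})")

    selected: list[int] = []  # column positions
    trace: list[StepRecord] = []
    step = 0
    reason = "no-candidate"

    for _ in range(config.max_iterations):
        moved = False

        # forward: admit the strongest candidate if it clears alpha_enter
        if len(selected) < config.max_features:
            best: tuple[float, int] | None = None
            best_stat = np.nan
            for j in range(p):
                if j in selected:
                    continue
                try:
                    stat, pval = partial_statistic(scores, selected, j, lv, "enter")
                except CollinearityError:
                    # current model already fits the labels exactly; nothing
                    # left for any candidate to explain
                    best = None
                    break
                if best is None or (pval, j) < best:
                    best = (pval, j)
                    best_stat = stat
            if best is not None and best[0] < config.alpha_enter:
                pval, j = best
                selected.append(j)
                trace.append(StepRecord(step, "enter", int(feature_ids[j]),
                                        best_stat, pval))
                step += 1
                moved = True

        # backward: shed weak features while any exceeds alpha_remove
        if config.backward:
            while selected:
                worst: tuple[float, int] | None = None
                worst_stat = np.nan
                for j in selected:
                    try:
                        stat, pval = partial_statistic(
                            scores, selected, j, lv, "remove"
                        )
                    except CollinearityError:
                        # the others fit the labels perfectly without j:
                        # j is redundant and maximally removable
                        stat, pval = 0.0, 1.0
                    # largest p first; ties broken by lower feature id
                    if worst is None or (-pval, j) < worst:
                        worst = (-pval, j)
                        worst_stat = stat
                if worst is None or -worst[0] <= config.alpha_remove:
                    break
                pval, j = -worst[0], worst[1]
                selected.remove(j)
                trace.append(StepRecord(step, "remove", int(feature_ids[j]),
                                        worst_stat, pval))
                step += 1
                moved = True

        if not moved:
            reason = (
                "cap-reached" if len(selected) >= config.max_features
                else "no-candidate"
            )
            break
    else:
        partial = SelectionResult(
            [int(feature_ids[j]) for j in selected], trace, "iteration-guard"
        )
        raise IterationGuardError(
            f"stepwise selection did not converge within "
            f"{config.max_iterations} iterations", partial
        )

    return SelectionResult([int(feature_ids[j]) for j in selected], trace, reason)
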