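"""Leave-one-block-out ablation and feature-attribution aggregation.

Ablation removes a named feature block (a descriptor's entire
name-prefixed column set, or the string block), re-fits the full
preprocessing + classifier on training rows only, and reports the
eight-metric delta against an all-blocks baseline.  The sign convention
is ``delta = metric(without block) - metric(baseline)``: positive means
removal *improved* the metric.

Importance aggregates per-sub-feature attributions (mean absolute SHAP
value over evaluation rows, normalized to sum 1) into per-block
cumulative weights — the sum of a block's sub-feature weights — plus a
top-N sub-feature ranking.  Permutation importance is the fallback for
non-tree models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone

from . import _treeshap
from .evaluation import METRIC_ORDER, EvaluationReport, evaluate
from .modeling import ThermophilicityClassifier, TrainedModel
from .tabular_prep import FeatureMatrix


@dataclass
class AblationRow:
    removed: tuple[str, ...]
    report: EvaluationReport
    delta: dict[str, float]


@dataclass
class AblationTable:
    baseline: EvaluationReport
    rows: list[AblationRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        data = [("baseline", *[getattr(self.baseline, m) for m in METRIC_ORDER])]
        for row in self.rows:
            label = "-" + "+".join(row.removed) if row.removed else "baseline(empty)"
            data.append((label, *[getattr(row.report, m) for m in METRIC_ORDER]))
        return pd.DataFrame(data, columns=["removed", *METRIC_ORDER]).set_index("removed")

    def delta_frame(self) -> pd.DataFrame:
        data = {
            "-" + "+".join(r.removed) if r.removed else "(none)": r.delta for r in self.rows
        }
        return pd.DataFrame(data).T[list(METRIC_ORDER)]


def _fit_eval(
    estimator: ThermophilicityClassifier, M_train: FeatureMatrix, M_test: FeatureMatrix
) -> EvaluationReport:
    est = clone(estimator)
    est.fit(M_train)
    scores = est.decision_scores(M_test)
    return evaluate(M_test.labels, scores)


def ablate(
    estimator: ThermophilicityClassifier,
    blocks_to_remove: Sequence[Sequence[str]],
    M_train: FeatureMatrix,
    M_test: FeatureMatrix,
) -> AblationTable:
    """Re-fit and re-evaluate the pipeline for each block-removal set."""
    manifest = set(M_train.blocks)
    baseline = _fit_eval(estimator, M_train, M_test)
    base_metrics = baseline.as_dict()
    rows = []
    for removal in blocks_to_remove:
        removal = tuple(removal)
        unknown = set(removal) - manifest
        if unknown:
            raise KeyError(f"unknown blocks {sorted(unknown)}")
        if set(removal) == manifest:
            raise ValueError("cannot remove every block")
        if not removal:
            report = baseline
        else:
            report = _fit_eval(
                estimator, M_train.drop_blocks(removal), M_test.drop_blocks(removal)
            )
        delta = {
            m: (0.0 if not removal else report.as_dict()[m] - base_metrics[m])
            for m in METRIC_ORDER
        }
        rows.append(AblationRow(removal, report, delta))
    return AblationTable(baseline, rows)


def single_block_sweep(
    estimator: ThermophilicityClassifier, M_train: FeatureMatrix, M_test: FeatureMatrix
) -> AblationTable:
    """Leave-one-out over every block in the manifest."""
    return ablate(estimator, [(b,) for b in M_train.blocks], M_train, M_test)


def paired_ablate(
    estimator: ThermophilicityClassifier,
    pair: tuple[str, str],
    M_train: FeatureMatrix,
    M_test: FeatureMatrix,
) -> AblationTable:
    """Baseline, minus-first, minus-second and minus-both comparisons."""
    a, b = pair
    if a == b:
        raise ValueError("pair must name two distinct blocks")
    return ablate(estimator, [(), (a,), (b,), (a, b)], M_train, M_test)


# ---------------------------------------------------------------------------
# importance


@dataclass
class ImportanceReport:
    """Normalized per-sub-feature weights and per-block cumulative sums."""

    per_feature: pd.Series  # index = sub-feature names, sums to 1
    per_block: dict[str, float]
    top: list[tuple[str, float]]

    def to_frame(self) -> pd.DataFrame:
        return self.per_feature.rename("weight").to_frame()


def _aggregate(
    weights: np.ndarray,
    columns: Sequence[str],
    blocks: dict[str, tuple[int, int]],
    top_n: int,
) -> ImportanceReport:
    total = weights.sum()
    norm = weights / total if total > 0 else weights
    per_feature = pd.Series(norm, index=list(columns))
    per_block = {
        name: float(per_feature.iloc[start:end].sum()) for name, (start, end) in blocks.items()
    }
    # deterministic: weight descending, name ascending on ties
    ranked = sorted(per_feature.items(), key=lambda kv: (-kv[1], kv[0]))
    return ImportanceReport(per_feature, per_block, ranked[:top_n])


def _resolve(model) -> ThermophilicityClassifier:
    est = model.estimator if isinstance(model, TrainedModel) else model
    if not isinstance(est, ThermophilicityClassifier):
        raise TypeError("expected a fitted ThermophilicityClassifier or TrainedModel")
    if not hasattr(est, "model_"):
        raise RuntimeError("model is not fitted")
    return est


def shap_importance(
    model: ThermophilicityClassifier | TrainedModel,
    M_eval: FeatureMatrix,
    top_n: int = 30,
    max_rows: Optional[int] = 200,
    seed: int = 0,
) -> ImportanceReport:
    """Mean-|SHAP| sub-feature weights, normalized to sum 1.

    Requires a tree-family classifier (exact tree-path attribution);
    evaluation rows beyond ``max_rows`` are subsampled with ``seed``.
    """
    est = _resolve(model)
    if M_eval.shape[0] == 0:
        raise ValueError("M_eval must be non-empty")
    X = est._transform_tabular(M_eval)
    if max_rows is not None and X.shape[0] > max_rows:
        rng = np.random.default_rng(seed)
        X = X[np.sort(rng.choice(X.shape[0], size=max_rows, replace=False))]
    sv = _treeshap.shap_values(est.model_, X)  # raises TypeError for non-tree
    weights = np.abs(sv).mean(axis=0)
    return _aggregate(weights, est.feature_columns_, est.blocks_, top_n)


def permutation_importance(
    model: ThermophilicityClassifier | TrainedModel,
    M_eval: FeatureMatrix,
    metric: str = "AUROC",
    n_repeats: int = 5,
    seed: int = 0,
    top_n: int = 30,
) -> ImportanceReport:
    """Mean metric drop over seeded column shuffles; model-agnostic."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    est = _resolve(model)
    y = M_eval.labels
    if y is None:
        raise ValueError("permutation importance requires labels")
    X = est._transform_tabular(M_eval)
    rng = np.random.default_rng(seed)

    def score(mat: np.ndarray) -> float:
        s = est.model_.predict_proba(mat)[:, 1]
        return evaluate(y, s).as_dict()[metric]

    base = score(X)
    drops = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j].copy()
        if np.all(col == col[0]):
            continue  # constant column: shuffling is a no-op
        acc = 0.0
        for _ in range(n_repeats):
            X[:, j] = rng.permutation(col)
            acc += base - score(X)
        X[:, j] = col
        drops[j] = acc / n_repeats
    weights = np.clip(drops, 0.0, None)
    return _aggregate(weights, est.feature_columns_, est.blocks_, top_n)
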