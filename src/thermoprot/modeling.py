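"""Classifier families, the end-to-end pipeline estimator, and k-fold CV.

The shipped recipe (see :func:`build_default_pipeline`) is: all 14
descriptor blocks + the hashed n-gram string block -> min-max scaling
-> SMOTE on training rows only -> ANOVA (f_classif) selection ->
gradient boosting, evaluated with stratified 5-fold cross-validation.
Every preprocessing stage is re-fitted inside each training fold, so no
test-row statistic ever leaks into training.

:class:`ThermophilicityClassifier` is the scikit-learn-style estimator
wrapping the whole recipe; the module-level ``train`` / ``predict`` /
``cross_validate`` functions are thin wrappers over it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import (
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import StratifiedKFold

from ._lstm import LSTMClassifier
from .descriptors import DESCRIPTOR_NAMES, encode_many, get_spec
from .evaluation import EvaluationReport, evaluate
from .sequence_io import SequenceSet, is_valid_sequence, read_fasta
from .string_features import StringScheme, default_final_scheme
from .tabular_prep import (
    FeatureMatrix,
    apply_scaler,
    fit_scaler,
    select_features,
    smote_oversample,
)

MODEL_FAMILIES = ("bagging", "random_forest", "gradient_boosting", "lstm_rnn")

#: name of the string-derived feature block
STR_BLOCK = "str_feature"


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family with hyperparameters and a seed."""

    family: str = "gradient_boosting"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0


def make_classifier(spec: ModelSpec):
    """Instantiate the sklearn (or in-package LSTM) backend for a spec."""
    hp = dict(spec.hyperparameters)
    if spec.family == "bagging":
        return BaggingClassifier(random_state=spec.seed, **hp)
    if spec.family == "random_forest":
        return RandomForestClassifier(random_state=spec.seed, **hp)
    if spec.family == "gradient_boosting":
        # feature subsampling keeps exact-split boosting tractable on the
        # ~14k-column default feature space
        hp.setdefault("max_features", "sqrt")
        return GradientBoostingClassifier(random_state=spec.seed, **hp)
    if spec.family == "lstm_rnn":
        return LSTMClassifier(seed=spec.seed, **hp)
    raise ValueError(f"unknown model family {spec.family!r}; choose from {MODEL_FAMILIES}")


# ---------------------------------------------------------------------------
# featurization


class SequenceFeaturizer(BaseEstimator):
    """Encode sequences into a FeatureMatrix of descriptor + string blocks."""

    def __init__(
        self,
        descriptors: Sequence[str] = DESCRIPTOR_NAMES,
        descriptor_params: Optional[dict] = None,
        string_scheme: Optional[StringScheme] = None,
        seed: int = 0,
    ):
        self.descriptors = tuple(descriptors)
        self.descriptor_params = descriptor_params
        self.string_scheme = string_scheme
        self.seed = seed

    def fit(self, X: SequenceSet, y=None) -> "SequenceFeaturizer":
        params = self.descriptor_params or {}
        self.specs_ = [get_spec(name, **params.get(name, {})) for name in self.descriptors]
        self.scheme_ = None
        if self.string_scheme is not None:
            self.scheme_ = self.string_scheme
            self.scheme_.seed = self.seed
            self.scheme_.fit(X)
        return self

    def transform(self, X: SequenceSet) -> FeatureMatrix:
        seqs = X.sequences
        parts = []
        for spec in self.specs_:
            parts.append((spec.name, spec.sub_feature_names, encode_many(spec, seqs)))
        if self.scheme_ is not None:
            names = [f"{STR_BLOCK}.{n}" for n in self.scheme_.get_feature_names_out()]
            parts.append((STR_BLOCK, names, self.scheme_.transform(X)))
        y = X.labels
        return FeatureMatrix.from_blocks(X.ids, parts, y=y)

    def fit_transform(self, X: SequenceSet, y=None) -> FeatureMatrix:
        return self.fit(X, y).transform(X)


# ---------------------------------------------------------------------------
# the end-to-end estimator


class ThermophilicityClassifier(BaseEstimator, ClassifierMixin):
    """Sequence-in, probability-out thermophilicity classifier.

    Accepts either a labelled :class:`SequenceSet` (or raw sequences
    plus ``y``) or a ready-made :class:`FeatureMatrix`.  The decision
    threshold is fixed at 0.5; ranked scores are available through
    :meth:`predict_proba`.
    """

    def __init__(
        self,
        descriptors: Sequence[str] = DESCRIPTOR_NAMES,
        use_string_block: bool = True,
        string_dim: int = 1024,
        scaler: str = "minmax",
        smote: bool = True,
        smote_k: int = 5,
        select_method: Optional[str] = "f_classif",
        select_param: Optional[float] = None,
        family: str = "gradient_boosting",
        hyperparameters: Optional[dict] = None,
        seed: int = 0,
    ):
        self.descriptors = tuple(descriptors)
        self.use_string_block = use_string_block
        self.string_dim = string_dim
        self.scaler = scaler
        self.smote = smote
        self.smote_k = smote_k
        self.select_method = select_method
        self.select_param = select_param
        self.family = family
        self.hyperparameters = hyperparameters
        self.seed = seed

    # -- featurization ------------------------------------------------------
    def _make_featurizer(self) -> SequenceFeaturizer:
        scheme = None
        if self.use_string_block:
            scheme = default_final_scheme()
            scheme.dim = self.string_dim
        return SequenceFeaturizer(
            descriptors=self.descriptors, string_scheme=scheme, seed=self.seed
        )

    def _coerce(self, X) -> FeatureMatrix:
        if isinstance(X, FeatureMatrix):
            return X
        if not isinstance(X, SequenceSet):
            from .sequence_io import SequenceRecord

            X = SequenceSet(
                [SequenceRecord(id=f"seq_{i}", sequence=s) for i, s in enumerate(X)]
            )
        if getattr(self, "featurizer_", None) is None:
            raise RuntimeError(
                "estimator was fitted on a FeatureMatrix; pass a FeatureMatrix to predict"
            )
        return self.featurizer_.transform(X)

    # -- core tabular stages (shared with cross_validate / ablation) -------
    def _fit_tabular(self, M: FeatureMatrix, y: np.ndarray) -> None:
        M = FeatureMatrix(M.X, dict(M.blocks), pd.Series(y, index=M.X.index))
        self.scaler_state_ = fit_scaler(self.scaler, M)
        M = apply_scaler(self.scaler_state_, M)
        if self.smote:
            M = smote_oversample(M, k_neighbors=self.smote_k, seed=self.seed)
        if self.select_method is not None and self.select_param is not None:
            cols, _ = select_features(self.select_method, M, self.select_param)
            self.selected_columns_ = cols
            M = M.select_columns(cols)
        else:
            self.selected_columns_ = None
        spec = ModelSpec(self.family, self.hyperparameters or {}, self.seed)
        self.model_ = make_classifier(spec)
        self.model_.fit(M.values, M.labels)
        self.feature_columns_ = M.columns
        self.blocks_ = dict(M.blocks)

    def _transform_tabular(self, M: FeatureMatrix) -> np.ndarray:
        M = apply_scaler(self.scaler_state_, M)
        if self.selected_columns_ is not None:
            M = M.select_columns(self.selected_columns_)
        return M.values

    # -- sklearn API --------------------------------------------------------
    def fit(self, X, y=None) -> "ThermophilicityClassifier":
        if isinstance(X, FeatureMatrix):
            yy = np.asarray(y, dtype=int) if y is not None else X.labels
            if yy is None:
                raise ValueError("labels required to fit")
            if len(np.unique(yy)) < 2:
                raise ValueError("training data must contain both classes")
            self.featurizer_ = None
            self._fit_tabular(X, yy)
        else:
            if not isinstance(X, SequenceSet):
                from .sequence_io import SequenceRecord

                X = SequenceSet(
                    [SequenceRecord(id=f"seq_{i}", sequence=s) for i, s in enumerate(X)]
                )
            yy = np.asarray(y, dtype=int) if y is not None else X.labels
            if yy is None:
                raise ValueError("labels required to fit")
            if len(np.unique(yy)) < 2:
                raise ValueError("training data must contain both classes")
            self.featurizer_ = self._make_featurizer()
            M = self.featurizer_.fit(X).transform(X)
            self._fit_tabular(M, yy)
        self.classes_ = np.array([0, 1])
        return self

    def decision_scores(self, X) -> np.ndarray:
        M = X if isinstance(X, FeatureMatrix) else self._coerce(X)
        vals = self._transform_tabular(M)
        return self.model_.predict_proba(vals)[:, 1]

    def predict_proba(self, X) -> np.ndarray:
        p = self.decision_scores(X)
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# spec-surface wrappers


@dataclass
class TrainedModel:
    """A fitted pipeline with its provenance manifest."""

    estimator: ThermophilicityClassifier
    manifest: dict

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        with open(path / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        joblib.dump(self.estimator, path / "estimator.joblib")

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        path = Path(path)
        with open(path / "manifest.json") as fh:
            manifest = json.load(fh)
        est = joblib.load(path / "estimator.joblib")
        return TrainedModel(est, manifest)


def train(
    spec: ModelSpec,
    M_train: FeatureMatrix,
    scaler: Optional[str] = None,
    smote: bool = False,
    select_method: Optional[str] = None,
    select_param: Optional[float] = None,
) -> TrainedModel:
    """Fit a classifier family on a (preprocessed) FeatureMatrix.

    By default the matrix is taken as already preprocessed; pass
    ``scaler``/``smote``/``select_*`` to run those stages here.
    """
    est = ThermophilicityClassifier(
        scaler=scaler or "minmax",
        smote=smote,
        select_method=select_method,
        select_param=select_param,
        family=spec.family,
        hyperparameters=spec.hyperparameters,
        seed=spec.seed,
    )
    if scaler is None:
        # identity scaling: still fits (harmless) min-max on given matrix
        est.scaler = "minmax"
    est.fit(M_train)
    manifest = {
        "family": spec.family,
        "hyperparameters": spec.hyperparameters,
        "seed": spec.seed,
        "n_train": M_train.shape[0],
        "n_features": M_train.shape[1],
        "blocks": {k: list(v) for k, v in M_train.blocks.items()},
    }
    return TrainedModel(est, manifest)


@dataclass
class CVResult:
    reports: list[EvaluationReport]
    fold_assignment: dict[str, int]
    mean: dict[str, float]
    sd: dict[str, float]


def cross_validate(
    estimator: ThermophilicityClassifier,
    M: FeatureMatrix,
    n_folds: int,
    seed: int,
) -> CVResult:
    """Stratified k-fold CV with in-fold preprocessing (no leakage)."""
    y = M.labels
    if y is None:
        raise ValueError("cross_validate requires labels")
    minority = int(min((y == 1).sum(), (y == 0).sum()))
    if n_folds > minority:
        raise ValueError(f"n_folds={n_folds} exceeds minority class count {minority}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    ids = M.ids
    reports, assignment = [], {}
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        for i in te:
            assignment[ids[i]] = fold
        est = ThermophilicityClassifier(**estimator.get_params())
        Mtr = M.select_rows([ids[i] for i in tr])
        Mte = M.select_rows([ids[i] for i in te])
        est.fit(Mtr)
        scores = est.decision_scores(Mte)
        reports.append(evaluate(y[te], scores))
    keys = reports[0].as_dict().keys()
    arr = {k: np.array([r.as_dict()[k] for r in reports]) for k in keys}
    return CVResult(
        reports=reports,
        fold_assignment=assignment,
        mean={k: float(v.mean()) for k, v in arr.items()},
        sd={k: float(v.std(ddof=1)) if len(v) > 1 else 0.0 for k, v in arr.items()},
    )


def build_default_pipeline(seed: int = 0) -> dict:
    """The shipped recipe: 15 feature blocks, min-max, SMOTE, f_classif,
    gradient boosting, 5-fold CV."""
    return {
        "feature_blocks": list(DESCRIPTOR_NAMES) + [STR_BLOCK],
        "string_dim": 1024,
        "scaler": "minmax",
        "smote": True,
        "smote_k": 5,
        "select_method": "f_classif",
        "select_param": None,  # keep all columns unless the user sets a budget
        "family": "gradient_boosting",
        "cv_folds": 5,
        "threshold": 0.5,
        "seed": seed,
    }


def default_estimator(seed: int = 0, **overrides) -> ThermophilicityClassifier:
    """Instantiate the default recipe as a ready-to-fit estimator."""
    cfg = build_default_pipeline(seed)
    params = dict(
        descriptors=DESCRIPTOR_NAMES,
        use_string_block=True,
        string_dim=cfg["string_dim"],
        scaler=cfg["scaler"],
        smote=cfg["smote"],
        smote_k=cfg["smote_k"],
        select_method=cfg["select_method"],
        select_param=cfg["select_param"],
        family=cfg["family"],
        seed=seed,
    )
    params.update(overrides)
    return ThermophilicityClassifier(**params)


def predict_table(model: ThermophilicityClassifier | TrainedModel, fasta_path) -> pd.DataFrame:
    """Predict every record in a FASTA; invalid records appear as REJECTED.

    Output columns: id, status, probability, predicted ("TP"/"NTP").
    The row count always equals the input record count.
    """
    est = model.estimator if isinstance(model, TrainedModel) else model
    raw = read_fasta(fasta_path)
    ok_idx = [i for i, r in enumerate(raw) if is_valid_sequence(r.sequence)]
    rows = {i: None for i in range(len(raw))}
    if ok_idx:
        valid = SequenceSet([raw[i] for i in ok_idx], name="query")
        if est.featurizer_ is None:
            raise ValueError("model was fitted on a FeatureMatrix; cannot featurize FASTA")
        scores = est.decision_scores(est.featurizer_.transform(valid))
        for j, i in enumerate(ok_idx):
            rows[i] = float(scores[j])
    out = []
    for i, r in enumerate(raw):
        p = rows[i]
        if p is None:
            out.append((r.id, "REJECTED", np.nan, ""))
        else:
            out.append((r.id, "OK", p, "TP" if p >= 0.5 else "NTP"))
    return pd.DataFrame(out, columns=["id", "status", "probability", "predicted"])
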