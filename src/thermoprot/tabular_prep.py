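"""Feature-matrix container, scaling, class rebalancing and selection.

The :class:`FeatureMatrix` is a pandas DataFrame (rows = sequence ids,
columns = sub-feature names) plus a *block manifest*: an ordered map
``block name -> [start, end)`` column range recording which encoder
produced which columns.  Every preprocessing step here is fitted on
training rows only and applied with stored statistics, never with
test-set statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_selection import chi2 as _sk_chi2
from sklearn.feature_selection import f_classif as _sk_f_classif
from sklearn.feature_selection import mutual_info_classif as _sk_mi
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import MinMaxScaler, StandardScaler


@dataclass
class FeatureMatrix:
    """Row-aligned concatenation of named feature blocks."""

    X: pd.DataFrame
    blocks: dict[str, tuple[int, int]]
    y: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.X.columns.duplicated().any():
            raise ValueError("duplicate column names in FeatureMatrix")
        if self.X.isna().any().any():
            raise ValueError("FeatureMatrix must not contain missing values")
        covered = np.zeros(self.X.shape[1], dtype=bool)
        for name, (start, end) in self.blocks.items():
            if not (0 <= start <= end <= self.X.shape[1]):
                raise ValueError(f"block {name!r} range [{start}, {end}) out of bounds")
            if covered[start:end].any():
                raise ValueError(f"block {name!r} overlaps another block")
            covered[start:end] = True
        if not covered.all():
            raise ValueError("block manifest does not cover all columns")
        if self.y is not None:
            self.y = pd.Series(np.asarray(self.y, dtype=int), index=self.X.index)
            if not set(np.unique(self.y)) <= {0, 1}:
                raise ValueError("labels must be binary 0/1")

    # -- basic accessors ----------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return list(self.X.index)

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    @property
    def values(self) -> np.ndarray:
        return self.X.to_numpy(dtype=float)

    @property
    def labels(self) -> Optional[np.ndarray]:
        return None if self.y is None else self.y.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def block_columns(self, name: str) -> list[str]:
        start, end = self.blocks[name]
        return list(self.X.columns[start:end])

    def block_of(self, column: str) -> str:
        i = self.X.columns.get_loc(column)
        for name, (start, end) in self.blocks.items():
            if start <= i < end:
                return name
        raise KeyError(column)

    # -- manipulation -------------------------------------------------------
    @staticmethod
    def from_blocks(
        ids: Sequence[str],
        parts: Sequence[tuple[str, Sequence[str], np.ndarray]],
        y: Optional[Sequence[int]] = None,
    ) -> "FeatureMatrix":
        """Assemble from ``(block name, column names, (n, d) array)`` parts."""
        frames, manifest, offset = [], {}, 0
        for name, cols, arr in parts:
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (len(ids), len(cols)):
                raise ValueError(f"block {name!r}: array shape {arr.shape} != ({len(ids)}, {len(cols)})")
            frames.append(pd.DataFrame(arr, index=list(ids), columns=list(cols)))
            manifest[name] = (offset, offset + len(cols))
            offset += len(cols)
        X = pd.concat(frames, axis=1) if frames else pd.DataFrame(index=list(ids))
        yy = None if y is None else pd.Series(list(y), index=list(ids))
        return FeatureMatrix(X, manifest, yy)

    def drop_blocks(self, names: Iterable[str]) -> "FeatureMatrix":
        """Remove whole blocks, rebuilding the manifest."""
        drop = set(names)
        unknown = drop - set(self.blocks)
        if unknown:
            raise KeyError(f"unknown blocks: {sorted(unknown)}")
        if drop == set(self.blocks):
            raise ValueError("cannot drop every block")
        parts = []
        for name, (start, end) in self.blocks.items():
            if name in drop:
                continue
            cols = list(self.X.columns[start:end])
            parts.append((name, cols, self.X.iloc[:, start:end].to_numpy(dtype=float)))
        return FeatureMatrix.from_blocks(self.ids, parts, y=self.labels)

    def select_rows(self, index: Sequence) -> "FeatureMatrix":
        sub = self.X.loc[list(index)]
        yy = None if self.y is None else self.y.loc[list(index)]
        return FeatureMatrix(sub, dict(self.blocks), yy)

    def select_columns(self, columns: Sequence[str]) -> "FeatureMatrix":
        """Keep the given columns (original order), shrinking blocks as needed."""
        keep = set(columns)
        parts = []
        for name, (start, end) in self.blocks.items():
            cols = [c for c in self.X.columns[start:end] if c in keep]
            if cols:
                parts.append((name, cols, self.X[cols].to_numpy(dtype=float)))
        return FeatureMatrix.from_blocks(self.ids, parts, y=self.labels)

    def with_values(self, values: np.ndarray) -> "FeatureMatrix":
        X = pd.DataFrame(values, index=self.X.index, columns=self.X.columns)
        return FeatureMatrix(X, dict(self.blocks), self.y)


# ---------------------------------------------------------------------------
# scaling


@dataclass
class ScalerState:
    """Fitted per-column statistics; transform never sees test statistics."""

    kind: str  # "minmax" | "zscore"
    scaler: object
    columns: list[str]
    constant_columns: list[str] = field(default_factory=list)


def fit_scaler(kind: str, M_train: FeatureMatrix) -> ScalerState:
    """Fit min-max (to [0, 1]) or z-score (population sd) column scaling.

    Constant training columns map to 0 under both kinds (degenerate
    denominator); they are recorded in the returned state.
    """
    if kind not in ("minmax", "zscore"):
        raise ValueError("kind must be 'minmax' or 'zscore'")
    if M_train.shape[0] == 0:
        raise ValueError("cannot fit a scaler on an empty matrix")
    X = M_train.values
    sk = MinMaxScaler(clip=False) if kind == "minmax" else StandardScaler()
    sk.fit(X)
    const = np.nonzero(X.max(axis=0) == X.min(axis=0))[0]
    constant_columns = [M_train.columns[i] for i in const]
    return ScalerState(kind, sk, M_train.columns, constant_columns)


def apply_scaler(state: ScalerState, M: FeatureMatrix) -> FeatureMatrix:
    if M.columns != state.columns:
        raise ValueError("matrix columns do not match the fitted scaler")
    return M.with_values(state.scaler.transform(M.values))


# ---------------------------------------------------------------------------
# SMOTE


def smote_oversample(
    M_train: FeatureMatrix, k_neighbors: int = 5, seed: int = 0
) -> FeatureMatrix:
    """Synthetic minority oversampling to exact class balance.

    Each synthetic row is ``x + u * (x_nn - x)`` with ``u ~ U(0, 1)`` and
    ``x_nn`` one of the ``k_neighbors`` nearest minority neighbours of a
    uniformly drawn minority row (Euclidean metric).  Original rows are
    retained unchanged; a balanced input comes back as-is.
    """
    y = M_train.labels
    if y is None:
        raise ValueError("SMOTE requires labels")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("SMOTE requires both classes present")
    if n_pos == n_neg:
        return M_train
    minority = 1 if n_pos < n_neg else 0
    n_min, n_maj = min(n_pos, n_neg), max(n_pos, n_neg)
    if n_min <= k_neighbors:
        raise ValueError(
            f"minority class has {n_min} members <= k_neighbors={k_neighbors}; "
            "use a smaller k"
        )
    rng = np.random.default_rng(seed)
    X = M_train.values
    min_idx = np.flatnonzero(y == minority)
    Xm = X[min_idx]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xm)
    _, neigh = nn.kneighbors(Xm)  # column 0 is the point itself
    n_new = n_maj - n_min
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(1, k_neighbors + 1, size=n_new)
    u = rng.random(size=n_new)
    x0 = Xm[base]
    x1 = Xm[neigh[base, pick]]
    synth = x0 + u[:, None] * (x1 - x0)

    ids = M_train.ids + [f"smote_{i}" for i in range(n_new)]
    Xout = np.vstack([X, synth])
    yout = np.concatenate([y, np.full(n_new, minority, dtype=int)])
    Xdf = pd.DataFrame(Xout, index=ids, columns=M_train.columns)
    return FeatureMatrix(Xdf, dict(M_train.blocks), pd.Series(yout, index=ids))


def cost_sensitive_weights(labels: Sequence[int]) -> dict[int, float]:
    """Inverse-frequency class weights: ``n_total / (2 * n_class)``.

    A balanced set gets weights (1, 1).
    """
    y = np.asarray(labels, dtype=int)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    n = n_pos + n_neg
    return {0: n / (2.0 * n_neg), 1: n / (2.0 * n_pos)}


# ---------------------------------------------------------------------------
# feature selection

SELECTION_METHODS = ("chi2", "f_classif", "mutual_information", "variance_threshold")


def select_features(
    method: str, M_train: FeatureMatrix, param: float
) -> tuple[list[str], np.ndarray]:
    """Score columns and return (selected names, scores over all columns).

    ``chi2`` / ``f_classif`` / ``mutual_information`` keep the
    top-``param`` columns by score (descending, ties broken by column
    order); ``variance_threshold`` keeps columns whose population
    variance exceeds ``param``.
    """
    if method not in SELECTION_METHODS:
        raise ValueError(f"method must be one of {SELECTION_METHODS}")
    X = M_train.values
    cols = M_train.columns
    if method == "variance_threshold":
        scores = X.var(axis=0)  # population variance (ddof=0)
        keep = [c for c, v in zip(cols, scores) if v > param]
        return keep, scores
    y = M_train.labels
    if y is None:
        raise ValueError(f"{method} requires labels")
    if method == "chi2":
        if (X < 0).any():
            raise ValueError("chi2 requires non-negative features; apply min-max scaling first")
        scores, _ = _sk_chi2(X, y)
    elif method == "f_classif":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant columns yield 0/0 -> nan
            scores, _ = _sk_f_classif(X, y)
    else:
        scores = _sk_mi(X, y, random_state=0)
    scores = np.nan_to_num(np.asarray(scores, dtype=float), nan=0.0)
    k = int(param)
    if k >= len(cols):
        if k > len(cols):
            warnings.warn(
                f"requested {k} features but only {len(cols)} exist; returning all",
                stacklevel=2,
            )
        return list(cols), scores
    # stable sort keeps column order among ties
    order = np.argsort(-scores, kind="stable")[:k]
    keep_set = set(order.tolist())
    return [c for i, c in enumerate(cols) if i in keep_set], scores
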