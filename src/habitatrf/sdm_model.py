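"""Random-forest occurrence model: tuning, validation, importance, mapping.

The model stage follows a fixed recipe:

1. extract predictor values under every occurrence point into a
   :class:`FeatureTable` (presence = 1, pseudo-absence = 0);
2. grid-search ``ntree`` x ``mtry`` by out-of-bag (OOB) error —
   ntree over {50, 100, 200, 500, 1000, 1500}, mtry over
   {3, 5, 7, 9, 10, 15, 20} — picking the OOB-minimal pair, ties broken
   toward the cheaper model;
3. repeated stratified 5-fold cross-validation (10 repeats) with
   imbalance-aware fold sampling: negatives drawn without replacement,
   the rarer positives resampled with replacement up to the negative
   count;
4. impurity-decrease (Gini) feature importance averaged over ten fixed
   seeds [11, 17, 22, 34, 54, 68, 96, 108, 224, 312]; predictors whose
   mean importance is exactly zero are pruned;
5. final fit and per-cell prediction: the Habitat Suitability Index is
   the fraction of trees voting presence, and the binary map is the
   majority vote (HSI >= 0.5).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .points import PRESENCE, OccurrenceSet
from .raster import DEFAULT_NODATA, EnvironmentalStack, RasterGrid

NTREE_GRID: tuple[int, ...] = (50, 100, 200, 500, 1000, 1500)
MTRY_GRID: tuple[int, ...] = (3, 5, 7, 9, 10, 15, 20)
IMPORTANCE_SEEDS: tuple[int, ...] = (11, 17, 22, 34, 54, 68, 96, 108, 224, 312)

__all__ = [
    "NTREE_GRID",
    "MTRY_GRID",
    "IMPORTANCE_SEEDS",
    "FeatureTable",
    "TuningResult",
    "CVReport",
    "ImportanceTable",
    "SDMModel",
    "extract_features",
    "tune_oob",
    "balanced_fold_sample",
    "repeated_cv",
    "feature_importance",
    "fit_final",
    "predict_hsi",
    "predict_class",
]


def _derive_seed(seed: int, *tags) -> int:
    """Stable sub-stream seed < 2**31 from a master seed and tags."""
    text = ":".join([str(seed), *map(str, tags)])
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


@dataclass
class FeatureTable:
    """Points x predictors matrix with a binary label (presence = 1)."""

    X: pd.DataFrame
    y: np.ndarray
    n_dropped: int = 0  # records discarded because they sat on nodata cells

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if len(self.X) != len(self.y):
            raise ValueError("X and y lengths differ")
        if self.X.isna().any().any():
            raise ValueError("feature table contains missing predictor values")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")

    @property
    def layer_names(self) -> list[str]:
        return list(self.X.columns)

    def __len__(self) -> int:
        return len(self.y)

    def require_both_classes(self) -> None:
        if len(np.unique(self.y)) < 2:
            raise ValueError("feature table must contain both classes")

    def drop_layers(self, names: list[str]) -> "FeatureTable":
        keep = [c for c in self.X.columns if c not in set(names)]
        return FeatureTable(self.X[keep], self.y, self.n_dropped)

    def to_csv(self, path) -> None:
        out = self.X.copy()
        out["label"] = self.y
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise ValueError("feature CSV must have a 'label' column")
        return cls(df.drop(columns="label"), df["label"].to_numpy())


def extract_features(stack: EnvironmentalStack, occ: OccurrenceSet) -> FeatureTable:
    """Predictor values under each occurrence point.

    Records whose cell is nodata in *any* layer are dropped; the count
    is kept on the table so the filter is auditable. Points outside the
    stack extent raise.
    """
    if len(occ) == 0:
        raise ValueError("empty occurrence set")
    stack.require_harmonized()
    cols = {name: grid.sample(occ.lon, occ.lat) for name, grid in stack.items()}
    df = pd.DataFrame(cols)
    valid = np.ones(len(df), dtype=bool)
    for name, grid in stack.items():
        valid &= (df[name].to_numpy() != grid.nodata) & np.isfinite(df[name].to_numpy())
    n_dropped = int((~valid).sum())
    if valid.sum() == 0:
        raise ValueError("all occurrence records fall on nodata cells")
    y = (occ.labels == PRESENCE).astype(int)
    return FeatureTable(df[valid].reset_index(drop=True), y[valid], n_dropped=n_dropped)


def _forest(ntree: int, mtry: int, seed: int, oob: bool = False) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=ntree,
        max_features=mtry,
        criterion="gini",
        oob_score=oob,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )


@dataclass
class TuningResult:
    """OOB error per (ntree, mtry) grid cell plus the selected pair."""

    oob_error: pd.DataFrame  # index = ntree, columns = mtry
    best: tuple[int, int]

    def __post_init__(self) -> None:
        if (self.oob_error.to_numpy() < 0).any():
            raise ValueError("OOB errors must be >= 0")
        best_err = self.oob_error.loc[self.best[0], self.best[1]]
        if not np.isclose(best_err, self.oob_error.to_numpy().min()):
            raise ValueError("best pair must attain the grid minimum")


def tune_oob(
    table: FeatureTable,
    ntree_grid: tuple[int, ...] = NTREE_GRID,
    mtry_grid: tuple[int, ...] = MTRY_GRID,
    seed: int = 0,
) -> TuningResult:
    """Fit one forest per grid cell and record its OOB error.

    The selected pair minimizes OOB error; ties go to the smaller
    ntree, then the smaller mtry (the cheaper model).
    """
    table.require_both_classes()
    p = len(table.layer_names)
    bad = [m for m in mtry_grid if m > p]
    if bad:
        raise ValueError(f"mtry values {bad} exceed the {p} available predictors")
    errs = pd.DataFrame(index=list(ntree_grid), columns=list(mtry_grid), dtype=float)
    errs.index.name = "ntree"
    errs.columns.name = "mtry"
    best: tuple[int, int] | None = None
    best_err = np.inf
    for nt in sorted(ntree_grid):
        for mt in sorted(mtry_grid):
            rf = _forest(nt, mt, _derive_seed(seed, "tune", nt, mt), oob=True)
            rf.fit(table.X.to_numpy(), table.y)
            e = 1.0 - rf.oob_score_
            errs.loc[nt, mt] = e
            if e < best_err - 1e-12:
                best_err, best = e, (nt, mt)
    assert best is not None
    return TuningResult(oob_error=errs.loc[list(ntree_grid), list(mtry_grid)], best=best)


def balanced_fold_sample(
    table: FeatureTable, seed: int, per_class: int | None = None
) -> np.ndarray:
    """Indices of an imbalance-corrected training sample.

    Negatives are drawn *without* replacement; positives *with*
    replacement up to ``per_class`` (default: the negative count), or
    without forced repetition when they already number at least the
    target. The returned indices point into ``table``.
    """
    table.require_both_classes()
    rng = np.random.default_rng(seed)
    neg = np.flatnonzero(table.y == 0)
    pos = np.flatnonzero(table.y == 1)
    target = len(neg) if per_class is None else per_class
    n_neg = min(target, len(neg))
    neg_draw = rng.choice(neg, size=n_neg, replace=False)
    if len(pos) >= target:
        pos_draw = rng.choice(pos, size=target, replace=False)
    else:
        pos_draw = rng.choice(pos, size=target, replace=True)
    return np.concatenate([neg_draw, pos_draw])


def fold_assignments(
    table: FeatureTable, k: int, repeat: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified (train, validation) index pairs for one CV repeat.

    Exposed so the fold structure itself is checkable: within a repeat
    the validation folds partition the records exactly.
    """
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=_derive_seed(seed, "cv", repeat))
    return list(skf.split(np.zeros((len(table), 1)), table.y))


@dataclass
class CVReport:
    """Per-(repeat, fold) training/validation accuracies, in percent."""

    records: pd.DataFrame  # columns: repeat, fold, train_acc_pct, val_acc_pct
    mean_train_acc_pct: float = field(init=False)
    mean_val_acc_pct: float = field(init=False)

    def __post_init__(self) -> None:
        req = {"repeat", "fold", "train_acc_pct", "val_acc_pct"}
        if set(self.records.columns) != req:
            raise ValueError(f"CV records need columns {sorted(req)}")
        accs = self.records[["train_acc_pct", "val_acc_pct"]].to_numpy()
        if ((accs < 0) | (accs > 100)).any():
            raise ValueError("accuracies must lie in [0, 100]")
        self.mean_train_acc_pct = float(self.records["train_acc_pct"].mean())
        self.mean_val_acc_pct = float(self.records["val_acc_pct"].mean())


def repeated_cv(
    table: FeatureTable,
    ntree: int,
    mtry: int,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    per_class: int | None = None,
) -> CVReport:
    """Repeated stratified k-fold CV with balanced fold sampling.

    Each repeat partitions the records into ``k`` stratified folds;
    every record validates exactly once per repeat. The forest trains
    on a balanced sample of the k-1 training folds; training accuracy
    is scored on that balanced sample and validation accuracy on the
    held-out fold. Repeating reshuffles the folds so, over repeats, all
    pseudo-absences face the presences in training.
    """
    table.require_both_classes()
    counts = np.bincount(table.y, minlength=2)
    if counts.min() < k:
        raise ValueError(f"each class needs >= k={k} members, got counts {counts.tolist()}")
    X = table.X.to_numpy()
    rows = []
    for rep in range(1, repeats + 1):
        for fold, (tr, va) in enumerate(fold_assignments(table, k, rep, seed), start=1):
            sub = FeatureTable(table.X.iloc[tr], table.y[tr])
            samp = balanced_fold_sample(sub, _derive_seed(seed, "bal", rep, fold), per_class)
            Xtr, ytr = sub.X.to_numpy()[samp], sub.y[samp]
            rf = _forest(ntree, mtry, _derive_seed(seed, "fit", rep, fold))
            rf.fit(Xtr, ytr)
            rows.append(
                {
                    "repeat": rep,
                    "fold": fold,
                    "train_acc_pct": 100.0 * rf.score(Xtr, ytr),
                    "val_acc_pct": 100.0 * rf.score(X[va], table.y[va]),
                }
            )
    return CVReport(pd.DataFrame(rows))


@dataclass
class ImportanceTable:
    """Seed-averaged impurity-decrease importances with zero pruning."""

    importances: pd.Series  # mean Gini importance per predictor
    seed_list: tuple[int, ...]
    pruned: list[str]

    def __post_init__(self) -> None:
        if (self.importances < 0).any():
            raise ValueError("importances must be >= 0")
        retained = set(self.importances.index) - set(self.pruned)
        if retained & set(self.pruned):
            raise ValueError("pruned and retained sets overlap")

    def ranked(self) -> pd.Series:
        return self.importances.sort_values(ascending=False)

    def to_csv(self, path) -> None:
        df = self.importances.rename("mean_importance").to_frame()
        df["pruned"] = [n in set(self.pruned) for n in df.index]
        df.index.name = "layer"
        df.to_csv(path)


def feature_importance(
    table: FeatureTable,
    seeds: tuple[int, ...] = IMPORTANCE_SEEDS,
    ntree: int = 500,
    mtry: int = 9,
    zero_tol: float = 0.0,
) -> ImportanceTable:
    """Mean impurity-decrease importance over one forest per seed.

    A predictor never selected for a split in any of the seeded forests
    accumulates exactly zero importance and is listed as pruned
    (``zero_tol`` admits a small tolerance for floating accumulation if
    ever needed; the default is the exact-zero test).
    """
    if len(seeds) == 0:
        raise ValueError("seed list must be non-empty")
    table.require_both_classes()
    if mtry > len(table.layer_names):
        raise ValueError(f"mtry={mtry} exceeds the {len(table.layer_names)} predictors")
    acc = np.zeros(len(table.layer_names))
    for s in seeds:
        rf = _forest(ntree, mtry, int(s))
        rf.fit(table.X.to_numpy(), table.y)
        acc += rf.feature_importances_
    mean_imp = pd.Series(acc / len(seeds), index=table.layer_names)
    pruned = [n for n, v in mean_imp.items() if v <= zero_tol]
    return ImportanceTable(importances=mean_imp, seed_list=tuple(seeds), pruned=pruned)


@dataclass
class SDMModel:
    """Fitted forest plus the exact predictor list it was trained on."""

    forest: RandomForestClassifier
    layer_names: list[str]
    ntree: int
    mtry: int
    seed: int


def fit_final(
    table: FeatureTable, ntree: int = 500, mtry: int = 9, seed: int = 0
) -> SDMModel:
    """Fit the production forest (defaults: the OOB-selected 500 trees, mtry 9)."""
    table.require_both_classes()
    if mtry > len(table.layer_names):
        raise ValueError(f"mtry={mtry} exceeds the {len(table.layer_names)} predictors")
    rf = _forest(ntree, mtry, _derive_seed(seed, "final"))
    rf.fit(table.X.to_numpy(), table.y)
    return SDMModel(rf, table.layer_names, ntree, mtry, seed)


def _vote_fraction(model: SDMModel, X: np.ndarray) -> np.ndarray:
    """Fraction of trees voting presence — the HSI definition."""
    votes = np.zeros(len(X))
    for est in model.forest.estimators_:
        votes += est.predict(X)
    return votes / len(model.forest.estimators_)


def predict_hsi(model: SDMModel, stack: EnvironmentalStack) -> RasterGrid:
    """Habitat Suitability Index surface in [0, 1]; nodata propagated.

    The stack must contain every layer the model was trained on (extra
    layers are ignored); a missing layer raises naming it.
    """
    sub = stack.subset(model.layer_names)
    geom = sub.require_harmonized()
    X, idx = sub.to_matrix()
    out = np.full(geom.nrows * geom.ncols, DEFAULT_NODATA)
    step = 200_000
    for i in range(0, len(X), step):
        out[idx[i : i + step]] = _vote_fraction(model, X[i : i + step])
    return RasterGrid(out.reshape(geom.shape), geom, nodata=DEFAULT_NODATA, name="hsi")


def predict_class(model: SDMModel, stack: EnvironmentalStack) -> RasterGrid:
    """Majority-vote binary map: presence (1) where HSI >= 0.5."""
    hsi = predict_hsi(model, stack)
    cls = np.where(hsi.valid_mask, (hsi.values >= 0.5).astype(float), hsi.nodata)
    return hsi.with_values(cls, name="predicted_class")
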