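"""Dataset assembly, feature screening, and the FPR-calibrated random forest.

Separate forests are trained for on-ss and off-ss variants and are never
cross-applied.  Predicted disease-causing probabilities are mapped to an
empirical false-positive rate via a calibration table built on validation
neutrals, and thresholded into three categories: Damaging (FPR < 0.05),
Possibly Damaging (0.05 <= FPR < 0.1) and Benign (FPR >= 0.1).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (average_precision_score, matthews_corrcoef,
                             roc_auc_score)
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .features import META_COLUMNS, feature_columns

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "pathogenic"
NEGATIVE_LABEL = "neutral"
DEFAULT_N_ESTIMATORS_GRID = (25, 50, 75, 100, 125, 150, 175, 200)
DEFAULT_MAX_DEPTH_GRID = (5, 10, 15, 20, 25)
MAF_THRESHOLD = 0.10
DISTANCE_BIN_BP = 10

#: feature-name prefixes pooled into one absence flag each
ABSENCE_GROUPS = {
    "absent_structural": ("mean_disorder", "longest_structured_run",
                          "frac_helix", "frac_sheet", "frac_coil", "mean_asa",
                          "domain_overlap_pct", "ptm_per_100aa"),
    "absent_conservation": ("cons_locus", "cons_mean_3bp", "cons_mean_7bp"),
    "absent_splicing": ("junction_donor", "junction_acceptor",
                        "delta_donor", "delta_acceptor"),
}


@dataclass
class FeatureMatrix:
    """A labeled (or unlabeled) feature table for one region class."""

    data: pd.DataFrame
    region_class: str

    def __post_init__(self) -> None:
        bad = set(self.data["region_class"].dropna().unique()) - {self.region_class}
        if bad:
            raise ValueError(f"rows of classes {bad} in a {self.region_class} matrix")

    @property
    def ids(self) -> np.ndarray:
        return self.data["variant_id"].to_numpy()

    @property
    def X(self) -> pd.DataFrame:
        return self.data[feature_columns(self.data)]

    @property
    def y(self) -> np.ndarray | None:
        lab = self.data["label"]
        if lab.isna().all():
            return None
        return (lab == POSITIVE_LABEL).to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def _match_distance_distribution(neutral: pd.DataFrame, pathogenic: pd.DataFrame,
                                 rng: np.random.Generator,
                                 bin_width: int = DISTANCE_BIN_BP) -> pd.DataFrame:
    """Subsample neutral rows so their junction-distance histogram matches
    the pathogenic one (fixed-width bins, sampling without replacement,
    capped at availability)."""
    bins_p = (pathogenic["min_distance"].to_numpy() - 1) // bin_width
    bins_n = (neutral["min_distance"].to_numpy() - 1) // bin_width
    keep: list[np.ndarray] = []
    for b, target in zip(*np.unique(bins_p, return_counts=True)):
        pool = np.flatnonzero(bins_n == b)
        if len(pool) < target:
            logger.warning("distance bin %d-%d bp: only %d neutral candidates "
                           "for %d pathogenic", b * bin_width + 1,
                           (b + 1) * bin_width, len(pool), target)
        take = min(int(target), len(pool))
        if take:
            keep.append(rng.choice(pool, size=take, replace=False))
    idx = np.sort(np.concatenate(keep)) if keep else np.array([], dtype=int)
    return neutral.iloc[idx]


def _stratified_split(df: pd.DataFrame, rng: np.random.Generator,
                      train_fraction: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    train_idx, val_idx = [], []
    for _, grp in df.groupby("label", sort=True):
        order = grp.index.to_numpy()[rng.permutation(len(grp))]
        n_train = int(round(train_fraction * len(order)))
        train_idx.extend(order[:n_train])
        val_idx.extend(order[n_train:])
    return df.loc[sorted(train_idx)], df.loc[sorted(val_idx)]


def assemble_datasets(pathogenic: pd.DataFrame, neutral: pd.DataFrame,
                      seed: int, maf_threshold: float = MAF_THRESHOLD,
                      bin_width: int = DISTANCE_BIN_BP,
                      train_fraction: float = 2.0 / 3.0
                      ) -> dict[str, dict[str, FeatureMatrix]]:
    """Build {on-ss, off-ss} x {train, validation} labeled matrices.

    Neutral variants must have MAF strictly above ``maf_threshold``;
    off-ss neutrals are further subsampled to match the pathogenic
    distance-to-junction histogram.  The split is stratified by label at
    ``train_fraction`` with a seeded RNG.
    """
    rng = np.random.default_rng(seed)
    pathogenic = pathogenic.copy()
    neutral = neutral.copy()
    pathogenic["label"] = POSITIVE_LABEL
    neutral["label"] = NEGATIVE_LABEL
    neutral = neutral[neutral["maf"].fillna(0.0) > maf_threshold]
    out: dict[str, dict[str, FeatureMatrix]] = {}
    for region in ("on-ss", "off-ss"):
        p = pathogenic[pathogenic["region_class"] == region]
        n = neutral[neutral["region_class"] == region]
        if region == "off-ss":
            n = _match_distance_distribution(n.reset_index(drop=True), p, rng,
                                             bin_width)
        both = pd.concat([p, n], ignore_index=True)
        both = both.dropna(axis=1, how="all")
        train, val = _stratified_split(both, rng, train_fraction)
        out[region] = {
            "train": FeatureMatrix(train.reset_index(drop=True), region),
            "validation": FeatureMatrix(val.reset_index(drop=True), region),
        }
    return out


# ---------------------------------------------------------------------------
# Feature screening
# ---------------------------------------------------------------------------

def screen_features(fm: FeatureMatrix) -> pd.DataFrame:
    """Wilcoxon rank-sum screen of every feature, BH-adjusted, with delta
    medians min-max rescaled to [-1, 1] across features."""
    y = fm.y
    if y is None or len(np.unique(y)) < 2:
        raise ValueError("screening needs both labels present")
    rows = []
    for col in fm.X.columns:
        x = fm.X[col].to_numpy(dtype=float)
        ok = np.isfinite(x)
        xp, xn = x[ok & (y == 1)], x[ok & (y == 0)]
        if len(xp) == 0 or len(xn) == 0 or (np.ptp(x[ok]) == 0 if ok.any() else True):
            rows.append({"feature": col, "p_value": 1.0, "delta_median": 0.0,
                         "constant": True})
            continue
        res = stats.mannwhitneyu(xp, xn, alternative="two-sided", method="auto")
        rows.append({"feature": col, "p_value": float(res.pvalue),
                     "delta_median": float(np.median(xp) - np.median(xn)),
                     "constant": False})
    df = pd.DataFrame(rows)
    df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    dm = df["delta_median"].to_numpy()
    span = dm.max() - dm.min()
    df["delta_median_rescaled"] = (0.0 if span == 0
                                   else 2.0 * (dm - dm.min()) / span - 1.0)
    return df


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

class FprCalibratedForest(BaseEstimator, ClassifierMixin):
    """Random forest with grid-searched hyperparameters and FPR calibration.

    Follows the scikit-learn estimator contract: hyperparameters are
    constructor arguments, ``fit`` learns ``forest_``, ``medians_`` (for
    NaN imputation) and ``best_params_``; ``calibrate`` adds a monotone
    probability-to-FPR step table from validation neutrals.  The optional
    ``region_class`` tag guards against applying an on-ss model to off-ss
    variants and vice versa.
    """

    def __init__(self, region_class: str | None = None,
                 n_estimators_grid: Sequence[int] = DEFAULT_N_ESTIMATORS_GRID,
                 max_depth_grid: Sequence[int] = DEFAULT_MAX_DEPTH_GRID,
                 cv: int = 3, random_state: int = 0,
                 fpr_damaging: float = 0.05, fpr_possibly: float = 0.10,
                 absence_flags: bool = True):
        self.region_class = region_class
        self.n_estimators_grid = n_estimators_grid
        self.max_depth_grid = max_depth_grid
        self.cv = cv
        self.random_state = random_state
        self.fpr_damaging = fpr_damaging
        self.fpr_possibly = fpr_possibly
        self.absence_flags = absence_flags

    # -- preprocessing ------------------------------------------------------

    def _prepare(self, X: pd.DataFrame, fitting: bool) -> np.ndarray:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        if fitting:
            self.feature_names_in_ = list(map(str, X.columns))
        else:
            check_is_fitted(self, "feature_names_in_")
            cols = list(map(str, X.columns))
            unknown = sorted(set(cols) - set(self.feature_names_in_))
            if unknown:
                raise ValueError(f"unknown feature columns: {unknown}")
            missing = sorted(set(self.feature_names_in_) - set(cols))
            if missing:
                raise ValueError(f"missing feature columns: {missing}")
            X = X[self.feature_names_in_]
        mat = X.to_numpy(dtype=float)
        flags = []
        if self.absence_flags:
            for flag, prefixes in ABSENCE_GROUPS.items():
                idx = [i for i, c in enumerate(self.feature_names_in_)
                       if c.startswith(prefixes)]
                if idx:
                    flags.append(np.isnan(mat[:, idx]).any(axis=1).astype(float))
        if fitting:
            med = np.nanmedian(mat, axis=0)
            med = np.where(np.isfinite(med), med, 0.0)
            self.medians_ = med
        mat = np.where(np.isnan(mat), self.medians_, mat)
        if flags:
            mat = np.column_stack([mat] + flags)
        return mat

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y):
        y = np.asarray(y)
        if y.dtype.kind in "OUS":
            y = (y == POSITIVE_LABEL).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        mat = self._prepare(X, fitting=True)
        skf = StratifiedKFold(n_splits=self.cv, shuffle=True,
                              random_state=self.random_state)
        best = None
        records = []
        for n_est in self.n_estimators_grid:
            for depth in self.max_depth_grid:
                forest = RandomForestClassifier(
                    n_estimators=n_est, max_depth=depth,
                    random_state=self.random_state, n_jobs=1)
                auc = float(np.mean(cross_val_score(
                    forest, mat, y, cv=skf, scoring="roc_auc")))
                records.append({"n_estimators": n_est, "max_depth": depth,
                                "cv_auroc": auc})
                # ties break toward fewer trees, then shallower depth
                if best is None or auc > best[0] + 1e-12:
                    best = (auc, n_est, depth)
        self.grid_search_record_ = pd.DataFrame(records)
        self.best_params_ = {"n_estimators": best[1], "max_depth": best[2]}
        self.best_cv_auroc_ = best[0]
        self.forest_ = RandomForestClassifier(
            random_state=self.random_state, n_jobs=1,
            **self.best_params_).fit(mat, y)
        self.classes_ = self.forest_.classes_
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(self._prepare(X, fitting=False))

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0.5).astype(int)

    # -- calibration --------------------------------------------------------

    def calibrate(self, X_val, y_val) -> pd.DataFrame:
        """Build the probability-to-FPR table from validation neutrals."""
        y_val = np.asarray(y_val)
        if y_val.dtype.kind in "OUS":
            y_val = (y_val == POSITIVE_LABEL).astype(int)
        probs = self.decision_function(X_val)
        neutral = np.sort(probs[y_val == 0])
        if neutral.size == 0:
            raise ValueError("calibration requires neutral validation examples")
        self.calibration_neutral_probs_ = neutral
        thresholds = np.unique(neutral)
        fpr = [(neutral >= t).mean() for t in thresholds]
        self.calibration_table_ = pd.DataFrame(
            {"threshold": thresholds, "fpr": fpr})
        return self.calibration_table_

    def fpr_of(self, probabilities: np.ndarray) -> np.ndarray:
        """Empirical FPR: fraction of calibration neutrals scoring >= p."""
        check_is_fitted(self, "calibration_neutral_probs_")
        neutral = self.calibration_neutral_probs_
        idx = np.searchsorted(neutral, np.asarray(probabilities), side="left")
        return (neutral.size - idx) / neutral.size

    def categorize(self, fpr: np.ndarray) -> np.ndarray:
        fpr = np.asarray(fpr)
        out = np.where(fpr < self.fpr_damaging, "Damaging",
                       np.where(fpr < self.fpr_possibly, "Possibly Damaging",
                                "Benign"))
        return out

    def predict_records(self, fm: FeatureMatrix) -> pd.DataFrame:
        """Full prediction output for a FeatureMatrix of the matching class."""
        if self.region_class is not None and fm.region_class != self.region_class:
            raise ValueError(
                f"model for {self.region_class!r} applied to "
                f"{fm.region_class!r} variants")
        probs = self.decision_function(fm.X)
        fpr = self.fpr_of(probs)
        return pd.DataFrame({
            "variant_id": fm.ids, "probability": probs, "fpr": fpr,
            "category": self.categorize(fpr)})


def train(fm: FeatureMatrix, seed: int = 0,
          n_estimators_grid: Sequence[int] = DEFAULT_N_ESTIMATORS_GRID,
          max_depth_grid: Sequence[int] = DEFAULT_MAX_DEPTH_GRID,
          cv: int = 3) -> FprCalibratedForest:
    """Fit a forest for one region class from a labeled FeatureMatrix."""
    est = FprCalibratedForest(region_class=fm.region_class,
                              n_estimators_grid=n_estimators_grid,
                              max_depth_grid=max_depth_grid, cv=cv,
                              random_state=seed)
    return est.fit(fm.X, fm.y)


def calibrate_fpr(model: FprCalibratedForest, fm_val: FeatureMatrix) -> pd.DataFrame:
    if model.region_class is not None and fm_val.region_class != model.region_class:
        raise ValueError("calibration set region class does not match model")
    return model.calibrate(fm_val.X, fm_val.y)


def evaluate(y_true: np.ndarray, probabilities: np.ndarray,
             threshold: float = 0.5) -> dict[str, float]:
    """AUROC, step-interpolated AUPR and MCC at a probability threshold."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("evaluation requires both classes")
    return {
        "auroc": float(roc_auc_score(y_true, probabilities)),
        "aupr": float(average_precision_score(y_true, probabilities)),
        "mcc": float(matthews_corrcoef(y_true,
                                       np.asarray(probabilities) >= threshold)),
    }


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: FprCalibratedForest, directory) -> None:
    import joblib
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "region_class": model.region_class,
        "params": model.get_params(),
        "best_params": model.best_params_,
        "feature_names": model.feature_names_in_,
        "medians": list(map(float, model.medians_)),
        "calibration_neutral_probs": list(
            map(float, getattr(model, "calibration_neutral_probs_", []))),
    }
    (d / "model.json").write_text(json.dumps(meta, indent=1))
    joblib.dump(model.forest_, d / "forest.joblib")


def load_model(directory) -> FprCalibratedForest:
    import joblib
    from pathlib import Path

    d = Path(directory)
    meta = json.loads((d / "model.json").read_text())
    est = FprCalibratedForest(**meta["params"])
    est.feature_names_in_ = meta["feature_names"]
    est.medians_ = np.asarray(meta["medians"], dtype=float)
    est.best_params_ = meta["best_params"]
    est.forest_ = joblib.load(d / "forest.joblib")
    est.classes_ = est.forest_.classes_
    probs = np.asarray(meta["calibration_neutral_probs"], dtype=float)
    if probs.size:
        est.calibration_neutral_probs_ = probs
        thresholds = np.unique(probs)
        est.calibration_table_ = pd.DataFrame(
            {"threshold": thresholds,
             "fpr": [(probs >= t).mean() for t in thresholds]})
    return est
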