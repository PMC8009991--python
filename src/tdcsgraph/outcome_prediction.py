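"""Treatment-response prediction from graph-measure change rates.

Features are the pre-to-post change rates of C_net, L_net, E_net and
L_local at the stimulation sites, taken at one density (default 0.3), for
active-arm samples only.  Features are ranked by the maximal information
coefficient (MIC) against the response label, a sequential forward search
(SFS) picks the best prefix by cross-validated accuracy, and an RBF-kernel
SVM is evaluated with nested cross-validation (outer folds estimate
ACC/SN/SP/AUC, inner folds grid-search C and gamma).

By default folds are group-aware: the overlapping windows of one subject
never straddle an outer train/test split.  ``paper_mode=True`` reproduces
sample-level splitting, which shares subjects across folds and is
leakage-prone with augmented data.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedGroupKFold,
    StratifiedKFold,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "FEATURE_NAMES",
    "FeatureMatrix",
    "PredictionReport",
    "change_rate",
    "build_feature_matrix",
    "mic",
    "rank_features_mic",
    "sfs_select",
    "nested_cv_svm",
    "roc_auc",
    "DEFAULT_PARAM_GRID",
]

FEATURE_NAMES = ("C_net", "L_net", "E_net", "L_local_site")

# Powers-of-two grid: C in 2^-5..2^15, gamma in 2^-15..2^3, step 2^2.
DEFAULT_PARAM_GRID = {
    "svc__C": [2.0**e for e in range(-5, 16, 2)],
    "svc__gamma": [2.0**e for e in range(-15, 4, 2)],
}


def change_rate(pre: float, post: float) -> float:
    """Relative change (post - pre)/pre of a measure across stimulation."""
    if pre == 0:
        raise ValueError("change rate undefined: pre-stimulation value is 0")
    return (post - pre) / pre


@dataclass
class FeatureMatrix:
    """Per-sample change-rate features with response labels.

    ``X`` has one row per active-arm sample (subject x window) and one named
    column per feature; ``y`` is the responder label; ``subjects`` gives the
    subject of each row for group-aware splitting.
    """

    X: pd.DataFrame
    y: np.ndarray
    subjects: np.ndarray

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y) or len(self.X) != len(self.subjects):
            raise ValueError("X, y and subjects must have equal length")
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")


def build_feature_matrix(
    measures: pd.DataFrame,
    groups: dict[str, str],
    density: float = 0.3,
    on_nonfinite: str = "drop",
) -> FeatureMatrix:
    """Change-rate features at one density for active-arm samples.

    ``measures`` is the tidy measure table (subject_id, condition,
    window_index, density, measure, scope, value).  Change rates are
    computed per paired window; sham subjects are excluded (they carry no
    response label).

    A window whose graph disconnects at the feature density has infinite
    path length, so its path-based change rates are undefined; such windows
    are excluded with a warning (``on_nonfinite="drop"``, analogous to
    motion-based scan exclusion) or raise (``on_nonfinite="error"``).
    """
    wanted = [
        ("C_net", "global"),
        ("L_net", "global"),
        ("E_net", "global"),
        ("L_local", "site"),
    ]
    df = measures[np.isclose(measures["density"], density)]
    if df.empty:
        raise ValueError(f"no measures at density {density}")
    active = {s for s, g in groups.items() if g.startswith("active")}
    rows: dict[tuple[str, int], dict[str, float]] = {}
    for name, (measure, scope) in zip(FEATURE_NAMES, wanted):
        sub = df[(df["measure"] == measure) & (df["scope"] == scope)]
        wide = sub.pivot_table(
            index=["subject_id", "window_index"], columns="condition",
            values="value",
        )
        for (subject, window), row in wide.iterrows():
            if subject not in active:
                continue
            if pd.isna(row.get("pre")) or pd.isna(row.get("post")):
                raise ValueError(
                    f"unpaired pre/post for {subject} window {window} ({name})"
                )
            rows.setdefault((subject, window), {})[name] = change_rate(
                row["pre"], row["post"]
            )
    bad = sorted(
        k for k, feats in rows.items()
        if not all(np.isfinite(feats.get(n, np.nan)) for n in FEATURE_NAMES)
    )
    if bad:
        msg = (
            f"{len(bad)} window(s) with undefined change rates at density "
            f"{density} (disconnected graph?): "
            + ", ".join(f"{s} w{w}" for s, w in bad[:5])
        )
        if on_nonfinite == "error":
            raise ValueError(msg)
        warnings.warn(msg + " - excluded", RuntimeWarning, stacklevel=2)
        for k in bad:
            del rows[k]
    index = sorted(rows)
    X = pd.DataFrame([rows[k] for k in index], columns=list(FEATURE_NAMES))
    subjects = np.array([k[0] for k in index])
    y = np.array([groups[s] == "active_responder" for s in subjects])
    return FeatureMatrix(X=X, y=y, subjects=subjects)


# ---------------------------------------------------------------------------
# Maximal information coefficient


def _entropy_bits(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _dp_max_partition_score(
    labels: np.ndarray, cut_positions: np.ndarray, n_bins_max: int, q: int
) -> dict[int, float]:
    """Maximize sum of per-bin scores over ordered partitions.

    Points are already sorted along the optimized axis; ``labels`` are their
    bins on the fixed axis (0..q-1) and ``cut_positions`` the admissible cut
    indices (value boundaries), including 0 and n.  For a bin of size s with
    fixed-axis counts c_b the additive score is
    sum_b (c_b/n) log2(c_b/n) - (s/n) log2(s/n), so that
    I = H(fixed axis) + sum of bin scores.  Returns {p: best score with
    exactly p nonempty bins} for p = 2..n_bins_max.
    """
    n = labels.size
    cuts = np.asarray(cut_positions)
    m = cuts.size  # includes 0 and n
    # prefix counts per fixed-axis bin at each cut position
    onehot = np.zeros((n + 1, q))
    np.add.at(onehot, np.arange(1, n + 1), np.eye(q)[labels])
    prefix = np.cumsum(onehot, axis=0)[cuts]  # m x q
    sizes = cuts.astype(float)

    def seg_scores(j: int) -> np.ndarray:
        # score of segment (cuts[i], cuts[j]) for all i < j, vectorized
        c = prefix[j] - prefix[:j]  # j x q
        s = sizes[j] - sizes[:j]
        with np.errstate(divide="ignore", invalid="ignore"):
            term_c = np.where(c > 0, c * np.log2(c / n), 0.0).sum(axis=1)
            term_s = np.where(s > 0, s * np.log2(s / n), 0.0)
        return (term_c - term_s) / n

    max_p = min(n_bins_max, m - 1)
    best: dict[int, float] = {}
    # f[j] = best score for prefix ending at cut j with current bin count
    f = np.full(m, -np.inf)
    for j in range(1, m):
        f[j] = seg_scores(j)[0]
    prev = f
    for t in range(2, max_p + 1):
        cur = np.full(m, -np.inf)
        for j in range(t, m):
            scores = seg_scores(j)
            cur[j] = np.max(prev[1:j] + scores[1:j]) if j > 1 else -np.inf
        best[t] = cur[m - 1]
        prev = cur
    return {p: v for p, v in best.items() if np.isfinite(v)}


def _boundaries(sorted_vals: np.ndarray) -> np.ndarray:
    """Admissible cut indices (0, value boundaries, n)."""
    n = sorted_vals.size
    inner = np.nonzero(sorted_vals[1:] != sorted_vals[:-1])[0] + 1
    return np.concatenate(([0], inner, [n]))


def _equipartition_cuts(boundaries: np.ndarray, n: int, q: int) -> np.ndarray:
    """q-bin cut set at value boundaries closest to equal point counts."""
    inner = boundaries[1:-1]
    if inner.size < q - 1:
        return boundaries
    targets = np.array([n * k / q for k in range(1, q)])
    chosen: list[int] = []
    avail = list(inner)
    for t in targets:
        if not avail:
            break
        idx = int(np.argmin(np.abs(np.array(avail) - t)))
        chosen.append(avail.pop(idx))
    return np.concatenate(([0], np.sort(chosen), [n]))


def _mic_oriented(
    outer: np.ndarray, inner: np.ndarray, B: int, max_enum: int
) -> float:
    """Max normalized MI with the outer axis enumerated, inner DP-optimized."""
    n = outer.size
    order_out = np.argsort(outer, kind="stable")
    out_sorted = outer[order_out]
    out_bounds = _boundaries(out_sorted)
    order_in = np.argsort(inner, kind="stable")
    in_sorted_vals = inner[order_in]
    in_cuts = _boundaries(in_sorted_vals)
    best = 0.0
    for q in range(2, B // 2 + 1):
        inner_bins_max = B // q
        if inner_bins_max < 2:
            break
        avail = out_bounds[1:-1]
        if avail.size < q - 1:
            break
        n_combos = math.comb(avail.size, q - 1)
        if n_combos <= max_enum:
            cut_sets = (
                np.concatenate(([0], np.array(c), [n]))
                for c in itertools.combinations(avail, q - 1)
            )
        else:
            cut_sets = iter([_equipartition_cuts(out_bounds, n, q)])
        for cuts in cut_sets:
            # outer-bin label of every point
            ranks = np.empty(n, dtype=int)
            ranks[order_out] = np.arange(n)
            labels_all = np.searchsorted(cuts[1:-1], ranks, side="right")
            h_outer = _entropy_bits(np.bincount(labels_all, minlength=q))
            labels_by_inner = labels_all[order_in]
            scores = _dp_max_partition_score(
                labels_by_inner, in_cuts, inner_bins_max, q
            )
            for p, score in scores.items():
                mi = h_outer + score
                norm = math.log2(min(p, q))
                if norm > 0:
                    best = max(best, mi / norm)
    return best


def mic(
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = 0.6,
    max_enum: int = 20000,
) -> float:
    """Maximal information coefficient of two variables.

    Maximizes grid-normalized mutual information I(p, q)/log2(min(p, q))
    over p-by-q grids with p * q <= B(n), B(n) = max(4, floor(n^alpha)).
    For each grid shape one axis's partition is enumerated exhaustively
    (when the number of candidate partitions is at most ``max_enum``;
    otherwise that axis is equipartitioned, the published approximation) and
    the other axis is optimized exactly by dynamic programming; both
    orientations are searched, making the result symmetric in (x, y) and
    exact whenever enumeration is feasible - in particular for small n and
    whenever one variable is binary.  Constant input gives 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    B = max(4, int(np.floor(n**alpha)))
    # A two-valued variable admits exactly one 2-bin partition, so with it
    # as the enumerated axis the DP already yields every achievable grid
    # shape exactly; enumerating the continuous axis would recompute the
    # same entries combinatorially slower (the common case: binary labels).
    if np.unique(y).size == 2 and np.unique(x).size > 2:
        best = _mic_oriented(y, x, B, max_enum)
    elif np.unique(x).size == 2 and np.unique(y).size > 2:
        best = _mic_oriented(x, y, B, max_enum)
    else:
        best = max(
            _mic_oriented(x, y, B, max_enum),
            _mic_oriented(y, x, B, max_enum),
        )
    return float(min(1.0, best))


def rank_features_mic(fm: FeatureMatrix) -> list[str]:
    """Feature names by descending MIC against the response label.

    Ties are broken by the fixed column order of the feature matrix.
    """
    labels = fm.y.astype(float)
    mics = np.array([mic(fm.X[c].to_numpy(), labels) for c in fm.X.columns])
    order = np.argsort(-mics, kind="stable")
    return [fm.X.columns[i] for i in order]


# ---------------------------------------------------------------------------
# Feature selection and nested cross-validation


def _make_svm(C: float = 1.0, gamma="auto", class_weight=None) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svc", SVC(kernel="rbf", C=C, gamma=gamma, class_weight=class_weight)),
        ]
    )


def _cv_splitter(k: int, group_aware: bool, seed: int):
    cls = StratifiedGroupKFold if group_aware else StratifiedKFold
    return cls(n_splits=k, shuffle=True, random_state=seed)


def _default_evaluator(
    X: pd.DataFrame,
    y: np.ndarray,
    subjects: np.ndarray,
    inner_k: int,
    group_aware: bool,
    seed: int,
    class_weight,
) -> Callable[[list[str]], float]:
    """CV-accuracy evaluator with a default RBF-SVM (C=1, gamma=1/p)."""

    def evaluate(features: list[str]) -> float:
        model = _make_svm(class_weight=class_weight)
        splitter = _cv_splitter(inner_k, group_aware, seed)
        accs = []
        Xf = X[features].to_numpy()
        for tr, te in splitter.split(Xf, y, groups=subjects):
            model.fit(Xf[tr], y[tr])
            accs.append(float(np.mean(model.predict(Xf[te]) == y[te])))
        return float(np.mean(accs))

    return evaluate


def sfs_select(
    fm: FeatureMatrix,
    ranked: Sequence[str],
    evaluator: Callable[[list[str]], float] | None = None,
    inner_k: int = 5,
    group_aware: bool = True,
    seed: int = 0,
    class_weight=None,
) -> list[str]:
    """Sequential forward search over the MIC-ranked feature list.

    Features are added greedily in ranked order; the prefix with maximal
    cross-validated accuracy is kept, with ties resolved in favor of fewer
    features.
    """
    if not ranked:
        raise ValueError("ranked feature list must be non-empty")
    if evaluator is None:
        evaluator = _default_evaluator(
            fm.X, fm.y, fm.subjects, inner_k, group_aware, seed, class_weight
        )
    best_features: list[str] = []
    best_score = -np.inf
    for k in range(1, len(ranked) + 1):
        prefix = list(ranked[:k])
        score = evaluator(prefix)
        if score > best_score:
            best_score = score
            best_features = prefix
    return best_features


def roc_auc(
    scores: Sequence[float], labels: Sequence[bool]
) -> tuple[np.ndarray, float]:
    """ROC points and AUC from decision scores.

    AUC is the rank statistic (probability a positive outscores a negative,
    ties counted half); ROC points are (fpr, tpr) at every threshold.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    return np.column_stack([fpr, tpr]), auc


@dataclass
class PredictionReport:
    """Nested-CV performance of the response classifier."""

    fold_acc: list[float]
    fold_sn: list[float]
    fold_sp: list[float]
    fold_auc: list[float]
    roc_points: np.ndarray  # pooled (fpr, tpr)
    pooled_auc: float
    selected_features: list[list[str]]
    best_params: list[dict]
    seed: int
    group_aware: bool

    @property
    def acc_mean(self) -> float:
        return float(np.mean(self.fold_acc))

    @property
    def acc_std(self) -> float:
        return float(np.std(self.fold_acc))

    @property
    def sn_mean(self) -> float:
        return float(np.mean(self.fold_sn))

    @property
    def sn_std(self) -> float:
        return float(np.std(self.fold_sn))

    @property
    def sp_mean(self) -> float:
        return float(np.mean(self.fold_sp))

    @property
    def sp_std(self) -> float:
        return float(np.std(self.fold_sp))

    @property
    def auc_mean(self) -> float:
        finite = [a for a in self.fold_auc if np.isfinite(a)]
        return float(np.mean(finite)) if finite else float("nan")

    @property
    def auc_std(self) -> float:
        finite = [a for a in self.fold_auc if np.isfinite(a)]
        return float(np.std(finite)) if finite else float("nan")

    def to_dict(self) -> dict:
        return {
            "acc_mean": self.acc_mean,
            "acc_std": self.acc_std,
            "sn_mean": self.sn_mean,
            "sn_std": self.sn_std,
            "sp_mean": self.sp_mean,
            "sp_std": self.sp_std,
            "auc_mean": self.auc_mean,
            "auc_std": self.auc_std,
            "pooled_auc": self.pooled_auc,
            "fold_acc": self.fold_acc,
            "fold_sn": self.fold_sn,
            "fold_sp": self.fold_sp,
            "fold_auc": self.fold_auc,
            "selected_features": self.selected_features,
            "best_params": self.best_params,
            "seed": self.seed,
            "group_aware": self.group_aware,
        }


def nested_cv_svm(
    fm: FeatureMatrix,
    outer_k: int = 5,
    inner_k: int = 5,
    seed: int = 0,
    group_aware: bool = True,
    paper_mode: bool = False,
    param_grid: dict | None = None,
    run_sfs: bool = True,
) -> PredictionReport:
    """Nested cross-validated RBF-SVM prediction of treatment response.

    Outer folds estimate ACC, SN and SP (positive class = responder); on
    each outer training set the features are MIC-ranked, SFS-selected and
    the SVM hyperparameters (C, gamma) tuned by an inner grid-search CV.
    Standardization is fitted on training folds only.  ROC/AUC are reported
    both pooled over outer-fold decision values and as per-fold mean +/- SD.

    ``paper_mode=True`` switches to sample-level splits and disables the
    inverse-frequency class weighting (leakage-prone but replicates the
    augmented-sample analysis); the default is group-aware subject-level
    splitting with balanced class weights.
    """
    if paper_mode:
        group_aware = False
    if np.unique(fm.y).size < 2:
        raise ValueError("need samples from both classes")
    counts = np.bincount(fm.y.astype(int))
    if counts.min() < 2:
        raise ValueError(
            "fewer than 2 samples in one class; collect more data"
        )
    class_weight = None if paper_mode else "balanced"
    grid = dict(param_grid or DEFAULT_PARAM_GRID)
    outer = _cv_splitter(outer_k, group_aware, seed)
    X_all = fm.X
    y_all = fm.y
    subj = fm.subjects

    fold_acc, fold_sn, fold_sp, fold_auc = [], [], [], []
    selected, params = [], []
    pooled_scores = np.empty(len(y_all))
    pooled_mask = np.zeros(len(y_all), dtype=bool)
    for tr, te in outer.split(X_all, y_all, groups=subj):
        if np.unique(y_all[tr]).size < 2 or np.unique(y_all[te]).size < 2:
            raise ValueError(
                "an outer fold contains a single class; use stratified "
                "group-aware folds or collect more data"
            )
        fm_train = FeatureMatrix(
            X=X_all.iloc[tr].reset_index(drop=True),
            y=y_all[tr],
            subjects=subj[tr],
        )
        ranked = rank_features_mic(fm_train)
        if run_sfs:
            feats = sfs_select(
                fm_train,
                ranked,
                inner_k=inner_k,
                group_aware=group_aware,
                seed=seed,
                class_weight=class_weight,
            )
        else:
            feats = ranked
        inner = _cv_splitter(inner_k, group_aware, seed)
        search = GridSearchCV(
            _make_svm(class_weight=class_weight),
            grid,
            cv=list(
                inner.split(X_all.iloc[tr][feats], y_all[tr], groups=subj[tr])
            ),
            scoring="accuracy",
            n_jobs=1,
        )
        search.fit(X_all.iloc[tr][feats], y_all[tr])
        model = search.best_estimator_
        X_te = X_all.iloc[te][feats]
        pred = model.predict(X_te)
        scores = model.decision_function(X_te)
        y_te = y_all[te]
        fold_acc.append(float(np.mean(pred == y_te)))
        fold_sn.append(float(np.mean(pred[y_te])))
        fold_sp.append(float(np.mean(~pred[~y_te])))
        fold_auc.append(float(roc_auc_score(y_te, scores)))
        pooled_scores[te] = scores
        pooled_mask[te] = True
        selected.append(list(feats))
        params.append(
            {k.removeprefix("svc__"): v for k, v in search.best_params_.items()}
        )
    roc_points, pooled_auc = roc_auc(
        pooled_scores[pooled_mask], y_all[pooled_mask]
    )
    return PredictionReport(
        fold_acc=fold_acc,
        fold_sn=fold_sn,
        fold_sp=fold_sp,
        fold_auc=fold_auc,
        roc_points=roc_points,
        pooled_auc=pooled_auc,
        selected_features=selected,
        best_params=params,
        seed=seed,
        group_aware=group_aware,
    )
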