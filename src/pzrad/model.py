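"""Feature selection, classification and validation.

The classifier chain per training fold is: min-max normalization (bounds
learned on the fold's training rows), correlation-based feature selection
(CFS), Bayesian optimization of the RBF-SVM hyperparameters C and gamma on
[1e-4, 1e3] by cross-validated AUROC, a final soft-margin RBF-SVM fit, and
Platt sigmoid calibration of its decision values.  Validation is
leave-one-patient-out (LOPO): no held-out voxel ever influences any
training-side statistic.

CFS scores a subset S of k features by

    merit(S) = k * mean|r_cf| / sqrt(k + k (k-1) * mean|r_ff|)

where r_cf are feature-class (point-biserial) and r_ff pairwise
feature-feature Pearson correlations; a best-first forward search grows the
subset and stops after a fixed number of consecutive non-improving
expansions.

The kernel is the standard Gaussian K(x, x') = exp(-gamma ||x - x'||^2).
Class imbalance (noncancer voxels greatly outnumber cancer voxels) is
handled with inverse-frequency class weights in the SVM loss.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.svm import SVC

from .config import RunConfig
from .texture_features import NormalizationState, feature_columns, minmax_fit_apply
from .volume_io import GridMismatchError, ROIMask


class LabelingError(ValueError):
    """Labels do not contain both classes (or masks overlap)."""


class CalibrationError(ValueError):
    """Platt calibration needs both classes among the labels."""


class StratificationError(ValueError):
    """Too few minority-class rows for the requested fold count."""


# ---------------------------------------------------------------------------
# Correlation-based feature selection
# ---------------------------------------------------------------------------

@dataclass
class CfsResult:
    selected: list[str]
    merit: float
    search_trace: list[tuple[int, float]] = field(default_factory=list)


def cfs_merit(k: int, mean_feature_class_corr: float,
              mean_feature_feature_corr: float) -> float:
    """Subset merit k*rcf / sqrt(k + k(k-1)*rff) on absolute correlations."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rcf = abs(mean_feature_class_corr)
    rff = abs(mean_feature_feature_corr)
    if rcf > 1 or rff > 1:
        raise ValueError("correlations must lie in [-1, 1]")
    denom = k + k * (k - 1) * rff
    if denom <= 0:
        raise ValueError("degenerate subset: non-positive merit denominator")
    return k * rcf / np.sqrt(denom)


def _correlations(df: pd.DataFrame) -> tuple[list[str], np.ndarray, np.ndarray]:
    cols = feature_columns(df)
    X = df[cols].to_numpy(dtype=np.float64)
    y = df["label"].to_numpy(dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        full = np.corrcoef(np.column_stack([X, y]), rowvar=False)
    full = np.nan_to_num(full, nan=0.0)  # constant columns correlate with nothing
    return cols, np.abs(full[:-1, :-1]), np.abs(full[:-1, -1])


def cfs_search(df: pd.DataFrame, patience: int = 5) -> CfsResult:
    """Best-first forward CFS; deterministic given column order."""
    if df["label"].nunique() < 2:
        raise LabelingError("both classes required for feature selection")
    cols, rff, rcf = _correlations(df)
    if len(cols) < 2:
        raise ValueError("need at least 2 features")

    selected: list[int] = []
    best_subset: list[int] = []
    best_merit = -np.inf
    trace: list[tuple[int, float]] = []
    stall = 0
    remaining = list(range(len(cols)))
    while remaining and stall <= patience:
        cand_merit = np.full(len(remaining), -np.inf)
        for pos, j in enumerate(remaining):
            subset = selected + [j]
            k = len(subset)
            m_cf = rcf[subset].mean()
            if k == 1:
                m_ff = 0.0
            else:
                sub = rff[np.ix_(subset, subset)]
                m_ff = sub[np.triu_indices(k, 1)].mean()
            cand_merit[pos] = cfs_merit(k, m_cf, m_ff)
        pick = int(np.argmax(cand_merit))
        merit = float(cand_merit[pick])
        selected.append(remaining.pop(pick))
        trace.append((len(selected), merit))
        if merit > best_merit + 1e-12:
            best_merit = merit
            best_subset = list(selected)
            stall = 0
        else:
            stall += 1
    if not best_subset:  # all-noise degenerate case: keep the single best
        best_subset = [int(np.argmax(rcf))]
        best_merit = float(rcf[best_subset[0]])
    return CfsResult([cols[j] for j in best_subset], best_merit, trace)


# ---------------------------------------------------------------------------
# RBF-SVM and Bayesian hyperparameter optimization
# ---------------------------------------------------------------------------

@dataclass
class SvmHyperparams:
    C: float
    gamma: float
    bounds: tuple[float, float] = (1e-4, 1e3)

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        for name, v in (("C", self.C), ("gamma", self.gamma)):
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside bounds [{lo}, {hi}]")


def train_rbf_svm(df: pd.DataFrame, hp: SvmHyperparams) -> SVC:
    """Fit a class-weighted Gaussian-kernel SVM on the normalized matrix."""
    y = df["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise LabelingError("both classes required to train the SVM")
    X = df[feature_columns(df)].to_numpy(dtype=np.float64)
    svc = SVC(C=hp.C, gamma=hp.gamma, kernel="rbf", class_weight="balanced")
    svc.fit(X, y)
    return svc


def _cv_splits(y: np.ndarray, groups: np.ndarray | None, folds: int, seed: int):
    counts = np.unique(y, return_counts=True)[1]
    if folds > counts.min():
        raise StratificationError(
            f"{folds} folds exceed the minority class size ({counts.min()})"
        )
    if groups is not None and len(np.unique(groups)) >= folds:
        cv = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
        return list(cv.split(np.zeros(len(y)), y, groups))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(cv.split(np.zeros(len(y)), y))


def _expected_improvement(mu: np.ndarray, sd: np.ndarray, best: float,
                          xi: float = 0.01) -> np.ndarray:
    sd = np.maximum(sd, 1e-12)
    z = (mu - best - xi) / sd
    return (mu - best - xi) * sstats.norm.cdf(z) + sd * sstats.norm.pdf(z)


def bayes_optimize(
    df: pd.DataFrame,
    folds: int = 10,
    iterations: int = 30,
    seed: int = 0,
    bounds: tuple[float, float] = (1e-4, 1e3),
    n_initial: int = 8,
) -> SvmHyperparams:
    """Gaussian-process expected-improvement search for (C, gamma).

    The objective is the mean cross-validated AUROC of the class-weighted
    RBF-SVM on the (already normalized, feature-selected) training matrix;
    folds are stratified by class and grouped by patient when enough
    patients are present.  The search works in log10 space over both
    hyperparameters with inclusive bounds, spends ``n_initial`` seeded
    space-filling evaluations and the rest on EI maximization, and returns
    the incumbent after ``iterations`` total evaluations.
    """
    rng = np.random.default_rng(seed)
    y = df["label"].to_numpy()
    groups = df["patient_id"].to_numpy() if "patient_id" in df else None
    X = df[feature_columns(df)].to_numpy(dtype=np.float64)
    splits = _cv_splits(y, groups, folds, seed)
    lo, hi = np.log10(bounds[0]), np.log10(bounds[1])

    def objective(point: np.ndarray) -> tuple[float, float]:
        """(mean CV AUROC, mean CV balanced accuracy of the sign rule)."""
        C, gamma = 10.0 ** point[0], 10.0 ** point[1]
        aucs, baccs = [], []
        for tr, va in splits:
            if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
                continue
            svc = SVC(C=C, gamma=gamma, kernel="rbf", class_weight="balanced")
            svc.fit(X[tr], y[tr])
            f = svc.decision_function(X[va])
            pos = y[va] == 1
            aucs.append(roc_auc_score(pos, f))
            baccs.append(((f[pos] > 0).mean() + (f[~pos] <= 0).mean()) / 2.0)
        if not aucs:
            return 0.5, 0.5
        return float(np.mean(aucs)), float(np.mean(baccs))

    # seeded space-filling initial design (jittered grid)
    n_initial = min(n_initial, iterations)
    g = int(np.ceil(np.sqrt(n_initial)))
    centers = np.stack(
        np.meshgrid(np.linspace(lo, hi, g + 2)[1:-1],
                    np.linspace(lo, hi, g + 2)[1:-1]),
        axis=-1,
    ).reshape(-1, 2)
    rng.shuffle(centers)
    init = centers[:n_initial] + rng.normal(0, 0.05 * (hi - lo), (n_initial, 2))
    init = np.clip(init, lo, hi)

    points = [p for p in init]
    evals = [objective(p) for p in points]
    scores = [e[0] for e in evals]  # AUROC drives the GP / EI

    kernel = ConstantKernel(1.0) * Matern(length_scale=(hi - lo) / 4, nu=2.5) \
        + WhiteKernel(noise_level=1e-4, noise_level_bounds=(1e-8, 1e-1))
    while len(points) < iterations:
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                      n_restarts_optimizer=1,
                                      random_state=int(rng.integers(2**31)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(np.array(points), np.array(scores))
            cand = rng.uniform(lo, hi, size=(512, 2))
            mu, sd = gp.predict(cand, return_std=True)
        ei = _expected_improvement(mu, sd, max(scores))
        nxt = cand[int(np.argmax(ei))]
        points.append(nxt)
        evals.append(objective(nxt))
        scores.append(evals[-1][0])
    # incumbent: best AUROC, quantized below its CV sampling noise so that
    # statistical ties (ubiquitous on separable data) are resolved by the
    # balanced accuracy of the sign rule and the operating point stays sound
    ranked = sorted(
        range(len(points)),
        key=lambda i: (round(evals[i][0] / 0.005), round(evals[i][1], 6)),
    )
    best = points[ranked[-1]]
    return SvmHyperparams(10.0 ** best[0], 10.0 ** best[1], bounds)


# ---------------------------------------------------------------------------
# Platt calibration
# ---------------------------------------------------------------------------

def platt_calibrate(decision_values, labels, max_iter: int = 100,
                    tol: float = 1e-10) -> tuple[float, float]:
    """Fit P(y=1|f) = 1 / (1 + exp(A f + B)) by regularized ML.

    Uses Platt's smoothed targets t+ = (N+ + 1)/(N+ + 2), t- = 1/(N- + 2)
    and a Newton iteration with backtracking on the negative log-likelihood
    (the model-trust approach).  With positives scoring higher than
    negatives the fitted A is negative, making the sigmoid increase in f.
    """
    f = np.asarray(decision_values, dtype=np.float64)
    y = np.asarray(labels)
    n_pos = int((y > 0).sum())
    n_neg = int((y <= 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise CalibrationError("both classes required for calibration")
    hi = (n_pos + 1.0) / (n_pos + 2.0)
    lo = 1.0 / (n_neg + 2.0)
    t = np.where(y > 0, hi, lo)

    def nll(a: float, b: float) -> float:
        fApB = f * a + b
        # numerically safe log(1 + exp(.)) split by sign
        pos = fApB >= 0
        val = np.empty_like(fApB)
        val[pos] = t[pos] * fApB[pos] + np.log1p(np.exp(-fApB[pos]))
        val[~pos] = (t[~pos] - 1.0) * fApB[~pos] + np.log1p(np.exp(fApB[~pos]))
        return float(val.sum())

    A, B = 0.0, float(np.log((n_neg + 1.0) / (n_pos + 1.0)))
    fval = nll(A, B)
    sigma = 1e-12  # Hessian ridge
    for _ in range(max_iter):
        fApB = f * A + B
        pos = fApB >= 0
        p = np.empty_like(fApB)
        q = np.empty_like(fApB)
        p[pos] = np.exp(-fApB[pos]) / (1.0 + np.exp(-fApB[pos]))
        q[pos] = 1.0 / (1.0 + np.exp(-fApB[pos]))
        p[~pos] = 1.0 / (1.0 + np.exp(fApB[~pos]))
        q[~pos] = np.exp(fApB[~pos]) / (1.0 + np.exp(fApB[~pos]))
        d1 = t - p
        d2 = p * q
        g1 = float((f * d1).sum())
        g2 = float(d1.sum())
        if abs(g1) < tol and abs(g2) < tol:
            break
        h11 = float((f * f * d2).sum()) + sigma
        h22 = float(d2.sum()) + sigma
        h21 = float((f * d2).sum())
        det = h11 * h22 - h21 * h21
        dA = -(h22 * g1 - h21 * g2) / det
        dB = -(-h21 * g1 + h11 * g2) / det
        gd = g1 * dA + g2 * dB
        step = 1.0
        while step >= 1e-10:
            newA, newB = A + step * dA, B + step * dB
            newf = nll(newA, newB)
            if newf < fval + 1e-4 * step * gd:
                A, B, fval = newA, newB, newf
                break
            step /= 2.0
        else:
            break
    return float(A), float(B)


def platt_probability(f, A: float, B: float) -> np.ndarray:
    """Calibrated P(y=1|f) for decision values ``f``, computed stably."""
    fApB = np.asarray(f, dtype=np.float64) * A + B
    out = np.empty_like(fApB)
    pos = fApB >= 0
    out[pos] = np.exp(-fApB[pos]) / (1.0 + np.exp(-fApB[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(fApB[~pos]))
    return out


# ---------------------------------------------------------------------------
# Metrics and mask agreement
# ---------------------------------------------------------------------------

def compute_metrics(scores, labels, threshold: float = 0.0) -> dict[str, float]:
    """AUROC (tie-aware Mann-Whitney) plus thresholded binary metrics.

    The binary label is ``score > threshold``; with decision values and the
    default threshold 0 this is the SVM's sign rule.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    pos = y > 0
    if pos.all() or (~pos).all():
        raise LabelingError("both classes required for metrics")
    auroc = float(roc_auc_score(pos, scores))
    pred = scores > threshold
    tp = int((pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    fp = int((pred & ~pos).sum())
    fn = int((~pred & pos).sum())
    return {
        "auroc": auroc,
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "accuracy": (tp + tn) / len(y),
    }


def dice(a: ROIMask, b: ROIMask) -> float:
    """Dice similarity 2|A n B| / (|A| + |B|); 1 when both masks are empty."""
    if a.shape != b.shape:
        raise GridMismatchError("masks must share a grid")
    na, nb = a.voxel_count, b.voxel_count
    if na + nb == 0:
        return 1.0
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)


def curate_reference_labels(
    rater1: list[ROIMask],
    rater2: list[ROIMask],
    pz: ROIMask,
    min_volume_cc: float = 0.25,
) -> tuple[ROIMask, ROIMask, list[dict]]:
    """Consensus cancer labels from two raters' lesion masks.

    Lesions are matched across raters by spatial overlap; the cancer mask is
    the union of voxelwise intersections over matched pairs.  Lesions seen
    by only one rater, and pairs with zero overlap, are excluded and
    reported (with their volumes; ``min_volume_cc`` annotates which
    exclusions are sub-threshold small).  Noncancer is the remainder of the
    peripheral zone.
    """
    for m in rater1 + rater2:
        m.check_companion(pz)
    cancer = np.zeros(pz.shape, dtype=bool)
    exclusions: list[dict] = []
    matched2: set[int] = set()
    for i, r1 in enumerate(rater1):
        overlaps = [
            (int((r1.data & r2.data).sum()), j)
            for j, r2 in enumerate(rater2)
            if j not in matched2
        ]
        best = max(overlaps, default=(0, -1))
        if best[0] > 0:
            j = best[1]
            matched2.add(j)
            cancer |= r1.data & rater2[j].data
        else:
            exclusions.append({
                "rater": 1, "lesion": i, "reason": "no_overlap",
                "volume_cc": r1.volume_cc,
                "sub_threshold": r1.volume_cc < min_volume_cc,
            })
    for j, r2 in enumerate(rater2):
        if j not in matched2:
            exclusions.append({
                "rater": 2, "lesion": j, "reason": "single_rater",
                "volume_cc": r2.volume_cc,
                "sub_threshold": r2.volume_cc < min_volume_cc,
            })
    outside = cancer & ~pz.data
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} consensus cancer voxels outside the "
            "peripheral zone were clipped", stacklevel=2
        )
        cancer &= pz.data
    noncancer = pz.data & ~cancer
    return (
        ROIMask(cancer, pz.spacing, "cancer"),
        ROIMask(noncancer, pz.spacing, "noncancer"),
        exclusions,
    )


# ---------------------------------------------------------------------------
# Trained model and leave-one-patient-out evaluation
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """One fold's fitted chain: normalization + CFS + RBF-SVM + Platt."""

    svc: SVC
    hyperparams: SvmHyperparams
    platt: tuple[float, float]
    selection: CfsResult
    normalization: NormalizationState
    train_patient_ids: tuple[str, ...]

    def decision_values(self, df: pd.DataFrame) -> np.ndarray:
        """Decision function on raw (unnormalized) feature rows."""
        norm, _ = minmax_fit_apply(df, self.normalization)
        X = norm[self.selection.selected].to_numpy(dtype=np.float64)
        return self.svc.decision_function(X)

    def probabilities(self, df: pd.DataFrame) -> np.ndarray:
        A, B = self.platt
        return platt_probability(self.decision_values(df), A, B)


@dataclass
class EvalReport:
    per_fold: list[dict]
    aggregate: dict[str, dict[str, float]]
    config: dict

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"per_fold": self.per_fold, "aggregate": self.aggregate,
                 "config": self.config},
                fh, indent=2, default=float,
            )


def subsample_matrix(df: pd.DataFrame, max_rows: int,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Seeded class-proportional subsample keeping at least 25 minority rows."""
    if max_rows <= 0 or len(df) <= max_rows:
        return df
    parts = []
    frac = max_rows / len(df)
    for _, grp in df.groupby("label", sort=True):
        n = max(min(len(grp), 25), int(round(len(grp) * frac)))
        idx = rng.choice(len(grp), size=min(n, len(grp)), replace=False)
        parts.append(grp.iloc[np.sort(idx)])
    return pd.concat(parts, ignore_index=True)


def train_fold(train_df: pd.DataFrame, config: RunConfig, seed: int) -> TrainedModel:
    """Fit the full per-fold chain on training rows only."""
    norm_df, state = minmax_fit_apply(train_df)
    selection = cfs_search(norm_df, patience=config.cfs_patience)
    sel_cols = list(selection.selected)
    sub = norm_df[["patient_id", "label"] + sel_cols]
    hp = bayes_optimize(
        sub, folds=config.bo_folds, iterations=config.bo_iterations,
        seed=seed, bounds=config.bo_bounds,
    )
    svc = train_rbf_svm(sub.drop(columns=["patient_id"]), hp)
    f_train = svc.decision_function(sub[sel_cols].to_numpy(dtype=np.float64))
    A, B = platt_calibrate(f_train, sub["label"].to_numpy())
    return TrainedModel(
        svc, hp, (A, B), selection, state,
        tuple(sorted(train_df["patient_id"].unique())),
    )


def _fold_seed(master: int, index: int) -> int:
    return int(np.random.SeedSequence([master, index]).generate_state(1)[0] % (2**31))


def lopo_run(
    cohort,
    config: RunConfig,
    matrices: dict[str, pd.DataFrame] | None = None,
) -> tuple[EvalReport, dict[str, TrainedModel]]:
    """Leave-one-patient-out evaluation of the full chain.

    ``cohort`` is a list of PatientCase; per-patient feature matrices are
    extracted once (or passed precomputed via ``matrices``).  For each fold
    the chain is fit on the remaining patients only and evaluated on the
    held-out patient's voxels; folds whose training side lacks a class are
    skipped with a warning.  Returns the report plus the per-fold models
    keyed by held-out patient.
    """
    if matrices is None:
        from .pipeline import extract_cohort_matrices  # local to avoid a cycle
        matrices = extract_cohort_matrices(cohort, config)
    ids = [c.patient_id for c in cohort]
    if len(ids) < 3:
        raise ValueError("LOPO needs at least 3 patients")
    rng = np.random.default_rng(config.seed)
    per_fold: list[dict] = []
    models: dict[str, TrainedModel] = {}
    for i, held_out in enumerate(ids):
        train_df = pd.concat(
            [matrices[p] for p in ids if p != held_out], ignore_index=True
        )
        if train_df["label"].nunique() < 2:
            warnings.warn(f"fold {held_out}: single-class training side, skipped")
            continue
        train_df = subsample_matrix(train_df, config.max_train_voxels, rng)
        model = train_fold(train_df, config, _fold_seed(config.seed, i))
        assert held_out not in model.train_patient_ids
        models[held_out] = model

        test_df = matrices[held_out]
        record: dict = {
            "patient_id": held_out,
            "n_train": int(len(train_df)),
            "n_test": int(len(test_df)),
            "train_patient_ids": list(model.train_patient_ids),
            "C": model.hyperparams.C,
            "gamma": model.hyperparams.gamma,
            "selected_features": list(model.selection.selected),
            "merit": model.selection.merit,
        }
        if test_df["label"].nunique() < 2:
            warnings.warn(f"fold {held_out}: single-class test patient")
        else:
            f = model.decision_values(test_df)
            y = test_df["label"].to_numpy()
            record.update(compute_metrics(f, y))
            pred = f > 0
            pos = y > 0
            tp = int((pred & pos).sum())
            record["dice"] = (
                2.0 * tp / (pred.sum() + pos.sum()) if (pred.sum() + pos.sum()) else 1.0
            )
        per_fold.append(record)

    metric_names = ("auroc", "sensitivity", "specificity", "accuracy", "dice")
    aggregate = {}
    for m in metric_names:
        vals = [r[m] for r in per_fold if m in r]
        if vals:
            aggregate[m] = {
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            }
    report = EvalReport(per_fold, aggregate, config.to_dict())
    return report, models


def permutation_control(
    matrices: dict[str, pd.DataFrame],
    config: RunConfig,
    n_permutations: int = 20,
    seed: int = 0,
    max_voxels: int = 400,
) -> np.ndarray:
    """Held-out AUROC under voxel-label permutation (null distribution).

    For each permutation the pooled matrix (subsampled for speed) gets its
    labels shuffled, one patient is held out, and the full per-fold chain is
    refit on the rest; the held-out AUROC of a sound, leakage-free pipeline
    is then centred on 0.5.
    """
    rng = np.random.default_rng(seed)
    # per-patient subsample with a guaranteed minority quota, so the
    # held-out side always has enough of both classes for a stable AUROC
    per_patient = max(50, max_voxels // max(len(matrices), 1))
    pooled = pd.concat(
        [subsample_matrix(df, per_patient, rng) for df in matrices.values()],
        ignore_index=True,
    )
    ids = sorted(pooled["patient_id"].unique())
    aucs = []
    for _ in range(n_permutations):
        perm = pooled.copy()
        perm["label"] = rng.permutation(perm["label"].to_numpy())
        held_out = ids[int(rng.integers(len(ids)))]
        train_df = perm[perm["patient_id"] != held_out]
        test_df = perm[perm["patient_id"] == held_out]
        if train_df["label"].nunique() < 2 or test_df["label"].nunique() < 2:
            continue
        model = train_fold(train_df, config, int(rng.integers(2**31)))
        f = model.decision_values(test_df)
        aucs.append(roc_auc_score(test_df["label"].to_numpy() > 0, f))
    return np.asarray(aucs)
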