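"""Elastic-net prediction of tumor phenotypes from segment-level CNA features.

The protocol: the cohort is split 70/30 into training and test sets,
stratified on clinical covariates.  On the training set a tuning grid is
built from mixing parameters alpha in {0.1, ..., 1.0} crossed with a
100-value lambda path per alpha (lambda_max from the closed form at the
null model, lambda_min = ratio * lambda_max, log-spaced).  The grid is
scored by Monte-Carlo cross-validation: 200 random 75/25 sub-splits of the
training set, classification accuracy at probability cutoff 0.5 (mean
squared error for the continuous variant).  The best (alpha, lambda) —
ties resolved toward larger lambda, then larger alpha — is refit on the
full training set, and evaluated by ROC AUC on designated test sets.
Phenotypes with AUC above 0.75 on all test sets count as highly
predictable; a label-permutation null calibrates that threshold.

Penalized objective (glmnet parameterization)::

    (1/n) * loss(beta) + lambda * [ alpha*||beta||_1 + (1-alpha)/2*||beta||_2^2 ]

with logistic loss for binary phenotypes and squared error for continuous
ones.  Features are standardized internally for fitting; coefficients are
reported on the original scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, LogisticRegression, enet_path
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import ValidationError
from .io import ClinicalTable, GeneCoords, SegmentDefinitionTable

logger = logging.getLogger(__name__)

FULL_ALPHAS = tuple(round(0.1 * k, 1) for k in range(1, 11))
DEFAULT_N_LAMBDA = 100
DEFAULT_N_ROUNDS = 200
DEFAULT_CV_TRAIN_FRAC = 0.75
DEFAULT_LAMBDA_MIN_RATIO = 1e-3
AUC_THRESHOLD = 0.75


# ---------------------------------------------------------------------------
# Stratified splitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitSpec:
    """A reproducible stratified train/test partition of a cohort."""

    train: list[str]
    test: list[str]
    strata_vars: tuple[str, ...]
    seed: int
    strata: pd.Series | None = None


def _stratum_keys(
    clinical: ClinicalTable, strata_vars: Sequence[str], max_levels: int = 10
) -> pd.Series:
    df = clinical.df
    missing = [v for v in strata_vars if v not in df.columns]
    if missing:
        raise ValidationError(f"strata variable(s) {missing} not in clinical table")
    parts = []
    for var in strata_vars:
        col = df[var]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > max_levels:
            med = col.median()
            binned = pd.Series(
                np.where(col.isna(), "missing", np.where(col <= med, "le_med", "gt_med")),
                index=col.index,
            )
            parts.append(binned)
        else:
            parts.append(col.astype(str).fillna("missing").where(col.notna(), "missing"))
    if not parts:
        return pd.Series("all", index=df.index)
    key = parts[0]
    for p in parts[1:]:
        key = key + "|" + p
    return key


def stratified_split(
    clinical: ClinicalTable,
    strata_vars: Sequence[str] = (),
    train_frac: float = 0.7,
    seed: int = 0,
) -> SplitSpec:
    """70/30-style split, proportional within each cross-classified stratum.

    Continuous strata (e.g. overall survival) are binned at their median;
    strata with fewer than 2 samples are merged into one pooled stratum.
    """
    n = len(clinical.df)
    if n < 20:
        raise ValidationError(f"cohort of {n} samples is too small to split (need >=20)")
    key = _stratum_keys(clinical, strata_vars)
    sizes = key.value_counts()
    small = set(sizes.index[sizes < 2])
    if small:
        key = key.where(~key.isin(small), "__pooled__")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for stratum in sorted(key.unique()):
        ids = sorted(key.index[key == stratum])
        perm = rng.permutation(len(ids))
        n_train = int(round(train_frac * len(ids)))
        picked = {ids[i] for i in perm[:n_train]}
        train.extend(s for s in ids if s in picked)
        test.extend(s for s in ids if s not in picked)
    return SplitSpec(
        train=sorted(train),
        test=sorted(test),
        strata_vars=tuple(strata_vars),
        seed=seed,
        strata=key,
    )


# ---------------------------------------------------------------------------
# Grid construction
# ---------------------------------------------------------------------------


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd, mean, sd


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest lambda at which all coefficients are zero (null-model gradient).

    For both families the null-model residual is y - ybar, so with
    standardized columns lambda_max = max_j |x_j^T (y - ybar)| / (n * alpha).
    """
    Xs, _, _ = _standardize(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    r = y - y.mean()
    n = len(y)
    return float(np.abs(Xs.T @ r).max() / (n * alpha))


def lambda_grid(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray | pd.Series,
    alphas: Sequence[float] = FULL_ALPHAS,
    n_lambda: int = DEFAULT_N_LAMBDA,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
) -> dict[float, np.ndarray]:
    """Per-alpha descending log-spaced lambda sequences from the training set."""
    y = np.asarray(y, dtype=float)
    if np.all(y == y[0]):
        raise ValidationError("constant outcome: lambda grid undefined")
    X = np.asarray(X, dtype=float)
    grid = {}
    for alpha in alphas:
        lmax = lambda_max(X, y, alpha)
        if lmax <= 0:
            lmax = 1e-4
        grid[float(alpha)] = np.geomspace(lmax, lambda_min_ratio * lmax, n_lambda)
    return grid


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class ElasticNetModel:
    """A fitted penalized linear model over named segment features."""

    alpha: float
    lam: float
    intercept: float
    coef: pd.Series  # original-scale coefficients, indexed by feature id
    family: str  # "binomial" | "gaussian"
    tuning: dict = field(default_factory=dict)

    @property
    def selected(self) -> pd.Series:
        return self.coef[self.coef != 0]

    def decision(self, X: pd.DataFrame) -> np.ndarray:
        Xa = X[self.coef.index].to_numpy(dtype=float)
        return self.intercept + Xa @ self.coef.to_numpy()

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        if self.family != "binomial":
            raise ValidationError("predict_proba is only defined for binomial models")
        return 1.0 / (1.0 + np.exp(-self.decision(X)))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if self.family == "binomial":
            return (self.predict_proba(X) > 0.5).astype(int)
        return self.decision(X)

    def to_report(self) -> dict:
        return {
            "family": self.family,
            "alpha": self.alpha,
            "lambda": self.lam,
            "intercept": self.intercept,
            "coefficients": {k: float(v) for k, v in self.coef.items() if v != 0},
            "n_features": int(len(self.coef)),
            "n_selected": int((self.coef != 0).sum()),
            "tuning": self.tuning,
        }


def _binomial_path(
    Xs: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lams: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Warm-started logistic elastic-net fits along a descending lambda path."""
    n = len(y)
    clf = LogisticRegression(
        solver="saga",
        l1_ratio=alpha,
        warm_start=True,
        fit_intercept=True,
        tol=tol,
        max_iter=max_iter,
        C=1.0,
        random_state=0,
    )
    coefs = np.empty((len(lams), Xs.shape[1]))
    intercepts = np.empty(len(lams))
    # CV path scans run at a loose tolerance by design; silence the
    # resulting convergence chatter from the solver.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for i, lam in enumerate(lams):
            clf.C = 1.0 / (n * lam)
            clf.fit(Xs, y)
            coefs[i] = clf.coef_[0]
            intercepts[i] = clf.intercept_[0]
    return coefs, intercepts


def _gaussian_path(
    Xs: np.ndarray, y: np.ndarray, alpha: float, lams: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray]:
    yc = y - y.mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coefs, _ = enet_path(
            Xs, yc, l1_ratio=alpha, alphas=lams, tol=tol, max_iter=max_iter
        )
    intercepts = np.full(len(lams), y.mean())
    return coefs.T, intercepts


def fit(
    X: pd.DataFrame,
    y: Sequence[int] | np.ndarray | pd.Series,
    alpha: float,
    lam: float,
    family: str = "binomial",
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> ElasticNetModel:
    """Fit one elastic-net model at fixed (alpha, lambda).

    Columns are standardized internally; returned coefficients and intercept
    are on the original feature scale.
    """
    features = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    Xs, mean, sd = _standardize(Xv)
    n = len(yv)
    if family == "binomial":
        if set(np.unique(yv)) - {0.0, 1.0}:
            raise ValidationError("binomial fit requires y in {0, 1}")
        clf = LogisticRegression(
            solver="saga",
            l1_ratio=alpha,
            C=1.0 / (n * lam),
            fit_intercept=True,
            tol=tol,
            max_iter=max_iter,
            random_state=0,
        )
        clf.fit(Xs, yv)
        if clf.n_iter_[0] >= max_iter:
            raise ValidationError(
                f"elastic-net fit did not converge (alpha={alpha}, lambda={lam}, "
                f"max_iter={max_iter})"
            )
        coef_std = clf.coef_[0]
        b0 = float(clf.intercept_[0])
    elif family == "gaussian":
        reg = ElasticNet(alpha=lam, l1_ratio=alpha, tol=tol, max_iter=max_iter)
        reg.fit(Xs, yv)
        if reg.n_iter_ >= max_iter:
            raise ValidationError(
                f"elastic-net fit did not converge (alpha={alpha}, lambda={lam})"
            )
        coef_std = reg.coef_
        b0 = float(reg.intercept_)
    else:
        raise ValueError(f"unknown family {family!r}")
    coef = coef_std / sd
    intercept = b0 - float((coef_std * mean / sd).sum())
    return ElasticNetModel(
        alpha=float(alpha),
        lam=float(lam),
        intercept=intercept,
        coef=pd.Series(coef, index=features),
        family=family,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo cross-validation tuning
# ---------------------------------------------------------------------------


def _cv_split(y: np.ndarray, frac: float, rng: np.random.Generator, family: str) -> np.ndarray:
    """Indices of the sub-training set; stratified on y for binary outcomes."""
    n = len(y)
    mask = np.zeros(n, dtype=bool)
    if family == "binomial":
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            k = int(round(frac * len(idx)))
            mask[rng.permutation(idx)[:k]] = True
    else:
        k = int(round(frac * n))
        mask[rng.permutation(n)[:k]] = True
    return mask


def tune(
    X: pd.DataFrame,
    y: Sequence[int] | np.ndarray | pd.Series,
    grid: Mapping[float, np.ndarray],
    n_rounds: int = DEFAULT_N_ROUNDS,
    cv_train_frac: float = DEFAULT_CV_TRAIN_FRAC,
    seed: int = 0,
    family: str = "binomial",
    cutoff: float = 0.5,
    tol: float = 1e-4,
    max_iter: int = 1000,
) -> tuple[float, float, pd.DataFrame]:
    """Select (alpha, lambda) by Monte-Carlo cross-validation.

    Each round draws a random ``cv_train_frac`` sub-split of the training
    set; every grid point is fit on the sub-training part and scored on the
    holdout (classification accuracy at ``cutoff`` for binary outcomes, MSE
    for continuous).  The grid point with the best mean score wins; exact
    ties go to the largest lambda, then the largest alpha.
    """
    Xv = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    alphas = sorted(grid)
    metric = {a: np.zeros(len(grid[a])) for a in alphas}
    done = 0
    redraws = 0
    while done < n_rounds:
        mask = _cv_split(yv, cv_train_frac, rng, family)
        y_tr, y_ho = yv[mask], yv[~mask]
        if family == "binomial" and (len(np.unique(y_tr)) < 2 or len(y_ho) == 0):
            redraws += 1
            if redraws > 100 * n_rounds:
                raise ValidationError("cannot draw a two-class CV sub-training set")
            continue
        Xs, mean, sd = _standardize(Xv[mask])
        X_ho = (Xv[~mask] - mean) / sd
        for a in alphas:
            if family == "binomial":
                coefs, b0 = _binomial_path(Xs, y_tr, a, grid[a], tol, max_iter)
                score = X_ho @ coefs.T + b0
                prob = 1.0 / (1.0 + np.exp(-score))
                acc = ((prob > cutoff).astype(float) == y_ho[:, None]).mean(axis=0)
                metric[a] += acc
            else:
                coefs, b0 = _gaussian_path(Xs, y_tr, a, grid[a], tol, max_iter)
                pred = X_ho @ coefs.T + b0
                mse = ((pred - y_ho[:, None]) ** 2).mean(axis=0)
                metric[a] -= mse  # maximize -MSE
        done += 1
    if redraws:
        logger.info("tuning: %d CV rounds redrawn for single-class sub-training sets", redraws)

    rows = []
    for a in alphas:
        for lam, m in zip(grid[a], metric[a] / n_rounds):
            rows.append((a, float(lam), float(m)))
    table = pd.DataFrame(rows, columns=["alpha", "lambda", "mean_metric"])
    # best metric; ties -> largest lambda, then largest alpha
    best = table.sort_values(
        ["mean_metric", "lambda", "alpha"], ascending=[False, False, False]
    ).iloc[0]
    return float(best["alpha"]), float(best["lambda"]), table


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class ModelEvaluation:
    """ROC/AUC summary of one model on one evaluation set."""

    auc: float
    roc: pd.DataFrame  # columns fpr, tpr, threshold
    n: int

    @property
    def highly_predictable(self) -> bool:
        return self.auc > AUC_THRESHOLD


def auc_score(y_true: np.ndarray, score: np.ndarray) -> float:
    """Pairwise concordance AUC with half credit for ties."""
    y_true = np.asarray(y_true, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValidationError("evaluation set has a single class")
    return float(roc_auc_score(y_true, score))


def evaluate(model: ElasticNetModel, X_eval: pd.DataFrame, y_eval) -> ModelEvaluation:
    """ROC curve and AUC of a fitted model on an evaluation set.

    Features are aligned by name, never by position.
    """
    missing = [f for f in model.coef.index if f not in X_eval.columns]
    if missing:
        raise ValidationError(f"evaluation set lacks feature(s) {missing[:5]}")
    y = np.asarray(y_eval, dtype=float)
    score = model.decision(X_eval)
    auc = auc_score(y, score)
    fpr, tpr, thr = roc_curve(y, score)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return ModelEvaluation(auc=auc, roc=roc, n=len(y))


def evaluate_continuous(model: ElasticNetModel, X_eval: pd.DataFrame, y_eval) -> dict:
    """Pearson r and RMSE of a continuous-outcome model on an evaluation set."""
    y = np.asarray(y_eval, dtype=float)
    pred = model.decision(X_eval)
    if np.std(pred) == 0:
        r = 0.0
    else:
        r = float(stats.pearsonr(y, pred).statistic)
    rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
    return {"pearson_r": r, "rmse": rmse, "n": len(y)}


def highly_predictable(evaluations: Iterable[ModelEvaluation], threshold: float = AUC_THRESHOLD) -> bool:
    """A phenotype is highly predictable when AUC exceeds the threshold on every test set."""
    evals = list(evaluations)
    return bool(evals) and all(e.auc > threshold for e in evals)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


class _ElasticNetProtocolBase(BaseEstimator):
    """Shared fit logic: grid -> MC-CV tuning -> final fit."""

    _family = "binomial"

    def __init__(
        self,
        alphas: Sequence[float] = FULL_ALPHAS,
        n_lambda: int = DEFAULT_N_LAMBDA,
        lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
        n_rounds: int = DEFAULT_N_ROUNDS,
        cv_train_frac: float = DEFAULT_CV_TRAIN_FRAC,
        cutoff: float = 0.5,
        cv_tol: float = 1e-4,
        cv_max_iter: int = 1000,
        fit_tol: float = 1e-7,
        fit_max_iter: int = 100_000,
        random_state: int | None = None,
    ):
        self.alphas = alphas
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.n_rounds = n_rounds
        self.cv_train_frac = cv_train_frac
        self.cutoff = cutoff
        self.cv_tol = cv_tol
        self.cv_max_iter = cv_max_iter
        self.fit_tol = fit_tol
        self.fit_max_iter = fit_max_iter
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        rng = np.random.default_rng(self.random_state)
        tune_seed = int(rng.integers(2**31))
        grid = lambda_grid(
            X, y, alphas=self.alphas, n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
        )
        alpha, lam, table = tune(
            X, y, grid,
            n_rounds=self.n_rounds,
            cv_train_frac=self.cv_train_frac,
            seed=tune_seed,
            family=self._family,
            cutoff=self.cutoff,
            tol=self.cv_tol,
            max_iter=self.cv_max_iter,
        )
        model = fit(
            X, y, alpha, lam,
            family=self._family, tol=self.fit_tol, max_iter=self.fit_max_iter,
        )
        model.tuning = {
            "alphas": [float(a) for a in self.alphas],
            "n_lambda": int(self.n_lambda),
            "n_rounds": int(self.n_rounds),
            "cv_train_frac": float(self.cv_train_frac),
            "lambda_min_ratio": float(self.lambda_min_ratio),
            "seed": {"master": self.random_state, "tune": tune_seed},
            "grid_points_explored": int(sum(len(v) for v in grid.values())),
        }
        self.model_ = model
        self.alpha_ = model.alpha
        self.lambda_ = model.lam
        self.coef_ = model.coef
        self.intercept_ = model.intercept
        self.tuning_results_ = table
        self.feature_names_in_ = np.asarray(list(X.columns), dtype=object)
        return self

    def report(self) -> dict:
        return self.model_.to_report()


class ElasticNetPhenotypeClassifier(_ElasticNetProtocolBase, ClassifierMixin):
    """Binary phenotype classifier over segment-level CNA features.

    Implements the full tuning protocol (alpha x lambda grid from the
    training data, Monte-Carlo cross-validation selection by classification
    accuracy) and exposes sklearn classifier semantics.
    """

    _family = "binomial"

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValidationError("classifier requires binary 0/1 labels")
        super().fit(X, y)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p1 = self.model_.predict_proba(X)
        return np.column_stack([1 - p1, p1])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.model_.predict_proba(X) > self.cutoff).astype(int)

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        return self.model_.decision(X)


class ElasticNetPhenotypeRegressor(_ElasticNetProtocolBase, RegressorMixin):
    """Continuous-outcome variant: identical protocol, MSE as the CV metric."""

    _family = "gaussian"

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.model_.decision(X)


def fit_continuous(
    X: pd.DataFrame,
    y_continuous,
    X_test: pd.DataFrame | None = None,
    y_test=None,
    **params,
) -> tuple[ElasticNetModel, dict | None]:
    """Tune and fit the continuous-outcome model; evaluate on a test set if given."""
    reg = ElasticNetPhenotypeRegressor(**params)
    reg.fit(X, y_continuous)
    result = None
    if X_test is not None:
        result = evaluate_continuous(reg.model_, X_test, y_test)
    return reg.model_, result


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    """Label-permutation null distribution of test-set AUC."""

    n_permutations: int
    aucs: np.ndarray

    @property
    def max_auc(self) -> float:
        return float(np.max(self.aucs))

    @property
    def median_auc(self) -> float:
        return float(np.median(self.aucs))


def permutation_null(
    X: pd.DataFrame,
    labels: pd.Series,
    clinical: ClinicalTable,
    strata_vars: Sequence[str] = (),
    n_perm: int = 100,
    seed: int = 0,
    train_frac: float = 0.7,
    **estimator_params,
) -> PermutationResult:
    """Permute phenotype labels, re-split, re-tune, re-fit, and record test AUC.

    ``X`` is samples x features for the full cohort; ``labels`` the binary
    phenotype.  Each permutation shuffles labels over samples, draws a fresh
    stratified 70/30 split, runs the full tuning protocol on the training
    part, and evaluates on the test part.
    """
    rng = np.random.default_rng(seed)
    samples = list(X.index)
    aucs = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(samples))
        y_perm = pd.Series(labels.loc[samples].to_numpy()[perm], index=samples)
        split_seed = int(rng.integers(2**31))
        est_seed = int(rng.integers(2**31))
        split = stratified_split(clinical, strata_vars, train_frac=train_frac, seed=split_seed)
        clf = ElasticNetPhenotypeClassifier(random_state=est_seed, **estimator_params)
        clf.fit(X.loc[split.train], y_perm.loc[split.train])
        ev = evaluate(clf.model_, X.loc[split.test], y_perm.loc[split.test])
        aucs[b] = ev.auc
    return PermutationResult(n_permutations=n_perm, aucs=aucs)


# ---------------------------------------------------------------------------
# Coefficient re-mapping
# ---------------------------------------------------------------------------


def remap_coefficients(
    model: ElasticNetModel,
    defs: SegmentDefinitionTable,
    coords: GeneCoords | None = None,
) -> pd.DataFrame:
    """Re-map segment coefficients to the member genes of each segment.

    Every member gene of a selected segment carries that segment's
    coefficient; a gene belonging to several selected segments carries the
    sum (logged).  Genes in no selected segment carry 0.
    """
    unknown = [f for f in model.coef.index if f not in defs.members]
    if unknown:
        raise ValidationError(f"model feature(s) {unknown[:5]} not in segment definitions")
    gene_coef: dict[str, float] = {}
    for seg_id, genes in defs.members.items():
        for g in genes:
            gene_coef.setdefault(g, 0.0)
    overlaps = 0
    seen: set[str] = set()
    for seg_id, c in model.selected.items():
        for g in defs.members[seg_id]:
            if g in seen:
                overlaps += 1
            seen.add(g)
            gene_coef[g] += float(c)
    if overlaps:
        logger.warning("%d genes lie in multiple selected segments; coefficients summed", overlaps)
    out = pd.DataFrame({"gene": list(gene_coef), "coefficient": list(gene_coef.values())})
    if coords is not None:
        out = out.merge(coords.df[["gene", "chrom", "start", "end"]], on="gene", how="left")
    return out.set_index("gene")
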