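"""Elastic-net protocol: splitting, grid, tuning, fitting, AUC, remapping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.linear_model import LogisticRegression

from cnascape import prediction as pred
from cnascape.errors import ValidationError
from cnascape.io import ClinicalTable, SegmentDefinitionTable


def _clinical(n, rng, extra=None):
    df = pd.DataFrame(
        {"grp": rng.choice(["a", "b"], size=n)},
        index=[f"S{i:03d}" for i in range(n)],
    )
    if extra is not None:
        df = df.assign(**extra)
    return ClinicalTable(df)


def _xy(rng, n=120, p=10, informative=3, noise=0.5):
    X = pd.DataFrame(
        rng.normal(size=(n, p)),
        index=[f"S{i:03d}" for i in range(n)],
        columns=[f"f{j}" for j in range(p)],
    )
    lin = X.iloc[:, :informative].sum(axis=1) + rng.normal(0, noise, size=n)
    y = (lin > lin.median()).astype(int)
    return X, pd.Series(y, index=X.index)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def test_split_proportional_within_strata(rng):
    clin = ClinicalTable(
        pd.DataFrame(
            {"er": ["pos"] * 40 + ["neg"] * 60},
            index=[f"S{i:03d}" for i in range(100)],
        )
    )
    split = pred.stratified_split(clin, ["er"], seed=3)
    train_er = clin.df.loc[split.train, "er"]
    assert (train_er == "pos").sum() == 28
    assert (train_er == "neg").sum() == 42
    assert sorted(split.train + split.test) == sorted(clin.df.index)


def test_split_determinism_and_seed_sensitivity(rng):
    clin = _clinical(80, rng)
    a = pred.stratified_split(clin, ["grp"], seed=5)
    b = pred.stratified_split(clin, ["grp"], seed=5)
    c = pred.stratified_split(clin, ["grp"], seed=6)
    assert a.train == b.train and a.test == b.test
    assert a.train != c.train
    # stratum counts identical across seeds
    key = clin.df["grp"]
    assert key.loc[a.train].value_counts().equals(key.loc[c.train].value_counts())


def test_split_per_stratum_fraction_within_one_sample(rng):
    clin = _clinical(
        200, rng, extra={"os": rng.exponential(60, 200), "ev": rng.integers(0, 2, 200)}
    )
    split = pred.stratified_split(clin, ["grp", "ev"], train_frac=0.7, seed=1)
    assert split.strata is not None
    for stratum in split.strata.unique():
        ids = split.strata.index[split.strata == stratum]
        n_train = len(set(ids) & set(split.train))
        assert abs(n_train - 0.7 * len(ids)) <= 1


def test_split_balance_chi2_across_seeds(rng):
    clin = _clinical(150, rng)
    sig_count = 0
    for seed in range(50):
        split = pred.stratified_split(clin, ["grp"], seed=seed)
        tab = pd.crosstab(
            clin.df["grp"],
            pd.Series(
                ["train" if s in set(split.train) else "test" for s in clin.df.index],
                index=clin.df.index,
            ),
        )
        _, p, *_ = stats.chi2_contingency(tab)
        sig_count += p < 0.05
    assert sig_count == 0  # proportional allocation cannot be confounded


def test_split_small_cohort_rejected(rng):
    with pytest.raises(ValidationError, match="too small"):
        pred.stratified_split(_clinical(10, rng), ["grp"], seed=0)


# ---------------------------------------------------------------------------
# lambda grid
# ---------------------------------------------------------------------------


def test_lambda_max_closed_form(rng):
    X, y = _xy(rng)
    Xs = (X - X.mean()) / X.std(ddof=0)
    want = np.abs(Xs.to_numpy().T @ (y - y.mean())).max() / (len(y) * 0.5)
    assert pred.lambda_max(X.to_numpy(), y.to_numpy(), 0.5) == pytest.approx(want, rel=1e-8)


def test_lambda_grid_shape_and_monotone(rng):
    X, y = _xy(rng)
    grid = pred.lambda_grid(X, y, alphas=(0.1, 1.0), n_lambda=100)
    for lams in grid.values():
        assert len(lams) == 100
        assert (np.diff(lams) < 0).all()


@pytest.mark.parametrize("alpha", [0.1, 0.5, 1.0])
def test_fit_at_lambda_max_is_null_model(rng, alpha):
    X, y = _xy(rng)
    lmax = pred.lambda_max(X.to_numpy(), y.to_numpy(), alpha)
    model = pred.fit(X, y, alpha, lmax * 1.0001, family="binomial")
    assert (model.coef.abs() < 1e-7).all()
    # intercept of the null model is the logit of prevalence
    prev = y.mean()
    assert model.intercept == pytest.approx(np.log(prev / (1 - prev)), abs=5e-3)


def test_lambda_grid_rejects_constant_outcome(rng):
    X, _ = _xy(rng)
    with pytest.raises(ValidationError, match="constant"):
        pred.lambda_grid(X, np.ones(len(X)))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def test_tiny_lambda_matches_unpenalized_logistic(rng):
    X, y = _xy(rng, n=400, p=4, informative=2, noise=1.5)
    model = pred.fit(X, y, 0.5, 1e-8, family="binomial")
    oracle = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=10_000, tol=1e-10)
    oracle.fit(X.to_numpy(), y.to_numpy())
    np.testing.assert_allclose(model.coef.to_numpy(), oracle.coef_[0], atol=1e-3)
    assert model.intercept == pytest.approx(oracle.intercept_[0], abs=1e-3)


def test_fit_sign_consistency(rng):
    n = 200
    X = pd.DataFrame(
        {"inf": rng.normal(size=n), "noise": rng.normal(size=n)},
        index=[f"S{i}" for i in range(n)],
    )
    y = (X["inf"] + rng.normal(0, 0.3, n) > 0).astype(int)
    model = pred.fit(X, y, 0.5, 0.01, family="binomial")
    assert model.coef["inf"] > 0


def test_continuous_noiseless_recovery(rng):
    n = 100
    X = pd.DataFrame(rng.normal(size=(n, 5)), index=[f"S{i}" for i in range(n)],
                     columns=[f"f{j}" for j in range(5)])
    y = 2.0 * X["f0"]
    model, res = pred.fit_continuous(
        X.iloc[:70], y.iloc[:70], X.iloc[70:], y.iloc[70:],
        alphas=(0.5,), n_lambda=10, n_rounds=5, lambda_min_ratio=1e-6, random_state=0,
    )
    assert res["pearson_r"] > 0.999


# ---------------------------------------------------------------------------
# tuning
# ---------------------------------------------------------------------------


def test_tune_single_point_grid_is_identity(rng):
    X, y = _xy(rng)
    grid = {0.5: np.array([0.05])}
    alpha, lam, _ = pred.tune(X, y, grid, n_rounds=5, seed=0)
    assert alpha == 0.5 and lam == pytest.approx(0.05)


def test_tune_tie_break_prefers_sparser_models(rng):
    """All-null grid points tie on accuracy: largest lambda then alpha wins."""
    X, y = _xy(rng)
    lmax = max(pred.lambda_max(X.to_numpy(), y.to_numpy(), a) for a in (0.5, 1.0))
    grid = {
        0.5: np.array([lmax * 4, lmax * 2]),
        1.0: np.array([lmax * 4, lmax * 2]),
    }
    alpha, lam, table = pred.tune(X, y, grid, n_rounds=3, seed=1)
    assert table["mean_metric"].nunique() == 1
    assert lam == pytest.approx(lmax * 4) and alpha == 1.0


def test_tune_reproducible(rng):
    X, y = _xy(rng)
    grid = pred.lambda_grid(X, y, alphas=(0.5,), n_lambda=5)
    out1 = pred.tune(X, y, grid, n_rounds=5, seed=9)
    out2 = pred.tune(X, y, grid, n_rounds=5, seed=9)
    assert out1[:2] == out2[:2]
    pd.testing.assert_frame_equal(out1[2], out2[2])


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def test_auc_examples():
    assert pred.auc_score(np.array([1, 1, 0, 0]), np.array([0.9, 0.8, 0.3, 0.2])) == 1.0
    assert pred.auc_score(np.array([1, 0, 1, 0]), np.array([0.9, 0.8, 0.3, 0.2])) == 0.75
    assert pred.auc_score(np.array([1, 0, 1, 0]), np.array([0.5] * 4)) == 0.5


def test_auc_label_flip_complements(rng):
    y = rng.integers(0, 2, size=50)
    y[0], y[1] = 0, 1
    s = rng.normal(size=50)
    assert pred.auc_score(y, s) + pred.auc_score(1 - y, s) == pytest.approx(1.0)


def test_evaluate_rejects_single_class(rng):
    X, y = _xy(rng, n=30)
    model = pred.fit(X, y, 0.5, 0.05)
    with pytest.raises(ValidationError, match="single class"):
        pred.evaluate(model, X, np.ones(len(X)))


def test_evaluate_aligns_features_by_name(rng):
    X, y = _xy(rng, n=60, p=4)
    model = pred.fit(X, y, 0.5, 0.01)
    shuffled = X[list(X.columns[::-1])]
    a = pred.evaluate(model, X, y)
    b = pred.evaluate(model, shuffled, y)
    assert a.auc == b.auc
    with pytest.raises(ValidationError, match="lacks feature"):
        pred.evaluate(model, X.drop(columns=["f0"]), y)


# ---------------------------------------------------------------------------
# estimator protocol & report metadata
# ---------------------------------------------------------------------------


def test_classifier_estimator_protocol(rng):
    X, y = _xy(rng, n=150, p=6)
    clf = pred.ElasticNetPhenotypeClassifier(
        alphas=(0.5, 1.0), n_lambda=5, n_rounds=5, random_state=0
    )
    params = clf.get_params()
    assert params["n_rounds"] == 5
    clf.fit(X, y)
    assert clf.coef_.index.tolist() == list(X.columns)
    proba = clf.predict_proba(X)
    assert proba.shape == (len(X), 2)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0)
    rep = clf.report()
    assert rep["tuning"]["alphas"] == [0.5, 1.0]
    assert rep["tuning"]["n_rounds"] == 5
    assert rep["tuning"]["grid_points_explored"] == 10


def test_default_protocol_is_full_grid():
    clf = pred.ElasticNetPhenotypeClassifier()
    assert list(clf.alphas) == [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
    assert clf.n_lambda == 100
    assert clf.n_rounds == 200
    assert clf.cv_train_frac == 0.75


def test_fit_refit_same_seed_identical(rng):
    X, y = _xy(rng, n=100, p=5)
    clfs = [
        pred.ElasticNetPhenotypeClassifier(
            alphas=(0.5,), n_lambda=5, n_rounds=5, random_state=11
        ).fit(X, y)
        for _ in range(2)
    ]
    pd.testing.assert_series_equal(clfs[0].coef_, clfs[1].coef_)
    assert clfs[0].lambda_ == clfs[1].lambda_


# ---------------------------------------------------------------------------
# remapping
# ---------------------------------------------------------------------------


def _model(coefs):
    return pred.ElasticNetModel(
        alpha=0.5, lam=0.1, intercept=0.0,
        coef=pd.Series(coefs), family="binomial",
    )


def test_remap_broadcast_and_zero():
    defs = SegmentDefinitionTable(
        members={"s1": [f"G{i}" for i in range(10)], "s2": ["H1", "H2"]}
    )
    out = pred.remap_coefficients(_model({"s1": 0.4, "s2": 0.0}), defs)
    assert (out.loc[[f"G{i}" for i in range(10)], "coefficient"] == 0.4).all()
    assert (out.loc[["H1", "H2"], "coefficient"] == 0.0).all()
    empty = pred.remap_coefficients(_model({"s1": 0.0, "s2": 0.0}), defs)
    assert (empty["coefficient"] == 0.0).all()


def test_remap_overlapping_segments_sum():
    defs = SegmentDefinitionTable(members={"s1": ["G1", "G2"], "s2": ["G2", "G3"]})
    out = pred.remap_coefficients(_model({"s1": 0.4, "s2": 0.1}), defs)
    assert out.loc["G2", "coefficient"] == pytest.approx(0.5)
    assert out.loc["G1", "coefficient"] == pytest.approx(0.4)


def test_remap_unknown_feature_rejected():
    defs = SegmentDefinitionTable(members={"s1": ["G1"]})
    with pytest.raises(ValidationError, match="not in segment definitions"):
        pred.remap_coefficients(_model({"sX": 1.0}), defs)


# ---------------------------------------------------------------------------
# permutation determinism
# ---------------------------------------------------------------------------


def test_permutation_null_deterministic(rng):
    X, y = _xy(rng, n=60, p=4)
    clin = ClinicalTable(pd.DataFrame({"g": ["a"] * 60}, index=X.index))
    kwargs = dict(
        strata_vars=["g"], n_perm=2, seed=21,
        alphas=(1.0,), n_lambda=3, n_rounds=3,
    )
    a = pred.permutation_null(X, y, clin, **kwargs)
    b = pred.permutation_null(X, y, clin, **kwargs)
    np.testing.assert_array_equal(a.aucs, b.aucs)
    assert a.n_permutations == 2
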