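"""Reference-design-point evaluations of the whole pipeline.

These routines generate synthetic cohorts at the reference design point
(n = 600 samples, 2000 genes, 40 segments, driver weight 1, expression
noise sd 1), run the full method, and measure recovery, calibration and
power.  They back both the acceptance-style tests and the reproduction
script, so the numbers reported there are always recomputed from scratch.

Tuning in these evaluations uses a reduced grid (3 alphas x 20 lambdas,
50 Monte-Carlo CV rounds) — the protocol is unchanged, only the grid
resolution is coarser than the full 10 x 100 x 200 default.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import association, prediction, survival as surv
from .preprocess import segment_scores
from .signatures import dichotomize, score_median
from .simulate import REFERENCE_SEED, SimulationConfig, confounded_config, simulate_cohort

REDUCED_GRID = dict(alphas=(0.1, 0.5, 1.0), n_lambda=20, n_rounds=50)
STRATA = ("gender", "er_status", "os_months", "os_event")


def _cohort_xy(cohort):
    X = segment_scores(cohort.gene_cna, cohort.segment_defs).T
    scores = score_median(cohort.expression, cohort.signatures[0])
    labels = dichotomize(scores, "top_third")
    return X, scores, labels


def driver_recovery(seed: int = REFERENCE_SEED, split_seed: int | None = None) -> dict:
    """Association + prediction recovery of the planted driver segment."""
    cohort = simulate_cohort(SimulationConfig(seed=seed))
    X, scores, labels = _cohort_xy(cohort)
    driver = cohort.truth.driver_segments[0]
    driver_genes = cohort.segment_defs.members[driver]

    land = association.landscape(scores, cohort.gene_cna)
    recall = float((land.loc[driver_genes, "call"] == "positive_gain").mean())

    split = prediction.stratified_split(
        cohort.clinical, STRATA, seed=seed if split_seed is None else split_seed
    )
    clf = prediction.ElasticNetPhenotypeClassifier(random_state=seed, **REDUCED_GRID)
    clf.fit(X.loc[split.train], labels.labels.loc[split.train])
    ev = prediction.evaluate(clf.model_, X.loc[split.test], labels.labels.loc[split.test])

    reg = prediction.ElasticNetPhenotypeRegressor(random_state=seed, **REDUCED_GRID)
    reg.fit(X.loc[split.train], scores.loc[split.train])
    cont = prediction.evaluate_continuous(reg.model_, X.loc[split.test], scores.loc[split.test])

    return {
        "n_samples": cohort.config.n_samples,
        "driver_gene_recall": recall,
        "landscape_calls_total": int((land["call"] != "none").sum()),
        "test_auc": float(ev.auc),
        "driver_coefficient": float(clf.coef_[driver]),
        "continuous_test_r": float(cont["pearson_r"]),
        "continuous_test_rmse": float(cont["rmse"]),
    }


def permutation_calibration(seed: int = REFERENCE_SEED, n_perm: int = 20) -> dict:
    """Label-permutation null of the test AUC at the reference design point."""
    cohort = simulate_cohort(SimulationConfig(seed=seed))
    X, _, labels = _cohort_xy(cohort)
    result = prediction.permutation_null(
        X, labels.labels, cohort.clinical,
        strata_vars=STRATA, n_perm=n_perm, seed=seed, **REDUCED_GRID,
    )
    return {
        "n_permutations": result.n_permutations,
        "max_auc": result.max_auc,
        "median_auc": result.median_auc,
        "aucs": [float(a) for a in result.aucs],
    }


def null_call_rates(seeds) -> list[float]:
    """Fraction of genes jointly called under the global null (all weights 0)."""
    rates = []
    for seed in seeds:
        cohort = simulate_cohort(SimulationConfig(seed=seed, driver_weights=(0.0,)))
        scores = score_median(cohort.expression, cohort.signatures[0])
        land = association.landscape(scores, cohort.gene_cna)
        rates.append(float((land["call"] != "none").mean()))
    return rates


def confounding_directionality(seeds) -> dict:
    """Unadjusted vs subtype-adjusted driver calls in the confounded scenario."""
    n_unadj, n_adj_zero, n_directional = 0, 0, 0
    for seed in seeds:
        cohort = simulate_cohort(confounded_config(seed))
        scores = score_median(cohort.expression, cohort.signatures[0])
        driver_genes = cohort.segment_defs.members[cohort.truth.driver_segments[0]]
        unadj = association.landscape(scores, cohort.gene_cna)
        adj = association.landscape_subtype_adjusted(
            scores, cohort.gene_cna, cohort.truth.subtypes
        )
        u = (unadj.loc[driver_genes, "call"] == "positive_gain").any()
        a = (adj.loc[driver_genes, "call"] != "none").sum() == 0
        n_unadj += u
        n_adj_zero += a
        n_directional += u and a
    return {
        "n_seeds": len(list(seeds)),
        "unadjusted_calls_driver": int(n_unadj),
        "adjusted_zero_driver_calls": int(n_adj_zero),
        "directional": int(n_directional),
    }


def survival_power(seeds, tune_seed: int | None = None) -> dict:
    """Log-rank significance of tertile groups, by observed score and by model.

    Hyperparameters are tuned once on the first seed's cohort (reduced grid)
    and the model is re-fit at those values for every seed.
    """
    seeds = list(seeds)
    alpha = lam = None
    p_obs, p_pred = [], []
    for i, seed in enumerate(seeds):
        cohort = simulate_cohort(SimulationConfig(seed=seed))
        X, scores, labels = _cohort_xy(cohort)
        split = prediction.stratified_split(cohort.clinical, STRATA, seed=seed)
        if alpha is None:
            clf = prediction.ElasticNetPhenotypeClassifier(
                random_state=tune_seed if tune_seed is not None else seed, **REDUCED_GRID
            )
            clf.fit(X.loc[split.train], labels.labels.loc[split.train])
            alpha, lam = clf.alpha_, clf.lambda_
            model = clf.model_
        else:
            model = prediction.fit(
                X.loc[split.train], labels.labels.loc[split.train], alpha, lam
            )
        records = surv.censor_10yr_cause_specific(cohort.survival)
        prob = pd.Series(model.predict_proba(X), index=X.index)
        p_obs.append(surv.logrank(records, surv.risk_groups(scores, records).groups)[1])
        p_pred.append(surv.logrank(records, surv.risk_groups(prob, records).groups)[1])
    return {
        "n_seeds": len(seeds),
        "observed_significant": int(sum(p < 0.01 for p in p_obs)),
        "predicted_significant": int(sum(p < 0.01 for p in p_pred)),
        "median_p_observed": float(np.median(p_obs)),
        "median_p_predicted": float(np.median(p_pred)),
    }


# ---------------------------------------------------------------------------
# Independent numeric oracles (enumeration / brute force)
# ---------------------------------------------------------------------------


def hypergeom_tail(a: int, n_high: int, K: int, N: int) -> float:
    """P(X >= a) by explicit enumeration of the hypergeometric pmf."""
    total = 0.0
    for x in range(a, min(K, n_high) + 1):
        total += math.comb(K, x) * math.comb(N - K, n_high - x) / math.comb(N, n_high)
    return total


def fisher_vs_enumeration(seed: int, n_tables: int = 500) -> float:
    """Max |p - enumeration| over random 2x2 gain tables."""
    from .signatures import PhenotypeLabels

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        n = int(rng.integers(8, 60))
        n_high = int(rng.integers(2, n - 1))
        lab_vals = np.zeros(n, dtype=int)
        lab_vals[rng.permutation(n)[:n_high]] = 1
        idx = [f"S{i:03d}" for i in range(n)]
        labels = PhenotypeLabels(
            labels=pd.Series(lab_vals, index=idx), rule="top_quartile",
            boundary=0.0, n_high=n_high,
        )
        vals = rng.choice([0.0, 0.6, -0.6], size=n, p=[0.5, 0.25, 0.25])
        g = pd.DataFrame([vals], index=["g"], columns=idx)
        got = association.fisher_per_gene(labels, g).loc["g", "p_gain"]
        K = int((vals > 0.3).sum())
        a = int(((vals > 0.3) & (lab_vals == 1)).sum())
        worst = max(worst, abs(got - hypergeom_tail(a, n_high, K, n)))
    return worst


def bh_vs_stepup(seed: int, n_vectors: int = 100) -> float:
    """Max |q - step-up formula| over random p-vectors."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        p = rng.random(int(rng.integers(1, 300)))
        q = association.bh_adjust(p)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        ref = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            running = min(running, p[order[rank - 1]] * m / rank)
            ref[order[rank - 1]] = running
        worst = max(worst, float(np.abs(q - ref).max()))
    return worst


def extreme_vs_bruteforce(seed: int, n_layouts: int = 1000) -> int:
    """Mismatch count between the extreme method and per-segment scanning."""
    from .io import GeneCoords, SegmentationTable
    from .preprocess import gene_cna_extreme

    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_layouts):
        cuts = np.sort(rng.choice(np.arange(1, 100), size=int(rng.integers(2, 8)), replace=False))
        bounds = np.concatenate([[0], cuts, [100]]) * 10
        keep = rng.random(len(bounds) - 1) < 0.7
        rows = [
            ("S1", "1", int(bounds[i]), int(bounds[i + 1]), float(rng.normal(0, 0.6)))
            for i in range(len(bounds) - 1)
            if keep[i]
        ]
        if not rows:
            continue
        a = int(rng.integers(0, 990))
        g_start, g_end = a, a + int(rng.integers(5, 120))
        seg = SegmentationTable(
            pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "value"])
        )
        coords = GeneCoords(
            pd.DataFrame([("G1", "1", g_start, g_end)], columns=["gene", "chrom", "start", "end"])
        )
        got = gene_cna_extreme(seg, coords).loc["G1", "S1"]
        overl = [v for (_, _, s, e, v) in rows if s < g_end and e > g_start]
        if not overl:
            want = np.nan
        else:
            hi, lo = max(overl), min(overl)
            want = hi if abs(hi) >= abs(lo) else lo
        same = (np.isnan(got) and np.isnan(want)) or got == want
        mismatches += not same
    return mismatches


def segment_mean_error(seed: int) -> float:
    """Max |segment score - independent summation| on a random matrix."""
    from .io import SegmentDefinitionTable

    rng = np.random.default_rng(seed)
    genes = [f"G{i}" for i in range(200)]
    g = pd.DataFrame(
        rng.normal(size=(200, 30)), index=genes,
        columns=[f"S{i}" for i in range(30)],
    )
    members = {f"seg{k}": genes[k * 20 : (k + 1) * 20] for k in range(10)}
    defs = SegmentDefinitionTable(members=members)
    out = segment_scores(g, defs)
    worst = 0.0
    for seg_id, mem in members.items():
        sums = np.zeros(30)
        for gene in mem:
            sums += g.loc[gene].to_numpy()
        worst = max(worst, float(np.abs(out.loc[seg_id].to_numpy() - sums / len(mem)).max()))
    return worst
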