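"""Genome-wide CNA-signature association landscapes.

For one signature, every gene is tested two ways against its gene-level
copy-number score: (i) a Spearman rank correlation between the continuous
signature score and the CNA score, and (ii) one-sided Fisher exact tests
comparing the frequency of copy-number gain (score > gain threshold) or
loss (score < loss threshold) between samples in the top score quartile and
all others.  Each p-value family is Benjamini-Hochberg adjusted across
genes.  A gene is called a candidate driver (``positive_gain``) when both
the correlation (rho > 0) and the gain enrichment are significant at the
same q threshold, and a candidate repressor (``negative_loss``) when the
negative correlation and the loss enrichment are.

The subtype-adjusted variant replaces the rank correlation with a linear
model of the signature on CNA plus molecular-subtype indicator covariates,
so associations explained entirely by subtype composition drop out; the
Fisher arm and the joint-call logic are unchanged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import ValidationError
from .signatures import PhenotypeLabels, dichotomize

logger = logging.getLogger(__name__)

MIN_PAIRS = 10


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs are passed through."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def _spearman_p(rho: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p from the large-sample t approximation."""
    rho = np.asarray(rho, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    p = np.where(np.isnan(rho), np.nan, p)
    return p


def spearman_per_gene(
    scores: pd.Series, gene_cna: pd.DataFrame, min_pairs: int = MIN_PAIRS
) -> pd.DataFrame:
    """Per-gene Spearman correlation of signature score with CNA score.

    Genes with fewer than ``min_pairs`` paired non-missing samples, or with
    a constant CNA vector, are skipped (NaN statistics).
    """
    scores = scores.loc[gene_cna.columns]
    X = gene_cna.to_numpy(dtype=float)
    y = scores.to_numpy(dtype=float)
    G, N = X.shape
    rho = np.full(G, np.nan)
    npairs = np.zeros(G, dtype=int)

    complete = ~np.isnan(X).any(axis=1)
    if complete.any():
        Xc = X[complete]
        const = Xc.min(axis=1) == Xc.max(axis=1)
        rx = stats.rankdata(Xc, axis=1)
        ry = stats.rankdata(y)
        rx = rx - rx.mean(axis=1, keepdims=True)
        ry = ry - ry.mean()
        denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (rx @ ry) / denom
        r[const] = np.nan
        rho[complete] = r
        npairs[complete] = N
    for i in np.flatnonzero(~complete):
        ok = ~np.isnan(X[i])
        n = int(ok.sum())
        npairs[i] = n
        if n < min_pairs or X[i, ok].min() == X[i, ok].max():
            continue
        rho[i] = stats.spearmanr(X[i, ok], y[ok]).statistic
    npairs_eff = np.where(npairs >= min_pairs, npairs, 0)
    p = _spearman_p(rho, np.maximum(npairs_eff, 3))
    p = np.where(npairs >= min_pairs, p, np.nan)
    rho = np.where(npairs >= min_pairs, rho, np.nan)
    return pd.DataFrame({"rho": rho, "p_corr": p, "n": npairs}, index=gene_cna.index)


def fisher_per_gene(
    labels: PhenotypeLabels,
    gene_cna: pd.DataFrame,
    gain_thr: float = 0.3,
    loss_thr: float = -0.3,
) -> pd.DataFrame:
    """One-sided Fisher exact tests for gain/loss enrichment in the high group.

    The p-value is the exact hypergeometric upper tail for over-representation
    of the event (gain or loss) among top-quartile samples; samples with a
    missing CNA value for a gene are excluded from that gene's table.
    Degenerate margins give p = 1.
    """
    if gain_thr <= 0 or loss_thr >= 0:
        raise ValidationError("thresholds must satisfy gain_thr > 0 > loss_thr")
    aligned = labels.labels.loc[gene_cna.columns].to_numpy()
    X = gene_cna.to_numpy(dtype=float)
    present = ~np.isnan(X)
    high = aligned == 1

    n_tot = present.sum(axis=1)
    n_high = (present & high).sum(axis=1)
    results = {}
    for arm, event in (("gain", X > gain_thr), ("loss", X < loss_thr)):
        event = event & present
        K = event.sum(axis=1)
        a = (event & high).sum(axis=1)
        # P(X >= a) for X ~ Hypergeom(N=n_tot, K, draws=n_high)
        p = stats.hypergeom.sf(a - 1, n_tot, K, n_high)
        p = np.where(n_tot == 0, 1.0, p)
        results[f"p_{arm}"] = np.minimum(p, 1.0)
    return pd.DataFrame(results, index=gene_cna.index)


def _joint_calls(table: pd.DataFrame, alpha: float) -> pd.Series:
    call = np.full(len(table), "none", dtype=object)
    sig_corr = table["q_corr"] < alpha
    pos = sig_corr & (table["rho"] > 0) & (table["q_gain"] < alpha)
    neg = sig_corr & (table["rho"] < 0) & (table["q_loss"] < alpha)
    call[pos.to_numpy()] = "positive_gain"
    call[neg.to_numpy()] = "negative_loss"
    return pd.Series(call, index=table.index, name="call")


def _assemble(corr: pd.DataFrame, fisher: pd.DataFrame, alpha: float) -> pd.DataFrame:
    table = corr.join(fisher)
    table["q_corr"] = bh_adjust(table["p_corr"])
    table["q_gain"] = bh_adjust(table["p_gain"])
    table["q_loss"] = bh_adjust(table["p_loss"])
    table["call"] = _joint_calls(table, alpha)
    cols = ["rho", "p_corr", "q_corr", "p_gain", "q_gain", "p_loss", "q_loss", "n", "call"]
    return table[cols]


def landscape(
    scores: pd.Series,
    gene_cna: pd.DataFrame,
    alpha: float = 0.01,
    gain_thr: float = 0.3,
    loss_thr: float = -0.3,
) -> pd.DataFrame:
    """Dual-test association landscape for one signature.

    BH adjustment is applied separately to the correlation p-vector and to
    each Fisher p-vector, each across all genes for this signature.
    """
    scores = scores.loc[gene_cna.columns]
    corr = spearman_per_gene(scores, gene_cna)
    labels = dichotomize(scores, rule="top_quartile")
    fisher = fisher_per_gene(labels, gene_cna, gain_thr=gain_thr, loss_thr=loss_thr)
    return _assemble(corr, fisher, alpha)


def _linear_adjusted(
    scores: pd.Series,
    gene_cna: pd.DataFrame,
    subtypes: pd.Series,
    min_subtype: int = 3,
) -> pd.DataFrame:
    """Per-gene least squares of score ~ CNA + subtype indicators (FWL form)."""
    samples = gene_cna.columns
    y = scores.loc[samples].to_numpy(dtype=float)
    sub = subtypes.loc[samples].astype(str)
    counts = sub.value_counts()
    small = counts[counts < min_subtype].index.tolist()
    if small:
        logger.warning("subtype(s) %s have <%d samples; dropped from covariates", small, min_subtype)
    levels = [s for s in counts.index if s not in small]
    dummies = pd.get_dummies(sub)[levels] if levels else pd.DataFrame(index=sub.index)
    # intercept + all-but-one indicator columns
    Z = np.column_stack([np.ones(len(samples))] + (
        [dummies.iloc[:, 1:].to_numpy(dtype=float)] if len(levels) > 1 else []
    ))
    Q, _ = np.linalg.qr(Z)
    k = Z.shape[1]

    X = gene_cna.to_numpy(dtype=float)
    G, N = X.shape
    beta = np.full(G, np.nan)
    pvals = np.full(G, np.nan)
    npairs = np.zeros(G, dtype=int)

    def fit_block(Xb: np.ndarray, yb: np.ndarray, Qb: np.ndarray, kb: int):
        yt = yb - Qb @ (Qb.T @ yb)
        Xt = Xb - (Xb @ Qb) @ Qb.T
        sxx = (Xt**2).sum(axis=1)
        syy = float((yt**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            b = (Xt @ yt) / sxx
            df = Xb.shape[1] - kb - 1
            s2 = np.maximum(syy - b**2 * sxx, 0.0) / df
            tstat = b / np.sqrt(s2 / sxx)
        pv = 2 * stats.t.sf(np.abs(tstat), df)
        bad = sxx <= 1e-12 * Xb.shape[1]
        b[bad] = np.nan
        pv[bad] = np.nan
        return b, pv

    complete = ~np.isnan(X).any(axis=1)
    if complete.any():
        b, pv = fit_block(X[complete], y, Q, k)
        beta[complete] = b
        pvals[complete] = pv
        npairs[complete] = N
    for i in np.flatnonzero(~complete):
        ok = ~np.isnan(X[i])
        n = int(ok.sum())
        npairs[i] = n
        if n < MIN_PAIRS + k:
            continue
        Zi = Z[ok]
        Qi, _ = np.linalg.qr(Zi)
        b, pv = fit_block(X[i : i + 1, ok], y[ok], Qi, Zi.shape[1])
        beta[i], pvals[i] = b[0], pv[0]
    return pd.DataFrame(
        {"rho": beta, "p_corr": pvals, "n": npairs}, index=gene_cna.index
    )


def landscape_subtype_adjusted(
    scores: pd.Series,
    gene_cna: pd.DataFrame,
    subtypes: pd.Series,
    alpha: float = 0.01,
    gain_thr: float = 0.3,
    loss_thr: float = -0.3,
) -> pd.DataFrame:
    """Subtype-adjusted landscape: linear model instead of rank correlation.

    ``rho`` holds the CNA coefficient from the adjusted linear model (its
    sign gives the direction); the Fisher arm and joint-call logic match the
    unadjusted landscape.
    """
    scores = scores.loc[gene_cna.columns]
    corr = _linear_adjusted(scores, gene_cna, subtypes)
    labels = dichotomize(scores, rule="top_quartile")
    fisher = fisher_per_gene(labels, gene_cna, gain_thr=gain_thr, loss_thr=loss_thr)
    return _assemble(corr, fisher, alpha)


class CnaSignatureAssociation(BaseEstimator):
    """Estimator wrapper for the dual-test association landscape.

    Parameters
    ----------
    alpha : joint significance threshold on BH q-values (both arms).
    gain_thr, loss_thr : CNA score cutoffs defining gain and loss events.
    adjust_subtypes : when True, ``fit`` requires ``subtypes`` and uses the
        linear-model variant.
    """

    def __init__(
        self,
        alpha: float = 0.01,
        gain_thr: float = 0.3,
        loss_thr: float = -0.3,
        adjust_subtypes: bool = False,
    ):
        self.alpha = alpha
        self.gain_thr = gain_thr
        self.loss_thr = loss_thr
        self.adjust_subtypes = adjust_subtypes

    def fit(self, gene_cna: pd.DataFrame, scores: pd.Series, subtypes: pd.Series | None = None):
        if self.adjust_subtypes:
            if subtypes is None:
                raise ValidationError("adjust_subtypes=True requires subtype labels")
            self.landscape_ = landscape_subtype_adjusted(
                scores, gene_cna, subtypes, self.alpha, self.gain_thr, self.loss_thr
            )
        else:
            self.landscape_ = landscape(
                scores, gene_cna, self.alpha, self.gain_thr, self.loss_thr
            )
        self.calls_ = self.landscape_["call"]
        return self
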