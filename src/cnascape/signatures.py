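"""Signature scoring and score dichotomization.

A median signature scores each sample as the median expression of the
signature's genes.  A centroid signature scores each sample by its
similarity (Pearson or Spearman correlation, or negative Euclidean
distance) to a target-class centroid over the shared genes.  Continuous
scores feed two dichotomization rules used downstream: top third vs bottom
two-thirds (prediction targets, survival groups) and top quartile vs bottom
three quartiles (enrichment testing).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import SignatureDefinition
from .preprocess import as_frame

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhenotypeLabels:
    """Binary high/low labels derived from a continuous score."""

    labels: pd.Series  # sample id -> 0/1
    rule: str
    boundary: float  # lowest score assigned to the high group
    n_high: int

    @property
    def samples(self) -> list[str]:
        return list(self.labels.index)


def score_median(x, sig: SignatureDefinition) -> pd.Series:
    """Per-sample median expression over the signature's genes."""
    df = as_frame(x)
    present = [g for g in sig.genes if g in df.index]
    if not present:
        raise ValidationError(f"signature {sig.name!r}: no signature gene is in the matrix")
    frac = len(present) / len(sig.genes)
    if frac < 1.0:
        logger.warning(
            "signature %s: %d/%d genes resolvable (%.0f%%)",
            sig.name, len(present), len(sig.genes), 100 * frac,
        )
    scores = df.loc[present].median(axis=0)
    scores.name = sig.name
    return scores


def score_centroid(x, sig: SignatureDefinition) -> pd.Series:
    """Per-sample similarity to the target-class centroid."""
    df = as_frame(x)
    if sig.centroids is None:
        raise ValidationError(f"signature {sig.name!r} has no centroid matrix")
    shared = [g for g in sig.centroids.index if g in df.index]
    if len(shared) < 3:
        raise ValidationError(
            f"signature {sig.name!r}: only {len(shared)} genes shared with the matrix (<3)"
        )
    centroid = sig.centroids.loc[shared, sig.target_class].to_numpy(dtype=float)
    mat = df.loc[shared].to_numpy(dtype=float)
    if sig.metric == "euclidean":
        vals = -np.sqrt(((mat - centroid[:, None]) ** 2).sum(axis=0))
    else:
        if sig.metric == "spearman":
            centroid = stats.rankdata(centroid)
            mat = np.apply_along_axis(stats.rankdata, 0, mat)
        c = centroid - centroid.mean()
        m = mat - mat.mean(axis=0)
        denom = np.sqrt((c**2).sum() * (m**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = (c @ m) / denom
    scores = pd.Series(vals, index=df.columns, name=sig.name)
    return scores


def score_signature(x, sig: SignatureDefinition) -> pd.Series:
    return score_median(x, sig) if sig.method == "median" else score_centroid(x, sig)


def score_archive(x, signatures) -> pd.DataFrame:
    """Score a list of signatures; returns signatures x samples."""
    return pd.DataFrame({s.name: score_signature(x, s) for s in signatures}).T


_RULE_HIGH = {
    "top_third": lambda n: math.ceil(n / 3),
    "top_quartile": lambda n: math.ceil(n / 4),
}


def dichotomize(scores: pd.Series, rule: str = "top_third") -> PhenotypeLabels:
    """Split samples into high (1) vs low (0) by a top-fraction rule.

    Boundary ties are broken by ascending sample id after score, so the
    assignment is deterministic across reruns.
    """
    if rule not in _RULE_HIGH:
        raise ValueError(f"unknown dichotomization rule {rule!r}")
    n = len(scores)
    if n < 6:
        raise ValidationError(f"need >=6 samples to dichotomize, got {n}")
    if scores.nunique() == 1:
        raise ValidationError("all scores identical: no informative split")
    n_high = _RULE_HIGH[rule](n)
    order = sorted(scores.index, key=lambda s: (-scores[s], str(s)))
    high = order[:n_high]
    labels = pd.Series(0, index=scores.index, dtype=int)
    labels.loc[high] = 1
    boundary = float(scores[high[-1]])
    return PhenotypeLabels(labels=labels, rule=rule, boundary=boundary, n_high=n_high)
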