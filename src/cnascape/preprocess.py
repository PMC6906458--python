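"""Expression normalization and copy-number feature construction.

Expression flows through a fixed pipeline — upper-quartile scaling with a
log2 transform, an expressed-fraction filter, per-gene median centering and
per-sample standardization — with each stage recorded as a state flag so the
order cannot silently be violated.

Gene-level copy number is derived from CBS-style segmentation by the
*extreme* method: a gene fully inside one segment takes that segment's
value; a gene overlapping several segments takes the overlapped value of
largest magnitude (the most extreme gain or loss); a gene covered by no
segment is missing.  Segment-level features are means of member-gene values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import (
    DEFAULT_VARIANT_CLASSES,
    GeneCoords,
    MafTable,
    SegmentDefinitionTable,
    SegmentationTable,
)

logger = logging.getLogger(__name__)

FLAG_UQ_LOG2 = "uq_log2"
FLAG_FILTERED = "filtered"
FLAG_MEDIAN_CENTERED = "median_centered"
FLAG_SAMPLE_STANDARDIZED = "sample_standardized"


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples expression matrix plus normalization-state flags."""

    values: pd.DataFrame
    flags: frozenset = frozenset()

    def with_flag(self, flag: str, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, flags=self.flags | {flag})

    def has(self, flag: str) -> bool:
        return flag in self.flags


def as_expression(x: "ExpressionMatrix | pd.DataFrame") -> ExpressionMatrix:
    if isinstance(x, ExpressionMatrix):
        return x
    return ExpressionMatrix(values=x)


def as_frame(x: "ExpressionMatrix | pd.DataFrame") -> pd.DataFrame:
    return x.values if isinstance(x, ExpressionMatrix) else x


# ---------------------------------------------------------------------------
# Normalization pipeline
# ---------------------------------------------------------------------------


def upper_quartile_log2(
    counts: "ExpressionMatrix | pd.DataFrame", scale: float = 1000.0
) -> ExpressionMatrix:
    """Upper-quartile normalize each sample, then log2(x + 1).

    Each sample is rescaled so the 75th percentile of its *positive* values
    equals ``scale``; the transform is invariant to per-sample library size.
    """
    x = as_expression(counts)
    for flag in (FLAG_UQ_LOG2, FLAG_MEDIAN_CENTERED, FLAG_SAMPLE_STANDARDIZED):
        if x.has(flag):
            raise ValidationError(f"upper_quartile_log2 requires raw counts, got {flag}")
    df = x.values
    if (df.values < 0).any():
        raise ValidationError("upper_quartile_log2 requires non-negative counts")
    out = df.copy().astype(float)
    for col in df.columns:
        pos = df[col][df[col] > 0]
        if pos.empty:
            raise ValidationError(f"sample {col!r} has all-zero counts")
        uq = float(np.percentile(pos.values, 75))
        out[col] = df[col] / uq * scale
    out = np.log2(out + 1.0)
    return x.with_flag(FLAG_UQ_LOG2, out)


def filter_expressed(
    x: "ExpressionMatrix | pd.DataFrame",
    fraction: float = 0.7,
    expressed: str = "positive",
) -> ExpressionMatrix:
    """Keep genes expressed in strictly more than ``fraction`` of samples.

    ``expressed="positive"`` counts values > 0 (count-like data);
    ``expressed="nonmissing"`` counts non-missing values (array-like data).
    """
    xm = as_expression(x)
    for flag in (FLAG_MEDIAN_CENTERED, FLAG_SAMPLE_STANDARDIZED):
        if xm.has(flag):
            raise ValidationError("filter_expressed must precede centering/standardization")
    df = xm.values
    if expressed == "positive":
        frac = (df > 0).sum(axis=1) / df.shape[1]
    elif expressed == "nonmissing":
        frac = df.notna().sum(axis=1) / df.shape[1]
    else:
        raise ValueError(f"unknown expressed rule {expressed!r}")
    kept = df.loc[frac > fraction]
    return xm.with_flag(FLAG_FILTERED, kept)


def median_center_genes(x: "ExpressionMatrix | pd.DataFrame") -> ExpressionMatrix:
    """Subtract each gene's median across samples."""
    xm = as_expression(x)
    if xm.has(FLAG_SAMPLE_STANDARDIZED):
        raise ValidationError("median centering must precede sample standardization")
    df = xm.values
    if df.isna().any().any():
        raise ValidationError("median_center_genes requires a complete matrix")
    out = df.sub(df.median(axis=1), axis=0)
    return xm.with_flag(FLAG_MEDIAN_CENTERED, out)


def standardize_samples(x: "ExpressionMatrix | pd.DataFrame") -> ExpressionMatrix:
    """Center and scale each sample (column) to mean 0, sd 1."""
    xm = as_expression(x)
    df = xm.values
    if df.isna().any().any():
        raise ValidationError("standardize_samples requires a complete matrix")
    sd = df.std(axis=0, ddof=1)
    if (sd <= 0).any() or sd.isna().any():
        bad = sd.index[(sd <= 0) | sd.isna()][0]
        raise ValidationError(f"sample {bad!r} has zero variance")
    out = df.sub(df.mean(axis=0), axis=1).div(sd, axis=1)
    return xm.with_flag(FLAG_SAMPLE_STANDARDIZED, out)


def normalize_expression(
    counts: "ExpressionMatrix | pd.DataFrame",
    scale: float = 1000.0,
    fraction: float = 0.7,
    from_counts: bool = True,
) -> ExpressionMatrix:
    """Run the full fixed-order pipeline: UQ+log2 -> filter -> center -> standardize."""
    x = as_expression(counts)
    if from_counts:
        x = upper_quartile_log2(x, scale=scale)
    x = filter_expressed(x, fraction=fraction)
    x = median_center_genes(x)
    return standardize_samples(x)


# ---------------------------------------------------------------------------
# Gene-level CNA by the extreme method
# ---------------------------------------------------------------------------


def _extreme(values: np.ndarray) -> float:
    hi = values.max()
    lo = values.min()
    # equal magnitudes, opposite signs: prefer the amplification
    return float(hi) if abs(hi) >= abs(lo) else float(lo)


def gene_cna_extreme(seg: SegmentationTable, coords: GeneCoords) -> pd.DataFrame:
    """Gene-level copy number from segmentation by the extreme method.

    Returns a genes x samples DataFrame; genes with no overlapping segment
    in a sample are NaN for that sample.
    """
    genes = coords.df.reset_index(drop=True)
    samples = seg.samples
    out = np.full((len(genes), len(samples)), np.nan)
    gene_pos = {c: grp for c, grp in genes.groupby("chrom", sort=False)}
    col_of = {s: j for j, s in enumerate(samples)}
    n_ties = 0
    for (sample, chrom), cseg in seg.df.groupby(["sample", "chrom"], sort=False):
        gdf = gene_pos.get(chrom)
        if gdf is None:
            continue
        j = col_of[sample]
        cseg = cseg.sort_values("start")
        s = cseg["start"].to_numpy()
        e = cseg["end"].to_numpy()
        v = cseg["value"].to_numpy()
        g_start = gdf["start"].to_numpy()
        g_end = gdf["end"].to_numpy()
        rows = gdf.index.to_numpy()
        # segments sorted & disjoint: overlapping run is [lo, hi]
        lo = np.searchsorted(e, g_start, side="right")
        hi = np.searchsorted(s, g_end, side="left") - 1
        single = lo == hi
        out[rows[single], j] = v[lo[single]]
        for k in np.flatnonzero(lo < hi):
            vals = v[lo[k] : hi[k] + 1]
            if abs(vals.max()) == abs(vals.min()) and vals.max() != vals.min():
                n_ties += 1
            out[rows[k], j] = _extreme(vals)
    if n_ties:
        logger.info("extreme method: %d gain/loss magnitude ties resolved to the gain", n_ties)
    return pd.DataFrame(out, index=genes["gene"].to_numpy(), columns=samples)


def segment_scores(
    gene_cna: pd.DataFrame, defs: SegmentDefinitionTable
) -> pd.DataFrame:
    """Segment-level CNA features: mean of non-missing member-gene values."""
    rows = {}
    for seg_id, members in defs.members.items():
        present = [g for g in members if g in gene_cna.index]
        if len(present) < len(members):
            logger.warning(
                "segment %s: %d/%d member genes missing from CNA matrix",
                seg_id,
                len(members) - len(present),
                len(members),
            )
        if not present:
            rows[seg_id] = pd.Series(np.nan, index=gene_cna.columns)
            continue
        rows[seg_id] = gene_cna.loc[present].mean(axis=0, skipna=True)
    return pd.DataFrame(rows).T.reindex(list(defs.members))


def restrict_panel(gene_cna: pd.DataFrame, panel: Iterable[str]) -> pd.DataFrame:
    """Restrict a gene-level CNA matrix to a gene panel (e.g. a clinical assay)."""
    panel = set(panel)
    if not panel:
        raise ValidationError("empty gene panel")
    keep = [g for g in gene_cna.index if g in panel]
    if not keep:
        raise ValidationError("gene panel is disjoint from the CNA matrix")
    return gene_cna.loc[keep]


# ---------------------------------------------------------------------------
# Mutation matrices
# ---------------------------------------------------------------------------


def mutation_matrix(
    maf: MafTable,
    allowed_classes: Iterable[str] = DEFAULT_VARIANT_CLASSES,
    samples: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Binary gene x sample mutation matrix plus per-sample mutation load.

    Records are filtered to ``allowed_classes``; a gene/sample cell is 1 if
    any retained record exists.  Mutation load is the number of mutated
    genes per sample (column sums).
    """
    allowed = set(allowed_classes)
    df = maf.df
    kept = df[df["variant_class"].isin(allowed)]
    all_samples = list(samples) if samples is not None else sorted(df["sample"].unique())
    genes = sorted(kept["gene"].unique())
    mat = pd.DataFrame(0, index=genes, columns=all_samples, dtype=int)
    for gene, sample in zip(kept["gene"], kept["sample"]):
        if sample in mat.columns:
            mat.loc[gene, sample] = 1
    load = mat.sum(axis=0)
    load.name = "mutation_load"
    return mat, load


def filter_mutation_genes(
    matrix: pd.DataFrame,
    min_freq: float = 0.05,
    keep_list: Iterable[str] = (),
    drop_prefixes: Iterable[str] = ("IGH", "HLA"),
) -> pd.DataFrame:
    """Keep genes mutated in strictly more than ``min_freq`` of samples.

    Genes in ``keep_list`` bypass the frequency rule; genes whose symbol
    starts with any of ``drop_prefixes`` are always removed.
    """
    keep_set = set(keep_list)
    prefixes = tuple(drop_prefixes)
    freq = matrix.mean(axis=1)
    selected = [
        g
        for g in matrix.index
        if not str(g).startswith(prefixes) and (freq[g] > min_freq or g in keep_set)
    ]
    return matrix.loc[selected]
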