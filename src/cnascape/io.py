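"""Readers and writers for the external formats the pipeline touches.

All genomic text formats (SEG, BED-like gene tables) are 1-based inclusive
on disk and converted to 0-based half-open coordinates in memory; writers
convert back, so reader/writer pairs are lossless round trips. Chromosome
labels are accepted with or without a ``chr`` prefix and stored without it.
Missing values are encoded as ``NA`` in every TSV dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

NA_REP = "NA"

#: Variant classifications retained when building mutation matrices.
DEFAULT_VARIANT_CLASSES = frozenset(
    {
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "RNA",
        "Splice_Site",
        "Translation_Start_Site",
    }
)


def normalize_chrom(label: str) -> str:
    """Strip an optional ``chr`` prefix from a chromosome label."""
    label = str(label).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    if not label:
        raise ValidationError("empty chromosome label")
    return label


def _check_genome(chroms: pd.Series, genome: Mapping[str, int] | None, what: str) -> None:
    if genome is None:
        return
    known = {normalize_chrom(c) for c in genome}
    bad = sorted(set(chroms) - known)
    if bad:
        raise ValidationError(f"{what}: chromosome(s) {bad} not in genome dictionary")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SegmentationTable:
    """CBS-style copy-number segmentation.

    ``df`` columns: sample, chrom, start, end (0-based half-open), value.
    Per-sample segments on a chromosome must not overlap.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample", "chrom", "start", "end", "value"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"SegmentationTable missing columns {missing}")
        df = self.df
        if (df["start"] >= df["end"]).any():
            row = df[df["start"] >= df["end"]].iloc[0]
            raise ValidationError(
                f"segment with start >= end for sample {row['sample']} "
                f"on chrom {row['chrom']}"
            )
        # overlap check within each (sample, chrom)
        s = df.sort_values(["sample", "chrom", "start"], kind="mergesort")
        same = (s["sample"].values[1:] == s["sample"].values[:-1]) & (
            s["chrom"].values[1:] == s["chrom"].values[:-1]
        )
        overlap = same & (s["start"].values[1:] < s["end"].values[:-1])
        if overlap.any():
            i = int(np.flatnonzero(overlap)[0])
            raise ValidationError(
                "overlapping segments for sample "
                f"{s['sample'].values[i + 1]} on chrom {s['chrom'].values[i + 1]}"
            )

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())


@dataclass
class GeneCoords:
    """Gene coordinates: gene, chrom, start, end (0-based half-open), strand."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene", "chrom", "start", "end"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"GeneCoords missing columns {missing}")
        if self.df["gene"].duplicated().any():
            dup = self.df["gene"][self.df["gene"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate gene id {dup!r} in gene coordinates")
        if (self.df["start"] >= self.df["end"]).any():
            g = self.df[self.df["start"] >= self.df["end"]]["gene"].iloc[0]
            raise ValidationError(f"gene {g!r} has start >= end")
        if "strand" not in self.df.columns:
            self.df = self.df.assign(strand=".")

    @property
    def genes(self) -> list[str]:
        return list(self.df["gene"])


@dataclass
class SignatureDefinition:
    """A gene-expression signature and how it is scored.

    ``method="median"`` scores a sample as the median expression of
    ``genes``.  ``method="centroid"`` scores a sample as its similarity
    (``metric``) to the ``target_class`` column of ``centroids``
    (genes x classes).
    """

    name: str
    method: str = "median"
    genes: list[str] = field(default_factory=list)
    description: str = ""
    centroids: pd.DataFrame | None = None
    metric: str = "pearson"
    target_class: str | None = None

    def __post_init__(self) -> None:
        if self.method not in {"median", "centroid"}:
            raise ValidationError(f"unknown signature method {self.method!r}")
        if self.method == "median" and not self.genes:
            raise ValidationError(f"signature {self.name!r} has an empty gene list")
        if self.method == "centroid":
            if self.centroids is None or self.centroids.shape[1] < 1:
                raise ValidationError(
                    f"centroid signature {self.name!r} needs a centroid matrix with >=1 class"
                )
            if self.metric not in {"pearson", "spearman", "euclidean"}:
                raise ValidationError(f"unknown centroid metric {self.metric!r}")
            if self.target_class is None:
                self.target_class = str(self.centroids.columns[0])


@dataclass
class SegmentDefinitionTable:
    """Predefined CNA segments: segment id -> ordered member gene ids."""

    members: dict[str, list[str]]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for seg, genes in self.members.items():
            if not genes:
                raise ValidationError(f"segment {seg!r} has no member genes")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"segment {seg!r} has duplicate member genes")

    @property
    def segment_ids(self) -> list[str]:
        return list(self.members)


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates, indexed by sample id."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.duplicated().any():
            dup = self.df.index[self.df.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r} in clinical table")

    @property
    def samples(self) -> list[str]:
        return list(self.df.index)


@dataclass
class MafTable:
    """Somatic mutation records: gene, sample, variant_class."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene", "sample", "variant_class"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"MafTable missing columns {missing}")
        vc = self.df["variant_class"].astype(str)
        if (vc.str.strip() == "").any():
            raise ValidationError("empty variant classification token in MAF")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column gene ids, header sample ids)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_REP], keep_default_na=False)
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate gene id {dup!r}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            gene = bad.index[0] if len(bad) else "?"
            raise ParseError(f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}")
    df.index.name = "gene"
    return df.astype(float)


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", na_rep=NA_REP, float_format="%.10g")


# ---------------------------------------------------------------------------
# SEG
# ---------------------------------------------------------------------------

_SEG_COLS = {"sample", "chromosome", "start", "end", "segment_mean"}


def read_seg(path: str | Path, genome: Mapping[str, int] | None = None) -> SegmentationTable:
    """Read a tab-separated SEG file (1-based inclusive coordinates)."""
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = {c.lower(): c for c in raw.columns}
    needed = {
        "sample": cols.get("sample") or cols.get("id"),
        "chromosome": cols.get("chromosome") or cols.get("chrom"),
        "start": cols.get("start"),
        "end": cols.get("end"),
        "segment_mean": cols.get("segment_mean") or cols.get("seg.mean"),
    }
    missing = [k for k, v in needed.items() if v is None]
    if missing:
        raise ParseError(f"{path}: missing SEG column(s) {missing}")
    try:
        start1 = raw[needed["start"]].astype(int)
        end1 = raw[needed["end"]].astype(int)
        value = raw[needed["segment_mean"]].astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric SEG coordinate or value ({exc})") from exc
    if (start1 > end1).any():
        i = int(np.flatnonzero(start1 > end1)[0])
        raise ValidationError(
            f"{path}: segment start > end at data row {i + 1} "
            f"(sample {raw[needed['sample']].iloc[i]!r})"
        )
    df = pd.DataFrame(
        {
            "sample": raw[needed["sample"]].astype(str),
            "chrom": raw[needed["chromosome"]].map(normalize_chrom),
            "start": start1 - 1,  # to 0-based half-open
            "end": end1,
            "value": value,
        }
    )
    _check_genome(df["chrom"], genome, str(path))
    return SegmentationTable(df)


def write_seg(table: SegmentationTable, path: str | Path) -> None:
    df = table.df
    out = pd.DataFrame(
        {
            "Sample": df["sample"],
            "Chromosome": df["chrom"],
            "Start": df["start"] + 1,  # back to 1-based inclusive
            "End": df["end"],
            "Segment_Mean": df["value"].map(lambda v: format(v, ".10g")),
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> list[SignatureDefinition]:
    """Read a GMT file: one median-method signature per line."""
    sigs: list[SignatureDefinition] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ParseError(f"{path}:{lineno}: signature {name!r} has no genes")
            sigs.append(SignatureDefinition(name=name, description=desc, genes=genes))
    return sigs


def write_gmt(signatures: Sequence[SignatureDefinition], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            if sig.method != "median":
                raise ValidationError(f"GMT can only hold gene-list signatures, not {sig.method!r}")
            fh.write("\t".join([sig.name, sig.description, *sig.genes]) + "\n")


def read_centroids(path: str | Path) -> pd.DataFrame:
    """Read a centroid table (genes x classes TSV)."""
    return read_expression_matrix(path)


# ---------------------------------------------------------------------------
# Gene coordinates (BED-like, but 1-based inclusive as emitted here)
# ---------------------------------------------------------------------------


def read_gene_coords(path: str | Path, genome: Mapping[str, int] | None = None) -> GeneCoords:
    """Read a 4/5-column gene table: chrom, start, end, gene[, strand]."""
    raw = pd.read_csv(
        path,
        sep="\t",
        header=None,
        dtype=str,
        keep_default_na=False,
        comment="#",
    )
    if raw.shape[1] < 4:
        raise ParseError(f"{path}: gene table needs >=4 columns (chrom start end gene)")
    try:
        start1 = raw[1].astype(int)
        end1 = raw[2].astype(int)
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer gene coordinate ({exc})") from exc
    df = pd.DataFrame(
        {
            "gene": raw[3].astype(str),
            "chrom": raw[0].map(normalize_chrom),
            "start": start1 - 1,
            "end": end1,
            "strand": raw[4].astype(str) if raw.shape[1] > 4 else ".",
        }
    )
    _check_genome(df["chrom"], genome, str(path))
    return GeneCoords(df)


def write_gene_coords(coords: GeneCoords, path: str | Path) -> None:
    df = coords.df
    out = pd.DataFrame(
        {
            0: df["chrom"],
            1: df["start"] + 1,
            2: df["end"],
            3: df["gene"],
            4: df["strand"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# Segment definitions (segment -> member genes)
# ---------------------------------------------------------------------------


def read_segment_definitions(path: str | Path) -> SegmentDefinitionTable:
    """Read a segment membership TSV: segment_id <tab> label <tab> gene1,gene2,..."""
    members: dict[str, list[str]] = {}
    labels: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("segment_id"):
            raise ParseError(f"{path}: expected header starting with 'segment_id'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 tab-separated fields")
            seg, label, genes_csv = fields
            if seg in members:
                raise ValidationError(f"{path}:{lineno}: duplicate segment id {seg!r}")
            genes = [g for g in genes_csv.split(",") if g]
            members[seg] = genes
            labels[seg] = label
    return SegmentDefinitionTable(members=members, labels=labels)


def write_segment_definitions(defs: SegmentDefinitionTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("segment_id\tlabel\tgenes\n")
        for seg, genes in defs.members.items():
            fh.write(f"{seg}\t{defs.labels.get(seg, '')}\t{','.join(genes)}\n")


# ---------------------------------------------------------------------------
# Clinical
# ---------------------------------------------------------------------------


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[NA_REP], keep_default_na=False
    )
    df.index = df.index.astype(str)
    df.index.name = "sample"
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    out = table.df.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t", na_rep=NA_REP)


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

_MAF_REQUIRED = ["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"]


def read_maf(path: str | Path) -> MafTable:
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    missing = [c for c in _MAF_REQUIRED if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: missing MAF column(s) {missing}")
    df = pd.DataFrame(
        {
            "gene": raw["Hugo_Symbol"].astype(str),
            "sample": raw["Tumor_Sample_Barcode"].astype(str),
            "variant_class": raw["Variant_Classification"].astype(str),
        }
    )
    return MafTable(df)


def write_maf(maf: MafTable, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "Hugo_Symbol": maf.df["gene"],
            "Tumor_Sample_Barcode": maf.df["sample"],
            "Variant_Classification": maf.df["variant_class"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Generic matrix TSV (scores, CNA matrices, ...)
# ---------------------------------------------------------------------------


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Alias for :func:`read_expression_matrix`; any row x column numeric TSV."""
    return read_expression_matrix(path)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    write_expression_matrix(df, path)
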